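"""From annotated behaviour events to labelled 3 s training windows.

Video-annotation event tables run on the camera clock, which in real
deployments lags the collar clock by one to a few minutes; events must be
shifted onto the accelerometer clock before labelling. Events outside the
four-category ethogram (rare behaviours such as playing or swimming) are
dropped, and windows are tiled *within* each event so that no training window
ever straddles a behaviour transition.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .ethogram import BEHAVIORS, EXCLUDED_RARE, canonical
from .features import (
    FEATURE_NAMES,
    dynamic_body_acceleration,
    odba,
    static_acceleration,
    summarize_window,
)

logger = logging.getLogger(__name__)


def clean_events(
    events: pd.DataFrame,
    ethogram: frozenset[str] | set[str] = BEHAVIORS,
    excluded: tuple[str, ...] = EXCLUDED_RARE,
) -> pd.DataFrame:
    """Keep ethogram behaviours, drop rare/unknown ones, canonicalize labels.

    Labels are matched case- and whitespace-insensitively. Behaviours on the
    exclusion list are silently dropped; labels in neither set are dropped
    with a warning naming them.
    """
    if events.empty:
        return events.copy()
    canon = events["behavior"].map(canonical)
    keep = canon.isin(ethogram)
    known_excluded = canon.isin(set(excluded))
    unknown = sorted(set(canon[~keep & ~known_excluded]))
    if unknown:
        logger.warning("dropping events with unknown behaviour labels: %s", unknown)
    if not keep.any():
        logger.warning("no events left after exclusion filtering")
    out = events.loc[keep].copy()
    out["behavior"] = canon[keep]
    return out.reset_index(drop=True)


def apply_clock_lag(events: pd.DataFrame, lag_s: float) -> pd.DataFrame:
    """Shift event start/end times by +lag_s seconds onto the collar clock."""
    if not np.isfinite(lag_s):
        raise ValueError("lag_s must be finite")
    out = events.copy()
    shift = pd.to_timedelta(lag_s, unit="s")
    out["start"] = pd.to_datetime(out["start"]) + shift
    out["end"] = pd.to_datetime(out["end"]) + shift
    return out


def estimate_clock_lag(
    events: pd.DataFrame,
    series: pd.DataFrame,
    search_range_s: tuple[float, float] = (0.0, 200.0),
    step_s: float = 1.0,
) -> float:
    """Estimate the annotation-vs-collar clock lag by ODBA correlation.

    The returned lag is the number of seconds the annotation (video) clock
    runs *ahead* of the collar clock; ``apply_clock_lag(events, -lag)`` puts
    the events onto the collar clock. Builds a per-second binary activity
    signal from the events (active = any non-resting behaviour) and the
    per-second mean ODBA from the stream, then scans candidate lags over
    ``search_range_s``, shifting the events back by each candidate, and
    returns the lag whose shifted annotation signal correlates best with
    ODBA (ties broken toward the smallest lag). Automates the visual
    transition-alignment step of manual workflows.

    The events must contain both active and inactive behaviours, otherwise
    the objective is flat and the lag is unidentifiable.
    """
    lo, hi = search_range_s
    lags = np.arange(lo, hi + step_s / 2, step_s)
    if lags.size == 0:
        raise ValueError("empty lag search range")
    active = set(pd.unique(events["behavior"].map(canonical))) - {"resting"}
    has_active = len(active) > 0
    has_inactive = (events["behavior"].map(canonical) == "resting").any()
    if not (has_active and has_inactive):
        raise ValueError("lag estimation needs both active and inactive behaviours")

    raw = series[["acc_x", "acc_y", "acc_z"]].to_numpy(dtype=float)
    dba = dynamic_body_acceleration(raw, static_acceleration(raw))
    t = pd.to_datetime(series["timestamp"])
    sec = t.dt.floor("s")
    odba_per_s = pd.Series(odba(dba), index=sec).groupby(level=0).mean()

    ev_start = pd.to_datetime(events["start"])
    ev_end = pd.to_datetime(events["end"])
    ev_active = (events["behavior"].map(canonical) != "resting").to_numpy()

    best_lag, best_r = None, -np.inf
    sec_index = odba_per_s.index
    for lag in lags:
        shift = pd.to_timedelta(-float(lag), unit="s")
        flag = pd.Series(np.nan, index=sec_index)
        for s0, e0, act in zip(ev_start, ev_end, ev_active):
            mask = (sec_index >= (s0 + shift).floor("s")) & (sec_index < (e0 + shift).floor("s"))
            flag[mask] = 1.0 if act else 0.0
        ok = flag.notna()
        if ok.sum() < 3 or flag[ok].nunique() < 2:
            continue
        r = float(np.corrcoef(flag[ok], odba_per_s[ok])[0, 1])
        if r > best_r + 1e-12:
            best_r, best_lag = r, float(lag)
    if best_lag is None:
        raise ValueError("lag objective undefined over the whole search range")
    return best_lag


def build_training_windows(
    events: pd.DataFrame,
    series: pd.DataFrame,
    window_s: float = 3.0,
    fs: float = 8.0,
) -> pd.DataFrame:
    """Labelled feature table of 3 s windows fully contained in single events.

    Windows are tiled from each event's start; a trailing remainder shorter
    than ``window_s`` is discarded, so behaviour transitions are excluded by
    construction. Events shorter than one window contribute nothing. The
    static/DBA chain is computed once on the continuous stream, so window
    edges use neighbouring samples. Per-label window counts are logged.

    Events must already be on the accelerometer clock (see
    :func:`apply_clock_lag` / :func:`estimate_clock_lag`).
    """
    n_expected = int(round(window_s * fs))
    series = series.sort_values("timestamp", kind="stable").reset_index(drop=True)
    raw = series[["acc_x", "acc_y", "acc_z"]].to_numpy(dtype=float)
    t = pd.to_datetime(series["timestamp"]).to_numpy()
    static = static_acceleration(raw, span_s=window_s, fs=fs)
    dba = dynamic_body_acceleration(raw, static)
    win_td = np.timedelta64(int(round(window_s * 1e9)), "ns")
    max_gap = np.timedelta64(int(round(1.01e9 / fs)), "ns")

    rows = []
    for ev in events.itertuples(index=False):
        label = canonical(ev.behavior)
        if label not in BEHAVIORS:
            raise ValueError(f"event label {ev.behavior!r} outside the ethogram")
        start = np.datetime64(pd.Timestamp(ev.start))
        end = np.datetime64(pd.Timestamp(ev.end))
        n_win = int((end - start) / win_td)
        for k in range(n_win):
            ws = start + k * win_td
            lo = int(np.searchsorted(t, ws, side="left"))
            hi = int(np.searchsorted(t, ws + win_td, side="left"))
            if hi - lo != n_expected:
                continue
            if n_expected > 1 and (np.diff(t[lo:hi]) > max_gap).any():
                continue
            feats = summarize_window(raw[lo:hi], dba[lo:hi], fs=fs)
            rows.append({"window_start": pd.Timestamp(ws), "label": label, **feats})
    out = pd.DataFrame(rows, columns=["window_start", "label", *FEATURE_NAMES])
    counts = out["label"].value_counts().to_dict() if not out.empty else {}
    logger.info("built %d training windows: %s", len(out), counts)
    return out
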