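"""Windowing of raw tri-axial accelerometry and per-window summary features.

The raw 8 Hz stream (axes: x = sway, y = surge, z = heave, in g) is cut into
consecutive non-overlapping 3 s windows of 24 samples. Each complete window is
summarized by 36 statistics over eight initial signal channels: the three raw
axes, their dynamic body acceleration (DBA = raw minus a 3 s running-mean
"static" component), the overall dynamic body acceleration
(ODBA = |DBAx| + |DBAy| + |DBAz|) and the vector magnitude
sqrt(x^2 + y^2 + z^2).

Conventions fixed here so results are exactly reproducible:

* The running mean for static acceleration is a centred 24-sample window
  (12 samples before the current one, the current one, 11 after), truncated
  symmetrically at recording edges, and is computed on the continuous stream
  *before* windowing, so window edges borrow neighbouring samples.
* Standard deviation is the sample convention (ddof = 1), matching R's ``sd``;
  Pearson correlations are computed on the raw axes.
* Skewness and kurtosis are plain population moment ratios
  (m3 / m2^1.5 and m4 / m2^2, no bias correction, kurtosis not excess);
  zero-variance channels report 0 for correlation, skewness and kurtosis so
  that exactly constant resting windows remain classifiable.
* The dominant power spectrum is the maximum of the one-sided, mean-removed,
  boxcar periodogram (density scaling) over strictly positive frequencies; a
  24-sample window at 8 Hz gives 1/3 Hz resolution. A constant channel
  returns 0.

Incomplete windows (missing samples or timestamp gaps) are flagged and
excluded from feature computation, never padded.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.signal import periodogram

#: Standard gravity, for the optional m/s^2 -> g conversion.
STANDARD_GRAVITY = 9.80665

_AXES = ("x", "y", "z")
_CHANNELS = ("x", "y", "z", "mag")

#: The 36 feature names, in the fixed column order of every feature table.
FEATURE_NAMES: tuple[str, ...] = tuple(
    [f"{stat}_{ch}" for stat in ("mean", "std", "max", "min", "kurt", "skew") for ch in _CHANNELS]
    + ["cor_xy", "cor_xz", "cor_yz"]
    + [f"mean_dba_{ax}" for ax in _AXES]
    + ["odba_total", "odba_mean"]
    + [f"dps_{ch}" for ch in _CHANNELS]
)


def _as_xyz(series: pd.DataFrame) -> np.ndarray:
    """(n, 3) float array of the acceleration columns."""
    return series[["acc_x", "acc_y", "acc_z"]].to_numpy(dtype=float)


def partition_windows(
    series: pd.DataFrame, window_s: float = 3.0, fs: float = 8.0
) -> pd.DataFrame:
    """Cut a time-sorted accelerometry stream into consecutive 3 s windows.

    Windows are anchored at the first sample: window k spans
    ``[t0 + k*window_s, t0 + (k+1)*window_s)``. A window is *complete* when it
    holds exactly ``window_s * fs`` samples and no intra-window sampling gap
    exceeds the nominal interval by more than 1%.

    Parameters
    ----------
    series
        Columns ``timestamp`` (datetime64), ``acc_x``, ``acc_y``, ``acc_z``.
    window_s, fs
        Window length in seconds and sampling rate in Hz.

    Returns
    -------
    DataFrame with one row per window: ``window_idx``, ``start``,
    ``n_samples``, ``complete``, plus ``sample_lo``/``sample_hi`` positional
    slices into the (sorted) input.
    """
    n_expected = int(round(window_s * fs))
    if series.empty:
        return pd.DataFrame(
            columns=["window_idx", "start", "n_samples", "complete", "sample_lo", "sample_hi"]
        )
    t = pd.to_datetime(series["timestamp"]).to_numpy()
    if len(t) > 1 and (np.diff(t) < np.timedelta64(0, "ns")).any():
        raise ValueError("series must be sorted by timestamp")
    t0 = t[0]
    rel_s = (t - t0) / np.timedelta64(1, "s")
    widx = np.floor(rel_s / window_s + 1e-9).astype(np.int64)
    max_gap = 1.01 / fs

    rows = []
    # samples are sorted, so each window is a contiguous slice
    bounds = np.flatnonzero(np.diff(widx)) + 1
    starts = np.concatenate([[0], bounds])
    stops = np.concatenate([bounds, [len(t)]])
    for lo, hi in zip(starts, stops):
        k = int(widx[lo])
        n = hi - lo
        complete = n == n_expected
        if complete and n > 1:
            gaps = np.diff(rel_s[lo:hi])
            complete = bool(np.all(gaps <= max_gap))
        rows.append(
            {
                "window_idx": k,
                "start": t0 + np.timedelta64(int(round(k * window_s * 1e9)), "ns"),
                "n_samples": int(n),
                "complete": bool(complete),
                "sample_lo": int(lo),
                "sample_hi": int(hi),
            }
        )
    return pd.DataFrame(rows)


def static_acceleration(
    raw: np.ndarray, span_s: float = 3.0, fs: float = 8.0
) -> np.ndarray:
    """Centred running mean per axis — the gravitational/postural component.

    The span is ``round(span_s * fs)`` samples; for the default 24 the window
    at sample i covers samples ``[i-12, i+11]`` and is truncated at the edges
    of the recording (a single-sample stream is its own static component).
    """
    raw = np.atleast_2d(np.asarray(raw, dtype=float))
    span = int(round(span_s * fs))
    if span < 1:
        raise ValueError(f"span_s * fs must be >= 1 sample, got {span}")
    before = span // 2
    after = span - before - 1
    n = raw.shape[0]
    csum = np.vstack([np.zeros((1, raw.shape[1])), np.cumsum(raw, axis=0)])
    idx = np.arange(n)
    lo = np.maximum(idx - before, 0)
    hi = np.minimum(idx + after + 1, n)
    return (csum[hi] - csum[lo]) / (hi - lo)[:, None]


def dynamic_body_acceleration(raw: np.ndarray, static: np.ndarray) -> np.ndarray:
    """DBA = raw − static, elementwise."""
    raw = np.asarray(raw, dtype=float)
    static = np.asarray(static, dtype=float)
    if raw.shape != static.shape:
        raise ValueError(f"raw shape {raw.shape} != static shape {static.shape}")
    return raw - static


def odba(dba: np.ndarray) -> np.ndarray:
    """Overall dynamic body acceleration: sum of |DBA| over the three axes."""
    return np.abs(np.asarray(dba, dtype=float)).sum(axis=-1)


def magnitude(raw: np.ndarray) -> np.ndarray:
    """Euclidean norm of the tri-axial vector per sample."""
    return np.sqrt((np.asarray(raw, dtype=float) ** 2).sum(axis=-1))


def dominant_power_spectrum(channel: np.ndarray, fs: float = 8.0) -> float:
    """Maximum spectral density of the mean-removed periodogram.

    One-sided boxcar periodogram with density scaling; the DC bin is removed
    together with the mean, so a constant channel returns exactly 0.
    """
    x = np.asarray(channel, dtype=float)
    if x.size < 4:
        raise ValueError(f"need >= 4 samples for a periodogram, got {x.size}")
    if np.ptp(x) == 0:
        return 0.0
    freqs, psd = periodogram(x, fs=fs, window="boxcar", detrend="constant", scaling="density")
    return float(psd[freqs > 0].max())


def _moments(v: np.ndarray) -> tuple[float, float]:
    """(skewness, kurtosis) as population moment ratios; 0 for zero variance."""
    c = v - v.mean()
    m2 = float(np.mean(c**2))
    if m2 == 0.0:
        return 0.0, 0.0
    m3 = float(np.mean(c**3))
    m4 = float(np.mean(c**4))
    return m3 / m2**1.5, m4 / m2**2


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(ddof=0), b.std(ddof=0)
    if sa == 0.0 or sb == 0.0:
        return 0.0
    r = float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))
    return min(1.0, max(-1.0, r))


def summarize_window(raw: np.ndarray, dba: np.ndarray, fs: float = 8.0) -> dict[str, float]:
    """The 36 summary statistics of one complete window.

    Parameters
    ----------
    raw
        (n, 3) raw acceleration of the window, in g.
    dba
        (n, 3) dynamic body acceleration of the same samples, taken from the
        static/DBA chain computed on the continuous stream.
    """
    raw = np.asarray(raw, dtype=float)
    dba = np.asarray(dba, dtype=float)
    if raw.shape != dba.shape:
        raise ValueError("raw and dba must be aligned")
    mag = magnitude(raw)
    channels = {"x": raw[:, 0], "y": raw[:, 1], "z": raw[:, 2], "mag": mag}
    out: dict[str, float] = {}
    for ch, v in channels.items():
        out[f"mean_{ch}"] = float(v.mean())
        out[f"std_{ch}"] = float(v.std(ddof=1)) if v.size > 1 else 0.0
        out[f"max_{ch}"] = float(v.max())
        out[f"min_{ch}"] = float(v.min())
        out[f"skew_{ch}"], out[f"kurt_{ch}"] = _moments(v)
    out["cor_xy"] = _pearson(raw[:, 0], raw[:, 1])
    out["cor_xz"] = _pearson(raw[:, 0], raw[:, 2])
    out["cor_yz"] = _pearson(raw[:, 1], raw[:, 2])
    for i, ax in enumerate(_AXES):
        out[f"mean_dba_{ax}"] = float(dba[:, i].mean())
    od = odba(dba)
    out["odba_total"] = float(od.sum())
    out["odba_mean"] = float(od.mean())
    for ch, v in channels.items():
        out[f"dps_{ch}"] = dominant_power_spectrum(v, fs=fs)
    return {name: out[name] for name in FEATURE_NAMES}


def featurize(
    series: pd.DataFrame,
    fs: float = 8.0,
    window_s: float = 3.0,
    bear_id: str | None = None,
    from_ms2: bool = False,
) -> pd.DataFrame:
    """Feature table of one accelerometry stream: one row per complete window.

    Columns: ``bear_id`` (if given), ``window_start``, then the 36 features in
    :data:`FEATURE_NAMES` order. Incomplete windows are dropped.

    Set ``from_ms2=True`` if the stream is recorded in m/s^2 rather than g.
    """
    series = series.sort_values("timestamp", kind="stable").reset_index(drop=True)
    raw = _as_xyz(series)
    if from_ms2:
        raw = raw / STANDARD_GRAVITY
    windows = partition_windows(series, window_s=window_s, fs=fs)
    if windows.empty:
        cols = (["bear_id"] if bear_id is not None else []) + ["window_start"] + list(FEATURE_NAMES)
        return pd.DataFrame(columns=cols)
    static = static_acceleration(raw, span_s=window_s, fs=fs)
    dba = dynamic_body_acceleration(raw, static)
    rows = []
    for w in windows.itertuples(index=False):
        if not w.complete:
            continue
        sl = slice(w.sample_lo, w.sample_hi)
        feats = summarize_window(raw[sl], dba[sl], fs=fs)
        rec = {"window_start": w.start, **feats}
        if bear_id is not None:
            rec = {"bear_id": bear_id, **rec}
        rows.append(rec)
    cols = (["bear_id"] if bear_id is not None else []) + ["window_start"] + list(FEATURE_NAMES)
    return pd.DataFrame(rows, columns=cols)
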