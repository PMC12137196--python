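"""Activity budgets from classified windows: bouts, legal hours, daily metrics.

Downstream of classification, wild-bear analyses work on three response
variables per bear-day: the number of running bouts (maximal runs of
consecutive 3 s windows classified as running), the proportion of those bouts
starting within legal hunting hours (1 h before local sunrise to 2 h before
local sunset), and the daily distance travelled summed over hourly GPS fixes.
Walking and feeding are first merged into a single "feedwalking" state
because slow berry-foraging locomotion confounds the two classes in wild
data.

All timestamps in these tables are local study-area time (UTC+2, naive);
calendar dates therefore break at local midnight. The study month of August
splits into a pre-hunting period (Aug 1-20) and the first days of the
hunting season (Aug 21-31).
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ethogram import FEEDWALKING
from .solar import sunrise_sunset

logger = logging.getLogger(__name__)

DEMOGRAPHIC_GROUPS: tuple[str, ...] = (
    "female_with_offspring",
    "subadult_solitary_female",
    "adult_solitary_female",
    "adult_male",
)


@dataclass(frozen=True)
class StudyCalendar:
    """Period boundaries and site geometry of the study.

    Periods are inclusive date ranges in local time; the defaults are the
    August study window (hunting opens Aug 21). The site centroid fixes the
    solar geometry for legal-hour computation.
    """

    pre_hunting: tuple[dt.date, dt.date] = (dt.date(2019, 8, 1), dt.date(2019, 8, 20))
    hunting: tuple[dt.date, dt.date] = (dt.date(2019, 8, 21), dt.date(2019, 8, 31))
    utc_offset_h: float = 2.0
    site_lat: float = 61.0
    site_lon: float = 15.0

    def __post_init__(self) -> None:
        if self.pre_hunting[1] >= self.hunting[0]:
            raise ValueError("periods must be non-overlapping and ordered")
        if self.hunting[0] - self.pre_hunting[1] != dt.timedelta(days=1):
            raise ValueError("periods must be contiguous")

    def with_year(self, year: int) -> "StudyCalendar":
        """Same calendar transposed to another year."""
        return StudyCalendar(
            tuple(d.replace(year=year) for d in self.pre_hunting),
            tuple(d.replace(year=year) for d in self.hunting),
            self.utc_offset_h,
            self.site_lat,
            self.site_lon,
        )

    def period_of(self, date: dt.date) -> str | None:
        """'pre_hunting', 'hunting', or None outside the study window.

        Month/day comparison, so one calendar serves multi-year data."""
        md = (date.month, date.day)
        if (self.pre_hunting[0].month, self.pre_hunting[0].day) <= md <= (
            self.pre_hunting[1].month,
            self.pre_hunting[1].day,
        ):
            return "pre_hunting"
        if (self.hunting[0].month, self.hunting[0].day) <= md <= (
            self.hunting[1].month,
            self.hunting[1].day,
        ):
            return "hunting"
        return None


def merge_feedwalk(labels: pd.Series) -> pd.Series:
    """Map walking and feeding to the merged 'feedwalking' state."""
    return labels.replace({"walking": FEEDWALKING, "feeding": FEEDWALKING})


def detect_bouts(
    windows: pd.DataFrame,
    behavior: str,
    window_s: float = 3.0,
    max_gap_windows: int = 0,
) -> pd.DataFrame:
    """Maximal runs of consecutive same-behaviour windows, per bear.

    ``windows`` needs columns ``bear_id``, ``window_start`` (time-sorted
    within bear) and ``label``. A bout ends at any window with another label
    or at a recording gap larger than ``max_gap_windows`` missing window
    slots (default: any gap ends the bout). Bout duration counts only the
    observed windows: ``duration_s = n_windows * window_s``.

    Returns a table with bear_id, behavior, start, end, duration_s,
    n_windows.
    """
    rows = []
    gap_tol = pd.to_timedelta((max_gap_windows + 1) * window_s * 1.01, unit="s")
    win_td = pd.to_timedelta(window_s, unit="s")
    for bear, grp in windows.groupby("bear_id", sort=True):
        ts = pd.to_datetime(grp["window_start"]).reset_index(drop=True)
        if not ts.is_monotonic_increasing:
            raise ValueError(f"windows of bear {bear!r} are not time-sorted")
        lab = grp["label"].reset_index(drop=True)
        cur_start = None
        cur_n = 0
        prev_t = None
        for t, l in zip(ts, lab):
            is_target = l == behavior
            contiguous = prev_t is not None and (t - prev_t) <= gap_tol
            if is_target and cur_start is not None and contiguous:
                cur_n += 1
                last_t = t
            elif is_target:
                if cur_start is not None:
                    rows.append((bear, behavior, cur_start, last_t + win_td, cur_n))
                cur_start, cur_n, last_t = t, 1, t
            else:
                if cur_start is not None:
                    rows.append((bear, behavior, cur_start, last_t + win_td, cur_n))
                    cur_start = None
            prev_t = t
        if cur_start is not None:
            rows.append((bear, behavior, cur_start, last_t + win_td, cur_n))
    out = pd.DataFrame(rows, columns=["bear_id", "behavior", "start", "end", "n_windows"])
    out["duration_s"] = out["n_windows"] * window_s
    return out[["bear_id", "behavior", "start", "end", "duration_s", "n_windows"]]


def legal_hours(
    date: dt.date, calendar: StudyCalendar | None = None
) -> tuple[dt.datetime, dt.datetime]:
    """Legal hunting interval of one date: [sunrise − 1 h, sunset − 2 h).

    Local naive datetimes from the NOAA solar routine at the study centroid
    (apparent sunrise/sunset, zenith 90.833°). The interval is half-open:
    a bout starting exactly at sunset − 2 h is outside.
    """
    calendar = StudyCalendar() if calendar is None else calendar
    sunrise, sunset = sunrise_sunset(
        date, calendar.site_lat, calendar.site_lon, calendar.utc_offset_h
    )
    start = sunrise - dt.timedelta(hours=1)
    end = sunset - dt.timedelta(hours=2)
    if end <= start:
        raise ValueError(f"empty legal interval on {date}")
    return start, end


def daily_distance(gps: pd.DataFrame) -> pd.DataFrame:
    """Daily distance travelled: sum of segments between successive fixes.

    Segments count toward a date only when both endpoints fall on it.
    Planar tracks (``x_m``/``y_m``) use Euclidean distance; geographic tracks
    (``lat``/``lon`` in degrees) use great-circle distance on a spherical
    Earth. Days with fewer than two fixes get NaN. Returns bear_id (if
    present), date, daily_distance_m.
    """
    gps = gps.copy()
    gps["timestamp"] = pd.to_datetime(gps["timestamp"])
    has_bear = "bear_id" in gps.columns
    group_cols = ["bear_id"] if has_bear else []
    out = []
    for key, grp in gps.groupby(group_cols, sort=True) if group_cols else [((), gps)]:
        grp = grp.sort_values("timestamp", kind="stable").reset_index(drop=True)
        if {"x_m", "y_m"} <= set(grp.columns):
            xy = grp[["x_m", "y_m"]].to_numpy(dtype=float)
            seg = np.sqrt((np.diff(xy, axis=0) ** 2).sum(axis=1))
        elif {"lat", "lon"} <= set(grp.columns):
            lat = np.radians(grp["lat"].to_numpy(dtype=float))
            lon = np.radians(grp["lon"].to_numpy(dtype=float))
            dlat, dlon = np.diff(lat), np.diff(lon)
            a = np.sin(dlat / 2) ** 2 + np.cos(lat[:-1]) * np.cos(lat[1:]) * np.sin(dlon / 2) ** 2
            seg = 2 * 6371000.0 * np.arcsin(np.sqrt(a))
        else:
            raise ValueError("GPS table needs x_m/y_m or lat/lon columns")
        dates = grp["timestamp"].dt.date.to_numpy()
        same_day = dates[:-1] == dates[1:]
        per_day: dict[dt.date, float] = {}
        fixes_per_day = pd.Series(dates).value_counts()
        for d, n in fixes_per_day.items():
            per_day[d] = 0.0 if n >= 2 else np.nan
        for s, d, keep in zip(seg, dates[:-1], same_day):
            if keep:
                per_day[d] += s
        for d in sorted(per_day):
            rec = {"date": d, "daily_distance_m": per_day[d]}
            if has_bear:
                rec = {"bear_id": key if np.isscalar(key) else key[0], **rec}
            out.append(rec)
    cols = (["bear_id"] if has_bear else []) + ["date", "daily_distance_m"]
    return pd.DataFrame(out, columns=cols)


def daily_metrics(
    bouts: pd.DataFrame,
    labels: pd.DataFrame,
    calendar: StudyCalendar | None = None,
    demographics: pd.DataFrame | None = None,
    gps: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """One record per bear-day: running-bout counts, legal-hour proportion,
    period, demographic group and daily distance.

    Bear-days are every (bear, date) with at least one classified window in
    ``labels``; a day with no running bout gets ``n_running_bouts = 0`` and an
    undefined (NaN) ``prop_legal``. A bout lies within legal hours when its
    *start* timestamp falls in the half-open legal interval of its date.
    Days outside the study periods are dropped; bears without a demographic
    assignment are excluded with a log message.
    """
    calendar = StudyCalendar() if calendar is None else calendar
    labels = labels.copy()
    labels["window_start"] = pd.to_datetime(labels["window_start"])
    labels["date"] = labels["window_start"].dt.date
    bear_days = labels[["bear_id", "date"]].drop_duplicates().sort_values(["bear_id", "date"])

    bouts = bouts.copy()
    if not bouts.empty:
        bouts["start"] = pd.to_datetime(bouts["start"])
        bouts["date"] = bouts["start"].dt.date

    demo_map: dict | None = None
    if demographics is not None:
        demo_map = dict(zip(demographics["bear_id"], demographics["demographic_group"]))

    dist = None
    if gps is not None and not gps.empty:
        dist = daily_distance(gps)
        dist_key = (
            dist.set_index(["bear_id", "date"])["daily_distance_m"]
            if "bear_id" in dist.columns
            else None
        )

    legal_cache: dict[dt.date, tuple[dt.datetime, dt.datetime]] = {}
    records = []
    dropped_bears: set = set()
    for bear, date in bear_days.itertuples(index=False):
        period = calendar.period_of(date)
        if period is None:
            continue
        if demo_map is not None and bear not in demo_map:
            dropped_bears.add(bear)
            continue
        if date not in legal_cache:
            legal_cache[date] = legal_hours(date, calendar)
        lo, hi = legal_cache[date]
        day_bouts = (
            bouts[(bouts["bear_id"] == bear) & (bouts["date"] == date)]
            if not bouts.empty
            else bouts
        )
        n_bouts = len(day_bouts)
        if n_bouts:
            starts = day_bouts["start"]
            n_legal = int(((starts >= lo) & (starts < hi)).sum())
        else:
            n_legal = 0
        rec = {
            "bear_id": bear,
            "date": date,
            "period": period,
            "demographic_group": demo_map.get(bear) if demo_map is not None else None,
            "n_running_bouts": n_bouts,
            "n_bouts_legal_hours": n_legal,
            "prop_legal": n_legal / n_bouts if n_bouts else np.nan,
            "daily_distance_m": np.nan,
        }
        if dist is not None and dist_key is not None and (bear, date) in dist_key.index:
            rec["daily_distance_m"] = float(dist_key.loc[(bear, date)])
        records.append(rec)
    if dropped_bears:
        logger.warning("bears without demographic assignment excluded: %s", sorted(dropped_bears))
    return pd.DataFrame(
        records,
        columns=[
            "bear_id",
            "date",
            "period",
            "demographic_group",
            "n_running_bouts",
            "n_bouts_legal_hours",
            "prop_legal",
            "daily_distance_m",
        ],
    )


def subsample_hourly(
    windows: pd.DataFrame, n_per_hour: int = 10, seed: int = 0
) -> pd.DataFrame:
    """Uniform without-replacement draw of windows per bear x date x hour.

    Keeps ``min(n_per_hour, available)`` windows in each cell; deterministic
    for a given seed (cells are visited in sorted order). Used to thin the
    3 s stream before model fitting so serial autocorrelation does not
    distort residuals.
    """
    if n_per_hour < 1:
        raise ValueError("n_per_hour must be >= 1")
    w = windows.copy()
    ts = pd.to_datetime(w["window_start"])
    key = pd.DataFrame(
        {"bear_id": w["bear_id"], "date": ts.dt.date, "hour": ts.dt.hour}, index=w.index
    )
    rng = np.random.default_rng(seed)
    keep_idx = []
    for _, grp in key.groupby(["bear_id", "date", "hour"], sort=True):
        idx = grp.index.to_numpy()
        if len(idx) <= n_per_hour:
            keep_idx.append(idx)
        else:
            keep_idx.append(rng.choice(idx, size=n_per_hour, replace=False))
    if not keep_idx:
        return w.iloc[0:0]
    kept = np.concatenate(keep_idx)
    return w.loc[np.sort(kept)].reset_index(drop=True)


def export_model_table(
    windows: pd.DataFrame,
    records: pd.DataFrame,
    calendar: StudyCalendar | None = None,
    demographics: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Analysis-ready tables for downstream mixed models.

    Returns ``(window_table, records)``: one row per (subsampled) window with
    bear_id, year, date, time_of_day_s, period, demographic_group,
    is_feedwalking, is_resting — plus the per-day records table unchanged.
    """
    calendar = StudyCalendar() if calendar is None else calendar
    w = windows.copy()
    ts = pd.to_datetime(w["window_start"])
    merged = merge_feedwalk(w["label"])
    demo_map = (
        dict(zip(demographics["bear_id"], demographics["demographic_group"]))
        if demographics is not None
        else {}
    )
    table = pd.DataFrame(
        {
            "bear_id": w["bear_id"],
            "year": ts.dt.year,
            "date": ts.dt.date,
            "time_of_day_s": (
                ts.dt.hour * 3600 + ts.dt.minute * 60 + ts.dt.second
            ).astype(int),
            "period": [calendar.period_of(d) for d in ts.dt.date],
            "demographic_group": w["bear_id"].map(demo_map) if demo_map else None,
            "is_feedwalking": (merged == FEEDWALKING).astype(int),
            "is_resting": (merged == "resting").astype(int),
        }
    )
    return table.reset_index(drop=True), records


def diel_profile(
    windows: pd.DataFrame,
    bin_minutes: int = 60,
    n_boot: int = 500,
    seed: int = 0,
) -> pd.DataFrame:
    """Proportion of feedwalking windows per time-of-day bin, with bootstrap CI.

    A descriptive diel activity curve: windows are pooled into time-of-day
    bins, and the per-bin feedwalking proportion is given a 95% percentile
    bootstrap interval resampling bear-days (the unit of independence).
    Empty bins report NaN. Returns bin_start_min, prop_feedwalking, ci_lo,
    ci_hi, n_windows.
    """
    if windows.empty:
        raise ValueError("need at least one labelled window")
    w = windows.copy()
    ts = pd.to_datetime(w["window_start"])
    w["is_fw"] = (merge_feedwalk(w["label"]) == FEEDWALKING).astype(float)
    w["tod_bin"] = (ts.dt.hour * 60 + ts.dt.minute) // bin_minutes * bin_minutes
    w["bear_day"] = list(zip(w["bear_id"], ts.dt.date))
    n_bins = (24 * 60) // bin_minutes
    bins = np.arange(n_bins) * bin_minutes

    point = w.groupby("tod_bin")["is_fw"].mean()
    counts = w.groupby("tod_bin")["is_fw"].size()

    days = sorted(set(w["bear_day"]))
    rng = np.random.default_rng(seed)
    boot = np.full((n_boot, n_bins), np.nan)
    by_day = {d: g for d, g in w.groupby("bear_day")}
    for b in range(n_boot):
        pick = rng.choice(len(days), size=len(days), replace=True)
        sample = pd.concat([by_day[days[i]] for i in pick])
        m = sample.groupby("tod_bin")["is_fw"].mean()
        boot[b, :] = m.reindex(bins).to_numpy()
    import warnings

    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="All-NaN slice")
        lo = np.nanpercentile(boot, 2.5, axis=0)
        hi = np.nanpercentile(boot, 97.5, axis=0)
    return pd.DataFrame(
        {
            "bin_start_min": bins,
            "prop_feedwalking": point.reindex(bins).to_numpy(),
            "ci_lo": lo,
            "ci_hi": hi,
            "n_windows": counts.reindex(bins).fillna(0).astype(int).to_numpy(),
        }
    )
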