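"""Collar-like synthetic accelerometry with known behavioural ground truth.

Real training data for the classifier come from video-annotated captive bears
wearing 8 Hz tri-axial collar accelerometers; wild-bear data are the same
signal without labels, plus hourly GPS fixes. This module emulates that whole
setup so every pipeline stage can be tested against known truth:

* a semi-Markov behaviour schedule — exponential dwell times per behaviour,
  state choice at each transition weighted by a diel (hour-of-day) activity
  profile for the active states, which yields the crepuscular, bimodal
  activity pattern typical of this population;
* a per-behaviour signal model — a constant gravity/posture vector, a single
  gait sinusoid on the surge and heave axes (90° phase offset) for locomotion
  states, and white Gaussian noise;
* annotation event tables with an injected annotation-vs-collar clock lag and
  optional event dropout, mimicking video-annotation exports;
* hourly GPS fixes whose displacement scales with the fraction of the hour
  spent in active states.

Default parameters are test fixtures chosen for class separability (running >
walking > feeding > resting in per-window ODBA), not field estimates of bear
biomechanics; dwell means put running bouts on the ~10 s scale observed for
escape running, with much longer resting and foraging bouts. All generators
take explicit integer seeds and share no global random state.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ethogram import ACTIVE_STATES, BEHAVIORS, CLASS_ORDER
from .features import featurize


@dataclass(frozen=True)
class BehaviorParams:
    """Signal and dwell parameters of one behaviour.

    gravity_axis_mean is the static posture component in g; gait_freq_hz and
    gait_amp describe the locomotion sinusoid (both 0 for non-locomotion
    states); noise_sd is the per-axis white-noise amplitude in g; mean_dwell_s
    the expected bout duration of the semi-Markov schedule.
    """

    behavior: str
    gravity_axis_mean: tuple[float, float, float]
    noise_sd: float
    gait_freq_hz: float
    gait_amp: float
    mean_dwell_s: float

    def __post_init__(self) -> None:
        if self.behavior not in BEHAVIORS:
            raise ValueError(f"unknown behavior {self.behavior!r}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.gait_amp < 0:
            raise ValueError("gait_amp must be >= 0")
        if self.mean_dwell_s <= 0:
            raise ValueError("mean_dwell_s must be > 0")


@dataclass(frozen=True)
class DielProfile:
    """Relative probability of choosing an active state, by hour of day."""

    activity_weight: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_DIEL.activity_weight)
    )

    def __post_init__(self) -> None:
        if any(w < 0 for w in self.activity_weight.values()):
            raise ValueError("activity weights must be >= 0")
        if not any(w > 0 for w in self.activity_weight.values()):
            raise ValueError("at least one activity weight must be positive")

    def weight(self, hour: int) -> float:
        return self.activity_weight.get(hour % 24, 0.0)


@dataclass(frozen=True)
class ScheduleEntry:
    """One behaviour bout of the simulated schedule; times in seconds from start."""

    behavior: str
    start: float
    end: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("entry end must exceed start")


def _bimodal_weights(peaks: tuple[int, int] = (4, 20), base: float = 0.3, peak: float = 3.0) -> dict[int, float]:
    w = {}
    for h in range(24):
        d = min(min(abs(h - p), 24 - abs(h - p)) for p in peaks)
        w[h] = base + (peak - base) * np.exp(-0.5 * (d / 1.5) ** 2)
    return w


#: Crepuscular default: activity peaks at 04:00 and 20:00 local.
DEFAULT_DIEL = DielProfile.__new__(DielProfile)
object.__setattr__(DEFAULT_DIEL, "activity_weight", _bimodal_weights())

#: Default per-behaviour fixtures (see module docstring).
DEFAULT_PARAMS: dict[str, BehaviorParams] = {
    "resting": BehaviorParams("resting", (0.0, 0.0, 1.0), 0.02, 0.0, 0.0, 120.0),
    "feeding": BehaviorParams("feeding", (0.0, 0.2, 0.95), 0.08, 0.0, 0.05, 60.0),
    "walking": BehaviorParams("walking", (0.0, 0.1, 0.98), 0.08, 1.5, 0.25, 30.0),
    "running": BehaviorParams("running", (0.0, 0.3, 0.90), 0.10, 3.0, 0.8, 9.0),
}

#: Baseline (diel-independent) transition propensities of the inactive states.
_BASE_WEIGHT = {"resting": 1.0, "running": 0.08}


def _state_weights(
    hour: int,
    diel: DielProfile,
    diel_by_behavior: dict[str, DielProfile] | None,
) -> np.ndarray:
    w = np.empty(len(CLASS_ORDER))
    for i, b in enumerate(CLASS_ORDER):
        if diel_by_behavior is not None and b in diel_by_behavior:
            w[i] = diel_by_behavior[b].weight(hour)
        elif b in ACTIVE_STATES:
            w[i] = diel.weight(hour)
        else:
            w[i] = _BASE_WEIGHT[b]
    return w


def simulate_schedule(
    params: dict[str, BehaviorParams] | None = None,
    diel: DielProfile | None = None,
    duration: float = 86400.0,
    seed: int = 0,
    start_behavior: str | None = None,
    diel_by_behavior: dict[str, DielProfile] | None = None,
) -> list[ScheduleEntry]:
    """Semi-Markov behaviour schedule covering ``[0, duration)`` seconds.

    Dwell times are exponential with each behaviour's ``mean_dwell_s``; the
    state entered at each transition is drawn with weights given by the diel
    activity profile (for feeding/walking) and fixed baseline propensities
    (for resting/running), never repeating the current state.
    ``diel_by_behavior`` optionally overrides the weight of individual
    behaviours with their own hour-of-day profile (e.g. to concentrate running
    in particular hours of a scenario).

    Deterministic for a given seed.
    """
    params = DEFAULT_PARAMS if params is None else params
    diel = DEFAULT_DIEL if diel is None else diel
    if duration < 60:
        raise ValueError(f"duration must be >= 60 s, got {duration}")
    missing = BEHAVIORS - set(params)
    if missing:
        raise ValueError(f"missing BehaviorParams for {sorted(missing)}")
    rng = np.random.default_rng(seed)
    t = 0.0
    if start_behavior is None:
        w = _state_weights(0, diel, diel_by_behavior)
        start_behavior = rng.choice(CLASS_ORDER, p=w / w.sum())
    state = str(start_behavior)
    entries: list[ScheduleEntry] = []
    while t < duration:
        dwell = rng.exponential(params[state].mean_dwell_s)
        end = min(t + dwell, duration)
        entries.append(ScheduleEntry(state, t, end))
        t = end
        if t >= duration:
            break
        hour = int(t // 3600) % 24
        w = _state_weights(hour, diel, diel_by_behavior)
        i_cur = CLASS_ORDER.index(state)
        w[i_cur] = 0.0
        if w.sum() == 0:
            w = np.ones(len(CLASS_ORDER))
            w[i_cur] = 0.0
        state = str(rng.choice(CLASS_ORDER, p=w / w.sum()))
    return entries


def simulate_accel(
    schedule: list[ScheduleEntry],
    params: dict[str, BehaviorParams] | None = None,
    fs: float = 8.0,
    seed: int = 0,
    start_time: str | pd.Timestamp = "2019-08-01 00:00:00",
) -> pd.DataFrame:
    """Tri-axial acceleration for a schedule, with per-sample truth labels.

    Each sample is the behaviour's gravity vector, plus the gait sinusoid on
    the surge (cosine) and heave (sine) axes, plus N(0, noise_sd) per axis.
    Returns columns ``timestamp``, ``acc_x``, ``acc_y``, ``acc_z``, ``label``.
    """
    params = DEFAULT_PARAMS if params is None else params
    if fs <= 0:
        raise ValueError("fs must be > 0")
    for p in params.values():
        if p.gait_freq_hz >= fs / 2:
            raise ValueError(
                f"{p.behavior}: gait_freq_hz {p.gait_freq_hz} >= Nyquist {fs / 2} (aliasing)"
            )
    if not schedule:
        return pd.DataFrame(columns=["timestamp", "acc_x", "acc_y", "acc_z", "label"])
    for prev, nxt in zip(schedule, schedule[1:]):
        if abs(nxt.start - prev.end) > 1e-9:
            raise ValueError("schedule must be contiguous")
    duration = schedule[-1].end - schedule[0].start
    n = int(duration * fs)
    t = schedule[0].start + np.arange(n) / fs
    rng = np.random.default_rng(seed)
    acc = np.empty((n, 3))
    labels = np.empty(n, dtype=object)
    starts = np.array([e.start for e in schedule])
    idx = np.clip(np.searchsorted(starts, t, side="right") - 1, 0, len(schedule) - 1)
    for k, entry in enumerate(schedule):
        sel = idx == k
        if not sel.any():
            continue
        p = params[entry.behavior]
        m = int(sel.sum())
        a = np.tile(np.asarray(p.gravity_axis_mean, dtype=float), (m, 1))
        if p.gait_amp > 0 and p.gait_freq_hz > 0:
            phase = 2 * np.pi * p.gait_freq_hz * t[sel]
            a[:, 1] += p.gait_amp * np.cos(phase)  # surge, 90 deg ahead
            a[:, 2] += p.gait_amp * np.sin(phase)  # heave
        if p.noise_sd > 0:
            a += rng.normal(0.0, p.noise_sd, size=(m, 3))
        acc[sel] = a
        labels[sel] = entry.behavior
    base = pd.Timestamp(start_time)
    timestamps = base + pd.to_timedelta(t, unit="s")
    return pd.DataFrame(
        {
            "timestamp": timestamps,
            "acc_x": acc[:, 0],
            "acc_y": acc[:, 1],
            "acc_z": acc[:, 2],
            "label": labels,
        }
    )


def simulate_annotations(
    schedule: list[ScheduleEntry],
    lag_s: float = 0.0,
    dropout_fraction: float = 0.0,
    seed: int = 0,
    start_time: str | pd.Timestamp = "2019-08-01 00:00:00",
) -> pd.DataFrame:
    """Annotation event table for a schedule, on a lagged video clock.

    Event times are schedule times shifted by ``+lag_s`` (the video clock runs
    ahead of the collar clock, as in real deployments where lags of 1–3 min
    must be corrected before training). A ``dropout_fraction`` of events is
    removed by seeded Bernoulli thinning. Columns: behavior, start, end.
    """
    if not 0 <= dropout_fraction < 1:
        raise ValueError("dropout_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    base = pd.Timestamp(start_time)
    rows = []
    for e in schedule:
        if dropout_fraction > 0 and rng.random() < dropout_fraction:
            continue
        rows.append(
            {
                "behavior": e.behavior,
                "start": base + pd.to_timedelta(e.start + lag_s, unit="s"),
                "end": base + pd.to_timedelta(e.end + lag_s, unit="s"),
            }
        )
    return pd.DataFrame(rows, columns=["behavior", "start", "end"])


def simulate_gps(
    schedule: list[ScheduleEntry],
    nominal_hourly_distance_m: float = 500.0,
    noise_sd_m: float = 0.0,
    fix_interval_s: float = 3600.0,
    seed: int = 0,
    start_time: str | pd.Timestamp = "2019-08-01 00:00:00",
) -> pd.DataFrame:
    """Hourly GPS fixes in planar metres driven by the activity schedule.

    Between consecutive fixes the bear is displaced by
    ``active_fraction * nominal_hourly_distance_m`` (active = any non-resting
    state) in a random heading, plus isotropic Gaussian noise. Columns:
    ``timestamp``, ``x_m``, ``y_m``.
    """
    if fix_interval_s <= 0:
        raise ValueError("fix_interval_s must be > 0")
    rng = np.random.default_rng(seed)
    base = pd.Timestamp(start_time)
    if not schedule:
        return pd.DataFrame(columns=["timestamp", "x_m", "y_m"])
    horizon = schedule[-1].end
    fix_times = np.arange(schedule[0].start, horizon + 1e-9, fix_interval_s)
    pos = np.zeros(2)
    rows = [{"timestamp": base + pd.to_timedelta(fix_times[0], unit="s"), "x_m": 0.0, "y_m": 0.0}]
    scale = fix_interval_s / 3600.0
    for t_prev, t_next in zip(fix_times[:-1], fix_times[1:]):
        active = sum(
            max(0.0, min(e.end, t_next) - max(e.start, t_prev))
            for e in schedule
            if e.behavior != "resting"
        )
        frac = active / (t_next - t_prev)
        heading = rng.uniform(0, 2 * np.pi)
        step = frac * nominal_hourly_distance_m * scale
        pos = pos + step * np.array([np.cos(heading), np.sin(heading)])
        if noise_sd_m > 0:
            pos = pos + rng.normal(0.0, noise_sd_m, size=2)
        rows.append(
            {
                "timestamp": base + pd.to_timedelta(t_next, unit="s"),
                "x_m": float(pos[0]),
                "y_m": float(pos[1]),
            }
        )
    return pd.DataFrame(rows)


def schedule_to_window_labels(
    schedule: list[ScheduleEntry],
    window_s: float = 3.0,
    start_time: str | pd.Timestamp = "2019-08-01 00:00:00",
    bear_id: str = "bear1",
) -> pd.DataFrame:
    """Truth behaviour of each 3 s window (label at the window midpoint).

    Convenience for activity-budget tests and scenario studies where the
    signal/classifier stages are not under test. Columns: bear_id,
    window_start, label.
    """
    if not schedule:
        return pd.DataFrame(columns=["bear_id", "window_start", "label"])
    base = pd.Timestamp(start_time)
    t0, t1 = schedule[0].start, schedule[-1].end
    n_win = int((t1 - t0) // window_s)
    starts = t0 + np.arange(n_win) * window_s
    mids = starts + window_s / 2
    entry_starts = np.array([e.start for e in schedule])
    idx = np.clip(np.searchsorted(entry_starts, mids, side="right") - 1, 0, len(schedule) - 1)
    return pd.DataFrame(
        {
            "bear_id": bear_id,
            "window_start": base + pd.to_timedelta(starts, unit="s"),
            "label": [schedule[int(i)].behavior for i in idx],
        }
    )


def simulate_labeled_windows(
    n_per_class: int,
    params: dict[str, BehaviorParams] | None = None,
    fs: float = 8.0,
    window_s: float = 3.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Class-balanced labelled feature windows for classifier experiments.

    Simulates one long uninterrupted bout per behaviour, featurizes it, and
    returns the concatenated feature table with a ``label`` column.
    """
    params = DEFAULT_PARAMS if params is None else params
    rng = np.random.default_rng(seed)
    frames = []
    for behavior in CLASS_ORDER:
        dur = n_per_class * window_s
        entry = ScheduleEntry(behavior, 0.0, dur)
        acc = simulate_accel(
            [entry], params, fs=fs, seed=int(rng.integers(0, 2**31 - 1))
        )
        feats = featurize(acc.drop(columns="label"), fs=fs, window_s=window_s)
        feats["label"] = behavior
        frames.append(feats.iloc[:n_per_class])
    return pd.concat(frames, ignore_index=True)


def simulate_hunting_response_population(
    n_bears: int = 4,
    days_per_period: int = 6,
    seed: int = 0,
    start_year: int = 2019,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Window labels for a population that shifts running into legal hours.

    Scenario generator for end-to-end activity-budget studies: each bear gets
    ``days_per_period`` days at the end of the pre-hunting period (running
    spread uniformly over the day) and ``days_per_period`` days at the start
    of the hunting period, where the running-state propensity is concentrated
    in daylight/legal hours (05:00-18:00), emulating bears flushed by
    daytime hound hunts. Returns ``(window_labels, demographics)`` ready for
    bout detection and daily metrics.
    """
    rng = np.random.default_rng(seed)
    uniform_running = DielProfile({h: 0.08 for h in range(24)})
    daytime_running = DielProfile(
        {h: (0.6 if 5 <= h < 18 else 0.005) for h in range(24)}
    )
    groups = ["female_with_offspring", "subadult_solitary_female",
              "adult_solitary_female", "adult_male"]
    frames = []
    demo_rows = []
    for b in range(n_bears):
        bear = f"bear{b:02d}"
        demo_rows.append(
            {"bear_id": bear, "year": start_year, "demographic_group": groups[b % len(groups)]}
        )
        pre_dates = [
            dt.date(start_year, 8, 21 - days_per_period + i) for i in range(days_per_period)
        ]
        hunt_dates = [dt.date(start_year, 8, 21 + i) for i in range(days_per_period)]
        for date in pre_dates + hunt_dates:
            override = daytime_running if date.day >= 21 else uniform_running
            sch = simulate_schedule(
                duration=86400.0,
                seed=int(rng.integers(0, 2**31 - 1)),
                diel_by_behavior={"running": override},
            )
            frames.append(
                schedule_to_window_labels(
                    sch, start_time=pd.Timestamp(date).strftime("%Y-%m-%d 00:00:00"), bear_id=bear
                )
            )
    return pd.concat(frames, ignore_index=True), pd.DataFrame(demo_rows)
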