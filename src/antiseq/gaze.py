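"""Saccade detection and antisaccade trial classification from gaze samples.

Input is a 500 Hz sample train (time in ms from target onset; horizontal /
vertical gaze position in degrees of visual angle, screen centre 0,
rightward positive). Processing stages:

1. :func:`filter_samples` — despiking: frames whose displacement velocity
   exceeds 1,500 deg/s, or whose velocity change exceeds 100,000 deg/s²,
   are removed (no interpolation).
2. :func:`detect_saccades` — a velocity/acceleration threshold detector
   (defaults 30 deg/s and 8,000 deg/s², a 20 ms merge window), with onset
   refinement back to the start of the velocity rise.
3. :func:`classify_trial` — outcome labelling: the primary saccade is the
   first event inside the 80–700 ms latency window (earlier → anticipatory,
   none → delayed; both excluded). A primary saccade toward the target is an
   inhibitory error; a later saccade carrying gaze across into the opposite
   hemifield marks it corrected. A primary saccade away from the target is
   correct. Latency is the primary-saccade onset.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .records import TRIAL_CSV_COLUMNS, TrialRecord


@dataclass(frozen=True)
class SaccadeEvent:
    onset_ms: float
    offset_ms: float
    start_x_deg: float
    end_x_deg: float
    peak_velocity_deg_s: float

    def __post_init__(self) -> None:
        if not self.offset_ms > self.onset_ms:
            raise ValueError("saccade offset must follow onset")

    @property
    def direction(self) -> str:
        return "right" if self.end_x_deg > self.start_x_deg else "left"

    @property
    def amplitude_deg(self) -> float:
        return abs(self.end_x_deg - self.start_x_deg)


@dataclass(frozen=True)
class ClassifierConfig:
    """Thresholds for despiking, saccade detection and trial labelling."""

    velocity_spike_limit: float = 1500.0     # deg/s
    accel_spike_limit: float = 100_000.0     # deg/s^2
    saccade_velocity_threshold: float = 30.0  # deg/s
    saccade_accel_threshold: float = 8000.0   # deg/s^2
    merge_window_ms: float = 20.0
    min_duration_ms: float = 6.0
    min_amplitude_deg: float = 1.0
    onset_floor_deg_s: float = 1.0
    min_latency_ms: float = 80.0
    max_latency_ms: float = 700.0
    hemifield_x_threshold_deg: float = 0.0
    correction_rule: str = "crossing"  # or "reversal"

    def validate(self) -> None:
        for name in ("velocity_spike_limit", "accel_spike_limit",
                     "saccade_velocity_threshold", "saccade_accel_threshold",
                     "merge_window_ms", "min_latency_ms", "max_latency_ms"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if not self.min_latency_ms < self.max_latency_ms:
            raise ValueError("min_latency_ms must be below max_latency_ms")
        if self.correction_rule not in ("crossing", "reversal"):
            raise ValueError("correction_rule must be 'crossing' or 'reversal'")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "ClassifierConfig":
        with open(path) as fh:
            return cls(**json.load(fh))


# ---------------------------------------------------------------------------
# despiking
# ---------------------------------------------------------------------------

def filter_samples(samples: pd.DataFrame, config: ClassifierConfig | None = None
                   ) -> pd.DataFrame:
    """Remove spike frames from a single-trial sample train.

    A causal pass compares each frame against the last retained frame: a
    frame whose displacement velocity exceeds ``velocity_spike_limit`` is
    dropped (so an isolated spike costs exactly one frame and the trace
    re-joins the smooth path). A second pass drops frames whose velocity
    change exceeds ``accel_spike_limit``. Order is preserved and nothing is
    interpolated.
    """
    config = config or ClassifierConfig()
    config.validate()
    if len(samples) < 3:
        warnings.warn("fewer than 3 gaze samples; returning empty trace")
        return samples.iloc[0:0]

    t = samples["t_ms"].to_numpy(float)
    x = samples["x_deg"].to_numpy(float)
    y = samples["y_deg"].to_numpy(float)

    keep = _despike_velocity(t, x, y, config.velocity_spike_limit)
    idx = np.flatnonzero(keep)
    keep2 = _despike_accel(t[idx], x[idx], y[idx], config.accel_spike_limit)
    return samples.iloc[idx[keep2]].reset_index(drop=True)


def _despike_velocity(t, x, y, limit) -> np.ndarray:
    keep = np.ones(len(t), dtype=bool)
    last = 0
    for i in range(1, len(t)):
        dt_s = (t[i] - t[last]) / 1000.0
        v = np.hypot(x[i] - x[last], y[i] - y[last]) / dt_s
        if v > limit:
            keep[i] = False
        else:
            last = i
    return keep


def _despike_accel(t, x, y, limit) -> np.ndarray:
    keep = np.ones(len(t), dtype=bool)
    if len(t) < 3:
        return keep
    prev, last = 0, 1
    for i in range(2, len(t)):
        dt1 = (t[last] - t[prev]) / 1000.0
        dt2 = (t[i] - t[last]) / 1000.0
        v1 = np.hypot(x[last] - x[prev], y[last] - y[prev]) / dt1
        v2 = np.hypot(x[i] - x[last], y[i] - y[last]) / dt2
        if abs(v2 - v1) / dt2 > limit:
            keep[i] = False
        else:
            prev, last = last, i
    return keep


# ---------------------------------------------------------------------------
# saccade detection
# ---------------------------------------------------------------------------

def detect_saccades(samples: pd.DataFrame, config: ClassifierConfig | None = None
                    ) -> list[SaccadeEvent]:
    """Velocity/acceleration threshold saccade detector.

    A sample is saccadic when its central-difference speed exceeds
    ``saccade_velocity_threshold`` or its acceleration magnitude exceeds
    ``saccade_accel_threshold``. Contiguous saccadic runs become events;
    events separated by less than ``merge_window_ms`` are merged; the onset
    is walked back along the rising velocity flank to its start so latencies
    track the true movement onset rather than the threshold crossing.
    """
    config = config or ClassifierConfig()
    config.validate()
    if len(samples) < 3:
        return []

    t = samples["t_ms"].to_numpy(float)
    x = samples["x_deg"].to_numpy(float)
    y = samples["y_deg"].to_numpy(float)

    t_s = t / 1000.0
    vx = np.gradient(x, t_s)
    vy = np.gradient(y, t_s)
    speed = np.hypot(vx, vy)
    accel = np.gradient(speed, t_s)

    marked = (speed >= config.saccade_velocity_threshold) | (
        np.abs(accel) >= config.saccade_accel_threshold
    )
    runs = _contiguous_runs(marked)
    runs = _merge_runs(runs, t, config.merge_window_ms)

    events: list[SaccadeEvent] = []
    for start, end in runs:
        start = _walk_flank(speed, start, -1, config.onset_floor_deg_s)
        end = _walk_flank(speed, end, +1, config.onset_floor_deg_s)
        if t[end] - t[start] < config.min_duration_ms:
            continue
        events.append(
            SaccadeEvent(
                onset_ms=float(t[start]),
                offset_ms=float(t[end]),
                start_x_deg=float(x[start]),
                end_x_deg=float(x[end]),
                peak_velocity_deg_s=float(speed[start:end + 1].max()),
            )
        )
    return events


def _contiguous_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    splits = np.flatnonzero(np.diff(idx) > 1)
    starts = np.insert(idx[splits + 1], 0, idx[0])
    ends = np.append(idx[splits], idx[-1])
    return list(zip(starts.tolist(), ends.tolist()))


def _merge_runs(runs, t, merge_window_ms) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for start, end in runs:
        if merged and t[start] - t[merged[-1][1]] < merge_window_ms:
            merged[-1] = (merged[-1][0], end)
        else:
            merged.append((start, end))
    return merged


def _walk_flank(speed: np.ndarray, i: int, step: int, floor: float) -> int:
    """Extend an event boundary along a monotone velocity flank above
    ``floor``, recovering the movement start/stop below threshold."""
    while 0 < i + step < len(speed) - 1:
        nxt = i + step
        if speed[nxt] <= floor or speed[nxt] > speed[i]:
            break
        i = nxt
    return i


# ---------------------------------------------------------------------------
# trial classification
# ---------------------------------------------------------------------------

def classify_trial(
    events: list[SaccadeEvent],
    target_side: str,
    config: ClassifierConfig | None = None,
    trial_index: int = 1,
) -> TrialRecord:
    """Label a trial from its detected saccade events.

    The primary saccade is the first event of at least ``min_amplitude_deg``
    amplitude. An onset before ``min_latency_ms`` is anticipatory and the
    trial is excluded; no event by ``max_latency_ms`` excludes it as delayed.
    A primary saccade toward the target is an inhibitory error, corrected if
    a later event lands in the opposite hemifield (or merely reverses
    direction, under ``correction_rule='reversal'``).
    """
    config = config or ClassifierConfig()
    config.validate()
    if target_side not in ("left", "right"):
        raise ValueError(f"unknown target side {target_side!r}")
    tsign = 1.0 if target_side == "right" else -1.0

    cands = [e for e in events if e.amplitude_deg >= config.min_amplitude_deg]

    def _excluded() -> TrialRecord:
        return TrialRecord(index=trial_index, target_side=target_side,
                           outcome="excluded", latency_ms=None)

    if not cands:
        return _excluded()  # no response by end of trial: delayed
    primary = cands[0]
    if primary.onset_ms < config.min_latency_ms:
        return _excluded()  # anticipatory
    if primary.onset_ms > config.max_latency_ms:
        return _excluded()  # delayed

    latency = float(primary.onset_ms)
    if primary.direction != target_side:
        return TrialRecord(index=trial_index, target_side=target_side,
                           outcome="correct", latency_ms=latency)

    # prosaccade error: search for a corrective saccade
    for e in cands[1:]:
        if e.onset_ms <= primary.offset_ms:
            continue
        if config.correction_rule == "crossing":
            corrected = e.end_x_deg * tsign < -config.hemifield_x_threshold_deg
        else:
            corrected = e.direction != primary.direction
        if corrected:
            return TrialRecord(
                index=trial_index, target_side=target_side,
                outcome="error_corrected", latency_ms=latency,
                correction_latency_ms=float(e.onset_ms),
            )
    return TrialRecord(index=trial_index, target_side=target_side,
                       outcome="error_uncorrected", latency_ms=latency)


def classify_samples(
    samples: pd.DataFrame,
    target_side: str,
    config: ClassifierConfig | None = None,
    trial_index: int = 1,
) -> TrialRecord:
    """Full single-trial chain: despike, detect, classify."""
    config = config or ClassifierConfig()
    filtered = filter_samples(samples, config)
    events = detect_saccades(filtered, config)
    return classify_trial(events, target_side, config, trial_index)


def classify_cohort(
    samples: pd.DataFrame,
    meta: pd.DataFrame,
    config: ClassifierConfig | None = None,
) -> pd.DataFrame:
    """Classify every trial in a sample-level table.

    ``meta`` supplies the per-trial target side and participant group
    (columns participant_id, group, trial_index, target_side — the
    trial-level CSV schema works directly). Returns a trial-level table in
    the same schema with recomputed outcome and latency columns.
    """
    config = config or ClassifierConfig()
    meta_idx = meta.set_index(["participant_id", "trial_index"])
    rows = []
    for (pid, tix), sub in samples.groupby(
        ["participant_id", "trial_index"], sort=False
    ):
        row = meta_idx.loc[(pid, tix)]
        trial = classify_samples(
            sub.reset_index(drop=True), str(row["target_side"]), config,
            trial_index=int(tix),
        )
        rows.append((str(pid), str(row["group"]), trial.index, trial.target_side,
                     trial.outcome, trial.latency_ms, trial.correction_latency_ms))
    out = pd.DataFrame(rows, columns=list(TRIAL_CSV_COLUMNS))
    return out.sort_values(["participant_id", "trial_index"]).reset_index(drop=True)
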