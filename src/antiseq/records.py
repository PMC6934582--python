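"""Core record types for antisaccade trial sequences.

A cohort is a list of :class:`ParticipantRecord`, each holding an ordered
sequence of :class:`TrialRecord`. Trial outcomes use the standard antisaccade
taxonomy: ``correct`` (first saccade away from the target), ``error_corrected``
(prosaccade error followed by a corrective saccade into the opposite
hemifield), ``error_uncorrected`` (error with no correction), and ``excluded``
(anticipatory or excessively delayed responses outside the 80-700 ms latency
window, which never enter any analysis).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

GROUPS = ("control", "MCI", "AD")

OUTCOME_CORRECT = "correct"
OUTCOME_ERROR_CORRECTED = "error_corrected"
OUTCOME_ERROR_UNCORRECTED = "error_uncorrected"
OUTCOME_EXCLUDED = "excluded"
OUTCOMES = (
    OUTCOME_CORRECT,
    OUTCOME_ERROR_CORRECTED,
    OUTCOME_ERROR_UNCORRECTED,
    OUTCOME_EXCLUDED,
)
ERROR_OUTCOMES = frozenset({OUTCOME_ERROR_CORRECTED, OUTCOME_ERROR_UNCORRECTED})

MIN_LATENCY_MS = 80.0
MAX_LATENCY_MS = 700.0

#: trial-level CSV column order shared by the generator, the classifier and
#: all analysis readers.
TRIAL_CSV_COLUMNS = (
    "participant_id",
    "group",
    "trial_index",
    "target_side",
    "outcome",
    "latency_ms",
    "correction_latency_ms",
)


@dataclass(frozen=True)
class TrialRecord:
    """A single antisaccade trial.

    ``latency_ms`` is the primary-saccade reaction time from target onset;
    ``correction_latency_ms`` is set only for corrected errors and must exceed
    the primary latency.
    """

    index: int
    target_side: str
    outcome: str
    latency_ms: float | None
    correction_latency_ms: float | None = None

    def __post_init__(self) -> None:
        if self.outcome not in OUTCOMES:
            raise ValueError(f"unknown outcome {self.outcome!r}")
        if self.target_side not in ("left", "right"):
            raise ValueError(f"unknown target side {self.target_side!r}")
        if self.outcome != OUTCOME_EXCLUDED:
            if self.latency_ms is None or not (
                MIN_LATENCY_MS <= self.latency_ms <= MAX_LATENCY_MS
            ):
                raise ValueError(
                    f"latency {self.latency_ms} outside the "
                    f"[{MIN_LATENCY_MS:.0f}, {MAX_LATENCY_MS:.0f}] ms window"
                )
        if self.correction_latency_ms is not None:
            if self.outcome != OUTCOME_ERROR_CORRECTED:
                raise ValueError("correction latency only valid for corrected errors")
            if self.latency_ms is not None and not (
                self.correction_latency_ms > self.latency_ms
            ):
                raise ValueError("correction latency must exceed primary latency")

    @property
    def is_error(self) -> bool:
        return self.outcome in ERROR_OUTCOMES


@dataclass
class ParticipantRecord:
    """One subject: group label, ordered trials and (for simulated cohorts)
    the realised random intercept ``u`` in logit units."""

    id: str
    group: str
    trials: list[TrialRecord] = field(default_factory=list)
    u: float | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        idx = [t.index for t in self.trials]
        if idx and (idx[0] != 1 or any(b - a != 1 for a, b in zip(idx, idx[1:]))):
            raise ValueError("trial indices must increase strictly from 1")

    @property
    def usable_trials(self) -> list[TrialRecord]:
        """Trials that enter the analysis (excluded trials dropped)."""
        return [t for t in self.trials if t.outcome != OUTCOME_EXCLUDED]


def cohort_to_frame(cohort: list[ParticipantRecord]) -> pd.DataFrame:
    """Flatten a cohort to the canonical trial-level table."""
    rows = [
        (p.id, p.group, t.index, t.target_side, t.outcome, t.latency_ms,
         t.correction_latency_ms)
        for p in cohort
        for t in p.trials
    ]
    return pd.DataFrame(rows, columns=list(TRIAL_CSV_COLUMNS))


def frame_to_cohort(df: pd.DataFrame) -> list[ParticipantRecord]:
    """Rebuild ParticipantRecords from a trial-level table."""
    cohort: list[ParticipantRecord] = []
    for (pid, group), sub in df.groupby(["participant_id", "group"], sort=False):
        sub = sub.sort_values("trial_index")
        trials = [
            TrialRecord(
                index=int(r.trial_index),
                target_side=str(r.target_side),
                outcome=str(r.outcome),
                latency_ms=None if _isna(r.latency_ms) else float(r.latency_ms),
                correction_latency_ms=(
                    None
                    if _isna(r.correction_latency_ms)
                    else float(r.correction_latency_ms)
                ),
            )
            for r in sub.itertuples()
        ]
        cohort.append(ParticipantRecord(id=str(pid), group=str(group), trials=trials))
    return cohort


def write_trials_csv(cohort_or_frame, path) -> None:
    df = (
        cohort_or_frame
        if isinstance(cohort_or_frame, pd.DataFrame)
        else cohort_to_frame(cohort_or_frame)
    )
    df.to_csv(path, index=False)


def read_trials_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(TRIAL_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trial CSV missing columns: {sorted(missing)}")
    return df


def _isna(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))
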