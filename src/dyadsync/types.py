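"""Core domain types shared across the pipeline.

All per-second streams use 0-based, half-open second indexing: second ``t``
covers task time ``[t, t+1)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

UNCODABLE = "uncodable"

AFFECT_CODES = ("positive_warm", "dysphoric", "angry_aggressive", "neutral")
ERSB_CODES = ("supportive", "dismissing", "mild_rejection", "firm_rejection", "none")
UNSUPPORTIVE_ERSB = ("dismissing", "mild_rejection", "firm_rejection")

ALPHABETS = {
    "affect": set(AFFECT_CODES) | {UNCODABLE},
    "ersb": set(ERSB_CODES) | {UNCODABLE},
}

# max tolerated disagreement between supplied beat times and intervals (ms)
_TIME_INTERVAL_TOL_MS = 1.0


@dataclass
class IBISeries:
    """Beat-by-beat interbeat intervals anchored to task time.

    ``beat_times[i]`` is the end of interval ``i`` in seconds from task start;
    ``intervals[i]`` is the interval length in ms (spanning beat i-1 -> beat i,
    with an implicit anchor at t=0 before the first beat).
    """

    person_id: str
    beat_times: np.ndarray
    intervals: np.ndarray

    def __post_init__(self) -> None:
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        self.intervals = np.asarray(self.intervals, dtype=float)

    @property
    def n_beats(self) -> int:
        return len(self.intervals)

    @property
    def span_s(self) -> float:
        """Time from first to last recorded beat."""
        return float(self.beat_times[-1] - self.beat_times[0]) if self.n_beats else 0.0

    def validate(self) -> None:
        if len(self.beat_times) != len(self.intervals):
            raise ValueError(
                f"{self.person_id}: beat_times and intervals length mismatch "
                f"({len(self.beat_times)} vs {len(self.intervals)})"
            )
        if np.any(self.intervals <= 0):
            idx = int(np.argmax(self.intervals <= 0))
            raise ValueError(f"{self.person_id}: non-positive interval at index {idx}")
        dt = np.diff(self.beat_times)
        if np.any(dt <= 0):
            idx = int(np.argmax(dt <= 0)) + 1
            raise ValueError(
                f"{self.person_id}: beat_times not strictly increasing at index {idx}"
            )
        # consistency between the two representations, where both carry signal
        gap_ms = dt * 1000.0
        mismatch = np.abs(gap_ms - self.intervals[1:]) >= _TIME_INTERVAL_TOL_MS
        if np.any(mismatch):
            idx = int(np.argmax(mismatch)) + 1
            raise ValueError(
                f"{self.person_id}: beat_times/intervals disagree by >= "
                f"{_TIME_INTERVAL_TOL_MS} ms at index {idx}"
            )


@dataclass
class CodedStream:
    """Per-second categorical behavior codes for one person and one pass."""

    person_id: str
    role: str  # "parent" | "child"
    stream_kind: str  # "affect" | "ersb"
    codes: np.ndarray  # dtype=object/str, one code per 1-second epoch

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=object)

    @property
    def task_length_s(self) -> int:
        return len(self.codes)

    @property
    def codable_mask(self) -> np.ndarray:
        return self.codes != UNCODABLE

    @property
    def codable_frac(self) -> float:
        if len(self.codes) == 0:
            return 0.0
        return float(np.mean(self.codable_mask))

    def validate(self) -> None:
        if self.stream_kind not in ALPHABETS:
            raise ValueError(f"unknown stream_kind {self.stream_kind!r}")
        if self.role not in ("parent", "child"):
            raise ValueError(f"unknown role {self.role!r}")
        alphabet = ALPHABETS[self.stream_kind]
        unknown = sorted({c for c in self.codes if c not in alphabet})
        if unknown:
            raise ValueError(
                f"{self.person_id}: unknown {self.stream_kind} codes: {unknown}"
            )


@dataclass
class UniformSeries:
    """Evenly sampled series on the task clock starting at t=0."""

    values: np.ndarray
    valid: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)

    @property
    def n_samples(self) -> int:
        return len(self.values)


@dataclass
class RSASeries:
    """Per-second time-varying RSA estimates, ln(ms^2) by default."""

    person_id: str
    values: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)

    @property
    def task_length_s(self) -> int:
        return len(self.values)

    @property
    def n_valid(self) -> int:
        return int(np.sum(self.valid))

    @property
    def mean(self) -> float:
        return float(np.mean(self.values[self.valid])) if self.n_valid else float("nan")

    @property
    def sd(self) -> float:
        if self.n_valid < 2:
            return float("nan")
        return float(np.std(self.values[self.valid], ddof=1))

    def copy(self) -> "RSASeries":
        return RSASeries(self.person_id, self.values.copy(), self.valid.copy())


@dataclass
class DiffSeries:
    """First-differenced per-second series; d(t) = v(t) - v(t-1)."""

    person_id: str
    values: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)

    @property
    def task_length_s(self) -> int:
        return len(self.values)


@dataclass
class DyadRecord:
    """One dyad's raw series, covariates and outcomes. Any component may be
    missing; missingness is data, not an error."""

    dyad_id: str
    parent_ibi: Optional[IBISeries] = None
    child_ibi: Optional[IBISeries] = None
    parent_affect: Optional[CodedStream] = None
    child_affect: Optional[CodedStream] = None
    parent_ersb: Optional[CodedStream] = None
    covariates: dict = field(default_factory=dict)
    parent_dep_T: Optional[float] = None
    child_dep_T: Optional[float] = None
    child_internalizing_T: Optional[float] = None
    child_total_T: Optional[float] = None

    def validate(self) -> None:
        for name in ("parent_dep_T", "child_dep_T", "child_internalizing_T", "child_total_T"):
            val = getattr(self, name)
            if val is not None and np.isfinite(val) and val < 0:
                raise ValueError(f"{self.dyad_id}: {name} must be >= 0, got {val}")
        for key, val in self.covariates.items():
            if val is not None and not (isinstance(val, float) and np.isnan(val)):
                if val not in (0, 1):
                    raise ValueError(
                        f"{self.dyad_id}: covariate {key} must be 0/1/missing, got {val!r}"
                    )
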