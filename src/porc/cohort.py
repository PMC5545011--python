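"""Patient-level data containers and plain-text (CSV) round-tripping.

The unit of analysis is one awake, freshly extubated patient assessed with a
battery of eight bedside muscle-function tests while the train-of-four ratio
(TOFR) is recorded by calibrated electromyography (EMG, the gold standard)
and, on the contralateral arm, by an uncalibrated acceleromyograph (AMG).
A :class:`PatientRecord` bundles the test scores, the instrumental TOFR
readings, the examiner's tactile fading judgement and the time-resolved EMG
trace that the stability quality-control rule inspects.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import TraceFormatError

#: Score ranges of the eight bedside tests, in the order of the published
#: test battery.  Timed tests (seconds the posture can be held) score 0-5;
#: graded tests score 0-3; diplopia is binary (1 = no double vision).
SCORE_RANGES: dict[str, tuple[int, int]] = {
    "open_eyes": (0, 5),
    "diplopia": (0, 1),
    "tongue": (0, 5),
    "spatula": (0, 3),
    "head_lift": (0, 5),
    "arm_lift": (0, 5),
    "hand_press": (0, 3),
    "swallow": (0, 3),
}

#: Canonical variable order used for deterministic tie-breaking in splits.
TEST_NAMES: list[str] = list(SCORE_RANGES)

#: Tests that cannot be performed after intraoral surgery.
INTRAORAL_MISSING: tuple[str, ...] = ("spatula", "swallow")

PALPABLE = "palpable"
NOT_PALPABLE = "not palpable"


@dataclass(frozen=True)
class TestScores:
    """One patient's eight muscle-function test scores.

    Scores are integers within :data:`SCORE_RANGES`; a score may be ``None``
    when the test could not be performed (swallowing and spatula pressure
    after intraoral surgery).
    """

    open_eyes: Optional[int]
    diplopia: Optional[int]
    tongue: Optional[int]
    spatula: Optional[int]
    head_lift: Optional[int]
    arm_lift: Optional[int]
    hand_press: Optional[int]
    swallow: Optional[int]

    def as_dict(self) -> dict[str, Optional[int]]:
        return dataclasses.asdict(self)

    def get(self, name: str) -> Optional[int]:
        return getattr(self, name)

    def validate(self, allow_missing: Sequence[str] = ()) -> None:
        for name, (lo, hi) in SCORE_RANGES.items():
            v = getattr(self, name)
            if v is None:
                if name in allow_missing:
                    continue
                raise ValueError(f"score '{name}' is missing")
            if not float(v).is_integer() or not lo <= int(v) <= hi:
                raise ValueError(
                    f"score '{name}'={v!r} outside its range [{lo}, {hi}]"
                )

    @classmethod
    def all_minimum(cls) -> "TestScores":
        return cls(**{k: lo for k, (lo, _) in SCORE_RANGES.items()})

    @classmethod
    def all_maximum(cls) -> "TestScores":
        return cls(**{k: hi for k, (_, hi) in SCORE_RANGES.items()})


@dataclass
class EmgTrace:
    """Time-ordered TOFR readings recorded at 20 s stimulation intervals.

    May be empty, representing an assessment where no usable EMG data could
    be obtained.
    """

    t_seconds: np.ndarray
    tofr: np.ndarray

    def __post_init__(self) -> None:
        self.t_seconds = np.asarray(self.t_seconds, dtype=float)
        self.tofr = np.asarray(self.tofr, dtype=float)

    def validate(self) -> None:
        if self.t_seconds.shape != self.tofr.shape:
            raise TraceFormatError("time and TOFR arrays differ in length")
        if len(self.t_seconds) and np.any(np.diff(self.t_seconds) <= 0):
            raise TraceFormatError("trace timestamps must be strictly increasing")
        if np.any(self.tofr < 0):
            raise TraceFormatError("TOFR readings must be >= 0")

    def __len__(self) -> int:
        return len(self.tofr)

    @property
    def is_empty(self) -> bool:
        return len(self) == 0

    def scaled(self, factor: float) -> "EmgTrace":
        """Trace with every reading multiplied by ``factor`` (gain change)."""
        return EmgTrace(self.t_seconds.copy(), self.tofr * factor)

    @classmethod
    def empty(cls) -> "EmgTrace":
        return cls(np.empty(0), np.empty(0))


@dataclass
class PatientRecord:
    """One assessed patient: scores, instrumental TOFRs and QC inputs."""

    id: str
    true_tofr: float
    emg_tofr: float
    amg_tofr: float
    t1_t0: float
    tactile_fading: str
    scores: TestScores
    intraoral_surgery: bool = False
    trace: Optional[EmgTrace] = None

    def validate(self) -> None:
        if self.emg_tofr < 0 or self.amg_tofr < 0 or self.t1_t0 < 0:
            raise ValueError("TOFR and T1/T0 values must be >= 0")
        if self.tactile_fading not in (PALPABLE, NOT_PALPABLE):
            raise ValueError(f"unknown tactile judgement {self.tactile_fading!r}")
        allow = INTRAORAL_MISSING if self.intraoral_surgery else ()
        self.scores.validate(allow_missing=allow)
        if self.trace is not None:
            self.trace.validate()


# ---------------------------------------------------------------------------
# CSV round-tripping (one row per patient; traces in a long-format sidecar).

_COHORT_COLUMNS = [
    "id", "true_tofr", "emg_tofr", "amg_tofr", "t1_t0", "tactile_fading",
    *TEST_NAMES, "intraoral_surgery",
]


def cohort_to_frame(records: Iterable[PatientRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row: dict = {
            "id": r.id,
            "true_tofr": r.true_tofr,
            "emg_tofr": r.emg_tofr,
            "amg_tofr": r.amg_tofr,
            "t1_t0": r.t1_t0,
            "tactile_fading": r.tactile_fading,
            "intraoral_surgery": r.intraoral_surgery,
        }
        row.update(r.scores.as_dict())
        rows.append(row)
    return pd.DataFrame(rows, columns=_COHORT_COLUMNS)


def traces_to_frame(records: Iterable[PatientRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        if r.trace is None:
            continue
        for t, v in zip(r.trace.t_seconds, r.trace.tofr):
            rows.append({"id": r.id, "t_seconds": t, "tofr": v})
    return pd.DataFrame(rows, columns=["id", "t_seconds", "tofr"])


def frame_to_cohort(
    cohort: pd.DataFrame, traces: Optional[pd.DataFrame] = None
) -> list[PatientRecord]:
    trace_map: dict[str, EmgTrace] = {}
    if traces is not None and len(traces):
        for pid, grp in traces.groupby("id", sort=False):
            trace_map[str(pid)] = EmgTrace(
                grp["t_seconds"].to_numpy(), grp["tofr"].to_numpy()
            )
    records = []
    for _, row in cohort.iterrows():
        scores = TestScores(
            **{
                k: (None if pd.isna(row[k]) else int(row[k]))
                for k in TEST_NAMES
            }
        )
        pid = str(row["id"])
        records.append(
            PatientRecord(
                id=pid,
                true_tofr=float(row["true_tofr"]),
                emg_tofr=float(row["emg_tofr"]),
                amg_tofr=float(row["amg_tofr"]),
                t1_t0=float(row["t1_t0"]),
                tactile_fading=str(row["tactile_fading"]),
                scores=scores,
                intraoral_surgery=bool(row["intraoral_surgery"]),
                trace=trace_map.get(pid, EmgTrace.empty()),
            )
        )
    return records


def write_cohort_csv(
    records: Sequence[PatientRecord],
    cohort_path: str | Path,
    trace_path: Optional[str | Path] = None,
) -> None:
    cohort_to_frame(records).to_csv(cohort_path, index=False)
    if trace_path is not None:
        traces_to_frame(records).to_csv(trace_path, index=False)


def read_cohort_csv(
    cohort_path: str | Path, trace_path: Optional[str | Path] = None
) -> list[PatientRecord]:
    cohort = pd.read_csv(cohort_path)
    traces = pd.read_csv(trace_path) if trace_path is not None else None
    return frame_to_cohort(cohort, traces)
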