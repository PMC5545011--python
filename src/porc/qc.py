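"""Analysability rules: EMG-stability screening and exclusion bookkeeping.

Neuromuscular monitoring in awake patients is artefact-prone, so a trace
review step decides which patients are analysable: a record is excluded when
no EMG data could be obtained or when the TOFR dropped by more than 20% at
least twice during the assessment.  Patients after intraoral surgery are
excluded separately because the swallowing and spatula tests cannot be
performed.  The ledger keeps the exclusion reasons a disjoint partition of
the enrolled cohort (instability is attributed first).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np

from .cohort import EmgTrace, PatientRecord

DropRule = Literal["consecutive", "running_max"]

REASON_OK = "ok"
REASON_NO_DATA = "no_data"
REASON_EXCESS_DROPS = "excess_drops"


@dataclass(frozen=True)
class StabilityResult:
    """Outcome of the 20%-drop stability review of one EMG trace."""

    n_drops: int
    stable: bool
    reason: str


def count_drops(trace: EmgTrace, rule: DropRule = "consecutive") -> int:
    """Count relative TOFR drops exceeding 20%.

    ``consecutive`` (default) compares each reading with its predecessor;
    ``running_max`` compares each reading with the running maximum seen so
    far, a stricter drop-from-reference reading of the same rule.  Both are
    invariant to rescaling the whole trace.
    """
    trace.validate()
    x = trace.tofr
    if len(x) < 2:
        return 0
    if rule == "consecutive":
        ref = x[:-1]
    elif rule == "running_max":
        ref = np.maximum.accumulate(x)[:-1]
    else:
        raise ValueError(f"unknown drop rule {rule!r}")
    curr = x[1:]
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(ref > 0, (ref - curr) / ref, 0.0)
    return int(np.sum(rel > 0.20))


def assess_stability(trace: EmgTrace, rule: DropRule = "consecutive") -> StabilityResult:
    """Classify one trace as stable or not under the 20%-twice rule.

    A trace is stable iff it is non-empty and shows at most one relative
    drop greater than 20%; two or more drops, or an empty trace, exclude the
    patient from analysis.
    """
    if trace is None or trace.is_empty:
        return StabilityResult(n_drops=0, stable=False, reason=REASON_NO_DATA)
    n = count_drops(trace, rule=rule)
    if n >= 2:
        return StabilityResult(n_drops=n, stable=False, reason=REASON_EXCESS_DROPS)
    return StabilityResult(n_drops=n, stable=True, reason=REASON_OK)


@dataclass(frozen=True)
class ExclusionLedger:
    """Counts of enrolled, excluded-by-reason and analysable patients."""

    enrolled: int
    unstable: int
    intraoral: int
    analysable: int

    def __post_init__(self) -> None:
        if self.enrolled != self.unstable + self.intraoral + self.analysable:
            raise ValueError("ledger counts must partition the enrolled cohort")

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def apply_exclusions(
    cohort: Sequence[PatientRecord], rule: DropRule = "consecutive"
) -> tuple[list[PatientRecord], ExclusionLedger]:
    """Split a cohort into analysable patients and an exclusion ledger.

    Instability is checked first, so a patient who is both unstable and
    post-intraoral counts under instability; the two reasons partition the
    excluded set.  Idempotent: re-applying to the analysable cohort excludes
    nobody.
    """
    analysable: list[PatientRecord] = []
    n_unstable = 0
    n_intraoral = 0
    for rec in cohort:
        stab = assess_stability(rec.trace if rec.trace is not None else EmgTrace.empty(),
                                rule=rule)
        if not stab.stable:
            n_unstable += 1
        elif rec.intraoral_surgery:
            n_intraoral += 1
        else:
            analysable.append(rec)
    ledger = ExclusionLedger(
        enrolled=len(cohort),
        unstable=n_unstable,
        intraoral=n_intraoral,
        analysable=len(analysable),
    )
    return analysable, ledger
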