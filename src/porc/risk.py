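"""Prevalence-dependent risk of overlooking residual block; sample size.

A tool that passes a patient as recovered (tool TOFR > epsilon, or the
algorithm's pass node) can still be wrong.  The posterior probability of a
missed block,

    P(TOFR_EMG < eps | tool passes)
        = p (1 - sens) / (p (1 - sens) + (1 - p) spec),

depends only on the tool's sensitivity and specificity at the cut-off and
on the (generally unknown) prevalence p of block at that cut-off — it is
1 - NPV by Bayes' theorem.  Two boundary facts drive the clinical reading:
a tool with sensitivity 1 has zero overlook risk at any prevalence, and a
tool with specificity 0 (tactile fading at the 0.9 cut) carries 100% risk
whenever sens < 1 and p > 0.

Confidence envelopes around the risk curve substitute the CI endpoints of
sens and spec (lower envelope: both upper endpoints; upper envelope: both
lower endpoints) — conservative and assumption-free.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import math

import numpy as np
from scipy import stats

from .diagnostics import clopper_pearson


@dataclass(frozen=True)
class RiskInput:
    """Sensitivity/specificity of one tool at one TOFR cut-off."""

    epsilon: float
    prevalence: float
    sens: float
    spec: float

    def __post_init__(self) -> None:
        for name in ("prevalence", "sens", "spec"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


def overlook_risk(sens: float, spec: float, prevalence: float) -> float:
    """P(block | tool passes) for given sensitivity, specificity, prevalence.

    Exact evaluation of the posterior-odds formula.  The degenerate case of
    a zero denominator can only occur with a zero numerator (the tool never
    passes anyone); it is defined as risk 0 with a warning.
    """
    for name, v in (("sens", sens), ("spec", spec), ("prevalence", prevalence)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {v}")
    num = prevalence * (1.0 - sens)
    den = num + (1.0 - prevalence) * spec
    if den == 0.0:
        warnings.warn(
            "overlook risk undefined (tool never passes a patient); "
            "returning 0", stacklevel=2,
        )
        return 0.0
    return num / den


def overlook_risk_input(inp: RiskInput) -> float:
    return overlook_risk(inp.sens, inp.spec, inp.prevalence)


@dataclass
class RiskCurve:
    """Overlook risk across a prevalence grid, with optional CI envelope."""

    prevalence: np.ndarray
    risk: np.ndarray
    lower: Optional[np.ndarray] = None
    upper: Optional[np.ndarray] = None

    def as_columns(self) -> dict[str, np.ndarray]:
        out = {"prevalence": self.prevalence, "risk": self.risk}
        if self.lower is not None:
            out["lower"] = self.lower
        if self.upper is not None:
            out["upper"] = self.upper
        return out


def risk_curve(
    sens: float,
    spec: float,
    prevalence_grid: Sequence[float],
    sens_ci: Optional[tuple[float, float]] = None,
    spec_ci: Optional[tuple[float, float]] = None,
) -> RiskCurve:
    """Overlook-risk curve over a prevalence grid.

    The point curve uses the point estimates; when CIs for sens and spec are
    supplied, the envelope substitutes endpoints: the lower envelope takes
    the upper ends of both intervals (best-case tool), the upper envelope
    the lower ends (worst-case tool).  The envelope contains the point
    curve everywhere.
    """
    grid = np.asarray(prevalence_grid, dtype=float)
    if np.any((grid < 0) | (grid > 1)):
        raise ValueError("prevalence grid must lie in [0, 1]")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        point = np.array([overlook_risk(sens, spec, p) for p in grid])
        lower = upper = None
        if sens_ci is not None and spec_ci is not None:
            lower = np.array(
                [overlook_risk(sens_ci[1], spec_ci[1], p) for p in grid]
            )
            upper = np.array(
                [overlook_risk(sens_ci[0], spec_ci[0], p) for p in grid]
            )
    return RiskCurve(prevalence=grid, risk=point, lower=lower, upper=upper)


# ---------------------------------------------------------------------------
# Sample size for a sensitivity estimate


def sample_size_sensitivity(
    target_sens: float,
    ci_halfwidth: float,
    confidence: float = 0.95,
    method: str = "wald",
) -> int:
    """Diseased patients needed to estimate sensitivity to a CI half-width.

    ``wald``: smallest n with z^2 s(1-s)/n <= h^2 (normal approximation).
    ``exact``: smallest n whose Clopper-Pearson interval at the integer
    count nearest n*s has half-width (upper - lower)/2 <= h.
    """
    if not 0.0 < target_sens < 1.0:
        raise ValueError("target_sens must lie in (0, 1)")
    if not 0.0 < ci_halfwidth < 1.0:
        raise ValueError("ci_halfwidth must lie in (0, 1)")
    if method == "wald":
        z = stats.norm.ppf(1.0 - (1.0 - confidence) / 2.0)
        n = z ** 2 * target_sens * (1.0 - target_sens) / ci_halfwidth ** 2
        return max(1, math.ceil(n - 1e-12))
    if method == "exact":
        for n in range(1, 1_000_000):
            x = round(n * target_sens)
            lo, hi = clopper_pearson(x, n, confidence)
            if (hi - lo) / 2.0 <= ci_halfwidth:
                return n
        raise RuntimeError("no sample size below 10^6 met the precision target")
    raise ValueError(f"unknown method {method!r}")
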