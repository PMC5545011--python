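"""Diagnostic-accuracy evaluation of residual-block detection tools.

Any tool (the clinical algorithm, uncalibrated AMG, tactile fading after
nerve stimulation) is evaluated against the EMG-measured train-of-four
ratio as gold standard.  The positive class is residual block, defined by a
strict cut: EMG TOFR < epsilon, with epsilon = 0.7 (historical) or 0.9
(modern).  Sensitivity and specificity come with exact (Clopper-Pearson)
binomial confidence intervals; discrimination is summarised by empirical
ROC curves whose trapezoid area equals the tie-corrected Mann-Whitney
concordance, and two tools measured on the same patients are compared with
the DeLong paired AUC test (a paired bootstrap alternative is provided).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .cohort import NOT_PALPABLE, PALPABLE
from .errors import UndefinedMarginError

BLOCK = "block"
NO_BLOCK = "no_block"


# ---------------------------------------------------------------------------
# Dichotomisation


def dichotomize_reference(emg_tofr: float, epsilon: float) -> str:
    """Gold-standard label: residual block iff EMG TOFR < epsilon (strict)."""
    if not 0.0 < epsilon < 1.3:
        raise ValueError("epsilon must lie in (0, 1.3)")
    return BLOCK if emg_tofr < epsilon else NO_BLOCK


def dichotomize_tactile(judgement: str) -> str:
    """Map the examiner's fading judgement to a block prediction."""
    j = judgement.strip().lower().replace("_", " ")
    if j == PALPABLE:
        return BLOCK
    if j == NOT_PALPABLE:
        return NO_BLOCK
    raise ValueError(f"unknown tactile judgement {judgement!r}")


# ---------------------------------------------------------------------------
# Exact binomial interval


def clopper_pearson(
    successes: int, trials: int, confidence: float = 0.95
) -> tuple[float, float]:
    """Exact (Clopper-Pearson) binomial confidence interval.

    Beta-quantile form: lower = Beta(alpha/2; x, n-x+1), upper =
    Beta(1-alpha/2; x+1, n-x), with the conventional closures lower = 0 at
    x = 0 and upper = 1 at x = n.
    """
    if trials < 1:
        raise UndefinedMarginError("trials must be >= 1")
    if not 0 <= successes <= trials:
        raise ValueError("successes must lie in [0, trials]")
    if not 0.0 < confidence < 1.0:
        raise ValueError("confidence must lie in (0, 1)")
    alpha = 1.0 - confidence
    lower = 0.0 if successes == 0 else float(
        stats.beta.ppf(alpha / 2.0, successes, trials - successes + 1)
    )
    upper = 1.0 if successes == trials else float(
        stats.beta.ppf(1.0 - alpha / 2.0, successes + 1, trials - successes)
    )
    return lower, upper


# ---------------------------------------------------------------------------
# 2x2 accuracy


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts; positive = residual block (EMG TOFR < epsilon)."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("counts must be >= 0")

    @property
    def n_diseased(self) -> int:
        return self.tp + self.fn

    @property
    def n_healthy(self) -> int:
        return self.tn + self.fp

    @classmethod
    def from_labels(
        cls, predicted_block: Sequence[bool], true_block: Sequence[bool]
    ) -> "ContingencyTable":
        pred = np.asarray(predicted_block, dtype=bool)
        true = np.asarray(true_block, dtype=bool)
        if pred.shape != true.shape:
            raise ValueError("prediction and reference lengths differ")
        return cls(
            tp=int(np.sum(pred & true)),
            fp=int(np.sum(pred & ~true)),
            fn=int(np.sum(~pred & true)),
            tn=int(np.sum(~pred & ~true)),
        )


@dataclass(frozen=True)
class DiagnosticAccuracy:
    """Sensitivity/specificity with exact CIs at one TOFR cut-off."""

    sens: float
    spec: float
    sens_ci: tuple[float, float]
    spec_ci: tuple[float, float]
    epsilon: float
    table: ContingencyTable
    confidence: float = 0.95


def sens_spec(
    table: ContingencyTable, confidence: float = 0.95, epsilon: float = 0.9
) -> DiagnosticAccuracy:
    """Point estimates and exact intervals from a 2x2 table.

    Raises :class:`UndefinedMarginError` when either margin (diseased or
    non-diseased) is empty.
    """
    if table.n_diseased < 1:
        raise UndefinedMarginError("no diseased patients: sensitivity undefined")
    if table.n_healthy < 1:
        raise UndefinedMarginError("no healthy patients: specificity undefined")
    sens = table.tp / table.n_diseased
    spec = table.tn / table.n_healthy
    return DiagnosticAccuracy(
        sens=sens,
        spec=spec,
        sens_ci=clopper_pearson(table.tp, table.n_diseased, confidence),
        spec_ci=clopper_pearson(table.tn, table.n_healthy, confidence),
        epsilon=epsilon,
        table=table,
        confidence=confidence,
    )


def evaluate_tool(
    predicted_block: Sequence[bool],
    emg_tofr: Sequence[float],
    epsilon: float,
    confidence: float = 0.95,
) -> DiagnosticAccuracy:
    """Evaluate a tool's block predictions against the EMG gold standard."""
    true = [dichotomize_reference(v, epsilon) == BLOCK for v in emg_tofr]
    table = ContingencyTable.from_labels(list(predicted_block), true)
    return sens_spec(table, confidence=confidence, epsilon=epsilon)


# ---------------------------------------------------------------------------
# ROC / AUC


@dataclass(frozen=True)
class RocResult:
    """Empirical ROC points and trapezoid AUC for one tool."""

    fpr: np.ndarray  # 1 - specificity, ascending
    tpr: np.ndarray  # sensitivity
    thresholds: np.ndarray
    auc: float
    n_pos: int
    n_neg: int


def roc(
    predictor: Sequence[float],
    is_block: Sequence[bool],
    block_low: bool = True,
) -> RocResult:
    """Empirical ROC of an ordinal predictor for residual block.

    ``block_low=True`` (default) fits TOFR-scale predictors — AMG readings
    or terminal nodes ordered by node mean TOFR — where LOW values indicate
    block; internally the predictor is negated so that higher score = more
    block-like, and the curve sweeps all decision thresholds.  The trapezoid
    area equals the Mann-Whitney concordance with half credit for ties.
    """
    y = np.asarray(is_block, dtype=bool)
    s = np.asarray(predictor, dtype=float)
    if s.shape != y.shape:
        raise ValueError("predictor and label lengths differ")
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to form a ROC curve")
    if block_low:
        s = -s
    order = np.argsort(-s, kind="mergesort")
    s_sorted = s[order]
    y_sorted = y[order]
    # cumulative counts at each distinct threshold (predict block if s >= t)
    distinct = np.r_[np.nonzero(np.diff(s_sorted))[0], len(s_sorted) - 1]
    tps = np.cumsum(y_sorted)[distinct]
    fps = np.cumsum(~y_sorted)[distinct]
    tpr = np.r_[0.0, tps / n_pos]
    fpr = np.r_[0.0, fps / n_neg]
    thresholds = np.r_[np.inf, s_sorted[distinct]]
    auc = float(np.trapezoid(tpr, fpr))
    return RocResult(fpr=fpr, tpr=tpr, thresholds=thresholds, auc=auc,
                     n_pos=n_pos, n_neg=n_neg)


def auc_concordance(
    predictor: Sequence[float],
    is_block: Sequence[bool],
    block_low: bool = True,
) -> float:
    """AUC as the pairwise concordance (Mann-Whitney) statistic.

    Computed via midranks; equals the trapezoid ROC area exactly, ties
    counting half.
    """
    y = np.asarray(is_block, dtype=bool)
    s = np.asarray(predictor, dtype=float)
    if block_low:
        s = -s
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(s, method="average")
    return float((ranks[y].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


# ---------------------------------------------------------------------------
# Paired AUC comparison (DeLong)


@dataclass(frozen=True)
class AucComparison:
    auc_a: float
    auc_b: float
    diff: float
    p_value: float
    method: str
    z: Optional[float] = None


def _placement_values(scores: np.ndarray, y: np.ndarray) -> tuple[
    float, np.ndarray, np.ndarray
]:
    """AUC and DeLong placement values for one predictor (higher = block)."""
    pos = scores[y]
    neg = scores[~y]
    m, n = len(pos), len(neg)
    tz = stats.rankdata(np.r_[pos, neg], method="average")
    tx = stats.rankdata(pos, method="average")
    ty = stats.rankdata(neg, method="average")
    v01 = (tz[:m] - tx) / n            # per diseased patient
    v10 = 1.0 - (tz[m:] - ty) / m      # per healthy patient
    auc = float((tz[:m].sum() - m * (m + 1) / 2.0) / (m * n))
    return auc, v01, v10


def compare_auc(
    predictor_a: Sequence[float],
    predictor_b: Sequence[float],
    is_block: Sequence[bool],
    block_low: bool = True,
) -> AucComparison:
    """DeLong paired test for the difference of two correlated AUCs.

    Both predictors must be measured on the same patients.  The variance of
    the AUC difference comes from the empirical covariance of the placement
    values; identical predictors give diff = 0 and p = 1.
    """
    a = np.asarray(predictor_a, dtype=float)
    b = np.asarray(predictor_b, dtype=float)
    y = np.asarray(is_block, dtype=bool)
    if not (a.shape == b.shape == y.shape):
        raise ValueError("paired comparison requires equal-length inputs on "
                         "the same patients")
    if y.all() or not y.any():
        raise ValueError("both classes must be present")
    if block_low:
        a, b = -a, -b
    auc_a, v01_a, v10_a = _placement_values(a, y)
    auc_b, v01_b, v10_b = _placement_values(b, y)
    m, n = len(v01_a), len(v10_a)
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1) if n > 1 else np.zeros((2, 2))
    var = (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / m \
        + (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / n
    diff = auc_a - auc_b
    if var <= 0:
        z = 0.0
        p = 1.0 if diff == 0 else 0.0
    else:
        z = diff / np.sqrt(var)
        p = float(2.0 * stats.norm.sf(abs(z)))
    return AucComparison(auc_a=auc_a, auc_b=auc_b, diff=diff, p_value=p,
                         method="delong", z=float(z))


def compare_auc_bootstrap(
    predictor_a: Sequence[float],
    predictor_b: Sequence[float],
    is_block: Sequence[bool],
    block_low: bool = True,
    n_boot: int = 10_000,
    seed: int = 0,
) -> AucComparison:
    """Paired-bootstrap alternative to the DeLong test.

    Patients are resampled with replacement ``n_boot`` times; the two-sided
    p-value inverts the percentile distribution of the AUC difference.
    Resamples missing one of the classes are redrawn implicitly by being
    skipped.
    """
    a = np.asarray(predictor_a, dtype=float)
    b = np.asarray(predictor_b, dtype=float)
    y = np.asarray(is_block, dtype=bool)
    if not (a.shape == b.shape == y.shape):
        raise ValueError("paired comparison requires equal-length inputs")
    rng = np.random.default_rng(seed)
    auc_a = auc_concordance(a, y, block_low=block_low)
    auc_b = auc_concordance(b, y, block_low=block_low)
    diffs = []
    n = len(y)
    while len(diffs) < n_boot:
        idx = rng.integers(0, n, size=n)
        yy = y[idx]
        if yy.all() or not yy.any():
            continue
        diffs.append(
            auc_concordance(a[idx], yy, block_low=block_low)
            - auc_concordance(b[idx], yy, block_low=block_low)
        )
    diffs = np.asarray(diffs)
    p_lo = float(np.mean(diffs <= 0.0))
    p_hi = float(np.mean(diffs >= 0.0))
    p = min(1.0, 2.0 * min(p_lo, p_hi))
    return AucComparison(auc_a=auc_a, auc_b=auc_b, diff=auc_a - auc_b,
                         p_value=p, method="bootstrap")


# ---------------------------------------------------------------------------
# Correlation


def model_correlation(
    tool_values: Sequence[float],
    emg_tofr: Sequence[float],
    method: str = "spearman",
) -> float:
    """Correlation between a tool's output and the EMG TOFR.

    Spearman by default (tool outputs are ordinal); Pearson available.
    """
    x = np.asarray(tool_values, dtype=float)
    y = np.asarray(emg_tofr, dtype=float)
    if len(x) < 3 or x.shape != y.shape:
        raise ValueError("need >= 3 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    if method == "spearman":
        return float(stats.spearmanr(x, y).statistic)
    if method == "pearson":
        return float(stats.pearsonr(x, y).statistic)
    raise ValueError(f"unknown correlation method {method!r}")
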