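"""Diagnostic accuracy of a probability score against a binary reference.

Conventions
-----------
* *Screener-positive* means the predicted probability is **strictly
  greater** than the cut-off; a score exactly equal to the cut-off is
  screener-negative. This matches the <=/ > split conventional for
  probability cut-off tables.
* Sensitivity = TP/(TP+FN), specificity = TN/(TN+FP), PPV = TP/(TP+FP),
  NPV = TN/(TN+FN). A metric with a zero denominator is reported as
  undefined (NaN), never as 0.
* Proportion confidence intervals default to Clopper-Pearson exact
  (Wilson and Wald selectable).
* The empirical ROC curve is evaluated at every distinct score plus
  sentinels; the trapezoidal AUC equals the Mann-Whitney two-sample
  statistic with ties counted 1/2.
* The AUC confidence interval uses DeLong's placement-based variance
  (Hanley-McNeil available as an alternative).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from pro55.errors import ContractError, DegenerateDataError, InvalidInputError

CI_METHODS = ("clopper_pearson", "wilson", "wald")
_STATSMODELS_NAMES = {"clopper_pearson": "beta", "wilson": "wilson", "wald": "normal"}


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConfusionTable:
    """2x2 cross-tabulation of screener result vs reference classification."""

    tp: int
    fp: int
    fn: int
    tn: int
    cutoff: float = float("nan")
    threshold: float = float("nan")

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise InvalidInputError(f"{name} must be >= 0")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def n_positive(self) -> int:
        """Reference-positive (low intake) count."""
        return self.tp + self.fn

    @property
    def n_negative(self) -> int:
        return self.fp + self.tn


@dataclass(frozen=True)
class MetricEstimate:
    """A proportion-type accuracy metric with its confidence interval.

    ``estimate`` is ``k / n``; all three of estimate/ci bounds are NaN when
    the denominator is zero (undefined metric).
    """

    name: str
    k: int
    n: int
    estimate: float
    ci_low: float
    ci_high: float
    ci_method: str
    ci_level: float

    @property
    def defined(self) -> bool:
        return self.n > 0


@dataclass(frozen=True)
class RocResult:
    """Empirical ROC curve with AUC and the best-trade-off operating point.

    ``operating_points`` is ordered by decreasing cut-off: (inf, 0, 0)
    first, (-inf, 1, 1) last, with one point per distinct observed score in
    between; tpr and fpr are non-decreasing along the list.
    """

    cutoffs: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    auc_ci_low: float = float("nan")
    auc_ci_high: float = float("nan")
    youden_cutoff: float = float("nan")
    youden_sens: float = float("nan")
    youden_spec: float = float("nan")

    @property
    def operating_points(self) -> list[tuple[float, float, float]]:
        return list(zip(self.cutoffs.tolist(), self.tpr.tolist(), self.fpr.tolist()))


# ---------------------------------------------------------------------------
# confusion tables and proportion metrics
# ---------------------------------------------------------------------------


def _check_scores_labels(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ContractError(
            f"scores and labels must be aligned 1-d arrays, got {scores.shape} vs {labels.shape}"
        )
    if scores.size == 0:
        raise ContractError("empty input")
    if np.any(~np.isfinite(scores)) or np.any(scores < 0) or np.any(scores > 1):
        raise InvalidInputError("scores must be probabilities in [0, 1]")
    return scores, labels


def confusion_at_cutoff(
    scores, labels, cutoff: float, threshold: float = float("nan")
) -> ConfusionTable:
    """Cross-tabulate screener result (score > cutoff) against the reference.

    ``labels`` are True for reference-positive (low protein intake). A
    score exactly equal to the cut-off counts as screener-negative.
    """
    scores, labels = _check_scores_labels(scores, labels)
    pos = scores > cutoff
    return ConfusionTable(
        tp=int(np.sum(pos & labels)),
        fp=int(np.sum(pos & ~labels)),
        fn=int(np.sum(~pos & labels)),
        tn=int(np.sum(~pos & ~labels)),
        cutoff=float(cutoff),
        threshold=threshold,
    )


def proportion_ci(
    k: int, n: int, method: str = "clopper_pearson", level: float = 0.95
) -> tuple[float, float]:
    """Confidence interval for a binomial proportion k/n.

    Clopper-Pearson (exact, by beta-quantile inversion of the binomial
    tails), Wilson score, or Wald. k=0 gives a lower bound of exactly 0,
    k=n an upper bound of exactly 1.
    """
    if n <= 0 or k < 0 or k > n:
        raise InvalidInputError(f"need 0 <= k <= n with n > 0, got k={k}, n={n}")
    if method not in CI_METHODS:
        raise InvalidInputError(f"unknown CI method {method!r}; choose from {CI_METHODS}")
    if not 0 < level < 1:
        raise InvalidInputError("level must be in (0, 1)")
    low, high = proportion_confint(k, n, alpha=1 - level, method=_STATSMODELS_NAMES[method])
    return float(np.clip(low, 0.0, 1.0)), float(np.clip(high, 0.0, 1.0))


def _metric(
    name: str, k: int, n: int, method: str, level: float
) -> MetricEstimate:
    if n == 0:
        nan = float("nan")
        return MetricEstimate(name, 0, 0, nan, nan, nan, method, level)
    low, high = proportion_ci(k, n, method=method, level=level)
    return MetricEstimate(name, k, n, k / n, low, high, method, level)


def accuracy_metrics(
    table: ConfusionTable,
    ci_method: str = "clopper_pearson",
    level: float = 0.95,
) -> dict[str, MetricEstimate]:
    """Sensitivity, specificity, PPV and NPV for one confusion table."""
    return {
        "sensitivity": _metric(
            "sensitivity", table.tp, table.tp + table.fn, ci_method, level
        ),
        "specificity": _metric(
            "specificity", table.tn, table.tn + table.fp, ci_method, level
        ),
        "ppv": _metric("ppv", table.tp, table.tp + table.fp, ci_method, level),
        "npv": _metric("npv", table.tn, table.tn + table.fn, ci_method, level),
    }


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------


def roc_curve(scores, labels) -> RocResult:
    """Empirical ROC over all distinct score cut-offs, with trapezoidal AUC.

    Operating points use the strict "score > cutoff" positivity rule at
    each distinct observed score, bracketed by (inf, 0, 0) and
    (-inf, 1, 1) sentinels. The trapezoidal area equals the probability
    that a random reference-positive outscores a random reference-negative,
    ties counted one half (the Mann-Whitney statistic).
    """
    scores, labels = _check_scores_labels(scores, labels)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise DegenerateDataError(
            f"ROC needs both classes; got {n_pos} positives and {n_neg} negatives"
        )
    cut = np.unique(scores)[::-1]  # descending distinct scores
    pos_sorted = np.sort(scores[labels])
    neg_sorted = np.sort(scores[~labels])
    # count strictly greater than each cutoff via searchsorted on sorted class scores
    tpr = 1.0 - np.searchsorted(pos_sorted, cut, side="right") / n_pos
    fpr = 1.0 - np.searchsorted(neg_sorted, cut, side="right") / n_neg
    cutoffs = np.concatenate(([np.inf], cut, [-np.inf]))
    tpr = np.concatenate(([0.0], tpr, [1.0]))
    fpr = np.concatenate(([0.0], fpr, [1.0]))
    auc = float(np.trapezoid(tpr, fpr))
    yc, ys, ysp = _youden(cutoffs, tpr, fpr)
    return RocResult(
        cutoffs=cutoffs, tpr=tpr, fpr=fpr, auc=auc,
        youden_cutoff=yc, youden_sens=ys, youden_spec=ysp,
    )


def _youden(cutoffs: np.ndarray, tpr: np.ndarray, fpr: np.ndarray):
    finite = np.isfinite(cutoffs)
    j = tpr[finite] - fpr[finite]
    c = cutoffs[finite]
    best = np.max(j)
    # ties resolved toward the lower cut-off (higher sensitivity), fitting
    # the screener's rule-out use
    idx = np.where(j >= best - 1e-12)[0]
    pick = idx[np.argmin(c[idx])]
    return float(c[pick]), float(tpr[finite][pick]), 1.0 - float(fpr[finite][pick])


def best_tradeoff_cutoff(roc: RocResult) -> tuple[float, float, float]:
    """Observed cut-off maximising sensitivity + specificity (Youden index).

    Returns (cutoff, sensitivity, specificity); ties go to the lower
    cut-off, i.e. the more sensitive operating point.
    """
    return _youden(roc.cutoffs, roc.tpr, roc.fpr)


def _placements(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """DeLong placement values V10 (per positive) and V01 (per negative)."""
    pos = scores[labels]
    neg = scores[~labels]
    neg_sorted = np.sort(neg)
    pos_sorted = np.sort(pos)
    m, n = pos.size, neg.size
    # P(neg < pos_i) + 0.5 P(neg == pos_i)
    lt = np.searchsorted(neg_sorted, pos, side="left")
    le = np.searchsorted(neg_sorted, pos, side="right")
    v10 = (lt + 0.5 * (le - lt)) / n
    gt = m - np.searchsorted(pos_sorted, neg, side="right")
    ge = m - np.searchsorted(pos_sorted, neg, side="left")
    v01 = (gt + 0.5 * (ge - gt)) / m
    return v10, v01


def delong_variance(scores, labels) -> tuple[float, float]:
    """AUC and its DeLong variance estimate.

    Requires at least two members per class (the placement variances use
    n-1 denominators).
    """
    scores, labels = _check_scores_labels(scores, labels)
    m = int(labels.sum())
    n = int((~labels).sum())
    if m < 2 or n < 2:
        raise DegenerateDataError("DeLong variance needs >= 2 members in each class")
    v10, v01 = _placements(scores, labels)
    auc = float(v10.mean())
    var = float(np.var(v10, ddof=1) / m + np.var(v01, ddof=1) / n)
    return auc, var


def hanley_mcneil_variance(auc: float, n_pos: int, n_neg: int) -> float:
    """Hanley-McNeil approximate AUC variance (exponential-model moments)."""
    q1 = auc / (2 - auc)
    q2 = 2 * auc**2 / (1 + auc)
    return (
        auc * (1 - auc)
        + (n_pos - 1) * (q1 - auc**2)
        + (n_neg - 1) * (q2 - auc**2)
    ) / (n_pos * n_neg)


def auc_ci(
    scores, labels, level: float = 0.95, method: str = "delong"
) -> tuple[float, float]:
    """Wald-type AUC confidence interval, truncated to [0, 1].

    ``method`` is ``"delong"`` (placement-based variance, default) or
    ``"hanley_mcneil"``.
    """
    if method == "delong":
        auc, var = delong_variance(scores, labels)
    elif method == "hanley_mcneil":
        scores_, labels_ = _check_scores_labels(scores, labels)
        roc = roc_curve(scores_, labels_)
        auc = roc.auc
        var = hanley_mcneil_variance(auc, int(labels_.sum()), int((~labels_).sum()))
    else:
        raise InvalidInputError(f"unknown AUC CI method {method!r}")
    z = stats.norm.ppf(0.5 + level / 2)
    half = z * math.sqrt(var)
    return float(max(0.0, auc - half)), float(min(1.0, auc + half))


def roc_with_ci(scores, labels, level: float = 0.95, method: str = "delong") -> RocResult:
    """Convenience: :func:`roc_curve` with the AUC interval filled in."""
    roc = roc_curve(scores, labels)
    low, high = auc_ci(scores, labels, level=level, method=method)
    return RocResult(
        cutoffs=roc.cutoffs, tpr=roc.tpr, fpr=roc.fpr, auc=roc.auc,
        auc_ci_low=low, auc_ci_high=high,
        youden_cutoff=roc.youden_cutoff, youden_sens=roc.youden_sens,
        youden_spec=roc.youden_spec,
    )
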