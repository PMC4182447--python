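"""Diagnostic statistics for grading: ROC/Youden/DeLong, LOOCV, McNemar,
group comparisons and Pearson regression.

The ROC machinery operates on a single scalar feature per case with a binary
grade label. Direction is chosen automatically so that the AUC is >= 0.5
(entropy flags high grade when *high*, fifth-percentile ADC when *low*).
AUC equals the normalized Mann–Whitney U statistic (ties get half credit);
its variance and the paired AUC-difference test use the DeLong placement
estimator. Single-cutoff classification uses the Youden index
(sensitivity + specificity − 1), and leave-one-out cross-validation
re-estimates the cutoff (and direction) on each training fold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "ROCResult",
    "CutoffEvaluation",
    "LOOCVResult",
    "GroupTestResult",
    "RegressionResult",
    "roc_analysis",
    "youden_cutoff",
    "confusion_metrics",
    "compare_aucs",
    "loocv_accuracy",
    "mcnemar_test",
    "group_tests",
    "pearson_regression",
]


def _as_binary(labels) -> np.ndarray:
    y = np.asarray(labels)
    if y.dtype == bool:
        return y
    return np.asarray(y, dtype=float) > 0.5


def _check_two_classes(y: np.ndarray) -> None:
    if y.all() or not y.any():
        raise ValueError("both classes must be present")


def _auc_mwu(scores: np.ndarray, y: np.ndarray) -> float:
    """AUC as the normalized Mann–Whitney U (midranks give ties half credit)."""
    n1, n0 = int(y.sum()), int((~y).sum())
    r = sps.rankdata(scores)
    return float((r[y].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def _delong_placements(scores: np.ndarray, y: np.ndarray):
    """AUC and DeLong structural components (placement values)."""
    pos, neg = scores[y], scores[~y]
    n1, n0 = pos.size, neg.size
    all_r = sps.rankdata(np.concatenate([pos, neg]))
    pos_r = sps.rankdata(pos)
    neg_r = sps.rankdata(neg)
    v10 = (all_r[:n1] - pos_r) / n0          # per-positive placement
    v01 = 1.0 - (all_r[n1:] - neg_r) / n1    # per-negative placement
    auc = float(v10.mean())
    return auc, v10, v01


def _delong_variance(v10: np.ndarray, v01: np.ndarray) -> float:
    s10 = np.var(v10, ddof=1) if v10.size > 1 else 0.0
    s01 = np.var(v01, ddof=1) if v01.size > 1 else 0.0
    return float(s10 / v10.size + s01 / v01.size)


@dataclass(frozen=True)
class ROCResult:
    """Empirical ROC curve with DeLong AUC confidence interval.

    ``direction`` is "higher" if larger feature values indicate the positive
    class, else "lower". ``thresholds`` are in the original feature scale;
    at threshold t a case is called positive when value > t ("higher") or
    value <= t ("lower").
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    auc_ci: tuple[float, float]
    auc_se: float
    pvalue_vs_chance: float
    direction: str
    n_pos: int
    n_neg: int
    scores: np.ndarray = field(repr=False)
    labels: np.ndarray = field(repr=False)


@dataclass(frozen=True)
class CutoffEvaluation:
    """Confusion counts and metrics at one operating cutoff."""

    cutoff: float
    direction: str
    tp: int
    fn: int
    tn: int
    fp: int
    sensitivity: float
    specificity: float
    accuracy: float
    youden: float

    @property
    def rule(self) -> str:
        op = ">" if self.direction == "higher" else "<="
        return f"positive if value {op} {self.cutoff:g}"


@dataclass(frozen=True)
class LOOCVResult:
    """Per-case leave-one-out predictions from a per-fold Youden cutoff."""

    predicted: np.ndarray
    correct: np.ndarray
    accuracy: float  # percent
    fold_cutoffs: np.ndarray
    fold_directions: tuple[str, ...]
    degenerate_folds: int = 0


@dataclass(frozen=True)
class GroupTestResult:
    """Two-group t-test, overall one-way ANOVA, and gated Tukey post-hoc."""

    t_stat: float
    t_pvalue: float
    f_stat: float
    anova_pvalue: float
    posthoc_pvalues: dict[tuple[str, str], float] | None
    posthoc_performed: bool


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    pvalue: float


def _candidate_cutoffs(values: np.ndarray, direction: str) -> np.ndarray:
    """Midpoints between adjacent distinct values, plus the two extremes.

    Midpoint cutoffs realize every achievable confusion table while placing
    the decision boundary centrally in the separating gap — the choice that
    generalizes to held-out cases. The sentinels min−1 and max cover the
    all-positive and no-positive ends for either direction.
    """
    u = np.unique(values)
    mids = (u[:-1] + u[1:]) / 2.0
    return np.concatenate([[u[0] - 1.0], mids, [u[-1]]])


def _confusion_at(values: np.ndarray, y: np.ndarray, cutoff: float, direction: str):
    pred = values > cutoff if direction == "higher" else values <= cutoff
    tp = int((pred & y).sum())
    fp = int((pred & ~y).sum())
    fn = int((~pred & y).sum())
    tn = int((~pred & ~y).sum())
    return tp, fn, tn, fp


def roc_analysis(scores, labels, direction: str = "auto") -> ROCResult:
    """Empirical ROC over all distinct thresholds, AUC and DeLong 95% CI.

    ``direction="auto"`` orients the feature so AUC >= 0.5. The reported
    p-value tests AUC = 0.5 by the DeLong normal approximation.
    """
    x = np.asarray(scores, dtype=float)
    y = _as_binary(labels)
    if x.shape != y.shape:
        raise ValueError("scores and labels must have equal length")
    _check_two_classes(y)
    if direction not in ("auto", "higher", "lower"):
        raise ValueError(f"unknown direction {direction!r}")
    if direction == "auto":
        direction = "higher" if _auc_mwu(x, y) >= 0.5 else "lower"
    oriented = x if direction == "higher" else -x
    auc, v10, v01 = _delong_placements(oriented, y)
    var = _delong_variance(v10, v01)
    se = float(np.sqrt(var))
    lo, hi = (max(0.0, auc - 1.96 * se), min(1.0, auc + 1.96 * se))
    if se > 0:
        z = (auc - 0.5) / se
        p_chance = float(2 * sps.norm.sf(abs(z)))
    else:
        p_chance = 1.0 if auc == 0.5 else 0.0

    thr = _candidate_cutoffs(x, direction)
    sens = np.empty(thr.size)
    spec = np.empty(thr.size)
    for i, t in enumerate(thr):
        tp, fn, tn, fp = _confusion_at(x, y, t, direction)
        sens[i] = tp / (tp + fn)
        spec[i] = tn / (tn + fp)
    return ROCResult(
        thresholds=thr,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        auc_ci=(lo, hi),
        auc_se=se,
        pvalue_vs_chance=p_chance,
        direction=direction,
        n_pos=int(y.sum()),
        n_neg=int((~y).sum()),
        scores=x,
        labels=y,
    )


def youden_cutoff(roc: ROCResult) -> CutoffEvaluation:
    """Operating cutoff maximizing the Youden index sensitivity+specificity−1.

    Ties are broken toward higher specificity (the more conservative rule).
    """
    j = roc.sensitivity + roc.specificity - 1.0
    best = np.flatnonzero(np.isclose(j, j.max(), rtol=0, atol=1e-12))
    k = best[np.argmax(roc.specificity[best])]
    cutoff = float(roc.thresholds[k])
    tp, fn, tn, fp = _confusion_at(roc.scores, roc.labels, cutoff, roc.direction)
    sens, spec, acc = confusion_metrics(tp, fn, tn, fp)
    return CutoffEvaluation(
        cutoff=cutoff,
        direction=roc.direction,
        tp=tp, fn=fn, tn=tn, fp=fp,
        sensitivity=sens, specificity=spec, accuracy=acc,
        youden=float(j[k]),
    )


def confusion_metrics(tp: int, fn: int, tn: int, fp: int) -> tuple[float, float, float]:
    """Sensitivity, specificity and accuracy in percent from confusion counts."""
    counts = (tp, fn, tn, fp)
    if any(c < 0 or int(c) != c for c in counts):
        raise ValueError(f"counts must be non-negative integers, got {counts}")
    if tp + fn == 0 or tn + fp == 0:
        raise ValueError("both positive and negative classes must be non-empty")
    sens = 100.0 * tp / (tp + fn)
    spec = 100.0 * tn / (tn + fp)
    acc = 100.0 * (tp + tn) / (tp + fn + tn + fp)
    return sens, spec, acc


def compare_aucs(scores_a, scores_b, labels) -> float:
    """DeLong paired test for the AUC difference of two features on the same cases.

    Each feature is auto-oriented so its AUC >= 0.5 before comparison.
    Returns the two-sided p-value; identical scores give p = 1.
    """
    xa = np.asarray(scores_a, dtype=float)
    xb = np.asarray(scores_b, dtype=float)
    y = _as_binary(labels)
    if xa.shape != xb.shape or xa.shape != y.shape:
        raise ValueError("paired scores and labels must have equal length")
    _check_two_classes(y)
    xa = xa if _auc_mwu(xa, y) >= 0.5 else -xa
    xb = xb if _auc_mwu(xb, y) >= 0.5 else -xb
    auc_a, v10a, v01a = _delong_placements(xa, y)
    auc_b, v10b, v01b = _delong_placements(xb, y)
    n1, n0 = v10a.size, v01a.size
    var_a = _delong_variance(v10a, v01a)
    var_b = _delong_variance(v10b, v01b)
    cov = 0.0
    if n1 > 1:
        cov += float(np.cov(v10a, v10b, ddof=1)[0, 1]) / n1
    if n0 > 1:
        cov += float(np.cov(v01a, v01b, ddof=1)[0, 1]) / n0
    var_diff = var_a + var_b - 2 * cov
    diff = auc_a - auc_b
    if var_diff <= 0:
        return 1.0 if np.isclose(diff, 0.0) else 0.0
    z = diff / np.sqrt(var_diff)
    return float(2 * sps.norm.sf(abs(z)))


def loocv_accuracy(values, labels) -> LOOCVResult:
    """Leave-one-out validation of the single-feature Youden-cutoff classifier.

    For each case the cutoff (and direction) is re-estimated on the other
    n−1 cases and the held-out case is classified by it. A training fold
    that degenerates to one class predicts the fold's majority class.
    """
    x = np.asarray(values, dtype=float)
    y = _as_binary(labels)
    n = x.size
    if n < 3:
        raise ValueError(f"LOOCV requires n >= 3, got {n}")
    _check_two_classes(y)
    predicted = np.zeros(n, dtype=bool)
    cutoffs = np.full(n, np.nan)
    directions: list[str] = []
    degenerate = 0
    for i in range(n):
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        xt, yt = x[keep], y[keep]
        if yt.all() or not yt.any():
            degenerate += 1
            predicted[i] = yt.mean() >= 0.5
            directions.append("degenerate")
            continue
        ev = youden_cutoff(roc_analysis(xt, yt))
        cutoffs[i] = ev.cutoff
        directions.append(ev.direction)
        predicted[i] = x[i] > ev.cutoff if ev.direction == "higher" else x[i] <= ev.cutoff
    correct = predicted == y
    return LOOCVResult(
        predicted=predicted,
        correct=correct,
        accuracy=100.0 * float(correct.mean()),
        fold_cutoffs=cutoffs,
        fold_directions=tuple(directions),
        degenerate_folds=degenerate,
    )


def mcnemar_test(correct_a, correct_b) -> float:
    """Exact binomial McNemar test on the discordant pairs of two classifiers.

    ``correct_a``/``correct_b`` are paired per-case correctness booleans.
    Two-sided; with no discordant pairs the classifiers are indistinguishable
    and p = 1.
    """
    a = np.asarray(correct_a, dtype=bool)
    b = np.asarray(correct_b, dtype=bool)
    if a.shape != b.shape or a.size == 0:
        raise ValueError("correctness vectors must be non-empty and equal length")
    n_disc = int((a != b).sum())
    if n_disc == 0:
        return 1.0
    k = int((a & ~b).sum())
    return float(sps.binomtest(k, n_disc, 0.5, alternative="two-sided").pvalue)


def group_tests(
    values,
    classes,
    low_classes: Sequence[str] = ("II",),
    welch: bool = False,
    posthoc_alpha: float = 0.05,
) -> GroupTestResult:
    """Two-group t-test (low vs high), one-way ANOVA across all classes, and
    Tukey HSD post-hoc pairwise comparisons.

    The t-test is the classical pooled-variance unpaired Student test
    (``welch=True`` switches to unequal-variance). The post-hoc is performed
    only when the overall ANOVA is significant at ``posthoc_alpha``;
    otherwise ``posthoc_pvalues`` is None.
    """
    x = np.asarray(values, dtype=float)
    cls = np.asarray(classes)
    if x.shape != cls.shape:
        raise ValueError("values and classes must have equal length")
    groups = [x[cls == g] for g in np.unique(cls)]
    names = [str(g) for g in np.unique(cls)]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    low = np.isin(cls, np.asarray(low_classes))
    if not low.any() or low.all():
        raise ValueError("binary split yields an empty group")
    t_stat, t_p = sps.ttest_ind(x[~low], x[low], equal_var=not welch)
    f_stat, f_p = sps.f_oneway(*groups)
    posthoc = None
    performed = False
    if len(groups) > 2 and f_p < posthoc_alpha:
        res = pairwise_tukeyhsd(x, cls, alpha=posthoc_alpha)
        performed = True
        rows = res._results_table.data[1:]  # group1, group2, meandiff, ...
        posthoc = {
            (str(r[0]), str(r[1])): float(p) for r, p in zip(rows, res.pvalues)
        }
    return GroupTestResult(
        t_stat=float(t_stat),
        t_pvalue=float(t_p),
        f_stat=float(f_stat),
        anova_pvalue=float(f_p),
        posthoc_pvalues=posthoc,
        posthoc_performed=performed,
    )


def pearson_regression(x, y) -> RegressionResult:
    """Ordinary least squares y on x; R² is the squared Pearson correlation,
    p the two-sided test of slope = 0."""
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.shape != yv.shape or xv.size < 3:
        raise ValueError("x and y must have equal length >= 3")
    if np.ptp(xv) == 0:
        raise ValueError("x is constant; regression undefined")
    res = sps.linregress(xv, yv)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        pvalue=float(res.pvalue),
    )
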