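"""Diagnostic-test statistics: confusion-matrix metrics, agreement, ROC and
group comparisons.

Sensitivity, specificity, accuracy, PPV and NPV are kept as raw fractions and
reported as percents rounded half-up to the requested precision (clinical
tables mix integer and one-decimal styles; both are exposed).  Cohen's kappa,
McNemar's test and the empirical ROC with Youden's J cutoff are implemented
here directly — they are the quantities under evaluation — and are
cross-checked in the test suite against independent library implementations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ConfusionCounts",
    "DiagnosticMetrics",
    "AgreementResult",
    "ROCResult",
    "GroupTestReport",
    "ManualCytologyRecord",
    "MANUAL_FEATURES",
    "round_half_up",
    "wilson_interval",
    "metrics_from_counts",
    "cohen_kappa",
    "mcnemar_test",
    "roc_analysis",
    "group_tests",
    "pearson_correlation",
    "manual_cytology_score",
]


def round_half_up(x: float, decimals: int = 0) -> float:
    """Decimal half-up rounding (0.5 always rounds away from zero)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 confusion counts for one positive-class definition."""

    tp: int
    fn: int
    tn: int
    fp: int
    positive_label: str = "positive"

    def __post_init__(self):
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.n < 1:
            raise ValueError("confusion table must contain at least one case")

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.tn + self.fp

    @classmethod
    def from_predictions(cls, predicted: Sequence, truth: Sequence,
                         positive) -> "ConfusionCounts":
        if len(predicted) != len(truth):
            raise ValueError("predicted and truth lengths differ")
        tp = fn = tn = fp = 0
        for p, t in zip(predicted, truth):
            if t == positive:
                if p == positive:
                    tp += 1
                else:
                    fn += 1
            else:
                if p == positive:
                    fp += 1
                else:
                    tn += 1
        return cls(tp=tp, fn=fn, tn=tn, fp=fp, positive_label=str(positive))


@dataclass(frozen=True)
class DiagnosticMetrics:
    """Raw-fraction diagnostic metrics; ``None`` marks an undefined metric
    (zero denominator), never silently 0."""

    sensitivity: float | None
    specificity: float | None
    accuracy: float | None
    ppv: float | None
    npv: float | None
    counts: ConfusionCounts

    def percent(self, decimals: int = 0) -> dict[str, float | None]:
        """Metrics as percents rounded half-up to ``decimals`` places."""
        out = {}
        for name in ("sensitivity", "specificity", "accuracy", "ppv", "npv"):
            v = getattr(self, name)
            out[name] = None if v is None else round_half_up(100.0 * v, decimals)
        return out


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else num / den


def metrics_from_counts(c: ConfusionCounts) -> DiagnosticMetrics:
    """Sensitivity, specificity, accuracy, PPV and NPV from 2x2 counts."""
    return DiagnosticMetrics(
        sensitivity=_ratio(c.tp, c.tp + c.fn),
        specificity=_ratio(c.tn, c.tn + c.fp),
        accuracy=_ratio(c.tp + c.tn, c.n),
        ppv=_ratio(c.tp, c.tp + c.fp),
        npv=_ratio(c.tn, c.tn + c.fn),
        counts=c,
    )


@dataclass
class AgreementResult:
    """Chance-corrected agreement and/or paired-proportion comparison."""

    kappa: float | None = None
    observed_agreement: float | None = None
    expected_agreement: float | None = None
    kappa_undefined: bool = False
    mcnemar_statistic: float | None = None
    mcnemar_p: float | None = None
    method: str | None = None  # 'exact' | 'chi2_corrected'
    degenerate: bool = False


def _contingency(x, y) -> tuple[np.ndarray, list]:
    cats = sorted(set(x) | set(y), key=str)
    idx = {c: i for i, c in enumerate(cats)}
    table = np.zeros((len(cats), len(cats)), dtype=np.int64)
    for a, b in zip(x, y):
        table[idx[a], idx[b]] += 1
    return table, cats


def cohen_kappa(x, y=None) -> AgreementResult:
    """Unweighted Cohen's kappa.

    Accepts either two equal-length rating sequences or a square contingency
    table (rows = rater 1, columns = rater 2).  When both raters are constant
    and identical the expected agreement is 1 and kappa is undefined (flagged,
    not NaN-silent).
    """
    if y is not None:
        if len(x) != len(y):
            raise ValueError("rating sequences must have equal length")
        if len(x) == 0:
            raise ValueError("at least one rating pair is required")
        table, _ = _contingency(x, y)
    else:
        table = np.asarray(x, dtype=np.int64)
        if table.ndim != 2 or table.shape[0] != table.shape[1]:
            raise ValueError("contingency table must be square")
        if table.sum() == 0:
            raise ValueError("contingency table is empty")
    n = table.sum()
    po = float(np.trace(table)) / n
    pe = float((table.sum(axis=1) * table.sum(axis=0)).sum()) / (n * n)
    if pe >= 1.0:
        return AgreementResult(kappa=None, observed_agreement=po,
                               expected_agreement=pe, kappa_undefined=True)
    return AgreementResult(kappa=(po - pe) / (1.0 - pe), observed_agreement=po,
                           expected_agreement=pe)


def mcnemar_test(b: int, c: int) -> AgreementResult:
    """McNemar's paired test on the discordant counts ``b`` and ``c``.

    Exact two-sided binomial p for b + c < 25, otherwise the chi-square
    statistic with continuity correction; the method used is tagged.
    """
    if b < 0 or c < 0:
        raise ValueError("discordant counts must be non-negative")
    n = b + c
    if n == 0:
        return AgreementResult(mcnemar_statistic=0.0, mcnemar_p=1.0,
                               method="exact", degenerate=True)
    if n < 25:
        k = min(b, c)
        p = min(1.0, 2.0 * float(stats.binom.cdf(k, n, 0.5)))
        return AgreementResult(mcnemar_statistic=float(k), mcnemar_p=p,
                               method="exact")
    chi2 = (abs(b - c) - 1.0) ** 2 / n
    p = float(stats.chi2.sf(chi2, df=1))
    return AgreementResult(mcnemar_statistic=chi2, mcnemar_p=p,
                           method="chi2_corrected")


@dataclass
class ROCResult:
    thresholds: np.ndarray  # candidate cutoffs, ascending
    tpr: np.ndarray  # sensitivity at each threshold (score >= t is positive)
    fpr: np.ndarray
    auc: float
    youden_cutoff: float
    youden_j: float
    non_informative: bool = False  # J == 0: no discriminative cutoff


def roc_analysis(scores, labels, positive=1) -> ROCResult:
    """Empirical ROC with trapezoidal AUC and the Youden-optimal cutoff.

    The decision rule is ``score >= cutoff -> positive``.  Candidate cutoffs
    are the midpoints between adjacent sorted unique scores plus sentinels
    below the minimum and above the maximum; ties in Youden's J break toward
    the lower cutoff (higher sensitivity).
    """
    s = np.asarray(scores, dtype=np.float64)
    y = np.asarray([1 if lab == positive else 0 for lab in labels])
    if s.size != y.size or s.size == 0:
        raise ValueError("scores and labels must be equal-length and non-empty")
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present for ROC analysis")
    uniq = np.unique(s)
    if uniq.size == 1:
        raise ValueError("no discriminative cutoff: all scores identical")
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    lo = uniq[0] - (uniq[1] - uniq[0]) / 2.0
    hi = uniq[-1] + (uniq[-1] - uniq[-2]) / 2.0
    thresholds = np.concatenate([[lo], mids, [hi]])
    tpr = np.array([(s[y == 1] >= t).mean() for t in thresholds])
    fpr = np.array([(s[y == 0] >= t).mean() for t in thresholds])
    order = np.lexsort((tpr, fpr))  # ties in FPR ordered by TPR
    auc = float(np.trapezoid(tpr[order], fpr[order]))
    j = tpr - fpr
    best_j = float(j.max())
    best_cut = float(thresholds[j == best_j].min())  # ties -> lower cutoff
    return ROCResult(thresholds=thresholds, tpr=tpr, fpr=fpr, auc=auc,
                     youden_cutoff=best_cut, youden_j=best_j,
                     non_informative=(best_j <= 0.0))


@dataclass
class GroupTestReport:
    kruskal_h: float | None
    kruskal_p: float | None
    normality: dict[str, tuple[float | None, float | None]]  # per group (stat, p)
    method: str = "kruskal-wallis + lilliefors-ks"
    degenerate: bool = False


def group_tests(values_by_class: dict[str, Sequence[float]]) -> GroupTestReport:
    """Kruskal-Wallis across the groups plus a per-group normality check.

    Normality uses the Kolmogorov-Smirnov statistic against a normal with
    moments estimated from the sample (Lilliefors correction via
    statsmodels when available, plain KS otherwise; tagged in ``method``).
    Degenerate groups (fewer than 2 values) mark the report instead of
    raising.
    """
    groups = {k: np.asarray(v, dtype=np.float64) for k, v in values_by_class.items()}
    if len(groups) < 2:
        raise ValueError("at least two groups are required")
    degenerate = any(g.size < 2 for g in groups.values())
    kh = kp = None
    if not degenerate:
        try:
            kh, kp = stats.kruskal(*groups.values())
            kh, kp = float(kh), float(kp)
        except ValueError:  # all values identical
            degenerate = True
    normality: dict[str, tuple[float | None, float | None]] = {}
    method = "kruskal-wallis + lilliefors-ks"
    for name, g in groups.items():
        if g.size < 4 or g.std(ddof=1) == 0:
            normality[name] = (None, None)
            continue
        try:
            from statsmodels.stats.diagnostic import lilliefors
            st, p = lilliefors(g, dist="norm")
        except ImportError:  # pragma: no cover
            st, p = stats.kstest(g, "norm", args=(g.mean(), g.std(ddof=1)))
            method = "kruskal-wallis + ks-fitted"
        normality[name] = (float(st), float(p))
    return GroupTestReport(kruskal_h=kh, kruskal_p=kp, normality=normality,
                           method=method, degenerate=degenerate)


def pearson_correlation(x, y) -> tuple[float, float]:
    """Pearson r and two-sided p between two feature vectors."""
    r, p = stats.pearsonr(np.asarray(x, float), np.asarray(y, float))
    return float(r), float(p)


def wilson_interval(successes: int, n: int, level: float = 0.95
                    ) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion.

    Provided as a convenience for putting an uncertainty band on the
    diagnostic proportions; no other interval type is offered.
    """
    if n < 1 or not (0 <= successes <= n):
        raise ValueError("need 0 <= successes <= n with n >= 1")
    z = float(stats.norm.ppf(0.5 + level / 2.0))
    p = successes / n
    denom = 1.0 + z * z / n
    centre = (p + z * z / (2 * n)) / denom
    half = z * math.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / denom
    return (max(0.0, centre - half), min(1.0, centre + half))


MANUAL_FEATURES = (
    "multi_nucleation",
    "mitotic_figures",
    "prominent_nucleoli",
    "altered_nc_ratio",
    "hyperchromatic_nucleus",
    "irregular_nuclear_membrane",
    "abnormal_cell_shape",
)

#: Score strictly above this calls the manual cytology read positive.
MANUAL_SCORE_THRESHOLD = 3


@dataclass
class ManualCytologyRecord:
    """Binary presence/absence of the seven conventional atypia features.

    ``abnormal_cell_shape`` is the optional seventh feature: classic scoring
    sheets list six, but abnormal shape ranks among the most informative
    features, so seven is the default configuration and six is available by
    scoring with ``n_features=6``.
    """

    multi_nucleation: int | None = None
    mitotic_figures: int | None = None
    prominent_nucleoli: int | None = None
    altered_nc_ratio: int | None = None
    hyperchromatic_nucleus: int | None = None
    irregular_nuclear_membrane: int | None = None
    abnormal_cell_shape: int | None = None


def manual_cytology_score(record: ManualCytologyRecord,
                          n_features: int = 7) -> tuple[int, bool]:
    """Total manual cytology score and the >3 positivity call.

    All counted features must be set to 0 or 1; a missing feature raises.
    """
    if n_features not in (6, 7):
        raise ValueError("n_features must be 6 or 7")
    feats = MANUAL_FEATURES[:n_features]
    total = 0
    for name in feats:
        v = getattr(record, name)
        if v is None:
            raise ValueError(f"manual feature {name!r} is missing")
        if v not in (0, 1):
            raise ValueError(f"manual feature {name!r} must be 0 or 1")
        total += v
    return total, total > MANUAL_SCORE_THRESHOLD
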