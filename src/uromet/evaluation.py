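"""ROC/AUC with DeLong machinery, operating points, biopsy avoidance,
and the cohort-comparison tests.

Score orientation is fixed throughout: higher score = more likely
endpoint-positive, and a subject is test-positive when score >=
threshold.  AUC is the tie-corrected concordance probability
(Mann-Whitney; ties count 1/2).  AUC variances and paired comparisons
use the DeLong placement decomposition.  "Biopsies avoided" reweights
the observed cohort back to the enrollment pool's risk-group
composition: it is the share of the at-risk population that is
endpoint-negative and test-negative at a given threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .strata import ENROLLMENT_WEIGHTS

__all__ = [
    "RocCurve",
    "OperatingPoint",
    "roc_auc",
    "delong_compare",
    "auc_p_vs_half",
    "auc_confidence_interval",
    "youden_threshold",
    "operating_point_at_sensitivity",
    "operating_point",
    "biopsies_avoided",
    "pearson_chi2_2x2",
    "mann_whitney_u",
]


@dataclass
class RocCurve:
    thresholds: np.ndarray  # observed score values, descending
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    delong_variance: float
    n_pos: int
    n_neg: int


@dataclass
class OperatingPoint:
    threshold: float
    sensitivity: float
    specificity: float
    npv: float
    ppv: float
    accuracy: float
    biopsies_avoided_pct: float | None = None

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "npv": self.npv,
            "ppv": self.ppv,
            "accuracy": self.accuracy,
            "biopsies_avoided_pct": self.biopsies_avoided_pct,
        }


def _split(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels differ in length")
    pos, neg = scores[labels == 1], scores[labels == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both outcome classes must be present")
    return scores, labels, pos, neg


def _placements(pos: np.ndarray, neg: np.ndarray):
    """DeLong placement values; mean of v10 (and of v01) is the AUC."""
    m, n = pos.size, neg.size
    all_r = stats.rankdata(np.concatenate([pos, neg]))
    v10 = (all_r[:m] - stats.rankdata(pos)) / n
    v01 = 1.0 - (all_r[m:] - stats.rankdata(neg)) / m
    return v10, v01


def roc_auc(scores, labels) -> RocCurve:
    """ROC curve over the observed score values with DeLong variance."""
    scores, labels, pos, neg = _split(scores, labels)
    thresholds = np.unique(scores)[::-1]
    pos_sorted, neg_sorted = np.sort(pos), np.sort(neg)
    # test-positive iff score >= threshold
    sens = 1.0 - np.searchsorted(pos_sorted, thresholds, side="left") / pos.size
    spec = np.searchsorted(neg_sorted, thresholds, side="left") / neg.size
    v10, v01 = _placements(pos, neg)
    auc = float(v10.mean())
    m, n = pos.size, neg.size
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    var = s10 / m + s01 / n
    return RocCurve(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        delong_variance=float(var),
        n_pos=m,
        n_neg=n,
    )


def delong_compare(scores_a, scores_b, labels):
    """Paired DeLong comparison of two AUCs on the same subjects.

    Returns (AUC_a - AUC_b, z, two-sided p).  With zero variance of the
    difference: p = 1 when the AUCs are equal, else p = 0 (degenerate).
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores_a.shape != scores_b.shape or scores_a.shape != labels.shape:
        raise ValueError("paired scores and labels must have equal length")
    mask_pos, mask_neg = labels == 1, labels == 0
    if not mask_pos.any() or not mask_neg.any():
        raise ValueError("both outcome classes must be present")
    m, n = int(mask_pos.sum()), int(mask_neg.sum())
    v10a, v01a = _placements(scores_a[mask_pos], scores_a[mask_neg])
    v10b, v01b = _placements(scores_b[mask_pos], scores_b[mask_neg])
    auc_a, auc_b = float(v10a.mean()), float(v10b.mean())
    d = auc_a - auc_b
    if m > 1 and n > 1:
        s10 = np.cov(v10a, v10b)
        s01 = np.cov(v01a, v01b)
        var_d = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (
            s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
        ) / n
    else:
        var_d = 0.0
    if var_d <= 0.0:
        return d, 0.0 if d == 0 else np.inf, 1.0 if d == 0 else 0.0
    z = d / np.sqrt(var_d)
    return d, float(z), float(2.0 * stats.norm.sf(abs(z)))


def auc_p_vs_half(curve: RocCurve) -> float:
    """Two-sided p for AUC != 0.5 from the DeLong variance."""
    if curve.delong_variance <= 0.0:
        return 1.0 if curve.auc == 0.5 else 0.0
    z = (curve.auc - 0.5) / np.sqrt(curve.delong_variance)
    return float(2.0 * stats.norm.sf(abs(z)))


def auc_confidence_interval(curve: RocCurve, level: float = 0.95):
    half = stats.norm.ppf(0.5 + level / 2.0) * np.sqrt(max(curve.delong_variance, 0.0))
    return (max(curve.auc - half, 0.0), min(curve.auc + half, 1.0))


def operating_point(
    scores, labels, threshold: float, strata=None, weights=None
) -> OperatingPoint:
    """All operating-point metrics at a threshold (positive: score >= t)."""
    scores, labels, pos, neg = _split(scores, labels)
    tp = int((pos >= threshold).sum())
    fn = pos.size - tp
    tn = int((neg < threshold).sum())
    fp = neg.size - tn

    def _ratio(a, b):
        return a / b if b else float("nan")

    avoided = None
    if strata is not None:
        avoided = biopsies_avoided(labels, scores, threshold, strata, weights)
    return OperatingPoint(
        threshold=float(threshold),
        sensitivity=_ratio(tp, tp + fn),
        specificity=_ratio(tn, tn + fp),
        npv=_ratio(tn, tn + fn),
        ppv=_ratio(tp, tp + fp),
        accuracy=(tp + tn) / scores.size,
        biopsies_avoided_pct=avoided,
    )


def youden_threshold(curve: RocCurve, scores=None, labels=None, strata=None, weights=None):
    """Operating point maximising J = sensitivity + specificity - 1.

    Ties resolve toward higher specificity.  When ``scores``/``labels``
    are omitted only threshold/sensitivity/specificity are filled.
    """
    j = curve.sensitivity + curve.specificity - 1.0
    best = np.flatnonzero(j >= j.max() - 1e-12)
    pick = best[np.argmax(curve.specificity[best])]
    thr = float(curve.thresholds[pick])
    if scores is None:
        return OperatingPoint(
            threshold=thr,
            sensitivity=float(curve.sensitivity[pick]),
            specificity=float(curve.specificity[pick]),
            npv=float("nan"),
            ppv=float("nan"),
            accuracy=float("nan"),
        )
    return operating_point(scores, labels, thr, strata=strata, weights=weights)


def operating_point_at_sensitivity(
    scores, labels, target: float, strata=None, weights=None
) -> OperatingPoint:
    """Highest threshold with sensitivity >= target (max specificity
    subject to the sensitivity constraint)."""
    if not 0.0 < target <= 1.0:
        raise ValueError(f"target sensitivity must be in (0, 1], got {target}")
    curve = roc_auc(scores, labels)
    ok = np.flatnonzero(curve.sensitivity >= target - 1e-12)
    if ok.size == 0:  # sensitivity reaches 1.0 at the lowest threshold
        raise ValueError(f"target sensitivity {target} unattainable")
    thr = float(curve.thresholds[ok[0]])  # thresholds descending; first = highest
    return operating_point(scores, labels, thr, strata=strata, weights=weights)


def biopsies_avoided(labels, scores, threshold, strata, weights=None) -> float:
    """Reweighted percentage of the at-risk population spared a biopsy.

    ``avoided = 100 * sum_g w_g * #{endpoint-negative & score < t in g} / n_g``
    with ``w_g`` the enrollment-pool composition; strata with no
    endpoint-negative members contribute nothing.
    """
    weights = dict(ENROLLMENT_WEIGHTS if weights is None else weights)
    total_w = sum(weights.values())
    if abs(total_w - 1.0) > 1e-9:
        raise ValueError(f"stratum weights must sum to 1, got {total_w}")
    if any(w < 0 for w in weights.values()):
        raise ValueError("stratum weights must be non-negative")
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    strata = np.asarray(strata)
    missing = sorted(set(strata) - set(weights))
    if missing:
        raise ValueError(f"strata without weights: {missing}")
    avoided = 0.0
    for g, w in weights.items():
        members = strata == g
        n_g = int(members.sum())
        if n_g == 0:
            continue
        spared = int(((labels == 0) & (scores < threshold) & members).sum())
        avoided += w * spared / n_g
    return 100.0 * avoided


def pearson_chi2_2x2(table) -> tuple[float, float]:
    """Uncorrected Pearson chi-square on a 2x2 table, 1 df."""
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {table.shape}")
    if np.any(table.sum(axis=0) <= 0) or np.any(table.sum(axis=1) <= 0):
        raise ValueError("all table marginals must be positive")
    res = stats.chi2_contingency(table, correction=False)
    return float(res.statistic), float(res.pvalue)


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U, normal approximation with tie and
    continuity corrections.

    Orientation: U is the statistic for ``x``; disjoint supports with
    every x above every y give U = len(x) * len(y).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    if np.ptp(combined) == 0.0:  # all values tied: zero variance, no evidence
        return float(x.size * y.size / 2.0), 1.0
    res = stats.mannwhitneyu(x, y, alternative="two-sided", use_continuity=True,
                             method="asymptotic")
    return float(res.statistic), float(res.pvalue)
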