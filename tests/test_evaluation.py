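"""ROC/AUC, DeLong comparisons, operating points, biopsy avoidance,
and the cohort-comparison tests, each against an independent oracle."""

import itertools

import numpy as np
import pytest
from scipy import stats

from uromet import (
    biopsies_avoided,
    delong_compare,
    mann_whitney_u,
    operating_point,
    operating_point_at_sensitivity,
    pearson_chi2_2x2,
    roc_auc,
    youden_threshold,
)


def pair_count_auc(scores, labels):
    """Exhaustive concordant-pair AUC oracle (ties count 1/2)."""
    scores = np.asarray(scores, float)
    pos = scores[np.asarray(labels) == 1]
    neg = scores[np.asarray(labels) == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def test_roc_auc_trivial_cases():
    assert roc_auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]).auc == 1.0
    assert roc_auc([1, 1, 1, 1], [1, 1, 0, 0]).auc == 0.5
    assert roc_auc([3, 5, 1, 4], [1, 1, 0, 0]).auc == 0.75
    with pytest.raises(ValueError, match="classes"):
        roc_auc([1, 2], [1, 1])


def test_roc_curve_monotone_and_auc_matches_concordance(rng):
    for _ in range(30):
        n = int(rng.integers(6, 50))
        scores = rng.choice(np.round(rng.normal(size=8), 2), size=n)
        labels = (rng.random(n) < 0.5).astype(int)
        if labels.min() == labels.max():
            continue
        c = roc_auc(scores, labels)
        assert c.auc == pytest.approx(pair_count_auc(scores, labels), abs=1e-12)
        assert np.all(np.diff(c.sensitivity) >= -1e-12)  # thresholds descend


def test_delong_self_comparison_is_null(rng):
    s = rng.normal(size=30)
    y = (rng.random(30) < 0.5).astype(int)
    y[:2] = [0, 1]
    d, z, p = delong_compare(s, s, y)
    assert d == 0.0 and p == 1.0


def test_delong_sign_flips_with_labels(rng):
    a, b = rng.normal(size=40), rng.normal(size=40)
    y = (rng.random(40) < 0.5).astype(int)
    y[:2] = [0, 1]
    d1, _, p1 = delong_compare(a, b, y)
    d2, _, p2 = delong_compare(a, b, 1 - y)
    # AUC(1-y) = 1 - AUC(y) for each model, so the difference negates
    assert d2 == pytest.approx(-d1, abs=1e-12)
    assert p2 == pytest.approx(p1, abs=1e-12)


def test_delong_matches_paired_bootstrap(rng):
    """DeLong p on a small paired instance agrees with a 1e5-resample
    paired bootstrap of the AUC difference."""
    n = 20
    latent = rng.normal(size=n)
    y = (latent > 0).astype(int)
    a = latent + rng.normal(scale=1.0, size=n)
    b = rng.normal(size=n)
    d, z, p = delong_compare(a, b, y)

    B = 100_000
    idx = rng.integers(0, n, size=(B, n))
    diffs = np.empty(B)
    pos = y == 1
    for i in range(B):
        take = idx[i]
        yy = y[take]
        if yy.min() == yy.max():
            diffs[i] = 0.0
            continue
        aa, bb = a[take], b[take]
        diffs[i] = _fast_auc(aa, yy) - _fast_auc(bb, yy)
    # two-sided bootstrap p for H0: delta = 0
    p_boot = 2 * min((diffs <= 0).mean(), (diffs >= 0).mean())
    assert abs(p - min(p_boot, 1.0)) < 0.02


def _fast_auc(scores, labels):
    r = stats.rankdata(scores)
    m = labels.sum()
    return (r[labels == 1].sum() - m * (m + 1) / 2) / (m * (len(labels) - m))


def test_youden_matches_brute_force(rng):
    for _ in range(25):
        n = 30
        scores = np.round(rng.normal(size=n), 1)
        labels = (rng.random(n) < 0.5).astype(int)
        labels[:2] = [0, 1]
        c = roc_auc(scores, labels)
        op = youden_threshold(c, scores, labels)
        # brute force over every observed threshold
        best_j, best_spec = -np.inf, -np.inf
        for t in np.unique(scores):
            sens = (scores[labels == 1] >= t).mean()
            spec = (scores[labels == 0] < t).mean()
            j = sens + spec - 1
            if j > best_j + 1e-12 or (abs(j - best_j) <= 1e-12 and spec > best_spec):
                best_j, best_spec = j, spec
        assert op.sensitivity + op.specificity - 1 == pytest.approx(best_j, abs=1e-12)
        assert op.specificity == pytest.approx(best_spec, abs=1e-12)


def test_youden_trivial_cases():
    perfect = roc_auc([0.9, 0.8, 0.1], [1, 1, 0])
    op = youden_threshold(perfect)
    assert op.sensitivity + op.specificity - 1 == pytest.approx(1.0)
    tied = roc_auc([1.0, 1.0, 1.0, 1.0], [1, 1, 0, 0])
    op = youden_threshold(tied)
    assert op.sensitivity + op.specificity - 1 == pytest.approx(0.0)


def test_operating_point_at_sensitivity_enumeration():
    scores = np.array([0.9, 0.8, 0.3, 0.1, 0.2, 0.7])
    labels = np.array([1, 1, 1, 0, 0, 0])
    op = operating_point_at_sensitivity(scores, labels, 0.90)
    assert op.threshold == pytest.approx(0.3)
    assert op.sensitivity == 1.0
    assert op.specificity == pytest.approx(2 / 3)


def test_operating_point_at_full_sensitivity(rng):
    scores = rng.normal(size=40)
    labels = (rng.random(40) < 0.5).astype(int)
    labels[:2] = [0, 1]
    op = operating_point_at_sensitivity(scores, labels, 1.0)
    assert op.threshold <= scores[labels == 1].min()
    assert op.sensitivity == 1.0


def test_operating_point_contingency_identities(rng):
    scores = rng.normal(size=50)
    labels = (rng.random(50) < 0.4).astype(int)
    labels[:2] = [0, 1]
    for t in np.unique(scores)[::7]:
        op = operating_point(scores, labels, t)
        pos, neg = scores[labels == 1], scores[labels == 0]
        tp, fn = (pos >= t).sum(), (pos < t).sum()
        tn, fp = (neg < t).sum(), (neg >= t).sum()
        assert op.accuracy == pytest.approx((tp + tn) / 50)
        if tn + fn:
            assert op.npv == pytest.approx(tn / (tn + fn))
        if tp + fp:
            assert op.ppv == pytest.approx(tp / (tp + fp))


class TestBiopsiesAvoided:
    def _fixture(self):
        # 50 benign negatives of which 46 score below 0.5 (spec 0.92),
        # plus positive cancer strata
        scores = np.r_[np.full(46, 0.1), np.full(4, 0.9), np.full(20, 0.9)]
        labels = np.r_[np.zeros(50), np.ones(20)].astype(int)
        strata = np.r_[["benign"] * 50, ["mPC"] * 20]
        return scores, labels, strata

    def test_reproduces_weighted_true_negative_share(self):
        scores, labels, strata = self._fixture()
        pct = biopsies_avoided(labels, scores, 0.5, strata)
        assert pct == pytest.approx(0.520 * 0.92 * 100)  # 47.84 ~ printed 48

    def test_threshold_below_all_scores_avoids_nothing(self):
        scores, labels, strata = self._fixture()
        assert biopsies_avoided(labels, scores, 0.0, strata) == 0.0

    def test_degenerate_weights_give_stratum_rate(self):
        scores, labels, strata = self._fixture()
        w = {"benign": 1.0, "mPC": 0.0}
        assert biopsies_avoided(labels, scores, 0.5, strata, w) == pytest.approx(92.0)

    def test_monotone_in_threshold(self, rng):
        scores = rng.normal(size=60)
        labels = (rng.random(60) < 0.5).astype(int)
        strata = rng.choice(["benign", "mPC"], size=60)
        w = {"benign": 0.7, "mPC": 0.3}
        vals = [
            biopsies_avoided(labels, scores, t, strata, w)
            for t in np.sort(np.unique(scores))
        ]
        assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))

    def test_unknown_stratum_raises(self):
        with pytest.raises(ValueError, match="without weights"):
            biopsies_avoided([0], [0.1], 0.5, ["weird"], {"benign": 1.0})


class TestCohortComparisonTests:
    def test_chi2_reproduces_printed_cohort_comparisons(self):
        """Uncorrected Pearson chi-square matches the published
        training-vs-validation p-values to 4 decimals."""
        cases = {
            (53, 539, 19, 299): 0.1126,   # family history
            (115, 424, 66, 213): 0.4486,  # previous negative biopsy
            (236, 356, 86, 233): 0.0001,  # abnormal DRE
        }
        for (a, b, c, d), expected in cases.items():
            _, p = pearson_chi2_2x2([[a, b], [c, d]])
            assert round(p, 4) == expected

    def test_chi2_null_table(self):
        stat, p = pearson_chi2_2x2([[10, 10], [10, 10]])
        assert stat == 0.0 and p == 1.0

    def test_chi2_zero_marginal_raises(self):
        with pytest.raises(ValueError, match="marginal"):
            pearson_chi2_2x2([[0, 0], [5, 5]])

    def test_mwu_identical_samples(self):
        u, p = mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0)

    def test_mwu_disjoint_supports(self):
        u, p = mann_whitney_u([10, 11, 12], [1, 2, 3])
        assert u == 9.0  # n1*n2 when every x exceeds every y

    def test_mwu_close_to_exact_enumeration(self, rng):
        """Normal-approximation p within 0.02 of the exact permutation
        distribution at n1=n2=5."""
        for _ in range(10):
            x = np.round(rng.normal(size=5), 2)
            y = np.round(rng.normal(loc=0.5, size=5), 2)
            u_obs, p_asym = mann_whitney_u(x, y)
            pooled = np.r_[x, y]
            r = stats.rankdata(pooled)
            obs_dev = abs(r[:5].sum() - 0.5 * r.sum())
            count = 0
            total = 0
            for comb in itertools.combinations(range(10), 5):
                dev = abs(r[list(comb)].sum() - 0.5 * r.sum())
                count += dev >= obs_dev - 1e-9
                total += 1
            assert abs(p_asym - count / total) < 0.02
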