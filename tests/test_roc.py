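"""ROC sweep, AUC (vs pair-counting and library oracles), cutoff
optimization, bootstrap CI, and confusion-matrix metrics."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import norm
from sklearn.metrics import roc_auc_score

import seromir as sm
from seromir.roc import ConfusionCounts, auc_ci, confusion_metrics, optimal_cutoff, roc_curve


def auc_by_pair_enumeration(scores, labels):
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = sum((a > b) + 0.5 * (a == b) for a in pos for b in neg)
    return total / (len(pos) * len(neg))


def sweep_oracle(scores, labels):
    """Exhaustive evaluation of sens+spec at every candidate threshold,
    with the tie rules applied literally."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    best = None
    for t in np.concatenate(([-np.inf], np.unique(scores))):
        pred = scores > t
        sens = np.sum(pred & (labels == 1)) / labels.sum()
        spec = np.sum(~pred & (labels == 0)) / (labels == 0).sum()
        key = (round(sens + spec, 12), round(spec, 12), t)
        if best is None or key > best:
            best = key
    return best[2]


def random_instance(seed, max_n=50, tie_prone=False):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, max_n))
    labels = np.zeros(n, int)
    labels[: max(1, n // 3)] = 1
    rng.shuffle(labels)
    if tie_prone:
        scores = rng.integers(0, 5, n).astype(float)
    else:
        scores = rng.normal(size=n) + labels
    return scores, labels


class TestConfusionMetrics:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            ((14, 2, 13, 1), (93.33, 86.67, 87.50, 92.86)),
            ((24, 0, 30, 1), (96.00, 100.00, 100.00, 96.77)),
            ((57, 3, 55, 7), (89.06, 94.83, 95.00, 88.71)),
        ],
    )
    def test_published_classification_counts(self, counts, expected):
        tp, fp, tn, fn = counts
        m = confusion_metrics(ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn))
        assert m["sensitivity"] == pytest.approx(expected[0], abs=0.005)
        assert m["specificity"] == pytest.approx(expected[1], abs=0.005)
        assert m["ppv"] == pytest.approx(expected[2], abs=0.005)
        assert m["npv"] == pytest.approx(expected[3], abs=0.005)

    def test_zero_denominator_is_undefined_not_zero(self):
        m = confusion_metrics(ConfusionCounts(tp=0, fp=0, tn=5, fn=0))
        assert np.isnan(m["sensitivity"])
        assert np.isnan(m["ppv"])
        assert m["specificity"] == 100.0

    def test_transpose_swap_exchanges_metric_pairs(self):
        c = ConfusionCounts(tp=14, fp=2, tn=13, fn=1)
        swapped = ConfusionCounts(tp=c.tn, fp=c.fn, tn=c.tp, fn=c.fp)
        m, ms = confusion_metrics(c), confusion_metrics(swapped)
        assert ms["sensitivity"] == m["specificity"]
        assert ms["specificity"] == m["sensitivity"]
        assert ms["ppv"] == m["npv"]
        assert ms["npv"] == m["ppv"]

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(tp=-1, fp=0, tn=1, fn=0)


class TestRocCurve:
    def test_perfect_separation_auc_one(self):
        roc = roc_curve([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert roc.auc == 1.0
        assert roc.sensitivity_at_optimum == 1.0
        assert roc.specificity_at_optimum == 1.0

    def test_coin_flip_labels_auc_half(self):
        rng = np.random.default_rng(17)
        scores = rng.normal(size=4000)
        labels = rng.integers(0, 2, 4000)
        assert roc_curve(scores, labels).auc == pytest.approx(0.5, abs=0.04)

    @pytest.mark.parametrize("tie_prone", [False, True])
    @pytest.mark.parametrize("seed", range(12))
    def test_auc_equals_pair_counting_oracle(self, seed, tie_prone):
        scores, labels = random_instance(seed, tie_prone=tie_prone)
        roc = roc_curve(scores, labels)
        assert roc.auc == pytest.approx(
            auc_by_pair_enumeration(scores, labels), abs=1e-12
        )
        assert roc.auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    def test_sensitivity_monotone_in_threshold(self):
        scores, labels = random_instance(99, tie_prone=True)
        roc = roc_curve(scores, labels)
        assert np.all(np.diff(roc.sensitivity) <= 1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="classes"):
            roc_curve([1.0, 2.0], [1, 1])

    @given(st.integers(0, 200))
    def test_complement_symmetry_without_ties(self, seed):
        rng = np.random.default_rng(seed)
        n = 20
        scores = rng.permutation(np.arange(n)).astype(float)  # distinct
        labels = np.zeros(n, int)
        labels[:7] = 1
        rng.shuffle(labels)
        a = roc_curve(scores, labels).auc
        b = roc_curve(-scores, labels).auc
        assert a + b == pytest.approx(1.0, abs=1e-12)

    @given(st.integers(0, 200))
    def test_invariance_under_monotone_transform(self, seed):
        scores, labels = random_instance(seed)
        transformed = np.exp(0.7 * scores) + 3
        assert roc_curve(scores, labels).auc == pytest.approx(
            roc_curve(transformed, labels).auc, abs=1e-12
        )


class TestOptimalCutoff:
    @pytest.mark.parametrize("seed", range(15))
    def test_matches_exhaustive_sweep(self, seed):
        scores, labels = random_instance(seed, tie_prone=(seed % 2 == 0))
        roc = roc_curve(scores, labels)
        cutoff, sens, spec = optimal_cutoff(roc)
        assert cutoff == sweep_oracle(scores, labels)
        pred = scores > cutoff
        assert sens == np.sum(pred & (labels == 1)) / labels.sum()
        assert spec == np.sum(~pred & (labels == 0)) / (labels == 0).sum()

    def test_equal_sums_tie_broken_by_specificity(self):
        # thresholds 1 and 2 both give sens+spec = 1.5; t=2 has higher spec
        scores = np.array([1.0, 2.0, 2.0, 3.0])
        labels = np.array([0, 1, 0, 1])
        cutoff, _, spec = optimal_cutoff(roc_curve(scores, labels))
        oracle = sweep_oracle(scores, labels)
        assert cutoff == oracle


class TestAucCI:
    def test_deterministic_given_seed(self):
        scores, labels = random_instance(3, max_n=40)
        assert auc_ci(scores, labels, n_boot=200, seed=5) == auc_ci(
            scores, labels, n_boot=200, seed=5
        )
        assert auc_ci(scores, labels, n_boot=200, seed=5) != auc_ci(
            scores, labels, n_boot=200, seed=6
        )

    def test_seed_required(self):
        scores, labels = random_instance(3)
        with pytest.raises(ValueError, match="seed"):
            auc_ci(scores, labels)

    def test_perfect_separation_upper_bound_one(self):
        scores = np.concatenate([np.zeros(10), np.ones(10)])
        labels = np.concatenate([np.zeros(10, int), np.ones(10, int)])
        low, high = auc_ci(scores, labels, n_boot=200, seed=1)
        assert high == 1.0
        assert low <= 1.0

    def test_binormal_coverage(self):
        """CI covers the closed-form AUC Phi(1/sqrt 2) in >=90% of
        seeded replicates."""
        target = norm.cdf(1 / np.sqrt(2))
        rng = np.random.default_rng(0)
        covered = 0
        n_rep = 60
        for rep in range(n_rep):
            cases = rng.normal(1, 1, 200)
            controls = rng.normal(0, 1, 200)
            scores = np.concatenate([cases, controls])
            labels = np.concatenate([np.ones(200, int), np.zeros(200, int)])
            low, high = auc_ci(scores, labels, n_boot=300, seed=rep)
            covered += low <= target <= high
        assert covered / n_rep >= 0.90
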