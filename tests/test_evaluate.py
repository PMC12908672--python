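import math

import numpy as np
import pytest

from scddi.evaluate import (
    ari,
    cluster_cells,
    detection_metrics,
    nmi,
    paired_compare,
    recovery_scores,
)
from scddi.io_preprocess import NormalizedMatrix


def _nm(vals):
    vals = np.asarray(vals, float)
    return NormalizedMatrix(
        vals,
        np.array([f"g{i}" for i in range(vals.shape[0])], dtype=object),
        np.array([f"c{j}" for j in range(vals.shape[1])], dtype=object),
    )


class TestARI:
    def test_identical_and_relabelled(self):
        assert ari([0, 0, 1, 1], [0, 0, 1, 1]) == pytest.approx(1.0)
        assert ari([0, 0, 1, 1], [1, 1, 0, 0]) == pytest.approx(1.0)

    def test_pair_count_oracle(self):
        # [0,0,1,1] vs [0,1,1,1]: contingency {(0,0):1,(0,1):1,(1,1):2}
        # index = sum C(n_ij,2) = 1; sum_a C(2,2)*2 = 2; sum_b C(1,2)+C(3,2)=3
        # expected = 2*3/C(4,2) = 1; max = (2+3)/2 = 2.5 -> ARI = 0
        assert ari([0, 0, 1, 1], [0, 1, 1, 1]) == pytest.approx(0.0)

    def test_permutation_invariance(self, rng):
        a = rng.integers(0, 4, 50)
        b = rng.integers(0, 3, 50)
        remap = {0: 7, 1: 5, 2: 9, 3: 0}
        a2 = np.array([remap[x] for x in a])
        assert ari(a, b) == pytest.approx(ari(a2, b))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            ari([0, 1], [0, 1, 2])


class TestNMI:
    def test_identical(self):
        assert nmi([0, 1, 2, 0], [5, 3, 1, 5]) == pytest.approx(1.0)

    def test_independent_labels_near_zero(self):
        rng = np.random.default_rng(0)
        a = rng.integers(0, 2, 10000)
        b = rng.integers(0, 2, 10000)
        assert nmi(a, b) <= 0.05

    def test_hand_entropy_oracle(self):
        # a=[0,0,1,1], b=[0,1,1,1]
        # H(a)=ln2; H(b)=-(1/4)ln(1/4)-(3/4)ln(3/4)
        # MI = 1/4 ln2 + 1/4 ln(2/3) + 1/2 ln(4/3)
        h_a = math.log(2)
        h_b = -(0.25 * math.log(0.25) + 0.75 * math.log(0.75))
        mi = (0.25 * math.log(2) + 0.25 * math.log(2 / 3)
              + 0.5 * math.log(4 / 3))
        expected = mi / ((h_a + h_b) / 2)
        assert nmi([0, 0, 1, 1], [0, 1, 1, 1]) == pytest.approx(expected,
                                                                abs=1e-10)


class TestRecoveryScores:
    def test_perfect_recovery(self, rng):
        t = rng.random((5, 5))
        mask = rng.random((5, 5)) < 0.5
        s = recovery_scores(t, t, mask)
        assert s["pearson"] == pytest.approx(1.0)
        assert s["spearman"] == pytest.approx(1.0)
        assert s["rmse"] == 0.0 and s["mae"] == 0.0

    def test_constant_shift(self, rng):
        t = rng.random((4, 4))
        mask = np.ones((4, 4), bool)
        s = recovery_scores(t + 0.7, t, mask)
        assert s["pearson"] == pytest.approx(1.0)
        assert s["rmse"] == pytest.approx(0.7)
        assert s["mae"] == pytest.approx(0.7)

    def test_textbook_formula_oracle(self):
        x = np.array([1.0, 2.0, 4.0, 3.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 5.0, 6.0])
        mask = np.ones(5, bool)
        s = recovery_scores(x, y, mask)
        xm, ym = x - x.mean(), y - y.mean()
        r = (xm * ym).sum() / np.sqrt((xm**2).sum() * (ym**2).sum())
        assert s["pearson"] == pytest.approx(r, abs=1e-12)
        rx = np.argsort(np.argsort(x)).astype(float)
        ry = np.argsort(np.argsort(y)).astype(float)
        rxm, rym = rx - rx.mean(), ry - ry.mean()
        rho = (rxm * rym).sum() / np.sqrt((rxm**2).sum() * (rym**2).sum())
        assert s["spearman"] == pytest.approx(rho, abs=1e-12)
        assert s["rmse"] == pytest.approx(np.sqrt(np.mean((x - y) ** 2)))
        assert s["mae"] == pytest.approx(np.mean(np.abs(x - y)))

    def test_rmse_at_least_mae(self, rng):
        for _ in range(10):
            x, y = rng.random(30), rng.random(30)
            s = recovery_scores(x, y, np.ones(30, bool))
            assert s["rmse"] >= s["mae"]

    def test_constant_under_mask_nan(self):
        with pytest.warns(UserWarning, match="constant"):
            s = recovery_scores(np.ones(5), np.arange(5.0), np.ones(5, bool))
        assert math.isnan(s["pearson"])

    def test_empty_mask_error(self):
        with pytest.raises(ValueError, match="empty"):
            recovery_scores(np.ones(3), np.ones(3), np.zeros(3, bool))


class TestDetectionMetrics:
    def test_perfect_probs(self):
        truth = np.random.default_rng(1).random((6, 6)) < 0.4
        met = detection_metrics(truth.astype(float), truth)
        for tau, d in met.items():
            assert d["precision"] == 1.0 and d["recall"] == 1.0 and d["f1"] == 1.0

    def test_no_calls_convention(self):
        probs = np.full((3, 3), 0.5)
        truth = np.ones((3, 3), bool)
        met = detection_metrics(probs, truth, taus=(0.99,))
        assert met[0.99] == {"precision": 0.0, "recall": 0.0, "f1": 0.0}

    def test_hand_counted_confusion(self):
        probs = np.array([[0.9, 0.9, 0.1, 0.1],
                          [0.9, 0.1, 0.9, 0.1],
                          [0.1, 0.1, 0.1, 0.1],
                          [0.9, 0.9, 0.9, 0.9]])
        truth = np.zeros((4, 4), bool)
        truth[0, :2] = True   # both called: 2 TP
        truth[1, 1] = True    # missed: FN
        truth[2, 0] = True    # missed: FN
        # calls: row0 (0,0),(0,1) TP; row1 (1,0),(1,2) FP; row3 all 4 FP
        # -> TP=2, FP=6, FN=2
        met = detection_metrics(probs, truth, taus=(0.5,))[0.5]
        assert met["precision"] == pytest.approx(2 / 8)
        assert met["recall"] == pytest.approx(2 / 4)
        f1 = 2 * (1 / 4) * (1 / 2) / ((1 / 4) + (1 / 2))
        assert met["f1"] == pytest.approx(f1)

    def test_empty_truth_warns(self):
        with pytest.warns(UserWarning, match="empty truth"):
            met = detection_metrics(np.full((2, 2), 0.9),
                                    np.zeros((2, 2), bool), taus=(0.5,))
        assert met[0.5]["recall"] == 0.0


class TestPairedCompare:
    def test_identical_scores(self):
        a = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        with pytest.warns(UserWarning, match="zero"):
            out = paired_compare(a, a)
        assert out["wilcoxon_p"] == 1.0

    def test_exact_p_six_positive_differences(self):
        b = np.zeros(6)
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        out = paired_compare(a, b)
        # all-positive signs: 2 / 2^6 two-sided
        assert out["wilcoxon_p"] == pytest.approx(2 / 64)

    def test_ci_of_constant_vector(self):
        a = np.full(6, 0.4)
        b = np.arange(6, dtype=float)
        out = paired_compare(a, b)
        assert out["ci_a"] == 0.0

    def test_t_interval_matches_formula(self, rng):
        from scipy import stats

        a = rng.random(8)
        b = rng.random(8)
        out = paired_compare(a, b)
        hw = stats.t.ppf(0.975, 7) * a.std(ddof=1) / np.sqrt(8)
        assert out["ci_a"] == pytest.approx(hw)

    def test_too_short(self):
        with pytest.raises(ValueError, match="at least 5"):
            paired_compare([1, 2], [3, 4])


class TestClusterCells:
    def _blobs(self, seed=0):
        # two populations with disjoint highly expressed gene sets, so
        # they are separable under the cosine metric
        rng = np.random.default_rng(seed)
        a = np.vstack([np.abs(rng.normal(6, 0.3, size=(15, 40))),
                       np.abs(rng.normal(0.3, 0.1, size=(15, 40)))])
        b = np.vstack([np.abs(rng.normal(0.3, 0.1, size=(15, 40))),
                       np.abs(rng.normal(6, 0.3, size=(15, 40)))])
        X = np.hstack([a, b])
        labels = np.array([0] * 40 + [1] * 40)
        return _nm(X), labels

    def test_separated_blobs_recovered(self):
        En, truth = self._blobs()
        pred = cluster_cells(En, n_pcs=10, resolution=0.3, seed=0)
        assert ari(truth, pred) == pytest.approx(1.0)

    def test_duplicated_cells_share_labels(self):
        En, _ = self._blobs(1)
        X = np.hstack([En.values, En.values])
        pred = cluster_cells(_nm(X), n_pcs=10, seed=0)
        n = En.n_cells
        assert (pred[:n] == pred[n:]).mean() > 0.95

    def test_deterministic(self):
        En, _ = self._blobs(2)
        p1 = cluster_cells(En, seed=3)
        p2 = cluster_cells(En, seed=3)
        np.testing.assert_array_equal(p1, p2)

    def test_neighbor_reduction_warning(self):
        En, _ = self._blobs(3)
        small = _nm(En.values[:, :10])
        with pytest.warns(UserWarning, match="reducing"):
            cluster_cells(small, n_neighbors=15, seed=0)
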