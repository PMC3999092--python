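"""Volume metrics, rank statistics and forward feature selection."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from plaqseg.constants import CLASS_CODES
from plaqseg.evaluate import (
    forward_select,
    friedman_compare,
    relative_volumes,
    volume_metrics,
)


def _brute_spearman(a, b):
    """Midrank Spearman via Pearson correlation of ranks."""

    def midranks(v):
        order = np.argsort(v, kind="stable")
        ranks = np.empty(len(v), dtype=float)
        i = 0
        sv = np.asarray(v, dtype=float)[order]
        while i < len(v):
            j = i
            while j + 1 < len(v) and sv[j + 1] == sv[i]:
                j += 1
            ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
            i = j + 1
        return ranks

    ra, rb = midranks(a), midranks(b)
    ra -= ra.mean()
    rb -= rb.mean()
    return float((ra @ rb) / np.sqrt((ra @ ra) * (rb @ rb)))


def _brute_friedman(values):
    """Classical Friedman chi-square with midranks and tie correction."""
    n, k = values.shape
    ranks = np.apply_along_axis(stats.rankdata, 1, values)
    chi = 12.0 * n / (k * (k + 1)) * ((ranks.mean(axis=0) - (k + 1) / 2) ** 2).sum()
    ties = 0.0
    for row in values:
        _, counts = np.unique(row, return_counts=True)
        ties += float((counts**3 - counts).sum())
    correction = 1.0 - ties / (n * k * (k**2 - 1))
    return chi / correction


class TestRelativeVolumes:
    def test_single_class_wall(self):
        wall = np.zeros((1, 10, 10), dtype=bool)
        wall[0, 2:8, 2:8] = True
        labels = np.where(wall, CLASS_CODES["F"], 0)
        per_slice, per_subject = relative_volumes(labels, wall)
        assert per_slice.iloc[0][["C", "F", "LRNC"]].tolist() == [0.0, 100.0, 0.0]
        assert per_subject.tolist() == [0.0, 100.0, 0.0]

    def test_hand_counted_percentages(self):
        wall = np.zeros((1, 20, 20), dtype=bool)
        wall[0, :10, :20] = True  # 200 voxels
        labels = np.zeros_like(wall, dtype=np.int8)
        flat = np.argwhere(wall)
        for count, code in ((10, 1), (120, 2), (70, 3)):
            take, flat = flat[:count], flat[count:]
            labels[tuple(take.T)] = code
        per_slice, per_subject = relative_volumes(labels, wall)
        assert per_subject.tolist() == [5.0, 60.0, 35.0]

    def test_percentages_sum_to_100(self, small_bundle):
        per_slice, per_subject = relative_volumes(
            small_bundle.true_labels.label_map,
            small_bundle.invivo_geometry.wall_mask,
        )
        np.testing.assert_allclose(
            per_slice[["C", "F", "LRNC"]].sum(axis=1), 100.0, atol=1e-6
        )
        assert per_subject.sum() == pytest.approx(100.0, abs=1e-6)

    def test_empty_wall_slice_excluded_with_warning(self):
        wall = np.zeros((2, 6, 6), dtype=bool)
        wall[0, 1:4, 1:4] = True
        labels = np.where(wall, 2, 0)
        with pytest.warns(UserWarning, match="empty wall"):
            per_slice, _ = relative_volumes(labels, wall)
        assert per_slice["slice_index"].tolist() == [0]


class TestVolumeMetrics:
    def test_perfect_prediction(self):
        truth = np.array([[5.0, 60.0, 35.0], [10.0, 55.0, 35.0], [2.0, 68.0, 30.0]])
        m = volume_metrics(truth, truth)
        np.testing.assert_allclose(m["bias"], 0.0)
        np.testing.assert_allclose(m["abs_error"], 0.0)
        np.testing.assert_allclose(m["spearman"], 1.0)

    def test_constant_offset(self):
        truth = np.array([[5.0, 60.0, 35.0], [10.0, 55.0, 35.0], [2.0, 68.0, 30.0]])
        m = volume_metrics(truth + 5.0, truth)
        np.testing.assert_allclose(m["bias"], 5.0)
        np.testing.assert_allclose(m["abs_error"], 5.0)
        np.testing.assert_allclose(m["spearman"], 1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_spearman_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(4, 11)
        a = rng.integers(0, 5, size=n).astype(float)  # ties likely
        b = rng.integers(0, 5, size=n).astype(float)
        if len(set(a)) < 2 or len(set(b)) < 2:
            a[0] += 1.5
            b[-1] += 2.5
        m = volume_metrics(a[:, None], b[:, None])
        assert m["spearman"].iloc[0] == pytest.approx(_brute_spearman(a, b), abs=1e-12)

    def test_too_few_pairs_flagged(self):
        m = volume_metrics(np.array([[1.0], [2.0]]), np.array([[1.0], [3.0]]))
        assert np.isnan(m["spearman"].iloc[0])


class TestFriedman:
    def test_identical_methods_statistic_zero(self):
        df = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [1.0, 2, 3, 4]})
        with pytest.warns(UserWarning, match="degenerate"):
            stat, p, ranks, _ = friedman_compare(df)
        assert stat == 0.0 and p == 1.0

    def test_uniformly_worse_method_ranks_highest(self):
        rng = np.random.default_rng(0)
        base = rng.normal(10, 1, size=20)
        df = pd.DataFrame(
            {"good": base, "mid": base + 1.0, "bad": base + 3.0}
        )
        stat, p, ranks, pairwise = friedman_compare(df)
        assert ranks.idxmax() == "bad"
        assert ranks.idxmin() == "good"
        assert p < 0.01
        worst_pair = pairwise[
            (pairwise["method_a"] == "good") & (pairwise["method_b"] == "bad")
        ]
        assert float(worst_pair["p_sign_bonferroni"].iloc[0]) < 0.01

    def test_hand_computed_toy_table(self):
        # ranks per slice: (1,2,3),(1,2,3),(2,1,3),(1,3,2) -> chi2 = 4.5
        df = pd.DataFrame(
            {
                "m1": [1.0, 1.0, 5.0, 1.0],
                "m2": [2.0, 2.0, 4.0, 3.0],
                "m3": [3.0, 3.0, 6.0, 2.0],
            }
        )
        stat, _, _, _ = friedman_compare(df)
        assert stat == pytest.approx(4.5, abs=1e-9)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_brute_force_on_random_tables(self, seed):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame(rng.normal(size=(8, 4)), columns=list("abcd"))
        stat, _, _, _ = friedman_compare(df)
        assert stat == pytest.approx(_brute_friedman(df.to_numpy()), abs=1e-9)


class TestForwardSelect:
    def test_perfect_feature_selected_first(self):
        rng = np.random.default_rng(0)
        n = 100
        y = np.array(["C"] * n + ["F"] * n)
        noise = rng.normal(size=(2 * n, 3))
        perfect = np.r_[np.zeros(n), np.ones(n)] * 10
        X = np.column_stack([noise[:, 0], perfect, noise[:, 1:]])
        names = ["n1", "perfect", "n2", "n3"]
        assert forward_select(X, y, names, k=2)[0] == "perfect"

    def test_duplicate_column_not_selected_before_original(self):
        rng = np.random.default_rng(1)
        n = 80
        y = np.array(["C"] * n + ["F"] * n)
        f = np.r_[rng.normal(0, 1, n), rng.normal(2, 1, n)]
        X = np.column_stack([f, f, rng.normal(size=2 * n)])
        sel = forward_select(X, y, ["f", "f_copy", "noise"], k=3)
        assert sel.index("f") < sel.index("f_copy")

    def test_fewer_features_than_k_warns(self):
        y = np.array(["C"] * 10 + ["F"] * 10)
        X = np.random.default_rng(2).normal(size=(20, 2))
        X[10:, 0] += 3
        with pytest.warns(UserWarning):
            sel = forward_select(X, y, ["a", "b"], k=5)
        assert len(sel) == 2

    def test_cta_first_for_calcification_pair(self, prepared_subject):
        """On the phantom, CTA intensity is the dominant feature for
        separating calcification from fibrous tissue."""
        from plaqseg.features import feature_names

        feats = feature_names("all")
        t = prepared_subject.train_table
        pair = t[t["hard_label"].isin(["C", "F"])]
        sel = forward_select(
            pair[feats].to_numpy(), pair["hard_label"].to_numpy(), feats, k=3
        )
        assert sel[0] == "cta"
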