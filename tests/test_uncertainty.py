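"""Soft labels, contour-distance weights, robust Gaussian fitting and
outlier rejection."""

import numpy as np
import pandas as pd
import pytest

from plaqseg.constants import CLASS_NAMES
from plaqseg.errors import NumericalError, ValidationError
from plaqseg.features import feature_names
from plaqseg.phantom import ReferenceLabels
from plaqseg.preproc import WallGeometry
from plaqseg.uncertainty import (
    contour_weights,
    reject_outliers,
    robust_gaussian_fit,
    soft_labels,
)


def _halfplane_geometry(lumen_mm, outer_mm, spacing=(1.0, 0.25, 0.25), shape=(1, 8, 160)):
    """Slab vessel: lumen = {x < lumen_mm}, outer = {x < outer_mm}."""
    x = np.arange(shape[2]) * spacing[2]
    lumen = np.broadcast_to(x < lumen_mm, shape).copy()
    outer = np.broadcast_to(x < outer_mm, shape).copy()
    return WallGeometry(lumen, outer, spacing)


class TestSoftLabels:
    def test_sigma_zero_n_zero_reproduces_hard_labels(self, small_bundle):
        labels = small_bundle.reference_labels
        field = soft_labels(
            labels, small_bundle.per_slice_dice, 0.0, 0.0,
            small_bundle.images.spacing_mm,
        )
        for cls in CLASS_NAMES:
            assert np.array_equal(field.w_c[cls], labels.masks[cls].astype(float))

    def test_per_voxel_sum_equals_dice_power_n(self, small_bundle):
        labels = small_bundle.reference_labels
        dice = small_bundle.per_slice_dice
        for n in (1.0, 5.0):
            field = soft_labels(labels, dice, 0.5, n, small_bundle.images.spacing_mm)
            total = sum(field.w_c[c] for c in CLASS_NAMES)
            for z in range(labels.shape[0]):
                inside = field.valid[z]
                if inside.any():
                    np.testing.assert_allclose(
                        total[z][inside], dice[z] ** n, atol=1e-6
                    )

    def test_slice_weight_ratio_closed_form(self):
        """n=24 amplifies a 0.9-vs-0.6 Dice contrast to ~1.7e4."""
        masks = np.zeros((2, 8, 8), dtype=np.int8)
        masks[:, 2:6, 2:6] = 2  # all fibrous
        labels = ReferenceLabels.from_label_map(masks)
        dice = np.array([0.9, 0.6])
        field = soft_labels(labels, dice, 0.0, 24.0, (1.0, 0.5, 0.5))
        ratio = field.w_c["F"][0, 3, 3] / field.w_c["F"][1, 3, 3]
        assert ratio == pytest.approx((0.9 / 0.6) ** 24, rel=1e-9)

    def test_monotone_in_n(self):
        """Raising n never favours the lower-Dice slice."""
        masks = np.zeros((2, 6, 6), dtype=np.int8)
        masks[:, 1:5, 1:5] = 2
        labels = ReferenceLabels.from_label_map(masks)
        dice = np.array([0.95, 0.7])
        prev = None
        for n in (0, 3, 9, 24, 39):
            field = soft_labels(labels, dice, 0.0, float(n), (1.0, 0.5, 0.5))
            rel = field.w_c["F"][1, 2, 2] / field.w_c["F"][0, 2, 2]
            if prev is not None:
                assert rel <= prev + 1e-12
            prev = rel

    def test_boundary_voxels_get_split_weights(self, small_bundle):
        field = soft_labels(
            small_bundle.reference_labels,
            small_bundle.per_slice_dice,
            1.0, 0.0,
            small_bundle.images.spacing_mm,
        )
        w = np.stack([field.w_c[c] for c in CLASS_NAMES])
        split = (w > 0.05).sum(axis=0) >= 2
        assert split.any()

    def test_negative_parameters_rejected(self, small_bundle):
        with pytest.raises(ValidationError):
            soft_labels(
                small_bundle.reference_labels, small_bundle.per_slice_dice,
                -0.1, 0.0, small_bundle.images.spacing_mm,
            )


class TestContourWeights:
    def test_identical_geometries_weight_one(self, small_bundle):
        geom = small_bundle.invivo_geometry
        field = contour_weights(geom, geom)
        assert np.all(field.w[geom.wall_mask] == 1.0)

    def test_five_mm_offset_gives_zero(self):
        """Both contours offset by 5 mm: weight exactly 0 in the band
        where both differences are 5 mm."""
        invivo = _halfplane_geometry(10.0, 20.0)
        ref = _halfplane_geometry(5.0, 15.0)
        field = contour_weights(ref, invivo)
        x = np.arange(160) * 0.25
        band = invivo.wall_mask & np.broadcast_to(
            (x >= 10.5) & (x <= 14.5), invivo.shape
        )
        assert band.any()
        assert np.all(field.w[band] == 0.0)

    def test_linear_midpoint(self):
        """2.5 mm lumen offset halves the lumen weight; the combined
        weight at the radial midpoint is 0.75."""
        invivo = _halfplane_geometry(10.0, 20.0)
        ref = _halfplane_geometry(7.5, 20.0)
        field = contour_weights(ref, invivo)
        wall = invivo.wall_mask
        assert np.allclose(field.w_lumen[wall], 0.5)
        assert np.allclose(field.w_outer[wall], 1.0)
        mid = wall & (np.abs(field.r - 0.5) < 0.02)
        assert mid.any()
        np.testing.assert_allclose(field.w[mid], 0.75, atol=0.02)
        # exact combination rule everywhere in the wall
        np.testing.assert_allclose(
            field.w[wall],
            (1 - field.r[wall]) * field.w_lumen[wall]
            + field.r[wall] * field.w_outer[wall],
        )

    def test_delta_symmetric_under_geometry_swap(self, small_bundle):
        a = contour_weights(
            small_bundle.reference_geometry, small_bundle.invivo_geometry
        )
        b = contour_weights(
            small_bundle.invivo_geometry, small_bundle.reference_geometry
        )
        np.testing.assert_allclose(a.w_lumen, b.w_lumen)
        np.testing.assert_allclose(a.w_outer, b.w_outer)


class TestRobustGaussianFit:
    def test_clean_gaussian_recovers_plain_estimates(self):
        rng = np.random.default_rng(0)
        mean = np.array([1.0, -2.0, 0.5])
        A = rng.normal(size=(3, 3))
        cov = A @ A.T + np.eye(3)
        X = rng.multivariate_normal(mean, cov, size=5000)
        fit = robust_gaussian_fit(X)
        assert np.abs(fit.mean - X.mean(axis=0)).max() < 0.15
        assert np.abs(fit.covariance - np.cov(X.T, bias=True)).max() < 0.6

    def test_outliers_hurt_plain_mean_more(self):
        """With 5% gross outliers the robust mean beats the plain mean
        in at least 95% of 100 replicates."""
        wins = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(300, 3))
            n_out = 15
            X[:n_out] += 10.0
            fit = robust_gaussian_fit(X)
            if np.linalg.norm(fit.mean) < np.linalg.norm(X.mean(axis=0)):
                wins += 1
        assert wins >= 95

    def test_duplicated_point_cloud_singular(self):
        X = np.tile(np.array([1.0, 2.0, 3.0]), (50, 1))
        with pytest.raises(NumericalError):
            robust_gaussian_fit(X)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValidationError):
            robust_gaussian_fit(np.zeros((4, 3)))


class TestRejectOutliers:
    @staticmethod
    def _table(n_per_class=1000, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for cls, shift in zip(CLASS_NAMES, (0.0, 5.0, 10.0)):
            X = rng.normal(shift, 1.0, size=(n_per_class, 3))
            df = pd.DataFrame(X, columns=["f1", "f2", "f3"])
            df["hard_label"] = cls
            rows.append(df)
        out = pd.concat(rows, ignore_index=True)
        out["voxel_index"] = np.arange(len(out))
        return out

    def test_exactly_ten_percent_per_class(self):
        t = self._table(1000)
        out = reject_outliers(t, ["f1", "f2", "f3"], 0.10)
        for cls in CLASS_NAMES:
            sel = out[out["hard_label"] == cls]
            assert (~sel["keep_flag"]).sum() == 100

    def test_ceil_count_rule(self):
        t = self._table(101)
        out = reject_outliers(t, ["f1", "f2", "f3"], 0.10)
        for cls in CLASS_NAMES:
            sel = out[out["hard_label"] == cls]
            assert (~sel["keep_flag"]).sum() == 11  # ceil(10.1)

    def test_fraction_zero_keeps_everything(self):
        t = self._table(50)
        out = reject_outliers(t, ["f1", "f2", "f3"], 0.0)
        assert out["keep_flag"].all()

    def test_rejection_invariant_to_row_permutation(self):
        t = self._table(200, seed=5)
        out_a = reject_outliers(t, ["f1", "f2", "f3"], 0.10)
        perm = np.random.default_rng(1).permutation(len(t))
        out_b = reject_outliers(
            t.iloc[perm].reset_index(drop=True), ["f1", "f2", "f3"], 0.10
        )
        rej_a = set(out_a.loc[~out_a["keep_flag"], "voxel_index"])
        rej_b = set(out_b.loc[~out_b["keep_flag"], "voxel_index"])
        assert rej_a == rej_b

    def test_small_class_rejected(self):
        t = self._table(30)
        t = t[t["hard_label"].isin(["F", "LRNC"]) | (t.index < 5)]
        with pytest.raises(ValidationError):
            reject_outliers(t, ["f1", "f2", "f3"], 0.10)
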