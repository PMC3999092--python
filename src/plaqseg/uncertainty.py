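"""Three strategies for training on misregistered reference labels.

1. **Soft labels with Dice weighting** — the binary component maps are
   blurred with an in-plane Gaussian, renormalized so the three classes
   sum to 1 per voxel, and the whole slice is multiplied by
   ``Dice_s ** n`` where ``Dice_s`` is the per-slice wall overlap
   between the reference and in vivo segmentations.  Per voxel the
   class weights then sum to ``Dice_s ** n``.
2. **Contour-distance weights** — each voxel's weight interpolates
   between the agreement of the lumen contours and of the outer-wall
   contours: weight 1 for a local contour difference of 0 mm, 0 at
   5 mm, linear in between, mixed by the voxel's relative radial
   position ``r = d_lumen / (d_lumen + d_outer)``.
3. **Gaussian outlier rejection** — per class, a Gaussian is robustly
   fitted by iteratively reweighting samples by their Mahalanobis
   distance to the running mean, and the 10% of samples farthest from
   the fitted distribution are rejected.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from plaqseg.constants import CLASS_NAMES
from plaqseg.errors import (
    DegenerateInputError,
    NumericalError,
    ValidationError,
)
from plaqseg.features import gaussian_blur_inplane
from plaqseg.phantom import ReferenceLabels
from plaqseg.preproc import WallGeometry

__all__ = [
    "SoftLabelField",
    "ContourWeightField",
    "RobustGaussianFit",
    "soft_labels",
    "contour_weights",
    "robust_gaussian_fit",
    "reject_outliers",
]


@dataclass
class SoftLabelField:
    """Per-class per-voxel soft-label weights after Dice^n weighting."""

    sigma_blur_mm: float
    n_exponent: float
    dice_per_slice: np.ndarray
    w_c: dict[str, np.ndarray]
    valid: np.ndarray  # voxels inside the union of blurred supports


@dataclass
class ContourWeightField:
    """Local registration-accuracy weights from contour distances."""

    w_lumen: np.ndarray
    w_outer: np.ndarray
    r: np.ndarray
    w: np.ndarray
    valid: np.ndarray


@dataclass
class RobustGaussianFit:
    mean: np.ndarray
    covariance: np.ndarray
    n_iter: int
    converged: bool

    def mahalanobis_sq(self, X: np.ndarray) -> np.ndarray:
        delta = np.asarray(X, dtype=float) - self.mean
        try:
            L = np.linalg.cholesky(self.covariance)
        except np.linalg.LinAlgError as exc:
            raise NumericalError("singular covariance") from exc
        sol = np.linalg.solve(L, delta.T)
        return np.einsum("ij,ij->j", sol, sol)


def soft_labels(
    labels: ReferenceLabels,
    dice_per_slice: np.ndarray,
    sigma_blur_mm: float,
    n_exponent: float,
    spacing_mm: tuple[float, float, float],
) -> SoftLabelField:
    """Blur-and-renormalize soft labels, slice-weighted by Dice^n.

    ``w_c(x) = Dice_s^n * (G_sigma * M_c)(x) / sum_c' (G_sigma * M_c')(x)``
    on slice ``s``.  Voxels outside all blurred supports (zero
    denominator) are excluded; sigma = 0 and n = 0 reproduce the
    one-hot hard labels exactly.
    """
    if sigma_blur_mm < 0 or n_exponent < 0:
        raise ValidationError("sigma and n must be >= 0")
    dice = np.asarray(dice_per_slice, dtype=float)
    if dice.shape[0] != labels.shape[0]:
        raise ValidationError("dice_per_slice length must equal slice count")
    blurred = {
        cls: gaussian_blur_inplane(
            labels.masks[cls].astype(float), sigma_blur_mm, spacing_mm
        )
        for cls in CLASS_NAMES
    }
    denom = sum(blurred.values())
    valid = denom > 1e-12
    if not valid.any():
        raise DegenerateInputError("blurred supports are empty everywhere")
    slice_w = np.where(np.isnan(dice), 0.0, dice) ** n_exponent
    slice_w = slice_w[:, None, None]
    w_c = {}
    for cls in CLASS_NAMES:
        w = np.zeros_like(denom)
        np.divide(blurred[cls], denom, out=w, where=valid)
        w_c[cls] = w * slice_w
    valid = valid & ~np.isnan(dice)[:, None, None]
    return SoftLabelField(
        sigma_blur_mm=sigma_blur_mm,
        n_exponent=n_exponent,
        dice_per_slice=dice,
        w_c=w_c,
        valid=valid,
    )


def contour_weights(
    ref_geometry: WallGeometry,
    invivo_geometry: WallGeometry,
    max_dist_mm: float = 5.0,
) -> ContourWeightField:
    """Per-voxel sample weights from local lumen/outer contour agreement.

    The lumen (outer) weight is ``clamp(1 - delta/max_dist, 0, 1)``
    where ``delta`` is the absolute difference of the unsigned distance
    maps of the two geometries; the combined weight mixes the two by the
    relative radial position, so lumen agreement dominates near the
    lumen and outer-wall agreement near the outer boundary.
    """
    if ref_geometry.shape != invivo_geometry.shape:
        raise ValidationError("geometries are on different grids")
    d_lum_ref = np.abs(ref_geometry.d_lumen)
    d_lum_inv = np.abs(invivo_geometry.d_lumen)
    d_out_ref = np.abs(ref_geometry.d_outer)
    d_out_inv = np.abs(invivo_geometry.d_outer)
    delta_lum = np.abs(d_lum_ref - d_lum_inv)
    delta_out = np.abs(d_out_ref - d_out_inv)
    w_lumen = np.clip(1.0 - delta_lum / max_dist_mm, 0.0, 1.0)
    w_outer = np.clip(1.0 - delta_out / max_dist_mm, 0.0, 1.0)
    denom = d_lum_inv + d_out_inv
    valid = denom > 0
    if not valid.all():
        warnings.warn(
            f"{int((~valid).sum())} voxels with zero lumen+outer distance excluded"
        )
    r = np.zeros_like(denom)
    np.divide(d_lum_inv, denom, out=r, where=valid)
    w = (1.0 - r) * w_lumen + r * w_outer
    w[~valid] = 0.0
    return ContourWeightField(w_lumen=w_lumen, w_outer=w_outer, r=r, w=w, valid=valid)


def robust_gaussian_fit(
    X: np.ndarray,
    max_iter: int = 50,
    tol: float = 1e-8,
    ridge: float = 1e-6,
) -> RobustGaussianFit:
    """Robust mean/covariance by iterative Mahalanobis reweighting.

    Sample weights are ``exp(-d^2/2)`` (floored at 1e-12) under the
    current estimate; the weighted covariance carries the Gaussian
    consistency factor 2 (for clean Gaussian data the uncorrected
    weighted covariance estimates Sigma/2, so the truth is the unique
    fixed point only after correction) and is ridge-regularized by
    ``ridge * trace/d * I``.  Iteration stops at relative parameter
    change below ``tol`` or ``max_iter`` sweeps.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValidationError("X must be 2D (samples x features)")
    n, d = X.shape
    if n < d + 2:
        raise ValidationError(f"need at least {d + 2} samples for {d} features")

    def _estimate(
        weights: np.ndarray, consistency: float
    ) -> tuple[np.ndarray, np.ndarray]:
        wsum = weights.sum()
        mean = weights @ X / wsum
        delta = X - mean
        cov = consistency * (weights[:, None] * delta).T @ delta / wsum
        cov += ridge * np.trace(cov) / d * np.eye(d)
        return mean, cov

    mean, cov = _estimate(np.ones(n), 1.0)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        fit = RobustGaussianFit(mean, cov, it, False)
        d2 = fit.mahalanobis_sq(X)
        w = np.maximum(np.exp(-0.5 * d2), 1e-12)
        new_mean, new_cov = _estimate(w, 2.0)
        scale = max(np.abs(mean).max(), np.abs(cov).max(), 1e-300)
        change = max(
            np.abs(new_mean - mean).max(), np.abs(new_cov - cov).max()
        ) / scale
        mean, cov = new_mean, new_cov
        if change < tol:
            converged = True
            break
    try:
        np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise NumericalError("covariance singular after regularization") from exc
    return RobustGaussianFit(mean=mean, covariance=cov, n_iter=it, converged=converged)


def reject_outliers(
    table: pd.DataFrame,
    feature_cols: list[str],
    fraction: float = 0.10,
) -> pd.DataFrame:
    """Per class, reject the ``ceil(fraction * n)`` samples with the
    largest Mahalanobis distance under a robustly fitted Gaussian.

    Rejected rows get ``keep_flag = False``; ties break by stable row
    order.  Each class must have at least 10 samples.
    """
    if not 0 <= fraction < 1:
        raise ValidationError("fraction must be in [0, 1)")
    out = table.copy()
    if "keep_flag" not in out.columns:
        out["keep_flag"] = True
    if fraction == 0:
        return out
    for cls in CLASS_NAMES:
        cls_pos = np.flatnonzero((out["hard_label"] == cls).to_numpy())
        n = len(cls_pos)
        if n == 0:
            continue
        if n < 10:
            raise ValidationError(f"class {cls} has {n} samples; need >= 10")
        Xc = out.iloc[cls_pos][feature_cols].to_numpy(dtype=float)
        fit = robust_gaussian_fit(Xc)
        d2 = fit.mahalanobis_sq(Xc)
        n_reject = math.ceil(fraction * n)
        order = np.argsort(-d2, kind="stable")
        reject_local = order[:n_reject]
        out.iloc[cls_pos[reject_local], out.columns.get_loc("keep_flag")] = False
    return out
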