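"""Per-voxel feature extraction and sample-table assembly.

The full feature set has 24 columns: the five normalized MR intensities,
the same five blurred with an in-plane Gaussian (sigma = 1 mm), their
gradient magnitudes and Laplacians at the same scale, the original CTA
intensity, the unsigned Euclidean distances to the lumen and outer wall,
and the product of the two distances.  Subsets select the MRI-only,
CTA-only and distance-only configurations and their combinations.

Derivative features are computed in-plane (2D per slice): the slice
thickness exceeds the 1 mm kernel scale, and the whole analysis is
slice-oriented.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage

from plaqseg.constants import CLASS_NAMES, CTA_CHANNEL, MR_CHANNELS
from plaqseg.errors import DegenerateInputError, ValidationError
from plaqseg.phantom import ReferenceLabels
from plaqseg.preproc import MultiModalStack, WallGeometry

__all__ = [
    "FEATURE_SUBSETS",
    "feature_names",
    "extract_features",
    "attach_labels",
    "subsample_training",
]

DISTANCE_FEATURES = ("d_lumen", "d_outer", "d_product")


def _mr_feature_names() -> list[str]:
    names = [f"{ch}" for ch in MR_CHANNELS]
    names += [f"{ch}_blur" for ch in MR_CHANNELS]
    names += [f"{ch}_gradmag" for ch in MR_CHANNELS]
    names += [f"{ch}_laplace" for ch in MR_CHANNELS]
    return names


FEATURE_SUBSETS: dict[str, list[str]] = {
    "all": _mr_feature_names() + [CTA_CHANNEL] + list(DISTANCE_FEATURES),
    "mri": _mr_feature_names(),
    "cta": [CTA_CHANNEL],
    "distances": list(DISTANCE_FEATURES),
    "mri+distances": _mr_feature_names() + list(DISTANCE_FEATURES),
    "cta+distances": [CTA_CHANNEL] + list(DISTANCE_FEATURES),
}

#: Columns of a sample table that are not features.
META_COLUMNS = ["subject_id", "slice_index", "voxel_index"]
LABEL_COLUMNS = ["hard_label", "w_C", "w_F", "w_LRNC", "keep_flag"]


def feature_names(subset: str = "all") -> list[str]:
    """Feature column names for a subset configuration."""
    try:
        return list(FEATURE_SUBSETS[subset])
    except KeyError:
        raise ValidationError(
            f"unknown feature subset {subset!r}; choose from {sorted(FEATURE_SUBSETS)}"
        ) from None


def _sigma_vox(sigma_mm: float, spacing_mm: tuple[float, float, float]) -> tuple[float, float]:
    _, dy, dx = spacing_mm
    return sigma_mm / dy, sigma_mm / dx


def gaussian_blur_inplane(
    volume: np.ndarray, sigma_mm: float, spacing_mm: tuple[float, float, float]
) -> np.ndarray:
    """In-plane Gaussian blur with sigma in physical mm (honours
    anisotropic in-plane spacing); sigma 0 is the identity."""
    if sigma_mm == 0:
        return np.asarray(volume, dtype=float).copy()
    sy, sx = _sigma_vox(sigma_mm, spacing_mm)
    return ndimage.gaussian_filter(np.asarray(volume, dtype=float), sigma=(0, sy, sx))


def gradient_magnitude_inplane(
    volume: np.ndarray, sigma_mm: float, spacing_mm: tuple[float, float, float]
) -> np.ndarray:
    """In-plane Gaussian gradient magnitude, derivatives per mm."""
    _, dy, dx = spacing_mm
    sy, sx = _sigma_vox(sigma_mm, spacing_mm)
    vol = np.asarray(volume, dtype=float)
    gy = ndimage.gaussian_filter(vol, sigma=(0, sy, sx), order=(0, 1, 0)) / dy
    gx = ndimage.gaussian_filter(vol, sigma=(0, sy, sx), order=(0, 0, 1)) / dx
    return np.hypot(gy, gx)


def _gauss_kernel(sigma_vox: float, order: int) -> np.ndarray:
    """Sampled Gaussian (order 0) or its second derivative (order 2),
    truncated at 4 sigma; the derivative kernel is zero-sum corrected so
    it annihilates constants exactly."""
    radius = int(4.0 * sigma_vox + 0.5)
    x = np.arange(-radius, radius + 1, dtype=float)
    g = np.exp(-0.5 * (x / sigma_vox) ** 2)
    g /= g.sum()
    if order == 0:
        return g
    g2 = g * ((x / sigma_vox**2) ** 2 - 1.0 / sigma_vox**2)
    return g2 - g2.sum() * g


def laplacian_inplane(
    volume: np.ndarray, sigma_mm: float, spacing_mm: tuple[float, float, float]
) -> np.ndarray:
    """In-plane Gaussian Laplacian, second derivatives per mm^2."""
    if sigma_mm <= 0:
        raise ValidationError("Laplacian scale sigma must be positive")
    _, dy, dx = spacing_mm
    sy, sx = _sigma_vox(sigma_mm, spacing_mm)
    vol = np.asarray(volume, dtype=float)
    gyy = ndimage.correlate1d(
        ndimage.correlate1d(vol, _gauss_kernel(sy, 2), axis=1), _gauss_kernel(sx, 0), axis=2
    ) / dy**2
    gxx = ndimage.correlate1d(
        ndimage.correlate1d(vol, _gauss_kernel(sx, 2), axis=2), _gauss_kernel(sy, 0), axis=1
    ) / dx**2
    return gyy + gxx


def extract_features(
    images: MultiModalStack,
    geometry: WallGeometry,
    mask: np.ndarray | None = None,
    sigma_mm: float = 1.0,
    subset: str = "all",
    subject_id: int = 0,
) -> pd.DataFrame:
    """Assemble the per-voxel feature table for the voxels of ``mask``.

    Distance features come from ``geometry`` (reference geometry for
    training rows, in vivo geometry for testing rows).  MR channels are
    expected to be ROI-normalized already; the CTA channel is used at
    its original intensities.
    """
    names = feature_names(subset)
    if mask is None:
        mask = geometry.wall_mask
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != geometry.shape:
        raise ValidationError("mask and geometry are on different grids")

    needs_mr = any(n.split("_")[0] in ("t1w2d", "pdw", "tof", "t1w3d") for n in names)
    required = set(MR_CHANNELS) if needs_mr else set()
    if CTA_CHANNEL in names:
        required.add(CTA_CHANNEL)
    missing = required - set(images.channels)
    if missing:
        raise ValidationError(f"missing channels for subset {subset!r}: {sorted(missing)}")
    if images.shape != geometry.shape:
        raise ValidationError("images and geometry are on different grids")

    spacing = images.spacing_mm
    volumes: dict[str, np.ndarray] = {}
    for ch in MR_CHANNELS:
        if ch not in images.channels:
            continue
        vol = images.channels[ch]
        if f"{ch}" in names:
            volumes[ch] = np.asarray(vol, dtype=float)
        if f"{ch}_blur" in names:
            volumes[f"{ch}_blur"] = gaussian_blur_inplane(vol, sigma_mm, spacing)
        if f"{ch}_gradmag" in names:
            volumes[f"{ch}_gradmag"] = gradient_magnitude_inplane(vol, sigma_mm, spacing)
        if f"{ch}_laplace" in names:
            volumes[f"{ch}_laplace"] = laplacian_inplane(vol, sigma_mm, spacing)
    if CTA_CHANNEL in names:
        volumes[CTA_CHANNEL] = np.asarray(images.channels[CTA_CHANNEL], dtype=float)
    if "d_lumen" in names:
        volumes["d_lumen"] = np.abs(geometry.d_lumen)
        volumes["d_outer"] = np.abs(geometry.d_outer)
        volumes["d_product"] = volumes["d_lumen"] * volumes["d_outer"]

    idx = np.argwhere(mask)
    flat = np.ravel_multi_index(tuple(idx.T), mask.shape)
    data = {
        "subject_id": np.full(len(idx), subject_id, dtype=int),
        "slice_index": idx[:, 0],
        "voxel_index": flat,
    }
    for name in names:
        data[name] = volumes[name][mask]
    return pd.DataFrame(data)


def attach_labels(table: pd.DataFrame, labels: ReferenceLabels) -> pd.DataFrame:
    """Add hard labels, one-hot per-class weights and keep_flag to a
    feature table, looking labels up by flat voxel index."""
    label_flat = labels.label_map.reshape(-1)
    codes = label_flat[table["voxel_index"].to_numpy()]
    if np.any(codes == 0):
        raise ValidationError("some table voxels fall outside the labelled wall")
    out = table.copy()
    out["hard_label"] = [CLASS_NAMES[c - 1] for c in codes]
    for i, cls in enumerate(CLASS_NAMES):
        out[f"w_{cls}"] = (codes == i + 1).astype(float)
    out["keep_flag"] = True
    return out


def subsample_training(
    table: pd.DataFrame, fraction: float = 0.10, seed: int = 0
) -> pd.DataFrame:
    """Deterministic stratified subsample of training voxels.

    Within each (subject, slice) group a seeded permutation selects
    ``floor(fraction * n)`` rows, so the identical subset is reused
    across experiment configurations for a given subject and seed.
    """
    if not 0 < fraction <= 1:
        raise ValidationError("fraction must be in (0, 1]")
    if len(table) == 0:
        raise DegenerateInputError("cannot subsample an empty table")
    if fraction == 1.0:
        return table
    rng = np.random.default_rng(seed)
    keep: list[np.ndarray] = []
    for _, group in table.groupby(["subject_id", "slice_index"], sort=True):
        n = int(np.floor(fraction * len(group)))
        perm = rng.permutation(len(group))
        keep.append(group.index.to_numpy()[perm[:n]])
    sel = np.sort(np.concatenate(keep)) if keep else np.array([], dtype=int)
    return table.loc[sel]
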