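"""Intensity normalization, in-plane resampling, distance maps, and
registration-quality metrics (per-slice Dice, mean contour distance).

All volumetric arrays are indexed ``(slice, row, col)`` = ``(z, y, x)``
with voxel spacing ``spacing_mm = (dz, dy, dx)`` in millimetres.
Physical coordinates are ``index * spacing`` (origin at the centre of
voxel 0, axes aligned with the grid).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from plaqseg.errors import DegenerateInputError, ValidationError

__all__ = [
    "MultiModalStack",
    "WallGeometry",
    "normalize_roi",
    "resample_inplane",
    "resample_labels",
    "signed_distance",
    "dice_per_slice",
    "mean_contour_distance",
]


@dataclass
class MultiModalStack:
    """Co-registered per-modality 3D intensity arrays on one grid.

    Parameters
    ----------
    channels
        Mapping of channel name (``t1w2d``, ``pdw``, ``tof``,
        ``t1w3d_pre``, ``t1w3d_post``, ``cta``) to a 3D float array.
    spacing_mm
        Voxel size ``(dz, dy, dx)`` in mm, shared by all channels.
    """

    channels: dict[str, np.ndarray]
    spacing_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValidationError("MultiModalStack needs at least one channel")
        shapes = {name: ch.shape for name, ch in self.channels.items()}
        if len(set(shapes.values())) != 1:
            raise ValidationError(f"channels disagree on grid shape: {shapes}")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValidationError(f"invalid spacing {self.spacing_mm}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return next(iter(self.channels.values())).shape


@dataclass
class WallGeometry:
    """Vessel-wall geometry: lumen/outer masks and signed distance maps.

    ``d_lumen`` / ``d_outer`` are signed Euclidean distances (mm) to the
    lumen and outer-wall boundaries: negative inside the respective
    mask, positive outside.  Downstream features use the unsigned
    distances restricted to the wall.
    """

    lumen_mask: np.ndarray
    outer_mask: np.ndarray
    spacing_mm: tuple[float, float, float]
    wall_mask: np.ndarray = field(init=False)
    d_lumen: np.ndarray = field(init=False)
    d_outer: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        lumen = np.asarray(self.lumen_mask, dtype=bool)
        outer = np.asarray(self.outer_mask, dtype=bool)
        if lumen.shape != outer.shape:
            raise ValidationError("lumen and outer masks differ in shape")
        if np.any(lumen & ~outer):
            raise ValidationError("lumen mask is not contained in outer mask")
        self.lumen_mask = lumen
        self.outer_mask = outer
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        self.wall_mask = outer & ~lumen
        self.d_lumen = signed_distance(lumen, self.spacing_mm)
        self.d_outer = signed_distance(outer, self.spacing_mm)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.outer_mask.shape


def normalize_roi(channel: np.ndarray, roi: np.ndarray) -> np.ndarray:
    """Affinely rescale a channel so the ROI has mean 0 and SD 100.

    The same affine map is applied to the whole channel; only the ROI
    statistics define it.  Raises :class:`DegenerateInputError` when the
    ROI has fewer than two voxels or zero intensity variance.
    """
    channel = np.asarray(channel, dtype=float)
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != channel.shape:
        raise ValidationError("roi shape does not match channel shape")
    vals = channel[roi]
    if vals.size < 2:
        raise DegenerateInputError("ROI must contain at least 2 voxels")
    mean = vals.mean()
    sd = vals.std()
    if sd == 0:
        raise DegenerateInputError("zero intensity variance inside ROI")
    return (channel - mean) * (100.0 / sd)


def _inplane_output_grid(
    shape: tuple[int, ...],
    spacing_mm: tuple[float, float, float],
    target_mm: float,
) -> tuple[tuple[int, int], np.ndarray, np.ndarray]:
    """Output in-plane grid size and input-space sample coordinates."""
    _, ny, nx = shape
    _, dy, dx = spacing_mm
    ny_out = max(int(round(ny * dy / target_mm)), 1)
    nx_out = max(int(round(nx * dx / target_mm)), 1)
    ys = np.arange(ny_out) * (target_mm / dy)
    xs = np.arange(nx_out) * (target_mm / dx)
    return (ny_out, nx_out), ys, xs


def _resample_volume(
    volume: np.ndarray,
    spacing_mm: tuple[float, float, float],
    target_mm: float,
    order: int,
) -> np.ndarray:
    (ny_out, nx_out), ys, xs = _inplane_output_grid(volume.shape, spacing_mm, target_mm)
    nz = volume.shape[0]
    zz = np.broadcast_to(np.arange(nz)[:, None, None], (nz, ny_out, nx_out))
    yy = np.broadcast_to(ys[None, :, None], (nz, ny_out, nx_out))
    xx = np.broadcast_to(xs[None, None, :], (nz, ny_out, nx_out))
    return ndimage.map_coordinates(
        np.asarray(volume, dtype=float),
        [zz, yy, xx],
        order=order,
        mode="nearest",
    )


def resample_inplane(
    channel: np.ndarray,
    spacing_mm: tuple[float, float, float],
    target_mm: float = 0.25,
) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Resample intensities in-plane to ``target_mm`` (default 0.25 mm)
    with cubic B-spline interpolation; through-plane spacing unchanged.

    Returns ``(resampled, new_spacing)``.
    """
    if spacing_mm is None:
        raise ValidationError("spacing metadata required for resampling")
    channel = np.asarray(channel)
    if channel.ndim != 3:
        raise ValidationError("expected a 3D volume")
    out = _resample_volume(channel, spacing_mm, target_mm, order=3)
    return out, (spacing_mm[0], target_mm, target_mm)


def resample_labels(
    label_map: np.ndarray,
    spacing_mm: tuple[float, float, float],
    target_mm: float = 0.25,
) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Resample an integer label map in-plane to ``target_mm``.

    Each class indicator (background included) is interpolated linearly
    and the output voxel takes the argmax class; exact ties resolve to
    the lowest class code.  The result is always a partition.
    """
    if spacing_mm is None:
        raise ValidationError("spacing metadata required for resampling")
    label_map = np.asarray(label_map)
    if label_map.ndim != 3:
        raise ValidationError("expected a 3D label map")
    codes = np.unique(label_map)
    stacks = [
        _resample_volume((label_map == code).astype(float), spacing_mm, target_mm, order=1)
        for code in codes
    ]
    best = np.argmax(np.stack(stacks, axis=0), axis=0)  # first max = lowest code
    out = codes[best].astype(label_map.dtype)
    return out, (spacing_mm[0], target_mm, target_mm)


def signed_distance(
    mask: np.ndarray, spacing_mm: tuple[float, float, float]
) -> np.ndarray:
    """Signed Euclidean distance map in mm: negative inside the mask,
    positive outside; ``|value|`` is the distance to the nearest voxel
    on the other side of the boundary.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise DegenerateInputError("empty mask has no boundary")
    if mask.all():
        raise DegenerateInputError("full mask has no boundary")
    sampling = tuple(float(s) for s in spacing_mm)
    outside = ndimage.distance_transform_edt(~mask, sampling=sampling)
    inside = ndimage.distance_transform_edt(mask, sampling=sampling)
    return np.where(mask, -inside, outside)


def dice_per_slice(wall_a: np.ndarray, wall_b: np.ndarray) -> np.ndarray:
    """Per-slice Dice overlap 2|A∩B|/(|A|+|B|) of two binary volumes.

    Slices where both masks are empty are undefined and returned as NaN
    (they are excluded from training downstream).
    """
    a = np.asarray(wall_a, dtype=bool)
    b = np.asarray(wall_b, dtype=bool)
    if a.shape != b.shape:
        raise ValidationError("masks differ in shape")
    na = a.reshape(a.shape[0], -1).sum(axis=1)
    nb = b.reshape(b.shape[0], -1).sum(axis=1)
    ninter = (a & b).reshape(a.shape[0], -1).sum(axis=1)
    denom = na + nb
    with np.errstate(invalid="ignore", divide="ignore"):
        dice = 2.0 * ninter / denom
    dice[denom == 0] = np.nan
    return dice


def _boundary(mask2d: np.ndarray) -> np.ndarray:
    """Inner boundary voxels of a 2D mask (4-connectivity erosion)."""
    eroded = ndimage.binary_erosion(
        mask2d, structure=ndimage.generate_binary_structure(2, 1), border_value=0
    )
    return mask2d & ~eroded


def mean_contour_distance(
    mask_a: np.ndarray,
    mask_b: np.ndarray,
    spacing_mm: tuple[float, float, float],
) -> float:
    """Symmetric mean in-plane distance (mm) between the boundaries of
    two masks.  Boundary voxels are matched to the nearest boundary
    voxel of the other mask within the same slice; the two directed
    means are averaged.
    """
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValidationError("masks differ in shape")
    if not a.any() or not b.any():
        raise DegenerateInputError("mean contour distance needs nonempty masks")
    if a.ndim == 2:
        a = a[None]
        b = b[None]
    _, dy, dx = spacing_mm
    d_ab: list[np.ndarray] = []
    d_ba: list[np.ndarray] = []
    for z in range(a.shape[0]):
        pa = np.argwhere(_boundary(a[z])) * np.array([dy, dx])
        pb = np.argwhere(_boundary(b[z])) * np.array([dy, dx])
        if len(pa) == 0 or len(pb) == 0:
            if len(pa) or len(pb):
                warnings.warn(f"slice {z}: contour present in only one mask; skipped")
            continue
        d_ab.append(cKDTree(pb).query(pa)[0])
        d_ba.append(cKDTree(pa).query(pb)[0])
    if not d_ab:
        raise DegenerateInputError("no slice has contours in both masks")
    return 0.5 * (
        float(np.concatenate(d_ab).mean()) + float(np.concatenate(d_ba).mean())
    )
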