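"""Volume I/O (NIfTI / MetaImage), cohort-directory validation, and run
manifests.

Arrays are exchanged as ``(z, y, x)`` with spacing ``(dz, dy, dx)`` in
mm, matching the package-wide convention; SimpleITK's ``(x, y, z)``
spacing order is converted at the boundary.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import SimpleITK as sitk

from plaqseg.constants import ALL_CHANNELS
from plaqseg.errors import FormatError, ValidationError

__all__ = [
    "read_volume",
    "write_volume",
    "export_phantom",
    "validate_cohort",
    "RunManifest",
]

_EXTENSIONS = (".nii", ".nii.gz", ".mha", ".mhd")


def _check_extension(path: Path) -> None:
    name = path.name.lower()
    if not any(name.endswith(ext) for ext in _EXTENSIONS):
        raise FormatError(f"unsupported volume format: {path.name}")


def read_volume(path: str | Path) -> tuple[np.ndarray, tuple[float, ...], dict]:
    """Read a NIfTI or MetaImage volume.

    Returns ``(array_zyx, spacing_zyx_mm, metadata)`` where metadata
    holds origin and direction in SimpleITK order.
    """
    path = Path(path)
    _check_extension(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as exc:
        raise FormatError(f"cannot read {path}: {exc}") from exc
    array = sitk.GetArrayFromImage(img)  # (z, y, x)
    spacing = tuple(reversed(img.GetSpacing()))
    meta = {"origin": img.GetOrigin(), "direction": img.GetDirection()}
    return array, spacing, meta


def write_volume(
    path: str | Path,
    array: np.ndarray,
    spacing_mm: tuple[float, ...],
) -> None:
    """Write a volume as NIfTI or MetaImage (by extension); round-trips
    values bit-exactly and spacing to 1e-9 mm."""
    path = Path(path)
    _check_extension(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    array = np.asarray(array)
    if array.dtype == bool:
        array = array.astype(np.uint8)
    img = sitk.GetImageFromArray(array)
    img.SetSpacing(tuple(float(s) for s in reversed(spacing_mm)))
    sitk.WriteImage(img, str(path))


def export_phantom(bundle, out_dir: str | Path) -> Path:
    """Write one phantom subject as a per-subject directory of volumes
    plus a per-slice Dice CSV; returns the subject directory."""
    import pandas as pd

    out = Path(out_dir) / f"subject_{bundle.subject_id:02d}"
    out.mkdir(parents=True, exist_ok=True)
    spacing = bundle.images.spacing_mm
    for name, vol in bundle.images.channels.items():
        write_volume(out / f"{name}.nii.gz", vol.astype(np.float32), spacing)
    write_volume(out / "lumen.nii.gz", bundle.invivo_geometry.lumen_mask, spacing)
    write_volume(out / "outer.nii.gz", bundle.invivo_geometry.outer_mask, spacing)
    write_volume(out / "true_labels.nii.gz", bundle.true_labels.label_map, spacing)
    write_volume(out / "ref_labels.nii.gz", bundle.reference_labels.label_map, spacing)
    write_volume(out / "ref_lumen.nii.gz", bundle.reference_geometry.lumen_mask, spacing)
    write_volume(out / "ref_outer.nii.gz", bundle.reference_geometry.outer_mask, spacing)
    pd.DataFrame(
        {
            "subject": bundle.subject_id,
            "slice": np.arange(len(bundle.per_slice_dice)),
            "dice": bundle.per_slice_dice,
        }
    ).to_csv(out / "dice.csv", index=False)
    return out


_REQUIRED_FILES = [f"{ch}.nii.gz" for ch in ALL_CHANNELS] + [
    "lumen.nii.gz",
    "outer.nii.gz",
    "ref_labels.nii.gz",
    "ref_lumen.nii.gz",
    "ref_outer.nii.gz",
]


def validate_cohort(directory: str | Path) -> list[str]:
    """Validate a cohort directory of ``subject_*`` folders.

    Checks channel completeness, grid consistency, and mask containment
    (lumen inside outer).  Returns a list of human-readable error
    strings (empty when the cohort is valid) instead of raising on the
    first fault.
    """
    directory = Path(directory)
    errors: list[str] = []
    subjects = sorted(directory.glob("subject_*"))
    if not subjects:
        return [f"no subject_* directories under {directory}"]
    for subj in subjects:
        shapes = {}
        for fname in _REQUIRED_FILES:
            fpath = subj / fname
            if not fpath.exists():
                errors.append(f"{subj.name}: missing {fname}")
                continue
            try:
                arr, spacing, _ = read_volume(fpath)
            except FormatError as exc:
                errors.append(f"{subj.name}: {exc}")
                continue
            shapes[fname] = (arr.shape, spacing)
        if len({s for s in shapes.values()}) > 1:
            errors.append(f"{subj.name}: inconsistent grids {shapes}")
        if "lumen.nii.gz" in shapes and "outer.nii.gz" in shapes:
            lumen, _, _ = read_volume(subj / "lumen.nii.gz")
            outer, _, _ = read_volume(subj / "outer.nii.gz")
            if lumen.shape == outer.shape and np.any((lumen > 0) & (outer == 0)):
                errors.append(f"{subj.name}: lumen mask not contained in outer mask")
    return errors


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    """Provenance record: config snapshot, seed, version, output digests."""

    config: dict
    seed: int
    version: str
    outputs: dict[str, str] = field(default_factory=dict)

    def add_output(self, path: str | Path) -> None:
        path = Path(path)
        self.outputs[path.name] = _digest(path)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "config": self.config,
                    "seed": self.seed,
                    "version": self.version,
                    "outputs": self.outputs,
                },
                indent=2,
                default=str,
            )
        )

    @classmethod
    def read(cls, path: str | Path) -> "RunManifest":
        obj = json.loads(Path(path).read_text())
        try:
            return cls(
                config=obj["config"],
                seed=obj["seed"],
                version=obj["version"],
                outputs=obj.get("outputs", {}),
            )
        except KeyError as exc:
            raise ValidationError(f"manifest missing key {exc}") from exc
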