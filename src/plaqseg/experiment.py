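"""Leave-one-subject-out evaluation protocol with nested hyperparameter
selection.

For each held-out subject, classifiers are trained on a fixed 10%
subsample of the voxels lying in both the reference (histology-like)
wall and the in vivo wall of the remaining subjects, with sample
weights given by the configured label-uncertainty method, and tested on
every voxel of the held-out subject's in vivo wall.  Free
hyperparameters — the soft-label blur sigma and Dice exponent n, or the
SVM's C and gamma — are chosen by a nested leave-one-subject-out grid
search minimizing the per-slice absolute volume error of the three
components against the reference labels (never against the phantom's
hidden truth, which in vivo data would not provide).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from plaqseg.constants import CLASS_CODES, CLASS_NAMES, MR_CHANNELS
from plaqseg.classify import fit_ldc, fit_svm, predict_ldc, predict_svm
from plaqseg.errors import ValidationError
from plaqseg.evaluate import VolumeReport, relative_volumes
from plaqseg.features import (
    attach_labels,
    extract_features,
    feature_names,
    subsample_training,
)
from plaqseg.phantom import PhantomBundle, ReferenceLabels
from plaqseg.preproc import (
    MultiModalStack,
    WallGeometry,
    dice_per_slice,
    normalize_roi,
    resample_labels,
    resample_inplane,
)
from plaqseg.uncertainty import contour_weights, reject_outliers, soft_labels

__all__ = [
    "ExperimentConfig",
    "ExperimentResult",
    "PreparedSubject",
    "prepare_subject",
    "loo_crossval",
    "select_hyperparams",
]

METHODS = ("hard", "soft_dice", "contour", "outlier")
CLASSIFIERS = ("ldc", "svm")

# composite region codes used when resampling labels+geometry together
_LUMEN = 4


@dataclass
class ExperimentConfig:
    """Protocol configuration (defaults follow the evaluation recipe)."""

    method: str = "hard"
    classifier: str = "ldc"
    feature_subset: str = "all"
    sigma_grid: tuple[float, ...] = (0.0, 0.25, 0.5, 0.75, 1.0, 1.5, 2.0)
    n_grid: tuple[int, ...] = tuple(range(0, 40, 3))
    svm_C_grid: tuple[float, ...] = (0.1, 1.0, 10.0, 100.0)
    svm_gamma_grid: tuple[float, ...] = (0.01, 0.1, 1.0)
    training_fraction: float = 0.10
    feature_sigma_mm: float = 1.0
    outlier_fraction: float = 0.10
    resample_mm: float | None = 0.25
    # forced hyperparameters; None means "select by nested grid search"
    sigma_blur_mm: float | None = None
    n_exponent: float | None = None
    svm_C: float | None = None
    svm_gamma: float | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.method not in METHODS:
            raise ValidationError(f"method must be one of {METHODS}")
        if self.classifier not in CLASSIFIERS:
            raise ValidationError(f"classifier must be one of {CLASSIFIERS}")
        if not self.sigma_grid or not self.n_grid:
            raise ValidationError("sigma and n grids must be nonempty")
        if not self.svm_C_grid or not self.svm_gamma_grid:
            raise ValidationError("SVM grids must be nonempty")
        feature_names(self.feature_subset)  # raises on unknown subset


@dataclass
class PreparedSubject:
    """Per-subject data after resampling, normalization and feature
    extraction; everything training or testing needs."""

    subject_id: int
    spacing_mm: tuple[float, float, float]
    train_table: pd.DataFrame
    test_table: pd.DataFrame
    reference_labels: ReferenceLabels
    dice: np.ndarray
    contour_w_train: np.ndarray
    invivo_wall: np.ndarray
    ref_volumes_per_slice: pd.DataFrame
    true_volumes_per_slice: pd.DataFrame
    true_volumes_per_subject: pd.Series


@dataclass
class ExperimentResult:
    config: ExperimentConfig
    report: VolumeReport
    selected_params: list[dict] = field(default_factory=list)


def _resample_composite(
    labels: ReferenceLabels,
    geometry: WallGeometry,
    spacing: tuple[float, float, float],
    target_mm: float,
) -> tuple[ReferenceLabels, WallGeometry]:
    """Resample labels and geometry as one code map so the component
    union stays exactly the resampled wall."""
    codes = labels.label_map.astype(np.int8)
    codes[geometry.lumen_mask] = _LUMEN
    out, new_spacing = resample_labels(codes, spacing, target_mm)
    lumen = out == _LUMEN
    outer = out != 0
    new_labels = ReferenceLabels.from_label_map(np.where(lumen, 0, out))
    return new_labels, WallGeometry(lumen, outer, new_spacing)


def _subject_seed(base_seed: int, subject_id: int) -> int:
    return (base_seed * 100003 + subject_id * 101 + 7) % (2**31)


def prepare_subject(bundle: PhantomBundle, config: ExperimentConfig) -> PreparedSubject:
    """Resample to the working grid, normalize MR intensities within the
    in vivo outer-wall ROI, extract training/testing feature tables and
    the fixed 10% training subsample."""
    config.validate()
    spacing = bundle.images.spacing_mm
    images = bundle.images
    true_labels, invivo_geom = bundle.true_labels, bundle.invivo_geometry
    ref_labels, ref_geom = bundle.reference_labels, bundle.reference_geometry

    if config.resample_mm is not None:
        channels = {}
        for name, vol in images.channels.items():
            channels[name], new_spacing = resample_inplane(
                vol, spacing, config.resample_mm
            )
        true_labels, invivo_geom = _resample_composite(
            true_labels, invivo_geom, spacing, config.resample_mm
        )
        ref_labels, ref_geom = _resample_composite(
            ref_labels, ref_geom, spacing, config.resample_mm
        )
        images = MultiModalStack(channels, new_spacing)
        spacing = new_spacing

    roi = invivo_geom.outer_mask
    channels = dict(images.channels)
    for ch in MR_CHANNELS:
        if ch in channels:
            channels[ch] = normalize_roi(channels[ch], roi)
    images = MultiModalStack(channels, spacing)

    dice = dice_per_slice(invivo_geom.wall_mask, ref_geom.wall_mask)
    valid_slices = ~np.isnan(dice)
    train_mask = ref_geom.wall_mask & invivo_geom.wall_mask
    train_mask &= valid_slices[:, None, None]

    train_table = extract_features(
        images,
        ref_geom,
        mask=train_mask,
        sigma_mm=config.feature_sigma_mm,
        subset=config.feature_subset,
        subject_id=bundle.subject_id,
    )
    train_table = attach_labels(train_table, ref_labels)
    train_table = subsample_training(
        train_table,
        config.training_fraction,
        seed=_subject_seed(config.seed, bundle.subject_id),
    )
    test_table = extract_features(
        images,
        invivo_geom,
        mask=invivo_geom.wall_mask,
        sigma_mm=config.feature_sigma_mm,
        subset=config.feature_subset,
        subject_id=bundle.subject_id,
    )

    cw = contour_weights(ref_geom, invivo_geom)
    contour_w_train = cw.w.reshape(-1)[train_table["voxel_index"].to_numpy()]

    ref_vols, _ = relative_volumes(
        ref_labels.label_map, ref_geom.wall_mask, bundle.subject_id
    )
    true_slice, true_subj = relative_volumes(
        true_labels.label_map, invivo_geom.wall_mask, bundle.subject_id
    )
    return PreparedSubject(
        subject_id=bundle.subject_id,
        spacing_mm=spacing,
        train_table=train_table,
        test_table=test_table,
        reference_labels=ref_labels,
        dice=dice,
        contour_w_train=contour_w_train,
        invivo_wall=invivo_geom.wall_mask,
        ref_volumes_per_slice=ref_vols,
        true_volumes_per_slice=true_slice,
        true_volumes_per_subject=true_subj,
    )


def _class_weights(
    subjects: Sequence[PreparedSubject], config: ExperimentConfig, params: dict
) -> tuple[pd.DataFrame, np.ndarray]:
    """Pooled training table and its (n, 3) per-class weight matrix for
    the configured uncertainty method."""
    feats = feature_names(config.feature_subset)
    tables, weights = [], []
    for subj in subjects:
        table = subj.train_table
        onehot = table[[f"w_{c}" for c in CLASS_NAMES]].to_numpy(dtype=float)
        if config.method == "hard" or config.method == "outlier":
            W = onehot
        elif config.method == "soft_dice":
            sl = soft_labels(
                subj.reference_labels,
                subj.dice,
                params["sigma_blur_mm"],
                params["n_exponent"],
                subj.spacing_mm,
            )
            vox = table["voxel_index"].to_numpy()
            W = np.column_stack(
                [sl.w_c[c].reshape(-1)[vox] for c in CLASS_NAMES]
            )
            W[~sl.valid.reshape(-1)[vox]] = 0.0
        elif config.method == "contour":
            W = onehot * subj.contour_w_train[:, None]
        else:  # pragma: no cover - guarded by validate()
            raise ValidationError(config.method)
        tables.append(table)
        weights.append(W)
    pooled = pd.concat(tables, ignore_index=True)
    W = np.vstack(weights)
    if config.method == "outlier":
        flagged = reject_outliers(pooled, feats, config.outlier_fraction)
        W = W * flagged["keep_flag"].to_numpy()[:, None]
    keep = W.sum(axis=1) > 0
    return pooled.loc[keep].reset_index(drop=True), W[keep]


def _train(subjects: Sequence[PreparedSubject], config: ExperimentConfig, params: dict):
    feats = feature_names(config.feature_subset)
    pooled, W = _class_weights(subjects, config, params)
    X = pooled[feats].to_numpy(dtype=float)
    if config.classifier == "ldc":
        return fit_ldc(X, W)
    y = pooled["hard_label"].to_numpy()
    cls_idx = np.array([CLASS_NAMES.index(c) for c in y])
    w_scalar = W[np.arange(len(W)), cls_idx]  # weight of the hard class
    return fit_svm(
        X, y, sample_weight=w_scalar, C=params["svm_C"], gamma=params["svm_gamma"]
    )


def _predict_volumes(
    model, config: ExperimentConfig, subj: PreparedSubject
) -> tuple[pd.DataFrame, pd.Series, np.ndarray]:
    feats = feature_names(config.feature_subset)
    X = subj.test_table[feats].to_numpy(dtype=float)
    if config.classifier == "ldc":
        _, labels = predict_ldc(model, X)
    else:
        labels = predict_svm(model, X)
    pred_map = np.zeros(subj.invivo_wall.shape, dtype=np.int8)
    flat = subj.test_table["voxel_index"].to_numpy()
    codes = np.array([CLASS_CODES[c] for c in labels], dtype=np.int8)
    pred_map.reshape(-1)[flat] = codes
    per_slice, per_subject = relative_volumes(
        pred_map, subj.invivo_wall, subj.subject_id
    )
    return per_slice, per_subject, pred_map


def _resolve_params(config: ExperimentConfig) -> tuple[dict, list[dict]]:
    """Fixed parameter values plus the grid of free ones (lexicographic
    order: sigma before n, C before gamma; ties later resolve to the
    earliest grid entry, i.e. the smallest values)."""
    fixed: dict = {}
    axes: list[tuple[str, tuple]] = []
    if config.method == "soft_dice":
        if config.sigma_blur_mm is not None and config.n_exponent is not None:
            fixed["sigma_blur_mm"] = config.sigma_blur_mm
            fixed["n_exponent"] = config.n_exponent
        else:
            axes.append(("sigma_blur_mm", config.sigma_grid))
            axes.append(("n_exponent", config.n_grid))
    if config.classifier == "svm":
        if config.svm_C is not None and config.svm_gamma is not None:
            fixed["svm_C"] = config.svm_C
            fixed["svm_gamma"] = config.svm_gamma
        else:
            axes.append(("svm_C", config.svm_C_grid))
            axes.append(("svm_gamma", config.svm_gamma_grid))
    if not axes:
        return fixed, []
    names = [a[0] for a in axes]
    grid = [dict(zip(names, combo), **fixed) for combo in product(*[a[1] for a in axes])]
    return fixed, grid


def _inner_objective(
    train_subjects: Sequence[PreparedSubject], config: ExperimentConfig
) -> Callable[[dict], float]:
    """Nested-LOO objective: mean over inner-fold slices of the
    component-averaged absolute volume error against the reference
    labels (equal slice weight)."""

    def objective(params: dict) -> float:
        errors: list[float] = []
        for i, held in enumerate(train_subjects):
            inner = [s for j, s in enumerate(train_subjects) if j != i]
            try:
                model = _train(inner, config, params)
                pred_slice, _, _ = _predict_volumes(model, config, held)
            except (ValidationError, np.linalg.LinAlgError):
                return np.nan
            merged = pred_slice.merge(
                held.ref_volumes_per_slice,
                on="slice_index",
                suffixes=("_pred", "_ref"),
            )
            for _, row in merged.iterrows():
                errors.append(
                    np.mean(
                        [abs(row[f"{c}_pred"] - row[f"{c}_ref"]) for c in CLASS_NAMES]
                    )
                )
        return float(np.mean(errors)) if errors else np.nan

    return objective


def select_hyperparams(
    training_subjects: Sequence[PreparedSubject],
    grid: Sequence[dict],
    objective: Callable[[dict], float],
) -> dict:
    """Exhaustive grid evaluation; the first grid entry attaining the
    minimum objective wins (grids are ordered so this is the smallest
    sigma then n, or smallest C then gamma)."""
    if len(training_subjects) < 2:
        raise ValidationError("nested selection needs >= 2 training subjects")
    if not grid:
        raise ValidationError("empty hyperparameter grid")
    best, best_val = None, np.inf
    for params in grid:
        val = objective(params)
        if np.isnan(val):
            continue
        if val < best_val:
            best, best_val = params, val
    if best is None:
        raise ValidationError("all grid evaluations degenerate")
    return best


def loo_crossval(
    cohort: Sequence[PhantomBundle | PreparedSubject],
    config: ExperimentConfig,
) -> ExperimentResult:
    """Leave-one-subject-out evaluation of one configuration.

    Accepts phantom bundles (prepared internally) or already-prepared
    subjects.  Returns pooled per-slice and per-subject
    prediction-vs-truth relative volumes and the hyperparameters chosen
    per fold.
    """
    config.validate()
    if len(cohort) < 3:
        raise ValidationError("need at least 3 subjects")
    prepared = [
        s if isinstance(s, PreparedSubject) else prepare_subject(s, config)
        for s in cohort
    ]
    ids = [s.subject_id for s in prepared]
    if len(set(ids)) != len(ids):
        raise ValidationError("subject ids must be unique")

    slice_rows, subject_rows, selected = [], [], []
    for i, held in enumerate(prepared):
        train_subjects = [s for j, s in enumerate(prepared) if j != i]
        assert held.subject_id not in {s.subject_id for s in train_subjects}
        fixed, grid = _resolve_params(config)
        if grid:
            params = select_hyperparams(
                train_subjects, grid, _inner_objective(train_subjects, config)
            )
        else:
            params = fixed
        selected.append({"subject_id": held.subject_id, **params})
        model = _train(train_subjects, config, params)
        pred_slice, pred_subj, _ = _predict_volumes(model, config, held)

        merged = pred_slice.merge(
            held.true_volumes_per_slice,
            on=["subject_id", "slice_index"],
            suffixes=("_pred", "_true"),
        )
        slice_rows.append(merged)
        row = {"subject_id": held.subject_id}
        for c in CLASS_NAMES:
            row[f"{c}_pred"] = float(pred_subj[c])
            row[f"{c}_true"] = float(held.true_volumes_per_subject[c])
        subject_rows.append(row)

    report = VolumeReport(
        per_slice=pd.concat(slice_rows, ignore_index=True),
        per_subject=pd.DataFrame(subject_rows),
    )
    return ExperimentResult(config=config, report=report, selected_params=selected)
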