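"""Volume-based evaluation: relative component volumes, bias / absolute
error / Spearman rank correlation, Friedman comparison of methods, and
a greedy forward-feature-selection diagnostic.

The primary endpoint is the relative volume of each component — its
voxel count as a percentage of the vessel-wall voxel count — computed
per slice and pooled per subject, compared between prediction and
ground truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from plaqseg.constants import CLASS_CODES, CLASS_NAMES
from plaqseg.classify import fit_ldc, predict_ldc
from plaqseg.errors import DegenerateInputError, ValidationError

__all__ = [
    "VolumeReport",
    "relative_volumes",
    "volume_metrics",
    "friedman_compare",
    "forward_select",
]


@dataclass
class VolumeReport:
    """Paired prediction/truth relative volumes.

    ``per_slice`` has columns subject_id, slice_index, and
    ``{cls}_pred`` / ``{cls}_true`` percentages; ``per_subject`` the
    same pooled per subject.  Percentages sum to 100 across classes in
    both prediction and truth.
    """

    per_slice: pd.DataFrame
    per_subject: pd.DataFrame

    def metrics(self, level: str = "per_subject") -> pd.DataFrame:
        df = self.per_subject if level == "per_subject" else self.per_slice
        pred = df[[f"{c}_pred" for c in CLASS_NAMES]].to_numpy()
        true = df[[f"{c}_true" for c in CLASS_NAMES]].to_numpy()
        return volume_metrics(pred, true)


def relative_volumes(
    labels: np.ndarray,
    wall_mask: np.ndarray,
    subject_id: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Relative component volumes (% of wall voxels) per slice and
    pooled per subject.

    ``labels`` is a code map (1=C, 2=F, 3=LRNC) defined on the wall
    voxels.  Empty wall slices are excluded with a warning.
    """
    labels = np.asarray(labels)
    wall = np.asarray(wall_mask, dtype=bool)
    if labels.shape != wall.shape:
        raise ValidationError("labels and wall mask differ in shape")
    rows = []
    for z in range(wall.shape[0]):
        n_wall = int(wall[z].sum())
        if n_wall == 0:
            warnings.warn(f"slice {z}: empty wall; excluded from volume report")
            continue
        row = {"subject_id": subject_id, "slice_index": z, "n_wall": n_wall}
        for cls in CLASS_NAMES:
            n_cls = int(((labels[z] == CLASS_CODES[cls]) & wall[z]).sum())
            row[cls] = 100.0 * n_cls / n_wall
        rows.append(row)
    if not rows:
        raise DegenerateInputError("no nonempty wall slices")
    per_slice = pd.DataFrame(rows)
    n_wall_total = per_slice["n_wall"].sum()
    per_subject = pd.Series(
        {
            cls: float((per_slice[cls] * per_slice["n_wall"]).sum() / n_wall_total)
            for cls in CLASS_NAMES
        }
    )
    return per_slice, per_subject


def volume_metrics(pred: np.ndarray, truth: np.ndarray) -> pd.DataFrame:
    """Bias, absolute error and Spearman rho per component.

    ``pred`` and ``truth`` are paired arrays (n_units, n_classes) of
    relative volumes; bias is the mean signed difference (pred - truth)
    and the Spearman correlation uses midranks for ties.  With fewer
    than 3 pairs the correlation is undefined (NaN).
    """
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape:
        raise ValidationError("pred and truth must be paired with equal shape")
    if pred.ndim == 1:
        pred = pred[:, None]
        truth = truth[:, None]
    out = []
    for k in range(pred.shape[1]):
        diff = pred[:, k] - truth[:, k]
        if len(diff) < 3:
            rho = np.nan
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rho = stats.spearmanr(pred[:, k], truth[:, k]).statistic
        name = CLASS_NAMES[k] if pred.shape[1] == len(CLASS_NAMES) else str(k)
        out.append(
            {
                "component": name,
                "bias": float(diff.mean()),
                "abs_error": float(np.abs(diff).mean()),
                "spearman": float(rho) if rho == rho else np.nan,
            }
        )
    return pd.DataFrame(out).set_index("component")


def friedman_compare(
    abs_errors: pd.DataFrame,
) -> tuple[float, float, pd.Series, pd.DataFrame]:
    """Friedman comparison of methods on per-slice mean absolute errors.

    ``abs_errors`` has one row per slice and one column per method (the
    per-slice errors of the three components already averaged).
    Returns ``(statistic, p_value, mean_ranks, pairwise)`` where
    ``pairwise`` holds Bonferroni-corrected sign-test p-values for each
    method pair.  Fully tied data are degenerate: statistic 0, p 1.
    """
    if abs_errors.shape[1] < 2:
        raise ValidationError("need at least 2 methods")
    if abs_errors.shape[0] < 2:
        raise ValidationError("need at least 2 slices")
    values = abs_errors.to_numpy(dtype=float)
    ranks = np.apply_along_axis(stats.rankdata, 1, values)  # midranks
    mean_ranks = pd.Series(ranks.mean(axis=0), index=abs_errors.columns)
    if np.all(values == values[:, [0]]):
        warnings.warn("all methods identical on every slice; Friedman degenerate")
        stat, p = 0.0, 1.0
    elif values.shape[1] >= 3:
        stat, p = stats.friedmanchisquare(*[values[:, j] for j in range(values.shape[1])])
    else:
        # classical midrank chi-square; scipy needs >= 3 methods
        n, k = ranks.shape
        stat = 12.0 * n / (k * (k + 1)) * float(
            ((ranks.mean(axis=0) - (k + 1) / 2.0) ** 2).sum()
        )
        p = float(stats.chi2.sf(stat, k - 1))
    methods = list(abs_errors.columns)
    n_pairs = len(methods) * (len(methods) - 1) // 2
    rows = []
    for a in range(len(methods)):
        for b in range(a + 1, len(methods)):
            diff = values[:, a] - values[:, b]
            nz = diff[diff != 0]
            if len(nz) == 0:
                p_ab = 1.0
            else:
                p_ab = stats.binomtest(int((nz > 0).sum()), len(nz), 0.5).pvalue
            rows.append(
                {
                    "method_a": methods[a],
                    "method_b": methods[b],
                    "p_sign_bonferroni": min(1.0, p_ab * n_pairs),
                }
            )
    return float(stat), float(p), mean_ranks, pd.DataFrame(rows)


def forward_select(
    X: np.ndarray,
    y: np.ndarray,
    feature_names_: list[str],
    k: int = 5,
) -> list[str]:
    """Greedy forward feature selection for a two-class problem,
    maximizing LDC training accuracy; ties resolve by column order.

    Returns the first ``k`` selected feature names (all features, with
    a warning, when fewer than ``k`` are available).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = tuple(pd.unique(y))
    if len(classes) != 2:
        raise ValidationError("forward_select expects exactly two classes")
    classes = tuple(sorted(classes, key=lambda c: CLASS_NAMES.index(c) if c in CLASS_NAMES else 0))
    n_feat = X.shape[1]
    if len(feature_names_) != n_feat:
        raise ValidationError("feature_names length mismatch")
    if n_feat < k:
        warnings.warn(f"only {n_feat} features available; returning all")
        k = n_feat
    W = np.column_stack([(y == c).astype(float) for c in classes])
    selected: list[int] = []
    remaining = list(range(n_feat))
    for _ in range(k):
        best_j, best_acc = None, -1.0
        for j in remaining:
            cols = selected + [j]
            model = fit_ldc(X[:, cols], W, classes=classes)
            _, pred = predict_ldc(model, X[:, cols])
            acc = float((pred == y).mean())
            if acc > best_acc:  # strict: ties keep the earlier column
                best_acc, best_j = acc, j
        selected.append(best_j)
        remaining.remove(best_j)
    return [feature_names_[j] for j in selected]
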