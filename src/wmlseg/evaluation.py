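"""Metrics and analyses: voxel-wise Dice, lesion-wise detection counts,
the combined F-score, burden stratification, Spearman correlation,
Bland-Altman agreement, and the two-fold cross-validated alpha/lambda
grid search.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .errors import InputError
from .lesion_segmentation import (
    STATUS_CANDIDATE,
    LabeledLesions,
    SegmentationContext,
    SegmentationParams,
    build_context,
    compute_threshold,
    compute_wm_ratios,
    detect_candidates,
    filter_by_size,
    label_components,
)
from .volume_io import BinaryMask, Volume, assert_coregistered

__all__ = [
    "DetectionResult",
    "EvalReport",
    "GridSearchResult",
    "dice",
    "match_lesions",
    "fn_volume_rate",
    "f_score",
    "stratify",
    "spearman",
    "bland_altman",
    "evaluate_case",
    "default_alpha_grid",
    "default_lambda_grid",
    "case_f_matrix",
    "grid_search",
]


@dataclass
class DetectionResult:
    """Lesion-wise detection counts and the derived rates.

    ``ppv_defined`` is False when there are no automatic detections; the
    PPV is then reported as 0 so the F-score stays computable.  Similarly
    ``tpr_defined`` is False when the ground truth has no lesions (TPR is
    then reported as 1: there was nothing to miss).
    """

    tp: int
    fp: int
    fn: int
    tpr: float = 0.0
    ppv: float = 0.0
    tpr_defined: bool = True
    ppv_defined: bool = True


@dataclass
class EvalReport:
    """Per-case evaluation summary."""

    dsc: float
    detection: DetectionResult
    fnr_volume: float
    f_score: float
    burden_group: int
    auto_volume_mm3: float
    gt_volume_mm3: float
    auto_lesion_count: int
    gt_lesion_count: int


@dataclass
class GridSearchResult:
    alpha_grid: np.ndarray
    lambda_grid: np.ndarray
    fold_scores: List[np.ndarray]  # one |alpha| x |lambda| matrix per fold
    best_per_fold: List[Tuple[float, float]]
    mean_scores: np.ndarray  # mean over all cases
    best: Tuple[float, float]
    fold_assignments: List[List[int]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# elementary metrics


def _dice_arrays(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        return 1.0
    inter = int(np.logical_and(a, b).sum())
    return 2.0 * inter / (na + nb)


def dice(a: BinaryMask, b: BinaryMask) -> float:
    """Dice similarity 2|A∩B| / (|A|+|B|); two empty masks agree (1)."""
    assert_coregistered([a, b])
    return _dice_arrays(a.as_bool(), b.as_bool())


def _match_arrays(auto_lab: np.ndarray, gt_lab: np.ndarray, n_auto: int, n_gt: int) -> DetectionResult:
    """Overlap-based lesion matching: >=1 shared voxel counts, many-to-many."""
    detected_gt = np.setdiff1d(np.unique(gt_lab[auto_lab > 0]), [0])
    overlapped_auto = np.setdiff1d(np.unique(auto_lab[gt_lab > 0]), [0])
    tp = int(detected_gt.size)
    fn = n_gt - tp
    fp = n_auto - int(overlapped_auto.size)
    res = DetectionResult(tp=tp, fp=fp, fn=fn)
    if tp + fn > 0:
        res.tpr = tp / (tp + fn)
    else:
        res.tpr, res.tpr_defined = 1.0, False
    if tp + fp > 0:
        res.ppv = tp / (tp + fp)
    else:
        res.ppv, res.ppv_defined = 0.0, False
    return res


def match_lesions(auto: LabeledLesions, gt: LabeledLesions) -> DetectionResult:
    """A GT component is detected iff >=1 of its voxels overlaps any auto
    component; an auto component overlapping no GT component is a FP."""
    assert_coregistered([auto.labels, gt.labels])
    return _match_arrays(
        np.asarray(auto.labels.data),
        np.asarray(gt.labels.data),
        len(auto.components),
        len(gt.components),
    )


def fn_volume_rate(auto: BinaryMask, gt: LabeledLesions) -> float:
    """Volume fraction of GT lesions left completely undetected."""
    assert_coregistered([auto, gt.labels])
    if not gt.components:
        return 0.0
    gt_lab = np.asarray(gt.labels.data)
    detected = np.setdiff1d(np.unique(gt_lab[auto.as_bool()]), [0])
    total = sum(c.volume_mm3 for c in gt.components)
    missed = sum(c.volume_mm3 for c in gt.components if c.id not in set(detected.tolist()))
    return missed / total if total > 0 else 0.0


def f_score(dsc: float, tpr: float, ppv: float, harmonic: bool = False) -> float:
    """Combined score 3*DSC*TPR*PPV / (DSC + TPR + PPV).

    ``harmonic=True`` switches to the true three-way harmonic mean
    3abc / (ab + bc + ca); the default keeps the printed formula.
    """
    for v in (dsc, tpr, ppv):
        if not (0.0 <= v <= 1.0):
            raise InputError("f_score arguments must lie in [0, 1]")
    if dsc == 0 or tpr == 0 or ppv == 0:
        return 0.0
    if harmonic:
        return 3.0 * dsc * tpr * ppv / (dsc * tpr + tpr * ppv + ppv * dsc)
    return 3.0 * dsc * tpr * ppv / (dsc + tpr + ppv)


def stratify(gt_lesion_count: int) -> int:
    """Burden group: 1 (<5 lesions), 2 (5-25), 3 (>25)."""
    if gt_lesion_count < 0:
        raise InputError("lesion count must be >= 0")
    if gt_lesion_count < 5:
        return 1
    if gt_lesion_count <= 25:
        return 2
    return 3


def spearman(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation (Pearson on mid-ranks, average-tie)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise InputError("spearman: length mismatch")
    if x.size < 3:
        raise InputError("spearman needs at least 3 observations")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise InputError("spearman undefined for a constant vector")
    r = stats.spearmanr(x, y).statistic
    return float(r)


def bland_altman(
    auto_vols: Sequence[float], gt_vols: Sequence[float]
) -> Tuple[float, Tuple[float, float]]:
    """Mean difference and 1.96-sd limits of agreement of d = gt - auto.

    Positive mean difference indicates undersegmentation.
    """
    a = np.asarray(auto_vols, dtype=float)
    g = np.asarray(gt_vols, dtype=float)
    if a.size != g.size:
        raise InputError("bland_altman: length mismatch")
    if a.size < 2:
        raise InputError("bland_altman needs at least 2 cases")
    d = g - a
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    return mean, (mean - 1.96 * sd, mean + 1.96 * sd)


# ---------------------------------------------------------------------------
# per-case evaluation


def gt_mask(gt: LabeledLesions) -> BinaryMask:
    """Binary union of all GT components."""
    arr = np.asarray(gt.labels.data) > 0
    return BinaryMask(arr.astype(np.uint8), gt.labels.spacing, gt.labels.affine)


def evaluate_case(
    auto_mask: BinaryMask,
    gt: LabeledLesions,
    auto_lesions: Optional[LabeledLesions] = None,
) -> EvalReport:
    """All per-case metrics for one automatic mask against GT lesions."""
    if auto_lesions is None:
        auto_lesions = label_components(auto_mask, 26)
    det = match_lesions(auto_lesions, gt)
    dsc = dice(auto_mask, gt_mask(gt))
    fnr = fn_volume_rate(auto_mask, gt)
    f = f_score(dsc, det.tpr, det.ppv)
    voxvol = auto_mask.voxel_volume_mm3
    return EvalReport(
        dsc=dsc,
        detection=det,
        fnr_volume=fnr,
        f_score=f,
        burden_group=stratify(len(gt.components)),
        auto_volume_mm3=float(auto_mask.n_voxels) * voxvol,
        gt_volume_mm3=sum(c.volume_mm3 for c in gt.components),
        auto_lesion_count=len(auto_lesions.components),
        gt_lesion_count=len(gt.components),
    )


# ---------------------------------------------------------------------------
# grid search


def default_alpha_grid() -> np.ndarray:
    """alpha from 1 to 3 in steps of 0.1 (21 values)."""
    return np.round(np.arange(1.0, 3.0 + 1e-9, 0.1), 10)


def default_lambda_grid() -> np.ndarray:
    """lambda from 0 to 1 in steps of 0.05 (21 values)."""
    return np.round(np.arange(0.0, 1.0 + 1e-9, 0.05), 10)


def case_f_matrix(
    ctx: SegmentationContext,
    gt: LabeledLesions,
    alpha_grid: np.ndarray,
    lambda_grid: np.ndarray,
    min_volume_mm3: float = 3.0,
) -> np.ndarray:
    """F-score of one case at every (alpha, lambda) grid point.

    The context (preprocessing, tissue model, GM peak) is shared across the
    grid; per alpha the candidate components and their WM ratios are
    computed once and the lambda filter is a pure cut on the stored ratios.
    """
    gt_lab = np.asarray(gt.labels.data)
    gt_bool = gt_lab > 0
    n_gt = len(gt.components)
    gt_total_vox = int(gt_bool.sum())
    F = np.zeros((len(alpha_grid), len(lambda_grid)))
    for i, alpha in enumerate(alpha_grid):
        thr = compute_threshold(ctx.gm_peak, float(alpha))
        cand = detect_candidates(ctx.flair, thr, ctx.brain, ctx.exclusion)
        lesions = label_components(cand, 26)
        filter_by_size(lesions, min_volume_mm3)
        compute_wm_ratios(lesions, ctx.labels)
        survivors = [
            (c.id, c.wm_ratio) for c in lesions.components if c.status == STATUS_CANDIDATE
        ]
        lab_arr = np.asarray(lesions.labels.data)
        for j, lam in enumerate(lambda_grid):
            kept = [cid for cid, r in survivors if r >= lam]
            if kept:
                auto_bool = np.isin(lab_arr, kept)
                auto_lab = np.where(auto_bool, lab_arr, 0)
            else:
                auto_bool = np.zeros_like(gt_bool)
                auto_lab = np.zeros_like(lab_arr)
            det = _match_arrays(auto_lab, gt_lab, len(kept), n_gt)
            na = int(auto_bool.sum())
            inter = int(np.logical_and(auto_bool, gt_bool).sum())
            dsc = 1.0 if na + gt_total_vox == 0 else 2.0 * inter / (na + gt_total_vox)
            F[i, j] = f_score(dsc, det.tpr, det.ppv)
    return F


def _argmax_first(matrix: np.ndarray, alpha_grid, lambda_grid) -> Tuple[float, float]:
    """Argmax with ties broken toward the smallest alpha, then lambda."""
    flat = int(np.argmax(matrix))  # row-major: alpha-major order
    i, j = np.unravel_index(flat, matrix.shape)
    return float(alpha_grid[i]), float(lambda_grid[j])


def grid_search(
    cases: Sequence,
    alpha_grid: Optional[np.ndarray] = None,
    lambda_grid: Optional[np.ndarray] = None,
    folds: int = 2,
    seed: int = 0,
    min_volume_mm3: float = 3.0,
    context_kwargs: Optional[Dict] = None,
) -> GridSearchResult:
    """Cross-validated parameter sweep.

    ``cases`` is a sequence of objects exposing ``t1``, ``flair``,
    ``pf_mask`` (or ``exclusion``, may be None) and ``lesion_gt``
    (phantom cases qualify directly).  Cases are shuffled with ``seed``
    and split into ``folds`` near-equal training sets; each fold's score
    matrix is the mean per-case F-score matrix over its cases.
    """
    if len(cases) < 2:
        raise InputError("grid_search needs at least 2 cases")
    alpha_grid = default_alpha_grid() if alpha_grid is None else np.asarray(alpha_grid, float)
    lambda_grid = default_lambda_grid() if lambda_grid is None else np.asarray(lambda_grid, float)
    if alpha_grid.size == 0 or lambda_grid.size == 0:
        raise InputError("parameter grids must be non-empty")
    context_kwargs = context_kwargs or {}

    matrices = []
    for idx, case in enumerate(cases):
        exclusion = getattr(case, "pf_mask", None)
        if exclusion is None:
            exclusion = getattr(case, "exclusion", None)
        try:
            ctx = build_context(
                case.t1, case.flair, exclusion=exclusion, seed=seed, **context_kwargs
            )
            M = case_f_matrix(
                ctx, case.lesion_gt, alpha_grid, lambda_grid, min_volume_mm3
            )
        except Exception as e:  # noqa: BLE001 - failed case scores 0 everywhere
            warnings.warn(f"case {idx} failed ({e}); scoring 0", RuntimeWarning)
            M = np.zeros((alpha_grid.size, lambda_grid.size))
        matrices.append(M)

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(cases))
    assignments = [sorted(order[f::folds].tolist()) for f in range(folds)]

    fold_scores = []
    best_per_fold = []
    for fold_idx in assignments:
        S = np.mean([matrices[i] for i in fold_idx], axis=0)
        fold_scores.append(S)
        best_per_fold.append(_argmax_first(S, alpha_grid, lambda_grid))
    mean_scores = np.mean(matrices, axis=0)
    best = _argmax_first(mean_scores, alpha_grid, lambda_grid)
    return GridSearchResult(
        alpha_grid=alpha_grid,
        lambda_grid=lambda_grid,
        fold_scores=fold_scores,
        best_per_fold=best_per_fold,
        mean_scores=mean_scores,
        best=best,
        fold_assignments=assignments,
    )
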