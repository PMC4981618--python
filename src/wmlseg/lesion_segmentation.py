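"""FLAIR hyperintense-outlier lesion segmentation.

The core method: locate the main peak of the FLAIR GM intensity histogram,
derive sigma from its full width at half maximum (FWHM), threshold at
mu + alpha*sigma, then refine candidate components by minimum size,
white-matter neighbourhood fraction, and an optional spatial exclusion
region applied at the candidate stage.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .errors import (
    DegenerateInputError,
    EdgePeakError,
    InputError,
    PipelineError,
)
from .preprocessing import (
    DiffusionParams,
    apply_bias_correction,
    compute_brain_mask,
    estimate_bias_field,
    perona_malik_3d,
)
from .tissue_model import (
    CSF,
    GM,
    WM,
    TissueLabels,
    TissueProbabilities,
    fit_three_class_em,
    max_probability_labels,
)
from .volume_io import BinaryMask, Volume, assert_coregistered

__all__ = [
    "GMPeakEstimate",
    "SegmentationParams",
    "LesionComponent",
    "LabeledLesions",
    "STATUS_CANDIDATE",
    "STATUS_REMOVED_SIZE",
    "STATUS_REMOVED_NEIGHBORHOOD",
    "STATUS_REMOVED_LOCATION",
    "STATUS_KEPT",
    "estimate_gm_peak",
    "estimate_peak_from_samples",
    "compute_threshold",
    "detect_candidates",
    "label_components",
    "filter_by_size",
    "neighborhood_wm_ratio",
    "filter_by_neighborhood",
    "SegmentationContext",
    "build_context",
    "run_from_context",
    "segment",
]

#: FWHM of a Gaussian = 2*sqrt(2*ln 2) * sigma
FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))

STATUS_CANDIDATE = "candidate"
STATUS_REMOVED_SIZE = "removed_size"
STATUS_REMOVED_NEIGHBORHOOD = "removed_neighborhood"
STATUS_REMOVED_LOCATION = "removed_location"
STATUS_KEPT = "kept"

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class GMPeakEstimate:
    """Location and width of the FLAIR GM histogram main peak."""

    mu: float
    fwhm: float
    sigma: float = None  # type: ignore[assignment]
    bin_width: float = 0.0

    def __post_init__(self):
        if not np.isfinite(self.mu):
            raise InputError("mu must be finite")
        if self.fwhm <= 0:
            raise InputError("fwhm must be > 0")
        derived = self.fwhm / FWHM_PER_SIGMA
        if self.sigma is None:
            self.sigma = derived
        elif abs(self.sigma - derived) > 1e-9:
            raise InputError("sigma must equal fwhm / (2*sqrt(2 ln 2))")


@dataclass
class SegmentationParams:
    """Tunable parameters of the refinement pipeline."""

    alpha: float = 2.5
    lam: float = 0.70
    min_volume_mm3: float = 3.0

    def __post_init__(self):
        if self.alpha <= 0:
            raise InputError("alpha must be > 0")
        if not (0.0 <= self.lam <= 1.0):
            raise InputError("lambda must be in [0, 1]")
        if self.min_volume_mm3 <= 0:
            raise InputError("min_volume_mm3 must be > 0")


@dataclass
class LesionComponent:
    """One connected candidate component and its filter bookkeeping."""

    id: int
    voxel_count: int
    volume_mm3: float
    centroid: Tuple[float, float, float]
    wm_ratio: Optional[float] = None
    status: str = STATUS_CANDIDATE


@dataclass
class LabeledLesions:
    """Connected components of a candidate mask with per-component records."""

    labels: Volume  # int array, 0 = background, k = component id
    components: List[LesionComponent] = field(default_factory=list)

    @property
    def spacing(self) -> tuple:
        return self.labels.spacing

    def by_status(self, status: str) -> List[LesionComponent]:
        return [c for c in self.components if c.status == status]

    def kept_mask(self) -> BinaryMask:
        """Binary union of status-kept components."""
        ids = [c.id for c in self.components if c.status == STATUS_KEPT]
        arr = np.asarray(self.labels.data)
        out = np.isin(arr, ids) if ids else np.zeros(arr.shape, dtype=bool)
        return BinaryMask(out.astype(np.uint8), self.labels.spacing, self.labels.affine)


# ---------------------------------------------------------------------------
# peak estimation and thresholding


def _smooth3(h: np.ndarray) -> np.ndarray:
    """3-bin moving average, edge bins averaged over the available window."""
    kernel = np.ones(3)
    num = np.convolve(h, kernel, mode="same")
    den = np.convolve(np.ones_like(h), kernel, mode="same")
    return num / den

def estimate_peak_from_samples(
    samples: np.ndarray, bin_rule="fd", min_bins: int = 64
) -> GMPeakEstimate:
    """Histogram-based peak/FWHM estimate on a 1D sample vector.

    Freedman-Diaconis binning (with a floor of ``min_bins`` bins), 3-bin
    moving-average smoothing, global-maximum peak picking with 3-point
    parabolic refinement of mu, and linear interpolation of the outermost
    half-maximum crossings for the FWHM.
    """
    x = np.asarray(samples, dtype=float).ravel()
    if x.size == 0:
        raise InputError("no samples for peak estimation")
    if not np.isfinite(x).all():
        raise InputError("peak estimation requires finite samples")
    lo, hi = x.min(), x.max()
    if hi <= lo:
        raise DegenerateInputError("all samples identical; histogram is degenerate")
    if bin_rule == "fd":
        iqr = float(np.percentile(x, 75) - np.percentile(x, 25))
        bw = 2.0 * iqr / x.size ** (1.0 / 3.0)
        nbins = int(np.ceil((hi - lo) / bw)) if bw > 0 else min_bins
        nbins = max(nbins, min_bins)
    elif isinstance(bin_rule, (int, np.integer)):
        nbins = int(bin_rule)
    else:
        raise InputError(f"unknown bin rule {bin_rule!r}")
    counts, edges = np.histogram(x, bins=nbins)
    width = edges[1] - edges[0]
    centers = 0.5 * (edges[:-1] + edges[1:])
    h = _smooth3(counts.astype(float))

    p = int(np.argmax(h))
    # parabolic refinement of the peak position: least-squares parabola on
    # log-counts over the contiguous bins above 60% of the peak (exact for
    # a Gaussian peak, far more stable than a 3-point fit on a flat top)
    mu = centers[p]
    lo_i, hi_i = p, p
    cut = 0.6 * h[p]
    while lo_i > 0 and h[lo_i - 1] >= cut:
        lo_i -= 1
    while hi_i < h.size - 1 and h[hi_i + 1] >= cut:
        hi_i += 1
    if hi_i - lo_i >= 2:
        cw = centers[lo_i : hi_i + 1]
        lh = np.log(h[lo_i : hi_i + 1])
        a2, a1, _ = np.polyfit(cw - centers[p], lh, 2)
        if a2 < 0:
            vertex = -a1 / (2.0 * a2)
            if abs(vertex) <= (hi_i - lo_i + 1) * width:
                mu = centers[p] + vertex

    half = h[p] / 2.0
    if h[0] >= half or h[-1] >= half:
        raise EdgePeakError(
            "histogram peak has no half-maximum crossing on one side; "
            "widen the intensity range or check the GM mask"
        )
    # outermost upward crossing left of the peak
    left = None
    for i in range(p):
        if h[i] < half <= h[i + 1]:
            left = i
            break
    # outermost downward crossing right of the peak
    right = None
    for j in range(h.size - 2, p - 1, -1):
        if h[j] >= half > h[j + 1]:
            right = j
            break
    if left is None or right is None:
        raise EdgePeakError("could not bracket the half-maximum around the peak")
    xl = centers[left] + (half - h[left]) / (h[left + 1] - h[left]) * width
    xr = centers[right] + (h[right] - half) / (h[right] - h[right + 1]) * width
    fwhm = float(xr - xl)
    if fwhm <= 0:
        raise DegenerateInputError("non-positive FWHM")
    return GMPeakEstimate(mu=float(mu), fwhm=fwhm, bin_width=float(width))


def estimate_gm_peak(
    flair: Volume, gm_mask: BinaryMask, bin_rule="fd"
) -> GMPeakEstimate:
    """Peak/FWHM of the FLAIR intensity histogram over GM voxels."""
    assert_coregistered([flair, gm_mask])
    m = gm_mask.as_bool()
    if not m.any():
        raise InputError("estimate_gm_peak: empty GM mask")
    if m.sum() < 1000:
        warnings.warn(
            f"GM mask has only {int(m.sum())} voxels; peak estimate may be noisy",
            RuntimeWarning,
            stacklevel=2,
        )
    return estimate_peak_from_samples(np.asarray(flair.data)[m], bin_rule=bin_rule)


def compute_threshold(peak: GMPeakEstimate, alpha: float) -> float:
    """Detection threshold mu + alpha * sigma."""
    if alpha <= 0:
        raise InputError("alpha must be > 0")
    return float(peak.mu + alpha * peak.sigma)


# ---------------------------------------------------------------------------
# candidate detection and component filters


def detect_candidates(
    flair: Volume,
    threshold: float,
    brain_mask: BinaryMask,
    exclusion: Optional[BinaryMask] = None,
) -> BinaryMask:
    """Candidate voxels: FLAIR >= threshold, inside the brain mask and
    outside the exclusion region (applied before any labelling)."""
    vols = [flair, brain_mask] + ([exclusion] if exclusion is not None else [])
    assert_coregistered(vols)
    cand = (np.asarray(flair.data) >= threshold) & brain_mask.as_bool()
    if exclusion is not None:
        cand &= ~exclusion.as_bool()
    return BinaryMask(cand.astype(np.uint8), flair.spacing, flair.affine)


def _structure(connectivity: int) -> np.ndarray:
    try:
        rank = {6: 1, 18: 2, 26: 3}[connectivity]
    except KeyError:
        raise InputError(f"connectivity must be 6, 18 or 26, got {connectivity}")
    return ndimage.generate_binary_structure(3, rank)


def label_components(mask: BinaryMask, connectivity: int = 26) -> LabeledLesions:
    """Connected components of a binary mask with contiguous ids from 1."""
    arr = mask.as_bool()
    lab, n = ndimage.label(arr, structure=_structure(connectivity))
    voxvol = mask.voxel_volume_mm3
    comps: List[LesionComponent] = []
    if n > 0:
        counts = np.bincount(lab.ravel())
        centroids = ndimage.center_of_mass(arr, lab, index=range(1, n + 1))
        for k in range(1, n + 1):
            comps.append(
                LesionComponent(
                    id=k,
                    voxel_count=int(counts[k]),
                    volume_mm3=float(counts[k]) * voxvol,
                    centroid=tuple(float(c) for c in centroids[k - 1]),
                )
            )
    return LabeledLesions(
        labels=Volume(lab.astype(np.int32), mask.spacing, mask.affine),
        components=comps,
    )


def filter_by_size(
    lesions: LabeledLesions, min_volume_mm3: float = 3.0
) -> LabeledLesions:
    """Mark candidate components with volume < min_volume_mm3 as removed.

    Strict less-than: a component of exactly ``min_volume_mm3`` survives.
    """
    for c in lesions.components:
        if c.status == STATUS_CANDIDATE and c.volume_mm3 < min_volume_mm3:
            c.status = STATUS_REMOVED_SIZE
    return lesions


def _shell_ratio(
    lab_arr: np.ndarray,
    comp_id: int,
    bbox: Tuple[slice, ...],
    tissue_arr: np.ndarray,
) -> float:
    """WM fraction of the 26-connected 1-voxel shell around one component.

    Background-labelled shell voxels count in neither numerator nor
    denominator; an empty denominator yields 0.
    """
    expanded = tuple(
        slice(max(s.start - 1, 0), min(s.stop + 1, n))
        for s, n in zip(bbox, lab_arr.shape)
    )
    sub = lab_arr[expanded] == comp_id
    shell = ndimage.binary_dilation(sub, structure=_STRUCT_26) & ~sub
    t = tissue_arr[expanded][shell]
    denom = int(((t == CSF) | (t == GM) | (t == WM)).sum())
    if denom == 0:
        return 0.0
    return float((t == WM).sum()) / denom


def neighborhood_wm_ratio(
    lesions: LabeledLesions, component_id: int, labels: TissueLabels
) -> float:
    """WM fraction of the 1-voxel 26-shell around ``component_id``."""
    assert_coregistered([lesions.labels, labels.labels])
    lab_arr = np.asarray(lesions.labels.data)
    tissue_arr = np.asarray(labels.labels.data)
    objects = ndimage.find_objects(lab_arr)
    if component_id < 1 or component_id > len(objects) or objects[component_id - 1] is None:
        raise InputError(f"no component with id {component_id}")
    return _shell_ratio(lab_arr, component_id, objects[component_id - 1], tissue_arr)


def compute_wm_ratios(lesions: LabeledLesions, labels: TissueLabels) -> LabeledLesions:
    """Store the neighbourhood WM ratio on every still-candidate component."""
    assert_coregistered([lesions.labels, labels.labels])
    lab_arr = np.asarray(lesions.labels.data)
    tissue_arr = np.asarray(labels.labels.data)
    objects = ndimage.find_objects(lab_arr)
    for c in lesions.components:
        if c.status == STATUS_CANDIDATE:
            c.wm_ratio = _shell_ratio(
                lab_arr, c.id, objects[c.id - 1], tissue_arr
            )
    return lesions


def filter_by_neighborhood(
    lesions: LabeledLesions, labels: TissueLabels, lam: float
) -> LabeledLesions:
    """Remove surviving candidates whose shell WM ratio is below lambda.

    Keeps ratio >= lambda (a ratio of exactly lambda survives).
    """
    compute_wm_ratios(lesions, labels)
    for c in lesions.components:
        if c.status == STATUS_CANDIDATE and c.wm_ratio < lam:
            c.status = STATUS_REMOVED_NEIGHBORHOOD
    return lesions


# ---------------------------------------------------------------------------
# full pipeline


@dataclass
class SegmentationContext:
    """Parameter-independent products of the pipeline front half.

    Everything up to (and including) the GM peak estimate is independent of
    alpha/lambda, so parameter sweeps reuse one context per case.
    """

    flair: Volume  # diffused and bias-corrected
    probs: TissueProbabilities
    labels: TissueLabels
    brain: BinaryMask
    gm_peak: GMPeakEstimate
    exclusion: Optional[BinaryMask]
    seed: int
    info: Dict = field(default_factory=dict)


def _stage(name: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except PipelineError:
        raise
    except Exception as e:  # noqa: BLE001 - re-raise with stage name
        raise PipelineError(name, str(e)) from e


def _foreground_region(t1: Volume) -> BinaryMask:
    """Crude head region for the tissue EM.

    Lowest cut of a 4-class multi-Otsu (background | CSF | GM | WM); a
    plain 2-class Otsu would merge CSF into the background when the
    air background dominates the histogram.
    """
    from skimage.filters import threshold_multiotsu, threshold_otsu

    arr = np.asarray(t1.data, dtype=float)
    try:
        thr = threshold_multiotsu(arr, classes=4)[0]
    except ValueError:  # too few distinct values for 4 classes
        thr = threshold_otsu(arr)
    return BinaryMask((arr > thr).astype(np.uint8), t1.spacing, t1.affine)


def build_context(
    t1: Volume,
    flair: Volume,
    exclusion: Optional[BinaryMask] = None,
    seed: int = 0,
    diffusion: Optional[DiffusionParams] = None,
    bias_order: int = 3,
    skip_diffusion: bool = False,
    skip_bias: bool = False,
    tissue_probs: Optional[TissueProbabilities] = None,
    bin_rule="fd",
) -> SegmentationContext:
    """Run the alpha/lambda-independent front half of the pipeline.

    Order: FLAIR diffusion -> tissue EM on T1 (unless probability maps are
    supplied) -> brain mask -> FLAIR bias correction inside the brain mask
    -> hard tissue labels -> GM peak estimate.
    """
    vols = [t1, flair] + ([exclusion] if exclusion is not None else [])
    _stage("assert_coregistered", assert_coregistered, vols)

    fl = flair
    if not skip_diffusion:
        fl = _stage("perona_malik_3d", perona_malik_3d, fl, diffusion or DiffusionParams())

    if tissue_probs is None:
        region = _stage("foreground_region", _foreground_region, t1)
        probs = _stage("fit_three_class_em", fit_three_class_em, t1, region, seed)
    else:
        probs = tissue_probs
    brain = _stage("compute_brain_mask", compute_brain_mask, probs)

    info: Dict = {}
    if not skip_bias:
        bias = _stage("estimate_bias_field", estimate_bias_field, fl, brain, bias_order)
        fl = _stage("apply_bias_correction", apply_bias_correction, fl, bias)
        info["bias_converged"] = bias.converged
        info["bias_iterations"] = bias.n_iter

    labels = _stage("max_probability_labels", max_probability_labels, probs)
    gm_mask = labels.mask(GM)
    peak = _stage("estimate_gm_peak", estimate_gm_peak, fl, gm_mask, bin_rule)
    return SegmentationContext(
        flair=fl,
        probs=probs,
        labels=labels,
        brain=brain,
        gm_peak=peak,
        exclusion=exclusion,
        seed=seed,
        info=info,
    )


def run_from_context(
    ctx: SegmentationContext, params: Optional[SegmentationParams] = None
) -> Tuple[BinaryMask, LabeledLesions, Dict]:
    """Back half of the pipeline: threshold, label, filter, report."""
    params = params or SegmentationParams()
    threshold = compute_threshold(ctx.gm_peak, params.alpha)
    cand = _stage(
        "detect_candidates", detect_candidates, ctx.flair, threshold, ctx.brain, ctx.exclusion
    )
    lesions = _stage("label_components", label_components, cand)
    n_candidates = len(lesions.components)
    _stage("filter_by_size", filter_by_size, lesions, params.min_volume_mm3)
    n_after_size = len(lesions.by_status(STATUS_CANDIDATE))
    _stage("filter_by_neighborhood", filter_by_neighborhood, lesions, ctx.labels, params.lam)
    for c in lesions.components:
        if c.status == STATUS_CANDIDATE:
            c.status = STATUS_KEPT
    mask = lesions.kept_mask()
    report = {
        "seed": ctx.seed,
        "params": {
            "alpha": params.alpha,
            "lambda": params.lam,
            "min_volume_mm3": params.min_volume_mm3,
        },
        "mu": ctx.gm_peak.mu,
        "sigma": ctx.gm_peak.sigma,
        "fwhm": ctx.gm_peak.fwhm,
        "threshold": threshold,
        "stage_counts": {
            "candidates": n_candidates,
            "after_size": n_after_size,
            "kept": len(lesions.by_status(STATUS_KEPT)),
            "removed_size": len(lesions.by_status(STATUS_REMOVED_SIZE)),
            "removed_neighborhood": len(lesions.by_status(STATUS_REMOVED_NEIGHBORHOOD)),
        },
        "components": [asdict(c) for c in lesions.components],
    }
    report.update({f"preprocessing_{k}": v for k, v in ctx.info.items()})
    return mask, lesions, report


def segment(
    t1: Volume,
    flair: Volume,
    exclusion: Optional[BinaryMask] = None,
    params: Optional[SegmentationParams] = None,
    seed: int = 0,
    **context_kwargs,
) -> Tuple[BinaryMask, LabeledLesions, Dict]:
    """Full pipeline from co-registered T1w/FLAIR to the final lesion mask.

    Returns (lesion mask, labelled components with statuses, run report).
    Any stage failure raises :class:`PipelineError` naming the stage.
    """
    ctx = build_context(t1, flair, exclusion=exclusion, seed=seed, **context_kwargs)
    return run_from_context(ctx, params)
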