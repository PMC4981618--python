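"""Synthetic co-registered T1w/FLAIR phantom cases with ground truth.

Geometry is three nested ellipsoids (CSF rim, GM ribbon, WM core) — not
anatomy, but enough structure to exercise every pipeline rule: focal WM
hyperintensities, juxtacortical placements, a labelled inferior "posterior
fossa" slab, smooth multiplicative bias, and additive Gaussian noise.

The FLAIR GM intensity carries a smooth multi-sinusoid texture field in
addition to iid noise.  The texture survives the (strongly noise-damping)
diffusion step, so the GM histogram width — and with it the detection
threshold — is dominated by a deterministic, reproducible component while
remaining close to Gaussian.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .errors import InputError, PhantomSpecError
from .lesion_segmentation import (
    STATUS_KEPT,
    LabeledLesions,
    LesionComponent,
)
from .tissue_model import BACKGROUND, CSF, GM, WM, TissueLabels
from .volume_io import BinaryMask, Volume

__all__ = [
    "LesionSpec",
    "ArtifactSpec",
    "PhantomSpec",
    "PhantomCase",
    "generate_phantom",
    "generate_suite",
    "generate_sweep_suite",
]


@dataclass
class LesionSpec:
    """One ground-truth lesion: a quasi-spherical blob of ``n_voxels``
    around ``center``, ``offset`` GM-sd units above the GM FLAIR mean."""

    center: Tuple[float, float, float]
    n_voxels: int
    offset: float = 5.5

    def __post_init__(self):
        if self.n_voxels < 1:
            raise InputError("lesion must have at least 1 voxel")
        if self.offset <= 0:
            raise InputError("FLAIR lesion offset must be > 0")


@dataclass
class ArtifactSpec:
    """A hyperintensity that is NOT a ground-truth lesion.

    kind: 'wm' (embedded in WM; exercises the alpha threshold),
    'gm_attached' (straddles the WM/GM border; exercises the lambda
    filter), or 'pf' (inside the posterior-fossa slab; exercises the
    location exclusion).
    """

    center: Tuple[float, float, float]
    n_voxels: int
    offset: float
    kind: str = "wm"

    def __post_init__(self):
        if self.kind not in ("wm", "gm_attached", "pf"):
            raise InputError(f"unknown artifact kind {self.kind!r}")


@dataclass
class PhantomSpec:
    shape: Tuple[int, int, int] = (64, 64, 64)
    spacing: Tuple[float, float, float] = (1.0, 1.0, 1.0)
    # ellipsoid semi-axes as fractions of the grid size
    csf_frac: float = 0.42
    gm_frac: float = 0.36
    wm_frac: float = 0.28
    t1_means: Tuple[float, float, float] = (30.0, 80.0, 130.0)  # CSF, GM, WM
    t1_noise_sd: float = 4.0
    flair_means: Tuple[float, float, float] = (30.0, 120.0, 90.0)  # CSF, GM, WM
    flair_noise_sd: float = 2.0
    gm_texture_sd: float = 5.0
    texture_modes: int = 12
    lesions: Optional[List[LesionSpec]] = None
    n_lesions: int = 5
    lesion_voxel_range: Tuple[int, int] = (4, 30)
    lesion_offset_range: Tuple[float, float] = (5.0, 6.5)
    artifacts: List[ArtifactSpec] = field(default_factory=list)
    bias_amplitude: float = 0.0
    pf_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if any(n < 32 for n in self.shape):
            raise InputError("phantom shape must be >= 32 along every axis")
        if not (0.0 <= self.bias_amplitude <= 0.3):
            raise InputError("bias_amplitude must be in [0, 0.3]")
        if not (self.wm_frac < self.gm_frac < self.csf_frac <= 0.5):
            raise InputError("ellipsoid fractions must satisfy wm < gm < csf <= 0.5")
        if not (0.0 <= self.pf_fraction < 1.0):
            raise InputError("pf_fraction must be in [0, 1)")
        c, g, w = self.t1_means
        if not (c < g < w):
            raise InputError("T1 means must be ordered CSF < GM < WM")
        fc, fg, fw = self.flair_means
        if not (fg > fw and fg > fc):
            raise InputError("FLAIR GM mean must be the brightest normal tissue")

    @property
    def gm_sigma_ref(self) -> float:
        """Reference GM intensity sd used to place lesion offsets."""
        s = self.gm_texture_sd
        if s <= 0:
            s = self.flair_noise_sd
        if s <= 0:
            s = 1.0
        return s


@dataclass
class PhantomCase:
    t1: Volume
    flair: Volume
    tissue_gt: TissueLabels
    lesion_gt: LabeledLesions
    pf_mask: BinaryMask
    spec: PhantomSpec
    seed: int


# ---------------------------------------------------------------------------
# geometry helpers


def _rho(shape, semi_axes) -> np.ndarray:
    """Normalized ellipsoidal radius field (<= 1 inside the ellipsoid)."""
    center = (np.asarray(shape) - 1) / 2.0
    grids = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    r2 = np.zeros(shape, dtype=float)
    for g, c, a in zip(grids, center, semi_axes):
        r2 += ((g - c) / a) ** 2
    return np.sqrt(r2)


def _ball_voxels(shape, center, n_voxels) -> np.ndarray:
    """The ``n_voxels`` grid points nearest to ``center`` (lexicographic
    tie-break); returns an (n, 3) integer index array."""
    center = np.asarray(center, dtype=float)
    r = max(2.0, 1.5 * (3.0 * n_voxels / (4.0 * math.pi)) ** (1.0 / 3.0) + 1.0)
    lo = np.maximum(np.floor(center - r).astype(int), 0)
    hi = np.minimum(np.ceil(center + r).astype(int) + 1, shape)
    grids = np.meshgrid(*[np.arange(l, h) for l, h in zip(lo, hi)], indexing="ij")
    pts = np.stack([g.ravel() for g in grids], axis=1)
    d = np.linalg.norm(pts - center, axis=1)
    order = np.lexsort((pts[:, 2], pts[:, 1], pts[:, 0], d))
    if pts.shape[0] < n_voxels:
        raise PhantomSpecError(f"cannot carve {n_voxels} voxels at {tuple(center)}")
    return pts[order[:n_voxels]]


def _gt_shell_ratio(voxels: np.ndarray, tissue: np.ndarray) -> float:
    """WM fraction of the 26-shell around a voxel set, using GT labels."""
    shape = tissue.shape
    blob = np.zeros(shape, dtype=bool)
    blob[tuple(voxels.T)] = True
    from scipy import ndimage

    shell = ndimage.binary_dilation(blob, np.ones((3, 3, 3), bool)) & ~blob
    t = tissue[shell]
    denom = int(((t >= CSF) & (t <= WM)).sum())
    if denom == 0:
        return 0.0
    return float((t == WM).sum()) / denom


def _texture_field(shape, modes: int, rng: np.random.Generator) -> np.ndarray:
    """Sum of random-phase 3D cosines, ~Gaussian marginal by mixing."""
    coords = [np.arange(n) / n for n in shape]
    X, Y, Z = np.meshgrid(*coords, indexing="ij")
    w = np.zeros(shape, dtype=float)
    for _ in range(modes):
        freq = rng.uniform(1.5, 4.0, size=3) * rng.choice([-1.0, 1.0], size=3)
        phase = rng.uniform(0.0, 2.0 * math.pi)
        w += np.cos(2.0 * math.pi * (freq[0] * X + freq[1] * Y + freq[2] * Z) + phase)
    return w


# ---------------------------------------------------------------------------
# generation


def _place_centers(
    rng: np.random.Generator,
    allowed: np.ndarray,
    n: int,
    radii: Sequence[float],
    existing: List[Tuple[np.ndarray, float]],
    min_gap: float = 3.0,
    max_attempts: int = 5000,
) -> List[np.ndarray]:
    """Rejection-sample ``n`` centers inside ``allowed`` with pairwise
    separation >= r_i + r_j + min_gap against all previously placed blobs."""
    idx = np.argwhere(allowed)
    if idx.shape[0] == 0:
        raise PhantomSpecError("no admissible voxels for placement")
    placed: List[np.ndarray] = []
    attempts = 0
    while len(placed) < n:
        attempts += 1
        if attempts > max_attempts:
            raise PhantomSpecError(
                f"could not place {n} blobs after {max_attempts} attempts"
            )
        c = idx[rng.integers(idx.shape[0])].astype(float)
        r = radii[len(placed)]
        ok = True
        for pc, pr in existing + [
            (placed[k], radii[k]) for k in range(len(placed))
        ]:
            if np.linalg.norm(c - pc) < r + pr + min_gap:
                ok = False
                break
        if ok:
            placed.append(c)
    return placed


def _blob_radius(n_voxels: int) -> float:
    return (3.0 * n_voxels / (4.0 * math.pi)) ** (1.0 / 3.0)


def generate_phantom(spec: PhantomSpec) -> PhantomCase:
    """Deterministically synthesize one phantom case from its spec."""
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.shape)
    S = np.asarray(shape, dtype=float)

    rho_csf = _rho(shape, spec.csf_frac * S)
    rho_gm = _rho(shape, spec.gm_frac * S)
    rho_wm = _rho(shape, spec.wm_frac * S)
    tissue = np.zeros(shape, dtype=np.uint8)
    tissue[rho_csf <= 1.0] = CSF
    tissue[rho_gm <= 1.0] = GM
    tissue[rho_wm <= 1.0] = WM

    # separability contract: tissue mean gaps >= 6 sd (when noisy)
    if spec.t1_noise_sd > 0:
        gaps = np.diff(sorted(spec.t1_means))
        if gaps.min() < 6.0 * spec.t1_noise_sd:
            raise PhantomSpecError(
                "T1 tissue contrast violates the 6-sd separability contract"
            )

    t1 = np.zeros(shape, dtype=float)
    flair = np.zeros(shape, dtype=float)
    for lab, t1m, flm in zip((CSF, GM, WM), spec.t1_means, spec.flair_means):
        t1[tissue == lab] = t1m
        flair[tissue == lab] = flm

    if spec.gm_texture_sd > 0:
        w = _texture_field(shape, spec.texture_modes, rng)
        gm_sel = tissue == GM
        w = (w - w[gm_sel].mean()) / w[gm_sel].std()
        flair[gm_sel] += spec.gm_texture_sd * w[gm_sel]

    sigma_ref = spec.gm_sigma_ref
    gm_flair_mean = spec.flair_means[1]

    # ---- lesions
    lesions = spec.lesions
    if lesions is None:
        lo, hi = spec.lesion_voxel_range
        sizes = rng.integers(lo, hi + 1, size=spec.n_lesions)
        offsets = rng.uniform(*spec.lesion_offset_range, size=spec.n_lesions)
        radii = [_blob_radius(int(s)) for s in sizes]
        deep = (rho_wm <= 0.75) & (tissue == WM)
        centers = _place_centers(rng, deep, spec.n_lesions, radii, [])
        lesions = [
            LesionSpec(tuple(c), int(s), float(o))
            for c, s, o in zip(centers, sizes, offsets)
        ]

    lesion_lab = np.zeros(shape, dtype=np.int32)
    components: List[LesionComponent] = []
    voxvol = float(np.prod(spec.spacing))
    for k, les in enumerate(lesions, start=1):
        vox = _ball_voxels(shape, les.center, les.n_voxels)
        inside = tissue[tuple(vox.T)] == WM
        if not inside.all():
            raise PhantomSpecError(
                f"lesion {k} at {les.center} extends outside WM "
                f"({int((~inside).sum())} voxels)"
            )
        if lesion_lab[tuple(vox.T)].any():
            raise PhantomSpecError(f"lesion {k} overlaps another lesion")
        lesion_lab[tuple(vox.T)] = k
        flair[tuple(vox.T)] = gm_flair_mean + les.offset * sigma_ref
        components.append(
            LesionComponent(
                id=k,
                voxel_count=int(les.n_voxels),
                volume_mm3=les.n_voxels * voxvol,
                centroid=tuple(vox.mean(axis=0)),
                status=STATUS_KEPT,
            )
        )

    # ---- artifacts (hyperintense, not ground truth)
    for art in spec.artifacts:
        vox = _ball_voxels(shape, art.center, art.n_voxels)
        in_brain = tissue[tuple(vox.T)] != BACKGROUND
        vox = vox[in_brain]
        if vox.shape[0] == 0:
            raise PhantomSpecError(f"artifact at {art.center} lies outside the brain")
        if lesion_lab[tuple(vox.T)].any():
            raise PhantomSpecError(f"artifact at {art.center} overlaps a lesion")
        flair[tuple(vox.T)] = gm_flair_mean + art.offset * sigma_ref

    # ---- noise, bias, posterior fossa
    if spec.t1_noise_sd > 0:
        t1 += rng.normal(0.0, spec.t1_noise_sd, size=shape)
    if spec.flair_noise_sd > 0:
        flair += rng.normal(0.0, spec.flair_noise_sd, size=shape)

    if spec.bias_amplitude > 0:
        coords = [np.linspace(-1.0, 1.0, n) for n in shape]
        X, Y, Z = np.meshgrid(*coords, indexing="ij")
        q = 0.5 * X + 0.3 * Y - 0.4 * Z + 0.35 * X * Y - 0.25 * Z * Z
        q = q / np.abs(q).max() * spec.bias_amplitude
        gain = 1.0 + q
        t1 *= gain
        flair *= gain

    nz = shape[2]
    zidx = np.arange(nz)[None, None, :]
    pf = (np.broadcast_to(zidx, shape) < spec.pf_fraction * nz) & (tissue != BACKGROUND)
    pf_lesion_overlap = pf[lesion_lab > 0]
    if pf_lesion_overlap.any():
        raise PhantomSpecError("a ground-truth lesion falls inside the posterior fossa")

    spacing = spec.spacing
    case = PhantomCase(
        t1=Volume(t1, spacing),
        flair=Volume(flair, spacing),
        tissue_gt=TissueLabels(Volume(tissue, spacing)),
        lesion_gt=LabeledLesions(Volume(lesion_lab, spacing), components),
        pf_mask=BinaryMask(pf.astype(np.uint8), spacing),
        spec=replace(spec, lesions=list(lesions)),
        seed=spec.seed,
    )
    return case


# ---------------------------------------------------------------------------
# suites


def _suite_counts(burden_mix, rng: np.random.Generator) -> List[int]:
    g1, g2, g3 = burden_mix
    if min(g1, g2, g3) < 0:
        raise InputError("burden mix counts must be >= 0")
    counts = (
        [int(rng.integers(2, 5)) for _ in range(g1)]
        + [int(rng.integers(5, 13)) for _ in range(g2)]
        + [int(rng.integers(26, 31)) for _ in range(g3)]
    )
    return counts


def generate_suite(
    n_cases: int,
    burden_mix: Optional[Tuple[int, int, int]] = None,
    seed: int = 0,
    **spec_overrides,
) -> List[PhantomCase]:
    """Generate ``n_cases`` phantoms with lesion counts hitting the
    requested burden groups ((<5, 5-25, >25) counts).  Case seeds derive
    from the master seed."""
    if n_cases < 1:
        raise InputError("n_cases must be >= 1")
    rng = np.random.default_rng(seed)
    fixed_count = spec_overrides.pop("n_lesions", None)
    if fixed_count is not None:
        counts = [int(fixed_count)] * n_cases
        if burden_mix is not None:
            raise InputError("pass either burden_mix or n_lesions, not both")
    elif burden_mix is None:
        counts = [int(rng.integers(2, 9)) for _ in range(n_cases)]
    else:
        if sum(burden_mix) != n_cases:
            raise InputError("sum of burden mix must equal n_cases")
        counts = _suite_counts(burden_mix, rng)
    cases = []
    for i, n_les in enumerate(counts):
        overrides = dict(spec_overrides)
        if n_les > 25:  # high burden needs small lesions to fit
            overrides.setdefault("lesion_voxel_range", (4, 12))
        spec = PhantomSpec(
            n_lesions=n_les, seed=int(rng.integers(0, 2**31 - 1)), **overrides
        )
        cases.append(generate_phantom(spec))
    return cases


# Sweep-suite calibration: offsets are in GM-sd units of the texture field.
# Faint-but-true lesions cap the useful alpha range from above; dim WM
# artifacts penalize alpha below ~2.3; bright GM-attached artifacts with a
# shell WM ratio just under 0.70 penalize lambda below 0.70.
FAINT_LESION_OFFSET = 3.35
ALPHA_ARTIFACT_OFFSET = 2.6
LAMBDA_ARTIFACT_RATIO_WINDOW = (0.55, 0.685)


def _find_gm_attached_center(
    rng: np.random.Generator,
    tissue: np.ndarray,
    rho_wm: np.ndarray,
    n_voxels: int,
    existing: List[Tuple[np.ndarray, float]],
    window=LAMBDA_ARTIFACT_RATIO_WINDOW,
    max_attempts: int = 600,
):
    """A blob center near the WM/GM border whose GT shell WM ratio falls in
    ``window``; falls back to the closest achieved ratio."""
    band = (rho_wm > 0.88) & (rho_wm < 1.1) & (tissue != BACKGROUND)
    idx = np.argwhere(band)
    if idx.shape[0] == 0:
        raise PhantomSpecError("no WM/GM border voxels available")
    r = _blob_radius(n_voxels)
    best = None
    best_err = np.inf
    mid = 0.5 * (window[0] + window[1])
    for _ in range(max_attempts):
        c = idx[rng.integers(idx.shape[0])].astype(float)
        clash = any(
            np.linalg.norm(c - pc) < r + pr + 3.0 for pc, pr in existing
        )
        if clash:
            continue
        vox = _ball_voxels(tissue.shape, c, n_voxels)
        ratio = _gt_shell_ratio(vox, tissue)
        if window[0] <= ratio <= window[1]:
            return c, ratio
        err = abs(ratio - mid)
        if err < best_err:
            best, best_err = (c, ratio), err
    if best is None:
        raise PhantomSpecError("could not place a GM-attached artifact")
    return best


def generate_sweep_suite(
    n_cases: int = 8,
    shape: Tuple[int, int, int] = (48, 48, 48),
    seed: int = 0,
    n_lesions: int = 5,
) -> List[PhantomCase]:
    """Phantoms constructed so the alpha/lambda grid search is informative.

    Each case carries bright true WM lesions, one faint true lesion (upper
    alpha bound), dim WM artifacts (lower alpha bound) and bright
    GM-attached artifacts with shell WM ratio just below 0.70 (lower
    lambda bound).
    """
    rng = np.random.default_rng(seed)
    cases = []
    for i in range(n_cases):
        case_seed = int(rng.integers(0, 2**31 - 1))
        crng = np.random.default_rng(case_seed)
        spec0 = PhantomSpec(shape=shape, seed=case_seed, lesions=[])
        S = np.asarray(shape, dtype=float)
        rho_wm = _rho(shape, spec0.wm_frac * S)
        rho_gm = _rho(shape, spec0.gm_frac * S)
        rho_csf = _rho(shape, spec0.csf_frac * S)
        tissue = np.zeros(shape, dtype=np.uint8)
        tissue[rho_csf <= 1.0] = CSF
        tissue[rho_gm <= 1.0] = GM
        tissue[rho_wm <= 1.0] = WM
        deep = (rho_wm <= 0.72) & (tissue == WM)

        n_bright = max(n_lesions - 1, 1)
        sizes = [int(crng.integers(6, 28)) for _ in range(n_bright)] + [33]
        offsets = [float(crng.uniform(5.0, 6.5)) for _ in range(n_bright)] + [
            FAINT_LESION_OFFSET
        ]
        radii = [_blob_radius(s) for s in sizes]
        centers = _place_centers(crng, deep, len(sizes), radii, [])
        placed = [(c, r) for c, r in zip(centers, radii)]
        lesions = [
            LesionSpec(tuple(c), s, o) for c, s, o in zip(centers, sizes, offsets)
        ]

        artifacts = []
        # alpha-discriminating: dim, deep in WM, survives the size filter
        for _ in range(2):
            (c,) = _place_centers(crng, deep, 1, [_blob_radius(19)], placed)
            placed.append((c, _blob_radius(19)))
            artifacts.append(ArtifactSpec(tuple(c), 19, ALPHA_ARTIFACT_OFFSET, "wm"))
        # lambda-discriminating: bright, straddling the WM/GM border
        for _ in range(2):
            c, _ratio = _find_gm_attached_center(crng, tissue, rho_wm, 19, placed)
            placed.append((c, _blob_radius(19)))
            artifacts.append(ArtifactSpec(tuple(c), 19, 5.0, "gm_attached"))

        spec = PhantomSpec(
            shape=shape, seed=case_seed, lesions=lesions, artifacts=artifacts
        )
        cases.append(generate_phantom(spec))
    return cases
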