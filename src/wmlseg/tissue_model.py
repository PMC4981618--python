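"""Three-class (CSF/GM/WM) intensity segmentation of the T1w volume.

A deliberately simple stand-in for an atlas-prior tissue segmenter: a
3-component 1D Gaussian mixture fitted by EM to in-region intensities,
components assigned to CSF/GM/WM in ascending order of mean T1 intensity.
Externally produced probability maps can be substituted downstream.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._gmm import fit_gmm_1d, gmm_log_resp, kmeans_1d
from .errors import DegenerateInputError, InputError
from .volume_io import BinaryMask, Volume, assert_coregistered

__all__ = [
    "TissueProbabilities",
    "TissueLabels",
    "fit_three_class_em",
    "max_probability_labels",
    "BACKGROUND",
    "CSF",
    "GM",
    "WM",
]

BACKGROUND, CSF, GM, WM = 0, 1, 2, 3


@dataclass
class TissueProbabilities:
    """Per-voxel CSF/GM/WM probability maps on a shared grid.

    Inside the fitted region the three maps sum to 1 (within 1e-6); outside
    they are all exactly 0.
    """

    csf: Volume
    gm: Volume
    wm: Volume
    converged: bool = True

    def __post_init__(self):
        assert_coregistered([self.csf, self.gm, self.wm])
        total = (
            np.asarray(self.csf.data)
            + np.asarray(self.gm.data)
            + np.asarray(self.wm.data)
        )
        inside = total > 0.5
        if inside.any() and not np.allclose(total[inside], 1.0, atol=1e-6):
            raise InputError("tissue probabilities must sum to 1 inside the region")
        for v in (self.csf, self.gm, self.wm):
            d = np.asarray(v.data)
            if d.min() < -1e-9 or d.max() > 1 + 1e-9:
                raise InputError("tissue probabilities must lie in [0, 1]")

    @property
    def region(self) -> np.ndarray:
        """Boolean array marking the fitted region."""
        return (
            np.asarray(self.csf.data)
            + np.asarray(self.gm.data)
            + np.asarray(self.wm.data)
        ) > 0.5


@dataclass
class TissueLabels:
    """Hard label map: 0 background, 1 CSF, 2 GM, 3 WM."""

    labels: Volume

    def __post_init__(self):
        values = np.unique(np.asarray(self.labels.data))
        if not np.isin(values, (BACKGROUND, CSF, GM, WM)).all():
            raise InputError(f"labels must be in {{0,1,2,3}}, found {values[:10]}")

    def mask(self, label: int) -> BinaryMask:
        """Binary mask of one tissue class."""
        return BinaryMask(
            (np.asarray(self.labels.data) == label).astype(np.uint8),
            self.labels.spacing,
            self.labels.affine,
        )


def fit_three_class_em(
    t1: Volume,
    region: BinaryMask,
    seed: int = 0,
    max_iter: int = 100,
    tol: float = 1e-5,
) -> TissueProbabilities:
    """Fit a 3-component Gaussian mixture to in-region T1 intensities.

    Initialization is deterministic: 3 k-means (Lloyd) centers started at
    the 10th/50th/90th in-region percentiles.  ``seed`` is accepted for
    interface stability but the procedure involves no sampling, so the
    output is bit-identical across calls regardless of its value.
    Components are mapped to CSF/GM/WM in ascending order of mean.
    """
    assert_coregistered([t1, region])
    m = region.as_bool()
    if not m.any():
        raise InputError("fit_three_class_em: empty region")
    x = np.asarray(t1.data, dtype=float)[m]
    if not np.isfinite(x).all():
        raise InputError("fit_three_class_em: non-finite T1 intensities")
    if np.unique(x).size < 3:
        raise DegenerateInputError(
            "fewer than 3 distinct intensity values inside the region"
        )
    init = kmeans_1d(x, np.percentile(x, [10, 50, 90]))
    means, variances, weights, converged = fit_gmm_1d(
        x, init, max_iter=max_iter, tol=tol
    )
    if not converged:
        warnings.warn(
            f"tissue EM did not converge in {max_iter} iterations",
            RuntimeWarning,
            stacklevel=2,
        )
    order = np.argsort(means)  # ascending T1 mean: CSF < GM < WM
    logp, lse = gmm_log_resp(x, means[order], variances[order], weights[order])
    resp = np.exp(logp - lse[:, None])
    resp /= resp.sum(axis=1, keepdims=True)

    maps = []
    for k in range(3):
        full = np.zeros(t1.shape, dtype=float)
        full[m] = resp[:, k]
        maps.append(t1.with_data(full))
    return TissueProbabilities(*maps, converged=converged)


def max_probability_labels(probs: TissueProbabilities) -> TissueLabels:
    """Per-voxel argmax over the three maps; background where all are 0.

    Ties break toward the higher label index (WM > GM > CSF).
    """
    stack = np.stack(
        [
            np.asarray(probs.wm.data),
            np.asarray(probs.gm.data),
            np.asarray(probs.csf.data),
        ]
    )
    # argmax over (wm, gm, csf) returns the first max, i.e. the highest label
    idx = np.argmax(stack, axis=0)
    labels = (3 - idx).astype(np.uint8)
    labels[~probs.region] = BACKGROUND
    return TissueLabels(probs.gm.with_data(labels))
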