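"""Voxelwise contrast maps between a component's positive and negative features.

The positive weights of a fitted component are rescaled to sum to +1 and
the negative weights to sum to -1; the resulting contrast vector, applied
to each voxel's standardized beta profile and z-scored across voxels,
scores how much each voxel favours the component's positive feature set
over its negative one.  The contrast is applied directly to the beta
matrix (a descriptive z-score, not a GLM statistic map).
"""

from __future__ import annotations

import numpy as np

from .core import StandardizedBetaMatrix

__all__ = ["contrast_vector", "voxel_contrast_scores"]


def contrast_vector(weights: np.ndarray) -> np.ndarray:
    """Rescale positive weights to sum to 1 and negative weights to -1.

    Zeros stay zero.  Requires at least one positive and one negative
    weight; the normalization makes the result invariant to positive
    rescaling of the raw component.
    """
    w = np.asarray(weights, dtype=float).ravel()
    if not np.all(np.isfinite(w)):
        raise ValueError("component weights contain non-finite values")
    pos = w > 0
    neg = w < 0
    if not pos.any() or not neg.any():
        raise ValueError("contrast needs at least one positive and one negative weight")
    out = np.zeros_like(w)
    out[pos] = w[pos] / w[pos].sum()
    out[neg] = w[neg] / abs(w[neg].sum())
    return out


def voxel_contrast_scores(
    betas: StandardizedBetaMatrix, contrast: np.ndarray
) -> np.ndarray:
    """Per-voxel contrast score, z-scored across voxels (mean 0, sd 1)."""
    c = np.asarray(contrast, dtype=float).ravel()
    if c.size != betas.n_conditions:
        raise ValueError("contrast vector length must match the number of conditions")
    raw = betas.values @ c
    sd = raw.std(ddof=1)
    if sd == 0:
        raise ValueError("contrast scores have zero variance across voxels")
    return (raw - raw.mean()) / sd
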