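"""Univariate parcel signatures: cone contrast, signal change, CRF slopes.

These are the classical single-feature statistics that accompany the
multivariate embedding: a grating pair's summary Michelson cone contrast,
percent signal change relative to the gray baseline, pairing of opposing
pole gratings into features, contrast-response-function (CRF) slopes with
run-bootstrap errors, the dorsal/ventral luminance-bias bootstrap, and
maximum-z eccentricity assignment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .core import ConditionCatalog

__all__ = [
    "cone_contrast",
    "percent_signal_change",
    "pair_axis_features",
    "crf_slope",
    "luminance_bias_difference",
    "assign_eccentricity",
    "LuminanceBiasResult",
]


def cone_contrast(
    pole_a: Sequence[float], pole_b: Sequence[float]
) -> float:
    """Summary Michelson cone contrast (%) of a grating pair.

    The mean of the two Euclidean norms of the per-pole (%L, %M, %S) cone
    contrasts.  Symmetric in the poles and invariant to negating either
    pole vector.
    """
    a = np.asarray(pole_a, dtype=float)
    b = np.asarray(pole_b, dtype=float)
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("cone contrasts must be finite")
    return float((np.linalg.norm(a) + np.linalg.norm(b)) / 2.0)


def percent_signal_change(beta_condition: float, beta_baseline: float) -> float:
    """100 * beta_condition / beta_baseline; errors on a zero baseline."""
    if beta_baseline == 0:
        raise ValueError("baseline beta is zero; percent signal change undefined")
    return 100.0 * beta_condition / beta_baseline


def pair_axis_features(
    betas: pd.DataFrame, catalog: ConditionCatalog
) -> pd.DataFrame:
    """Average opposing-pole grating responses into named features.

    ``betas`` columns are pole grating names (any index, e.g. voxels or
    (voxel, run) observations); the output has one column per catalog
    feature, the mean of its two pole columns.  Single-grating features
    pass through unchanged.  Missing poles raise an error listing them.
    """
    missing = []
    out = {}
    for cond in catalog:
        poles = [cond.pole_a_name, cond.pole_b_name]
        absent = [p for p in poles if p not in betas.columns]
        if absent:
            missing.extend(absent)
            continue
        if cond.is_single_pole:
            out[cond.name] = betas[cond.pole_a_name].to_numpy(dtype=float)
        else:
            out[cond.name] = betas[poles].mean(axis=1).to_numpy(dtype=float)
    if missing:
        raise ValueError(
            "betas table is missing pole condition(s): " + ", ".join(sorted(set(missing)))
        )
    return pd.DataFrame(out, index=betas.index)


def crf_slope(
    responses: np.ndarray,
    contrasts: Sequence[float],
    n_boot: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """OLS slope of response versus cone contrast, with run-bootstrap sd.

    ``responses`` is (runs x levels) percent signal change; ``contrasts``
    gives the cone contrast of each level.  The point estimate pools all
    runs; the sd is the standard deviation of the slope over ``n_boot``
    resamples of runs with replacement.
    """
    resp = np.atleast_2d(np.asarray(responses, dtype=float))
    x = np.asarray(contrasts, dtype=float)
    if x.size != resp.shape[1]:
        raise ValueError("one contrast per response level required")
    if np.unique(x).size < 2:
        raise ValueError("need at least 2 distinct contrast levels for a slope")

    def _slope(block: np.ndarray) -> float:
        xs = np.tile(x, block.shape[0])
        ys = block.ravel()
        return float(scipy.stats.linregress(xs, ys).slope)

    point = _slope(resp)
    rng = np.random.default_rng(seed)
    n_runs = resp.shape[0]
    if n_runs < 2:
        return point, 0.0
    slopes = np.empty(n_boot)
    for b in range(n_boot):
        slopes[b] = _slope(resp[rng.integers(0, n_runs, size=n_runs)])
    return point, float(slopes.std(ddof=1))


@dataclass(frozen=True)
class LuminanceBiasResult:
    """Bootstrap distribution of the ventral-vs-dorsal luminance-bias gap."""

    deltas: np.ndarray
    delta_mean: float
    p_one_sided: float
    n_boot: int


def luminance_bias_difference(
    color_ventral: np.ndarray,
    luminance_ventral: np.ndarray,
    color_dorsal: np.ndarray,
    luminance_dorsal: np.ndarray,
    n_boot: int = 1000,
    seed: int = 0,
) -> LuminanceBiasResult:
    """Bootstrap the gap Delta = (color - lum)_ventral - (color - lum)_dorsal.

    Inputs are per-run response vectors.  Each bootstrap iteration resamples
    runs with replacement independently within each of the four sets and
    recomputes Delta from the resampled means.  The one-sided p-value for
    the alternative Delta > 0 is the fraction of resamples with Delta < 0,
    counting exact ties as half (mid-p; for continuous responses ties have
    probability zero, and a degenerate all-zero Delta gives p = 0.5).
    """
    groups = [
        np.asarray(g, dtype=float).ravel()
        for g in (color_ventral, luminance_ventral, color_dorsal, luminance_dorsal)
    ]
    if any(g.size == 0 for g in groups):
        raise ValueError("every response group must be non-empty")
    rng = np.random.default_rng(seed)
    deltas = np.empty(n_boot)
    for b in range(n_boot):
        means = [g[rng.integers(0, g.size, size=g.size)].mean() for g in groups]
        deltas[b] = (means[0] - means[1]) - (means[2] - means[3])
    p = float(np.mean(deltas < 0) + 0.5 * np.mean(deltas == 0))
    return LuminanceBiasResult(
        deltas=deltas, delta_mean=float(deltas.mean()), p_one_sided=p, n_boot=n_boot
    )


def assign_eccentricity(ring_zscores: np.ndarray) -> np.ndarray:
    """Assign each voxel to the ring with the maximum z-score.

    Columns are ordered fovea -> periphery; returns 1-based level indices.
    Ties resolve to the more foveal (earlier) level, matching an outward
    scan from the fovea.
    """
    z = np.atleast_2d(np.asarray(ring_zscores, dtype=float))
    if z.shape[1] < 1:
        raise ValueError("need at least one ring score per voxel")
    if np.any(np.isnan(z)):
        raise ValueError("ring z-scores contain NaN")
    # np.argmax returns the first maximum, i.e. the foveal-first tie rule
    return z.argmax(axis=1) + 1
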