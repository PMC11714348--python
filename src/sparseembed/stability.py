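"""Bootstrap stability: run resampling, rotational alignment, CIs, CV.

A fitted k-dimensional transform is only identified up to an orthogonal
change of basis within the embedding subspace, so transforms fitted on
bootstrap resamples cannot be compared entrywise as-is.  Each fitted
transform is therefore right-multiplied by an orthogonal k x k matrix
(reflections allowed, absorbing the arbitrary component signs) chosen to
minimize the total variance across fits — a generalized Procrustes
alignment onto an iterated consensus mean.  Residual variance across the
aligned transforms then reflects genuine variability of the subspace.

The exchangeable unit for resampling is the acquisition run: a resample
draws runs with replacement, averages their raw beta matrices, standardizes
the average, and refits the embedding from a fresh random initialization.
Means and standard deviations are the moments of a normal distribution fit
over all resamples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
import scipy.stats

from .core import (
    BootstrapResult,
    EmbeddingTransform,
    FitConfig,
    PairWeights,
    ParcelLabeling,
    RunBetaStack,
)
from .objective import class_centroids, fit

__all__ = [
    "align_transforms",
    "bootstrap",
    "significant_features",
    "cross_validate",
    "CrossValidationResult",
]


def align_transforms(
    transforms: list[np.ndarray] | list[EmbeddingTransform],
    tol: float = 1e-9,
    max_iter: int = 100,
) -> tuple[list[np.ndarray], np.ndarray]:
    """Generalized Procrustes alignment of m x k transforms.

    Iterates {orthogonally align every transform onto the current consensus
    mean; recompute the mean} until the mean moves by less than ``tol`` in
    Frobenius norm.  Returns the aligned transforms and the consensus.
    """
    mats = [
        np.asarray(t.components if isinstance(t, EmbeddingTransform) else t, dtype=float)
        for t in transforms
    ]
    if len(mats) < 2:
        raise ValueError("alignment needs at least 2 transforms")
    shapes = {mat.shape for mat in mats}
    if len(shapes) != 1:
        raise ValueError("all transforms must share one m x k shape")
    m, k = mats[0].shape
    if k > m:
        raise ValueError("need k <= m")

    aligned = [mat.copy() for mat in mats]
    mean = np.mean(mats, axis=0)
    # the raw mean can vanish when transforms differ by reflections; seed
    # the consensus with the first transform in that degenerate case
    scale = np.mean([np.linalg.norm(mat) for mat in mats])
    if np.linalg.norm(mean) < 1e-8 * max(scale, 1e-30):
        mean = mats[0]
    for _ in range(max_iter):
        for i, mat in enumerate(mats):
            # orthogonal Procrustes: argmin_R ||mat @ R - mean||_F over O(k)
            R, _ = scipy.linalg.orthogonal_procrustes(mat, mean)
            aligned[i] = mat @ R
        new_mean = np.mean(aligned, axis=0)
        if np.linalg.norm(new_mean - mean) < tol:
            mean = new_mean
            break
        mean = new_mean
    return aligned, mean


def _subseeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def bootstrap(
    stack: RunBetaStack,
    labels: ParcelLabeling,
    M: PairWeights,
    config: FitConfig,
    n_boot: int = 1000,
    seed: int = 0,
) -> BootstrapResult:
    """Run-level bootstrap of the embedding fit with rotational alignment.

    Resamples whole runs with replacement ``n_boot`` times, refits the
    transform on each resample from a fresh random initialization, aligns
    the fitted transforms, and summarizes weights and parcel-centroid
    projections by their normal-approximation mean and sd.  Resamples whose
    fit fails to converge are excluded and counted.
    """
    if n_boot < 2:
        raise ValueError("need n_boot >= 2 bootstrap resamples")
    if labels.n_voxels != stack.values.shape[1]:
        raise ValueError("labeling covers a different voxel panel than the run stack")
    rng = np.random.default_rng(seed)
    fit_seeds = _subseeds(seed, n_boot)
    n_runs = stack.n_runs

    transforms: list[np.ndarray] = []
    projections: list[np.ndarray] = []
    excluded = 0
    for b in range(n_boot):
        draw = rng.integers(0, n_runs, size=n_runs)
        betas = stack.standardized_average(draw)
        result = fit(betas, labels, M, config=config.replace(seed=fit_seeds[b]))
        if not result.converged:
            excluded += 1
            continue
        transforms.append(result.components)
        projections.append(class_centroids(betas.values, labels))
    if len(transforms) < 2:
        raise RuntimeError(
            f"fewer than 2 converged bootstrap fits ({excluded} of {n_boot} excluded)"
        )

    aligned, consensus = align_transforms(transforms)
    stack_T = np.stack(aligned)                              # (B, m, k)
    proj = np.einsum("brm,bmk->brk", np.stack(projections), stack_T)  # (B, |R|, k)

    # normal fit over resamples: mean and sd per entry
    ddof = 1
    return BootstrapResult(
        aligned_transforms=tuple(aligned),
        consensus=consensus,
        weight_means=stack_T.mean(axis=0),
        weight_sds=stack_T.std(axis=0, ddof=ddof),
        projection_means=proj.mean(axis=0),
        projection_sds=proj.std(axis=0, ddof=ddof),
        condition_names=stack.condition_names,
        class_labels=tuple(labels.class_labels()),
        n_boot=n_boot,
        n_excluded=excluded,
        seed=seed,
    )


def significant_features(
    result: BootstrapResult, level: float = 0.95
) -> list[list[str]]:
    """Features whose two-sided normal CI excludes zero, per component.

    The CI is mean +/- z * sd with z the standard-normal quantile for the
    given two-sided level.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("confidence level must lie in (0, 1)")
    z = scipy.stats.norm.ppf(0.5 + level / 2.0)
    out: list[list[str]] = []
    for j in range(result.k):
        lo = result.weight_means[:, j] - z * result.weight_sds[:, j]
        hi = result.weight_means[:, j] + z * result.weight_sds[:, j]
        out.append(
            [
                name
                for i, name in enumerate(result.condition_names)
                if lo[i] > 0 or hi[i] < 0
            ]
        )
    return out


@dataclass(frozen=True)
class CrossValidationResult:
    """Held-out parcel projections from the even/odd run split.

    ``*_train`` are the projections of the training-half centroids through
    the transform fitted on that half; ``*_test`` project the held-out
    half's centroids through the same transform.  CI half-widths come from
    run-level bootstrap of the held-out half (the transform stays fixed).
    """

    transform_even: EmbeddingTransform
    transform_odd: EmbeddingTransform
    proj_even_train: np.ndarray
    proj_odd_test: np.ndarray
    proj_odd_train: np.ndarray
    proj_even_test: np.ndarray
    proj_odd_test_sd: np.ndarray
    proj_even_test_sd: np.ndarray
    class_labels: tuple[str, ...]


def _project_half(
    stack: RunBetaStack,
    labels: ParcelLabeling,
    transform: EmbeddingTransform,
    run_positions: np.ndarray,
    n_boot: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    betas = stack.standardized_average(run_positions)
    point = class_centroids(betas.values, labels) @ transform.components
    reps = []
    for _ in range(n_boot):
        draw = rng.choice(run_positions, size=run_positions.size, replace=True)
        b = stack.standardized_average(draw)
        reps.append(class_centroids(b.values, labels) @ transform.components)
    sd = np.stack(reps).std(axis=0, ddof=1)
    return point, sd


def cross_validate(
    stack: RunBetaStack,
    labels: ParcelLabeling,
    M: PairWeights,
    config: FitConfig,
    seed: int = 0,
    n_boot: int = 200,
) -> CrossValidationResult:
    """Even/odd-run split validation of the embedding.

    Runs are split by the parity of their position in sorted run-id order;
    the transform is fitted on each half and the held-out half's parcel
    centroids are projected into the fitted embedding.
    """
    if stack.n_runs < 2:
        raise ValueError("cross-validation needs at least 2 runs")
    order = np.argsort(np.asarray(stack.run_ids))
    even = order[0::2]
    odd = order[1::2]
    seeds = _subseeds(seed, 4)

    betas_even = stack.standardized_average(even)
    betas_odd = stack.standardized_average(odd)
    t_even = fit(betas_even, labels, M, config=config.replace(seed=seeds[0]))
    t_odd = fit(betas_odd, labels, M, config=config.replace(seed=seeds[1]))

    rng_a = np.random.default_rng(seeds[2])
    rng_b = np.random.default_rng(seeds[3])
    proj_even_train = class_centroids(betas_even.values, labels) @ t_even.components
    proj_odd_train = class_centroids(betas_odd.values, labels) @ t_odd.components
    proj_odd_test, sd_odd = _project_half(stack, labels, t_even, odd, n_boot, rng_a)
    proj_even_test, sd_even = _project_half(stack, labels, t_odd, even, n_boot, rng_b)

    return CrossValidationResult(
        transform_even=t_even,
        transform_odd=t_odd,
        proj_even_train=proj_even_train,
        proj_odd_test=proj_odd_test,
        proj_odd_train=proj_odd_train,
        proj_even_test=proj_even_test,
        proj_odd_test_sd=sd_odd,
        proj_even_test_sd=sd_even,
        class_labels=tuple(labels.class_labels()),
    )
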