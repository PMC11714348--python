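import numpy as np
import pytest

import sparseembed as se


@pytest.fixture
def two_class_labels():
    """Two parcels of the same area at different eccentricity levels."""
    classes = (se.ParcelClass("A", "dorsal", 1), se.ParcelClass("A", "dorsal", 2))
    return se.ParcelLabeling(np.repeat([0, 1], 2), classes)


@pytest.fixture
def hand_worked_instance(two_class_labels):
    """The 4-voxel, 2-condition instance whose objective is hand-computable.

    Class A at x in {0, 2}, class B at x in {4, 6}, second condition zero,
    T = [1, 0], unit pair weight, sparsity 0.005: distance 8, covariance 2,
    L1 1, total 5.995.
    """
    raw = np.array([[0.0, 0.0], [2.0, 0.0], [4.0, 0.0], [6.0, 0.0]])
    betas = se.StandardizedBetaMatrix(raw, ("c1", "c2"), standardized=False)
    M = se.PairWeights(np.array([[0.0, 1.0], [1.0, 0.0]]))
    T = np.array([[1.0], [0.0]])
    return betas, two_class_labels, M, T


def make_labels(n_area_divisions: int, n_levels: int, voxels_per_class: int = 2):
    """A labeling with the given number of (area, division) groups x levels."""
    classes = []
    for g in range(n_area_divisions):
        for lev in range(1, n_levels + 1):
            classes.append(se.ParcelClass(f"A{g}", "dorsal", lev))
    idx = np.repeat(np.arange(len(classes)), voxels_per_class)
    return se.ParcelLabeling(idx, tuple(classes))


def planted_two_class(
    seed: int,
    n_per_class: int = 30,
    m: int = 8,
    effect: float = 2.0,
    planted: int = 0,
):
    """Two classes differing only in one condition; all others pure noise."""
    rng = np.random.default_rng(seed)
    raw = rng.normal(size=(2 * n_per_class, m))
    raw[:n_per_class, planted] += effect
    names = tuple(f"c{i}" for i in range(m))
    betas = se.standardize(raw, names)
    labels = se.ParcelLabeling(
        np.repeat([0, 1], n_per_class),
        (se.ParcelClass("A", "dorsal", 1), se.ParcelClass("A", "dorsal", 2)),
    )
    M = se.mask_custom(labels, [(0, 1)])
    return betas, labels, M


@pytest.fixture(scope="session")
def small_synthetic():
    """A small generated dataset shared by read-only tests."""
    cfg = se.GeneratorConfig(seed=11, voxels_per_class=8, runs=8)
    return se.generate(cfg)
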