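"""Pairwise class-weight (mask) construction for the two standard analyses.

The mask decides which parcel pairs the embedding is asked to separate:
``mask_eccentricity`` compares eccentricity levels within each retinotopic
area, ``mask_area_within_eccentricity`` compares areas within each
eccentricity level.  Both are binary; graded masks go through
``mask_custom``.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .core import PairWeights, ParcelLabeling

__all__ = [
    "mask_eccentricity",
    "mask_area_within_eccentricity",
    "mask_custom",
    "mask_to_frame",
    "mask_from_frame",
]


def _require_levels(labels: ParcelLabeling):
    if len({c.ecc_level for c in labels.classes}) < 1:
        raise ValueError("class catalog carries no eccentricity levels")


def mask_eccentricity(labels: ParcelLabeling) -> PairWeights:
    """Weight 1 for pairs of the same (area, division) at different levels."""
    _require_levels(labels)
    n = labels.n_classes
    W = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = labels.classes[i], labels.classes[j]
            if (a.area, a.division) == (b.area, b.division) and a.ecc_level != b.ecc_level:
                W[i, j] = W[j, i] = 1.0
    return PairWeights(W)


def mask_area_within_eccentricity(labels: ParcelLabeling) -> PairWeights:
    """Weight 1 for pairs at the same eccentricity level in different areas."""
    _require_levels(labels)
    n = labels.n_classes
    W = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = labels.classes[i], labels.classes[j]
            if a.ecc_level == b.ecc_level and (a.area, a.division) != (b.area, b.division):
                W[i, j] = W[j, i] = 1.0
    return PairWeights(W)


def mask_custom(
    labels: ParcelLabeling,
    pairs: Sequence[tuple[int, int]],
    weights: Sequence[float] | float = 1.0,
) -> PairWeights:
    """Symmetric mask from an explicit unordered pair list.

    Pairs are class indices into the labeling's catalog; duplicates (in
    either order) are rejected rather than summed.
    """
    n = labels.n_classes
    pairs = list(pairs)
    if np.isscalar(weights):
        weights = [float(weights)] * len(pairs)
    weights = list(weights)
    if len(weights) != len(pairs):
        raise ValueError("one weight per pair required")
    W = np.zeros((n, n))
    seen: set[tuple[int, int]] = set()
    for (i, j), w in zip(pairs, weights):
        i, j = int(i), int(j)
        if not (0 <= i < n and 0 <= j < n):
            raise ValueError(f"unknown class index in pair ({i}, {j})")
        if i == j:
            raise ValueError("within-class (diagonal) pairs are not allowed")
        if w < 0:
            raise ValueError("pair weights must be nonnegative")
        key = (min(i, j), max(i, j))
        if key in seen:
            raise ValueError(f"duplicate pair {key}")
        seen.add(key)
        W[i, j] = W[j, i] = w
    return PairWeights(W)


def mask_to_frame(M: PairWeights, labels: ParcelLabeling) -> pd.DataFrame:
    """Export the positive unordered pairs as a tidy class-pair table."""
    rows = [
        {
            "class_a": labels.classes[i].label,
            "class_b": labels.classes[j].label,
            "weight": M.weights[i, j],
        }
        for i, j in M.positive_pairs()
    ]
    return pd.DataFrame(rows, columns=["class_a", "class_b", "weight"])


def mask_from_frame(df: pd.DataFrame, labels: ParcelLabeling) -> PairWeights:
    """Rebuild a mask from a class-pair table written by :func:`mask_to_frame`."""
    index = {c.label: i for i, c in enumerate(labels.classes)}
    pairs, weights = [], []
    for row in df.itertuples(index=False):
        try:
            pairs.append((index[row.class_a], index[row.class_b]))
        except KeyError as exc:
            raise ValueError(f"unknown class label {exc.args[0]!r} in pair table") from None
        weights.append(float(row.weight))
    return mask_custom(labels, pairs, weights)
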