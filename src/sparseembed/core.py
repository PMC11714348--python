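"""Core data model: beta matrices, parcel labels, pair weights, transforms.

The central container is a voxels x conditions matrix of standardized GLM
beta coefficients.  Voxels belong to parcels (classes) defined by the triple
(retinotopic area, dorsal/ventral division, eccentricity level); the
embedding machinery separates those parcels.  Everything here is plain
numpy/pandas with validated constructors so downstream numerics can assume
their invariants.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "StandardizedBetaMatrix",
    "ParcelLabeling",
    "ParcelClass",
    "PairWeights",
    "EmbeddingTransform",
    "FitConfig",
    "ObjectiveBreakdown",
    "BootstrapResult",
    "Condition",
    "ConditionCatalog",
    "RunBetaStack",
    "standardize",
    "load_condition_catalog",
    "load_betas_table",
    "load_voxel_metadata",
    "UNDIVIDED",
]

UNDIVIDED = "undivided"

_MEAN_TOL = 1e-8
_SD_TOL = 1e-6


# ---------------------------------------------------------------------------
# beta matrices

@dataclass(frozen=True)
class StandardizedBetaMatrix:
    """A voxels x conditions matrix of z-scored beta coefficients.

    Each column (condition) has mean 0 and unit sample standard deviation
    across voxels.  ``run_ids`` optionally records per-row run provenance
    when the rows are (voxel, run) observations rather than run-averages.
    """

    values: np.ndarray
    condition_names: tuple[str, ...]
    run_ids: tuple[int, ...] | None = None
    standardized: bool = True

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "condition_names", tuple(self.condition_names))
        if self.run_ids is not None:
            object.__setattr__(self, "run_ids", tuple(int(r) for r in self.run_ids))
        if values.ndim != 2:
            raise ValueError("beta matrix must be 2-D (voxels x conditions)")
        if values.shape[1] != len(self.condition_names):
            raise ValueError(
                f"{values.shape[1]} columns but {len(self.condition_names)} condition names"
            )
        if len(set(self.condition_names)) != len(self.condition_names):
            raise ValueError("condition names must be unique")
        if not np.all(np.isfinite(values)):
            raise ValueError("beta matrix contains non-finite values")
        if self.run_ids is not None and len(self.run_ids) != values.shape[0]:
            raise ValueError("run_ids length must match the number of rows")
        if self.standardized:
            mu = values.mean(axis=0)
            sd = values.std(axis=0, ddof=1)
            if np.any(np.abs(mu) > _MEAN_TOL) or np.any(np.abs(sd - 1.0) > _SD_TOL):
                raise ValueError("matrix flagged standardized but columns are not z-scored")

    @property
    def n_voxels(self) -> int:
        return self.values.shape[0]

    @property
    def n_conditions(self) -> int:
        return self.values.shape[1]


def standardize(
    raw_betas: np.ndarray,
    condition_names: Sequence[str],
    run_ids: Sequence[int] | None = None,
) -> StandardizedBetaMatrix:
    """Z-score each condition column across voxels (sample sd, n-1).

    Column order is preserved.  Raises if the input has fewer than two rows,
    non-finite entries, or a zero-variance column (named in the error).
    """
    raw = np.asarray(raw_betas, dtype=float)
    names = tuple(condition_names)
    if raw.ndim != 2:
        raise ValueError("raw betas must be 2-D (voxels x conditions)")
    if raw.shape[0] < 2:
        raise ValueError("need at least 2 voxels to standardize")
    if raw.shape[1] != len(names):
        raise ValueError("number of condition names must match columns")
    if not np.all(np.isfinite(raw)):
        raise ValueError("raw betas contain NaN or infinite values")
    sd = raw.std(axis=0, ddof=1)
    zero = np.where(sd == 0.0)[0]
    if zero.size:
        raise ValueError(
            "zero-variance condition column(s): " + ", ".join(names[i] for i in zero)
        )
    z = (raw - raw.mean(axis=0)) / sd
    return StandardizedBetaMatrix(z, names, run_ids=run_ids, standardized=True)


# ---------------------------------------------------------------------------
# parcels

@dataclass(frozen=True, order=True)
class ParcelClass:
    """One parcel: (area, dorsal/ventral division, eccentricity level 1..4)."""

    area: str
    division: str
    ecc_level: int

    def __post_init__(self):
        if self.division not in ("dorsal", "ventral", UNDIVIDED):
            raise ValueError(f"unknown division {self.division!r}")
        if self.ecc_level < 1:
            raise ValueError("eccentricity level indices start at 1")

    @property
    def label(self) -> str:
        return f"{self.area}:{self.division}:e{self.ecc_level}"


@dataclass(frozen=True)
class ParcelLabeling:
    """Per-voxel class assignment over a catalog of parcel classes.

    ``voxel_to_class`` holds integer indices into ``classes``.  Every class
    must have at least two member voxels so a within-class covariance is
    estimable.
    """

    voxel_to_class: np.ndarray
    classes: tuple[ParcelClass, ...]

    def __post_init__(self):
        idx = np.asarray(self.voxel_to_class, dtype=int)
        object.__setattr__(self, "voxel_to_class", idx)
        object.__setattr__(self, "classes", tuple(self.classes))
        if idx.ndim != 1:
            raise ValueError("voxel_to_class must be a 1-D vector")
        n = len(self.classes)
        if n == 0:
            raise ValueError("class catalog is empty")
        if len(set(self.classes)) != n:
            raise ValueError("duplicate classes in catalog")
        if idx.min(initial=0) < 0 or (idx.size and idx.max() >= n):
            raise ValueError("voxel class index out of catalog range")
        counts = np.bincount(idx, minlength=n)
        small = np.where(counts < 2)[0]
        if small.size:
            bad = ", ".join(self.classes[i].label for i in small)
            raise ValueError(f"class(es) with fewer than 2 voxels: {bad}")

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    @property
    def n_voxels(self) -> int:
        return self.voxel_to_class.size

    def members(self, class_index: int) -> np.ndarray:
        return np.where(self.voxel_to_class == class_index)[0]

    def class_labels(self) -> list[str]:
        return [c.label for c in self.classes]


@dataclass(frozen=True)
class PairWeights:
    """Symmetric nonnegative |R| x |R| matrix weighting class-pair separation."""

    weights: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("pair weights must be a square matrix")
        if not np.all(np.isfinite(w)):
            raise ValueError("pair weights contain non-finite values")
        if np.any(w < 0):
            raise ValueError("pair weights must be nonnegative")
        if not np.allclose(w, w.T):
            raise ValueError("pair weights must be symmetric")
        if np.any(np.diag(w) != 0):
            raise ValueError("pair weights must have zero diagonal")
        if not np.any(w > 0):
            raise ValueError("pair weights must have at least one positive pair")

    @property
    def n_classes(self) -> int:
        return self.weights.shape[0]

    def positive_pairs(self) -> list[tuple[int, int]]:
        """Unordered (i < j) pairs with strictly positive weight."""
        i, j = np.where(np.triu(self.weights, k=1) > 0)
        return list(zip(i.tolist(), j.tolist()))


# ---------------------------------------------------------------------------
# transforms and fit results

@dataclass(frozen=True)
class FitConfig:
    """Optimizer settings for fitting the embedding.

    Optimization runs in two phases: ``adam_iter`` Adam steps (default a
    third of ``max_iter``) for fast global progress, then proximal
    projected-gradient ascent with step ``polish_step`` until the objective
    is stationary; the L1 term enters through its proximal soft-threshold
    operator in both phases, so small weights reach exactly zero.  Columns
    of the component matrix are re-projected to unit L2 norm after every
    step when ``normalize_columns`` is on (the default); without a scale
    constraint the objective is unbounded in ``T``.
    """

    k: int = 1
    sparsity: float = 0.005
    learning_rate: float = 0.01
    max_iter: int = 2000
    adam_iter: int | None = None
    polish_step: float = 0.02
    tol: float = 1e-6
    tol_window: int = 50
    init_sd: float = 0.1
    seed: int = 0
    normalize_columns: bool = True

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("k must be a positive integer")
        if self.sparsity < 0:
            raise ValueError("sparsity must be nonnegative")
        if self.max_iter < 1 or self.tol_window < 1:
            raise ValueError("iteration budget must be positive")

    def replace(self, **kw) -> "FitConfig":
        return dataclasses.replace(self, **kw)


@dataclass(frozen=True)
class ObjectiveBreakdown:
    """The three addends of the embedding objective at a given transform."""

    distance_term: float
    covariance_term: float
    l1_term: float
    sparsity: float

    @property
    def total(self) -> float:
        return self.distance_term - self.covariance_term - self.sparsity * self.l1_term


@dataclass(frozen=True)
class EmbeddingTransform:
    """An m x k component matrix mapping condition space into the embedding."""

    components: np.ndarray
    condition_names: tuple[str, ...]
    fit_config: FitConfig | None = None
    converged: bool = True
    n_iter: int = 0
    breakdown: ObjectiveBreakdown | None = None

    def __post_init__(self):
        comps = np.asarray(self.components, dtype=float)
        object.__setattr__(self, "components", comps)
        object.__setattr__(self, "condition_names", tuple(self.condition_names))
        if comps.ndim != 2:
            raise ValueError("components must be an m x k matrix")
        m, k = comps.shape
        if len(self.condition_names) != m:
            raise ValueError("condition names must match component rows")
        if k < 1 or k > m:
            raise ValueError("need 1 <= k <= m components")
        if not np.all(np.isfinite(comps)):
            raise ValueError("components contain non-finite values")
        if self.fit_config is not None and self.fit_config.normalize_columns:
            norms = np.linalg.norm(comps, axis=0)
            if np.any(np.abs(norms - 1.0) > 1e-6):
                raise ValueError("column normalization flagged but columns are not unit norm")

    @property
    def m(self) -> int:
        return self.components.shape[0]

    @property
    def k(self) -> int:
        return self.components.shape[1]

    def to_frame(self) -> pd.DataFrame:
        cols = [f"component_{i + 1}" for i in range(self.k)]
        return pd.DataFrame(self.components, index=list(self.condition_names), columns=cols)


@dataclass(frozen=True)
class BootstrapResult:
    """Aligned bootstrap fits and their normal-approximation summaries."""

    aligned_transforms: tuple[np.ndarray, ...]
    consensus: np.ndarray
    weight_means: np.ndarray
    weight_sds: np.ndarray
    projection_means: np.ndarray
    projection_sds: np.ndarray
    condition_names: tuple[str, ...]
    class_labels: tuple[str, ...]
    n_boot: int
    n_excluded: int = 0
    seed: int | None = None

    def __post_init__(self):
        shapes = {t.shape for t in self.aligned_transforms}
        if len(shapes) > 1:
            raise ValueError("aligned transforms must share one shape")
        if np.any(self.weight_sds < 0) or np.any(self.projection_sds < 0):
            raise ValueError("standard deviations must be nonnegative")

    @property
    def k(self) -> int:
        return self.consensus.shape[1]

    def weights_frame(self) -> pd.DataFrame:
        rows = []
        for j in range(self.k):
            for i, name in enumerate(self.condition_names):
                rows.append(
                    {
                        "component": j + 1,
                        "condition": name,
                        "mean": self.weight_means[i, j],
                        "sd": self.weight_sds[i, j],
                    }
                )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# condition catalog (stimulus metadata)

@dataclass(frozen=True)
class Condition:
    """One averaged stimulus feature and its two pole gratings.

    ``pole_a``/``pole_b`` are the (%L, %M, %S) Michelson cone contrasts of
    the two monochromatic gratings averaged into the feature; single-grating
    features store identical a/b entries.
    """

    name: str
    axis: str
    level: float
    pole_a_name: str
    pole_a: tuple[float, float, float]
    pole_b_name: str
    pole_b: tuple[float, float, float]

    def __post_init__(self):
        if self.axis not in ("LM", "S", "LMS", "daylight", "antidaylight"):
            raise ValueError(f"unknown color axis {self.axis!r}")
        vals = np.array(self.pole_a + self.pole_b, dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValueError(f"non-finite cone contrast for {self.name}")

    @property
    def is_single_pole(self) -> bool:
        return self.pole_a_name == self.pole_b_name


@dataclass(frozen=True)
class ConditionCatalog:
    """The set of stimulus features used to label beta-matrix columns."""

    conditions: tuple[Condition, ...]

    def __post_init__(self):
        object.__setattr__(self, "conditions", tuple(self.conditions))
        names = [c.name for c in self.conditions]
        if len(set(names)) != len(names):
            raise ValueError("duplicate feature names in catalog")

    def __len__(self) -> int:
        return len(self.conditions)

    def __iter__(self):
        return iter(self.conditions)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.conditions)

    def get(self, name: str) -> Condition:
        for c in self.conditions:
            if c.name == name:
                return c
        raise KeyError(name)


def load_condition_catalog(path: str | Path | None = None) -> ConditionCatalog:
    """Load a condition catalog from a TSV; defaults to the packaged one.

    The packaged table lists the 29 grating features (20 saturation-series
    and 9 spatial-frequency-series) with the published per-pole L/M/S
    Michelson cone contrasts.
    """
    if path is None:
        ref = importlib.resources.files("sparseembed").joinpath("data/conditions.tsv")
        with importlib.resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    required = {"feature", "axis", "level", "pole_a", "La", "Ma", "Sa", "pole_b", "Lb", "Mb", "Sb"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"catalog is missing column(s): {sorted(missing)}")
    conds = [
        Condition(
            name=row.feature,
            axis=row.axis,
            level=float(row.level),
            pole_a_name=row.pole_a,
            pole_a=(float(row.La), float(row.Ma), float(row.Sa)),
            pole_b_name=row.pole_b,
            pole_b=(float(row.Lb), float(row.Mb), float(row.Sb)),
        )
        for row in df.itertuples(index=False)
    ]
    return ConditionCatalog(tuple(conds))


# ---------------------------------------------------------------------------
# per-run stacks and table I/O

@dataclass(frozen=True)
class RunBetaStack:
    """Raw (unstandardized) per-run beta matrices over a fixed voxel panel.

    ``values`` has shape (runs, voxels, conditions).  The run is the
    exchangeable unit for bootstrap resampling and cross-validation splits.
    """

    values: np.ndarray
    condition_names: tuple[str, ...]
    voxel_ids: tuple[str, ...]
    run_ids: tuple[int, ...]

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "condition_names", tuple(self.condition_names))
        object.__setattr__(self, "voxel_ids", tuple(str(v) for v in self.voxel_ids))
        object.__setattr__(self, "run_ids", tuple(int(r) for r in self.run_ids))
        if vals.ndim != 3:
            raise ValueError("run stack must be 3-D (runs x voxels x conditions)")
        r, v, m = vals.shape
        if r != len(self.run_ids):
            raise ValueError("run_ids must match the first axis")
        if v != len(self.voxel_ids):
            raise ValueError("voxel_ids must match the second axis")
        if m != len(self.condition_names):
            raise ValueError("condition names must match the third axis")
        if len(set(self.run_ids)) != r:
            raise ValueError("run ids must be unique")
        if not np.all(np.isfinite(vals)):
            raise ValueError("run stack contains non-finite values")

    @property
    def n_runs(self) -> int:
        return self.values.shape[0]

    def average(self, run_indices: Sequence[int] | None = None) -> np.ndarray:
        """Average raw betas over the given run positions (with repeats)."""
        if run_indices is None:
            return self.values.mean(axis=0)
        idx = np.asarray(run_indices, dtype=int)
        if idx.size == 0:
            raise ValueError("cannot average over an empty run selection")
        return self.values[idx].mean(axis=0)

    def standardized_average(self, run_indices: Sequence[int] | None = None) -> StandardizedBetaMatrix:
        return standardize(self.average(run_indices), self.condition_names)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for ri, run in enumerate(self.run_ids):
            df = pd.DataFrame(self.values[ri], columns=list(self.condition_names))
            df.insert(0, "run_id", run)
            df.insert(0, "voxel_id", list(self.voxel_ids))
            rows.append(df)
        return pd.concat(rows, ignore_index=True)


def load_betas_table(path: str | Path) -> RunBetaStack:
    """Read a delimited betas table into a per-run stack.

    Expected columns: ``voxel_id``, ``run_id``, then one column per
    condition.  Every run must cover the identical voxel panel.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t" if path.suffix.lower() in (".tsv", ".txt") else ",")
    for col in ("voxel_id", "run_id"):
        if col not in df.columns:
            raise ValueError(f"betas table {path} is missing required column '{col}'")
    cond_names = [c for c in df.columns if c not in ("voxel_id", "run_id")]
    if not cond_names:
        raise ValueError(f"betas table {path} has no condition columns")
    run_ids = sorted(df["run_id"].unique().tolist())
    panels = []
    mats = []
    for run in run_ids:
        sub = df[df["run_id"] == run]
        panels.append(tuple(sub["voxel_id"].astype(str).tolist()))
        mats.append(sub[cond_names].to_numpy(dtype=float))
    if len(set(panels)) != 1:
        raise ValueError("voxel panel must match across runs (found differing voxel sets)")
    return RunBetaStack(
        np.stack(mats), tuple(cond_names), panels[0], tuple(int(r) for r in run_ids)
    )


def load_voxel_metadata(path: str | Path, voxel_ids: Sequence[str]) -> ParcelLabeling:
    """Read voxel metadata (voxel_id, area, division, ecc_level) into labels.

    Rows are matched to ``voxel_ids`` (the beta-matrix row order).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t" if path.suffix.lower() in (".tsv", ".txt") else ",")
    for col in ("voxel_id", "area", "division", "ecc_level"):
        if col not in df.columns:
            raise ValueError(f"voxel metadata {path} is missing required column '{col}'")
    df = df.drop_duplicates(subset="voxel_id").set_index(df["voxel_id"].astype(str))
    missing = [v for v in voxel_ids if v not in df.index]
    if missing:
        raise ValueError(f"metadata missing voxel id(s): {missing[:5]}")
    sub = df.loc[list(voxel_ids)]
    triples = list(
        zip(sub["area"].astype(str), sub["division"].astype(str), sub["ecc_level"].astype(int))
    )
    # area order follows first appearance in the table: the file's area
    # ordering is taken as the hierarchy ranking used downstream
    area_rank: dict[str, int] = {}
    for a, _, _ in triples:
        area_rank.setdefault(a, len(area_rank))
    div_rank = {"dorsal": 0, "ventral": 1, UNDIVIDED: 2}
    catalog = sorted(
        set(ParcelClass(a, d, int(e)) for a, d, e in triples),
        key=lambda c: (area_rank[c.area], div_rank[c.division], c.ecc_level),
    )
    index = {c: i for i, c in enumerate(catalog)}
    vox = np.array([index[ParcelClass(a, d, int(e))] for a, d, e in triples], dtype=int)
    return ParcelLabeling(vox, tuple(catalog))
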