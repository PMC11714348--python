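"""Synthetic voxel-response generator with planted parcel signatures.

Emulates the structure of a retinotopic-cortex grating experiment: voxels
grouped into parcels (area x dorsal/ventral division x eccentricity level)
respond to the 29 grating features with class-mean profiles that carry two
planted effects —

* an eccentricity gradient: responses to high-spatial-frequency gratings
  fall, and to low-spatial-frequency gratings rise, with eccentricity
  level;
* a dorsal/ventral offset: dorsal parcels favour luminance gratings and
  ventral parcels favour daylight-axis chromatic gratings, with a magnitude
  that grows linearly along the area hierarchy.

Per-run betas add a fixed per-voxel effect and an independent per-run
effect, both Gaussian, so the run is a meaningful resampling unit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (
    UNDIVIDED,
    ConditionCatalog,
    ParcelClass,
    ParcelLabeling,
    RunBetaStack,
    load_condition_catalog,
)

__all__ = ["GeneratorConfig", "generate", "HIGH_FREQ_FEATURES", "LOW_FREQ_FEATURES"]

# 4 and 8 CpD gratings: responses decrease with eccentricity
HIGH_FREQ_FEATURES = (
    "LM_high_freq",
    "LM_med_freq",
    "S_high_freq",
    "S_med_freq",
    "LMS_high_freq",
    "LMS_med_freq",
)
# 0.2 CpD gratings: responses increase with eccentricity
LOW_FREQ_FEATURES = ("LM_low_freq", "S_low_freq", "LMS_low_freq")

# dorsal parcels favour luminance, ventral parcels favour daylight chroma
_LUMINANCE_FEATURES = ("LMS_high_sat", "LMS_med_sat", "LMS_low_sat", "LMS_xlow_sat")
_DAYLIGHT_FEATURES = (
    "Daylight_high_sat",
    "Daylight_med_sat",
    "Daylight_low_sat",
    "Daylight_xlow_sat",
)


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic dataset.

    ``dv_offset_slope`` defaults to 0.09 per area step, the size of the
    dorsal/ventral separation growth along the visual hierarchy the
    embedding is meant to recover; areas are ranked by their position in
    ``areas``.  Noise sds are on the (standardized-beta) response scale.
    """

    areas: tuple[str, ...] = ("V1", "V2", "V3", "V4", "V3a", "MT")
    undivided_areas: tuple[str, ...] = ("V3a", "MT")
    ecc_levels: int = 4
    voxels_per_class: int = 20
    runs: int = 20
    seed: int = 0
    eccentricity_gradient: float = 0.5
    dv_offset_base: float = 0.1
    dv_offset_slope: float = 0.09
    voxel_noise_sd: float = 0.3
    run_noise_sd: float = 0.3

    def __post_init__(self):
        if self.ecc_levels < 1:
            raise ValueError("need at least one eccentricity level")
        if self.voxels_per_class < 2:
            raise ValueError("need at least 2 voxels per class")
        if self.runs < 2:
            raise ValueError("need at least 2 runs")
        if min(self.voxel_noise_sd, self.run_noise_sd) < 0:
            raise ValueError("noise sds must be nonnegative")
        if not self.areas:
            raise ValueError("need at least one area")
        unknown = set(self.undivided_areas) - set(self.areas)
        if unknown:
            raise ValueError(f"undivided areas not in area list: {sorted(unknown)}")
        n_div = sum(1 if a in self.undivided_areas else 2 for a in self.areas)
        if n_div * self.ecc_levels < 2:
            raise ValueError("configuration yields fewer than 2 classes")

    def parcel_classes(self) -> tuple[ParcelClass, ...]:
        classes = []
        for area in self.areas:
            divisions = (
                (UNDIVIDED,) if area in self.undivided_areas else ("dorsal", "ventral")
            )
            for div in divisions:
                for lev in range(1, self.ecc_levels + 1):
                    classes.append(ParcelClass(area, div, lev))
        return tuple(classes)


def _class_profile(
    cls: ParcelClass, cfg: GeneratorConfig, feature_names: tuple[str, ...]
) -> np.ndarray:
    area_rank = cfg.areas.index(cls.area)
    profile = np.zeros(len(feature_names))
    grad = cfg.eccentricity_gradient * (cls.ecc_level - 1)
    # undivided areas sit on the dorsal surface and group with dorsal parcels
    dv_sign = -1.0 if cls.division == "ventral" else 1.0
    offset = dv_sign * (cfg.dv_offset_base + cfg.dv_offset_slope * area_rank)
    for i, name in enumerate(feature_names):
        if name in HIGH_FREQ_FEATURES:
            profile[i] -= grad
        elif name in LOW_FREQ_FEATURES:
            profile[i] += grad
        if name in _LUMINANCE_FEATURES:
            profile[i] += offset
        elif name in _DAYLIGHT_FEATURES:
            profile[i] -= offset
    return profile


def generate(
    config: GeneratorConfig | None = None,
    catalog: ConditionCatalog | None = None,
) -> tuple[RunBetaStack, ParcelLabeling, ConditionCatalog]:
    """Generate per-run beta matrices with planted parcel structure.

    Reproducible under ``config.seed``.  Returns the raw per-run stack, the
    voxel labeling, and the condition catalog describing the columns.
    """
    cfg = config if config is not None else GeneratorConfig()
    cat = catalog if catalog is not None else load_condition_catalog()
    names = cat.names
    m = len(names)
    classes = cfg.parcel_classes()
    n_classes = len(classes)
    v = n_classes * cfg.voxels_per_class

    rng = np.random.default_rng(cfg.seed)
    profiles = np.stack([_class_profile(c, cfg, names) for c in classes])

    voxel_class = np.repeat(np.arange(n_classes), cfg.voxels_per_class)
    class_means = profiles[voxel_class]                      # (v, m)
    voxel_effect = rng.normal(0.0, cfg.voxel_noise_sd, size=(v, m))
    run_effect = rng.normal(0.0, cfg.run_noise_sd, size=(cfg.runs, v, m))
    values = class_means[None, :, :] + voxel_effect[None, :, :] + run_effect

    voxel_ids = tuple(f"vox{i:05d}" for i in range(v))
    stack = RunBetaStack(values, names, voxel_ids, tuple(range(1, cfg.runs + 1)))
    labels = ParcelLabeling(voxel_class, classes)
    return stack, labels, cat
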