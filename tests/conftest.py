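"""Shared fixtures: small synthetic datasets with known causal truth."""

import numpy as np
import pytest

from voxelsem import ModelKind
from voxelsem import synthetic_data as sd
from voxelsem import voxel_pipeline as vp

OBSERVED_2IND = ["age", "rt_verbal", "rt_visuospatial", "neg_fa", "md"]


@pytest.fixture(scope="session")
def cohort88():
    """Default 88-subject cohort with behavioral indicators attached."""
    cohort = sd.generate_cohort(seed=101)
    behavior = sd.generate_behavior(cohort, seed=102)
    return sd.attach_indicators(cohort, behavior.trials), behavior


def scaled_strata(mult: int):
    """The default age strata with every count multiplied by ``mult``."""
    return tuple(
        sd.AgeStratum(s.age_min, s.age_max, s.n * mult, s.n_male * mult,
                      s.n_female * mult, s.mean_age, s.sd_age)
        for s in sd.COHORT_STRATA
    )


def make_region_dataset(kind, shape=(4, 4, 1), seed=0, n_mult=1,
                        params=None, tasks=("verbal", "spatial")):
    """One-region synthetic dataset under a single causal diagram.

    Returns (cohort_with_indicators, behavior, ground_truth, volumes).
    ``kind`` may be a ModelKind or None for a NULL region.
    """
    params = params or sd.RegionParams()
    if n_mult == 1:
        cohort = sd.generate_cohort(seed=seed)
    else:
        strata = scaled_strata(n_mult)
        cohort = sd.generate_cohort(n=88 * n_mult, strata=strata, seed=seed)
    behavior = sd.generate_behavior(cohort, seed=seed + 1, tasks=tasks)
    cohort = sd.attach_indicators(cohort, behavior.trials)
    truth = sd.GroundTruthSpec(
        region_labels=np.ones(shape, dtype=np.int32),
        region_model={1: kind},
        region_params={1: params},
    )
    volumes = sd.generate_volumes(cohort, behavior, truth, seed=seed + 2)
    return cohort, behavior, truth, volumes


def voxel_data(kind, seed=0, n_mult=1):
    """A single prepared (0-10 scaled) voxel data matrix under ``kind``."""
    cohort, _, _, volumes = make_region_dataset(kind, shape=(1, 1, 1),
                                                seed=seed, n_mult=n_mult)
    return vp.prepare_voxel(volumes.fa[0, 0, 0], volumes.md[0, 0, 0], cohort)


@pytest.fixture(scope="session")
def cogmed_voxels():
    """A small block of cognitive-mediation voxels plus their cohort."""
    cohort, behavior, truth, volumes = make_region_dataset(
        ModelKind.COGNITIVE_MEDIATION, shape=(3, 3, 1), seed=7)
    return cohort, behavior, truth, volumes
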