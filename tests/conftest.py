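import warnings

import pytest

import cadmb
from cadmb.simulate import CohortConfig, generate_cohort

warnings.filterwarnings(
    "ignore", message="rarefy: dropping", category=UserWarning)


@pytest.fixture(scope="session")
def default_cohort():
    """One default-configuration cohort, shared read-only across tests."""
    return generate_cohort(CohortConfig(seed=11))


@pytest.fixture(scope="session")
def rarefied_cohort(default_cohort):
    """(rarefied counts, genus relative abundances, aligned metadata)."""
    rare = cadmb.rarefy(default_cohort.counts, 6247, seed=12)
    genus = cadmb.aggregate_to_genus(rare, default_cohort.taxonomy)
    meta = default_cohort.metadata.loc[rare.index]
    return rare, genus, meta


def small_null_config(seed: int) -> CohortConfig:
    """Reduced-size all-null cohort used for calibration batteries."""
    return CohortConfig(
        seed=seed, n_asvs=60, n_genera=15, depth_mean=8000,
        effect_up=1.0, effect_down=1.0, imp_coupling=0.0,
        confounding_shift=0.0)


@pytest.fixture(scope="session")
def null_battery():
    """120 small all-null cohorts: (genus table, metadata) pairs.

    Under this configuration the three CAD groups are exchangeable, so
    every downstream test statistic should be at its null calibration.
    """
    out = []
    for seed in range(120):
        cohort = generate_cohort(small_null_config(seed))
        rare = cadmb.rarefy(cohort.counts, 6247, seed=seed)
        genus = cadmb.aggregate_to_genus(rare, cohort.taxonomy)
        out.append((genus, cohort.metadata.loc[rare.index]))
    return out
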