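"""Shared fixtures: small simulated cohorts reused across test modules."""

import numpy as np
import pytest

from oakpop.simulate import (
    ContaminationSpec,
    HetSpec,
    SimulationConfig,
    simulate_cohort,
    paperlike_config,
)
from oakpop import paint


@pytest.fixture(scope="session")
def two_clade_cohort():
    """Two clades split 10 kya, three strains each, 500 kb; no profiles."""
    cfg = SimulationConfig(
        seed=1,
        clades=["A", "B"],
        strains_per_clade=3,
        chromosome_lengths=[500_000],
        split_times_years={"A|B": 10_000.0},
        make_profiles=False,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def paperlike_cohort():
    return simulate_cohort(paperlike_config(seed=3))


@pytest.fixture(scope="session")
def paperlike_panel(paperlike_cohort):
    return paint.panel_from_cohort(paperlike_cohort)


@pytest.fixture(scope="session")
def qc_cohort():
    """Cohort with one heterozygous, one contaminated, one shallow strain."""
    cfg = SimulationConfig(
        seed=11,
        clades=["A", "B"],
        strains_per_clade=3,
        chromosome_lengths=[1_000_000],
        split_times_years={"A|B": 20_000.0},
        extra_strains=[("hetty", "A"), ("dirty", "A"), ("shallow", "B")],
        het_specs=[HetSpec("hetty", 0.002)],
        contamination_specs=[ContaminationSpec("dirty", "B", 0.10)],
        depth_overrides={"shallow": 20.0},
    )
    return simulate_cohort(cfg)


def random_pair(rng, length=2000, divergence=0.05, ti_frac=0.6):
    """A random sequence and a transition-biased mutated copy, as strings."""
    bases = np.array(list("ACGT"))
    s1 = rng.integers(0, 4, length)
    s2 = s1.copy()
    idx = rng.random(length) < divergence
    u = rng.random(int(idx.sum()))
    b = s2[idx]
    tv = ti_frac + (1 - ti_frac) / 2
    s2[idx] = np.where(u < ti_frac, b ^ 2, np.where(u < tv, b ^ 1, b ^ 3))
    return "".join(bases[s1]), "".join(bases[s2])
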