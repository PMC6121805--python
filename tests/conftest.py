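"""Shared fixtures.

The expensive session fixtures (full-scale simulation, synthetic dataset
with all SNPs fitted) are built lazily, so unit-test-only runs stay fast.
"""

import numpy as np
import pandas as pd
import pytest

from shoreclines.fitting import LikelihoodConfig, fit_many
from shoreclines.pipeline import neutral_null_varex, stage_seed
from shoreclines.simulate import SimulationConfig, run_simulation
from shoreclines.synth import SynthConfig, generate_study_like_dataset


@pytest.fixture(scope="session")
def default_sim():
    """One full study-condition simulation (152 demes, N=100, sigma=1.46,
    s=0.7, 200 selected + 500 neutral loci, 4000 generations)."""
    return run_simulation(SimulationConfig(), seed=stage_seed(101, "simulate"))


@pytest.fixture(scope="session")
def default_null_fits(default_sim):
    """Cline fits for the neutral loci of the default simulation, sampled
    like the study (373 individuals, gaps + density trough)."""
    return neutral_null_varex(default_sim.config, LikelihoodConfig(),
                              seed=101, sim=default_sim)


@pytest.fixture(scope="session")
def synth_dataset():
    return generate_study_like_dataset(SynthConfig(seed=7))


@pytest.fixture(scope="session")
def synth_fits(synth_dataset):
    ds = synth_dataset
    return fit_many(ds.reads.ref, ds.reads.alt, ds.positions,
                    LikelihoodConfig(), seed=11, snp_ids=list(ds.reads.snp_id))
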