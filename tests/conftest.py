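import numpy as np
import pytest
from hypothesis import settings

from sibline import SimParams, SyntheticConfig, run_ensemble
from sibline.synth import ArtifactRates, StrainSpec, generate

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")

# master test seeds, fixed up front
SEED_WF = 20260923
SEED_SIB = 20260924


@pytest.fixture(scope="session")
def paper_ensemble():
    """Reference-configuration ensemble: mu=1e-8 over 2,725,521,370 sites,
    100 generations, 1000 replicates, offspring drawn from the parental
    allele pool (wf_selfing)."""
    return run_ensemble(SimParams(seed=SEED_WF))


@pytest.fixture(scope="session")
def sib_ensemble():
    """Strict sib-mating ensemble at reduced replicate count."""
    return run_ensemble(SimParams(replicates=300, mating="sib_mating", seed=SEED_SIB))


@pytest.fixture(scope="session")
def clean_synth_dataset(tmp_path_factory):
    """Artifact-free synthetic cohort (defaults otherwise)."""
    cfg = SyntheticConfig(artifacts=ArtifactRates.none(), seed=101)
    return generate(cfg, tmp_path_factory.mktemp("synth_clean"))


@pytest.fixture(scope="session")
def dirty_synth_dataset(tmp_path_factory):
    """Cohort with every artifact class injected at elevated rates."""
    cfg = SyntheticConfig(
        artifacts=ArtifactRates(
            paralog_cluster=1e-5,
            bait_impurity=2e-5,
            low_qual=2e-5,
            low_depth=2e-5,
            multiallelic=1e-5,
            indel=1e-5,
        ),
        seed=202,
    )
    return generate(cfg, tmp_path_factory.mktemp("synth_dirty"))
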