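import numpy as np
import pytest

from erclients import TruthConfig, generate_cohort
from erclients.proteome_io import LfqCohort, SampleDesign


def make_design(n_replicates=3, n_experiments=1, groups=("control", "sirna1", "sirna2")):
    return [
        SampleDesign(name=f"{g}_e{e}_r{r}", group=g, replicate=r, experiment=e)
        for e in range(1, n_experiments + 1)
        for g in groups
        for r in range(1, n_replicates + 1)
    ]


def make_cohort(intensity, n_replicates=3, n_experiments=1, proteins=None):
    intensity = np.asarray(intensity, dtype=float)
    samples = make_design(n_replicates, n_experiments)
    proteins = proteins or [f"P{i + 1}" for i in range(intensity.shape[0])]
    return LfqCohort(proteins=proteins, samples=samples, intensity=intensity)


@pytest.fixture(scope="session")
def default_cohort():
    """Study-condition synthetic cohort with conflict decoys enabled."""
    config = TruthConfig(conflict_fraction=0.01)
    return generate_cohort(2000, config=config, seed=7)


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(200, seed=11)
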