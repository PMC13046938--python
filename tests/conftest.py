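import numpy as np
import pytest

from deltabind.motif_engine import build_pwm, score_pvalue_table
from deltabind.synthetic_data import SimulationConfig, packaged_toy_motifs, simulate


@pytest.fixture(scope="session")
def toy_motifs():
    return packaged_toy_motifs()


@pytest.fixture(scope="session")
def toy_models(toy_motifs):
    models = []
    for rm in toy_motifs:
        m = build_pwm(rm.counts, motif_id=rm.motif_id, tf_name=rm.tf_name)
        score_pvalue_table(m, granularity=1000)
        models.append(m)
    return models


@pytest.fixture(scope="session")
def default_bundle():
    """Default synthetic study (3 cell types, 30 donors, 500 peaks), seed 0."""
    return simulate(SimulationConfig(seed=0))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))
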