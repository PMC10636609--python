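import numpy as np
import pytest

from tlkinetics import PoissonMixtureKinetics, SimConfig, simulate_experiment


@pytest.fixture(scope="session")
def small_experiment():
    """Modest two-condition experiment with realistic gene-level spread."""
    kd = np.tile(np.array([[0.35, 0.7]]), (30, 1))
    cfg = SimConfig(n_genes=30, reads_per_gene=200,
                    replicates_per_condition=2, kdeg_truth=kd, seed=42)
    return simulate_experiment(cfg)


@pytest.fixture(scope="session")
def fitted_small(small_experiment):
    model = PoissonMixtureKinetics(small_experiment.reads)
    return model.fit(chains=2, warmup=400, draws=400, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
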