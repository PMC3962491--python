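import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_data(rng):
    """Small dense problem (N > m) with a real signal."""
    N, m = 60, 8
    Z = rng.integers(0, 3, size=(N, m)).astype(float)
    u = np.zeros(m)
    u[0], u[3] = 1.2, -0.7
    y = 5.0 + Z @ u + rng.normal(0, 1.0, N)
    return y, Z


@pytest.fixture
def dh_dataset(rng):
    """Simulated doubled-haploid data set with genotype/phenotype containers."""
    import gwpredict as gw

    cfg = gw.SimConfig(
        n_chr=2, marker_dist_cM=5.0, ngen=2, n_intermate=150, n_dh=120, h2=0.8, seed=11
    )
    pop = gw.simulate_population(cfg, np.random.default_rng(11))
    g = gw.genotypic_values(pop, cfg)
    pheno, _ = gw.calibrate_phenotypes(g, cfg.h2, np.random.default_rng(12), pop.individual_ids())
    return pop.to_genotype_matrix(), pheno, cfg
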