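import logging

import numpy as np
import pytest

import selstack as ss

# library warnings are exercised explicitly where relevant; keep logs quiet
logging.getLogger("selstack").setLevel(logging.ERROR)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def sim_small():
    """Small simulated dataset shared across read-only tests."""
    cfg = ss.SimConfig(n_markers=120, n_qtl=40, n_chromosomes=4,
                       variance_shares=(0.7, 0.0, 0.3), target_h2=0.4, seed=321)
    g, records, true, effects = ss.simulate_dataset(cfg)
    return {"cfg": cfg, "g": g, "records": records, "true": true,
            "effects": effects}


@pytest.fixture(scope="session")
def sim_small_adjusted(sim_small):
    fit = ss.fit_vc_reml(sim_small["records"])
    return fit.adjust_phenotypes()


@pytest.fixture()
def toy_genotype():
    return ss.GenotypeMatrix(
        samples=["a", "b", "c"],
        markers=["m1", "m2"],
        dosage=np.array([[0.0, 2.0], [1.0, 1.0], [2.0, 0.0]]),
    )
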