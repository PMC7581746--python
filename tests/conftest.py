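import numpy as np
import pandas as pd
import pytest

import tracheidgwas as tg


@pytest.fixture(scope="session")
def small_cfg():
    """Desk-scale config: enough structure for every stage, fast to simulate."""
    return tg.SimulationConfig(
        n_families=40,
        trees_per_family=4,
        n_sites=2,
        n_blocks_per_site=2,
        n_markers=100,
        n_qtl=3,
        qtl_a=0.4,
        n_rings=12,
        knots=(3, 8),
        missing_rate=0.02,
        seed=1234,
    )


@pytest.fixture(scope="session")
def small_dataset(small_cfg):
    design = tg.simulate_design(small_cfg)
    geno = tg.simulate_genotypes(small_cfg)
    rings, truth = tg.simulate_phenotypes(small_cfg, geno, design)
    return {"cfg": small_cfg, "design": design, "geno": geno, "rings": rings, "truth": truth}


@pytest.fixture()
def balanced_oneway():
    """Balanced single-site, no-block design with known family structure."""
    rng = np.random.default_rng(3)
    n_fam, n_per = 30, 8
    fam = np.repeat(np.arange(n_fam), n_per)
    u = rng.normal(0, np.sqrt(0.5), n_fam)
    y = 10 + u[fam] + rng.normal(0, 1.0, n_fam * n_per)
    design = pd.DataFrame(
        {
            "tree_id": [f"t{i}" for i in range(n_fam * n_per)],
            "site": "S1",
            "block": "S1_B1",
            "family": [f"F{f:03d}" for f in fam],
        }
    )
    return y, design, n_per
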