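"""Shared fixtures: one desk-scale simulated L×T study per session.

The demo study plants an additive fiber-length QTL on marker M001 and a
pure-dominance boll-weight QTL on marker M006, so downstream stages have
known signals to find.
"""

import numpy as np
import pandas as pd
import pytest

import lxthet as lx
from lxthet.simulate import DEFAULT_RESID_SD


@pytest.fixture(scope="session")
def demo():
    a = 0.6 * DEFAULT_RESID_SD["FL"]
    d = 0.6 * DEFAULT_RESID_SD["BW"]
    cfg = lx.demo_config(
        seed=11,
        qtl_spec=[lx.QTL(0, "FL", a, 0.0), lx.QTL(5, "BW", 0.0, d)],
    )
    truth, design, pheno = lx.simulate_dataset(cfg)
    return {"cfg": cfg, "truth": truth, "design": design, "pheno": pheno}


@pytest.fixture(scope="session")
def demo_means(demo):
    return lx.entry_means(demo["pheno"], mode="shrunk")


@pytest.fixture(scope="session")
def demo_ca(demo):
    return {t: lx.combining_ability(demo["pheno"], demo["design"], t)
            for t in lx.TRAITS}


@pytest.fixture(scope="session")
def demo_het(demo):
    return lx.heterosis_table(demo["pheno"], demo["design"])


@pytest.fixture(scope="session")
def demo_ctx(demo, demo_means, demo_ca, demo_het):
    """Full 32-combination association scan of the demo study."""
    truth, design = demo["truth"], demo["design"]
    return lx.run_all(truth.all_bands(), truth.marker_map, design,
                      demo_means, demo_ca, demo_het, lx.AssocConfig())


def random_band_matrix(rng, n=30, n_bands=12, missing=0.1, prefix="B"):
    vals = (rng.random((n, n_bands)) < rng.uniform(0.2, 0.8, size=n_bands)).astype(float)
    if missing:
        vals[rng.random((n, n_bands)) < missing] = np.nan
    return lx.BandMatrix(pd.DataFrame(
        vals, index=[f"I{i:03d}" for i in range(n)],
        columns=[f"{prefix}{j:02d}" for j in range(n_bands)]))
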