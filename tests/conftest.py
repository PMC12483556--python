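import numpy as np
import pandas as pd
import pytest

import gardkit as gk


@pytest.fixture(scope="session")
def gard_fit():
    """Calibrated GARD70 distribution (shared: the fit is deterministic)."""
    return gk.calibrate_rsi_distribution()


@pytest.fixture(scope="session")
def group_models(gard_fit):
    return gk.default_group_models(float(gard_fit.sf(42.0)))


@pytest.fixture(scope="session")
def rsi_source(gard_fit):
    rng = np.random.default_rng(20240901)
    return gard_fit.sample_rsi(191, rng)


@pytest.fixture(scope="session")
def synthetic_cohort_600():
    sc = gk.generate_cohort(gk.CohortSpec(n=600, seed=11))
    return gk.annotate_gard(sc.table)


@pytest.fixture
def toy_expression():
    """4 samples x 12 genes, the 10 signature genes plus 2 extras."""
    rng = np.random.default_rng(7)
    genes = list(gk.RSI_SIGNATURE.gene_symbols) + ["GAPDH", "ACTB"]
    return pd.DataFrame(
        rng.normal(8.0, 2.0, size=(len(genes), 4)),
        index=genes,
        columns=[f"S{i}" for i in range(4)],
    )
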