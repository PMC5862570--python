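import numpy as np
import pytest

import netheat as nh


@pytest.fixture(scope="session")
def default_cohort():
    """One fully simulated study at the default design (34/168, 500 genes)."""
    return nh.simulate_cohort(nh.SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def cohort_assoc(default_cohort):
    """QC'd association scan and gene heat for the default cohort."""
    gm_qc, report = nh.apply_qc(default_cohort.genotypes)
    assoc = nh.run_gwas(gm_qc, default_cohort.snp_map)
    gene_heat = nh.aggregate_min_p(assoc, default_cohort.snp_map)
    return gm_qc, report, assoc, gene_heat


@pytest.fixture()
def rng():
    return np.random.default_rng(20260921)
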