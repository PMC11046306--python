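import pytest
from hypothesis import settings

import feshift as fs

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_screen():
    """Desk-scale simulated screen with aligned expression table."""
    cfg = fs.ScreenSimConfig(n_genes=300, n_ntc=120, seq_depth=500_000, seed=11)
    ds = fs.gen_screen_dataset(cfg)
    expr = fs.expression_for_screen(ds, seed=11)
    return ds, expr


@pytest.fixture(scope="session")
def small_tmt():
    """Stochastic synthetic TMT experiment at reduced protein count."""
    cfg = fs.ProteomicsSimConfig(n_proteins=400, seed=7)
    return fs.gen_proteomics_dataset(cfg)


@pytest.fixture(scope="session")
def noise_free_tmt():
    """Noise-free TMT experiment: no peptide noise, strong channel mixing."""
    cfg = fs.ProteomicsSimConfig(
        n_proteins=400, peptide_noise_cv=0.0, impurity_spillover=0.1,
        background_fc_sigma=1e-15, seed=5)
    return fs.gen_proteomics_dataset(cfg)
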