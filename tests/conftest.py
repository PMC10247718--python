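import pytest

import cnp


@pytest.fixture(scope="session")
def uniform_world():
    """Gap-free provincial-uniform world: the exact-recovery regime."""
    cfg = cnp.WorldConfig(n_provinces=2, counties_per_province=(10, 10),
                          grid_rows=40, grid_cols=50, missing_rate=0.0,
                          heterogeneous=False, seed=42)
    return cnp.generate_world(cfg)


@pytest.fixture(scope="session")
def het_world():
    """Heterogeneous world with sporadic missing county-years."""
    cfg = cnp.WorldConfig(n_provinces=3, counties_per_province=(6, 9),
                          grid_rows=40, grid_cols=50, missing_rate=0.05,
                          heterogeneous=True, seed=7)
    return cnp.generate_world(cfg)


@pytest.fixture(scope="session")
def uniform_result(uniform_world):
    w = uniform_world
    return cnp.run_pipeline(w.prov_rates, w.prov_totals, w.county)


@pytest.fixture(scope="session")
def het_result(het_world):
    w = het_world
    return cnp.run_pipeline(w.prov_rates, w.prov_totals, w.county)
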