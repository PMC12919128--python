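import pytest

import c9wta as c


@pytest.fixture(scope="session")
def default_params():
    return c.default_params(seed=11)


@pytest.fixture(scope="session")
def small_cohort(default_params):
    """120 cases + 120 controls with elevated HRE prevalence so subgroup
    statistics have enough carriers."""
    params = c.GeneratorParams(seed=11, hre_prevalence=0.3)
    return c.simulate_cohort(params, 120, 120)


@pytest.fixture(scope="session")
def cohort_dir(small_cohort, tmp_path_factory):
    d = tmp_path_factory.mktemp("cohort")
    c.write_cohort(small_cohort, d)
    return d


@pytest.fixture(scope="session")
def cohort_tables(cohort_dir):
    return c.load_cohort_tables(cohort_dir)


def lean_params(seed, **kw):
    """Generator params without cut events or junction noise, for cheap
    expression/survival-only simulations."""
    defaults = dict(seed=seed, peaks=(), n_background_junctions=1)
    defaults.update(kw)
    return c.GeneratorParams(**defaults)
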