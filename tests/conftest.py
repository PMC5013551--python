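import numpy as np
import pytest

import accelwalk as aw
from accelwalk import fitting

#: root seed for every deterministic test in the suite
SUITE_SEED = 20260929


@pytest.fixture
def rng():
    return np.random.default_rng(SUITE_SEED)


@pytest.fixture(scope="session")
def ref_params():
    return aw.REFERENCE_PARAMS


@pytest.fixture(scope="session")
def big_population():
    """One million reduced-sampler trips at the reference parameters —
    the simulate-and-refit material shared by the recovery tests."""
    rng = np.random.default_rng(SUITE_SEED)
    return aw.simulate_population(1_000_000, aw.REFERENCE_PARAMS, rng,
                                  mode="eq_speed")


@pytest.fixture(scope="session")
def smooth_population():
    """One million trips whose speeds are drawn from the continuous
    conditional speed law — the Monte-Carlo counterpart of the analytic
    displacement mixture."""
    rng = np.random.default_rng(SUITE_SEED + 1)
    return aw.simulate_population(1_000_000, aw.REFERENCE_PARAMS, rng,
                                  mode="smooth")


@pytest.fixture(scope="session")
def recovery_fit(big_population):
    """Full pipeline run on the big population: linear speed fit, surface,
    lattice kick fit."""
    lin = fitting.fit_v0_accel(big_population)
    surface = fitting.bin_speed_surface(big_population, v0=lin.v0)
    kick = fitting.fit_kick_params(surface, v0=lin.v0, model_eval="lattice")
    return lin, surface, kick


def decile_masses(sample, pdf_grid, pdf_vals):
    """Observed sample mass (0.1 each) vs model mass per sample decile,
    with the model mass integrated from a densely tabulated pdf."""
    edges = np.quantile(sample, np.linspace(0.0, 1.0, 11))
    cdf = np.concatenate(
        ([0.0], np.cumsum(np.diff(pdf_grid)
                          * 0.5 * (pdf_vals[1:] + pdf_vals[:-1]))))
    cdf_at = np.interp(edges, pdf_grid, cdf)
    model_mass = np.diff(cdf_at)
    return model_mass


def assert_decile_match(sample, pdf_grid, pdf_vals, n_se=3.0):
    """Every decile of the sample carries model mass within n_se binomial
    standard errors of the observed 0.1."""
    model_mass = decile_masses(sample, pdf_grid, pdf_vals)
    se = np.sqrt(0.1 * 0.9 / len(sample))
    err = np.abs(model_mass - 0.1)
    assert np.all(err < n_se * se), (
        f"decile mismatch: worst {err.max():.2e} vs {n_se * se:.2e}; "
        f"model masses {np.round(model_mass, 4)}")
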