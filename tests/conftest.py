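"""Shared fixtures: small simulated datasets and session-scoped fits.

Fit fixtures are session-scoped because FOCE-I fits are the expensive
part of the suite; every test reads, never mutates, them.
"""

import numpy as np
import pytest

import ruvdiag as rd


@pytest.fixture(scope="session")
def additive_ds():
    """Small additive-error dataset under the study conditions."""
    return rd.simulate_dataset(rd.default_protocol("additive", n_subjects=40,
                                                   seed=123))


@pytest.fixture(scope="session")
def proportional_ds():
    return rd.simulate_dataset(rd.default_protocol("proportional",
                                                   n_subjects=40, seed=124))


@pytest.fixture(scope="session")
def combined_ds():
    return rd.simulate_dataset(rd.default_protocol("combined", n_subjects=50,
                                                   seed=125))


@pytest.fixture(scope="session")
def additive_fits(additive_ds):
    """ADD.1/ADD.2/ADD.3 fitted to the same additive dataset."""
    return {cid: rd.fit(additive_ds, cid) for cid in ("ADD.1", "ADD.2", "ADD.3")}


@pytest.fixture(scope="session")
def proportional_fits(proportional_ds):
    return {cid: rd.fit(proportional_ds, cid)
            for cid in ("PROP.1", "PROP.2", "PROP.3")}


@pytest.fixture(scope="session")
def combined_fits(combined_ds):
    return {cid: rd.fit(combined_ds, cid)
            for cid in ("COMB_VAR1", "COMB_VAR3", "COMB_SD")}


@pytest.fixture(scope="session")
def additive_tables(additive_ds, additive_fits):
    return {cid: rd.diagnostics_table(additive_fits[cid], additive_ds, cid)
            for cid in additive_fits}


@pytest.fixture(scope="session")
def proportional_tables(proportional_ds, proportional_fits):
    return {cid: rd.diagnostics_table(proportional_fits[cid],
                                      proportional_ds, cid)
            for cid in proportional_fits}


@pytest.fixture(scope="session")
def combined_tables(combined_ds, combined_fits):
    return {cid: rd.diagnostics_table(combined_fits[cid], combined_ds, cid)
            for cid in combined_fits}


@pytest.fixture(scope="session")
def true_pop_additive():
    """Population parameters at the additive study truths."""
    proto = rd.default_protocol("additive")
    return rd.PopulationParams(
        structural=proto.structural,
        omega2_cl=proto.omega2_cl, omega2_v=proto.omega2_v,
        error_params=rd.ErrorParams(sigma1=proto.sigma_add ** 2),
    )


def column_with_sd(sd: float, n: int = 1000, seed: int = 0) -> np.ndarray:
    """A zero-mean column whose sample SD (ddof=1) is exactly ``sd``."""
    rng = np.random.default_rng(seed)
    z = rng.normal(size=n)
    z = z - z.mean()
    return z * (sd / np.std(z, ddof=1))
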