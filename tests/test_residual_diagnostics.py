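"""IWRES/WRES/CWRESI computation and the epsilon-shrinkage statistic."""

import numpy as np
import pytest

import ruvdiag as rd
from ruvdiag.error_coding import ErrorParams, get_coding
from ruvdiag.foce_engine import FitResult, PopulationParams, design_arrays
from ruvdiag.pk_model import StructuralParams
from ruvdiag.residual_diagnostics import (FIT_COLUMNS, conditional_residuals,
                                          diagnostics_table,
                                          epsilon_shrinkage,
                                          individual_residuals,
                                          population_residuals,
                                          read_diagnostics, write_diagnostics)
from conftest import column_with_sd


def fit_at(pop, dataset, coding_id):
    """A FitResult frozen at a chosen parameter point (no optimization)."""
    coding = get_coding(coding_id)
    etas = rd.estimate_etas(dataset, pop, coding)
    return FitResult(params=pop, ofv=np.nan, etas=etas, coding_id=coding_id,
                     converged=True, n_iter=0, n_ofv_evals=0, grad_norm=0.0)


@pytest.fixture(scope="module")
def pop_additive():
    return PopulationParams(
        structural=StructuralParams(tvcl=5.0, tvv=50.0, ka=1.0),
        omega2_cl=0.09, omega2_v=0.09,
        error_params=ErrorParams(sigma1=0.25),
    )


class TestIndividualResiduals:
    def test_unit_w_makes_iwres_equal_ires(self, pop_additive, additive_ds):
        fr = fit_at(pop_additive, additive_ds, "ADD.2")
        table = individual_residuals(fr, additive_ds, "ADD.2")
        np.testing.assert_array_equal(table["IWRES"], table["IRES"])

    def test_iwres_ratio_is_sqrt_sigma_at_matched_parameters(
            self, pop_additive, additive_ds):
        # same parameter point, only W differs: per-observation ratio of
        # the non-normalized to the normalized IWRES is exactly sqrt(sigma1)
        fr = fit_at(pop_additive, additive_ds, "ADD.1")
        t1 = individual_residuals(fr, additive_ds, "ADD.1")
        t2 = individual_residuals(fr, additive_ds, "ADD.2")
        ratio = t2["IWRES"] / t1["IWRES"]
        np.testing.assert_allclose(ratio, np.sqrt(0.25), rtol=1e-12)

    def test_proportional_rescaling_is_constant_to_machine_precision(
            self, proportional_ds):
        pop = PopulationParams(
            structural=StructuralParams(tvcl=5.0, tvv=50.0, ka=1.0),
            omega2_cl=0.09, omega2_v=0.09,
            error_params=ErrorParams(sigma1=0.04),
        )
        fr = fit_at(pop, proportional_ds, "PROP.1")
        t1 = individual_residuals(fr, proportional_ds, "PROP.1")
        t2 = individual_residuals(fr, proportional_ds, "PROP.2")
        ratio = (t2["IWRES"] / t1["IWRES"]).to_numpy()
        assert np.std(ratio, ddof=1) < 1e-13
        np.testing.assert_allclose(ratio, 0.2, rtol=1e-12)


class TestPopulationResiduals:
    def test_zero_omega_wres_is_res_over_sigma(self, additive_ds):
        pop = PopulationParams(
            structural=StructuralParams(tvcl=5.0, tvv=50.0, ka=1.0),
            omega2_cl=0.0, omega2_v=0.0,
            error_params=ErrorParams(sigma1=0.25),
        )
        fr = fit_at(pop, additive_ds, "ADD.1")
        table = population_residuals(fr, additive_ds, "ADD.1")
        np.testing.assert_allclose(table["WRES"], table["RES"] / 0.5,
                                   rtol=1e-12)

    def test_wres_identical_between_codings_sharing_variance(
            self, pop_additive, additive_ds):
        fr = fit_at(pop_additive, additive_ds, "ADD.1")
        t1 = population_residuals(fr, additive_ds, "ADD.1")
        t2 = population_residuals(fr, additive_ds, "ADD.2")
        np.testing.assert_array_equal(t1["WRES"], t2["WRES"])

    def test_whitening_under_the_first_order_model(self):
        # Monte-Carlo oracle: data generated from the linearized marginal
        # model y = f(0) + J(0) eta + eps must whiten to ~identity sample
        # covariance.  (On data from the full nonlinear model the
        # linearization itself biases WRES — that is model behavior, not
        # a defect of the whitening.)
        import pandas as pd
        from ruvdiag.foce_engine import PKEtaModel
        from ruvdiag.synthetic_data import Dataset

        rng = np.random.default_rng(31)
        m = 1500
        proto = rd.default_protocol("additive", n_subjects=m)
        pop = PopulationParams(
            structural=proto.structural,
            omega2_cl=proto.omega2_cl, omega2_v=proto.omega2_v,
            error_params=ErrorParams(sigma1=proto.sigma_add ** 2),
        )
        model = PKEtaModel(proto.dose, proto.sample_times, proto.structural)
        pred, jac0 = model.predict_and_jac(np.zeros((m, 2)))
        etas = rng.normal(size=(m, 2)) * np.sqrt([0.09, 0.09])
        y = pred + np.einsum("mnk,mk->mn", jac0, etas) \
            + proto.sigma_add * rng.normal(size=pred.shape)
        n = len(proto.sample_times)
        ids = np.arange(1, m + 1)
        records = pd.concat([
            pd.DataFrame({"ID": ids, "TIME": 0.0, "AMT": proto.dose,
                          "DV": 0.0, "EVID": 1, "MDV": 1}),
            pd.DataFrame({"ID": np.repeat(ids, n),
                          "TIME": np.tile(proto.sample_times, m),
                          "AMT": 0.0, "DV": y.ravel(), "EVID": 0, "MDV": 0}),
        ], ignore_index=True)
        ds = Dataset(records=records)
        fr = fit_at(pop, ds, "ADD.1")
        table = population_residuals(fr, ds, "ADD.1")
        wres = table["WRES"].to_numpy().reshape(m, -1)
        cov = np.cov(wres, rowvar=False)
        assert np.abs(np.diag(cov) - 1.0).max() < 0.15
        off = cov - np.diag(np.diag(cov))
        assert np.abs(off).max() < 0.15


class TestConditionalResiduals:
    def test_reduces_to_wres_when_etas_vanish(self, additive_ds):
        # with negligible BSV the MAP etas are zero, the linearization
        # point coincides with the population prediction, and CWRESI == WRES
        pop = PopulationParams(
            structural=StructuralParams(tvcl=5.0, tvv=50.0, ka=1.0),
            omega2_cl=1e-13, omega2_v=1e-13,
            error_params=ErrorParams(sigma1=0.25),
        )
        fr = fit_at(pop, additive_ds, "ADD.1")
        cw = conditional_residuals(fr, additive_ds, "ADD.1")["CWRESI"]
        w = population_residuals(fr, additive_ds, "ADD.1")["WRES"]
        np.testing.assert_allclose(cw, w, atol=1e-4)

    def test_unit_spread_for_correctly_specified_fit(self, additive_ds,
                                                     additive_fits,
                                                     additive_tables):
        sd = np.std(additive_tables["ADD.1"]["CWRESI"], ddof=1)
        assert sd == pytest.approx(1.0, abs=0.1)

    def test_cwresi_identical_between_codings_sharing_variance(
            self, pop_additive, additive_ds):
        fr = fit_at(pop_additive, additive_ds, "ADD.1")
        c1 = conditional_residuals(fr, additive_ds, "ADD.1")["CWRESI"]
        c2 = conditional_residuals(fr, additive_ds, "ADD.2")["CWRESI"]
        np.testing.assert_array_equal(c1, c2)

    def test_combined_parameterizations_differ_most_in_the_tails(
            self, combined_tables):
        # the two variance-style parameterizations agree closely; what
        # differences remain are concentrated in a few observations
        delta = np.abs(combined_tables["COMB_VAR1"]["CWRESI"].to_numpy()
                       - combined_tables["COMB_VAR3"]["CWRESI"].to_numpy())
        assert delta.max() > delta.mean()
        # the SD approximation deviates far more than the exact
        # reparameterization does
        delta_sd = np.abs(combined_tables["COMB_VAR1"]["CWRESI"].to_numpy()
                          - combined_tables["COMB_SD"]["CWRESI"].to_numpy())
        assert delta_sd.max() > delta_sd.mean()
        assert delta_sd.max() > delta.max()


class TestDiagnosticsTable:
    def test_column_set_and_order(self, additive_ds, additive_fits):
        table = diagnostics_table(additive_fits["ADD.1"], additive_ds, "ADD.1")
        assert list(table.columns)[:9] == FIT_COLUMNS
        assert len(table) == additive_ds.n_observations
        np.testing.assert_allclose(table["IWRES"] * np.sqrt(
            additive_fits["ADD.1"].params.error_params.sigma1),
            table["IRES"], rtol=1e-12)

    def test_round_trip(self, tmp_path, additive_ds, additive_fits):
        table = diagnostics_table(additive_fits["ADD.1"], additive_ds, "ADD.1")
        path = tmp_path / "table.csv"
        write_diagnostics(table, path)
        back = read_diagnostics(path)
        assert list(back.columns) == FIT_COLUMNS
        np.testing.assert_allclose(back["CWRESI"], table["CWRESI"],
                                   rtol=1e-9)


class TestEpsilonShrinkage:
    @pytest.mark.parametrize("sd,expected", [(0.947, 0.053), (0.933, 0.067),
                                             (1.0, 0.0)])
    def test_reference_values(self, sd, expected):
        column = column_with_sd(sd)
        assert epsilon_shrinkage(column) == pytest.approx(expected,
                                                          abs=1e-12)

    def test_requires_two_values(self):
        with pytest.raises(ValueError):
            epsilon_shrinkage([0.5])
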