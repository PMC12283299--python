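"""FOCE-I engine: oracles, invariances, covariate machinery, stepwise screening."""

import numpy as np
import pandas as pd
import pytest

from remipk import (
    CovariateEffect,
    ModelSpec,
    PKParameters,
    chi2_threshold,
    concentration,
    fit,
    foce_objective,
    individual_parameters,
    simulate_cohort,
)
from remipk.cohort_sim import PopulationModel, FINAL_MODEL_PK
from remipk.dataset_io import Dataset
from remipk.nlme_fit import (
    backward_elimination,
    foce_subject_contribution,
    forward_selection,
)


class TestChiSquareThresholds:
    def test_printed_stepwise_cutoffs(self):
        assert chi2_threshold(0.05, 1) == pytest.approx(3.84, abs=0.005)
        # the alpha=0.001 quantile is 10.828, slightly above the printed 10.82
        assert chi2_threshold(0.001, 1) == pytest.approx(10.83, abs=0.005)
        assert chi2_threshold(0.001, 1) > 10.82

    def test_median_quantile(self):
        assert chi2_threshold(0.5, 1) == pytest.approx(0.455, abs=0.001)

    @pytest.mark.parametrize("alpha,df", [(0.0, 1), (1.0, 1), (0.05, 0)])
    def test_domain(self, alpha, df):
        with pytest.raises(ValueError):
            chi2_threshold(alpha, df)


class TestIndividualParameters:
    def test_identity_without_effects(self):
        out = individual_parameters(FINAL_MODEL_PK, [], {}, np.zeros(4))
        assert out == FINAL_MODEL_PK

    def test_continuous_effect_is_unity_at_median(self):
        eff = CovariateEffect("CL", "ALT", "continuous_power", theta_j=0.7,
                              reference=34.85)
        out = individual_parameters(FINAL_MODEL_PK, [eff], {"ALT": 34.85}, np.zeros(4))
        assert out.cl == pytest.approx(FINAL_MODEL_PK.cl, rel=1e-12)

    def test_categorical_sex_effect(self):
        eff = CovariateEffect("CL", "SEX", "categorical_exponent", theta_j=1.3)
        female = individual_parameters(FINAL_MODEL_PK, [eff], {"SEX": 1}, np.zeros(4))
        male = individual_parameters(FINAL_MODEL_PK, [eff], {"SEX": 0}, np.zeros(4))
        assert female.cl == pytest.approx(1.3 * male.cl, rel=1e-12)
        assert male.cl == pytest.approx(FINAL_MODEL_PK.cl, rel=1e-12)

    def test_eta_acts_multiplicatively_on_iiv_subset(self):
        out = individual_parameters(
            FINAL_MODEL_PK, [], {}, np.array([0.2]), iiv_parameters=("CL",)
        )
        assert out.cl == pytest.approx(FINAL_MODEL_PK.cl * np.exp(0.2), rel=1e-12)
        assert out.v1 == FINAL_MODEL_PK.v1

    def test_nonpositive_covariate_in_power_model(self):
        eff = CovariateEffect("CL", "ALT", "continuous_power", 0.5, reference=30.0)
        with pytest.raises(ValueError, match="non-positive"):
            individual_parameters(FINAL_MODEL_PK, [eff], {"ALT": 0.0}, np.zeros(4))


class TestFoceObjectiveOracles:
    def test_single_observation_vanishing_omega_closed_form(self):
        # with omega -> 0 the conditional mode is 0 and the contribution
        # collapses to log v + (y-f)^2 / v
        y, f0, sigma = 150.0, 130.0, 0.25
        contrib, eta = foce_subject_contribution(
            [y], lambda e: [f0 * np.exp(e[0] * 0)], omega=[1e-8],
            sigma_prop=sigma, n_eta=1,
        )
        v = sigma**2 * f0**2
        assert contrib == pytest.approx(np.log(v) + (y - f0) ** 2 / v, rel=1e-9)

    def test_matches_gauss_hermite_marginal_on_linear_gaussian_model(self):
        # f linear in eta + additive error: FOCE is exact, so it must agree
        # with high-order quadrature of the true marginal likelihood
        a = np.array([8.0, 11.0, 14.0])
        b = np.array([1.5, 2.5, -1.0])
        y = np.array([9.2, 10.1, 15.3])
        omega, sig = 0.6, 1.3

        contrib, _ = foce_subject_contribution(
            y, lambda e: a + b * e[0], omega=[omega],
            sigma_prop=0.0, sigma_add=sig, n_eta=1,
        )

        nodes, weights = np.polynomial.hermite.hermgauss(120)
        etas = np.sqrt(2.0) * omega * nodes
        dens = np.array([
            np.prod(np.exp(-0.5 * ((y - (a + b * e)) / sig) ** 2)
                    / (np.sqrt(2 * np.pi) * sig))
            for e in etas
        ])
        marginal = float(np.sum(weights * dens) / np.sqrt(np.pi))
        oracle = -2.0 * np.log(marginal) - len(y) * np.log(2 * np.pi)
        assert contrib == pytest.approx(oracle, abs=1e-6)

    def test_batched_engine_matches_per_subject_reference(self):
        pop = PopulationModel(
            omega={"CL": 0.3, "V1": 0.2, "Q": 0.0, "V2": 0.0}, sigma_prop=0.2
        )
        ds = simulate_cohort(pop, n=4, seed=31, dropout=0.0)
        spec = ModelSpec(iiv_parameters=("CL", "V1"))
        omega = np.array([0.3, 0.2])
        ofv, ebes = foce_objective(ds, spec, FINAL_MODEL_PK, omega, 0.2)

        total = 0.0
        for sub in ds.subjects():
            def f_of_eta(eta, sub=sub):
                p = individual_parameters(
                    FINAL_MODEL_PK, [], sub.covariates, eta, iiv_parameters=("CL", "V1")
                )
                return concentration(p, sub.regimen, sub.times)

            contrib, _ = foce_subject_contribution(
                sub.dv, f_of_eta, omega=omega, sigma_prop=0.2, n_eta=2,
                eta0=ebes.loc[sub.subject_id].to_numpy(),
            )
            total += contrib
        assert ofv == pytest.approx(total, abs=0.01)


@pytest.fixture(scope="module")
def small_ds():
    return simulate_cohort(n=6, seed=33, dropout=0.0)


@pytest.fixture(scope="module")
def tiny_ds():
    pop = PopulationModel(omega={"CL": 0.4, "V1": 0.0, "Q": 0.0, "V2": 0.0})
    return simulate_cohort(pop, n=8, seed=35, dropout=0.0)


class TestFoceObjectiveInvariances:
    def test_duplicating_subjects_doubles_ofv(self, small_ds):
        spec = ModelSpec()
        omega = np.full(4, 0.4)
        ofv1, _ = foce_objective(small_ds, spec, FINAL_MODEL_PK, omega, 0.25)
        frame = small_ds.frame
        dup = frame.copy()
        dup["ID"] = dup["ID"] + 100
        both = Dataset(pd.concat([frame, dup], ignore_index=True))
        ofv2, _ = foce_objective(both, spec, FINAL_MODEL_PK, omega, 0.25)
        assert ofv2 == pytest.approx(2.0 * ofv1, rel=1e-8)

    def test_permuting_subject_ids_leaves_ofv_unchanged(self, small_ds):
        spec = ModelSpec()
        omega = np.full(4, 0.4)
        ofv1, _ = foce_objective(small_ds, spec, FINAL_MODEL_PK, omega, 0.25)
        frame = small_ds.frame.copy()
        ids = sorted(frame["ID"].unique())
        mapping = dict(zip(ids, np.roll(ids, 2)))
        frame["ID"] = frame["ID"].map(mapping)
        ofv2, _ = foce_objective(Dataset(frame), spec, FINAL_MODEL_PK, omega, 0.25)
        assert ofv2 == pytest.approx(ofv1, rel=1e-10)

    def test_unit_rescaling_shifts_ofv_by_known_constant(self, small_ds):
        # scaling concentrations by s (and volumes/clearances by 1/s) leaves
        # the proportional-error OFV shifted by exactly n*log(s^2)
        spec = ModelSpec()
        omega = np.full(4, 0.4)
        s = 10.0
        ofv1, _ = foce_objective(small_ds, spec, FINAL_MODEL_PK, omega, 0.25)
        frame = small_ds.frame.copy()
        frame.loc[frame["EVID"] == 0, "DV"] *= s
        scaled_theta = PKParameters(
            FINAL_MODEL_PK.cl / s, FINAL_MODEL_PK.v1 / s, FINAL_MODEL_PK.q / s, FINAL_MODEL_PK.v2 / s
        )
        ofv2, _ = foce_objective(Dataset(frame), spec, scaled_theta, omega, 0.25)
        n = small_ds.n_observations
        assert ofv2 - ofv1 == pytest.approx(n * np.log(s**2), rel=1e-6)


class TestFit:
    def test_recovers_cl_from_clean_data(self, small_clean_cohort):
        spec = ModelSpec(iiv_parameters=("CL",))
        res = fit(small_clean_cohort, spec, compute_rse=True, maxfun=800)
        assert res.converged
        assert res.theta.cl == pytest.approx(58.2, rel=0.05)
        assert res.theta.v1 == pytest.approx(25.5, rel=0.15)
        assert res.sigma_prop == pytest.approx(0.05, rel=0.3)
        # RSE present and sane for the best-identified parameter
        assert 0.0 < res.rse["CL"] < 50.0

    def test_shrinkage_definition(self, study_fit):
        for p, omega in study_fit.omega.items():
            if omega <= 1e-3:
                continue
            sd_ebe = study_fit.ebes[f"eta_{p}"].std(ddof=1)
            expected = 100.0 * (1.0 - sd_ebe / omega)
            assert study_fit.shrinkage[p] == pytest.approx(expected, abs=1e-6)

    def test_estimates_table_layout(self, study_fit):
        table = study_fit.estimates_table()
        assert list(table.columns) == [
            "block", "parameter", "estimate", "rse_percent", "shrinkage_percent"
        ]
        assert set(table.loc[table.block == "theta", "parameter"]) == {
            "CL", "V1", "Q", "V2"
        }
        prop = table[table.parameter == "proportional error (%)"]
        assert prop.estimate.iloc[0] == pytest.approx(100 * study_fit.sigma_prop)


class TestStepwiseScreening:
    def test_infinite_threshold_returns_base(self, tiny_ds):
        spec = ModelSpec(iiv_parameters=("CL",))
        cand = [CovariateEffect("CL", "WT", "continuous_power", 0.0,
                                reference=tiny_ds.covariate_median("WT"))]
        selected, trace, _ = forward_selection(
            tiny_ds, spec, cand, threshold=np.inf, maxfun=500
        )
        assert selected.covariate_effects == ()
        assert len(trace) == 1 and not trace.selected.iloc[0]

    def test_backward_on_empty_model_is_identity(self, tiny_ds):
        spec = ModelSpec(iiv_parameters=("CL",))
        final, trace, _ = backward_elimination(tiny_ds, spec, maxfun=500)
        assert final == spec
        assert trace.empty
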