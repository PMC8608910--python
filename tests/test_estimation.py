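"""MAP objective, power-prior behaviour, phi sweep and population fitting."""

from dataclasses import replace

import numpy as np
import pytest
from scipy.optimize import least_squares

from iohexolpk.dataio import SubjectRecord
from iohexolpk.estimation import (
    EstimationSettings,
    UnidentifiableError,
    estimate_ebe,
    fit_population,
    map_objective,
    phi_sweep,
)
from iohexolpk.pk_models import StructuralParams, predict_concentration
from iohexolpk.population import PopulationModel, ResidualModel, individual_params
from iohexolpk.simulate import CohortSpec, simulate_subjects, true_clearances


def _additive_pop(sigma=10.0, omega=(0.09, 0.09)):
    """2-RE three-compartment model with constant residual SD (µg/mL)."""
    return PopulationModel(
        structural=StructuralParams(CL=0.05, V1=10.0, Q2=0.18, V2=4.6, Q3=0.045, V3=3.6),
        re_mask=("CL", "V1"),
        omega=np.diag(omega),
        residual=ResidualModel(kind="additive", sigma_add=sigma),
        name="additive-test",
    )


def _subject(times, conc, dose=1000.0, sid=1):
    return SubjectRecord(subject_id=sid, dose_mg=dose, times=np.asarray(times),
                         concentrations=np.asarray(conc))


class TestMapObjective:
    def test_hand_value_single_observation(self):
        # t=0 observation: IPRED = dose/V1 = 100 regardless of the CL effect
        pop = _additive_pop(sigma=10.0)
        subj = _subject([0.0], [110.0])
        obj = map_objective(pop, subj, np.array([0.1, 0.0]), phi=1.0)
        assert obj == pytest.approx(np.log(100.0) + 1.0 + 0.1**2 / 0.09, rel=1e-12)

    def test_zero_residual_zero_prior_leaves_log_variance_sum(self):
        pop = _additive_pop(sigma=5.0)
        eta = np.array([0.0, 0.0])
        times = np.array([30.0, 120.0, 300.0])
        ipred = predict_concentration(pop.structural, 1000.0, times)
        subj = _subject(times, ipred)
        obj = map_objective(pop, subj, eta, phi=1.0)
        assert obj == pytest.approx(3 * np.log(25.0), rel=1e-12)

    def test_phi_zero_is_independent_of_omega(self):
        subj = _subject([30.0, 120.0], [80.0, 55.0])
        eta = np.array([0.2, -0.1])
        a = map_objective(_additive_pop(omega=(0.09, 0.09)), subj, eta, phi=0.0)
        b = map_objective(_additive_pop(omega=(4.0, 0.01)), subj, eta, phi=0.0)
        assert a == b


class TestEstimateEbe:
    def test_no_observations_returns_prior_mode(self):
        pop = _additive_pop()
        subj = _subject([], [], sid=9)
        res = estimate_ebe(pop, subj, EstimationSettings(phi=1.0, seed=0))
        assert np.array_equal(res.eta_hat, np.zeros(2))
        assert res.params == pop.structural

    def test_dominant_prior_forces_eta_to_zero(self, cmt3_limited, noisy_cohort):
        subj = noisy_cohort[0].record
        res = estimate_ebe(cmt3_limited, subj, EstimationSettings(phi=1e6, seed=0))
        assert np.linalg.norm(res.eta_hat) < 1e-3

    def test_rich_noiseless_data_recovers_known_eta(self):
        """Pure ML on noiseless data with a homoscedastic error model must
        land on the simulated eta (the heteroscedastic log-variance term
        would otherwise shift the optimum slightly, as it should)."""
        pop = _additive_pop(sigma=1.0)
        eta_true = np.array([0.2, -0.1])
        params = individual_params(pop, eta_true)
        times = np.array([10, 30, 60, 90, 120, 180, 240, 300, 600, 1440], dtype=float)
        conc = predict_concentration(params, 3235.0, times)
        subj = _subject(times, conc, dose=3235.0)
        ml = estimate_ebe(pop, subj, EstimationSettings(phi=0.0, seed=0))
        assert np.allclose(ml.eta_hat, eta_true, atol=1e-5)
        # with phi=1 the prior shrinks the estimate slightly towards zero
        ebe = estimate_ebe(pop, subj, EstimationSettings(phi=1.0, seed=0))
        assert 0 < np.linalg.norm(ebe.eta_hat - eta_true) < 0.05

    def test_phi_zero_with_sparse_data_is_unidentifiable(self, cmt3_limited,
                                                         noisy_cohort):
        subj = noisy_cohort[0].record.restricted([300.0])
        with pytest.raises(UnidentifiableError):
            estimate_ebe(cmt3_limited, subj, EstimationSettings(phi=0.0, seed=0))

    def test_objective_at_optimum_not_worse_than_prior_mode(self, cmt3_limited,
                                                            noisy_cohort):
        settings = EstimationSettings(phi=1.0, seed=0)
        for sim in noisy_cohort[:6]:
            res = estimate_ebe(cmt3_limited, sim.record, settings)
            at_zero = map_objective(cmt3_limited, sim.record, np.zeros(2), 1.0)
            assert res.objective <= at_zero + 1e-9

    def test_shrinkage_penalty_non_increasing_in_phi(self, cmt3_limited, noisy_cohort):
        subj = noisy_cohort[1].record
        omega_inv = cmt3_limited.omega_inverse()
        penalties = []
        for phi in (0.0, 0.01, 0.1, 1.0, 10.0):
            res = estimate_ebe(cmt3_limited, subj, EstimationSettings(phi=phi, seed=0))
            penalties.append(res.eta_hat @ omega_inv @ res.eta_hat)
        assert all(b <= a + 1e-8 for a, b in zip(penalties, penalties[1:]))

    def test_classical_ebe_matches_penalized_least_squares(self):
        """phi=1 MAP equals an independently formulated weighted PLS solve."""
        pop = _additive_pop(sigma=4.0)
        rng = np.random.default_rng(17)
        times = np.array([30.0, 60.0, 120.0, 240.0, 300.0, 1440.0])
        chol_inv = np.linalg.cholesky(np.linalg.inv(pop.omega))
        for sid in range(20):
            eta_true = rng.normal(0, 0.25, size=2)
            params = individual_params(pop, eta_true)
            conc = predict_concentration(params, 3235.0, times)
            y = conc + rng.normal(0, 4.0, size=times.size)
            subj = _subject(times, y, dose=3235.0, sid=sid)

            def residuals(eta):
                p = individual_params(pop, eta)
                pred = predict_concentration(p, 3235.0, times)
                return np.concatenate([(y - pred) / 4.0, chol_inv.T @ eta])

            pls = least_squares(residuals, np.zeros(2), xtol=1e-14, ftol=1e-14,
                                gtol=1e-14)
            res = estimate_ebe(pop, subj, EstimationSettings(phi=1.0, seed=3))
            assert np.allclose(res.eta_hat, pls.x, atol=1e-6)


class TestPhiSweep:
    def _cohort(self, cmt3_limited, n=5):
        spec = CohortSpec.simulation_grid(n_subjects=n, seed=21)
        sims = simulate_subjects(cmt3_limited, spec)
        return [s.record for s in sims], true_clearances(sims)

    def test_duplicate_phis_give_identical_rows(self, cmt3_limited, fast_settings):
        subs, ref = self._cohort(cmt3_limited)
        table = phi_sweep(cmt3_limited, subs, ref, [1.0, 1.0], fast_settings)
        assert table.iloc[0].equals(table.iloc[1])

    def test_single_noiseless_subject_recomputed_per_phi(self, cmt3_limited):
        spec = CohortSpec.simulation_grid(n_subjects=1, seed=5, residual_noise=False)
        sims = simulate_subjects(cmt3_limited, spec)
        subs, ref = [sims[0].record], true_clearances(sims)
        phis = [0.1, 1.0, 10.0]
        settings = EstimationSettings(seed=2, multistart=2)
        table = phi_sweep(cmt3_limited, subs, ref, phis, settings)
        # brute-force: re-estimate each phi independently and rebuild the RMSE
        for phi, row in zip(phis, table.itertuples()):
            ebe = estimate_ebe(cmt3_limited, subs[0],
                               replace(settings, phi=phi))
            assert row.rmse_cl == pytest.approx(abs(ebe.cl_ml_min - ref[0]), rel=1e-12)

    def test_unidentifiable_phi_zero_rows_are_flagged(self, cmt3_limited,
                                                      fast_settings):
        subs, ref = self._cohort(cmt3_limited, n=3)
        sparse = [s.restricted([300.0]) for s in subs]
        table = phi_sweep(cmt3_limited, sparse, ref, [0.0, 1.0], fast_settings)
        assert table.loc[table.phi == 0.0, "n_failed"].item() == 3
        assert np.isnan(table.loc[table.phi == 0.0, "rmse_cl"].item())
        assert table.loc[table.phi == 1.0, "n_failed"].item() == 0

    def test_empty_subject_list_raises(self, cmt3_limited, fast_settings):
        with pytest.raises(Exception):
            phi_sweep(cmt3_limited, [], np.array([]), [1.0], fast_settings)


class TestFitPopulation:
    def test_degenerate_noiseless_fit_recovers_theta_exactly(self):
        """With Omega ~ 0 and no residual noise the typicals are identified
        to numerical precision (additive error keeps the likelihood clean)."""
        truth = PopulationModel(
            structural=StructuralParams(CL=0.05, V1=9.0, Q2=0.12, V2=6.0),
            re_mask=("CL", "V1"),
            omega=np.diag([1e-8, 1e-8]),
            residual=ResidualModel(kind="additive", sigma_add=1.0),
            name="degenerate",
        )
        spec = CohortSpec.development_like(n_subjects=8, seed=31,
                                           residual_noise=False)
        sims = simulate_subjects(truth, spec)
        start = truth.with_structural(
            truth.structural.replace(CL=0.06, V1=7.5)
        )
        res = fit_population([s.record for s in sims], start,
                             fix=("Q2", "V2"),
                             settings=EstimationSettings(seed=1, multistart=1))
        assert res.model.structural.CL == pytest.approx(0.05, rel=1e-4)
        assert res.model.structural.V1 == pytest.approx(9.0, rel=1e-4)

    def test_true_covariate_effect_reduces_ofv(self, cmt3_cov):
        """Fitting the covariate submodel on covariate-driven data must beat
        the covariate-free fit in -2 log likelihood."""
        spec = CohortSpec(n_subjects=25, seed=13, include_1440=False)
        sims = simulate_subjects(cmt3_cov, spec)
        subs = [s.record for s in sims]
        settings = EstimationSettings(seed=1, multistart=1)
        fix_struct = ("Q2", "V2", "Q3", "V3")
        no_cov_start = PopulationModel(
            structural=cmt3_cov.structural,
            re_mask=cmt3_cov.re_mask,
            omega=cmt3_cov.omega,
            residual=cmt3_cov.residual,
            covariates=None,
            name="no-cov",
        )
        fit_plain = fit_population(subs, no_cov_start, fix=fix_struct,
                                   settings=settings, maxiter=60)
        fit_cov = fit_population(
            subs, cmt3_cov,
            fix=fix_struct + ("age_exp", "weight_exp_cl", "female_shift",
                              "weight_exp_v1"),
            settings=settings, maxiter=60,
        )
        assert fit_cov.ofv < fit_plain.ofv
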