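"""Structural model, covariate model and clinical-formula checks."""

import numpy as np
import pytest
from scipy.integrate import quad, solve_ivp

from iohexolpk.pk_models import (
    ConfigurationError,
    Covariates,
    CovariateCoefficients,
    InvalidParameterError,
    StructuralParams,
    apply_covariates,
    auc_zero_inf,
    bsa_dubois,
    egfr_bis2,
    predict_concentration,
)
from iohexolpk.population import load_bis2_coefficients

TIMES = np.array([30.0, 60.0, 90.0, 120.0, 180.0, 240.0, 300.0, 1440.0])


def random_params(rng, n_cmt):
    kw = dict(
        CL=rng.uniform(0.01, 0.12),
        V1=rng.uniform(4.0, 15.0),
        Q2=rng.uniform(0.02, 0.4),
        V2=rng.uniform(2.0, 10.0),
    )
    if n_cmt == 3:
        kw["Q3"] = rng.uniform(0.01, 0.2)
        kw["V3"] = rng.uniform(1.0, 8.0)
    return StructuralParams(**kw)


def ode_concentration(params, dose, times):
    """Independent oracle: adaptive-step integration of the mass balance."""
    M = params.rate_matrix()
    a0 = np.zeros(params.n_compartments)
    a0[0] = dose
    sol = solve_ivp(
        lambda t, a: M @ a,
        (0.0, float(times[-1])),
        a0,
        t_eval=times,
        method="LSODA",
        jac=lambda t, a: M,
        rtol=1e-13,
        atol=1e-13,
    )
    return sol.y[0] / params.V1


class TestPredictConcentration:
    def test_bolus_initial_condition(self):
        p2 = StructuralParams(CL=0.05, V1=10.0, Q2=0.1, V2=5.0)
        p3 = StructuralParams(CL=0.05, V1=10.0, Q2=0.1, V2=5.0, Q3=0.02, V3=3.0)
        for p in (p2, p3):
            assert predict_concentration(p, 3235.0, 0.0)[0] == pytest.approx(323.5)

    def test_monoexponential_limit(self):
        p = StructuralParams(CL=0.05, V1=10.0, Q2=0.0, V2=1.0, Q3=0.0, V3=1.0)
        got = predict_concentration(p, 3235.0, 100.0)[0]
        assert got == pytest.approx(323.5 * np.exp(-0.5), rel=1e-12)

    @pytest.mark.parametrize("n_cmt", [2, 3])
    def test_matches_ode_integration(self, n_cmt):
        rng = np.random.default_rng(101 + n_cmt)
        for _ in range(10):
            p = random_params(rng, n_cmt)
            analytic = predict_concentration(p, 3235.0, TIMES)
            numeric = ode_concentration(p, 3235.0, TIMES)
            assert np.allclose(analytic, numeric, rtol=1e-8, atol=0)

    @pytest.mark.parametrize("n_cmt", [2, 3])
    def test_auc_conservation(self, n_cmt):
        rng = np.random.default_rng(7)
        p = random_params(rng, n_cmt)
        dose = 3235.0
        # adaptive quadrature over [0, T] plus the analytic mono-exponential tail
        T = 50000.0
        head, _ = quad(
            lambda t: predict_concentration(p, dose, t)[0], 0, T, limit=400
        )
        from iohexolpk.pk_models import exponential_terms

        lam, w = exponential_terms(p)
        tail = dose / p.V1 * np.sum(-w / lam * np.exp(lam * T))
        assert head + tail == pytest.approx(dose / p.CL, rel=1e-6)
        # the closed-form AUC helper agrees too
        assert auc_zero_inf(p, dose) == pytest.approx(dose / p.CL, rel=1e-10)

    def test_dose_linearity_exact(self):
        p = StructuralParams(CL=0.05, V1=8.0, Q2=0.2, V2=5.0, Q3=0.05, V3=4.0)
        c1 = predict_concentration(p, 1000.0, TIMES)
        c2 = predict_concentration(p, 2000.0, TIMES)
        assert np.array_equal(c2, 2.0 * c1)

    def test_three_compartment_nests_two(self):
        p2 = StructuralParams(CL=0.05, V1=8.0, Q2=0.2, V2=5.0)
        sup = []
        for q3 in (1e-6, 1e-9, 1e-12):
            p3 = StructuralParams(CL=0.05, V1=8.0, Q2=0.2, V2=5.0, Q3=q3, V3=4.0)
            sup.append(
                np.max(
                    np.abs(
                        predict_concentration(p3, 3235.0, TIMES)
                        - predict_concentration(p2, 3235.0, TIMES)
                    )
                )
            )
        assert sup[0] > sup[1] > sup[2]
        assert sup[2] < 1e-8

    def test_terminal_phase_slope_is_smallest_eigenvalue(self):
        p = StructuralParams(CL=0.05, V1=8.0, Q2=0.2, V2=5.0, Q3=0.05, V3=4.0)
        lam = np.linalg.eigvals(p.rate_matrix()).real
        slowest = lam.max()  # eigenvalues are negative; max is smallest magnitude
        t = np.array([4000.0, 5000.0])
        logc = np.log(predict_concentration(p, 3235.0, t))
        slope = (logc[1] - logc[0]) / (t[1] - t[0])
        assert slope == pytest.approx(slowest, rel=1e-6)

    def test_near_degenerate_eigenvalues_stay_finite(self):
        # symmetric peripheral compartments force eigenvalue near-collision
        p = StructuralParams(CL=1e-9, V1=10.0, Q2=0.1, V2=5.0, Q3=0.1, V3=5.0)
        c = predict_concentration(p, 3235.0, TIMES)
        assert np.all(np.isfinite(c)) and np.all(c > 0)

    def test_invalid_inputs_raise(self):
        with pytest.raises(InvalidParameterError):
            StructuralParams(CL=-0.05, V1=10.0, Q2=0.1, V2=5.0)
        with pytest.raises(InvalidParameterError):
            StructuralParams(CL=0.05, V1=10.0, Q2=0.1, V2=5.0, Q3=0.1, V3=None)
        p = StructuralParams(CL=0.05, V1=10.0, Q2=0.1, V2=5.0)
        with pytest.raises(InvalidParameterError):
            predict_concentration(p, 0.0, TIMES)
        with pytest.raises(InvalidParameterError):
            predict_concentration(p, 3235.0, np.array([-1.0]))


COEF = CovariateCoefficients(
    typical_cl=0.0546,
    cr_exp=-0.38,
    cc_exp=-0.60,
    age_exp=-0.30,
    weight_exp_cl=0.42,
    female_shift=-0.07,
    typical_v1=7.9,
    weight_exp_v1=0.80,
)


def _reference_subject(**overrides):
    base = dict(age=77.0, sex="male", weight=77.0, creatinine=0.9, cystatin_c=1.03)
    base.update(overrides)
    return Covariates(**base)


class TestCovariateModel:
    def test_reference_subject_gets_typical_values(self):
        cl, v1 = apply_covariates(COEF, _reference_subject())
        assert cl == pytest.approx(COEF.typical_cl, rel=1e-14)
        assert v1 == pytest.approx(COEF.typical_v1, rel=1e-14)

    def test_female_shift_is_proportional(self):
        cl_m, _ = apply_covariates(COEF, _reference_subject())
        cl_f, _ = apply_covariates(COEF, _reference_subject(sex="female"))
        assert cl_f == pytest.approx(cl_m * (1 + COEF.female_shift), rel=1e-14)

    def test_weight_doubling_scales_volume_by_power(self):
        _, v1 = apply_covariates(COEF, _reference_subject(weight=154.0))
        assert v1 == pytest.approx(COEF.typical_v1 * 2**COEF.weight_exp_v1, rel=1e-12)

    def test_mixed_subject_matches_hand_evaluation(self):
        cov = _reference_subject(age=80.0, weight=90.0, creatinine=1.8, cystatin_c=2.0)
        cl, v1 = apply_covariates(COEF, cov)
        expected_cl = (
            0.0546
            * (1.8 / 0.9) ** -0.38
            * (2.0 / 1.03) ** -0.60
            * (80.0 / 77.0) ** -0.30
            * (90.0 / 77.0) ** 0.42
        )
        assert cl == pytest.approx(expected_cl, rel=1e-12)
        assert v1 == pytest.approx(7.9 * (90.0 / 77.0) ** 0.80, rel=1e-12)

    def test_invalid_covariates_raise(self):
        with pytest.raises(InvalidParameterError):
            _reference_subject(creatinine=-1.0)
        with pytest.raises(InvalidParameterError):
            _reference_subject(sex="unknown")


class TestClinicalFormulas:
    def test_bsa_unit_inputs(self):
        assert bsa_dubois(1.0, 1.0) == pytest.approx(0.20247)

    def test_bsa_hand_value(self):
        assert bsa_dubois(1.70, 77.0) == pytest.approx(1.8844937830902164, rel=1e-12)

    def test_bsa_power_law_in_weight(self):
        assert bsa_dubois(1.7, 160.0) == pytest.approx(
            bsa_dubois(1.7, 80.0) * 2**0.425, rel=1e-12
        )

    def test_bsa_invalid(self):
        with pytest.raises(InvalidParameterError):
            bsa_dubois(0.0, 70.0)

    def test_egfr_degenerate_config_returns_scale(self):
        coef = dict(scale=1.0, creatinine_exp=0.0, cystatin_exp=0.0, age_exp=0.0,
                    female_factor=1.0)
        cov = _reference_subject(creatinine=5.0, cystatin_c=3.0)
        assert egfr_bis2(cov, coef) == 1.0

    def test_egfr_monotone_decreasing_in_creatinine(self):
        coef = load_bis2_coefficients()
        lo = egfr_bis2(_reference_subject(creatinine=1.0), coef)
        hi = egfr_bis2(_reference_subject(creatinine=2.0), coef)
        assert hi < lo

    def test_egfr_hand_value_with_packaged_config(self):
        coef = load_bis2_coefficients()
        cov = Covariates(age=79.2, sex="female", weight=79.5, creatinine=1.91,
                         cystatin_c=2.13)
        assert egfr_bis2(cov, coef) == pytest.approx(26.87301274260801, rel=1e-10)
        male = Covariates(age=79.2, sex="male", weight=79.5, creatinine=1.91,
                          cystatin_c=2.13)
        assert egfr_bis2(male, coef) == pytest.approx(30.888520393802313, rel=1e-10)

    def test_egfr_missing_config_raises(self):
        with pytest.raises(ConfigurationError):
            egfr_bis2(_reference_subject(), {"scale": 1.0})
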