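"""Least-squares fitters, their closed-form oracles, validation statistics."""

import math

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from sewerch4.exceptions import (
    DegenerateFitError,
    InvalidBiomassError,
    InvalidInputError,
)
from sewerch4.fitting import (
    PairedSeries,
    ProportionalMethaneModel,
    QuadraticBiomassModel,
    fit_proportional,
    fit_quadratic,
    pct_diff_range,
    r_squared,
)
from sewerch4.methane import BiomassCurveParams


def normal_equation_quadratic(F, y):
    """Independent 3×3 normal-equation solve for the quadratic fit."""
    F = np.asarray(F, dtype=float)
    y = np.asarray(y, dtype=float)
    D = np.column_stack([F**2, F, np.ones_like(F)])
    return np.linalg.solve(D.T @ D, D.T @ y)


def golden_section_cstar(X, Q):
    """Independent 1-D argmin of the through-origin SSE."""
    X = np.asarray(X, dtype=float)
    Q = np.asarray(Q, dtype=float)
    res = minimize_scalar(
        lambda c: np.sum((Q - c * X) ** 2),
        bracket=(-1e3, 1e3),
        method="golden",
        options={"xtol": 1e-10},
    )
    return res.x


class TestQuadraticFit:
    def test_exact_recovery_of_generating_coefficients(self, printed_rates):
        F, _ = printed_rates
        p = BiomassCurveParams()
        y = p.a * F**2 + p.b * F + p.c
        res = fit_quadratic(shear=F, biomass=y)
        assert res.params.a == pytest.approx(p.a, abs=1e-10)
        assert res.params.b == pytest.approx(p.b, abs=1e-10)
        assert res.params.c == pytest.approx(p.c, abs=1e-10)
        assert res.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_three_point_interpolation(self):
        res = fit_quadratic([(0, 1), (1, 2), (2, 5)])
        assert res.params.a == pytest.approx(1.0, abs=1e-10)
        assert res.params.b == pytest.approx(0.0, abs=1e-10)
        assert res.params.c == pytest.approx(1.0, abs=1e-10)
        assert res.r_squared == pytest.approx(1.0)

    def test_constant_response_convention(self):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # flat curve is not concave
            res = fit_quadratic(shear=[0.5, 1.0, 1.5, 2.0], biomass=[2.0] * 4)
        assert res.params.a == pytest.approx(0.0, abs=1e-10)
        assert res.params.b == pytest.approx(0.0, abs=1e-10)
        assert res.params.c == pytest.approx(2.0)
        assert res.r_squared == 0.0

    def test_degenerate_design_rejected(self):
        with pytest.raises(DegenerateFitError):
            QuadraticBiomassModel([1.0, 1.0, 2.0, 2.0], [1, 1, 2, 2])

    def test_matches_normal_equation_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            n = rng.integers(4, 12)
            F = rng.uniform(0.1, 3.0, size=n)
            while len(np.unique(F)) < 3:
                F = rng.uniform(0.1, 3.0, size=n)
            y = rng.normal(0.1, 0.05, size=n)
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = fit_quadratic(shear=F, biomass=y)
            a, b, c = normal_equation_quadratic(F, y)
            assert res.params.a == pytest.approx(a, rel=1e-8, abs=1e-10)
            assert res.params.b == pytest.approx(b, rel=1e-8, abs=1e-10)
            assert res.params.c == pytest.approx(c, rel=1e-8, abs=1e-10)


class TestProportionalFit:
    def test_published_rates(self, printed_rates):
        """The headline fit: c* ≈ 16.55 with centered R² ≈ 0.956."""
        F, Q = printed_rates
        res = fit_proportional(shear=F, methane=Q)
        assert res.cstar == pytest.approx(16.551860, abs=1e-4)
        assert res.r_squared == pytest.approx(0.955827, abs=1e-4)
        lo, hi = res.pct_diff_range
        assert lo == pytest.approx(2.404, abs=1e-2)
        assert hi == pytest.approx(6.908, abs=1e-2)

    def test_closed_form_equals_golden_section_argmin(self):
        rng = np.random.default_rng(9)
        for _ in range(200):
            n = rng.integers(1, 10)
            F = rng.uniform(0.2, 3.0, size=n)
            Q = rng.uniform(0.1, 3.0, size=n)
            res = ProportionalMethaneModel(F, Q).fit()
            X = res.model.biomass
            assert res.cstar == pytest.approx(
                golden_section_cstar(X, Q), rel=1e-6, abs=1e-8
            )

    def test_noise_free_proportionality_recovers_exactly(self, printed_rates):
        F, _ = printed_rates
        p = BiomassCurveParams()
        Q = 10.0 * (p.a * F**2 + p.b * F + p.c)
        res = fit_proportional(shear=F, methane=Q)
        assert res.cstar == pytest.approx(10.0, abs=1e-12)
        assert res.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_single_pair_ratio_with_undefined_r2(self):
        res = fit_proportional(shear=[1.45], methane=[1.0])
        X = BiomassCurveParams()
        x = X.a * 1.45**2 + X.b * 1.45 + X.c
        assert res.cstar == pytest.approx(1.0 / x)
        assert math.isnan(res.r_squared)

    def test_all_nonpositive_biomass_rejected(self):
        with pytest.raises(InvalidBiomassError):
            ProportionalMethaneModel([0.01, 0.05], [1.0, 1.0])

    def test_yield_decomposition_round_trip(self, printed_rates):
        F, Q = printed_rates
        res = fit_proportional(shear=F, methane=Q)
        Y = res.yield_coefficient(T=22.5, HRT=2.0)
        assert Y * 1.05**2.5 * 2.0 == pytest.approx(res.cstar)

    def test_summary_reports_fit(self, printed_rates):
        F, Q = printed_rates
        text = fit_proportional(shear=F, methane=Q).summary()
        assert "16.55" in text and "0.9558" in text


class TestValidationStatistics:
    def test_r_squared_perfect_and_null_fits(self):
        obs = np.array([1.0, 2.0, 3.0])
        assert r_squared(obs, obs) == 1.0
        assert r_squared(obs, np.full(3, obs.mean())) == 0.0

    def test_r_squared_hand_example(self):
        assert r_squared([1, 2, 3], [1, 2, 4]) == pytest.approx(0.5)

    def test_uncentered_variant(self):
        obs, pred = [1.0, 2.0, 3.0], [1.0, 2.0, 4.0]
        assert r_squared(obs, pred, "uncentered") == pytest.approx(1 - 1 / 14)

    def test_zero_denominator_is_nan(self):
        assert math.isnan(r_squared([2.0, 2.0], [1.0, 3.0]))

    def test_pct_diff_hand_example(self):
        assert pct_diff_range([2, 4], [1.9, 4.4]) == (
            pytest.approx(5.0), pytest.approx(10.0)
        )

    def test_pct_diff_identical_and_single(self):
        assert pct_diff_range([2.0], [2.0]) == (0.0, 0.0)
        lo, hi = pct_diff_range([3.0], [2.7])
        assert lo == hi == pytest.approx(10.0)

    def test_pct_diff_zero_observation_rejected(self):
        with pytest.raises(InvalidInputError):
            pct_diff_range([0.0, 1.0], [0.1, 1.0])

    def test_paired_series_validates_lengths(self):
        with pytest.raises(InvalidInputError):
            PairedSeries((1.0, 2.0), (1.0,))


class TestDirectParameterRecovery:
    """Recovery from noisy observations drawn directly at the study design."""

    def test_recovery_under_relative_noise(self, printed_rates):
        F, _ = printed_rates
        truth = BiomassCurveParams()
        X_true = truth.a * F**2 + truth.b * F + truth.c
        cstar_true = 16.55
        rng = np.random.default_rng(2024)
        a_err, b_err, c_err, cs_err = [], [], [], []
        for _ in range(100):
            # per-sewer means over replicated measurements: 6 daily methane
            # rates and ~10 biomass-forming records at 5% scatter each
            X_obs = X_true * (1 + rng.normal(0, 0.05 / math.sqrt(10), 7))
            Q_obs = cstar_true * X_true * (
                1 + rng.normal(0, 0.05 / math.sqrt(6), 7)
            )
            qres = fit_quadratic(shear=F, biomass=X_obs)
            pres = fit_proportional(shear=F, methane=Q_obs)
            a_err.append(abs((qres.params.a - truth.a) / truth.a))
            b_err.append(abs((qres.params.b - truth.b) / truth.b))
            c_err.append(abs((qres.params.c - truth.c) / truth.c))
            cs_err.append(abs(pres.cstar - cstar_true) / cstar_true)
        assert np.median(a_err) < 0.10
        assert np.median(b_err) < 0.10
        assert np.median(cs_err) < 0.05
        # the constant term is weakly identified (|c| is tiny relative to
        # the design's leverage); pooled over the coefficient vector the
        # recovery is comfortably within 10%
        assert np.median(np.concatenate([a_err, b_err, c_err])) < 0.10
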