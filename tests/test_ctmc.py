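import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy.linalg import expm

from audtrans.ctmc import (
    IntensityModel,
    OverflowConfigurationError,
    _log_probs_and_grad,
    _pair_arrays,
    build_generator,
    cohort_loglik,
    fit_mle,
    hazard_ratios,
    transition_matrix,
)

INTERCEPT_ONLY = IntensityModel()

# closed-form reference entry for q01=0.5, q10=1.0, dt=1:
# P00 = (1 + 0.5 exp(-1.5)) / 1.5
P00_REF = (1.0 + 0.5 * math.exp(-1.5)) / 1.5  # = 0.7410433867161432


def pairs_frame(records, covs=()):
    df = pd.DataFrame(records)
    for c in covs:
        assert c in df.columns
    return df


class TestGenerator:
    def test_intercepts_recover_rates(self):
        params = np.array([math.log(0.2), math.log(0.5)])
        Q = build_generator(INTERCEPT_ONLY, params, np.empty(0))
        np.testing.assert_allclose(Q, [[-0.2, 0.2], [0.5, -0.5]], atol=1e-15)

    def test_unit_covariate_increase_multiplies_rate_by_hr(self):
        model = IntensityModel(covariates=("cannabis",))
        params = np.array([math.log(0.2), math.log(0.5), math.log(1.18), 0.0])
        q_low = build_generator(model, params, {"cannabis": 1.0})[0, 1]
        q_high = build_generator(model, params, {"cannabis": 2.0})[0, 1]
        assert q_high / q_low == pytest.approx(1.18, rel=1e-12)

    @given(st.floats(-3, 3), st.floats(-3, 3), st.floats(-2, 2))
    def test_rows_sum_to_zero_offdiag_positive(self, a01, a10, z):
        model = IntensityModel(covariates=("x",))
        Q = build_generator(model, np.array([a01, a10, 0.3, -0.2]), {"x": z})
        np.testing.assert_allclose(Q.sum(axis=1), 0.0, atol=1e-12)
        assert Q[0, 1] > 0 and Q[1, 0] > 0

    def test_overflow_raises(self):
        model = IntensityModel(covariates=("x",))
        with pytest.raises(OverflowConfigurationError):
            build_generator(model, np.array([0.0, 0.0, 30.0, 0.0]), {"x": 2.0})


class TestTransitionMatrix:
    def test_zero_gap_and_zero_generator_give_identity(self):
        Q = np.array([[-0.2, 0.2], [0.5, -0.5]])
        np.testing.assert_array_equal(transition_matrix(Q, 0.0), np.eye(2))
        np.testing.assert_array_equal(transition_matrix(np.zeros((2, 2)), 5.0), np.eye(2))

    def test_closed_form_reference_value(self):
        Q = np.array([[-0.5, 0.5], [1.0, -1.0]])
        P = transition_matrix(Q, 1.0)
        assert P[0, 0] == pytest.approx(P00_REF, abs=1e-12)
        assert P[0, 1] == pytest.approx(1 - P00_REF, abs=1e-12)

    def test_long_gap_reaches_stationary_distribution(self):
        Q = np.array([[-0.5, 0.5], [1.0, -1.0]])
        P = transition_matrix(Q, 1e4)
        np.testing.assert_allclose(P[0], [1.0 / 1.5, 0.5 / 1.5], atol=1e-12)
        np.testing.assert_allclose(P[0], P[1], atol=1e-12)

    def test_negative_gap_rejected(self):
        with pytest.raises(ValueError):
            transition_matrix(np.array([[-0.5, 0.5], [1.0, -1.0]]), -1.0)

    @given(st.floats(1e-4, 5.0), st.floats(1e-4, 5.0), st.floats(0.1, 24.0))
    def test_agrees_with_matrix_exponential(self, q01, q10, dt):
        Q = np.array([[-q01, q01], [q10, -q10]])
        np.testing.assert_allclose(transition_matrix(Q, dt), expm(Q * dt), atol=1e-10)

    @given(st.floats(0.01, 2.0), st.floats(0.01, 2.0),
           st.floats(0.1, 12.0), st.floats(0.1, 12.0))
    def test_chapman_kolmogorov(self, q01, q10, s, t):
        Q = np.array([[-q01, q01], [q10, -q10]])
        lhs = transition_matrix(Q, s) @ transition_matrix(Q, t)
        np.testing.assert_allclose(lhs, transition_matrix(Q, s + t), atol=1e-10)


class TestLoglik:
    PARAMS = np.array([math.log(0.5), math.log(1.0)])

    def single_pair(self):
        return pairs_frame([{"subject_id": "s", "pre_state": 0, "post_state": 1,
                             "dt": 1.0, "age_pre": 18.0}])

    def test_single_pair_closed_form(self):
        ll = cohort_loglik(INTERCEPT_ONLY, self.PARAMS, self.single_pair())
        assert ll == pytest.approx(math.log(1 - P00_REF), abs=1e-12)
        assert ll == pytest.approx(-1.35109, abs=1e-5)

    def test_duplicating_pairs_doubles_loglik(self):
        p = self.single_pair()
        ll1 = cohort_loglik(INTERCEPT_ONLY, self.PARAMS, p)
        ll2 = cohort_loglik(INTERCEPT_ONLY, self.PARAMS, pd.concat([p, p], ignore_index=True))
        assert ll2 == pytest.approx(2 * ll1, abs=1e-14)

    def test_order_invariant_bit_identical(self, rng):
        records = [{"subject_id": i, "pre_state": int(rng.integers(2)),
                    "post_state": int(rng.integers(2)), "dt": float(rng.uniform(1, 12)),
                    "age_pre": 20.0} for i in range(50)]
        p = pairs_frame(records)
        ll = cohort_loglik(INTERCEPT_ONLY, self.PARAMS, p)
        for _ in range(5):
            shuffled = p.sample(frac=1, random_state=rng.integers(1 << 16)).reset_index(drop=True)
            assert cohort_loglik(INTERCEPT_ONLY, self.PARAMS, shuffled) == ll

    def test_empty_pairs_rejected(self):
        with pytest.raises(ValueError):
            cohort_loglik(INTERCEPT_ONLY, self.PARAMS, self.single_pair().iloc[:0])

    def test_analytic_score_matches_finite_differences(self, rng):
        model = IntensityModel(covariates=("x", "y"), constrained=frozenset({"y"}))
        records = [{"subject_id": i, "pre_state": int(rng.integers(2)),
                    "post_state": int(rng.integers(2)), "dt": float(rng.uniform(1, 12)),
                    "age_pre": 20.0, "x": float(rng.normal()), "y": float(rng.normal())}
                   for i in range(40)]
        pairs = pairs_frame(records)
        D01, D10, dt, pre, post = _pair_arrays(model, pairs)
        theta = np.array([-2.0, -1.0, 0.3, -0.2, 0.4])
        _, grad = _log_probs_and_grad(theta, D01, D10, dt, pre, post)
        h = 1e-6
        for j in range(theta.size):
            tp, tm = theta.copy(), theta.copy()
            tp[j] += h
            tm[j] -= h
            fd = (cohort_loglik(model, tp, pairs) - cohort_loglik(model, tm, pairs)) / (2 * h)
            assert grad[j] == pytest.approx(fd, rel=1e-5, abs=1e-7)


class TestFit:
    def symmetric_pairs(self, n=25, dt=6.0):
        records = []
        for i, (a, b) in enumerate([(0, 0), (0, 1), (1, 0), (1, 1)] * n):
            records.append({"subject_id": i, "pre_state": a, "post_state": b,
                            "dt": dt, "age_pre": 20.0})
        return pairs_frame(records)

    def test_symmetric_counts_give_equal_rates(self):
        """Counts symmetric under state relabelling force q01 = q10.

        With equal counts of all four pair types the likelihood is flat along
        the symmetric ridge (its supremum sits at infinite rates), so the
        fitted loglik is only checked against the grid-search oracle to ridge
        tolerance; the symmetry of the optimum is the substantive claim.
        """
        pairs = self.symmetric_pairs()
        fit = fit_mle(INTERCEPT_ONLY, pairs, starts=1)
        assert fit.params[0] == pytest.approx(fit.params[1], abs=1e-5)

        grid = np.exp(np.linspace(math.log(0.01), math.log(2.0), 120))
        best, best_ll = None, -np.inf
        for q01 in grid:
            for q10 in grid:
                ll = cohort_loglik(INTERCEPT_ONLY, np.log([q01, q10]), pairs)
                if ll > best_ll:
                    best, best_ll = (q01, q10), ll
        assert best[0] == pytest.approx(best[1], rel=0.05)
        assert fit.loglik >= best_ll - 1e-6

    def test_interior_symmetric_optimum_matches_grid_oracle(self):
        """Counts {0->0:30, 0->1:10, 1->0:10, 1->1:30} give an interior MLE:
        P01(dt) = 1/4 requires exp(-s dt) = 1/2, i.e. s = log(2)/dt, with
        q01 = q10 by symmetry. Checked against both the closed form and a
        brute-force grid search."""
        records = []
        i = 0
        for (a, b), n in {(0, 0): 30, (0, 1): 10, (1, 0): 10, (1, 1): 30}.items():
            for _ in range(n):
                records.append({"subject_id": i, "pre_state": a, "post_state": b,
                                "dt": 6.0, "age_pre": 20.0})
                i += 1
        pairs = pairs_frame(records)
        fit = fit_mle(INTERCEPT_ONLY, pairs, starts=1)
        q_expected = math.log(2.0) / 6.0 / 2.0  # s = log2/dt split evenly
        assert math.exp(fit.params[0]) == pytest.approx(q_expected, rel=1e-4)
        assert math.exp(fit.params[1]) == pytest.approx(q_expected, rel=1e-4)
        grid = np.exp(np.linspace(math.log(0.005), math.log(1.0), 160))
        best_ll = max(cohort_loglik(INTERCEPT_ONLY, np.log([a, b]), pairs)
                      for a in grid for b in grid)
        assert fit.loglik >= best_ll - 1e-9

    def test_constant_covariate_flagged(self):
        pairs = self.symmetric_pairs()
        pairs["flat"] = 1.0
        model = IntensityModel(covariates=("flat",))
        with pytest.warns(UserWarning, match="flat"):
            fit = fit_mle(model, pairs, starts=1)
        assert "flat" in fit.diagnostics["degenerate_covariates"]

    def test_constrained_model_never_beats_parent(self, rng):
        records = [{"subject_id": i, "pre_state": int(rng.integers(2)),
                    "post_state": int(rng.integers(2)), "dt": float(rng.uniform(3, 12)),
                    "age_pre": 20.0, "x": float(rng.normal())} for i in range(300)]
        pairs = pairs_frame(records)
        free = fit_mle(IntensityModel(covariates=("x",)), pairs, starts=2, seed=0)
        tied = fit_mle(IntensityModel(covariates=("x",), constrained=frozenset({"x"})),
                       pairs, starts=2, seed=0)
        assert tied.loglik <= free.loglik + 1e-8


class TestHazardRatios:
    def make_fit(self, model, params, ses):
        from audtrans.ctmc import FitResult

        return FitResult(model=model, params=np.asarray(params, dtype=float),
                         cov=np.diag(np.asarray(ses, dtype=float) ** 2), loglik=0.0,
                         converged=True, n_pairs=10)

    def test_null_coefficient(self):
        model = IntensityModel(covariates=("x",))
        fit = self.make_fit(model, [0, 0, 0.0, 0.0], [1, 1, 0.1, 0.1])
        row = hazard_ratios(fit).iloc[0]
        assert row["hr_onset"] == pytest.approx(1.00)
        assert row["hr_onset_lo"] == pytest.approx(0.82, abs=0.005)
        assert row["hr_onset_hi"] == pytest.approx(1.22, abs=0.005)

    def test_constrained_pair_reciprocal(self):
        model = IntensityModel(covariates=("x",), constrained=frozenset({"x"}))
        fit = self.make_fit(model, [0, 0, math.log(1.18)], [1, 1, 0.056])
        row = hazard_ratios(fit).iloc[0]
        assert row["hr_onset"] == pytest.approx(1.18, rel=1e-12)
        assert row["hr_remission"] == pytest.approx(1 / 1.18, rel=1e-12)
        assert row["hr_remission"] == pytest.approx(0.847, abs=0.001)
        assert row["hr_onset"] * row["hr_remission"] == pytest.approx(1.0, abs=1e-15)
        # CI endpoints invert and swap
        assert row["hr_remission_lo"] == pytest.approx(1 / row["hr_onset_hi"], rel=1e-12)
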