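import numpy as np
import pandas as pd
import pytest

from mepsim.errors import DomainError, InvalidSpecError
from mepsim.theory import (
    averaged_error_variance,
    conditional_error_variance,
    fit_mse_scaling,
    lemma1_gap,
    sigma_reduced_log,
    tradeoff_table,
)


class TestAveragedErrorVariance:
    def test_printed_within_person_variance_halved(self):
        assert averaged_error_variance(38.0, 2) == pytest.approx(19.0)

    def test_single_replicate_identity(self):
        assert averaged_error_variance(1.7, 1) == pytest.approx(1.7)

    def test_vanishes_in_k(self):
        assert averaged_error_variance(5.0, 10**9) == pytest.approx(0.0, abs=1e-8)

    def test_rejects_zero_k(self):
        with pytest.raises(InvalidSpecError):
            averaged_error_variance(1.0, 0)


class TestSigmaReducedLog:
    @pytest.mark.parametrize("s2", [0.1, 0.25, 1.0, 2.0])
    def test_k1_collapses_to_sigma2(self, s2):
        assert sigma_reduced_log(s2, 1) == pytest.approx(s2, rel=1e-12)

    @pytest.mark.parametrize("s2", [0.1, 0.5, 1.0, 2.0])
    @pytest.mark.parametrize("k", range(2, 11))
    def test_bounds_between_full_and_additive_reduction(self, s2, k):
        r = sigma_reduced_log(s2, k)
        assert s2 / k <= r <= s2

    def test_monotone_decreasing_in_k_increasing_in_sigma2(self):
        grid = [0.1, 0.5, 1.0, 2.0]
        for s2 in grid:
            vals = [sigma_reduced_log(s2, k) for k in range(1, 11)]
            assert all(a > b for a, b in zip(vals, vals[1:]))
        for k in range(2, 11):
            vals = [sigma_reduced_log(s2, k) for s2 in grid]
            assert all(a < b for a, b in zip(vals, vals[1:]))

    def test_matches_variance_matching_mc_oracle(self):
        """Independent oracle: simulate averages of k lognormal errors,
        numerically invert the single-error variance map."""
        rng = np.random.default_rng(2024)
        eps = rng.normal(0.0, 1.0, size=(2_000_000, 4))
        v = np.exp(eps).mean(axis=1).var(ddof=1)
        oracle = np.log(0.5 * (1 + np.sqrt(1 + 4 * v)))
        assert sigma_reduced_log(1.0, 4) == pytest.approx(oracle, rel=0.01)


class TestLemma1:
    def test_affine_equality_exact_under_common_randomness(self):
        res = lemma1_gap("affine", sigma2=0.7, k=4, mc_draws=50_000, seed=3,
                         slope=3.0)
        assert res.lhs == pytest.approx(res.rhs, rel=1e-12)
        assert res.lhs == pytest.approx(9 * 0.7 / 4, rel=0.05)

    def test_exp_transform_average_first_wins(self):
        res = lemma1_gap("exp", sigma2=1.0, k=5, mc_draws=200_000, seed=4)
        assert res.lhs < res.rhs
        assert (res.rhs - res.lhs) / res.gap_se > 5

    def test_cube_transform_average_first_wins(self):
        res = lemma1_gap("cube", sigma2=0.5, k=3, mc_draws=200_000, seed=5,
                         omega=1.0)
        assert res.lhs <= res.rhs + 2 * res.gap_se

    def test_unknown_transform(self):
        with pytest.raises(InvalidSpecError):
            lemma1_gap("sine", 1.0, 3)


class TestConditionalErrorVariance:
    def test_symmetric_case(self):
        assert conditional_error_variance(1.0, 1.0, 1) == pytest.approx(0.5)

    def test_printed_formula_value(self):
        assert conditional_error_variance(2.0, 3.0, 4) == pytest.approx(6 / 14)

    def test_limits_and_bounds(self):
        assert conditional_error_variance(1.0, 1.0, 10**9) == pytest.approx(
            0.0, abs=1e-8
        )
        for k in (1, 2, 5):
            v = conditional_error_variance(2.0, 3.0, k)
            assert v <= min(2.0 / k, 3.0) + 1e-12
        # decreasing in k, increasing in sigmaV2
        assert conditional_error_variance(2.0, 3.0, 2) < conditional_error_variance(
            2.0, 3.0, 1
        )
        assert conditional_error_variance(1.0, 3.0, 2) < conditional_error_variance(
            2.0, 3.0, 2
        )

    def test_conjugate_normal_mc_oracle(self):
        """Regression residual variance of Vbar on Xbar* matches the closed form."""
        rng = np.random.default_rng(11)
        n = 500_000
        sv2, sx2, k = 2.0, 3.0, 4
        X = rng.normal(0.0, np.sqrt(sx2), n)
        Vbar = rng.normal(0.0, np.sqrt(sv2 / k), n)
        Xbar = X + Vbar
        slope = np.cov(Vbar, Xbar)[0, 1] / Xbar.var()
        resid = Vbar - slope * Xbar
        assert conditional_error_variance(sv2, sx2, k) == pytest.approx(
            resid.var(), rel=0.02
        )

    def test_degenerate_inputs(self):
        with pytest.raises(DomainError):
            conditional_error_variance(0.0, 0.0, 1)
        with pytest.raises(InvalidSpecError):
            conditional_error_variance(1.0, 1.0, 0)


class TestMseScaling:
    @staticmethod
    def _records(sigmaY2, C1, C2, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for n in (1000, 4000, 16000):
            for k in (1, 2, 4, 8):
                mse = sigmaY2 + C1 / k + C2 / n + rng.normal(scale=noise)
                rows.append({"n": n, "k": k, "value": mse})
        return pd.DataFrame(rows)

    def test_exact_recovery(self):
        fit = fit_mse_scaling(self._records(1.0, 10.0, 500.0))
        assert fit.sigmaY2_hat == pytest.approx(1.0, abs=1e-6)
        assert fit.C1_hat == pytest.approx(10.0, abs=1e-6)
        assert fit.C2_hat == pytest.approx(500.0, abs=1e-3)

    def test_noisy_recovery(self):
        fit = fit_mse_scaling(self._records(1.0, 10.0, 500.0, noise=0.05, seed=4))
        assert fit.sigmaY2_hat == pytest.approx(1.0, abs=0.3)
        assert fit.C1_hat == pytest.approx(10.0, rel=0.2)

    def test_flat_records_put_everything_in_floor(self):
        df = self._records(3.3, 0.0, 0.0)
        fit = fit_mse_scaling(df)
        assert fit.sigmaY2_hat == pytest.approx(3.3, abs=1e-8)
        assert fit.C1_hat == pytest.approx(0.0, abs=1e-8)
        assert fit.C2_hat == pytest.approx(0.0, abs=1e-5)

    def test_degenerate_design_rejected(self):
        df = pd.DataFrame({"n": [100, 100], "k": [1, 2], "value": [1.0, 2.0]})
        with pytest.raises(InvalidSpecError):
            fit_mse_scaling(df)

    def test_prediction_consistent_with_fit(self):
        fit = fit_mse_scaling(self._records(1.0, 10.0, 500.0))
        assert fit.predict(1000, 2) == pytest.approx(1 + 5 + 0.5, abs=1e-5)


class TestTradeoffTable:
    def test_rows_follow_budget_and_monotone_floor(self):
        df = tradeoff_table(2.0, 3.0, budget=40, k_values=(1, 2, 4, 5, 8))
        assert (df.n * df.k == 40).all()
        assert df.cond_error_var.is_monotonic_decreasing
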