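import numpy as np
import pytest

from mepsim.errors import DomainError, InvalidSpecError
from mepsim.synthetic_data import (
    ErrorModelSpec,
    OutcomeModelSpec,
    draw_replicates,
    generate_outcome,
    make_scenario,
    mean_response,
    simulate_dataset,
    true_usual_intake,
)
from mepsim.transforms import boxcox


class TestErrorModelSpec:
    def test_rejects_non_psd_covariance(self):
        with pytest.raises(InvalidSpecError):
            ErrorModelSpec(
                p=2, q=0, lambda_bc=1.0, beta0=np.zeros(2), betaZ=np.zeros((2, 0)),
                Sigma_u=np.array([[1.0, 2.0], [2.0, 1.0]]),  # eigenvalue -1
                Sigma_eps=np.eye(2),
            )

    def test_rejects_asymmetric_covariance(self):
        with pytest.raises(InvalidSpecError):
            ErrorModelSpec(
                p=2, q=0, lambda_bc=1.0, beta0=np.zeros(2), betaZ=np.zeros((2, 0)),
                Sigma_u=np.array([[1.0, 0.5], [0.2, 1.0]]), Sigma_eps=np.eye(2),
            )

    def test_rejects_bad_counts(self):
        with pytest.raises(InvalidSpecError):
            ErrorModelSpec(
                p=0, q=0, lambda_bc=1.0, beta0=[], betaZ=np.zeros((0, 0)),
                Sigma_u=np.zeros((0, 0)), Sigma_eps=np.zeros((0, 0)),
            )


class TestDrawReplicates:
    def test_zero_variance_degenerate(self):
        spec = ErrorModelSpec(
            p=2, q=0, lambda_bc=1.0, beta0=np.array([36.0, 27.5]),
            betaZ=np.zeros((2, 0)), Sigma_u=np.zeros((2, 2)),
            Sigma_eps=np.zeros((2, 2)), observation="identity",
        )
        Xstar, u = draw_replicates(spec, n=5, k=3, seed=0)
        np.testing.assert_allclose(Xstar[:, 0, :], 36.0)
        np.testing.assert_allclose(Xstar[:, 1, :], 27.5)
        np.testing.assert_allclose(u, 0.0)

    def test_additive_scale_total_covariance(self, sim1_scenario):
        """Law of total covariance: cov of f(X*) across persons is
        Sigma_u + Sigma_eps."""
        spec = sim1_scenario.error
        Xstar, _ = draw_replicates(spec, n=60_000, k=1, seed=7)
        add = boxcox(Xstar[:, :, 0], 0.35)
        cov = np.cov(add.T)
        expected = spec.Sigma_u + spec.Sigma_eps
        np.testing.assert_allclose(cov, expected, rtol=0.05)

    def test_within_person_covariance_is_sigma_u(self, sim1_scenario):
        spec = sim1_scenario.error
        Xstar, _ = draw_replicates(spec, n=60_000, k=2, seed=8)
        add = boxcox(Xstar, 0.35)
        c = np.cov(add[:, 0, 0], add[:, 0, 1])[0, 1]
        assert c == pytest.approx(spec.Sigma_u[0, 0], rel=0.08)

    def test_replicates_share_person_effect(self, identity_spec):
        """With no day error, all replicates of a person coincide."""
        spec = ErrorModelSpec(
            p=2, q=0, lambda_bc=1.0, beta0=identity_spec.beta0,
            betaZ=np.zeros((2, 0)), Sigma_u=identity_spec.Sigma_u,
            Sigma_eps=np.zeros((2, 2)), observation="identity",
        )
        Xstar, u = draw_replicates(spec, n=50, k=4, seed=1)
        assert np.ptp(Xstar, axis=2).max() == 0.0

    def test_replicate_mean_converges_to_truth(self, identity_spec):
        """In classical additive mode the per-person replicate mean is a
        consistent estimate of usual intake as days accumulate."""
        Xstar, u = draw_replicates(identity_spec, n=200, k=3000, seed=2)
        truth = identity_spec.beta0[None, :] + u
        gap = np.abs(Xstar.mean(axis=2) - truth).max()
        # within-person sd <= sqrt(0.5); mean of 3000 days has sd ~ 0.013
        assert gap < 0.08

    def test_requires_finite_covariates(self, identity_spec):
        spec = ErrorModelSpec(
            p=2, q=1, lambda_bc=1.0, beta0=identity_spec.beta0,
            betaZ=np.ones((2, 1)), Sigma_u=identity_spec.Sigma_u,
            Sigma_eps=identity_spec.Sigma_eps, observation="identity",
        )
        with pytest.raises(InvalidSpecError):
            draw_replicates(spec, n=2, k=1, Z=np.array([[1.0], [np.inf]]), seed=0)


class TestTrueUsualIntake:
    def test_identity_mode_is_exact_linear(self):
        spec = ErrorModelSpec(
            p=1, q=1, lambda_bc=1.0, beta0=[5.0], betaZ=[[2.0]],
            Sigma_u=[[1.0]], Sigma_eps=[[3.0]], observation="identity",
        )
        x = true_usual_intake(spec, Z_row=[1.5], u_row=[0.7])
        assert x[0] == pytest.approx(5.0 + 3.0 + 0.7)

    def test_log_transform_matches_lognormal_mean(self):
        sigma2 = 0.49
        spec = ErrorModelSpec(
            p=1, q=0, lambda_bc=0.0, beta0=[1.2], betaZ=np.zeros((1, 0)),
            Sigma_u=[[1.0]], Sigma_eps=[[sigma2]], observation="boxcox",
        )
        x = true_usual_intake(spec, u_row=[0.4])
        assert x[0] == pytest.approx(np.exp(1.6) * np.exp(sigma2 / 2), rel=1e-10)

    def test_quadrature_matches_monte_carlo(self, sim1_scenario):
        spec = sim1_scenario.error
        u = np.array([3.0, -2.0])
        x = true_usual_intake(spec, u_row=u)
        rng = np.random.default_rng(99)
        eps = rng.multivariate_normal(np.zeros(2), spec.Sigma_eps, size=10_000_000)
        for l in range(2):
            arg = np.clip(0.35 * (spec.beta0[l] + u[l] + eps[:, l]) + 1, 0, None)
            mc = np.mean(arg ** (1 / 0.35))
            assert x[l] == pytest.approx(mc, rel=1e-3)


class TestGenerateOutcome:
    def test_ratio_map_exact_with_printed_coefficients(self):
        spec = OutcomeModelSpec(
            link="identity", feature_map="ratio", alpha=[98.5, 4.0], sigmaY2=0.0
        )
        y = generate_outcome(spec, X=np.array([[3.0, 3.0]]), seed=0)
        assert y[0] == pytest.approx(102.5)

    def test_threshold_indicator_cancellation(self):
        spec = make_scenario("sim4").outcome
        p = mean_response(spec, X=np.array([[100.0, 30.0, 30.0]]))
        from scipy.special import expit

        assert p[0] == pytest.approx(expit(-1 + 0.25 * np.log(30.0)))

    def test_expit_no_signal_balanced(self):
        spec = OutcomeModelSpec(
            link="expit", feature_map="linear", alpha=[0.0, 0.0]
        )
        y = generate_outcome(spec, X=np.zeros((40_000, 1)), seed=3)
        assert y.mean() == pytest.approx(0.5, abs=0.02)

    def test_identity_zero_noise_is_deterministic(self):
        spec = OutcomeModelSpec(
            link="identity", feature_map="linear", alpha=[1.0, 2.0], sigmaY2=0.0
        )
        X = np.arange(5.0).reshape(-1, 1)
        y1 = generate_outcome(spec, X, seed=1)
        y2 = generate_outcome(spec, X, seed=2)
        np.testing.assert_array_equal(y1, y2)
        np.testing.assert_allclose(y1, 1.0 + 2.0 * X[:, 0])

    def test_log_of_nonpositive_intake_raises(self):
        spec = make_scenario("sim4").outcome
        with pytest.raises(DomainError):
            mean_response(spec, X=np.array([[100.0, 30.0, -1.0]]))

    def test_alpha_length_validated(self):
        spec = OutcomeModelSpec(
            link="identity", feature_map="ratio", alpha=[1.0, 2.0, 3.0]
        )
        with pytest.raises(InvalidSpecError):
            mean_response(spec, X=np.ones((2, 2)))


class TestScenarioCatalogue:
    def test_sim1_printed_parameters(self):
        scn = make_scenario("sim1")
        assert scn.error.Sigma_eps[0, 0] == 38.0
        assert scn.error.Sigma_u[0, 1] == 15.5
        np.testing.assert_allclose(scn.error.lambda_bc, 0.35)
        np.testing.assert_allclose(scn.error.beta0, [36.0, 27.5])
        np.testing.assert_allclose(scn.outcome.alpha, [98.5, 4.0])
        assert scn.outcome.sigmaY2 == 1.0

    def test_sim2_differs_only_in_lambda(self):
        s1, s2 = make_scenario("sim1"), make_scenario("sim2")
        np.testing.assert_allclose(s2.error.lambda_bc, 0.5)
        np.testing.assert_array_equal(s1.error.Sigma_u, s2.error.Sigma_u)
        np.testing.assert_array_equal(s1.error.Sigma_eps, s2.error.Sigma_eps)
        np.testing.assert_array_equal(s1.outcome.alpha, s2.outcome.alpha)

    def test_sim4_threshold_coefficients(self):
        scn = make_scenario("sim4")
        np.testing.assert_allclose(scn.outcome.alpha, [-1.0, 1 / 30, 0.25])
        assert scn.error.observation == "identity"
        assert scn.k == 2

    def test_unknown_scenario(self):
        with pytest.raises(InvalidSpecError):
            make_scenario("sim99")

    def test_overrides_routed_to_specs(self):
        scn = make_scenario("sim1", overrides={"lambda_bc": 0.2, "sigmaY2": 4.0})
        np.testing.assert_allclose(scn.error.lambda_bc, 0.2)
        assert scn.outcome.sigmaY2 == 4.0
        with pytest.raises(InvalidSpecError):
            make_scenario("sim1", overrides={"nonsense": 1})


class TestSimulateDataset:
    def test_same_seed_bit_identical(self, sim1_scenario):
        a = simulate_dataset(sim1_scenario, 200, 3, seed=42)
        b = simulate_dataset(sim1_scenario, 200, 3, seed=42)
        np.testing.assert_array_equal(a.Y, b.Y)
        np.testing.assert_array_equal(a.Xstar, b.Xstar)
        np.testing.assert_array_equal(a.Xtrue, b.Xtrue)

    def test_shapes_and_positivity(self, sim1_scenario):
        ds = simulate_dataset(sim1_scenario, 150, 4, seed=5)
        assert ds.Xstar.shape == (150, 2, 4)
        assert ds.Xtrue.shape == (150, 2)
        assert ds.Xstar.min() > 0

    def test_frame_round_trip_columns(self, sim1_scenario):
        ds = simulate_dataset(sim1_scenario, 10, 2, seed=5)
        frame = ds.to_frame()
        assert list(frame.columns) == [
            "y", "x1_rep1", "x1_rep2", "x2_rep1", "x2_rep2", "xtrue1", "xtrue2",
        ]
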