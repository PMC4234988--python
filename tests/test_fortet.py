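import numpy as np
import pytest
from scipy.integrate import solve_ivp

import sinlif as sl
from sinlif.model import ModelParams


class TestDeterministicVoltage:
    def test_starts_at_zero(self, critical):
        for phi in [0.0, 1.0, np.pi]:
            assert sl.deterministic_voltage(critical, phi, 0.0) == pytest.approx(0.0, abs=1e-14)

    def test_unforced_closed_form(self):
        m = ModelParams(alpha=1.4, beta=0.3, gamma=0.0, Omega=1.0)
        assert sl.deterministic_voltage(m, 0.0, 1.0) == pytest.approx(
            1.4 * (1 - np.exp(-1)), abs=1e-12
        )

    def test_matches_ode_oracle(self, critical):
        phi = np.pi / 2

        def rhs(t, y):
            return [critical.alpha - y[0] + critical.gamma * np.sin(critical.Omega * (t + phi))]

        sol = solve_ivp(rhs, (0, 2.0), [0.0], rtol=1e-11, atol=1e-13, dense_output=True)
        assert sl.deterministic_voltage(critical, phi, 2.0) == pytest.approx(
            float(sol.y[0, -1]), abs=1e-8
        )

    def test_moving_threshold_starts_at_one(self, critical):
        assert sl.moving_threshold(critical, 0.3, 0.0) == pytest.approx(1.0)


class TestTransitionCdf:
    def test_median_at_zero(self):
        for t in [0.1, 1.0, 10.0]:
            assert sl.transition_cdf(0.3, 0.0, t, 0.0, 0.0) == pytest.approx(0.5)

    def test_stationary_one_sigma(self):
        # long-horizon law is N(0, beta^2/2); one s.d. above gives Phi(1)
        beta = 0.3
        val = sl.transition_cdf(beta, beta / np.sqrt(2), 50.0, 0.7, 0.0)
        assert val == pytest.approx(0.8413, abs=1e-4)

    def test_cdf_limits(self):
        assert sl.transition_cdf(0.3, 50.0, 1.0, 0.0, 0.0) == pytest.approx(1.0)
        assert sl.transition_cdf(0.3, -50.0, 1.0, 0.0, 0.0) == pytest.approx(0.0)

    def test_rejects_nonpositive_lag(self):
        with pytest.raises(ValueError):
            sl.transition_cdf(0.3, 0.0, 1.0, 0.0, 1.0)


@pytest.fixture(scope="module")
def fixed_phase_sample(critical):
    return sl.fixed_phase_isis(critical, np.pi / 2, 2000, seed=77)


class TestFortetResidual:
    def test_small_at_true_parameters(self, critical, fixed_phase_sample):
        r = sl.fortet_residual(fixed_phase_sample, critical, np.pi / 2)
        assert r < 0.08

    def test_grows_under_alpha_perturbation(self, critical, fixed_phase_sample):
        r0 = sl.fortet_residual(fixed_phase_sample, critical, np.pi / 2)
        mp = ModelParams(alpha=critical.alpha + 0.3, beta=critical.beta,
                         gamma=critical.gamma, Omega=critical.Omega)
        assert sl.fortet_residual(fixed_phase_sample, mp, np.pi / 2) > r0

    def test_normalized_residual_in_unit_interval(self, critical, fixed_phase_sample):
        """The sup|LHS| normalizer keeps the residual within [0, 1] wherever
        the threshold-exceedance probability is non-negligible; for trial
        parameters that essentially never reach threshold the ratio may
        exceed 1 (and usefully repels the optimizer)."""
        s_probe = np.linspace(0.05, fixed_phase_sample.max(), 200)
        for a in [0.1, 0.5, 1.4]:
            for b in [0.1, 0.3, 0.8]:
                m = ModelParams(alpha=a, beta=b, gamma=0.7, Omega=1.0)
                bth = np.asarray(sl.moving_threshold(m, np.pi / 2, s_probe))
                lhs = 1.0 - np.asarray(
                    sl.transition_cdf(b, bth, s_probe, 0.0, 0.0)
                )
                r = sl.fortet_residual(fixed_phase_sample, m, np.pi / 2)
                assert r >= 0.0
                # both sides are probabilities, so |LHS - RHS| <= 1 and the
                # normalized residual is bounded by 1/sup|LHS|
                assert r <= 1.0 / np.abs(lhs).max() + 1e-9

    def test_residual_at_truth_within_unit_interval(self, critical, fixed_phase_sample):
        r = sl.fortet_residual(fixed_phase_sample, critical, np.pi / 2)
        assert 0.0 <= r <= 1.0

    def test_continuous_under_small_perturbations(self, critical, fixed_phase_sample):
        r0 = sl.fortet_residual(fixed_phase_sample, critical, np.pi / 2)
        m_eps = ModelParams(alpha=critical.alpha + 1e-6, beta=critical.beta * (1 + 1e-6),
                            gamma=critical.gamma + 1e-6, Omega=critical.Omega)
        r1 = sl.fortet_residual(fixed_phase_sample, m_eps, np.pi / 2)
        assert abs(r1 - r0) < 1e-4

    def test_empty_bin_rejected(self, critical):
        with pytest.raises(ValueError):
            sl.fortet_residual(np.array([]), critical, 0.0)


class TestFortetLoss:
    def test_single_bin_is_count_times_residual(self, critical):
        isis = sl.fixed_phase_isis(critical, np.pi, 100, seed=5)
        train_like = sl.bin_isis(isis, np.full(100, np.pi), sl.make_bins(1, 1.0))
        loss = sl.fortet_loss(train_like, critical)
        r = sl.fortet_residual(isis, critical, train_like.bins.centers[0])
        assert loss == pytest.approx(100 * r, rel=1e-9)

    def test_true_params_beat_perturbed(self, supra, supra_train):
        data = sl.bin_train(supra_train, 20)
        perturbed = ModelParams(alpha=supra.alpha + 0.5, beta=supra.beta,
                                gamma=supra.gamma, Omega=supra.Omega)
        assert sl.fortet_loss(data, supra) < sl.fortet_loss(data, perturbed)

    def test_invariant_to_within_bin_permutation(self, supra):
        rng = np.random.default_rng(0)
        isis = rng.uniform(0.3, 2.0, 50)
        bins = sl.make_bins(1, 1.0)
        a = sl.fortet_loss(sl.bin_isis(isis, np.full(50, 1.0), bins), supra)
        b = sl.fortet_loss(sl.bin_isis(rng.permutation(isis), np.full(50, 1.0), bins), supra)
        assert a == pytest.approx(b, rel=1e-12)


class TestHomogenizationTransform:
    def test_crossings_agree_pathwise(self, critical):
        """X hits 1 exactly when Y = X - v(t) hits the moving threshold
        1 - v(t): simulate both with shared noise and compare crossing
        times to one step."""
        rng = np.random.default_rng(123)
        dt = 1e-4
        phi = 0.9
        n = 60_000
        z = rng.standard_normal(n)
        sq = np.sqrt(dt)
        x, y = 0.0, 0.0
        cross_x = cross_y = None
        for k in range(n):
            s = k * dt
            drive = critical.gamma * np.sin(critical.Omega * (s + phi))
            x = x + (critical.alpha - x + drive) * dt + critical.beta * sq * z[k]
            y = y + (-y) * dt + critical.beta * sq * z[k]
            t_next = (k + 1) * dt
            if cross_x is None and x >= 1.0:
                cross_x = t_next
            if cross_y is None and y >= sl.moving_threshold(critical, phi, t_next):
                cross_y = t_next
            if cross_x is not None and cross_y is not None:
                break
        assert cross_x is not None and cross_y is not None
        # Euler discretizations of X and Y - v differ at O(dt), so allow a
        # few steps of slack around the common crossing
        assert abs(cross_x - cross_y) <= 5 * dt
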