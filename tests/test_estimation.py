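import numpy as np
import pytest
from sklearn.base import clone

import sinlif as sl
from sinlif.binning import bin_train
from sinlif.estimation import fp_loss, mle_loss
from sinlif.model import ModelParams


@pytest.fixture(scope="module")
def supra_small(supra):
    """A short train keeping PDE-loss tests cheap."""
    return sl.simulate_train(supra, 300, seed=41)


class TestFpLoss:
    def test_true_params_beat_perturbations(self, supra, supra_train):
        data = bin_train(supra_train, 20)
        base = fp_loss(data, supra)
        worse_a = ModelParams(alpha=supra.alpha + 0.3, beta=supra.beta,
                              gamma=supra.gamma, Omega=1.0)
        worse_b = ModelParams(alpha=supra.alpha, beta=2 * supra.beta,
                              gamma=supra.gamma, Omega=1.0)
        assert base < fp_loss(data, worse_a)
        assert base < fp_loss(data, worse_b)

    def test_single_isi_per_bin_is_finite(self, supra):
        isis = np.array([0.8, 1.1, 1.3])
        phases = np.array([0.5, 2.5, 4.5])
        data = sl.bin_isis(isis, phases, sl.make_bins(3, 1.0))
        assert np.isfinite(fp_loss(data, supra))

    def test_single_bin_unforced_reduces_to_plain_sup_distance(self):
        """With M=1 and gamma=0 the loss is N times the sup distance between
        one empirical survivor and one homogeneous model curve."""
        m = ModelParams(alpha=1.4, beta=0.3, gamma=0.0, Omega=1.0)
        train = sl.simulate_train(m, 200, seed=9)
        data = bin_train(train, 1)
        loss = fp_loss(data, m)
        from sinlif.estimation import NX_FIT
        t, g = sl.survivor_trace(m, data.bins.centers[0],
                                 t_max=float(train.isis.max()) + 2.0, nx=NX_FIT,
                                 t_stop_min=float(train.isis.max()))
        from sinlif.estimation import _bin_spline
        emp = _bin_spline(train.isis)(t)
        emp = np.where(np.isnan(emp), 0.0, np.clip(emp, 0, 1))
        sup = np.abs(emp - np.clip(g, 0, 1)).max()
        assert loss == pytest.approx(len(train) * sup, rel=1e-9)


class TestMleLoss:
    def test_likelihood_improves_toward_truth(self, supra, supra_small):
        data = bin_train(supra_small, 8)
        start = ModelParams(alpha=supra.alpha + 0.3, beta=supra.beta * 1.5,
                            gamma=supra.gamma, Omega=1.0)
        assert mle_loss(data, supra) < mle_loss(data, start)

    def test_floor_keeps_tail_isi_finite(self, supra):
        isis = np.array([0.5, 0.9, 25.0])  # far-tail ISI underflows density
        data = sl.bin_isis(isis, np.full(3, 1.0), sl.make_bins(1, 1.0))
        with pytest.warns(UserWarning, match="floor"):
            val = mle_loss(data, supra)
        assert np.isfinite(val)


class TestEstimators:
    def test_fit_is_deterministic(self, supra_small):
        a = sl.FortetEstimator(Omega=1.0, M=8).fit(supra_small)
        b = sl.FortetEstimator(Omega=1.0, M=8).fit(supra_small)
        assert (a.alpha_, a.beta_, a.gamma_, a.loss_) == (b.alpha_, b.beta_, b.gamma_, b.loss_)

    def test_sklearn_contract(self, supra_small):
        est = sl.FortetEstimator(Omega=1.0, M=8, maxiter=40)
        cloned = clone(est)
        assert cloned.get_params() == est.get_params()
        est.set_params(maxiter=50)
        assert est.get_params()["maxiter"] == 50
        est.fit(supra_small)
        for attr in ("alpha_", "beta_", "gamma_", "loss_", "converged_", "M_"):
            assert hasattr(est, attr)
        assert est.beta_ > 0

    def test_fortet_recovers_supra_parameters(self, supra, supra_train):
        est = sl.FortetEstimator(Omega=1.0, M=20).fit(supra_train)
        assert est.alpha_ == pytest.approx(supra.alpha, abs=0.1)
        assert est.beta_ == pytest.approx(supra.beta, abs=0.06)
        assert est.gamma_ == pytest.approx(supra.gamma, abs=0.1)

    def test_fokker_planck_recovers_supra_parameters(self, supra, supra_train):
        est = sl.FokkerPlanckEstimator(Omega=1.0, M=20).fit(supra_train)
        assert est.alpha_ == pytest.approx(supra.alpha, abs=0.1)
        assert est.beta_ == pytest.approx(supra.beta, abs=0.06)
        assert est.gamma_ == pytest.approx(supra.gamma, abs=0.1)

    def test_methods_agree_on_large_supra_sample(self, supra_train):
        """Survivor-matching and Fortet estimates from the same train should
        differ by less than the replicate spread of either method."""
        f = sl.FortetEstimator(Omega=1.0, M=20).fit(supra_train)
        p = sl.FokkerPlanckEstimator(Omega=1.0, M=20).fit(supra_train)
        assert abs(f.alpha_ - p.alpha_) < 0.06
        assert abs(f.beta_ - p.beta_) < 0.06
        assert abs(f.gamma_ - p.gamma_) < 0.08

    def test_tiny_noise_train_still_returns_finite_estimates(self):
        m = ModelParams(alpha=1.4, beta=1e-6, gamma=0.14, Omega=1.0)
        train = sl.simulate_train(m, 150, seed=3)
        est = sl.FortetEstimator(Omega=1.0, M=8, maxiter=120).fit(train)
        assert np.isfinite([est.alpha_, est.beta_, est.gamma_]).all()
        assert est.beta_ < 0.1

    def test_explicit_init_is_honored(self, supra_small):
        est = sl.FortetEstimator(Omega=1.0, M=8, init=(1.3, 0.25, 0.2),
                                 maxiter=5).fit(supra_small)
        assert est.init_params_.alpha == 1.3
        assert est.init_params_.beta == 0.25

    def test_mle_objective_runs(self, supra, supra_small):
        est = sl.FokkerPlanckEstimator(Omega=1.0, M=8, objective="mle",
                                       maxiter=60).fit(supra_small)
        assert est.result().method == "mle"
        assert est.alpha_ == pytest.approx(supra.alpha, abs=0.25)

    def test_fit_function_wrapper(self, supra_small):
        res = sl.fit(supra_small, method="fortet", M=8, seed=12)
        assert res.method == "fortet"
        assert res.seed == 12
        assert np.isfinite(res.loss_value)
        assert res.params_hat.beta > 0
        d = res.to_dict()
        assert set(d) >= {"alpha", "beta", "gamma", "loss", "method", "converged"}

    def test_unknown_method_rejected(self, supra_small):
        with pytest.raises(ValueError, match="unknown method"):
            sl.fit(supra_small, method="bogus")
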