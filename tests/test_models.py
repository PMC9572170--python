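"""Autoencoder architectures, training protocol, and anomaly-score probes."""

import math

import numpy as np
import pytest
from scipy import integrate

from relapsekit.detection import (
    ErrorDistribution,
    TrainingDiverged,
    TrainSpec,
    anomaly_score,
    error_vectors,
    fit_error_distribution,
    kl_score,
    mahalanobis,
    random_baseline,
    recon_score,
    train,
)
from relapsekit.models import ARCHITECTURES, ModelConfig, build_model
from relapsekit.nn import Tensor

SMALL = ModelConfig(cnn_filters=(8, 16, 24, 32), cae_filters=(4, 8, 12, 16))


def _spec(arch, **kw):
    base = TrainSpec.for_architecture(arch)
    return TrainSpec(**{**base.__dict__, **kw})


class TestBuildModel:
    @pytest.mark.parametrize("arch", ["fnn", "cnn", "gru", "transformer"])
    def test_sequence_autoencoder_contract(self, arch):
        model = build_model(arch, (48, 10), SMALL, seed=0)
        x = np.random.default_rng(0).random((3, 48, 10))
        out = model(Tensor(x))
        assert out.shape == (3, 48, 10)
        assert model.n_parameters() > 0

    def test_gru_hidden_size_default(self):
        model = build_model("gru", (48, 10), ModelConfig(), seed=0)
        assert model.hidden == 100

    def test_cae_reconstruction_shape(self):
        model = build_model("cae", (128, 64), SMALL, seed=0)
        out = model(Tensor(np.random.default_rng(0).random((2, 1, 128, 64))))
        assert out.shape == (2, 1, 128, 64)

    def test_cvae1d_shape(self):
        model = build_model("cvae1d", (30, 5), SMALL, seed=0)
        recon, mu, logvar = model(Tensor(np.random.default_rng(0).random((4, 30, 5))))
        assert recon.shape == (4, 30, 5)
        assert mu.shape == logvar.shape

    def test_incompatible_shape_rejected(self):
        with pytest.raises(ValueError):
            build_model("cae", (64, 64))
        with pytest.raises(ValueError):
            build_model("warp", (48, 10))


class TestKL:
    def test_standard_normal_is_zero(self):
        model = build_model("cvae1d", (30, 5), SMALL, seed=0)
        mu = Tensor(np.zeros((2, 4)))
        logvar = Tensor(np.zeros((2, 4)))
        assert np.allclose(model.kl(mu, logvar).data, 0.0)

    def test_scalar_closed_form(self):
        model = build_model("cvae1d", (30, 5), SMALL, seed=0)
        kl = model.kl(Tensor(np.array([[1.0]])), Tensor(np.array([[0.0]])))
        assert kl.data[0] == pytest.approx(0.5)

    def test_matches_quadrature_oracle(self):
        model = build_model("cvae1d", (30, 5), SMALL, seed=0)
        mus, sigmas = [0.7, -0.3], [1.4, 0.6]

        def kl_1d(mu, sigma):
            q = lambda z: math.exp(-((z - mu) ** 2) / (2 * sigma**2)) / (
                sigma * math.sqrt(2 * math.pi))
            p = lambda z: math.exp(-(z**2) / 2) / math.sqrt(2 * math.pi)
            f = lambda z: q(z) * math.log(q(z) / p(z))
            return integrate.quad(f, -12, 12)[0]

        expected = sum(kl_1d(m, s) for m, s in zip(mus, sigmas))
        got = model.kl(Tensor(np.array([mus])),
                       Tensor(np.array([[2 * math.log(s) for s in sigmas]])))
        assert got.data[0] == pytest.approx(expected, abs=1e-4)


class TestTraining:
    def _data(self, n=40):
        return np.random.default_rng(1).random((n, 16, 4))

    def test_zero_epoch_budget_returns_initial(self):
        model = build_model("fnn", (16, 4), SMALL, seed=0)
        before = [p.copy() for p in model.state()]
        model, hist = train(model, self._data(), self._data(8),
                            _spec("fnn", max_epochs=0))
        assert hist["train"] == [] and hist["val1"] == []
        assert all(np.array_equal(a, b) for a, b in zip(before, model.state()))

    def test_loss_decreases(self):
        model = build_model("fnn", (16, 4), SMALL, seed=0)
        _, hist = train(model, self._data(), self._data(8),
                        _spec("fnn", max_epochs=8, lr=1e-3))
        assert hist["train"][-1] <= hist["train"][0]

    def test_same_seed_identical_final_loss(self):
        results = []
        for _ in range(2):
            model = build_model("fnn", (16, 4), SMALL, seed=3)
            _, hist = train(model, self._data(), self._data(8),
                            _spec("fnn", max_epochs=3, seed=3))
            results.append(hist["train"][-1])
        assert results[0] == results[1]

    def test_non_finite_loss_aborts(self):
        model = build_model("fnn", (16, 4), SMALL, seed=0)
        bad = self._data()
        bad[0, 0, 0] = np.inf
        with pytest.raises(TrainingDiverged):
            train(model, bad, self._data(8), _spec("fnn", max_epochs=2))

    def test_variational_loss_is_weighted_sum(self):
        """Total CVAE loss = W_MSE * MSE + W_KL * KL exactly; W_KL = 0
        leaves the pure reconstruction objective."""
        from relapsekit.detection import _forward_loss

        model = build_model("cvae1d", (30, 5), SMALL, seed=0)
        model.eval()                      # deterministic latent (mu)
        x = np.random.default_rng(2).random((4, 30, 5))
        spec = _spec("cvae1d", w_mse=1.0, w_kl=0.01)
        total = float(_forward_loss(model, x, spec).data)
        recon, mu, logvar = model(Tensor(x))
        mse = float(((recon.data - x) ** 2).mean())
        kl = float(model.kl(mu, logvar).data.mean())
        assert total == pytest.approx(mse + 0.01 * kl, rel=1e-12)
        spec0 = _spec("cvae1d", w_kl=0.0)
        assert float(_forward_loss(model, x, spec0).data) == pytest.approx(mse, rel=1e-12)

    def test_reference_hyperparameters(self):
        assert TrainSpec.for_architecture("fnn").optimizer == "adam"
        assert TrainSpec.for_architecture("cnn").optimizer == "rmsprop"
        assert TrainSpec.for_architecture("gru").optimizer == "rmsprop"
        tr = TrainSpec.for_architecture("transformer")
        assert tr.optimizer == "adam" and tr.lr == pytest.approx(1e-3)
        assert TrainSpec.for_architecture("fnn").lr == pytest.approx(1e-4)
        assert TrainSpec.for_architecture("fnn").batch_size == 64
        assert TrainSpec.for_architecture("fnn").max_epochs == 50
        audio = TrainSpec.for_architecture("cvae")
        assert (audio.lr, audio.batch_size, audio.max_epochs,
                audio.patience) == (3e-4, 8, 200, 10)
        assert (audio.w_mse, audio.w_kl) == (1.0, 0.01)


class _IdentityModel:
    """Perfect reconstructor used to probe the error-distribution fit."""

    def eval(self):
        pass

    def __call__(self, x):
        return Tensor(x.data.copy())


class TestErrorDistribution:
    def test_perfect_reconstructor_gives_zero_mean_ridge_cov(self):
        spec = _spec("fnn")
        data = np.random.default_rng(0).random((6, 8, 3))
        errs = error_vectors(_IdentityModel(), data, spec)
        dist = fit_error_distribution(errs)
        assert np.allclose(dist.mu, 0.0)
        assert np.allclose(dist.sigma, dist.ridge * np.eye(3))

    def test_three_point_hand_arithmetic(self):
        e = np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 9.0]])
        dist = fit_error_distribution(e, ridge_scale=0.0)
        assert dist.mu == pytest.approx([3.0, 5.0])
        assert dist.sigma == pytest.approx(np.cov(e, rowvar=False))

    def test_ridge_makes_spd(self, rng):
        e = rng.standard_normal((3, 10))      # fewer points than dims
        dist = fit_error_distribution(e)
        np.linalg.cholesky(dist.sigma)        # raises if not SPD
        assert np.allclose(dist.sigma, dist.sigma.T)


class TestAnomalyScore:
    def test_zero_at_the_mean(self):
        dist = fit_error_distribution(np.random.default_rng(0).random((50, 4)))
        assert mahalanobis(dist.mu[None, :], dist)[0] == pytest.approx(0.0)

    def test_identity_covariance_is_squared_norm(self):
        dist = ErrorDistribution(mu=np.zeros(3), sigma=np.eye(3), ridge=0.0)
        e = np.array([[1.0, 2.0, 2.0]])
        assert mahalanobis(e, dist)[0] == pytest.approx(9.0)

    def test_three_dim_hand_inverse(self, rng):
        e = rng.standard_normal((40, 3))
        dist = fit_error_distribution(e)
        v = rng.standard_normal(3)
        diff = v - dist.mu
        expected = diff @ np.linalg.inv(dist.sigma) @ diff
        assert mahalanobis(v[None, :], dist)[0] == pytest.approx(expected, abs=1e-10)

    def test_permutation_invariance(self, rng):
        e = rng.standard_normal((60, 4))
        v = rng.standard_normal((5, 4))
        perm = [2, 0, 3, 1]
        d1 = fit_error_distribution(e)
        d2 = fit_error_distribution(e[:, perm])
        assert mahalanobis(v, d1) == pytest.approx(mahalanobis(v[:, perm], d2))

    def test_scores_non_negative(self, rng):
        spec = _spec("fnn")
        model = build_model("fnn", (16, 4), SMALL, seed=0)
        data = rng.random((5, 16, 4))
        dist = fit_error_distribution(error_vectors(model, data, spec))
        assert (anomaly_score(model, dist, rng.random((4, 16, 4)), spec) >= 0).all()


class TestKLScore:
    def test_requires_variational_model(self):
        model = build_model("fnn", (16, 4), SMALL, seed=0)
        with pytest.raises(TypeError):
            kl_score(model, np.zeros((2, 16, 4)))

    def test_kl_scores_finite_nonnegative(self, rng):
        model = build_model("cvae1d", (30, 5), SMALL, seed=0)
        scores = kl_score(model, rng.random((6, 30, 5)))
        assert scores.shape == (6,)
        assert (scores >= 0).all() and np.isfinite(scores).all()


class TestRandomBaseline:
    def test_validation_mean_scores_zero(self, rng):
        val = rng.standard_normal((100, 5))
        scores = random_baseline(val, val.mean(axis=0, keepdims=True))
        assert scores[0] == pytest.approx(0.0, abs=1e-10)

    def test_detects_large_shift(self, rng):
        val = rng.standard_normal((200, 5))
        near = rng.standard_normal((50, 5))
        far = rng.standard_normal((50, 5)) + 4.0
        assert random_baseline(val, far).mean() > random_baseline(val, near).mean()


class TestReconScore:
    def test_per_instance_shape(self, rng):
        model = build_model("fnn", (16, 4), SMALL, seed=0)
        scores = recon_score(model, rng.random((7, 16, 4)), _spec("fnn"))
        assert scores.shape == (7,) and (scores >= 0).all()
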