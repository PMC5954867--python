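import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import spearmanr

import eegfatigue as ef
from eegfatigue.features import BandFeatures
from eegfatigue.scoring import FatigueScorer, combined_deviation, mahalanobis
from eegfatigue.simulate import step_trajectory


def session_features(seed, duration=120.0, trajectory=None):
    cfg = ef.SimConfig(duration=duration, seed=seed)
    traj = trajectory(cfg.n_epochs) if trajectory else None
    record, labels = ef.simulate_eeg(cfg, traj)
    X = ef.extract_features(ef.epoch_stream(record, 2.0), record.sfreq)
    return X, labels


class TestMahalanobis:
    def test_zero_at_mean(self):
        assert mahalanobis([1.0, 2.0], [1.0, 2.0], np.eye(2)) == 0.0

    def test_identity_covariance_is_euclidean(self):
        assert mahalanobis([3.0, 4.0], [0.0, 0.0], np.eye(2)) == pytest.approx(5.0)

    def test_diagonal_covariance(self):
        d = mahalanobis([2.0, 1.0], [0.0, 0.0], np.diag([2.0, 1.0]))
        assert d == pytest.approx(np.sqrt(3.0), abs=1e-12)

    def test_matches_explicit_inversion(self, rng):
        """Oracle: direct inverse + quadratic form."""
        for _ in range(20):
            dim = rng.integers(2, 7)
            A = rng.normal(size=(dim, dim))
            cov = A @ A.T + dim * np.eye(dim)
            x, mu = rng.normal(size=dim), rng.normal(size=dim)
            expect = np.sqrt((x - mu) @ np.linalg.inv(cov) @ (x - mu))
            assert mahalanobis(x, mu, cov) == pytest.approx(expect, abs=1e-10)

    def test_singular_covariance_names_condition_number(self):
        with pytest.raises(np.linalg.LinAlgError, match="condition number"):
            mahalanobis([1.0, 0.0], [0.0, 0.0], np.ones((2, 2)))

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="dimension"):
            mahalanobis([1.0, 2.0, 3.0], [0.0, 0.0], np.eye(2))


class TestCombinedDeviation:
    @pytest.mark.parametrize(
        "sigma,d_alpha,d_theta,expect",
        [(1.0, 2.0, 4.0, 2.0), (0.0, 2.0, 4.0, 4.0), (0.5, 2.0, 4.0, 3.0)],
    )
    def test_convex_combination(self, sigma, d_alpha, d_theta, expect):
        assert combined_deviation(d_alpha, d_theta, sigma) == expect

    @pytest.mark.parametrize("sigma", [-0.1, 1.1])
    def test_sigma_domain(self, sigma):
        with pytest.raises(ValueError, match="sigma"):
            combined_deviation(1.0, 1.0, sigma)

    @given(
        st.floats(0, 1),
        st.floats(0, 100, allow_nan=False),
        st.floats(0, 100, allow_nan=False),
    )
    def test_bounded_by_components(self, sigma, d_alpha, d_theta):
        d_c = combined_deviation(d_alpha, d_theta, sigma)
        assert min(d_alpha, d_theta) - 1e-12 <= d_c <= max(d_alpha, d_theta) + 1e-12


class TestFitBaseline:
    def test_identical_vectors_give_diagonal_positive_cov(self):
        X = np.tile([1.0, 2.0, 3.0, 4.0, 5.0, 6.0], (5, 1))
        model = ef.fit_baseline(X)
        assert np.allclose(model.mu_theta_, [1, 2, 3])
        assert np.allclose(model.mu_alpha_, [4, 5, 6])
        for cov in (model.cov_theta_, model.cov_alpha_):
            assert np.allclose(cov, np.diag(np.diag(cov)))
            assert (np.linalg.eigvalsh(cov) > 0).all()

    def test_fewer_epochs_than_bins_still_invertible(self, rng):
        """Shrinkage keeps the covariance conditioned when n < dim."""
        X = rng.normal(size=(2, 6))
        model = ef.fit_baseline(X, shrinkage=0.1)
        for cov in (model.cov_theta_, model.cov_alpha_):
            eigs = np.linalg.eigvalsh(cov)
            assert eigs.min() > 0
            assert np.isfinite(eigs.max() / eigs.min())

    def test_insufficient_epochs_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            ef.fit_baseline(np.zeros((1, 6)))

    def test_deterministic_from_seeded_simulation(self):
        Xa, _ = session_features(31, duration=60.0)
        Xb, _ = session_features(31, duration=60.0)
        ma, mb = ef.fit_baseline(Xa[:20]), ef.fit_baseline(Xb[:20])
        assert np.array_equal(ma.mu_alpha_, mb.mu_alpha_)
        assert np.array_equal(ma.cov_theta_, mb.cov_theta_)

    def test_from_band_features_objects(self):
        feats = [
            BandFeatures(np.array([1.0, 2, 3]), np.array([4.0, 5, 6]), i)
            for i in range(3)
        ]
        model = ef.fit_baseline(feats)
        assert model.n_epochs_used_ == 3


class TestFatigueScorer:
    def test_baseline_mean_scores_zero(self, alert_feature_matrix):
        model = ef.fit_baseline(alert_feature_matrix[:30])
        x = np.concatenate([model.mu_theta_, model.mu_alpha_])
        assert model.transform(x[None, :])[0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_gaussian_baseline_scores_bounded(self, rng):
        """Monte-Carlo oracle: mean D_C on the baseline's own Gaussian
        features stays near sqrt(dim)."""
        X = rng.normal(size=(200, 6))
        model = ef.fit_baseline(X)
        d_c = model.transform(X)[:, 0]
        assert d_c.mean() < 3 * np.sqrt(3)

    def test_affine_invariance(self, rng):
        """Invertible feature maps leave Mahalanobis distances unchanged."""
        for _ in range(5):
            A = rng.normal(size=(3, 3)) + 3 * np.eye(3)
            S = rng.normal(size=(3, 3))
            cov = S @ S.T + np.eye(3)
            mu, x = rng.normal(size=3), rng.normal(size=3)
            d0 = mahalanobis(x, mu, cov)
            d1 = mahalanobis(A @ x, A @ mu, A @ cov @ A.T)
            assert d1 == pytest.approx(d0, abs=1e-8)

    def test_drift_ramp_correlates_with_score(self):
        X, _ = session_features(3, trajectory=lambda n: np.linspace(0, 1, n))
        model = ef.fit_baseline(X[:10])
        d_c = model.transform(X)[:, 0]
        rho = spearmanr(np.linspace(0, 1, len(d_c)), d_c).statistic
        assert rho > 0.8

    def test_step_change_raises_mean_score(self):
        """Post-step mean D_C exceeds pre-step mean in >=95% of seeded runs."""
        wins = 0
        seeds = range(20)
        for seed in seeds:
            X, _ = session_features(
                seed, duration=60.0, trajectory=lambda n: step_trajectory(n, n // 2)
            )
            model = ef.fit_baseline(X[: len(X) // 2])
            d_c = model.transform(X)[:, 0]
            half = len(d_c) // 2
            wins += d_c[half:].mean() > d_c[:half].mean()
        assert wins >= 0.95 * len(list(seeds))

    def test_score_epoch_fields_consistent(self, alert_feature_matrix):
        model = ef.fit_baseline(alert_feature_matrix[:30])
        feats = BandFeatures(
            alert_feature_matrix[40, :3], alert_feature_matrix[40, 3:], epoch_index=40
        )
        score = ef.score_epoch(feats, model, sigma=0.3)
        assert score.d_c == pytest.approx(
            0.3 * score.d_alpha + 0.7 * score.d_theta, abs=1e-12
        )
        assert min(score.d_alpha, score.d_theta) <= score.d_c <= max(
            score.d_alpha, score.d_theta
        )

    def test_json_round_trip(self, alert_feature_matrix, tmp_path):
        model = ef.fit_baseline(alert_feature_matrix[:30])
        path = tmp_path / "baseline.json"
        model.to_json(path)
        back = FatigueScorer.from_json(path)
        assert np.allclose(back.transform(alert_feature_matrix),
                           model.transform(alert_feature_matrix))

    def test_sklearn_params(self):
        model = FatigueScorer(sigma=0.25)
        assert model.get_params()["sigma"] == 0.25
        model.set_params(shrinkage=0.2)
        assert model.shrinkage == 0.2

    def test_sigma_out_of_range_rejected(self, alert_feature_matrix):
        with pytest.raises(ValueError, match="sigma"):
            FatigueScorer(sigma=1.5).fit(alert_feature_matrix[:10])
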