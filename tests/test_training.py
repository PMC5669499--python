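import numpy as np
import pytest

from fovod import features as F
from fovod.detector import init_components
from fovod.training import (CovarianceError, TrainConfig, _inner_solve,
                            cluster_shapes, estimate_global_stats,
                            lda_template, pooled_stats,
                            stats_from_feature_maps, assign_latents,
                            warped_positive_mean)
from fovod.evaluation import iou  # noqa: F401
from fovod.synthetic import glyph_mask


class TestGlobalStats:
    def test_white_noise_diagonal_recovery(self):
        rng = np.random.default_rng(0)
        var = np.array([1.0, 4.0, 0.25, 9.0])
        maps = [rng.standard_normal((50, 50, 4)) * np.sqrt(var)
                for _ in range(4)]
        stats = stats_from_feature_maps(maps, (3, 3), ridge_frac=0.0)
        diag = np.diag(stats.gamma[2, 2])
        np.testing.assert_allclose(diag, var, rtol=0.10)
        # off-offset correlation near zero for white noise
        scale = np.sqrt(np.outer(var, var))
        assert (np.abs(stats.gamma[2, 3]) / scale).max() < 0.05

    def test_rank_deficient_without_ridge_raises(self):
        rng = np.random.default_rng(1)
        # 108 cell samples < 279 template dimensions, no ridge
        base = rng.standard_normal(31)
        maps = [np.tile(base, (6, 9, 1)) + 1e-6 * rng.standard_normal((6, 9, 31))
                for _ in range(2)]
        stats = stats_from_feature_maps(maps, (3, 3), ridge_frac=0.0)
        with pytest.raises(CovarianceError):
            stats.build_cov(3, 3, ridge=0.0)

    def test_stationarity_under_cell_shift(self):
        rng = np.random.default_rng(2)
        m = rng.standard_normal((60, 60, 5))
        s1 = stats_from_feature_maps([m], (3, 3))
        s2 = stats_from_feature_maps([m[:, 5:]], (3, 3))
        np.testing.assert_allclose(s1.gamma[2, 2], s2.gamma[2, 2], atol=0.15)

    def test_block_toeplitz_assembly(self):
        rng = np.random.default_rng(3)
        maps = [rng.standard_normal((30, 30, 3)) for _ in range(3)]
        stats = stats_from_feature_maps(maps, (2, 2))
        cov = stats.build_cov(2, 2, ridge=0.0, check=False)
        # block (cell0, cell3) is the (dy=1, dx=1) autocovariance
        np.testing.assert_allclose(cov[0:3, 9:12], stats.gamma[2, 2],
                                   atol=1e-12)

    def test_insufficient_samples_rejected(self):
        with pytest.raises(ValueError):
            stats_from_feature_maps([np.zeros((5, 5, 3))], (2, 2))


class TestLdaTemplate:
    def test_identity_covariance_gives_mean_difference(self):
        mu1 = np.arange(6.0)
        mu0 = np.ones(6)
        w = lda_template(np.eye(6), mu1, mu0)
        np.testing.assert_allclose(w, mu1 - mu0)

    def test_equal_means_give_zero(self):
        w = lda_template(np.eye(4), np.ones(4), np.ones(4))
        np.testing.assert_allclose(w, 0.0)

    def test_two_gaussian_closed_form_direction(self):
        rng = np.random.default_rng(4)
        A = rng.standard_normal((2, 2))
        cov_true = A @ A.T + 0.5 * np.eye(2)
        mu1, mu0 = np.array([1.0, 2.0]), np.array([-1.0, 0.5])
        L = np.linalg.cholesky(cov_true)
        x1 = mu1 + (L @ rng.standard_normal((2, 1000))).T
        x0 = mu0 + (L @ rng.standard_normal((2, 1000))).T
        pooled = np.cov(np.vstack([x1 - x1.mean(0), x0 - x0.mean(0)]).T)
        w = lda_template(pooled, x1.mean(0), x0.mean(0))
        w_true = np.linalg.solve(cov_true, mu1 - mu0)
        cos = w @ w_true / (np.linalg.norm(w) * np.linalg.norm(w_true))
        assert cos >= 0.99


class TestPooledStats:
    def test_identity_pooling_recovers_foveal_covariance(self, field52):
        rng = np.random.default_rng(5)
        maps = [rng.standard_normal((40, 40, 31)) for _ in range(2)]
        stats = stats_from_feature_maps(maps, (3, 3))
        comps = init_components([(3, 3)], field52, shapes_in_cells=True)
        fov = next(c for c in comps if c.is_foveal)
        cov_fov = stats.build_cov(3, 3)
        sig_t, mu_neg = pooled_stats(stats, fov, field52, cov_fov)
        # permutation congruence: same eigenvalues, same diagonal blocks set
        np.testing.assert_allclose(np.sort(np.linalg.eigvalsh(sig_t)),
                                   np.sort(np.linalg.eigvalsh(
                                       cov_fov + (stats.ridge()) * np.eye(
                                           cov_fov.shape[0]))), rtol=1e-8)
        np.testing.assert_allclose(mu_neg, np.tile(stats.mu, (9, 1)))

    def test_matches_kronecker_oracle_and_is_psd(self, field52):
        rng = np.random.default_rng(6)
        maps = [rng.standard_normal((40, 40, 31)) for _ in range(2)]
        stats = stats_from_feature_maps(maps, (3, 3))
        comps = init_components([(3, 3)], field52, shapes_in_cells=True)
        per = next(c for c in comps if not c.is_foveal)
        cov_fov = stats.build_cov(3, 3)
        sig_t, _ = pooled_stats(stats, per, field52, cov_fov)
        P = np.kron(per.pooling.spatial.toarray(), np.eye(31))
        oracle = P @ cov_fov @ P.T
        oracle[np.diag_indices_from(oracle)] += stats.ridge()
        np.testing.assert_allclose(sig_t, 0.5 * (oracle + oracle.T),
                                   atol=1e-10)
        assert np.linalg.eigvalsh(sig_t).min() > 0


class TestCalibrationSolver:
    def test_separable_problem_reaches_zero_hinge(self):
        # one group, positives at r=+2, background mean response m=-2
        t_group = np.array([0])
        t_norm2 = np.array([1.0])
        t_m = np.array([-2.0])
        pos_group = np.zeros(5, dtype=int)
        pos_r = np.full(5, 2.0)
        cw = np.array([5.0 * 50.0])
        obj, a, b = _inner_solve(np.ones(1), np.zeros(1), 50.0, cw,
                                 t_group, t_norm2, t_m, pos_group, pos_r,
                                 1, 400, 0.5)
        assert a[0] > 0
        assert 1 - (a[0] * 2 + b[0]) <= 1e-2        # positive margin met
        assert 1 + (a[0] * -2 + b[0]) <= 1e-2       # negative margin met

    def test_regularizer_only_drives_alpha_to_zero(self):
        t_group = np.array([0])
        t_norm2 = np.array([1.0])
        t_m = np.array([0.0])
        obj, a, b = _inner_solve(np.ones(1), np.ones(1), 0.0, np.zeros(1),
                                 t_group, t_norm2, t_m,
                                 np.zeros(0, dtype=int), np.zeros(0),
                                 1, 300, 0.5)
        assert abs(a[0]) < 0.05 and abs(b[0]) < 0.05


class TestTrainedModel:
    def test_objective_trace_non_increasing(self, small_trained):
        trace = small_trained["model"].meta["objective_trace"]
        assert len(trace) >= 1
        assert all(a >= b - 1e-8 for a, b in zip(trace, trace[1:]))

    def test_alphas_nonnegative_and_calibration_preserves_direction(
            self, small_trained):
        model = small_trained["model"]
        for c in model.components:
            assert c.alpha >= 0
            # compiled template is exactly alpha * (P^T w_lda)
            eff = (c.pooling.spatial.T
                   @ (c.alpha * c.w_lda.reshape(c.n_regions, 31)))
            np.testing.assert_allclose(
                c.w_eff, eff.reshape(c.p_cells, c.k_cells, 31), atol=1e-12)

    def test_two_viewpoint_shapes_from_aspect_clustering(self, small_trained):
        shapes = small_trained["model"].shapes
        aspects = [k / p for p, k in shapes]
        assert len(shapes) == 2
        assert (min(aspects) < 1.0) and (max(aspects) > 1.0)

    def test_assign_latents_returns_admissible_placement(self, small_trained):
        model = small_trained["model"]
        img, box = small_trained["positives"][0]
        out = assign_latents(model, img, box, small_trained["config"])
        assert out is not None
        sigma, comp, f = out
        assert sigma in [s for s, _ in model.pyramid_of(img)]
        assert 0 <= f[0] < img.shape[1] and 0 <= f[1] < img.shape[0]

    def test_warped_positive_mean_tracks_clean_glyph(self, small_trained):
        """A clean rendered glyph correlates with the learned appearance."""
        model = small_trained["model"]
        positives = small_trained["positives"]
        cfg = small_trained["config"]
        shapes, labels = cluster_shapes(
            np.array([np.asarray(b, dtype=float)[:2] for _, b in positives]),
            cfg)
        mu = warped_positive_mean(positives, labels, shapes,
                                  context_frac=cfg.context_frac)
        s = int(np.argmax([k / p for p, k in shapes]))  # wide cluster
        pad = cfg.context_frac
        # independent single-glyph scenes with the generator's background
        # statistics give the reference mean appearance
        from fovod.synthetic import one_over_f_noise
        gw, gh = 112, 80
        fresh = []
        for i in range(8):
            rng = np.random.default_rng(100 + i)
            img = 0.45 + one_over_f_noise((gh * 2, gw * 2), rng, 0.07)
            y0, x0 = gh // 2, gw // 2
            m = glyph_mask("wedge", 0, gw, gh)
            img[y0:y0 + gh, x0:x0 + gw][m] = 1.0
            fresh.append((np.clip(img, 0, 1), (gw, gh, x0, y0)))
        clean = warped_positive_mean(fresh, [s] * len(fresh), shapes,
                                     context_frac=pad)[s]
        corr = np.corrcoef(mu[s].ravel(), clean.ravel())[0, 1]
        assert corr > 0.8


def test_train_requires_positives_and_negatives(default_field):
    from fovod.training import train_fod
    with pytest.raises(ValueError):
        train_fod([], [np.zeros((64, 64))], default_field)
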