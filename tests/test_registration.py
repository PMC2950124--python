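import numpy as np
import pytest

from microtem import registration as reg
from microtem import synthetic_data as syn


def _solve_planted(spec):
    """Solve a generated mosaic from its exact correspondences."""
    res = syn.generate_mosaic(spec)
    init = {
        t: reg.RigidTransform2D(0.0, np.array(res.nominal_offsets[t]))
        for t in res.true_transforms
    }
    sol = reg.solve_montage(
        list(res.true_transforms), res.correspondences, res.anchor_tile, initial=init
    )
    return res, sol


class TestMLSWarp:
    def test_identity_when_before_equals_after(self, rng):
        pts = rng.uniform(0, 100, (6, 2))
        warp = reg.fit_section_warp(pts, pts)
        grid = np.stack(np.meshgrid(np.linspace(0, 100, 9), np.linspace(0, 100, 9)), -1).reshape(-1, 2)
        assert np.abs(warp.apply(grid) - grid).max() < 1e-9

    def test_single_control_point_rigid_is_pure_translation(self):
        warp = reg.MLSWarp2D([[10.0, 10.0]], [[13.0, 7.0]], model="rigid")
        q = np.array([[0.0, 0.0], [50.0, 20.0]])
        assert np.allclose(warp.apply(q), q + [3.0, -3.0])

    def test_interpolates_control_points_exactly(self, rng):
        p = rng.uniform(0, 100, (10, 2))
        q = p + rng.uniform(-5, 5, (10, 2))
        warp = reg.fit_section_warp(p, q)
        assert np.abs(warp.apply(p) - q).max() < 1e-9

    @pytest.mark.parametrize("model", ["rigid", "affine"])
    def test_reproduces_global_rigid_motion(self, rng, model):
        ang = 0.3
        R = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        t = np.array([5.0, -3.0])
        p = rng.uniform(0, 100, (8, 2))
        warp = reg.MLSWarp2D(p, p @ R.T + t, model=model)
        v = rng.uniform(-50, 150, (20, 2))
        assert np.abs(warp.apply(v) - (v @ R.T + t)).max() < 1e-9

    def test_affine_model_reproduces_global_affine(self, rng):
        A = np.array([[1.2, 0.3], [-0.1, 0.9]])
        t = np.array([4.0, 1.0])
        p = rng.uniform(0, 100, (8, 2))
        warp = reg.MLSWarp2D(p, p @ A.T + t, model="affine")
        v = rng.uniform(0, 100, (20, 2))
        assert np.abs(warp.apply(v) - (v @ A.T + t)).max() < 1e-9

    def test_large_alpha_approaches_nearest_control_transform(self):
        # two translation clusters; far from the boundary the warp follows
        # the local (nearest) cluster's translation
        p = np.array([[0.0, 0.0], [1.0, 0.0], [100.0, 0.0], [101.0, 0.0]])
        q = p + np.array([[0, 5], [0, 5], [0, -5], [0, -5]], dtype=float)
        warp = reg.MLSWarp2D(p, q, alpha=16.0, model="rigid")
        assert np.allclose(warp.apply([[0.5, 1.0]]), [[0.5, 6.0]], atol=1e-6)
        assert np.allclose(warp.apply([[100.5, 1.0]]), [[100.5, -4.0]], atol=1e-6)

    def test_query_at_control_point_returns_target(self):
        warp = reg.MLSWarp2D([[0, 0], [10, 10]], [[1, 1], [12, 9]], model="rigid")
        assert np.allclose(warp.apply([[10.0, 10.0]]), [[12.0, 9.0]])

    def test_duplicate_sources_with_conflicting_targets_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            reg.fit_section_warp([[0, 0], [0, 0]], [[1, 1], [2, 2]])


class TestMontageSolver:
    def test_two_tiles_exact_translation(self):
        corrs = [
            reg.Correspondence("a", "b", (90.0 + d, 10.0 * k), (d, 10.0 * k))
            for k, d in enumerate([0.0, 5.0, 2.0, 8.0])
        ]
        sol = reg.solve_montage(["a", "b"], corrs, "a")
        assert np.abs(sol.transforms["b"].translation - [90.0, 0.0]).max() < 1e-6
        assert abs(sol.transforms["b"].angle) < 1e-9

    def test_recovers_planted_transforms_noise_free(self):
        res, sol = _solve_planted(syn.MosaicSpec(rows=3, cols=3, seed=3))
        for tid, truth in res.true_transforms.items():
            assert abs(sol.transforms[tid].angle - truth.angle) < 1e-6
            assert np.abs(sol.transforms[tid].translation - truth.translation).max() < 1e-6

    def test_residual_monotone_nonincreasing(self):
        _, sol = _solve_planted(syn.MosaicSpec(rows=3, cols=3, seed=5))
        h = np.array(sol.residual_history)
        assert np.all(np.diff(h) <= 1e-15)

    def test_noisy_residual_matches_least_squares_expectation(self):
        # sigma = 0.5 px on correspondence positions: mean residual <= 2 sigma^2
        sigma = 0.5
        residuals = [
            _solve_planted(
                syn.MosaicSpec(rows=3, cols=3, noise_sigma=sigma, seed=100 + rep)
            )[1].residual
            for rep in range(20)
        ]
        assert np.mean(residuals) <= 2 * sigma ** 2

    def test_gauge_invariance_across_anchor_choice(self):
        res = syn.generate_mosaic(syn.MosaicSpec(rows=2, cols=2, seed=9))
        ids = list(res.true_transforms)
        init = {
            t: reg.RigidTransform2D(0.0, np.array(res.nominal_offsets[t])) for t in ids
        }
        sol_a = reg.solve_montage(ids, res.correspondences, ids[0], initial=init)
        sol_b = reg.solve_montage(ids, res.correspondences, ids[-1], initial=init)
        # align solution b onto a through the anchor-difference transform
        Ta = sol_a.transforms[ids[-1]]
        Tb = sol_b.transforms[ids[-1]]
        # g = Ta o Tb^{-1} maps b-frame to a-frame
        g_R = Ta.matrix @ Tb.matrix.T
        g_t = Ta.translation - g_R @ Tb.translation
        for tid in ids:
            Rb = sol_b.transforms[tid]
            aligned_R = g_R @ Rb.matrix
            aligned_t = g_R @ Rb.translation + g_t
            assert np.abs(aligned_R - sol_a.transforms[tid].matrix).max() < 1e-6
            assert np.abs(aligned_t - sol_a.transforms[tid].translation).max() < 1e-6

    def test_disconnected_graph_reports_components(self):
        corrs = [reg.Correspondence("a", "b", (0, 0), (1, 1))]
        with pytest.raises(ValueError, match="disconnected"):
            reg.solve_montage(["a", "b", "c"], corrs, "a")


class TestLensDistortion:
    CENTER = (64.0, 64.0)

    def test_zero_distortion_recovers_near_zero_coefficients(self):
        zero = reg.PolynomialDistortion2D.identity(2, self.CENTER)
        corrs, _ = syn.generate_lens_calibration_set(zero, seed=2, grid_step=14)
        est = reg.estimate_lens_distortion(corrs, center=self.CENTER, degree=2)
        assert max(np.abs(est.coef_x).max(), np.abs(est.coef_y).max()) < 1e-6

    def test_planted_quadratic_recovered_and_residual_reduced(self):
        cx = np.array([1e-4, 5e-5, -8e-5])
        cy = np.array([-6e-5, 1e-4, 9e-5])
        true = reg.PolynomialDistortion2D(2, cx, cy, self.CENTER)
        corrs, _ = syn.generate_lens_calibration_set(true, seed=1, grid_step=14)
        est = reg.estimate_lens_distortion(corrs, center=self.CENTER, degree=2)
        rel = np.abs(np.concatenate([est.coef_x - cx, est.coef_y - cy])) / np.abs(
            np.concatenate([cx, cy])
        )
        assert rel.max() < 0.01

        ids = sorted({c.tile_a for c in corrs} | {c.tile_b for c in corrs})
        before = reg.solve_montage(ids, corrs, ids[0]).residual
        corrected = [
            reg.Correspondence(
                c.tile_a, c.tile_b,
                tuple(est.apply(np.asarray(c.point_a))),
                tuple(est.apply(np.asarray(c.point_b))),
            )
            for c in corrs
        ]
        after = reg.solve_montage(ids, corrected, ids[0]).residual
        assert before >= 10.0 * after
        assert np.sqrt(after) < 1e-3  # corrected residual below a millipixel

    def test_rank_deficiency_reported(self):
        # collinear correspondences cannot constrain a 2D polynomial
        corrs = [
            reg.Correspondence("p0", "p1", (x, 10.0), (x + 1.0, 10.0)) for x in range(8)
        ]
        with pytest.raises(ValueError, match="rank"):
            reg.estimate_lens_distortion(corrs, center=self.CENTER, degree=2)

    def test_degree_below_two_rejected(self):
        with pytest.raises(ValueError):
            reg.estimate_lens_distortion([], center=self.CENTER, degree=1)


class TestFeatureMatching:
    def test_self_match_zero_displacement(self):
        img = syn.generate_texture((160, 160), 2.0, 5)
        matches = reg.match_features(img, img)
        assert len(matches) > 10
        disp = np.array([np.array(m.point_b) - np.array(m.point_a) for m in matches])
        assert np.abs(np.median(disp, axis=0)).max() < 1e-9

    def test_planted_integer_shift_recovered(self):
        world = syn.generate_texture((220, 220), 2.0, 7)
        a = world[:160, :160]
        b = world[20:180, 12:172]  # content of a appears shifted by (-12, -20)
        matches = reg.match_features(a, b)
        assert len(matches) > 10
        disp = np.array([np.array(m.point_b) - np.array(m.point_a) for m in matches])
        assert np.abs(np.median(disp, axis=0) - [-12.0, -20.0]).max() <= 0.5

    def test_uncorrelated_noise_yields_almost_no_matches(self):
        n1 = np.random.default_rng(1).uniform(0, 255, (128, 128))
        n2 = np.random.default_rng(2).uniform(0, 255, (128, 128))
        assert len(reg.match_features(n1, n2)) < 5


class TestMipmaps:
    def test_256_gives_nine_levels(self):
        levels = reg.build_mipmaps(np.zeros((256, 256)))
        assert len(levels) == 9
        assert levels[0].shape == (256, 256) and levels[-1].shape == (1, 1)

    def test_constant_image_preserved_at_every_level(self):
        levels = reg.build_mipmaps(np.full((100, 60), 7.25))
        assert all(np.allclose(l, 7.25) for l in levels)

    def test_level1_pixels_are_block_means(self, rng):
        img = rng.uniform(0, 255, (64, 64))
        lvl1 = reg.build_mipmaps(img)[1]
        for i in range(32):
            for j in range(32):
                assert lvl1[i, j] == pytest.approx(
                    img[2 * i : 2 * i + 2, 2 * j : 2 * j + 2].mean()
                )

    def test_empty_image_rejected(self):
        with pytest.raises(ValueError):
            reg.build_mipmaps(np.empty((0, 0)))


class TestRenderSection:
    def test_single_untransformed_tile_copied(self, rng):
        img = rng.uniform(0, 255, (32, 32))
        out = reg.render_section({"t": img}, {"t": reg.RigidTransform2D()}, (40, 48))
        assert out.shape == (40, 48)
        assert np.abs(out[:32, :32] - img).max() < 1e-9

    def test_two_tile_mosaic_seam_is_smooth(self):
        world = syn.generate_texture((80, 160), 2.0, 3)
        a = world[:, :96]
        b = world[:, 64:160]
        transforms = {
            "a": reg.RigidTransform2D(),
            "b": reg.RigidTransform2D(0.0, np.array([64.0, 0.0])),
        }
        out = reg.render_section({"a": a, "b": b}, transforms, (80, 160))
        # reconstruction of a noise-free planted mosaic matches the world
        assert np.abs(out - world).mean() < 1.0

    def test_missing_transform_reported(self):
        with pytest.raises(ValueError, match="tile"):
            reg.render_section({"t": np.zeros((4, 4))}, {}, (8, 8))
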