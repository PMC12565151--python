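import numpy as np
import pytest

from corofuse.fusion import (
    FluidProperties,
    FusionConfig,
    FusionWeights,
    base_weights,
    combine_and_normalize,
    compute_fusion_weights,
    fuse,
    geometric_weight,
    local_reynolds,
)
from corofuse.synthetic import (
    MotionParams,
    TubeParams,
    generate_phase_sequence,
    generate_stenosed_vessel,
)


class TestBaseWeights:
    def test_uniform_profile(self):
        np.testing.assert_allclose(base_weights(np.ones(11)), 1 / 11)

    def test_single_active_phase(self):
        vp = np.zeros(11)
        vp[7] = 3.0
        w = base_weights(vp)
        assert w[7] == 1.0 and w.sum() == 1.0

    def test_matches_normalization_oracle(self, default_params):
        from corofuse.flow_profile import velocity

        t = np.linspace(0, 1, 11)
        vp = np.atleast_1d(velocity(t, default_params))
        np.testing.assert_allclose(base_weights(vp), vp / vp.sum(), rtol=1e-14)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            base_weights(np.zeros(11))


class TestLocalReynolds:
    def test_one_meter_per_second_reference_case(self):
        # v̄ = 1 m/s through D_h = 3.5 mm: Re = 1060·1·0.0035/0.00371 = 1000
        a = np.pi * 1.75**2  # mm²
        q = 1000.0 * a  # mm³/s gives v̄ = 1 m/s
        assert local_reynolds(q, a) == pytest.approx(1000.0, rel=1e-12)

    def test_zero_flow(self):
        assert local_reynolds(0.0, 10.0) == 0.0

    def test_linear_in_flow(self):
        assert local_reynolds(8.0, 5.0) == pytest.approx(2 * local_reynolds(4.0, 5.0))

    def test_nonpositive_area_rejected(self):
        with pytest.raises(ValueError):
            local_reynolds(1.0, 0.0)


class TestGeometricWeight:
    def test_featureless_tube_gets_floor_only(self):
        n = 20
        cfg = FusionConfig()
        w = geometric_weight(
            area=np.full(n, 10.0),
            dA_ds=np.zeros(n),
            kappa=np.zeros(n),
            tau=np.zeros(n),
            dh=np.full(n, 3.0),
            re=np.full(n, 500.0),
            a_ref=np.full(n, 10.0),
            config=cfg,
        )
        np.testing.assert_allclose(w, cfg.weight_floor, rtol=1e-12)

    def test_stenosis_term(self):
        cfg = FusionConfig(alpha=0.0, beta=1e-30, gamma=1.0)
        w = geometric_weight(
            area=np.array([4.0]),
            dA_ds=np.zeros(1),
            kappa=np.zeros(1),
            tau=np.zeros(1),
            dh=np.array([2.0]),
            re=np.array([500.0]),
            a_ref=np.array([10.0]),
            config=cfg,
        )
        assert w[0] == pytest.approx(0.6**1.5 + cfg.weight_floor, rel=1e-9)

    def test_dean_flow_term(self):
        cfg = FusionConfig(alpha=0.0, beta=1.0, gamma=0.0)
        w = geometric_weight(
            area=np.array([7.0]),
            dA_ds=np.zeros(1),
            kappa=np.array([0.1]),
            tau=np.zeros(1),
            dh=np.array([3.0]),
            re=np.array([500.0]),
            a_ref=np.array([7.0]),
            config=cfg,
        )
        assert w[0] == pytest.approx(0.1 * 9.0 * 1.0 + cfg.weight_floor, rel=1e-9)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            geometric_weight(
                np.ones(5), np.ones(4), np.ones(5), np.ones(5), np.ones(5),
                np.ones(5), np.ones(5),
            )

    def test_monotone_in_stenosis_severity(self):
        cfg = FusionConfig()
        prev = -np.inf
        for severity in (0.0, 0.3, 0.5, 0.7, 0.85):
            w = geometric_weight(
                area=np.array([10.0 * (1 - severity)]),
                dA_ds=np.zeros(1),
                kappa=np.zeros(1),
                tau=np.zeros(1),
                dh=np.array([2.0]),
                re=np.array([300.0]),
                a_ref=np.array([10.0]),
                config=cfg,
            )
            assert w[0] >= prev
            prev = w[0]


class TestCombineNormalize:
    def test_identical_geometry_recovers_base_weights(self):
        wb = base_weights(np.arange(1.0, 12.0))
        wg = np.full((11, 7), 0.37)
        wn = combine_and_normalize(wb, wg)
        for col in wn.T:
            np.testing.assert_allclose(col, wb, rtol=1e-12)

    def test_uniform_base_proportional_to_geometry(self):
        wb = np.full(3, 1 / 3)
        wg = np.array([[1.0], [2.0], [3.0]])
        wn = combine_and_normalize(wb, wg)
        np.testing.assert_allclose(wn[:, 0], [1 / 6, 2 / 6, 3 / 6], rtol=1e-12)

    def test_three_phase_toy_matches_hand_normalization(self):
        wb = np.array([0.2, 0.3, 0.5])
        wg = np.array([[1.0, 2.0], [4.0, 1.0], [2.0, 2.0]])
        wn = combine_and_normalize(wb, wg)
        raw = wb[:, None] * wg
        np.testing.assert_allclose(wn, raw / raw.sum(axis=0), rtol=1e-14)
        np.testing.assert_allclose(wn.sum(axis=0), 1.0, atol=1e-12)


def _uniform_weights(models):
    """Equal-weight FusionWeights for a sequence (uniform base, flat geometry)."""
    n, n_s = len(models), len(models[0].centerline)
    wn = np.full((n, n_s), 1.0 / n)
    return FusionWeights(
        w_base=np.full(n, 1.0 / n), w_geo=np.ones((n, n_s)), w_norm=wn,
        s=models[0].centerline.s,
    )


class TestFuse:
    def test_identical_phases_fuse_to_themselves(self, static_sequence):
        fused = fuse(static_sequence, _uniform_weights(static_sequence))
        np.testing.assert_allclose(
            fused.mesh.vertices, static_sequence[0].mesh.vertices, atol=1e-12
        )
        np.testing.assert_allclose(
            fused.r_eff, static_sequence[0].centerline.radius, rtol=1e-12
        )

    def test_delta_weights_return_single_phase(self, moving_sequence):
        n, n_s = len(moving_sequence), len(moving_sequence[0].centerline)
        k = 4
        vp = np.zeros(n)
        vp[k] = 1.0
        weights = compute_fusion_weights(moving_sequence, vp)
        fused = fuse(moving_sequence, weights)
        np.testing.assert_allclose(
            fused.mesh.vertices, moving_sequence[k].mesh.vertices, atol=1e-6
        )

    def test_two_phase_radius_average(self, small_tube):
        models = []
        for r in (1.9, 2.1):
            tube = TubeParams(length=40.0, radius=r, n_axial=31, n_theta=12)
            models.append(
                generate_phase_sequence(tube, MotionParams(0, 0, 0), n_phases=2, seed=0)[0]
            )
        fused = fuse(models, _uniform_weights(models))
        np.testing.assert_allclose(fused.r_eff, 2.0, atol=1e-9)

    def test_topology_mismatch_rejected(self, static_sequence, small_tube):
        other = generate_phase_sequence(
            TubeParams(length=40.0, radius=2.0, n_axial=30, n_theta=12),
            MotionParams(0, 0, 0), n_phases=2, seed=0,
        )
        with pytest.raises(ValueError, match="mismatch"):
            fuse([static_sequence[0], other[0]], _uniform_weights(static_sequence))


class TestPipelineWeightProperties:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_normalization_on_randomized_tubes(self, seed):
        rng = np.random.default_rng(seed)
        tube = TubeParams(
            length=float(rng.uniform(30, 60)),
            radius=float(rng.uniform(1.5, 3.0)),
            n_axial=31,
            n_theta=12,
            bend_amplitude=float(rng.uniform(0, 3)),
            noise_amplitude=float(rng.uniform(0, 0.1)),
        )
        models = generate_phase_sequence(tube, MotionParams(), seed=seed)
        vp = rng.uniform(0.1, 1.0, size=11)
        weights = compute_fusion_weights(models, vp)
        np.testing.assert_allclose(weights.w_norm.sum(axis=0), 1.0, atol=1e-9)
        assert weights.w_norm.min() >= 0.0

    def test_convexity_bounds_on_fused_quantities(self, moving_sequence):
        vp = np.linspace(0.2, 1.0, 11)
        weights = compute_fusion_weights(moving_sequence, vp)
        fused = fuse(moving_sequence, weights)
        radii = np.array([m.centerline.radius for m in moving_sequence])
        assert (fused.r_eff <= radii.max(axis=0) + 1e-12).all()
        assert (fused.r_eff >= radii.min(axis=0) - 1e-12).all()
        kappas = np.array([m.centerline.curvature for m in moving_sequence])
        assert (fused.kappa_eff <= kappas.max(axis=0) + 1e-12).all()
        verts = np.stack([m.mesh.vertices for m in moving_sequence])
        assert (fused.mesh.vertices <= verts.max(axis=0) + 1e-12).all()
        assert (fused.mesh.vertices >= verts.min(axis=0) - 1e-12).all()

    def test_permutation_equivariance(self, moving_sequence):
        vp = np.linspace(0.2, 1.0, 11)
        weights = compute_fusion_weights(moving_sequence, vp)
        fused = fuse(moving_sequence, weights)
        perm = np.random.default_rng(5).permutation(11)
        models_p = [moving_sequence[i] for i in perm]
        weights_p = compute_fusion_weights(models_p, vp[perm])
        fused_p = fuse(models_p, weights_p)
        np.testing.assert_allclose(fused_p.mesh.vertices, fused.mesh.vertices, atol=1e-9)
        np.testing.assert_allclose(fused_p.r_eff, fused.r_eff, atol=1e-12)

    def test_stenosis_severity_raises_gamma_weight(self, small_tube):
        # deepening a narrowing in ONE phase (others uniform) never lowers that
        # phase's geometric weight at the throat
        uniform = generate_phase_sequence(
            small_tube, MotionParams(0, 0, 0), n_phases=11, seed=0
        )
        prev = -np.inf
        for severity in (0.0, 0.3, 0.5, 0.7):
            narrowed, _ = generate_stenosed_vessel(
                severity, small_tube, MotionParams(0, 0, 0), n_phases=2, seed=0
            )
            models = [narrowed[0]] + uniform[1:]
            weights = compute_fusion_weights(models, np.ones(11))
            i_throat = np.argmin(models[0].centerline.area)
            w = weights.w_geo[0, i_throat]
            assert w >= prev
            prev = w


class TestFusionConfigValidation:
    def test_all_zero_coefficients_rejected(self):
        with pytest.raises(ValueError):
            FusionConfig(alpha=0.0, beta=0.0, gamma=0.0)

    def test_fluid_properties_positive(self):
        with pytest.raises(ValueError):
            FluidProperties(rho=-1.0)
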