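"""Phantom generator, plan generator and the analytic dose oracle."""

import dataclasses

import numpy as np
import pytest

from geodose import (
    BeamGeometry,
    FluenceGrid,
    FluenceMap,
    OracleConfig,
    PhantomSpec,
    VolumeGrid,
    generate_phantom,
    generate_plan,
    oracle_dose_from_fms,
)


class TestPhantom:
    def test_seeded_determinism_bit_identical(self, toy_grid):
        spec = PhantomSpec(grid=toy_grid, seed=7)
        red1, m1 = generate_phantom(spec)
        red2, m2 = generate_phantom(spec)
        np.testing.assert_array_equal(red1, red2)
        for k in m1:
            np.testing.assert_array_equal(m1[k], m2[k])

    def test_zero_target_radius_rejected(self, toy_grid):
        with pytest.raises(ValueError, match="ptv"):
            generate_phantom(PhantomSpec(grid=toy_grid, target_radius=0.0))

    def test_oversized_body_rejected(self, toy_grid):
        with pytest.raises(ValueError, match="body"):
            generate_phantom(
                PhantomSpec(grid=toy_grid, body_semi_axes=(400.0, 110.0))
            )

    def test_red_bounds_and_masks(self, phantom):
        _, red, masks = phantom
        assert {"body", "couch", "ptv"} <= set(masks)
        assert sum(k.startswith("oar_") for k in masks) >= 2
        inside = masks["body"] | masks["couch"]
        assert red[inside].min() >= 0 and red[inside].max() <= 2.0
        np.testing.assert_array_equal(red[~inside], 0.0)

    def test_encoding_ring_clears_body_and_couch(self, phantom, toy_grid,
                                                 geometry, fm_grid):
        # body within a 250 mm cylinder never touches the 300 mm ring
        from geodose import encode_integrated_volume
        _, red, masks = phantom
        fms = [
            FluenceMap(a, np.ones((fm_grid.n_pixels,) * 2), fm_grid)
            for a in geometry.sampled_angles()
        ]
        iv = encode_integrated_volume(
            red, toy_grid, fms, geometry,
            body_mask=masks["body"] | masks["couch"], overlap="error",
        )
        assert iv.painted_mask.any()


class TestPlan:
    def test_one_control_point_per_sampled_angle(self, toy_plan, geometry):
        cps = toy_plan.arcs[0].control_points
        assert len(cps) == geometry.n_angles == 36
        np.testing.assert_allclose(
            [cp.gantry_angle for cp in cps], geometry.sampled_angles()
        )

    def test_two_arcs_draw_independently(self, phantom, toy_grid, geometry,
                                         fm_grid):
        _, _, masks = phantom
        plan = generate_plan(masks, geometry, n_arcs=2, seed=5,
                             grid=toy_grid, fm_grid=fm_grid)
        a0, a1 = plan.arcs
        assert not all(
            np.allclose(c0.mlc_a, c1.mlc_a)
            for c0, c1 in zip(a0.control_points, a1.control_points)
        )

    def test_meterset_shares_positive_and_sum_to_mu(self, toy_plan):
        from geodose.fluence import _arc_mu_shares
        for arc in toy_plan.arcs:
            shares = [s for _, s in _arc_mu_shares(arc)]
            assert all(s > 0 for s in shares)
            assert sum(shares) == pytest.approx(arc.beam_mu)

    def test_empty_target_rejected(self, toy_grid, geometry, phantom):
        _, _, masks = phantom
        empty = dict(masks)
        empty["ptv"] = np.zeros_like(masks["ptv"])
        with pytest.raises(ValueError, match="empty target"):
            generate_plan(empty, geometry, grid=toy_grid)

    def test_seeded_determinism(self, phantom, toy_grid, geometry, fm_grid):
        _, _, masks = phantom
        p1 = generate_plan(masks, geometry, seed=3, grid=toy_grid,
                           fm_grid=fm_grid)
        p2 = generate_plan(masks, geometry, seed=3, grid=toy_grid,
                           fm_grid=fm_grid)
        for c1, c2 in zip(p1.arcs[0].control_points, p2.arcs[0].control_points):
            np.testing.assert_array_equal(c1.mlc_a, c2.mlc_a)
            assert c1.cumulative_weight == c2.cumulative_weight


class TestOracle:
    def test_zero_fluence_gives_zero_dose(self, phantom, toy_grid, geometry,
                                          fm_grid, oracle_cfg):
        _, red, _ = phantom
        n = fm_grid.n_pixels
        fms = [FluenceMap(0.0, np.zeros((n, n)), fm_grid)]
        dose = oracle_dose_from_fms(red, toy_grid, fms, geometry, oracle_cfg)
        np.testing.assert_array_equal(dose, 0.0)

    def test_linearity_in_fluence(self, phantom, toy_grid, geometry, toy_fms,
                                  oracle_cfg):
        _, red, _ = phantom
        d1 = oracle_dose_from_fms(red, toy_grid, toy_fms, geometry, oracle_cfg)
        scaled = [
            FluenceMap(f.gantry_angle, 3.5 * f.intensity, f.grid)
            for f in toy_fms
        ]
        d2 = oracle_dose_from_fms(red, toy_grid, scaled, geometry, oracle_cfg)
        np.testing.assert_allclose(d2, 3.5 * d1, rtol=1e-6)

    def test_superposition_of_fluence_maps(self, phantom, toy_grid, geometry,
                                           toy_fms, oracle_cfg):
        _, red, _ = phantom
        a, b = toy_fms[3], toy_fms[20]
        mix = FluenceMap(a.gantry_angle, 2.0 * a.intensity, a.grid)
        da = oracle_dose_from_fms(red, toy_grid, [a], geometry, oracle_cfg)
        db = oracle_dose_from_fms(red, toy_grid, [b], geometry, oracle_cfg)
        dmix = oracle_dose_from_fms(red, toy_grid, [mix, b], geometry,
                                    oracle_cfg)
        np.testing.assert_allclose(dmix, 2.0 * da + db, rtol=1e-6, atol=1e-12)

    def test_depth_dose_matches_closed_form(self):
        """Single anterior beamlet through a uniform RED=1 slab: the ratio of
        doses at two depths is exp(-mu (d1 - d2)) x the inverse-square
        ratio."""
        geom = BeamGeometry(angular_spacing=10.0)
        grid = VolumeGrid(origin=(-152.0, -100.0, -20.0),
                          spacing=(4.0, 4.0, 4.0), dims=(77, 51, 11))
        slab = np.ones(grid.shape)
        fmg = FluenceGrid(pixel_spacing=4.0, fov=100.0)
        n = fmg.n_pixels
        inten = np.zeros((n, n))
        inten[n // 2, n // 2] = 100.0  # beamlet on the central axis
        cfg = OracleConfig(mu_eff=0.005, lateral_sigma=5.0, beamlet_spacing=4.0)
        dose = oracle_dose_from_fms(
            slab, grid, [FluenceMap(0.0, inten, fmg)], geom, cfg
        )
        ix, iz = 38, 5  # the (x=0, z=0) column
        ys = grid.axis_coords(1)
        prof = dose[iz, :, ix]
        i1, i2 = 10, 40
        expect = np.exp(-cfg.mu_eff * (ys[i2] - ys[i1])) * (
            (geom.sad + ys[i1]) ** 2 / (geom.sad + ys[i2]) ** 2
        )
        assert prof[i2] / prof[i1] == pytest.approx(expect, rel=1e-9)

    def test_rotational_covariance(self, toy_grid, geometry, fm_grid,
                                   oracle_cfg):
        """Rotating all gantry angles by 90 deg on a cylindrically symmetric
        phantom rotates the dose by 90 deg within 2% of max."""
        x, y, _ = toy_grid.voxel_centers()
        red = np.broadcast_to(
            (np.hypot(x, y) <= 150.0).astype(float), toy_grid.shape
        ).copy()
        n = fm_grid.n_pixels
        angles = [0.0, 40.0, 200.0]
        fms = [FluenceMap(a, np.ones((n, n)), fm_grid) for a in angles]
        fms_rot = [
            FluenceMap(a + 90.0, np.ones((n, n)), fm_grid) for a in angles
        ]
        d = oracle_dose_from_fms(red, toy_grid, fms, geometry, oracle_cfg)
        d_rot = oracle_dose_from_fms(red, toy_grid, fms_rot, geometry,
                                     oracle_cfg)
        # rotate dose by +90 deg about z: k=-1 on (y, x) index axes
        np.testing.assert_allclose(
            np.rot90(d, k=-1, axes=(1, 2)), d_rot, atol=0.02 * d.max()
        )

    def test_beamlet_missing_grid_contributes_zero(self, toy_grid, geometry,
                                                   oracle_cfg):
        # beamlet far off-axis projects outside the volume: dose is zero
        fmg = FluenceGrid(pixel_spacing=5.0, fov=900.0)
        n = fmg.n_pixels
        inten = np.zeros((n, n))
        inten[0, 0] = 50.0  # corner pixel, ~(-447, -447) mm offset
        cfg = dataclasses.replace(oracle_cfg, lateral_sigma=0.0)
        red = np.zeros(toy_grid.shape)
        dose = oracle_dose_from_fms(
            red, toy_grid, [FluenceMap(0.0, inten, fmg)], geometry, cfg
        )
        np.testing.assert_array_equal(dose, 0.0)

    def test_dose_non_negative(self, phantom, toy_grid, geometry, toy_fms,
                               oracle_cfg):
        _, red, _ = phantom
        dose = oracle_dose_from_fms(red, toy_grid, toy_fms, geometry,
                                    oracle_cfg)
        assert dose.min() >= 0.0
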