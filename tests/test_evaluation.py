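"""γ-analysis, DVH and dose-metric computations."""

import numpy as np
import pytest

from gamma_oracle import brute_force_gamma
from geodose import (
    GammaCriteria,
    VolumeGrid,
    dose_metrics,
    dvh,
    evaluate_case,
    gamma_index,
    relative_error,
)
from geodose.evaluation import dvh_inverse


class TestGamma:
    def test_identical_fields_pass_everywhere(self, rng):
        dose = rng.random((16, 16)) * 50
        gmap, rate = gamma_index(dose, dose, (2.0, 2.0), GammaCriteria())
        assert rate == 100.0
        assert np.nanmax(gmap) == 0.0

    def test_uniform_offset_beyond_tolerance_fails_everywhere(self):
        # spatially uniform fields 3.1% apart: distance search cannot help
        ref = np.full((12, 12), 50.0)
        ev = ref * 1.031
        _, rate = gamma_index(ref, ev, (1.0, 1.0), GammaCriteria(3.0, 2.0, 10.0))
        assert rate == 0.0

    def test_matches_brute_force_oracle(self, rng):
        crit = GammaCriteria(3.0, 2.0, 10.0)
        spacing = (2.0, 2.0)
        for trial in range(20):
            r = np.random.default_rng(100 + trial)
            ref = r.random((32, 32)) * 40 + 5
            ev = ref + r.normal(0, 1.5, ref.shape)
            gmap, _ = gamma_index(ref, ev, spacing, crit, step=1.0,
                                  search_radius_factor=5.0)
            oracle = brute_force_gamma(ref, ev, spacing, crit,
                                       radius=10.0, step=1.0)
            np.testing.assert_allclose(gmap, oracle, atol=1e-6)

    @pytest.mark.parametrize("tighter", [
        GammaCriteria(2.0, 2.0, 10.0),  # tighter dose tolerance
        GammaCriteria(3.0, 1.0, 10.0),  # tighter DTA
        GammaCriteria(2.0, 1.0, 10.0),
    ])
    def test_tightening_never_raises_pass_rate(self, rng, tighter):
        ref = rng.random((24, 24)) * 45 + 2
        ev = ref + rng.normal(0, 1.0, ref.shape)
        _, base = gamma_index(ref, ev, (2.0, 2.0), GammaCriteria(3.0, 2.0, 10.0))
        _, tight = gamma_index(ref, ev, (2.0, 2.0), tighter)
        assert tight <= base + 1e-9

    def test_all_below_threshold_rejected(self):
        ref = np.zeros((8, 8))
        ref[0, 0] = 100.0
        ref_low = np.where(ref > 0, ref, 1.0)
        with pytest.raises(ValueError, match="no evaluable"):
            gamma_index(np.zeros((8, 8)), np.zeros((8, 8)), (1, 1),
                        GammaCriteria())
        # only the single hot voxel is evaluable
        _, rate = gamma_index(ref_low, ref_low, (1, 1), GammaCriteria())
        assert rate == 100.0

    def test_works_in_3d(self, rng):
        dose = rng.random((4, 8, 8)) * 40 + 5
        _, rate = gamma_index(dose, dose * 1.005, (3.0, 2.7, 2.7),
                              GammaCriteria())
        assert rate == 100.0


class TestDvh:
    def test_uniform_dose_step_curve(self):
        mask = np.ones((5, 5, 5), dtype=bool)
        dose = np.full(mask.shape, 45.0)
        levels, vol = dvh(dose, mask, bin_width=1.0)
        assert np.all(vol[levels <= 45.0] == 100.0)
        assert np.all(vol[levels > 45.0] == 0.0)

    def test_two_level_field(self):
        dose = np.concatenate([np.full(50, 10.0), np.full(50, 20.0)])
        levels, vol = dvh(dose, np.ones(100, dtype=bool), bin_width=0.5)
        mid = (levels > 10.0) & (levels <= 20.0)
        assert np.all(vol[mid] == 50.0)

    def test_ramp_d95_by_inverse_lookup(self):
        # 0..100 Gy ramp: the hottest 95% of the volume all get >= 5 Gy
        dose = np.linspace(0.0, 100.0, 101)
        levels, vol = dvh(dose, np.ones(101, dtype=bool), bin_width=0.5)
        assert dvh_inverse(levels, vol, 95.0) == pytest.approx(5.0, abs=0.5)

    def test_monotone_non_increasing_from_100(self, rng):
        dose = rng.random(500) * 60
        levels, vol = dvh(dose, np.ones(500, dtype=bool))
        assert vol[0] == 100.0
        assert np.all(np.diff(vol) <= 0)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty structure"):
            dvh(np.ones(10), np.zeros(10, dtype=bool))


class TestDoseMetrics:
    def test_uniform_field_all_metrics_equal(self):
        m = dose_metrics(np.full(64, 12.5), np.ones(64, dtype=bool))
        assert m.d98 == m.d95 == m.dmax == m.dmin == m.dmean == 12.5

    def test_ramp_percentiles_sort_oracle(self):
        # 100 voxels at 1..100 Gy: hottest 98 voxels' minimum is 3 Gy
        dose = np.arange(1.0, 101.0)
        m = dose_metrics(dose, np.ones(100, dtype=bool))
        assert m.d98 == 3.0
        assert m.dmax == 100.0 and m.dmin == 1.0
        assert m.dmean == pytest.approx(50.5)
        # 101 voxels at 0..100 Gy: hottest 95% minimum is 5 Gy
        ramp = np.linspace(0.0, 100.0, 101)
        assert dose_metrics(ramp, np.ones(101, dtype=bool)).d95 == 5.0

    def test_single_voxel_mask(self):
        dose = np.array([1.0, 42.0, 3.0])
        mask = np.array([False, True, False])
        m = dose_metrics(dose, mask)
        assert m.d98 == m.d95 == m.dmax == m.dmin == m.dmean == 42.0

    def test_ordering_invariant_on_random_fields(self):
        for trial in range(100):
            r = np.random.default_rng(trial)
            dose = r.random(r.integers(5, 200)) * 80
            m = dose_metrics(dose, np.ones(dose.size, dtype=bool))
            assert m.dmin <= m.d98 <= m.d95 <= m.dmax
            assert m.dmin <= m.dmean <= m.dmax

    def test_dvh_and_percentile_agree_within_bin(self, rng):
        dose = rng.random(300) * 70
        mask = np.ones(300, dtype=bool)
        levels, vol = dvh(dose, mask, bin_width=0.25)
        m = dose_metrics(dose, mask)
        assert dvh_inverse(levels, vol, 95.0) == pytest.approx(m.d95, abs=0.25)
        assert dvh_inverse(levels, vol, 98.0) == pytest.approx(m.d98, abs=0.25)


class TestRelativeError:
    @pytest.mark.parametrize("est,gt,rx,expected", [
        (45.5, 45.0, 45.0, 100 * 0.5 / 45.0),
        (45.0, 45.0, 45.0, 0.0),
        (44.0, 45.0, 50.0, -2.0),
    ])
    def test_formula(self, est, gt, rx, expected):
        assert relative_error(est, gt, rx) == pytest.approx(expected)

    def test_non_positive_prescription_rejected(self):
        with pytest.raises(ValueError, match="prescription"):
            relative_error(1.0, 1.0, 0.0)


class TestEvaluateCase:
    @pytest.fixture()
    def case(self, rng):
        grid = VolumeGrid(origin=(0, 0, 0), spacing=(2.0, 2.0, 3.0),
                          dims=(16, 16, 4))
        gt = rng.random(grid.shape) * 40 + 5
        masks = {
            "ptv": np.zeros(grid.shape, dtype=bool),
            "oar_rectum": np.zeros(grid.shape, dtype=bool),
        }
        masks["ptv"][1:3, 6:10, 6:10] = True
        masks["oar_rectum"][1:3, 10:12, 6:10] = True
        return gt, grid, masks

    def test_identical_doses_report_perfect(self, case):
        gt, grid, masks = case
        rep = evaluate_case(gt, gt.copy(), grid, masks, 45.0)
        assert all(v == 100.0 for v in rep["gamma"].values())
        for s in rep["structures"].values():
            assert all(v == 0.0 for v in s["rel_error_pct"].values())

    def test_uniform_shift_relative_error(self, case):
        gt, grid, masks = case
        rep = evaluate_case(gt, gt + 1.0, grid, masks, 45.0)
        for s in rep["structures"].values():
            assert s["rel_error_pct"]["dmean"] == pytest.approx(100 / 45.0)

    def test_report_serializes_and_round_trips(self, case, tmp_path):
        import yaml
        gt, grid, masks = case
        rep = evaluate_case(gt, gt + 0.5, grid, masks, 45.0)
        f = tmp_path / "report.yaml"
        f.write_text(yaml.safe_dump(rep))
        assert yaml.safe_load(f.read_text()) == rep

    def test_grid_mismatch_rejected(self, case):
        gt, grid, masks = case
        with pytest.raises(ValueError, match="grid"):
            evaluate_case(gt, gt[:, :-1], grid, masks, 45.0)

    def test_missing_oar_rejected(self, case):
        gt, grid, masks = case
        with pytest.raises(ValueError, match="OAR"):
            evaluate_case(gt, gt, grid, {"ptv": masks["ptv"]}, 45.0)
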