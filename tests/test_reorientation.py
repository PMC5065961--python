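import numpy as np
import pytest
from shapely.geometry import Polygon

from plumetrace.dispersion import DispersionConfig, Receptor, advect_backward
from plumetrace.reorientation import (ExposureEvent, TurnRecord,
                                      angle_turn_relation,
                                      chi_square_contingency, corridor_exposure,
                                      hotelling_paired, plume_bearing,
                                      turn_analysis, v_test)
from conftest import hourly_track, uniform_wind
from test_plume_stats import make_raster


def box(x0, y0, x1, y1):
    return Polygon([(x0, y0), (x1, y0), (x1, y1), (x0, y1)])


class TestCorridorExposure:
    def test_all_mass_inside(self):
        r = make_raster(np.ones((4, 4)))
        frac, exposed = corridor_exposure(r, box(-1, -1, 10, 10), threshold=0.05)
        assert frac == 1.0 and exposed

    def test_all_mass_outside(self):
        r = make_raster(np.ones((4, 4)))
        frac, exposed = corridor_exposure(r, box(50, 50, 60, 60), threshold=0.05)
        assert frac == 0.0 and not exposed

    def test_half_mass_split_between_two_cells(self):
        v = np.zeros((1, 2))
        v[0, 0] = 3.0
        v[0, 1] = 3.0
        r = make_raster(v)          # centers at lon 0.5 and 1.5
        frac, _ = corridor_exposure(r, box(0, 0, 1, 1), threshold=0.5)
        assert frac == pytest.approx(0.5)

    def test_scale_invariance_and_zero_mass(self):
        v = np.random.default_rng(0).random((5, 5))
        poly = box(0, 0, 3, 3)
        f1, _ = corridor_exposure(make_raster(v), poly)
        f2, _ = corridor_exposure(make_raster(v * 137.0), poly)
        assert f1 == pytest.approx(f2, rel=1e-12)
        f0, exp0 = corridor_exposure(make_raster(np.zeros((3, 3))), poly)
        assert f0 == 0.0 and not exp0

    def test_invalid_polygon_rejected(self):
        with pytest.raises(ValueError):
            corridor_exposure(make_raster(np.ones((2, 2))), None)


class TestPlumeBearing:
    def _bearing_for_wind(self, u, v):
        wf = uniform_wind(u=u, v=v)
        cfg = DispersionConfig(n_particles=300, max_age_h=3.0, dt=600.0,
                               kh=0.0, kz=0.0, reception_window=1e-6, seed=1)
        rec = Receptor(0.0, 0.0, float(wf.time_axis[0]) + 40 * 3600.0)
        ens = advect_backward(rec, wf, cfg)
        return plume_bearing(ens, rec)

    def test_wind_from_east(self):
        brg, r = self._bearing_for_wind(u=-10.0, v=0.0)
        assert brg == pytest.approx(90.0, abs=1.0) and r > 0.99

    def test_wind_from_north(self):
        brg, r = self._bearing_for_wind(u=0.0, v=-10.0)
        assert min(brg, 360.0 - brg) == pytest.approx(0.0, abs=1.0)
        assert r > 0.99

    def test_pure_diffusion_has_no_preferred_direction(self):
        wf = uniform_wind(u=0.0, v=0.0)
        cfg = DispersionConfig(n_particles=2000, max_age_h=3.0, dt=600.0,
                               kh=50_000.0, kz=0.0, reception_window=1e-6, seed=2)
        rec = Receptor(0.0, 0.0, float(wf.time_axis[0]) + 40 * 3600.0)
        _brg, r = plume_bearing(advect_backward(rec, wf, cfg), rec)
        assert r < 0.1

    def test_unreachable_trail_marker(self):
        wf = uniform_wind(u=0.0, v=0.0)
        cfg = DispersionConfig(n_particles=20, max_age_h=1.0, dt=600.0,
                               kh=0.0, kz=0.0, seed=3)
        rec = Receptor(0.0, 0.0, float(wf.time_axis[0]) + 40 * 3600.0)
        brg, r = plume_bearing(advect_backward(rec, wf, cfg), rec)
        assert np.isnan(brg) and r == 0.0


class TestTurnRecords:
    @pytest.mark.parametrize("before,after,delta", [
        (180.0, 180.0, 0.0),
        (180.0, 150.0, -30.0),
        (350.0, 10.0, 20.0),
    ])
    def test_delta_wrap_convention(self, before, after, delta):
        rec = TurnRecord("b", before, after, plume_bearing=90.0)
        assert rec.delta == pytest.approx(delta)

    def test_turn_analysis_straight_south_track(self):
        track = hourly_track(np.zeros(20), 50 - 0.3 * np.arange(20))
        ev = ExposureEvent("b", float(track.epoch_seconds()[10]), 10,
                           0.0, 47.0, 0.5, True, plume_bearing=90.0)
        rec = turn_analysis(track, ev, before_m=100_000, after_m=100_000)
        assert rec.delta == pytest.approx(0.0, abs=1e-6)
        assert rec.plume_relative_angle == pytest.approx(-90.0, abs=1e-6)

    def test_event_at_endpoint_rejected(self):
        track = hourly_track(np.zeros(5), 50 - 0.3 * np.arange(5))
        ev = ExposureEvent("b", float(track.epoch_seconds()[0]), 0,
                           0.0, 50.0, 0.5, True, plume_bearing=90.0)
        with pytest.raises(ValueError):
            turn_analysis(track, ev)


class TestVTest:
    def test_concentrated_sample_closed_form(self):
        res = v_test([30.0] * 8, mu0=30.0)
        assert res.r == pytest.approx(1.0)
        assert res.statistic == pytest.approx(4.0)          # u = V*sqrt(2/n) = 4
        assert res.p_value == pytest.approx(3.167e-5, rel=1e-3)

    def test_uniform_four_points(self):
        res = v_test([0.0, 90.0, 180.0, 270.0], mu0=0.0)
        assert res.r == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(0.5)

    def test_orthogonal_concentration_gives_zero_v(self):
        res = v_test([120.0] * 6, mu0=30.0)
        assert res.r == pytest.approx(1.0)
        assert res.statistic == pytest.approx(0.0, abs=1e-9)

    def test_needs_two_angles(self):
        with pytest.raises(ValueError):
            v_test([10.0], mu0=0.0)


class TestHotellingPaired:
    def test_no_change_reported_as_p_one(self):
        res = hotelling_paired([10, 200, 355], [10, 200, 355])
        assert res.p_value == 1.0

    def test_strong_shift_of_concentrated_sample_detected(self):
        # concentrated migratory bearings (southbound +- 20 deg) shifted by
        # 90 deg: the paired test detects the turn essentially always.
        # (For a circular-uniform 'before' sample a pure rotation leaves the
        # mean difference vector at zero, so no paired test can see it.)
        rng = np.random.default_rng(0)
        detected = 0
        for _ in range(100):
            before = rng.normal(180.0, 20.0, 20) % 360.0
            after = (before + 90.0) % 360.0
            if hotelling_paired(before, after).p_value < 0.001:
                detected += 1
        assert detected >= 99

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            hotelling_paired([0, 10], [20, 30])


class TestChiSquare:
    def test_perfect_association(self):
        x2, df, _p = chi_square_contingency([[10, 0], [0, 10]])
        assert x2 == pytest.approx(20.0) and df == 1

    def test_independence(self):
        x2, _df, p = chi_square_contingency([[5, 5], [5, 5]])
        assert x2 == 0.0 and p == 1.0

    def test_reconstructed_two_by_three_study_table(self):
        # 11 smell-intact birds: 8 exposed-and-reoriented, 3 never exposed;
        # 6 anosmic: 1 reoriented, 5 did not
        x2, df, _ = chi_square_contingency([[8, 0, 3], [1, 5, 0]])
        assert df == 2
        assert x2 == pytest.approx(13.105, abs=0.01)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            chi_square_contingency([[5, 0], [3, 0]])


class TestAngleTurnRelation:
    @staticmethod
    def _records(x, y):
        return [TurnRecord(f"b{i}", 0.0, yi, plume_bearing=xi)
                for i, (xi, yi) in enumerate(zip(x, y))]

    def test_identity_relation(self):
        x = np.array([-60.0, -30.0, 20.0, 45.0])
        res = angle_turn_relation(self._records(x, x))
        assert res["slope"] == pytest.approx(1.0)
        assert res["correlation"] == pytest.approx(1.0)

    def test_flat_response(self):
        x = np.array([-60.0, -30.0, 20.0, 45.0])
        res = angle_turn_relation(self._records(x, np.full(4, 15.0)))
        assert res["slope"] == 0.0 and res["correlation"] == 0.0

    def test_zero_predictor_variance_rejected(self):
        with pytest.raises(ValueError):
            angle_turn_relation(self._records(np.full(4, 30.0),
                                              [1.0, 2.0, 3.0, 4.0]))


def test_v_test_p_uniform_under_null_small():
    # smaller-scale uniformity screen (the full 10k-replicate version runs
    # with the acceptance checks)
    rng = np.random.default_rng(42)
    ps = [v_test(rng.uniform(0, 360, 20), mu0=0.0).p_value for _ in range(500)]
    from scipy import stats
    assert stats.kstest(ps, "uniform").pvalue > 0.01
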