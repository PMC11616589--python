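import math

import numpy as np
import pytest

import epimap as em
from epimap.errors import ParameterError
from epimap.recording import adc_scale_mv
from epimap.synthetic import BlockLine, apply_block_lines, sigma_for


class TestGroundTruthLat:
    def test_planar_neighbor_delta_is_pitch_over_velocity(self, grid):
        act = em.ActivationModel(mode="planar", cv_cm_s=80.0, direction_deg=0.0)
        lat = em.ground_truth_lat(grid, act)
        np.testing.assert_allclose(np.diff(lat, axis=1), 2.5)  # 2 mm / 0.8 mm/ms
        np.testing.assert_allclose(np.diff(lat, axis=0), 0.0)

    def test_direction_orthogonal_to_rows_gives_zero_row_gradient(self, grid):
        act = em.ActivationModel(mode="planar", cv_cm_s=50.0, direction_deg=90.0)
        lat = em.ground_truth_lat(grid, act)
        np.testing.assert_allclose(np.diff(lat, axis=1), 0.0, atol=1e-12)

    def test_focal_lat_matches_brute_force_distances(self, grid):
        act = em.ActivationModel(mode="focal", cv_cm_s=50.0, origin_electrode=(0, 0))
        lat = em.ground_truth_lat(grid, act)
        # independent oracle: explicit per-electrode distance computation
        expected = np.empty((grid.rows, grid.cols))
        for r in range(grid.rows):
            for c in range(grid.cols):
                d_mm = math.hypot(r * 2.0, c * 2.0)
                expected[r, c] = d_mm / 0.5  # 50 cm/s = 0.5 mm/ms
        np.testing.assert_allclose(lat, expected)
        assert lat.max() == pytest.approx(math.hypot(18.0, 22.0) / 0.5)

    def test_nonpositive_velocity_rejected(self):
        with pytest.raises(ParameterError):
            em.ActivationModel(cv_cm_s=0.0)


class TestSynthPotential:
    def _wf(self, **kw):
        base = dict(app_mv=15.3, sigma_ms=10.0, noise_sd_mv=0.0,
                    baseline_amp_mv=0.0, seed=0)
        base.update(kw)
        return em.WaveformParams(**base)

    def test_noise_free_peak_to_peak_within_quantization(self):
        trace = em.synth_potential(self._wf(), 100.0, 1000, 2000.0)
        assert abs(np.ptp(trace) - 15.3) <= adc_scale_mv() + 1e-12

    def test_amplitude_linearity(self):
        t1 = em.synth_potential(self._wf(app_mv=8.0), 100.0, 1000, 2000.0)
        t2 = em.synth_potential(self._wf(app_mv=16.0), 100.0, 1000, 2000.0)
        np.testing.assert_allclose(t2, 2.0 * t1, atol=2 * adc_scale_mv())

    def test_steepest_negative_slope_at_lat(self):
        trace = em.synth_potential(self._wf(), 123.0, 1000, 2000.0)
        deriv = np.gradient(trace, 0.5)
        assert abs(deriv.argmin() * 0.5 - 123.0) <= 0.5

    def test_biphasic_positive_then_negative(self):
        trace = em.synth_potential(self._wf(), 100.0, 1000, 2000.0)
        assert trace.argmax() < trace.argmin()

    def test_lat_outside_span_rejected(self):
        with pytest.raises(ParameterError):
            em.synth_potential(self._wf(), 600.0, 1000, 2000.0)

    def test_pacing_at_70_bpm_gives_at_least_5_deflections(self, grid):
        wf = self._wf(pacing_bpm=70.0)
        rec, gt = em.synth_recording(
            grid, em.ActivationModel(cv_cm_s=80.0), em.IschemiaModel(), wf)
        assert len(gt.stim_times_ms) >= 5


class TestSynthRecording:
    def test_uniform_amplitude_without_ischemia(self, planar_recording):
        _, gt = planar_recording
        np.testing.assert_allclose(gt.amplitude_mv, 15.3)

    def test_patch_scales_exactly_the_masked_electrodes(self, grid):
        mask = np.zeros((10, 12), bool)
        mask[2:5, 2:12] = True  # 30 electrodes
        isch = em.IschemiaModel(patch_mask=mask, amplitude_factor=0.25)
        wf = em.WaveformParams(app_mv=10.0, noise_sd_mv=0, baseline_amp_mv=0)
        _, gt = em.synth_recording(grid, em.ActivationModel(), isch, wf)
        assert mask.sum() == 30
        np.testing.assert_allclose(gt.amplitude_mv[mask], 2.5)
        np.testing.assert_allclose(gt.amplitude_mv[~mask], 10.0)

    def test_block_line_delays_exactly_the_crossing_pairs(self, grid):
        # wave along rows so crossing pairs carry exactly the line delay
        act = em.ActivationModel(mode="planar", cv_cm_s=80.0, direction_deg=90.0)
        line = BlockLine("col", 6, 14.0)
        lat, pairs = apply_block_lines(em.ground_truth_lat(grid, act), grid, [line])
        deltas_cross = [abs(lat[a] - lat[b]) for a, b in pairs]
        np.testing.assert_allclose(deltas_cross, 14.0)
        for r in range(grid.rows):
            for c in range(grid.cols - 1):
                if ((r, c), (r, c + 1)) not in pairs:
                    assert abs(lat[r, c + 1] - lat[r, c]) < 12.0
        for r in range(grid.rows - 1):
            for c in range(grid.cols):
                assert abs(lat[r + 1, c] - lat[r, c]) < 12.0

    def test_declared_block_must_delay_at_least_12ms(self):
        with pytest.raises(ParameterError):
            BlockLine("col", 4, delay_ms=8.0)


class TestPerfusate:
    def test_noise_free_series_is_exactly_linear(self):
        series = em.simulate_perfusate(9.0, -24.0, np.arange(20.0, 121.0, 20.0), 0.0)
        lact = [s.lactate_mmol_l for s in series]
        assert lact[0] == 9.0
        assert lact[-1] == pytest.approx(6.6)
        np.testing.assert_allclose(np.diff(lact), -0.48)

    def test_zero_trend_gives_constant_series(self):
        series = em.simulate_perfusate(8.0, 0.0, [20, 40, 60], 0.0)
        assert {s.lactate_mmol_l for s in series} == {8.0}

    @pytest.mark.parametrize("trend", [-36.0, -24.0, 0.0, 10.0])
    def test_trend_round_trip_through_lactate_trend(self, trend):
        series = em.simulate_perfusate(9.0, trend, [20, 40, 60, 80], 0.0)
        assert em.lactate_trend(series).slope_um_min == pytest.approx(trend)

    def test_empty_times_rejected(self):
        with pytest.raises(ParameterError):
            em.simulate_perfusate(9.0, -24.0, [], 0.0)


class TestSimulateCohort:
    def test_structure_matches_study_design(self):
        spec = em.CohortSpec(positions_per_ventricle=1, seed=11)
        bundle = em.simulate_cohort(spec)
        assert len(bundle.hearts) == 8
        assert sum(h.group == "group1" for h in bundle.hearts) == 4
        for h in bundle.hearts:
            vents = {rec.position.ventricle for rec, _ in h.recordings}
            assert vents == {"RV", "LV"}
            assert len(h.contractility) == 3

    def test_same_seed_reproduces_identical_bytes(self):
        spec = em.CohortSpec(positions_per_ventricle=1, seed=5)
        b1 = em.simulate_cohort(spec)
        b2 = em.simulate_cohort(spec)
        for h1, h2 in zip(b1.hearts, b2.hearts):
            for (r1, g1), (r2, g2) in zip(h1.recordings, h2.recordings):
                assert r1.samples.tobytes() == r2.samples.tobytes()
                assert g1.lat_rel_ms.tobytes() == g2.lat_rel_ms.tobytes()
            assert [s.lactate_mmol_l for s in h1.perfusate] == \
                   [s.lactate_mmol_l for s in h2.perfusate]
            assert h1.contractility == h2.contractility

    def test_group_median_true_amplitude_matches_spec_target(self):
        spec = em.CohortSpec(positions_per_ventricle=1, noise_sd_mv=0.0,
                             baseline_amp_mv=0.0, seed=2)
        bundle = em.simulate_cohort(spec)
        for group, ventricle, target in [
            ("group1", "RV", 3.6), ("group2", "RV", 15.3),
            ("group1", "LV", 10.8), ("group2", "LV", 23.6),
        ]:
            amps = np.concatenate([
                gt.amplitude_mv.ravel()
                for h in bundle.hearts if h.group == group
                for rec, gt in h.recordings
                if rec.position.ventricle == ventricle
            ])
            assert np.median(amps) == pytest.approx(target, rel=0.05)

    def test_ground_truth_block_pairs_separated_by_12ms(self):
        bundle = em.simulate_cohort(em.CohortSpec(positions_per_ventricle=1, seed=4))
        checked = 0
        for h, rec, gt in bundle.iter_recordings():
            lat = gt.lat_rel_ms
            for r in range(lat.shape[0]):
                for c in range(lat.shape[1]):
                    for nb in ((r, c + 1), (r + 1, c)):
                        if nb[0] >= lat.shape[0] or nb[1] >= lat.shape[1]:
                            continue
                        d = abs(lat[nb] - lat[r, c])
                        pair = ((r, c), nb)
                        if pair in gt.block_pairs:
                            assert d >= 12.0
                            checked += 1
                        else:
                            assert d < 12.0
        assert checked > 0

    def test_group1_scores_lower_on_average(self):
        bundle = em.simulate_cohort(em.CohortSpec(positions_per_ventricle=1, seed=9))
        means = {g: np.mean([c.score_whole
                             for h in bundle.hearts if h.group == g
                             for c in h.contractility])
                 for g in ("group1", "group2")}
        assert means["group1"] < means["group2"]


def test_sigma_for_inverts_deflection_scale():
    from epimap.synthetic import deflection_scale
    sigma = sigma_for(15.3, 1.2)
    assert deflection_scale(15.3, sigma) == pytest.approx(1.2)
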