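"""Valve tracking: direction estimation, plane building, background
correction, flow-rate and cycle integration."""

from __future__ import annotations

import numpy as np
import pytest

import valveflow as vf
from valveflow.phantom import in_plane_axis
from valveflow.reformat import reformat_plane
from valveflow.valve_tracking import (
    NoJetDetectedError,
    auto_jet_roi,
    default_tissue_roi,
    series_volume,
)

from conftest import make_uniform_dataset


def angle_between(a, b):
    return np.degrees(np.arccos(np.clip(np.dot(a, b), -1.0, 1.0)))


class TestJetDirection:
    def test_phantom_jet_direction_recovered_within_3_deg(self, noise_free_phantom):
        spec, ds, _ = noise_free_phantom
        p = 5
        true_dir = spec.jet_directions(spec.jets[0])[p]
        est = vf.estimate_jet_direction(ds, np.asarray([0.0, 0.0, 7.0]), p)
        assert angle_between(est, true_dir) < 3.0

    def test_zero_field_raises_no_jet(self):
        ds = make_uniform_dataset(velocity=(0.0, 0.0, 0.0))
        with pytest.raises(NoJetDetectedError):
            vf.estimate_jet_direction(ds, np.zeros(3), 0)

    def test_two_jet_phantom_directions_recovered(self):
        spec = vf.two_jet_phantom_spec(seed=9, noise_sd=0.0)
        ds, _ = vf.generate_phantom(spec)
        p = 5
        for jet in spec.jets:
            seed = np.asarray(jet.orifice_center) + np.array([0.0, 0.0, 7.0])
            est = vf.estimate_jet_direction(ds, seed, p)
            true_dir = spec.jet_directions(jet)[p]
            assert angle_between(est, true_dir) < 3.0

    def test_trajectory_tracks_programmed_sweep(self, default_phantom):
        spec, ds, _ = default_phantom
        phases = list(spec.systolic_phases())
        dirs = vf.estimate_jet_trajectory(ds, np.array([0.0, 0.0, 7.0]), phases)
        true_dirs = spec.jet_directions(spec.jets[0])
        for p in phases:
            assert angle_between(dirs[p], true_dirs[p]) < 3.0


class TestTrackedPlanes:
    def test_static_jet_plane_parallel_to_annulus(self, uniform_dataset):
        d = np.array([0.0, 0.0, 1.0])
        series = vf.build_tracked_planes(
            uniform_dataset, {0: np.zeros(3), 1: np.zeros(3)},
            {0: d, 1: d}, offset_mm=15.0,
        )
        for plane in series.planes.values():
            np.testing.assert_allclose(plane.normal, d, atol=1e-12)
            np.testing.assert_allclose(plane.center, [0, 0, 15.0], atol=1e-9)

    def test_offset_outside_proximal_range_warns(self, uniform_dataset):
        d = np.array([0.0, 0.0, 1.0])
        with pytest.warns(UserWarning, match="proximal"):
            series = vf.build_tracked_planes(
                uniform_dataset, {0: np.zeros(3)}, {0: d}, offset_mm=5.0
            )
        assert 0 in series.planes

    def test_missing_phase_rejected(self, uniform_dataset):
        with pytest.raises(ValueError, match="disagree"):
            vf.build_tracked_planes(
                uniform_dataset, {0: np.zeros(3)}, {1: np.array([0.0, 0, 1.0])}
            )

    def test_noncontiguous_series_rejected(self):
        plane = vf.Plane((0, 0, 0), (1.0, 0, 0), (0, 1.0, 0))
        with pytest.raises(ValueError, match="contiguous"):
            vf.TrackedPlaneSeries("x", {0: plane, 2: plane})


class TestBackgroundCorrection:
    def _map_with_offset(self, offset):
        ds = make_uniform_dataset(velocity=(0.0, 0.0, offset), shape=(20, 20, 10))
        plane = vf.Plane.centered(np.zeros(3), np.array([1.0, 0, 0]),
                                  np.array([0, 1.0, 0]), rows=16, cols=16)
        return reformat_plane(ds, plane, 0)

    def test_constant_offset_cancelled(self):
        m = self._map_with_offset(5.0)
        tissue = np.array([[0.0, 0.0], [4.0, 0.0], [4.0, 4.0], [0.0, 4.0]])
        corrected = vf.background_correct(m, tissue)
        np.testing.assert_allclose(corrected.through_plane[corrected.in_bounds()],
                                   0.0, atol=1e-12)

    def test_zero_velocity_tissue_leaves_map_unchanged(self):
        m = self._map_with_offset(0.0)
        m.through_plane[8, 8] = 40.0  # a "jet" pixel away from the tissue ROI
        tissue = np.array([[0.0, 0.0], [4.0, 0.0], [4.0, 4.0], [0.0, 4.0]])
        corrected = vf.background_correct(m, tissue)
        np.testing.assert_array_equal(corrected.through_plane, m.through_plane)

    def test_empty_tissue_roi_rejected(self):
        m = self._map_with_offset(1.0)
        with pytest.raises(ValueError):
            vf.background_correct(m, np.array([[0.1, 0.1], [0.2, 0.1], [0.2, 0.2]]))


class TestFlowRate:
    def test_uniform_50cm_s_over_4cm2_gives_200ml_s(self):
        ds = make_uniform_dataset(velocity=(0.0, 0.0, 50.0), shape=(30, 30, 10))
        plane = vf.Plane.centered(np.zeros(3), np.array([1.0, 0, 0]),
                                  np.array([0, 1.0, 0]), rows=32, cols=32)
        m = reformat_plane(ds, plane, 0)
        # 20 x 20 pixels of 1 mm^2 = 4 cm^2 (polygon encloses centres 5..24)
        roi = np.array([[4.5, 4.5], [24.5, 4.5], [24.5, 24.5], [4.5, 24.5]])
        assert vf.flow_rate(m, roi) == pytest.approx(50.0 * 400 * 1e-2)

    def test_zero_field_zero_rate(self):
        ds = make_uniform_dataset(velocity=(0.0, 0.0, 0.0))
        plane = vf.Plane.centered(np.zeros(3), np.array([1.0, 0, 0]),
                                  np.array([0, 1.0, 0]), rows=8, cols=8)
        m = reformat_plane(ds, plane, 0)
        assert vf.flow_rate(m, np.array([[0, 0], [7, 0], [7, 7], [0, 7]])) == 0.0

    def test_orifice_plane_rate_matches_analytic_within_2pct(self, noise_free_phantom):
        spec, ds, truth = noise_free_phantom
        p = truth.peak_phase
        d = spec.jet_directions(spec.jets[0])[p]
        u = in_plane_axis(d)
        plane = vf.Plane.centered(15.0 * d, u, np.cross(d, u))
        m = reformat_plane(ds, plane, p)
        rate = vf.flow_rate(m, auto_jet_roi(m))
        assert rate == pytest.approx(truth.per_phase_rate["lavv_jet_1"][p], rel=0.02)


class TestIntegrateVolume:
    def test_constant_rate(self):
        times = np.linspace(0.0, 300.0, 11)
        assert vf.integrate_volume(np.full(11, 100.0), times) == pytest.approx(30.0)

    def test_triangular_rate(self):
        times = np.linspace(0.0, 300.0, 7)
        rates = np.array([0, 100 / 3, 200 / 3, 100.0, 200 / 3, 100 / 3, 0])
        assert vf.integrate_volume(rates, times) == pytest.approx(15.0)

    def test_half_sine_within_1pct_at_10_intervals(self):
        times = np.linspace(0.0, 300.0, 11)
        rates = 100.0 * np.sin(np.pi * times / 300.0)
        exact = (2 / np.pi) * 100.0 * 0.3  # closed form: 2/pi * peak * duration
        assert vf.integrate_volume(rates, times) == pytest.approx(exact, rel=0.01)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            vf.integrate_volume(np.ones(3), np.array([0.0, 1.0]))


class TestQuantify:
    def test_fraction_arithmetic(self):
        # regurgitant 10 mL over forward 70 mL -> 14.3%
        r = vf.FlowResult(
            forward_volume=70.0, regurgitant_volumes={"j": 10.0},
            total_regurgitant=10.0, effective_forward=60.0,
            regurgitant_fraction=100 * 10 / 70, aortic_volume=60.0,
            internal_validation_diff=0.0,
        )
        assert r.regurgitant_fraction == pytest.approx(14.3, abs=0.05)

    def test_zero_regurgitation_phantom(self):
        spec = vf.default_phantom_spec(seed=41, regurgitant_volume=0.0, jets=[])
        report = vf.run_pipeline(vf.PipelineConfig(seed=41, phantom=spec.to_dict()))
        assert report.flow.regurgitant_fraction_pct == 0.0
        assert report.flow.effective_forward_ml == report.flow.forward_volume_ml
        assert report.jets == []

    def test_result_identities_asserted(self):
        with pytest.raises(AssertionError):
            vf.FlowResult(
                forward_volume=70.0, regurgitant_volumes={"j": 10.0},
                total_regurgitant=12.0, effective_forward=60.0,
                regurgitant_fraction=0.0, aortic_volume=60.0,
                internal_validation_diff=0.0,
            )

    def test_conservation_between_parallel_planes(self, noise_free_phantom):
        """Flux through two parallel planes cutting the same jet segment
        agrees within 2% (noise-free, default grid)."""
        spec, ds, truth = noise_free_phantom
        p = truth.peak_phase
        d = spec.jet_directions(spec.jets[0])[p]
        u = in_plane_axis(d)
        v = np.cross(d, u)
        fluxes = []
        for off in (12.0, 18.0):
            plane = vf.Plane.centered(off * d, u, v)
            m = reformat_plane(ds, plane, p)
            fluxes.append(vf.flow_rate(m, auto_jet_roi(m)))
        assert fluxes[0] == pytest.approx(fluxes[1], rel=0.02)

    def test_quantification_invariant_to_in_plane_axis_choice(self, noise_free_phantom):
        spec, ds, truth = noise_free_phantom
        p = truth.peak_phase
        d = spec.jet_directions(spec.jets[0])[p]
        u1 = in_plane_axis(d)
        v1 = np.cross(d, u1)
        th = 0.6
        u2 = np.cos(th) * u1 + np.sin(th) * v1
        v2 = np.cross(d, u2)
        r = []
        for u, v in ((u1, v1), (u2, v2)):
            m = reformat_plane(ds, vf.Plane.centered(15.0 * d, u, v), p)
            r.append(vf.flow_rate(m, auto_jet_roi(m)))
        assert r[0] == pytest.approx(r[1], rel=0.01)


class TestSeriesVolume:
    def test_noise_free_volume_within_5pct(self, noise_free_phantom):
        spec, ds, truth = noise_free_phantom
        phases = list(spec.systolic_phases())
        dirs = vf.estimate_jet_trajectory(ds, np.array([0.0, 0.0, 7.0]), phases)
        centers = {p: np.zeros(3) for p in phases}
        series = vf.build_tracked_planes(ds, centers, dirs, label="jet")
        vol, record = series_volume(ds, series, background_correction=False)
        assert vol == pytest.approx(truth.total_regurgitant, rel=0.05)
        assert len(record["rate_ml_s"]) == len(phases)

    def test_tissue_roi_avoids_jet(self, noise_free_phantom):
        spec, ds, truth = noise_free_phantom
        p = truth.peak_phase
        d = spec.jet_directions(spec.jets[0])[p]
        u = in_plane_axis(d)
        m = reformat_plane(ds, vf.Plane.centered(15.0 * d, u, np.cross(d, u)), p)
        poly = default_tissue_roi(m)
        from valveflow.reformat import roi_pixel_mask

        tissue = roi_pixel_mask(m, poly)
        assert np.abs(m.through_plane[tissue]).max() < 0.1 * np.abs(m.through_plane).max()
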