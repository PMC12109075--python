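"""Background-offset estimation/subtraction and aliasing correction."""

import numpy as np
import pytest

from cineflow.correction import (
    InsufficientStaticTissueError,
    background_correct,
    detect_static_tissue,
    unalias,
)
from cineflow.flow_quant import flow_curve
from cineflow.phantom import render_subject
from cineflow.segmentation import VesselROI, segment_vessel
from cineflow.series_io import phase_to_velocity
from conftest import single_vessel_spec


def _segmented(series):
    vel = phase_to_velocity(series)
    roi = segment_vessel(vel, (48, 48))
    return vel, roi


class TestDetectStaticTissue:
    def test_uniform_offset_recovered_exactly(self):
        spec = single_vessel_spec(velocity=20.0, kind="arterial",
                                  pulsatility=0.9,
                                  background_poly=np.array([[2.0]]))
        series, _ = render_subject(spec)
        vel, roi = _segmented(series)
        static = detect_static_tissue(series, vel, [roi])
        assert static.mean_offset == pytest.approx(2.0, abs=1e-9)

    def test_air_only_background_rejected(self):
        import dataclasses
        spec = single_vessel_spec(velocity=20.0, kind="arterial",
                                  pulsatility=0.9)
        spec = dataclasses.replace(spec, tissue_magnitude=0.0)
        series, _ = render_subject(spec)
        vel, roi = _segmented(series)
        with pytest.raises(InsufficientStaticTissueError, match="insufficient"):
            detect_static_tissue(series, vel, [roi])

    @pytest.mark.parametrize("seed", range(10))
    def test_noisy_offset_recovered_within_tolerance(self, seed):
        spec = single_vessel_spec(velocity=20.0, kind="arterial",
                                  pulsatility=0.9, snr=20.0, seed=seed,
                                  background_poly=np.array([[1.5]]))
        series, _ = render_subject(spec)
        vel, roi = _segmented(series)
        static = detect_static_tissue(series, vel, [roi])
        assert static.mean_offset == pytest.approx(1.5, abs=0.2)

    def test_static_mask_disjoint_from_rois(self):
        spec = single_vessel_spec(velocity=20.0, kind="arterial",
                                  pulsatility=0.9)
        series, _ = render_subject(spec)
        vel, roi = _segmented(series)
        static = detect_static_tissue(series, vel, [roi])
        assert not np.logical_and(static.mask, roi.mask).any()
        assert static.mask.sum() >= 20


class TestBackgroundCorrect:
    def test_static_mean_zero_after_correction(self):
        spec = single_vessel_spec(velocity=20.0, kind="arterial",
                                  pulsatility=0.9,
                                  background_poly=np.array([[2.0]]))
        series, _ = render_subject(spec)
        vel, roi = _segmented(series)
        static = detect_static_tissue(series, vel, [roi])
        corrected = background_correct(vel, static)
        assert abs(corrected.velocity.mean(axis=0)[static.mask].mean()) < 1e-9

    def test_zero_offset_is_identity(self):
        spec = single_vessel_spec(velocity=20.0, kind="arterial",
                                  pulsatility=0.9)
        series, _ = render_subject(spec)
        vel, roi = _segmented(series)
        static = detect_static_tissue(series, vel, [roi])
        corrected = background_correct(vel, static)
        np.testing.assert_allclose(corrected.velocity, vel.velocity, atol=1e-9)

    def test_second_pass_offset_near_zero(self):
        spec = single_vessel_spec(velocity=20.0, kind="arterial",
                                  pulsatility=0.9,
                                  background_poly=np.array([[2.0]]))
        series, _ = render_subject(spec)
        vel, roi = _segmented(series)
        static = detect_static_tissue(series, vel, [roi])
        corrected = background_correct(vel, static)
        second = detect_static_tissue(series, corrected, [roi])
        assert abs(second.mean_offset) < 1e-9

    def test_uniform_offset_flow_bias_removed(self):
        # +2 cm/s over ~50 mm^2 inflates flow by ~60 mL/min; correction
        # restores the 300 mL/min truth
        spec = single_vessel_spec(velocity=300.0 / (50.0 * 0.6), radius=3.99,
                                  background_poly=np.array([[2.0]]))
        series, truth = render_subject(spec)
        vel, roi = _segmented(series)
        static = detect_static_tissue(series, vel, [roi])
        raw = flow_curve(vel, roi).mean
        corrected = flow_curve(background_correct(vel, static), roi).mean
        true_flow = truth.true_mean_flow("vessel")
        assert raw - corrected == pytest.approx(2.0 * roi.n_pixels * 0.6,
                                                rel=1e-6)
        assert corrected == pytest.approx(true_flow, rel=0.05)


class TestUnalias:
    def _roi(self, shape=(4, 4), direction=1):
        mask = np.zeros(shape, dtype=bool)
        mask[1:3, 1:3] = True
        return VesselROI(mask=mask, label="v", seed=(1, 1),
                         direction_sign=direction)

    def _vel_with(self, value, venc=60.0):
        from cineflow.series_io import N_FRAMES, VelocitySeries
        data = np.full((N_FRAMES, 4, 4), float(value))
        return VelocitySeries(velocity=data, venc=venc, pixel_area=1.0)

    def test_wrapped_sample_restored(self):
        vel = self._vel_with(-40.0)
        out = unalias(vel, self._roi(direction=1))
        assert np.allclose(out.velocity[:, self._roi().mask], 80.0)

    def test_consistent_sample_unchanged(self):
        vel = self._vel_with(30.0)
        out = unalias(vel, self._roi(direction=1))
        np.testing.assert_array_equal(out.velocity, vel.velocity)

    def test_negative_dominant_direction_symmetric(self):
        vel = self._vel_with(50.0)
        out = unalias(vel, self._roi(direction=-1))
        assert np.allclose(out.velocity[:, self._roi().mask], -70.0)

    def test_outside_roi_untouched(self):
        vel = self._vel_with(-40.0)
        out = unalias(vel, self._roi(direction=1))
        outside = ~self._roi().mask
        np.testing.assert_array_equal(out.velocity[:, outside],
                                      vel.velocity[:, outside])

    def test_never_leaves_twice_venc_range(self):
        rng = np.random.default_rng(0)
        from cineflow.series_io import N_FRAMES, VelocitySeries
        data = rng.uniform(-59.9, 59.9, (N_FRAMES, 4, 4))
        vel = VelocitySeries(velocity=data, venc=60.0, pixel_area=1.0)
        out = unalias(vel, self._roi(direction=1))
        assert np.all(out.velocity > -120.0)
        assert np.all(out.velocity <= 120.0)

    def test_guard_protects_small_opposing_samples(self):
        vel = self._vel_with(-5.0)
        out = unalias(vel, self._roi(direction=1), min_opposing_frac=0.2)
        np.testing.assert_array_equal(out.velocity, vel.velocity)

    def test_noiseless_wrapped_peak_restored_exactly(self):
        # arterial peak ~76 cm/s at Venc 60 wraps; after unaliasing the
        # ROI-mean curve equals the ground-truth curve
        spec = single_vessel_spec(velocity=40.0, kind="arterial",
                                  pulsatility=1.1, direction_sign=-1)
        series, truth = render_subject(spec)
        vel = phase_to_velocity(series)
        roi = segment_vessel(vel, (48, 48))
        assert roi.direction_sign == -1
        out = unalias(vel, roi)
        frac = truth.lumen_fractions["vessel"]
        full = frac == 1.0
        expected = -spec.vessels[0].waveform.samples
        got = out.velocity[:, full]
        np.testing.assert_allclose(
            got, np.broadcast_to(expected[:, None], got.shape), atol=1e-9)
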