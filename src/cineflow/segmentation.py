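"""Semi-automatic fixed-ROI vessel segmentation from the cardiac spectrum.

Pulsatile blood stands out from static tissue in the temporal frequency
domain: the amplitude of the fundamental cardiac-frequency Fourier component
of each pixel's velocity waveform is large inside a vessel lumen and near
zero elsewhere.  Segmentation grows a single 4-connected region from one
operator-provided seed pixel over the amplitude map, with a threshold
relative to the brightest pixel of the (evolving) region.  The resulting
mask is fixed for all 32 frames — vessel wall motion and caliber change over
the cycle are deliberately not modelled.

Near-steady veins can carry a strong mean velocity but almost no cardiac
modulation, in which case the spectral criterion fails; the grower then
falls back to the magnitude of the temporal-mean velocity and flags the ROI
accordingly.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy import ndimage

from .series_io import N_FRAMES, VelocitySeries

__all__ = [
    "SpectralMap",
    "VesselROI",
    "NoVesselAtSeedError",
    "cardiac_component_amplitude",
    "segment_vessel",
]

#: 4-connectivity in 2D
_STRUCTURE = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)

#: Rayleigh scale from the median of a noise-only amplitude map
_RAYLEIGH_MEDIAN = math.sqrt(2.0 * math.log(2.0))


class NoVesselAtSeedError(ValueError):
    """Raised when the seed pixel shows neither cardiac pulsatility nor flow."""


@dataclasses.dataclass(frozen=True, eq=False)
class SpectralMap:
    """Per-pixel amplitude (cm/s) of the cardiac-frequency velocity component."""

    amplitude: np.ndarray  # (H, W), >= 0

    def __post_init__(self) -> None:
        amp = np.asarray(self.amplitude, dtype=float)
        if np.any(amp < 0):
            raise ValueError("amplitude must be non-negative")
        object.__setattr__(self, "amplitude", amp)


@dataclasses.dataclass(frozen=True, eq=False)
class VesselROI:
    """Fixed boolean vessel mask with label, seed and flow-direction sign."""

    mask: np.ndarray  # (H, W) bool
    label: str
    seed: tuple[int, int]
    direction_sign: int
    grown_on: str = "cardiac_amplitude"  # or "mean_velocity"

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask, dtype=bool)
        if not mask.any():
            raise ValueError("ROI mask must be non-empty")
        if not mask[self.seed]:
            raise ValueError("seed must lie inside the ROI mask")
        n_comp = ndimage.label(mask, structure=_STRUCTURE)[1]
        if n_comp != 1:
            raise ValueError("ROI mask must be a single 4-connected component")
        object.__setattr__(self, "mask", mask)

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


def cardiac_component_amplitude(vel: VelocitySeries,
                                n_harmonics: int = 1) -> SpectralMap:
    """Amplitude of the cardiac-frequency component of each pixel's v(t).

    For the fundamental, the amplitude is ``2 |DFT_1(v)| / 32`` — the peak
    amplitude of the best-fitting cosine at one cycle per cardiac cycle.
    With ``n_harmonics > 1`` the root-sum-square of the first harmonics is
    returned.  The DC term (mean velocity) is always excluded.
    """
    if n_harmonics < 1:
        raise ValueError("n_harmonics must be >= 1")
    spectrum = np.fft.rfft(vel.velocity, axis=0)
    harmonics = 2.0 * np.abs(spectrum[1:1 + n_harmonics]) / N_FRAMES
    amplitude = np.sqrt((harmonics ** 2).sum(axis=0))
    return SpectralMap(amplitude=amplitude)


def _grow(score: np.ndarray, seed: tuple[int, int], rel_threshold: float,
          floor: float) -> np.ndarray:
    """Region-grow a 4-connected component around ``seed``.

    Pixels qualify when their score is at least ``rel_threshold`` times the
    running maximum score of the region (never below ``floor``); the seed
    always qualifies.  The region maximum is read off a 3x3-mean-smoothed
    copy of the score: the lumen interior is a plateau, so smoothing leaves
    the true maximum unchanged while suppressing the upward noise bias of a
    pointwise max (which would silently raise the effective threshold and
    shave partial-volume edge pixels).  The running maximum only increases,
    so the threshold is monotone and the iteration converges; the final mask
    depends on the vessel, not on which in-lumen pixel seeded it.
    """
    smoothed = ndimage.uniform_filter(score, size=3)
    region_max = float(smoothed[seed])
    mask = np.zeros(score.shape, dtype=bool)
    mask[seed] = True
    for _ in range(20):
        thr = max(rel_threshold * region_max, floor)
        candidates = score >= thr
        candidates[seed] = True
        labels, _ = ndimage.label(candidates, structure=_STRUCTURE)
        new_mask = labels == labels[seed]
        new_max = max(region_max, float(smoothed[new_mask].max()))
        if np.array_equal(new_mask, mask) and new_max == region_max:
            break
        mask, region_max = new_mask, new_max
    return mask


def segment_vessel(vel: VelocitySeries, seed: tuple[int, int],
                   rel_threshold: float = 0.3, *, n_harmonics: int = 1,
                   label: str = "vessel") -> VesselROI:
    """Grow a fixed vessel ROI from a single seed pixel.

    Parameters
    ----------
    vel : VelocitySeries
        Decoded velocities (aliasing need not be resolved; wrapped systolic
        frames only increase the cardiac amplitude).
    seed : (row, col)
        One in-lumen pixel, the "operator click".
    rel_threshold : float
        Fraction of the region's maximum score a pixel must reach to join,
        default 0.3.

    Raises
    ------
    NoVesselAtSeedError
        If the seed shows neither cardiac-frequency amplitude above the
        noise floor nor appreciable mean velocity.
    """
    seed = (int(seed[0]), int(seed[1]))
    H, W = vel.velocity.shape[1:]
    if not (0 <= seed[0] < H and 0 <= seed[1] < W):
        raise ValueError(f"seed {seed} outside {H}x{W} grid")
    if not 0 < rel_threshold < 1:
        raise ValueError("rel_threshold must be in (0, 1)")

    amp = cardiac_component_amplitude(vel, n_harmonics).amplitude
    # noise scale of the amplitude map, from its median (Rayleigh statistics;
    # vessels occupy a small minority of pixels)
    noise_scale = float(np.median(amp)) / _RAYLEIGH_MEDIAN
    eps = 1e-6 * vel.venc
    # The spectral criterion needs solid contrast: below ~6x the noise scale
    # a partial-volume edge pixel cannot be told from background on the
    # amplitude map, and the grown mask shaves real edge flow.
    amp_floor = max(6.0 * noise_scale, eps)

    if amp[seed] >= amp_floor:
        mask = _grow(amp, seed, rel_threshold, floor=2.0 * noise_scale)
        grown_on = "cardiac_amplitude"
    else:
        # Low-pulsatility fallback: grow on |temporal-mean velocity|,
        # flattened by a local median so a smooth background offset can
        # neither flood the growth nor shift the threshold.
        mv_signed = vel.velocity.mean(axis=0)
        local_bg = ndimage.median_filter(mv_signed, size=25)
        mean_vel = np.abs(mv_signed - local_bg)
        med = float(np.median(mean_vel))
        mad = float(np.median(np.abs(mean_vel - med)))
        mv_floor = max(med + 5.0 * 1.4826 * mad, 0.02 * vel.venc, eps)
        if mean_vel[seed] < mv_floor:
            raise NoVesselAtSeedError(
                f"no vessel at seed {seed}: cardiac amplitude "
                f"{amp[seed]:.3g} below floor {amp_floor:.3g} and mean "
                f"velocity {mean_vel[seed]:.3g} below {mv_floor:.3g} cm/s"
            )
        mask = _grow(mean_vel, seed, rel_threshold,
                     floor=med + 3.0 * 1.4826 * mad)
        grown_on = "mean_velocity"

    roi_mean = float(vel.velocity.mean(axis=0)[mask].mean())
    direction = -1 if roi_mean < 0 else 1
    return VesselROI(mask=mask, label=label, seed=seed,
                     direction_sign=direction, grown_on=grown_on)
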