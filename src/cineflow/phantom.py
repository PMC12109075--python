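"""Synthetic CINE phase-contrast acquisitions with known ground truth.

Real cardiac-gated PC-MRI of the neck and head cannot be shipped with the
package, so this module renders circular vessel cross-sections on a 2D grid
and encodes their pulsatile through-plane velocities into magnitude/phase
stacks the way a scanner would:

* phase encoding ``phi = pi * v / Venc``, wrapped to [-pi, pi) so that
  velocities above Venc alias with opposite sign;
* partial-volume averaging at vessel edges (lumina are rasterised on a 4x
  supersampled grid and averaged down; the pixel velocity is the lumen-mean
  velocity scaled by the pixel's lumen coverage);
* a spatially smooth, temporally static background velocity offset
  (eddy-current-like), expressed as a low-order 2D polynomial;
* independent Gaussian noise on the two complex channels, giving Rician
  magnitude noise and phase noise at the requested SNR.

Arterial waveforms have a single dominant systolic peak (plus a small
dicrotic bump); venous waveforms are low-pulsatility quasi-sinusoids.  Both
are parameterised by the target mean flow (mL/min) and target pulsatility
index (max-min)/mean, which the rendered ground-truth curve attains exactly.

Cohort presets reproduce the population structure of a healthy-adult study
at the two planes: per-vessel mean flows are drawn from truncated normals
with the published per-vessel moments, epidural veins are absent in a
fraction of subjects, and the left/right jugular asymmetry spreads subjects
across drainage-dominance classes.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
from scipy import stats

from . import anatomy
from .series_io import (
    CineSeries,
    FLOW_ML_MIN_PER_CM_S_MM2,
    N_FRAMES,
    wrap_phase,
)

__all__ = [
    "FlowWaveform",
    "VesselSpec",
    "PhantomSpec",
    "GroundTruth",
    "make_waveform",
    "render_subject",
    "make_cohort",
    "COHORT_PRESETS",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True, eq=False)
class FlowWaveform:
    """32 lumen-mean velocities (cm/s) over one cardiac cycle."""

    samples: np.ndarray  # (32,), cm/s
    mean_flow_target: float  # mL/min
    pulsatility_target: float

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.shape != (N_FRAMES,):
            raise ValueError(f"waveform must have {N_FRAMES} samples")
        object.__setattr__(self, "samples", samples)


@dataclasses.dataclass(frozen=True, eq=False)
class VesselSpec:
    """One circular vessel: position, size, waveform, and flow direction.

    ``direction_sign`` follows the acquisition convention that flow toward
    the heart is positive: +1 for veins, -1 for the ascending arteries.
    """

    label: str
    center: tuple[float, float]  # (row, col), pixels
    radius: float  # mm
    waveform: FlowWaveform
    direction_sign: int = 1

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise ValueError(f"radius must be > 0, got {self.radius}")
        if self.direction_sign not in (-1, 1):
            raise ValueError("direction_sign must be +1 or -1")


@dataclasses.dataclass(frozen=True, eq=False)
class PhantomSpec:
    """Generative description of one synthetic acquisition."""

    vessels: Sequence[VesselSpec]
    grid: tuple[int, int] = (96, 96)
    pixel_area: float = 1.0  # mm^2
    venc: float = 60.0  # cm/s
    background_poly: np.ndarray | None = None  # cm/s, coeffs c[i,j] * y^i x^j
    snr: float = math.inf  # lumen magnitude / complex-channel noise sigma
    rr_ms: float = 60_000.0 / 72.0  # 72 bpm
    plane: str = "extracranial"
    tissue_magnitude: float = 0.6  # relative to lumen magnitude 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.venc > 0:
            raise ValueError(f"venc must be > 0, got {self.venc}")
        if not self.snr > 0:
            raise ValueError(f"snr must be > 0, got {self.snr}")
        labels = [v.label for v in self.vessels]
        if len(labels) != len(set(labels)):
            raise ValueError("vessel labels must be unique within a PhantomSpec")


#: a pixel belongs to the true lumen mask when at least this fraction of its
#: area is blood; matches the default relative segmentation threshold so the
#: boundary is supersampling-consistent
TRUTH_COVERAGE = 0.3


@dataclasses.dataclass(frozen=True, eq=False)
class GroundTruth:
    """True masks, flow curves (mL/min, flow-positive), and offset map."""

    masks: dict[str, np.ndarray]  # label -> (H, W) bool, coverage >= TRUTH_COVERAGE
    true_curves: dict[str, np.ndarray]  # label -> (32,) mL/min
    true_offset: np.ndarray  # (H, W), cm/s
    lumen_fractions: dict[str, np.ndarray]  # label -> (H, W) coverage in [0, 1]

    def true_mean_flow(self, label: str) -> float:
        return float(np.mean(self.true_curves[label]))


# ---------------------------------------------------------------------------
# Waveform synthesis
# ---------------------------------------------------------------------------

def _base_shape(kind: str) -> np.ndarray:
    t = np.arange(N_FRAMES, dtype=float)
    if kind == "arterial":
        # sharp systolic peak ~1/4 into the cycle + small dicrotic bump
        shape = (np.exp(-0.5 * ((t - 8.0) / 2.8) ** 2)
                 + 0.18 * np.exp(-0.5 * ((t - 17.0) / 2.5) ** 2))
    elif kind == "venous":
        # gentle quasi-sinusoidal modulation with a mild second harmonic
        shape = (np.cos(2.0 * np.pi * (t - 5.0) / N_FRAMES)
                 + 0.2 * np.cos(4.0 * np.pi * t / N_FRAMES + 0.6))
    else:
        raise ValueError(f"unknown waveform kind '{kind}'")
    return shape


def make_waveform(kind: str, mean_flow: float, pulsatility: float = 0.0,
                  area: float = 1.0) -> FlowWaveform:
    """Build a 32-sample velocity waveform with exact mean flow and PI.

    Parameters
    ----------
    kind : {"arterial", "venous", "constant"}
        Base temporal shape.  Arterial shapes carry one dominant systolic
        peak; venous shapes are low-amplitude and smooth; "constant" requires
        ``pulsatility == 0``.
    mean_flow : float
        Target cycle-averaged flow in mL/min (> 0).
    pulsatility : float
        Target pulsatility index (max - min) / mean of the flow curve.
    area : float
        Lumen area in mm^2 used to convert flow to lumen-mean velocity.

    The implied flow curve ``v * area * 0.6`` attains the requested mean and
    PI exactly (up to float round-off).  A pulsatility so large that flow
    would reverse within the cycle is rejected as infeasible for the base
    shape.
    """
    if not mean_flow > 0:
        raise ValueError(f"mean_flow must be > 0, got {mean_flow}")
    if pulsatility < 0:
        raise ValueError(f"pulsatility must be >= 0, got {pulsatility}")
    if not area > 0:
        raise ValueError(f"area must be > 0, got {area}")

    if kind == "constant":
        if pulsatility != 0:
            raise ValueError("constant waveform requires pulsatility == 0")
        factor = np.ones(N_FRAMES)
    else:
        shape = _base_shape(kind)
        s = shape - shape.mean()
        span = s.max() - s.min()
        a = pulsatility / span
        factor = 1.0 + a * s
        if factor.min() < 0:
            raise ValueError(
                f"pulsatility {pulsatility} infeasible for '{kind}' base "
                f"shape: flow would reverse (max feasible ~"
                f"{span / -s.min():.2f})"
            )
    flows = mean_flow * factor  # mL/min
    velocities = flows / (area * FLOW_ML_MIN_PER_CM_S_MM2)
    return FlowWaveform(samples=velocities, mean_flow_target=mean_flow,
                        pulsatility_target=pulsatility)


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

_SUPERSAMPLE = 4


def _disc_coverage(grid: tuple[int, int], center: tuple[float, float],
                   radius_px: float) -> np.ndarray:
    """Fraction of each pixel covered by the disc, on a 4x supersampled grid."""
    H, W = grid
    cy, cx = center
    r0 = max(0, int(math.floor(cy - radius_px - 1)))
    r1 = min(H, int(math.ceil(cy + radius_px + 2)))
    c0 = max(0, int(math.floor(cx - radius_px - 1)))
    c1 = min(W, int(math.ceil(cx + radius_px + 2)))
    n = _SUPERSAMPLE
    ys = r0 + (np.arange((r1 - r0) * n) + 0.5) / n - 0.5
    xs = c0 + (np.arange((c1 - c0) * n) + 0.5) / n - 0.5
    yy, xx = np.meshgrid(ys, xs, indexing="ij")
    inside = ((yy - cy) ** 2 + (xx - cx) ** 2) <= radius_px ** 2
    block = inside.reshape(r1 - r0, n, c1 - c0, n).mean(axis=(1, 3))
    out = np.zeros((H, W))
    out[r0:r1, c0:c1] = block
    return out


def _offset_map(grid: tuple[int, int], coeffs: np.ndarray | None) -> np.ndarray:
    """Evaluate the background polynomial on normalized [-1, 1] coordinates."""
    H, W = grid
    if coeffs is None:
        return np.zeros((H, W))
    coeffs = np.atleast_2d(np.asarray(coeffs, dtype=float))
    y = np.linspace(-1.0, 1.0, H)[:, None] * np.ones((1, W))
    x = np.ones((H, 1)) * np.linspace(-1.0, 1.0, W)[None, :]
    return np.polynomial.polynomial.polyval2d(y, x, coeffs)


def render_subject(spec: PhantomSpec) -> tuple[CineSeries, GroundTruth]:
    """Render a phantom acquisition (magnitude + wrapped phase) and its truth.

    In-lumen phase equals ``wrap(pi * (v + offset) / Venc)`` plus noise; the
    magnitude is bright in lumina, intermediate in tissue and (optionally)
    dark in air.  Rendering is deterministic given ``spec.seed``.
    """
    H, W = spec.grid
    px_size = math.sqrt(spec.pixel_area)  # mm per pixel side

    fractions: dict[str, np.ndarray] = {}
    for vessel in spec.vessels:
        cy, cx = vessel.center
        r_px = vessel.radius / px_size
        if (cy - r_px < 0 or cy + r_px > H - 1
                or cx - r_px < 0 or cx + r_px > W - 1):
            raise ValueError(
                f"vessel '{vessel.label}' (center {vessel.center}, radius "
                f"{r_px:.1f} px) extends outside the {H}x{W} grid"
            )
        fractions[vessel.label] = _disc_coverage((H, W), (cy, cx), r_px)

    # pairwise-disjoint lumina
    support = np.zeros((H, W), dtype=int)
    for frac in fractions.values():
        support += frac > 0
    if np.any(support > 1):
        raise ValueError("vessel lumina overlap; PhantomSpec requires disjoint vessels")

    offset = _offset_map(spec.grid, spec.background_poly)

    velocity = np.zeros((N_FRAMES, H, W))
    total_frac = np.zeros((H, W))
    for vessel in spec.vessels:
        frac = fractions[vessel.label]
        velocity += (vessel.direction_sign
                     * vessel.waveform.samples[:, None, None]
                     * frac[None, :, :])
        total_frac += frac
    velocity += offset[None, :, :]

    magnitude = spec.tissue_magnitude + (1.0 - spec.tissue_magnitude) * total_frac
    magnitude = np.broadcast_to(magnitude, (N_FRAMES, H, W)).copy()
    phase = wrap_phase(np.pi * velocity / spec.venc)

    if math.isfinite(spec.snr):
        rng = np.random.default_rng(spec.seed)
        sigma = 1.0 / spec.snr  # lumen magnitude is 1.0
        re = magnitude * np.cos(phase) + rng.normal(0.0, sigma, phase.shape)
        im = magnitude * np.sin(phase) + rng.normal(0.0, sigma, phase.shape)
        magnitude = np.hypot(re, im)
        phase = wrap_phase(np.arctan2(im, re))

    series = CineSeries(magnitude=magnitude, phase=phase, venc=spec.venc,
                        pixel_area=spec.pixel_area, rr_ms=spec.rr_ms,
                        plane=spec.plane)
    truth = GroundTruth(
        masks={lab: frac >= TRUTH_COVERAGE for lab, frac in fractions.items()},
        true_curves={
            v.label: (v.waveform.samples
                      * fractions[v.label].sum() * spec.pixel_area
                      * FLOW_ML_MIN_PER_CM_S_MM2)
            for v in spec.vessels
        },
        true_offset=offset,
        lumen_fractions=fractions,
    )
    return series, truth


# ---------------------------------------------------------------------------
# Cohort presets
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class _VesselPreset:
    label: str
    center: tuple[float, float]
    radius: float  # mm (pixel size is 1 mm in the presets)
    kind: str  # "arterial" | "venous"
    mean_flow: float  # mL/min, population mean
    sd_flow: float  # mL/min, population SD
    pulsatility: float
    direction_sign: int
    presence: float = 1.0  # probability the vessel is present in a subject


# Population moments follow the published healthy-adult per-vessel flows
# (mL/min, mean +/- SD); lumen radii are a modelling choice derived from
# those flows and typical lumen-mean velocities (arterial peaks of a few
# tens of cm/s), since per-vessel areas are not reported.
COHORT_PRESETS: dict[str, tuple[_VesselPreset, ...]] = {
    "extracranial": (
        _VesselPreset(anatomy.RIGHT_ICA, (30.0, 30.0), 3.0, "arterial", 288.0, 47.0, 0.95, -1),
        _VesselPreset(anatomy.LEFT_ICA, (30.0, 66.0), 3.0, "arterial", 300.0, 47.0, 0.95, -1),
        _VesselPreset(anatomy.RIGHT_VA, (44.0, 36.0), 2.5, "arterial", 99.0, 48.0, 0.90, -1),
        _VesselPreset(anatomy.LEFT_VA, (44.0, 60.0), 2.5, "arterial", 122.0, 48.0, 0.90, -1),
        _VesselPreset(anatomy.RIGHT_IJV, (28.0, 14.0), 4.5, "venous", 329.0, 168.0, 0.70, 1),
        _VesselPreset(anatomy.LEFT_IJV, (28.0, 82.0), 4.5, "venous", 207.0, 134.0, 0.70, 1),
        _VesselPreset(anatomy.RIGHT_EV, (56.0, 40.0), 2.0, "venous", 32.0, 39.0, 0.50, 1,
                      presence=28.0 / 36.0),
        _VesselPreset(anatomy.LEFT_EV, (56.0, 56.0), 2.0, "venous", 23.0, 18.0, 0.50, 1,
                      presence=27.0 / 36.0),
        _VesselPreset(anatomy.POSTERIOR, (66.0, 48.0), 3.0, "venous", 127.0, 99.0, 0.50, 1),
    ),
    "intracranial": (
        _VesselPreset(anatomy.RIGHT_ICA, (38.0, 32.0), 3.0, "arterial", 284.0, 60.0, 0.85, -1),
        _VesselPreset(anatomy.LEFT_ICA, (38.0, 64.0), 3.0, "arterial", 289.0, 67.0, 0.85, -1),
        _VesselPreset(anatomy.BASILAR, (24.0, 48.0), 2.5, "arterial", 178.0, 61.0, 0.80, -1),
        _VesselPreset(anatomy.STRAIGHT_SINUS, (58.0, 48.0), 2.5, "venous", 116.0, 37.0, 0.35, 1),
        _VesselPreset(anatomy.SSS, (72.0, 48.0), 4.0, "venous", 341.0, 61.0, 0.35, 1),
    ),
}

_MIN_FLOW = 5.0  # mL/min, truncation floor for sampled mean flows


def _sample_mean_flow(rng: np.random.Generator, mean: float, sd: float) -> float:
    a = (_MIN_FLOW - mean) / sd
    return float(stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, random_state=rng))


def preset_flow_distribution(preset: str, label: str) -> tuple[float, float, float]:
    """(truncated-normal mean, population mean, SD) for one preset vessel."""
    for v in COHORT_PRESETS[preset]:
        if v.label == label:
            a = (_MIN_FLOW - v.mean_flow) / v.sd_flow
            tmean = float(stats.truncnorm.mean(a, np.inf, loc=v.mean_flow,
                                               scale=v.sd_flow))
            return tmean, v.mean_flow, v.sd_flow
    raise KeyError(label)


def subject_spec(preset: str, seed: int, *, snr: float = 20.0,
                 rng: np.random.Generator | None = None,
                 suppress: Sequence[str] = ()) -> PhantomSpec:
    """Sample one subject's PhantomSpec from a cohort preset.

    ``suppress`` forces the named vessels to be absent (used e.g. to build
    subjects without jugular drainage).
    """
    if preset not in COHORT_PRESETS:
        raise ValueError(f"unknown preset '{preset}'")
    if rng is None:
        rng = np.random.default_rng(seed)
    vessels = []
    for vp in COHORT_PRESETS[preset]:
        if vp.label in suppress:
            continue
        if vp.presence < 1.0 and rng.random() >= vp.presence:
            continue
        flow = _sample_mean_flow(rng, vp.mean_flow, vp.sd_flow)
        pi = max(0.1, rng.normal(vp.pulsatility, 0.05))
        area = math.pi * vp.radius ** 2
        wave = make_waveform(vp.kind, flow, pi, area)
        # anatomical position varies between subjects; sub-pixel jitter
        center = (vp.center[0] + rng.uniform(-0.5, 0.5),
                  vp.center[1] + rng.uniform(-0.5, 0.5))
        vessels.append(VesselSpec(label=vp.label, center=center,
                                  radius=vp.radius, waveform=wave,
                                  direction_sign=vp.direction_sign))
    # smooth eddy-current-like offset, |offset| <= ~0.05 * Venc
    coeffs = np.array([
        [rng.uniform(-1.5, 1.5), rng.uniform(-0.7, 0.7), rng.uniform(-0.3, 0.3)],
        [rng.uniform(-0.7, 0.7), rng.uniform(-0.3, 0.3), 0.0],
        [rng.uniform(-0.3, 0.3), 0.0, 0.0],
    ])
    return PhantomSpec(vessels=tuple(vessels), venc=60.0, snr=snr,
                       background_poly=coeffs, plane=preset,
                       seed=int(rng.integers(0, 2 ** 31)))


def make_cohort(n_subjects: int, preset: str, seed: int, *,
                snr: float = 20.0) -> list[tuple[CineSeries, GroundTruth]]:
    """Render ``n_subjects`` independent subjects from a plane preset.

    Per-vessel mean flows are drawn from truncated normals with the preset's
    published moments; epidural veins are present only in the published
    fraction of subjects.  Deterministic given ``seed``.
    """
    if n_subjects < 1:
        raise ValueError(f"n_subjects must be >= 1, got {n_subjects}")
    root = np.random.SeedSequence(seed)
    out = []
    for child in root.spawn(n_subjects):
        rng = np.random.default_rng(child)
        spec = subject_spec(preset, 0, snr=snr, rng=rng)
        out.append(render_subject(spec))
    return out
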