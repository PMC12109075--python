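"""Per-vessel flow curves and the pulsatility index.

The flow through a fixed ROI at cardiac phase t is the ROI-mean velocity
times the ROI area,

    Q_t = mean(v_t over mask) * (n_pixels * pixel_area) * 0.6   [mL/min]

with the exact unit constant 0.6 converting cm/s * mm^2 to mL/min.  The
pulsatility index of a curve is (max - min) / mean; it is dimensionless,
invariant under positive scaling, and zero iff the curve is constant.

Curves keep the signed flow convention (toward the heart positive).  The PI
formula uses signed flows; a curve with non-positive mean is rejected rather
than silently flipped — pass ``negate=True`` to :func:`flow_curve` for
vessels whose dominant direction is away from the heart.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .segmentation import VesselROI
from .series_io import FLOW_ML_MIN_PER_CM_S_MM2, N_FRAMES, VelocitySeries

__all__ = ["FlowCurve", "flow_curve", "pulsatility_index"]


@dataclasses.dataclass(frozen=True, eq=False)
class FlowCurve:
    """A 32-sample flow waveform in mL/min."""

    samples: np.ndarray  # (32,)
    label: str = "flow"

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.shape != (N_FRAMES,):
            raise ValueError(f"flow curve must have {N_FRAMES} samples")
        object.__setattr__(self, "samples", samples)

    @property
    def mean(self) -> float:
        return float(self.samples.mean())

    @property
    def min(self) -> float:
        return float(self.samples.min())

    @property
    def max(self) -> float:
        return float(self.samples.max())

    @property
    def pulsatility_index(self) -> float:
        return pulsatility_index(self)

    def summary(self) -> dict:
        return {"label": self.label, "mean": self.mean, "min": self.min,
                "max": self.max, "pi": self.pulsatility_index}


def flow_curve(vel: VelocitySeries, roi: VesselROI, *, negate: bool = False,
               label: str | None = None) -> FlowCurve:
    """Flow curve of one vessel ROI over the cardiac cycle.

    ``negate=True`` flips the sign, orienting arterial (heart-to-head)
    curves positive.  Flow is linear in the ROI: the curve of a union of
    disjoint ROIs equals the sum of their curves exactly.
    """
    if not roi.mask.any():
        raise ValueError("ROI must be non-empty")
    samples = (vel.velocity[:, roi.mask].sum(axis=1)
               * vel.pixel_area * FLOW_ML_MIN_PER_CM_S_MM2)
    if negate:
        samples = -samples
    return FlowCurve(samples=samples, label=label or roi.label)


def pulsatility_index(curve: FlowCurve) -> float:
    """(maximum flow - minimum flow) / mean flow of a cycle.

    Requires a positive mean; orient the curve first (see
    :func:`flow_curve`) for vessels measured against the sign convention.
    """
    mean = curve.mean
    if mean == 0:
        raise ValueError("pulsatility index undefined for zero-mean curve")
    if mean < 0:
        raise ValueError(
            "pulsatility index requires positive mean flow; negate the "
            "curve for vessels flowing away from the heart"
        )
    return (curve.max - curve.min) / mean
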