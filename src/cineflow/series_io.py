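"""I/O and phase decoding for cardiac-gated CINE phase-contrast series.

A CINE-PC acquisition stores, for one imaging plane, a magnitude image and a
phase image at each of 32 reconstructed cardiac phases.  Velocity is encoded
linearly in the phase: a pixel moving through-plane at the velocity-encoding
limit (Venc, in cm/s) acquires a phase of +/- pi radians, so

    v = (phi / pi) * Venc        [cm/s]

Velocities beyond Venc wrap (alias) and reappear with opposite sign; the
decoded value is always in [-Venc, Venc).  Unwrapping up to 2*Venc is handled
downstream by :mod:`cineflow.correction`.

Conventions used throughout the package:

* arrays are indexed ``(frame, row, col)``, 0-based, frame 0 at the R-wave;
* positive velocity means flow directed toward the heart;
* the native on-disk format is a pair of 4D NIfTI volumes (magnitude, phase)
  plus a JSON sidecar carrying Venc, pixel geometry, and cardiac timing.
  Vendor DICOM dialects are deliberately out of scope.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable

import nibabel as nib
import numpy as np
import pandas as pd

#: Number of reconstructed images per cardiac cycle.
N_FRAMES = 32

#: Flow produced by 1 cm/s across 1 mm^2, in mL/min:
#: 1 cm/s = 10 mm/s -> 10 mm^3/s across 1 mm^2 -> * 60 s/min / 1000 mm^3/mL.
FLOW_ML_MIN_PER_CM_S_MM2 = 10.0 * 60.0 / 1000.0

#: Required JSON sidecar fields.
SIDECAR_FIELDS = ("venc_cm_s", "pixel_area_mm2", "rr_ms", "plane")


def wrap_phase(phi: np.ndarray | float) -> np.ndarray | float:
    """Wrap phase to the half-open interval [-pi, pi)."""
    return np.mod(np.asarray(phi) + np.pi, 2.0 * np.pi) - np.pi


@dataclasses.dataclass(frozen=True, eq=False)
class CineSeries:
    """One acquisition plane: magnitude + phase stacks over a cardiac cycle.

    Attributes
    ----------
    magnitude : ndarray, shape (32, H, W)
        Non-negative signal magnitude.
    phase : ndarray, shape (32, H, W)
        Phase in radians, wrapped to [-pi, pi).
    venc : float
        Velocity-encoding limit in cm/s.
    pixel_area : float
        In-plane pixel area in mm^2.
    rr_ms : float
        Cardiac (R-R) period in ms.
    plane : str
        Plane label, e.g. ``"extracranial"`` or ``"intracranial"``.
    """

    magnitude: np.ndarray
    phase: np.ndarray
    venc: float
    pixel_area: float
    rr_ms: float
    plane: str

    def __post_init__(self) -> None:
        mag = np.asarray(self.magnitude, dtype=float)
        phs = np.asarray(self.phase, dtype=float)
        if mag.shape != phs.shape:
            raise ValueError(
                f"magnitude shape {mag.shape} != phase shape {phs.shape}"
            )
        if mag.ndim != 3 or mag.shape[0] != N_FRAMES:
            raise ValueError(
                f"expected ({N_FRAMES}, H, W) stacks, got shape {mag.shape}"
            )
        if np.any(mag < 0):
            raise ValueError("magnitude must be non-negative")
        if not self.venc > 0:
            raise ValueError(f"venc must be > 0, got {self.venc}")
        if not self.pixel_area > 0:
            raise ValueError(f"pixel_area must be > 0, got {self.pixel_area}")
        object.__setattr__(self, "magnitude", mag)
        object.__setattr__(self, "phase", phs)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.magnitude.shape


@dataclasses.dataclass(frozen=True, eq=False)
class VelocitySeries:
    """Decoded through-plane velocity in cm/s over the cardiac cycle."""

    velocity: np.ndarray  # (32, H, W), cm/s
    venc: float
    pixel_area: float

    def __post_init__(self) -> None:
        vel = np.asarray(self.velocity, dtype=float)
        if vel.ndim != 3 or vel.shape[0] != N_FRAMES:
            raise ValueError(
                f"expected ({N_FRAMES}, H, W) velocities, got shape {vel.shape}"
            )
        if not self.venc > 0:
            raise ValueError(f"venc must be > 0, got {self.venc}")
        object.__setattr__(self, "velocity", vel)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.velocity.shape


def phase_to_velocity(series: CineSeries) -> VelocitySeries:
    """Decode phase into through-plane velocity, v = (phi/pi) * Venc.

    The mapping is linear and odd; wrapped phases decode to velocities in
    [-Venc, Venc) regardless of the true speed (aliasing is not resolved
    here).
    """
    if not series.venc > 0:
        raise ValueError(f"venc must be > 0, got {series.venc}")
    v = (series.phase / np.pi) * series.venc
    return VelocitySeries(velocity=v, venc=series.venc, pixel_area=series.pixel_area)


# ---------------------------------------------------------------------------
# On-disk round trip: NIfTI pair + JSON sidecar
# ---------------------------------------------------------------------------

def write_series(series: CineSeries, prefix: str | Path) -> Path:
    """Write a series as ``<prefix>_mag.nii.gz``, ``<prefix>_phase.nii.gz``
    and ``<prefix>.json``; returns the prefix path."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    affine = np.eye(4)
    for name, stack in (("mag", series.magnitude), ("phase", series.phase)):
        # NIfTI wants spatial axes first: (row, col, 1, frame)
        data = np.moveaxis(stack, 0, -1)[:, :, np.newaxis, :]
        nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine),
                 str(prefix) + f"_{name}.nii.gz")
    sidecar = {
        "venc_cm_s": series.venc,
        "pixel_area_mm2": series.pixel_area,
        "rr_ms": series.rr_ms,
        "plane": series.plane,
    }
    Path(str(prefix) + ".json").write_text(json.dumps(sidecar, indent=2))
    return prefix


def read_series(prefix: str | Path) -> CineSeries:
    """Read a series written by :func:`write_series`.

    Raises
    ------
    FileNotFoundError
        If any of the three files is absent.
    ValueError
        If the sidecar lacks a required field (the message names it).
    """
    prefix = Path(prefix)
    sidecar_path = Path(str(prefix) + ".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    for field in SIDECAR_FIELDS:
        if field not in sidecar:
            raise ValueError(f"sidecar missing required field '{field}'")
    stacks = {}
    for name in ("mag", "phase"):
        path = Path(str(prefix) + f"_{name}.nii.gz")
        if not path.exists():
            raise FileNotFoundError(f"missing image file {path}")
        data = np.asanyarray(nib.load(str(path)).dataobj, dtype=np.float64)
        stacks[name] = np.moveaxis(data[:, :, 0, :], -1, 0)
    return CineSeries(
        magnitude=stacks["mag"],
        phase=stacks["phase"],
        venc=float(sidecar["venc_cm_s"]),
        pixel_area=float(sidecar["pixel_area_mm2"]),
        rr_ms=float(sidecar["rr_ms"]),
        plane=str(sidecar["plane"]),
    )


# ---------------------------------------------------------------------------
# Tabular results
# ---------------------------------------------------------------------------

def write_results(curves: Iterable, path: str | Path, *,
                  subject: str = "subject", plane: str = "unknown") -> Path:
    """Write flow curves as a long CSV table.

    ``curves`` is any iterable of objects with ``.label`` and ``.samples``
    (e.g. :class:`cineflow.flow_quant.FlowCurve`).  Columns:
    subject, plane, vessel, frame (0-31), flow_ml_min.
    """
    rows = []
    for curve in curves:
        samples = np.asarray(curve.samples, dtype=float)
        for frame, q in enumerate(samples):
            rows.append((subject, plane, curve.label, frame, q))
    table = pd.DataFrame(
        rows, columns=["subject", "plane", "vessel", "frame", "flow_ml_min"]
    )
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)
    return path


def read_results(path: str | Path) -> pd.DataFrame:
    """Read a flow-curve table written by :func:`write_results`."""
    table = pd.read_csv(path)
    expected = {"subject", "plane", "vessel", "frame", "flow_ml_min"}
    missing = expected - set(table.columns)
    if missing:
        raise ValueError(f"results table missing columns: {sorted(missing)}")
    return table
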