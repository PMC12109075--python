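"""Shared phantom fixtures.

All fixtures are generated programmatically; nothing is read from disk.
"""

from __future__ import annotations

import math

import pytest

from cineflow.phantom import (
    PhantomSpec,
    VesselSpec,
    make_waveform,
    render_subject,
)
from cineflow.series_io import FLOW_ML_MIN_PER_CM_S_MM2


def single_vessel_spec(*, velocity: float = 30.0, radius: float = 4.0,
                       venc: float = 60.0, kind: str = "constant",
                       pulsatility: float = 0.0, center=(48.0, 48.0),
                       direction_sign: int = 1, snr: float = math.inf,
                       background_poly=None, seed: int = 0) -> PhantomSpec:
    """One circular vessel with a lumen-mean velocity waveform."""
    area = math.pi * radius ** 2
    mean_flow = velocity * area * FLOW_ML_MIN_PER_CM_S_MM2
    wave = make_waveform(kind, mean_flow, pulsatility, area)
    vessel = VesselSpec(label="vessel", center=center, radius=radius,
                        waveform=wave, direction_sign=direction_sign)
    return PhantomSpec(vessels=(vessel,), venc=venc, snr=snr,
                       background_poly=background_poly, seed=seed)


@pytest.fixture
def noiseless_artery():
    """Noiseless pulsatile artery (PI 0.9, mean 20 cm/s, r = 4 px)."""
    spec = single_vessel_spec(velocity=20.0, radius=4.0, kind="arterial",
                              pulsatility=0.9)
    return render_subject(spec)


@pytest.fixture
def noiseless_constant_vessel():
    """Noiseless steady vessel: 30 cm/s everywhere in the lumen, Venc 60."""
    spec = single_vessel_spec(velocity=30.0, radius=4.0)
    return render_subject(spec)
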