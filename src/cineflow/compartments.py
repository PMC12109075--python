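"""Compartment sums, contribution ratios, drainage dominance and statistics.

At each plane the vessel curves are summed into an arterial and a venous
compartment (ExtraArt/ExtraVein at the cervical level, IntraArt/IntraVein
intracranially).  Each vessel's contribution is its mean flow divided by its
compartment's mean.  Because cerebral venous anatomy is variable, some veins
are genuinely undetectable in a subject; they contribute zero flow and are
flagged missing, never imputed.  The "remaining" flow — arterial inflow
minus measured venous outflow — estimates drainage through pathways the
acquisition misses, under the assumption that cycle-averaged inflow equals
outflow (Monro–Kellie).

Venous drainage dominance compares the main venous pathway (jugular veins
extracranially, straight + superior sagittal sinuses intracranially) to the
arterial compartment mean: a share above 60% is pathway-dominant, 40–60%
(inclusive) balanced, below 40% peripheral-dominant.  A sensitivity analysis
re-classifies a cohort under shifted thresholds.

Group comparisons use the two-sample pooled-variance Student's t-test with
``df = n_a + n_b - 2``, two-sided, without multiple-comparison correction.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .flow_quant import FlowCurve
from .series_io import N_FRAMES

__all__ = [
    "CompartmentFlow",
    "DominanceResult",
    "TTestResult",
    "sum_compartment",
    "vessel_contribution",
    "remaining_flow",
    "classify_dominance",
    "sensitivity_analysis",
    "compare_groups",
    "CATEGORIES",
]

CATEGORIES = ("dominant", "balanced", "peripheral")


@dataclasses.dataclass(frozen=True, eq=False)
class CompartmentFlow:
    """Framewise sum of member vessel curves."""

    name: str
    members: tuple[str, ...]
    curve: np.ndarray  # (32,), mL/min
    missing: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        curve = np.asarray(self.curve, dtype=float)
        if curve.shape != (N_FRAMES,):
            raise ValueError(f"compartment curve must have {N_FRAMES} samples")
        object.__setattr__(self, "curve", curve)

    @property
    def mean(self) -> float:
        return float(self.curve.mean())


@dataclasses.dataclass(frozen=True)
class DominanceResult:
    """Drainage classification of one venous pathway share."""

    ratio: float
    category: str
    thresholds: tuple[float, float] = (0.40, 0.60)


TTestResult = dataclasses.make_dataclass(
    "TTestResult", [("t", float), ("df", int), ("p", float)], frozen=True
)


def sum_compartment(curves: Iterable[FlowCurve], name: str,
                    members: Sequence[str], *,
                    known_labels: Sequence[str] | None = None) -> CompartmentFlow:
    """Sum the member vessels' curves framewise.

    Members without a measured curve contribute zero and are recorded in
    ``missing`` (anatomically absent or undetected veins).  If
    ``known_labels`` is given, any member outside that vocabulary is
    rejected as an unknown vessel label.
    """
    members = tuple(members)
    if known_labels is not None:
        unknown = [m for m in members if m not in known_labels]
        if unknown:
            raise ValueError(f"unknown member label(s): {unknown}")
    by_label: dict[str, FlowCurve] = {}
    for curve in curves:
        if curve.label in by_label:
            raise ValueError(f"duplicate curve label '{curve.label}'")
        by_label[curve.label] = curve
    total = np.zeros(N_FRAMES)
    missing = []
    for member in members:
        if member in by_label:
            total = total + by_label[member].samples
        else:
            missing.append(member)
    return CompartmentFlow(name=name, members=members, curve=total,
                           missing=tuple(missing))


def vessel_contribution(vessel: FlowCurve, compartment: CompartmentFlow) -> float:
    """Mean-flow share of one vessel within its compartment."""
    if not compartment.mean > 0:
        raise ValueError(
            f"compartment '{compartment.name}' mean must be > 0 "
            f"(got {compartment.mean})"
        )
    return vessel.mean / compartment.mean


def remaining_flow(arterial: CompartmentFlow,
                   venous_measured: CompartmentFlow) -> float:
    """Arterial inflow minus measured venous outflow, in mL/min.

    Positive values estimate drainage through undetected pathways; negative
    values (measured venous outflow exceeding arterial inflow) are returned
    as-is, not clamped.
    """
    if not arterial.mean > 0:
        raise ValueError("arterial compartment mean must be > 0")
    return arterial.mean - venous_measured.mean


def classify_dominance(ratio: float, low: float = 0.40,
                       high: float = 0.60) -> DominanceResult:
    """Classify a venous pathway share of arterial inflow.

    ``ratio > high`` -> dominant; ``low <= ratio <= high`` -> balanced
    (boundaries inclusive); ``ratio < low`` -> peripheral.  The three
    categories partition [0, inf).
    """
    if ratio < 0:
        raise ValueError(f"ratio must be >= 0, got {ratio}")
    if not low < high:
        raise ValueError(f"thresholds must satisfy low < high, got {(low, high)}")
    if ratio > high:
        category = "dominant"
    elif ratio >= low:
        category = "balanced"
    else:
        category = "peripheral"
    return DominanceResult(ratio=float(ratio), category=category,
                           thresholds=(low, high))


def sensitivity_analysis(ratios: Sequence[float],
                         thresholds: Sequence[tuple[float, float]]
                         ) -> pd.DataFrame:
    """Category counts of a cohort under each (low, high) threshold pair.

    Returns a DataFrame indexed by threshold pair with one column per
    category; counts sum to ``len(ratios)`` in every row.
    """
    ratios = list(ratios)
    if not ratios:
        raise ValueError("ratios must be non-empty")
    rows = {}
    for low, high in thresholds:
        if not low < high:
            raise ValueError(f"thresholds must satisfy low < high, got {(low, high)}")
        counts = dict.fromkeys(CATEGORIES, 0)
        for r in ratios:
            counts[classify_dominance(r, low, high).category] += 1
        rows[(low, high)] = counts
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=CATEGORIES)
    frame.index.name = "thresholds"
    return frame


def compare_groups(a: Sequence[float], b: Sequence[float]) -> TTestResult:
    """Two-sample pooled-variance Student's t-test, two-sided."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    df = a.size + b.size - 2
    pooled = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / df
    if pooled == 0:
        raise ValueError("zero pooled variance: t statistic undefined")
    result = stats.ttest_ind(a, b, equal_var=True)
    return TTestResult(t=float(result.statistic), df=df,
                       p=float(result.pvalue))
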