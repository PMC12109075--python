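"""Compartment sums, drainage classification and group statistics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cineflow import anatomy
from cineflow.compartments import (
    CATEGORIES,
    classify_dominance,
    compare_groups,
    remaining_flow,
    sensitivity_analysis,
    sum_compartment,
    vessel_contribution,
)
from cineflow.flow_quant import FlowCurve
from cineflow.series_io import N_FRAMES


def _const_curve(label: str, value: float) -> FlowCurve:
    return FlowCurve(samples=np.full(N_FRAMES, float(value)), label=label)


class TestSumCompartment:
    def test_member_means_add(self):
        members = list(anatomy.EXTRA_ART_MEMBERS)
        curves = [_const_curve(m, v)
                  for m, v in zip(members, (288.0, 300.0, 99.0, 122.0))]
        comp = sum_compartment(curves, "ExtraArt", members)
        assert comp.mean == pytest.approx(809.0)
        assert comp.missing == ()

    def test_absent_members_flagged_missing(self):
        comp = sum_compartment([], "ExtraVein", anatomy.EXTRA_VEIN_MEMBERS)
        assert comp.mean == 0.0
        assert set(comp.missing) == set(anatomy.EXTRA_VEIN_MEMBERS)

    def test_framewise_sum_is_exact(self):
        rng = np.random.default_rng(3)
        curves = [FlowCurve(samples=rng.normal(200, 80, N_FRAMES), label=f"v{i}")
                  for i in range(4)]
        comp = sum_compartment(curves, "c", [c.label for c in curves])
        expected = np.sum([c.samples for c in curves], axis=0)
        np.testing.assert_array_equal(comp.curve, expected)
        assert comp.mean == pytest.approx(np.mean([c.mean for c in curves])
                                          * len(curves))

    def test_unknown_member_label_rejected(self):
        with pytest.raises(ValueError, match="unknown member"):
            sum_compartment([], "IntraArt", ["middle_cerebral"],
                            known_labels=anatomy.PLANE_VESSELS["intracranial"])

    def test_duplicate_curve_labels_rejected(self):
        curves = [_const_curve("a", 100.0), _const_curve("a", 200.0)]
        with pytest.raises(ValueError, match="duplicate"):
            sum_compartment(curves, "c", ["a"])


class TestContributionsAndRemaining:
    def test_half_contribution(self):
        comp = sum_compartment([_const_curve("a", 300.0),
                                _const_curve("b", 300.0)], "c", ["a", "b"])
        assert vessel_contribution(_const_curve("a", 300.0), comp) == 0.5

    def test_sole_vessel_contributes_everything(self):
        comp = sum_compartment([_const_curve("a", 250.0)], "c", ["a"])
        assert vessel_contribution(_const_curve("a", 250.0), comp) == 1.0

    def test_contributions_sum_to_one(self):
        rng = np.random.default_rng(4)
        curves = [FlowCurve(samples=rng.uniform(50, 400, N_FRAMES),
                            label=f"v{i}") for i in range(5)]
        comp = sum_compartment(curves, "c", [c.label for c in curves])
        total = sum(vessel_contribution(c, comp) for c in curves)
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_remaining_flow_difference(self):
        art = sum_compartment([_const_curve("a", 800.0)], "art", ["a"])
        ven = sum_compartment([_const_curve("v", 600.0)], "ven", ["v"])
        assert remaining_flow(art, ven) == pytest.approx(200.0)

    def test_perfect_balance_gives_zero(self):
        art = sum_compartment([_const_curve("a", 800.0)], "art", ["a"])
        assert remaining_flow(art, art) == 0.0

    def test_excess_venous_flow_not_clamped(self):
        art = sum_compartment([_const_curve("a", 700.0)], "art", ["a"])
        ven = sum_compartment([_const_curve("v", 900.0)], "ven", ["v"])
        assert remaining_flow(art, ven) == pytest.approx(-200.0)


class TestClassifyDominance:
    @pytest.mark.parametrize("ratio, category", [
        (0.65, "dominant"),
        (0.50, "balanced"),
        (0.35, "peripheral"),
        (0.40, "balanced"),  # boundaries inclusive
        (0.60, "balanced"),
        (0.601, "dominant"),
        (0.0, "peripheral"),
        (1.5, "dominant"),
    ])
    def test_forty_sixty_rule(self, ratio, category):
        assert classify_dominance(ratio).category == category

    @given(st.floats(min_value=0.0, max_value=2.0))
    @settings(max_examples=200, deadline=None)
    def test_partition_is_exhaustive_and_exclusive(self, ratio):
        result = classify_dominance(ratio)
        assert result.category in CATEGORIES

    @given(st.floats(min_value=0.0, max_value=2.0),
           st.floats(min_value=0.0, max_value=2.0))
    @settings(max_examples=200, deadline=None)
    def test_classification_is_monotone(self, r1, r2):
        order = {"peripheral": 0, "balanced": 1, "dominant": 2}
        lo, hi = sorted((r1, r2))
        assert (order[classify_dominance(lo).category]
                <= order[classify_dominance(hi).category])

    def test_negative_ratio_rejected(self):
        with pytest.raises(ValueError):
            classify_dominance(-0.1)


class TestSensitivityAnalysis:
    def test_three_way_split(self):
        table = sensitivity_analysis([0.65, 0.50, 0.35], [(0.40, 0.60)])
        assert table.loc[(0.40, 0.60)].tolist() == [1, 1, 1]

    def test_matches_per_ratio_oracle(self):
        rng = np.random.default_rng(9)
        ratios = rng.uniform(0.0, 1.2, 50)
        thresholds = [(0.35, 0.55), (0.40, 0.60), (0.45, 0.65)]
        table = sensitivity_analysis(ratios, thresholds)
        for low, high in thresholds:
            counts = dict.fromkeys(CATEGORIES, 0)
            for r in ratios:  # brute-force reclassification
                if r > high:
                    counts["dominant"] += 1
                elif r >= low:
                    counts["balanced"] += 1
                else:
                    counts["peripheral"] += 1
            assert table.loc[(low, high)].to_dict() == counts

    def test_counts_partition_sample_at_every_threshold(self):
        rng = np.random.default_rng(10)
        ratios = rng.uniform(0.0, 1.2, 37)
        table = sensitivity_analysis(ratios, [(0.3, 0.5), (0.4, 0.6)])
        assert (table.sum(axis=1) == 37).all()

    def test_unordered_thresholds_rejected(self):
        with pytest.raises(ValueError):
            sensitivity_analysis([0.5], [(0.6, 0.4)])
        with pytest.raises(ValueError, match="non-empty"):
            sensitivity_analysis([], [(0.4, 0.6)])

    def test_deterministic_recovery_of_generative_classes(self):
        # ratios drawn with known class labels are recovered exactly
        rng = np.random.default_rng(11)
        labels = rng.choice(CATEGORIES, size=200, p=[0.6, 0.3, 0.1])
        span = {"dominant": (0.61, 1.3), "balanced": (0.40, 0.60),
                "peripheral": (0.0, 0.399)}
        ratios = [rng.uniform(*span[lab]) for lab in labels]
        recovered = [classify_dominance(r).category for r in ratios]
        assert recovered == list(labels)


class TestCompareGroups:
    def test_identical_groups(self):
        result = compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert result.t == pytest.approx(0.0)
        assert result.p == pytest.approx(1.0)
        assert result.df == 4

    def test_matches_pooled_variance_closed_form(self):
        a, b = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        result = compare_groups(a, b)
        # independent closed-form oracle
        na, nb = len(a), len(b)
        sp2 = ((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1)) / (na + nb - 2)
        t_oracle = (np.mean(a) - np.mean(b)) / math.sqrt(sp2 * (1 / na + 1 / nb))
        assert result.t == pytest.approx(t_oracle, rel=1e-12)
        assert result.df == 4

    def test_swapping_groups_negates_t(self):
        r1 = compare_groups([1.0, 2.0, 4.0], [3.0, 5.0, 8.0])
        r2 = compare_groups([3.0, 5.0, 8.0], [1.0, 2.0, 4.0])
        assert r1.t == pytest.approx(-r2.t)
        assert r1.p == pytest.approx(r2.p)

    def test_zero_pooled_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            compare_groups([2.0, 2.0], [2.0, 2.0])

    def test_tiny_groups_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([1.0], [2.0, 3.0])
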