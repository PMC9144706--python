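"""OEL resolution: tier hierarchy, group matching, RCP, the three methods."""

import pytest
from hypothesis import given, settings, strategies as st

from olfrisk import (
    assign_oels,
    match_group,
    rcp_oel,
    resolve_specific_oel,
)
from olfrisk.types import ValidationError

from conftest import cm, make_sample


class TestSpecificResolution:
    def test_single_tier_candidate(self, small_catalogues):
        a = resolve_specific_oel(cm("ethanol", 1.0, cas="64-17-5"), small_catalogues)
        assert a.method == "specific"
        assert a.tier == "dnel"
        assert a.oel_15min == 1900.0

    def test_absent_substance_is_unassigned(self, small_catalogues):
        a = resolve_specific_oel(cm("unobtainium", 1.0), small_catalogues)
        assert a.method == "unassigned"
        assert a.oel_15min is None

    def test_lowest_value_within_tier(self, small_catalogues):
        # two national OELs, 300 and 190: the precautionary choice is 190
        a = resolve_specific_oel(cm("styrene", 1.0, cas="100-42-5"), small_catalogues)
        assert a.oel_15min == 190.0

    def test_higher_tier_beats_lower_value(self, small_catalogues):
        # benzene: international 3.25 outranks the lower DNEL 1.6
        a = resolve_specific_oel(cm("benzene", 1.0, cas="71-43-2"), small_catalogues)
        assert a.tier == "international_oel"
        assert a.oel_15min == 3.25

    def test_name_match_without_cas(self, small_catalogues):
        a = resolve_specific_oel(cm("  Toluene ", 1.0), small_catalogues)
        assert a.oel_15min == 384.0


class TestGroupMatching:
    def test_aromatic_c9_matches_c9_c14(self, small_catalogues):
        a = match_group(cm("1,2,4-trimethylbenzene", 1.0, cas="95-63-6"),
                        small_catalogues)
        assert a.method == "group"
        assert a.oel_15min == 100.0

    def test_overlapping_groups_take_lowest(self, small_catalogues):
        # aliphatic C7 is inside both C6-C8 (1400) and the C5-C8 mixture
        # group (300): 300 wins
        a = match_group(cm("n-heptane", 1.0, cas="142-82-5"), small_catalogues)
        assert a.oel_15min == 300.0

    def test_aliphatic_c10(self, small_catalogues):
        a = match_group(cm("n-decane", 1.0, cas="124-18-5"), small_catalogues)
        assert a.oel_15min == 600.0

    def test_unannotated_compound_unassigned(self, small_catalogues):
        a = match_group(cm("mystery", 1.0), small_catalogues)
        assert a.method == "unassigned"
        assert "annotation" in a.trace


class TestRCP:
    def test_equal_limits_identity(self):
        assert rcp_oel([0.25, 0.25, 0.5], [600.0, 600.0, 600.0]) == pytest.approx(600.0)

    def test_harmonic_mean_arithmetic(self):
        # 1 / (0.5/100 + 0.5/300) = 150
        assert rcp_oel([0.5, 0.5], [100.0, 300.0]) == pytest.approx(150.0)

    def test_single_component(self):
        assert rcp_oel([1.0], [250.0]) == pytest.approx(250.0)

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValidationError, match="sum to 1"):
            rcp_oel([0.5, 0.4], [100.0, 300.0])

    def test_nonpositive_limit_rejected(self):
        with pytest.raises(ValidationError):
            rcp_oel([0.5, 0.5], [100.0, 0.0])

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.tuples(
                st.floats(0.01, 10.0),     # raw weight
                st.floats(0.1, 5000.0),    # component limit
            ),
            min_size=1,
            max_size=10,
        )
    )
    def test_result_bounded_by_components(self, pairs):
        weights = [w for w, _ in pairs]
        limits = [o for _, o in pairs]
        total = sum(weights)
        fractions = [w / total for w in weights]
        # renormalise exactly within tolerance
        fractions[-1] = 1.0 - sum(fractions[:-1])
        value = rcp_oel(fractions, limits)
        assert min(limits) - 1e-9 <= value <= max(limits) + 1e-9


class TestAssignMethods:
    def test_fully_covered_sample_identical_across_methods(self, small_catalogues):
        sample = make_sample([cm("toluene", 2.0, cas="108-88-3"),
                              cm("benzene", 0.05, cas="71-43-2")])
        sets = [assign_oels(sample, small_catalogues, m) for m in (1, 2, 3)]
        values = [[a.oel_15min for a in s.assignments] for s in sets]
        assert values[0] == values[1] == values[2]
        assert all(s.coverage.nc_percent_count == 0 for s in sets)

    def test_method2_gains_exactly_the_group_matchable(self, small_catalogues):
        comps = [cm("toluene", 1.0, cas="108-88-3")] * 8 + [
            cm("n-decane", 0.6, cas="124-18-5"),                 # group-matchable
            cm("1,2,4-trimethylbenzene", 0.5, cas="95-63-6"),    # group-matchable
        ]
        sample = make_sample(comps)
        s1 = assign_oels(sample, small_catalogues, 1)
        s2 = assign_oels(sample, small_catalogues, 2)
        assert s1.coverage.n_assigned == 8
        assert s2.coverage.n_assigned == 10
        assert s2.coverage.n_assigned - s1.coverage.n_assigned == 2

    def test_method3_shares_one_rcp_limit(self, small_catalogues):
        sample = make_sample([
            cm("toluene", 1.0, cas="108-88-3"),
            cm("n-decane", 0.6, cas="124-18-5"),
            cm("1,2,4-trimethylbenzene", 0.4, cas="95-63-6"),
        ])
        s3 = assign_oels(sample, small_catalogues, 3)
        rcp = [a for a in s3.assignments if a.method == "rcp"]
        assert len(rcp) == 2
        # hand computation: fractions 0.6 and 0.4 of the sub-mixture;
        # surrogates 600 (aliphatic C9-14) and 100 (aromatic C9-14)
        expected = 1.0 / (0.6 / 600.0 + 0.4 / 100.0)
        assert rcp[0].oel_15min == rcp[1].oel_15min == pytest.approx(expected)

    def test_unmatchable_compound_stays_unassigned_all_methods(self, small_catalogues):
        sample = make_sample([cm("toluene", 1.0, cas="108-88-3"),
                              cm("mystery", 0.5)])
        for m in (1, 2, 3):
            s = assign_oels(sample, small_catalogues, m)
            unassigned = [a for a in s.assignments if not a.assigned]
            assert [a.compound.name for a in unassigned] == ["mystery"]
            assert s.coverage.nc_percent_count == pytest.approx(50.0)

    def test_invalid_method_rejected(self, small_catalogues):
        sample = make_sample([cm("toluene", 1.0)])
        with pytest.raises(ValidationError, match="method"):
            assign_oels(sample, small_catalogues, 4)

    def test_order_invariance(self, small_catalogues):
        comps = [
            cm("toluene", 1.0, cas="108-88-3"),
            cm("n-decane", 0.6, cas="124-18-5"),
            cm("benzene", 0.05, cas="71-43-2"),
            cm("1,2,4-trimethylbenzene", 0.4, cas="95-63-6"),
        ]
        for m in (1, 2, 3):
            fwd = assign_oels(make_sample(comps), small_catalogues, m)
            rev = assign_oels(make_sample(comps[::-1]), small_catalogues, m)
            by_name_fwd = {a.compound.name: a.oel_15min for a in fwd.assignments}
            by_name_rev = {a.compound.name: a.oel_15min for a in rev.assignments}
            assert by_name_fwd == by_name_rev

    def test_coverage_monotonicity_on_campaign(self, default_campaign):
        for sample in default_campaign.samples:
            covered = {}
            for m in (1, 2, 3):
                s = assign_oels(sample, default_campaign.catalogues, m)
                covered[m] = {a.compound.name for a in s.assignments if a.assigned}
            assert covered[1] <= covered[2]
            assert covered[1] <= covered[3]
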