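"""Flags, interpretation labels, impact index, and headline tallies."""

import itertools

import pytest
from hypothesis import given
from hypothesis import strategies as st

from warhealth.classify import (
    ImpactIndexRecord,
    UnitClassification,
    classify_endpoint,
    classify_rate_change,
    impact_weight,
    interpret,
    label_to_flags,
    reconcile_labels,
    tally,
    tally_from_labels,
)
from warhealth.core import ConflictClass, Flag, Indicator, PrintedInterpretation, UnitMeta

FLAGS3 = [Flag.WORSE, Flag.BETTER, Flag.SAME]
ALL_FLAGS = list(Flag)


class TestRateFlag:
    @pytest.mark.parametrize(
        "pre, conflict, expected",
        [
            (-0.066, -0.019, Flag.WORSE),   # improvement slowed
            (-0.027, -0.038, Flag.BETTER),  # improvement accelerated
            (-0.05, -0.05, Flag.SAME),
            (-0.086, 0.031, Flag.WORSE),    # improvement reversed outright
        ],
    )
    def test_known_district_rates(self, pre, conflict, expected):
        assert classify_rate_change(pre, conflict, 0.0) is expected

    def test_tolerance_absorbs_small_differences(self):
        assert classify_rate_change(-0.050, -0.048, 0.005) is Flag.SAME
        assert classify_rate_change(-0.050, -0.040, 0.005) is Flag.WORSE


class TestEndpointFlag:
    @pytest.mark.parametrize(
        "actual, cf, expected",
        [
            (17.6, 11.6, Flag.WORSE),
            (6.0, 12.7, Flag.BETTER),
            (4.7, 4.7, Flag.SAME),
        ],
    )
    def test_lower_is_better(self, actual, cf, expected):
        assert classify_endpoint(actual, cf, True, 0.0) is expected

    def test_missing_values_are_not_assessable(self):
        assert classify_endpoint(None, 4.0) is Flag.NOT_ASSESSABLE
        assert classify_endpoint(4.0, None) is Flag.NOT_ASSESSABLE

    @given(
        st.floats(0.01, 1e3), st.floats(0.01, 1e3), st.floats(1e-3, 1e3)
    )
    def test_scale_invariance(self, actual, cf, c):
        assert classify_endpoint(actual, cf) is classify_endpoint(c * actual, c * cf)


class TestInterpret:
    @pytest.mark.parametrize(
        "rate, end, indicator, label",
        [
            (Flag.WORSE, Flag.BETTER, Indicator.IMR, "Rate is worse; IMR is better"),
            (Flag.WORSE, Flag.WORSE, Indicator.IMR, "Rate and IMR are worse"),
            (Flag.BETTER, Flag.WORSE, Indicator.MMR, "Rate is better; MMR is worse"),
            (Flag.WORSE, Flag.SAME, Indicator.MMR, "Rate is worse; MMR is same"),
            (Flag.NOT_ASSESSABLE, Flag.WORSE, Indicator.IMR, "Unable to determine"),
            # a known rate with an unassessable endpoint keeps its half
            (Flag.WORSE, Flag.NOT_ASSESSABLE, Indicator.MMR, "Rate is worse"),
        ],
    )
    def test_published_vocabulary(self, rate, end, indicator, label):
        assert interpret(rate, end, indicator) == label

    def test_label_round_trips_through_inverse(self):
        for rate, end in itertools.product(FLAGS3, ALL_FLAGS):
            label = interpret(rate, end, Indicator.MMR)
            back_rate, back_end = label_to_flags(label)
            assert back_rate is rate and back_end is end

    def test_label_mapping_is_injective_on_defined_flags(self):
        labels = {
            interpret(r, e, Indicator.IMR)
            for r, e in itertools.product(FLAGS3, ALL_FLAGS)
        }
        assert len(labels) == len(FLAGS3) * len(ALL_FLAGS)

    def test_unknown_label_is_rejected(self):
        with pytest.raises(ValueError, match="vocabulary"):
            label_to_flags("IMR exploded")


class TestImpactWeight:
    @staticmethod
    def _cls(unit, indicator, rate, end):
        return UnitClassification(unit, indicator, rate, end)

    def test_weight_counts_worse_flags_over_entire_flag_space(self):
        # brute force over all 4^4 component combinations
        for flags in itertools.product(ALL_FLAGS, repeat=4):
            imr = self._cls("D", Indicator.IMR, flags[0], flags[1])
            mmr = self._cls("D", Indicator.MMR, flags[2], flags[3])
            record = impact_weight(imr, mmr)
            imr_gone = flags[0] is Flag.NOT_ASSESSABLE and flags[1] is Flag.NOT_ASSESSABLE
            mmr_gone = flags[2] is Flag.NOT_ASSESSABLE and flags[3] is Flag.NOT_ASSESSABLE
            if imr_gone or mmr_gone:
                assert record.weight is None
            else:
                assert record.weight == sum(f is Flag.WORSE for f in flags)

    def test_extremes(self):
        worse = self._cls("D", Indicator.IMR, Flag.WORSE, Flag.WORSE)
        worse_m = self._cls("D", Indicator.MMR, Flag.WORSE, Flag.WORSE)
        better = self._cls("D", Indicator.IMR, Flag.BETTER, Flag.BETTER)
        better_m = self._cls("D", Indicator.MMR, Flag.BETTER, Flag.BETTER)
        assert impact_weight(worse, worse_m).weight == 4
        assert impact_weight(better, better_m).weight == 0
        one = impact_weight(
            self._cls("D", Indicator.IMR, Flag.WORSE, Flag.BETTER), better_m
        )
        assert one.weight == 1


units_meta = st.builds(
    lambda cc: cc, st.sampled_from([ConflictClass.HIGH, ConflictClass.INTERMITTENT, ConflictClass.NONE])
)


class TestTally:
    @given(
        st.lists(
            st.tuples(
                st.sampled_from(ALL_FLAGS),
                st.sampled_from(ALL_FLAGS),
                units_meta,
            ),
            max_size=40,
        )
    )
    def test_counts_match_brute_force_scan(self, rows):
        classifications = []
        meta = {}
        for i, (rate, end, cc) in enumerate(rows):
            unit = f"D{i:03d}"
            classifications.append(
                UnitClassification(unit, Indicator.IMR, rate, end)
            )
            meta[unit] = UnitMeta(unit, cc)
        summary = tally(classifications, (), meta)
        worse = [c for c in classifications if c.endpoint_flag is Flag.WORSE]
        assert summary.endpoint_worse.get("IMR", 0) == len(worse)
        assert summary.endpoint_worse_outside_conflict.get("IMR", 0) == sum(
            meta[c.unit_id].conflict_class is not ConflictClass.HIGH for c in worse
        )
        assert summary.rate_worse.get("IMR", 0) == sum(
            c.rate_flag is Flag.WORSE for c in classifications
        )
        assert summary.rate_worse_endpoint_not_worse.get("IMR", 0) == sum(
            c.rate_flag is Flag.WORSE and c.endpoint_flag is not Flag.WORSE
            for c in classifications
        )

    def test_empty_input_gives_zero_counts(self):
        summary = tally([], [], {})
        assert summary.endpoint_worse == {} and summary.weight_histogram == {}

    def test_national_pseudo_unit_is_excluded(self):
        meta = {
            "NATIONAL": UnitMeta("NATIONAL", ConflictClass.NATIONAL),
            "D1": UnitMeta("D1", ConflictClass.NONE),
        }
        classifications = [
            UnitClassification("NATIONAL", Indicator.IMR, Flag.WORSE, Flag.WORSE),
            UnitClassification("D1", Indicator.IMR, Flag.WORSE, Flag.WORSE),
        ]
        assert tally(classifications, (), meta).endpoint_worse == {"IMR": 1}

    def test_weight_histogram_keys(self):
        records = [
            ImpactIndexRecord("A", 4),
            ImpactIndexRecord("B", 4),
            ImpactIndexRecord("C", None),
        ]
        summary = tally([], records, {})
        assert summary.weight_histogram == {"4": 2, "N/A": 1}

    def test_tally_from_labels_matches_flag_tally(self):
        printed = [
            PrintedInterpretation("A", Indicator.MMR, "Rate and MMR are worse"),
            PrintedInterpretation("B", Indicator.MMR, "Rate is worse; MMR is better"),
            PrintedInterpretation("C", Indicator.MMR, "Rate is worse"),
            PrintedInterpretation("D", Indicator.MMR, "Unable to determine"),
        ]
        summary = tally_from_labels(printed)
        assert summary.endpoint_worse == {"MMR": 1}
        assert summary.rate_worse == {"MMR": 3}
        assert summary.rate_worse_endpoint_not_worse == {"MMR": 2}


class TestReconcileLabels:
    def test_flags_only_disagreements(self):
        computed = [
            UnitClassification("Vavuniya", Indicator.MMR, Flag.WORSE, Flag.WORSE),
            UnitClassification("Jaffna", Indicator.MMR, Flag.WORSE, Flag.WORSE),
        ]
        printed = [
            PrintedInterpretation("Vavuniya", Indicator.MMR, "Rate is worse; MMR is same"),
            PrintedInterpretation("Jaffna", Indicator.MMR, "Rate and MMR are worse"),
        ]
        report = reconcile_labels(computed, printed)
        assert [d.unit_id for d in report] == ["Vavuniya"]
        assert report[0].computed == "Rate and MMR are worse"

    def test_identical_sets_give_empty_report(self):
        computed = [UnitClassification("X", Indicator.IMR, Flag.BETTER, Flag.BETTER)]
        printed = [PrintedInterpretation("X", Indicator.IMR, "Rate and IMR are better")]
        assert reconcile_labels(computed, printed) == []
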