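import math

import numpy as np
import pytest

from ethoflow.catalogue import BehaviouralEvent, Group, MatingSequence, sequence_from_tokens
from ethoflow.copulation import (
    CopulationComposition,
    classify_composition,
    compare_groups,
    duration_summary,
    group_metrics,
    round_half_up,
)
from ethoflow.simulate import fixture_counts, generate_sequence, rei_profile


class TestComposition:
    @pytest.mark.parametrize(
        "pattern,n_short,n_long,ends_long,icl",
        [("L", 0, 1, True, 0), ("SL", 1, 1, True, 1),
         ("SSL", 2, 1, True, 2), ("SSS", 3, 0, False, 2),
         ("SSSS", 4, 0, False, 3)],
    )
    def test_from_pattern(self, pattern, n_short, n_long, ends_long, icl):
        c = CopulationComposition.from_pattern(pattern)
        assert (c.n_short, c.n_long, c.ends_with_long, c.icl_count) == (
            n_short, n_long, ends_long, icl)

    @pytest.mark.parametrize("pattern", ["", "LS", "LL", "SLS", "X"])
    def test_malformed_patterns_rejected(self, pattern):
        with pytest.raises(ValueError):
            CopulationComposition.from_pattern(pattern)

    def test_classify_short_then_long(self):
        tokens = ["pounce", "sound", "ant", "abdom", "back", "rot", "short",
                  "end_cop", "abdom", "inact", "ant", "sound", "ant", "abdom",
                  "back", "rot", "long", "end_cop", "scratch", "bye_bye"]
        c = classify_composition(sequence_from_tokens(tokens))
        assert c.pattern == "SL"
        assert c.ends_with_long
        assert c.icl_count == 1

    def test_classify_canonical_single_long(self, canonical_l_sequence):
        c = classify_composition(canonical_l_sequence)
        assert c.pattern == "L"
        assert c.icl_count == 0

    def test_classify_all_short_mating(self):
        tokens = ["pounce", "sound", "rot", "short", "end_cop", "abdom",
                  "inact", "ant", "sound", "rot", "short", "end_cop", "abdom",
                  "inact", "ant", "sound", "rot", "short", "end_cop", "abdom",
                  "inact", "ant", "sound", "rot", "short", "end_cop", "bye_bye"]
        c = classify_composition(sequence_from_tokens(tokens))
        assert c.pattern == "SSSS"
        assert not c.ends_with_long
        assert c.icl_count == 3  # the final short is not followed by a resumption

    def test_no_copulation_is_an_error(self):
        seq = sequence_from_tokens(["pounce", "sound", "ant"])
        with pytest.raises(ValueError, match="no copulation"):
            classify_composition(seq)


class TestGroupMetrics:
    def test_natural_emergence_group_statistics(self):
        m = group_metrics(fixture_counts("REI"), group="REI")
        assert (m.n_events, m.n_long, m.n_short) == (34, 34, 7)
        assert m.ratio_long_short == pytest.approx(34 / 7)
        assert m.freq_long_pct == pytest.approx(100 * 34 / 41)
        assert m.pct_end_long == 100.0
        assert m.composition_histogram == {"L": 27, "SL": 7}

    def test_aged_group_statistics(self):
        m = group_metrics(fixture_counts("AEI"), group="AEI")
        assert (m.n_events, m.n_long, m.n_short) == (32, 22, 62)
        assert m.freq_long_pct == pytest.approx(100 * 22 / 84)
        assert m.freq_short_pct == pytest.approx(100 * 62 / 84)
        assert m.freq_long_pct + m.freq_short_pct == pytest.approx(100.0)
        assert m.ratio_long_short == pytest.approx(22 / 62)
        assert m.pct_end_long == pytest.approx(100 * 22 / 32)

    def test_single_long_event_gives_infinite_ratio(self):
        m = group_metrics([CopulationComposition.from_pattern("L")])
        assert m.ratio_is_infinite
        assert math.isinf(m.ratio_long_short)
        assert m.freq_long_pct == 100.0

    def test_empty_input_is_an_error(self):
        with pytest.raises(ValueError):
            group_metrics([])

    def test_permutation_invariance(self):
        comps = fixture_counts("AEI")
        rng = np.random.default_rng(3)
        perm = list(rng.permutation(len(comps)))
        shuffled = [comps[i] for i in perm]
        a = group_metrics(comps, group="AEI")
        b = group_metrics(shuffled, group="AEI")
        assert a == b

    def test_long_frequency_decreases_with_added_short_only_events(self):
        comps = fixture_counts("REI")
        freqs = []
        for k in range(4):
            extra = [CopulationComposition.from_pattern("SSS")] * k
            freqs.append(group_metrics(comps + extra).freq_long_pct)
        assert all(a > b for a, b in zip(freqs, freqs[1:]))

    def test_mean_duration_by_pattern_from_timings(self):
        comps = [CopulationComposition.from_pattern(p) for p in ("L", "L", "SL")]
        m = group_metrics(comps, timings=[100.0, 300.0, 500.0])
        assert m.mean_duration_by_pattern == {"L": 200.0, "SL": 500.0}


class TestGroupComparison:
    def test_reproductive_failure_increase_between_groups(self):
        rei = group_metrics(fixture_counts("REI"), group="REI")
        aei = group_metrics(fixture_counts("AEI"), group="AEI")
        cmp_result = compare_groups(rei, aei)
        assert cmp_result.failure_increase_pct == pytest.approx(31.25)
        assert round_half_up(cmp_result.failure_increase_pct, 1) == 31.3

    def test_identical_groups_show_no_increase(self):
        m = group_metrics(fixture_counts("AEI"), group="AEI")
        assert compare_groups(m, m).failure_increase_pct == 0.0

    def test_hand_computed_increase(self):
        a = group_metrics([CopulationComposition.from_pattern("L")] * 2)
        b = group_metrics([CopulationComposition.from_pattern(p)
                           for p in ("L", "SSS")])
        assert compare_groups(a, b).failure_increase_pct == pytest.approx(50.0)


class TestDurationSummary:
    @staticmethod
    def _timed_sequence(subject, total, pattern="L"):
        events = [BehaviouralEvent("pounce", 0, 1),
                  BehaviouralEvent("rot", 1, 61)]
        t = 61.0
        for sym in pattern:
            tok = "long" if sym == "L" else "short"
            events.append(BehaviouralEvent(tok, t, t + 10))
            t += 10
        events.append(BehaviouralEvent("bye_bye", t, total))
        return MatingSequence(subject, Group.OTHER, events)

    def test_single_sequence_span(self):
        summary = duration_summary([self._timed_sequence("a", 1890.0)])
        mean, lo, hi, n = summary["L"]
        assert (mean, lo, hi, n) == (1890.0, 1890.0, 1890.0, 1)

    def test_mean_over_two_sequences(self):
        seqs = [self._timed_sequence("a", 100.0),
                self._timed_sequence("b", 300.0)]
        assert duration_summary(seqs)["L"][0] == pytest.approx(200.0)

    def test_simulated_durations_grow_with_added_loops(self):
        """Adding a copulation loop to a pattern lengthens the mating.

        Compared along chains of patterns that extend one another (L -> SL ->
        SSL, and SSS -> SSSS); across terminal types the comparison is not
        structural, since only long copulations carry the postcopulatory tail.
        """
        rng = np.random.default_rng(99)
        profile = rei_profile()
        means = {}
        for pattern in ("L", "SL", "SSL", "SSS", "SSSS"):
            seqs = [generate_sequence(pattern, profile, rng, subject_id=f"{pattern}{i}")
                    for i in range(200)]
            means[pattern] = duration_summary(seqs)[pattern][0]
        assert means["L"] < means["SL"] < means["SSL"]
        assert means["SSS"] < means["SSSS"]
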