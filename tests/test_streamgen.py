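"""Stream construction: lexicons, constraints, transitional probabilities."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from slentrain import streamgen as sg


class TestLexicon:
    def test_partition_of_six_ids(self, lexicon_a):
        ids = sorted(i for d in lexicon_a.duplets for i in d)
        assert len(lexicon_a.duplets) == 3
        assert ids == list(range(6))

    def test_list_a_contains_petu(self, lexicon_a):
        pe, tu = sg.SYLLABLES.index("pe"), sg.SYLLABLES.index("tu")
        assert (pe, tu) in lexicon_a.duplets

    def test_lists_are_boundary_complements(self, lexicon_a, lexicon_b):
        assert set(lexicon_b.words) <= set(lexicon_a.partwords)
        assert set(lexicon_a.words) <= set(lexicon_b.partwords)

    def test_invalid_partition_rejected(self):
        with pytest.raises(ValueError):
            sg.Lexicon(sg.Feature.phoneme, ((0, 1), (1, 2), (4, 5)))

    def test_json_roundtrip(self, lexicon_a):
        again = sg.Lexicon.from_json(lexicon_a.to_json())
        assert again == lexicon_a


class TestStructuredStream:
    def test_each_duplet_80_times_in_240(self, lexicon_a):
        stream = sg.generate_structured_stream(lexicon_a, 240, seed=0)
        ids = stream.feature_ids("phoneme")
        pairs = list(zip(ids[::2], ids[1::2]))
        for d in lexicon_a.duplets:
            assert pairs.count(d) == 80

    @pytest.mark.parametrize("n", [10, 11, 240])
    def test_duplet_count_conservation(self, lexicon_a, n):
        stream = sg.generate_structured_stream(lexicon_a, n, seed=3)
        ids = stream.feature_ids("phoneme")
        pairs = list(zip(ids[::2], ids[1::2]))
        counts = sorted(pairs.count(d) for d in lexicon_a.duplets)
        assert counts[0] >= n // 3 and counts[-1] <= -(-n // 3)
        assert sum(counts) == n

    def test_onsets_and_duration(self, lexicon_a):
        stream = sg.generate_structured_stream(lexicon_a, 240, seed=1)
        assert stream.duration_s == pytest.approx(120.0)
        steps = np.diff(stream.onsets_s)
        assert np.allclose(steps, 0.25)

    def test_within_duplet_tp_is_one(self, lexicon_a):
        stream = sg.generate_structured_stream(lexicon_a, 300, seed=2)
        tp = sg.empirical_tp(stream, "phoneme")
        for a, b in lexicon_a.duplets:
            assert tp.probabilities[a, b] == pytest.approx(1.0)

    def test_between_duplet_tp_near_half(self, lexicon_a):
        stream = sg.generate_structured_stream(lexicon_a, 20000, seed=4)
        tp = sg.empirical_tp(stream, "phoneme")
        firsts = [d[0] for d in lexicon_a.duplets]
        for a, b in lexicon_a.duplets:
            for f in firsts:
                if f == a:
                    continue
                assert tp.probabilities[b, f] == pytest.approx(0.5, abs=0.03)

    def test_unstructured_tp_near_fifth(self, lexicon_a):
        stream = sg.generate_structured_stream(lexicon_a, 20000, seed=5)
        off = sg.empirical_tp(stream, "voice").off_diagonal()
        assert np.all(np.abs(off - 0.2) < 0.03)

    def test_generation_error_when_infeasible(self, rng):
        # a single id cannot be sequenced without immediate repetition
        with pytest.raises(sg.GenerationError):
            sg._constrained_sequence(10, 3, rng, counts=[10, 0, 0])


class TestRandomStream:
    def test_duration_480_tokens(self):
        stream = sg.generate_random_stream(480, seed=0)
        assert stream.duration_s == pytest.approx(120.0)

    def test_no_feature_repeats(self):
        stream = sg.generate_random_stream(500, seed=1)
        for feat in ("phoneme", "voice"):
            ids = stream.feature_ids(feat)
            assert np.all(ids[1:] != ids[:-1])

    def test_tp_near_uniform(self):
        stream = sg.generate_random_stream(30000, seed=2)
        for feat in ("phoneme", "voice"):
            off = sg.empirical_tp(stream, feat).off_diagonal()
            assert np.all(np.abs(off - 0.2) < 0.03)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            sg.generate_random_stream(1, seed=0)


class TestEmpiricalTP:
    def test_two_token_stream_single_count(self):
        stream = sg.Stream(
            [sg.Token(0, 1), sg.Token(2, 3)], sg.Condition.random
        )
        tp = sg.empirical_tp(stream, "phoneme")
        assert tp.counts.sum() == 1
        assert tp.counts[0, 2] == 1
        assert tp.probabilities[0, 2] == pytest.approx(1.0)

    def test_rows_sum_to_one_or_flagged(self, lexicon_a):
        stream = sg.generate_structured_stream(lexicon_a, 200, seed=7)
        tp = sg.empirical_tp(stream, "voice")
        sums = tp.probabilities.sum(axis=1)
        assert np.allclose(sums[~tp.undefined_rows], 1.0)

    def test_empty_stream_errors(self):
        with pytest.raises(ValueError):
            sg.empirical_tp(sg.Stream([sg.Token(0, 0)], sg.Condition.random), "phoneme")


class TestTestBlocks:
    def test_block_composition(self, lexicon_a):
        items = sg.make_test_block(lexicon_a, seed=0)
        assert len(items) == 18
        assert sum(i.item_type == "word" for i in items) == 9
        assert all(2.0 <= i.soa_s <= 2.3 for i in items)

    def test_ten_blocks_give_90_per_type(self, lexicon_a):
        items = [it for s in range(10) for it in sg.make_test_block(lexicon_a, seed=s)]
        assert sum(i.item_type == "word" for i in items) == 90
        assert sum(i.item_type == "partword" for i in items) == 90

    def test_pairs_match_lexicon_structure(self, lexicon_a):
        items = sg.make_test_block(lexicon_a, seed=3)
        for it in items:
            pair = tuple(t.feature("phoneme") for t in it.pair)
            if it.item_type == "word":
                assert pair in lexicon_a.words
            else:
                assert pair in lexicon_a.partwords

    def test_complement_property(self, lexicon_a, lexicon_b):
        """A-lexicon words occur in a B-structured stream only across boundaries."""
        stream = sg.generate_structured_stream(lexicon_b, 2000, seed=9)
        ids = stream.feature_ids("phoneme")
        for a, b in lexicon_a.words:
            hits = np.flatnonzero((ids[:-1] == a) & (ids[1:] == b))
            assert len(hits) > 0
            assert np.all(hits % 2 == 1)  # second syllable -> next duplet's first


@settings(max_examples=25, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000), structured=st.booleans())
def test_constraint_checker_property(seed, structured):
    lex = sg.build_lexicon("phoneme", "A")
    if structured:
        stream = sg.generate_structured_stream(lex, 60, seed)
    else:
        stream = sg.generate_random_stream(120, seed)
    assert sg.check_stream_constraints(stream) == []


def test_checker_flags_planted_violations(lexicon_a):
    """The audit itself must detect repeats and ABAB alternations."""
    toks = [sg.Token(s, v) for s, v in zip([2, 3, 2, 3], [0, 1, 2, 3])]
    stream = sg.Stream(toks, sg.Condition.structured_long, lexicon_a)
    problems = sg.check_stream_constraints(stream)
    assert any("ABAB" in p or "repeat" in p for p in problems)
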