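"""Turn construction, latency computation, and utterance I/O."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from turntaking.turns_io import (BackchannelPolicy, DataError, FormatError,
                                 compute_latencies, corpus_latencies,
                                 merge_backchannels, read_utterances,
                                 utterances_to_frame, write_utterances)
from turntaking.types import Utterance

from conftest import make_utt

META = dict(dyad_id="d1", child_id="c1", group="autism", visit=1,
            context="convo_parent")


class TestReadWrite:
    def test_csv_roundtrip_preserves_fields_to_1ms(self, tmp_path):
        utts = [make_utt("adult", 0.0, 2.0, token_count=4),
                make_utt("child", 2.5, 4.0, token_count=3)]
        path = tmp_path / "u.csv"
        write_utterances(utts, path)
        back = read_utterances(path, format="csv")
        assert len(back) == 2
        for a, b in zip(utts, back):
            assert abs(a.onset_s - b.onset_s) < 1e-3
            assert abs(a.offset_s - b.offset_s) < 1e-3
            assert a.speaker_role == b.speaker_role
            assert a.token_count == b.token_count

    def test_sorted_by_onset(self, tmp_path):
        df = utterances_to_frame([make_utt("child", 2.5, 4.0),
                                  make_utt("adult", 0.0, 2.0)])
        path = tmp_path / "u.csv"
        df.to_csv(path, index=False)
        back = read_utterances(path, format="csv")
        assert [u.onset_s for u in back] == sorted(u.onset_s for u in back)

    def test_invalid_interval_names_row(self, tmp_path):
        df = utterances_to_frame([make_utt("adult", 0.0, 2.0),
                                  make_utt("child", 2.5, 4.0),
                                  make_utt("adult", 5.0, 6.0)])
        df.loc[2, "offset_s"] = 4.5  # row index 2: offset < onset
        path = tmp_path / "bad.csv"
        df.to_csv(path, index=False)
        with pytest.raises(DataError, match="2"):
            read_utterances(path, format="csv")

    def test_missing_column_is_format_error(self, tmp_path):
        path = tmp_path / "m.csv"
        pd.DataFrame({"onset_s": [0.0], "offset_s": [1.0]}).to_csv(path, index=False)
        with pytest.raises(FormatError):
            read_utterances(path, format="csv")

    def test_ms_units_flag(self, tmp_path):
        df = utterances_to_frame([make_utt("adult", 0.0, 2.0)])
        df["onset_s"], df["offset_s"] = [1000.0], [3000.0]
        path = tmp_path / "ms.csv"
        df.to_csv(path, index=False)
        (u,) = read_utterances(path, format="csv", units="ms")
        assert u.onset_s == pytest.approx(1.0) and u.offset_s == pytest.approx(3.0)

    def test_textgrid_parse_matches_expected_records(self, tmp_path):
        tg = tmp_path / "s.TextGrid"
        tg.write_text(
            'File type = "ooTextFile"\nObject class = "TextGrid"\n\n'
            "xmin = 0\nxmax = 10\ntiers? <exists>\nsize = 2\nitem []:\n"
            "    item [1]:\n"
            '        class = "IntervalTier"\n        name = "child"\n'
            "        xmin = 0\n        xmax = 10\n        intervals: size = 2\n"
            "        intervals [1]:\n            xmin = 0\n            xmax = 2.5\n"
            '            text = ""\n'
            "        intervals [2]:\n            xmin = 2.5\n            xmax = 4\n"
            '            text = "yes I did"\n'
            "    item [2]:\n"
            '        class = "IntervalTier"\n        name = "adult"\n'
            "        xmin = 0\n        xmax = 10\n        intervals: size = 2\n"
            "        intervals [1]:\n            xmin = 0\n            xmax = 2\n"
            '            text = "did you"\n'
            "        intervals [2]:\n            xmin = 2\n            xmax = 10\n"
            '            text = ""\n')
        utts = read_utterances(tg, format="textgrid", metadata=dict(META))
        # oracle: the two nonempty intervals, sorted by onset
        assert [(u.speaker_role, u.onset_s, u.offset_s, u.token_count)
                for u in utts] == [("adult", 0.0, 2.0, 2), ("child", 2.5, 4.0, 3)]


class TestMergeBackchannels:
    def test_backchannel_merges_into_next_substantial_turn(self):
        # latency must run from the substantial content, not the backchannel
        utts = [make_utt("adult", 0.0, 3.0),
                make_utt("child", 1.0, 1.3, is_backchannel=True),
                make_utt("child", 3.4, 6.0)]
        turns = merge_backchannels(utts)
        assert len(turns) == 2
        assert turns[0].speaker_role == "adult"
        assert turns[1].onset_s == pytest.approx(3.4)
        assert turns[1].merged_backchannel

    def test_alternating_no_flags_is_identity(self):
        utts = [make_utt("adult", 0.0, 2.0), make_utt("child", 2.5, 4.0),
                make_utt("adult", 4.2, 5.0)]
        turns = merge_backchannels(utts)
        assert [(t.speaker_role, t.onset_s, t.offset_s) for t in turns] == \
            [("adult", 0.0, 2.0), ("child", 2.5, 4.0), ("adult", 4.2, 5.0)]

    def test_same_speaker_consolidation(self):
        utts = [make_utt("adult", 0.0, 2.0), make_utt("adult", 2.5, 4.0),
                make_utt("child", 4.5, 5.0)]
        turns = merge_backchannels(utts)
        assert [(t.speaker_role, t.onset_s, t.offset_s) for t in turns] == \
            [("adult", 0.0, 4.0), ("child", 4.5, 5.0)]

    def test_trailing_backchannel_dropped(self):
        utts = [make_utt("adult", 0.0, 3.0),
                make_utt("child", 1.0, 1.3, is_backchannel=True)]
        turns = merge_backchannels(utts)
        assert len(turns) == 1 and turns[0].speaker_role == "adult"

    def test_empty_input_gives_empty_output(self):
        assert merge_backchannels([]) == []

    def test_idempotent(self, small_corpus):
        from turntaking.turns_io import iter_sessions

        utts = small_corpus.utterance_objects()[:400]
        for meta, sess in iter_sessions(utts):
            turns = merge_backchannels(sess)
            # rebuild utterances from turns and re-merge
            again = [Utterance(speaker_role=t.speaker_role, onset_s=t.onset_s,
                               offset_s=t.offset_s, token_count=t.token_count,
                               is_backchannel=False, **META)
                     for t in turns]
            turns2 = merge_backchannels(again)
            assert [(t.speaker_role, t.onset_s, t.offset_s) for t in turns] == \
                [(t.speaker_role, t.onset_s, t.offset_s) for t in turns2]

    def test_heuristic_policy_flags_short_overlapped(self):
        utts = [make_utt("adult", 0.0, 3.0),
                make_utt("child", 1.0, 1.3, token_count=1),  # inside adult turn
                make_utt("child", 3.4, 6.0, token_count=5)]
        policy = BackchannelPolicy(use_flag=False)
        flags = policy.classify(utts)
        assert list(flags) == [False, True, False]


class TestComputeLatencies:
    @pytest.mark.parametrize("prev_off,next_on,lat,overlap", [
        (2.0, 2.5, 0.5, False),
        (2.0, 1.8, -0.2, True),
        (2.0, 2.0, 0.0, False),  # exact zero counts as a gap
    ])
    def test_latency_and_overlap_convention(self, prev_off, next_on, lat, overlap):
        utts = [make_utt("adult", 0.0, prev_off),
                make_utt("child", next_on, next_on + 1.0)]
        obs = compute_latencies(merge_backchannels(utts), META)
        assert len(obs) == 1
        assert obs[0].latency_s == pytest.approx(lat)
        assert obs[0].is_overlap is overlap

    def test_fewer_than_two_turns_empty(self):
        obs = compute_latencies(merge_backchannels([make_utt("adult", 0, 1)]), META)
        assert obs == []

    def test_observation_count_is_turns_minus_one(self, small_corpus):
        from turntaking.turns_io import iter_sessions

        utts = small_corpus.utterance_objects()
        for meta, sess in list(iter_sessions(utts))[:10]:
            turns = merge_backchannels(sess)
            obs = compute_latencies(turns, meta)
            assert len(obs) == len(turns) - 1

    @given(shift=st.floats(min_value=-100, max_value=100,
                           allow_nan=False, allow_infinity=False))
    @settings(max_examples=25, deadline=None)
    def test_time_shift_invariance(self, shift):
        utts = [make_utt("adult", 0.0, 2.0), make_utt("child", 1.8, 4.0),
                make_utt("adult", 4.5, 5.5)]
        base = compute_latencies(merge_backchannels(utts), META)
        shifted = [make_utt(u.speaker_role, u.onset_s + shift, u.offset_s + shift)
                   for u in utts]
        moved = compute_latencies(merge_backchannels(shifted), META)
        for a, b in zip(base, moved):
            assert b.latency_s == pytest.approx(a.latency_s, abs=1e-9)

    def test_lag_fields(self):
        utts = [make_utt("adult", 0.0, 1.0), make_utt("child", 1.2, 2.0),
                make_utt("adult", 2.1, 3.0), make_utt("child", 3.4, 4.0)]
        obs = compute_latencies(merge_backchannels(utts), META)
        # turn 1: no lags; turn 2: partner lag only; turn 3: both
        assert obs[0].prev_partner_latency_s is None
        assert obs[1].prev_partner_latency_s == pytest.approx(0.2)
        assert obs[1].prev_self_latency_s is None
        assert obs[2].prev_partner_latency_s == pytest.approx(obs[1].latency_s)
        assert obs[2].prev_self_latency_s == pytest.approx(0.2)
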