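import json

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from turnalign.corpus_io import (
    CorpusError,
    attrition_table,
    clean_transcript_text,
    conversation_from_utterances,
    count_turn_pairs,
    filter_conversations,
    merge_consecutive_same_speaker,
    read_conversations,
    validate_alternation,
    write_conversations,
)
from turnalign.design import USER_SIDE

from .conftest import alternating_conversation, make_conversation


def _write_jsonl(path, records):
    with open(path, "w") as fh:
        for rec in records:
            fh.write(rec if isinstance(rec, str) else json.dumps(rec))
            fh.write("\n")


class TestReadConversations:
    def test_reads_wellformed_file_in_order(self, tmp_path):
        path = tmp_path / "c.jsonl"
        _write_jsonl(
            path,
            [
                {"id": "a", "turns": [{"role": "user", "text": "hi"}]},
                {"id": "b", "meta": {"lang": "en"}, "turns": []},
            ],
        )
        convs = list(read_conversations(path))
        assert [c.id for c in convs] == ["a", "b"]
        assert convs[0].turns[0].role == "user"
        assert len(convs[1].turns) == 0
        assert convs[1].metadata == {"lang": "en"}

    def test_truncated_line_error_names_line_number(self, tmp_path):
        path = tmp_path / "c.jsonl"
        good = json.dumps({"id": "a", "turns": [{"role": "user", "text": "x"}]})
        _write_jsonl(path, [good, good[: len(good) // 2], good])
        with pytest.raises(CorpusError, match="line 2"):
            list(read_conversations(path))

    def test_unknown_role_error_names_role(self, tmp_path):
        path = tmp_path / "c.jsonl"
        _write_jsonl(path, [{"id": "a", "turns": [{"role": "narrator", "text": "x"}]}])
        with pytest.raises(CorpusError, match="narrator"):
            list(read_conversations(path))

    def test_speaker_letters_map_to_canonical_roles(self, tmp_path):
        path = tmp_path / "c.jsonl"
        _write_jsonl(
            path,
            [{"id": "a", "turns": [{"role": "A", "text": "x"}, {"role": "B", "text": "y"}]}],
        )
        (conv,) = read_conversations(path)
        assert [t.role for t in conv.turns] == ["user", "assistant"]

    def test_round_trip_preserves_turns_and_metadata(self, tmp_path):
        conv = alternating_conversation("rt", 3)
        conv.metadata = {"model": "x", "topic": "misc"}
        path = tmp_path / "rt.jsonl"
        write_conversations([conv], path)
        (back,) = read_conversations(path)
        assert back.id == conv.id
        assert back.metadata == conv.metadata
        assert [(t.role, t.text, t.index) for t in back.turns] == [
            (t.role, t.text, t.index) for t in conv.turns
        ]


class TestCleanTranscript:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ("so [laughter] yeah", "so yeah"),
            ("okay", "okay"),
            ("[silence]", ""),
            ("i was say- saying that", "i was saying that"),
            ("[noise] well [laughter] fine", "well fine"),
        ],
    )
    def test_markers_removed_lexical_content_kept(self, raw, expected):
        assert clean_transcript_text(raw) == expected


class TestMergeSameSpeaker:
    @pytest.mark.parametrize(
        "utterances,expected",
        [
            ([("A", 0, "hi"), ("A", 1, "there"), ("B", 2, "hello")],
             [("A", "hi there"), ("B", "hello")]),
            ([("A", 0, "hi")], [("A", "hi")]),
            ([("B", 0, "x"), ("A", 1, "y"), ("B", 2, "z")],
             [("B", "x"), ("A", "y"), ("B", "z")]),
        ],
    )
    def test_enumerated_examples(self, utterances, expected):
        assert merge_consecutive_same_speaker(utterances) == expected

    def test_timestamp_ties_keep_input_order(self):
        merged = merge_consecutive_same_speaker([("A", 0, "x"), ("B", 0, "y")])
        assert merged == [("A", "x"), ("B", "y")]

    @given(
        st.lists(
            st.tuples(
                st.sampled_from(["A", "B"]),
                st.integers(min_value=0, max_value=50),
                st.sampled_from(["uh", "yeah", "so"]),
            ),
            min_size=1,
            max_size=30,
        )
    )
    @settings(deadline=None, max_examples=50)
    def test_output_never_has_adjacent_same_speaker(self, utterances):
        merged = merge_consecutive_same_speaker(utterances)
        speakers = [s for s, _ in merged]
        assert all(a != b for a, b in zip(speakers, speakers[1:]))

    def test_marker_only_utterances_dropped_before_merging(self):
        conv = conversation_from_utterances(
            "sw1",
            [("A", 0.0, "well hi"), ("B", 1.0, "[laughter]"), ("A", 2.0, "you there")],
        )
        # B's marker-only utterance vanishes, so A's turns merge
        assert [t.role for t in conv.turns] == ["user"]
        assert conv.turns[0].text == "well hi you there"


class TestFilterAndAlternation:
    def test_ten_alternating_messages_retained_at_min_five(self):
        conv = alternating_conversation("k", 5)
        assert filter_conversations([conv], min_turn_pairs=5) == [conv]

    def test_nine_messages_dropped_at_min_five(self):
        conv = alternating_conversation("k", 5)
        conv.turns = conv.turns[:9]
        assert filter_conversations([conv], min_turn_pairs=5) == []

    def test_min_one_keeps_any_alternating_pair(self):
        conv = alternating_conversation("k", 1)
        assert filter_conversations([conv], min_turn_pairs=1) == [conv]

    def test_min_zero_rejected(self):
        with pytest.raises(ValueError):
            filter_conversations([], min_turn_pairs=0)

    def test_metadata_predicates_apply(self):
        conv = alternating_conversation("k", 5)
        conv.metadata["model"] = "m1"
        keep = filter_conversations([conv], 5, predicates=[lambda m: m.get("model") == "m1"])
        drop = filter_conversations([conv], 5, predicates=[lambda m: m.get("model") == "m2"])
        assert keep == [conv] and drop == []

    @given(st.lists(st.sampled_from(["user", "assistant"]), min_size=1, max_size=14))
    @settings(deadline=None, max_examples=80)
    def test_pair_count_matches_brute_force(self, roles):
        conv = make_conversation("p", [(r, "x") for r in roles])
        # brute force: scan for non-overlapping adjacent (user, assistant)
        expected, i = 0, 0
        while i + 1 < len(roles):
            if roles[i] == "user" and roles[i + 1] == "assistant":
                expected += 1
                i += 2
            else:
                i += 1
        assert count_turn_pairs(conv) == expected

    def test_assistant_first_conversation_rejected(self):
        conv = make_conversation("a", [("assistant", "x"), ("user", "y")])
        with pytest.raises(CorpusError, match="first turn"):
            validate_alternation(conv)


class TestAttrition:
    def test_counts_follow_eligible_turns(self):
        convs = [
            alternating_conversation("c1", 11),
            alternating_conversation("c2", 11),
            alternating_conversation("c3", 5),  # user-side eligible indices 1..4
        ]
        table = attrition_table(convs, (1, 10), USER_SIDE)
        assert list(table.loc[1:4]) == [3, 3, 3, 3]
        assert list(table.loc[5:10]) == [2, 2, 2, 2, 2, 2]
        diffs = table.diff().dropna()
        assert (diffs <= 0).all()

    def test_empty_corpus_gives_zeros(self):
        table = attrition_table([], (1, 10), USER_SIDE)
        assert (table == 0).all()

    def test_single_conversation_all_ones(self):
        table = attrition_table([alternating_conversation("c", 11)], (1, 10), USER_SIDE)
        assert (table == 1).all()


class TestTimestampedTranscript:
    def test_word_aligned_file_to_conversation(self, tmp_path):
        from turnalign.corpus_io import read_timestamped_utterances

        path = tmp_path / "sw.tsv"
        rows = [
            ("A", "0.0", "0.4", "so"),
            ("A", "0.4", "0.6", "[laughter]"),
            ("A", "0.6", "0.9", "yeah"),
            ("B", "1.0", "1.2", "okay"),
            ("A", "1.5", "1.9", "right"),
        ]
        path.write_text("\n".join("\t".join(r) for r in rows) + "\n")
        units = read_timestamped_utterances(path)
        assert units[0] == ("A", 0.0, "so")
        conv = conversation_from_utterances("sw0", units)
        assert [(t.role, t.text) for t in conv.turns] == [
            ("user", "so yeah"),
            ("assistant", "okay"),
            ("user", "right"),
        ]

    def test_malformed_row_names_line(self, tmp_path):
        from turnalign.corpus_io import read_timestamped_utterances

        path = tmp_path / "bad.tsv"
        path.write_text("A\t0.0\t0.4\tso\nA\toops\n")
        with pytest.raises(CorpusError, match="line 2"):
            read_timestamped_utterances(path)
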