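"""Reading, cleaning, filtering, and indexing dyadic conversations.

The canonical on-disk format is JSON-lines: one conversation per line,

    {"id": ..., "meta": {...}, "turns": [{"role": "user", "text": ...}, ...]}

Roles are normalized at read time to the canonical pair ``user`` /
``assistant`` via a role map (e.g. spoken-transcript speaker ``A`` -> ``user``,
``B`` -> ``assistant``).  Timestamped utterance transcripts (spoken corpora)
are converted to dialogue turns with :func:`merge_consecutive_same_speaker`.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd

USER = "user"
ASSISTANT = "assistant"

#: Default role normalization: chat-style and speaker-letter conventions.
DEFAULT_ROLE_MAP: Mapping[str, str] = {
    "user": USER,
    "assistant": ASSISTANT,
    "A": USER,
    "B": ASSISTANT,
}

#: Default transcript marker patterns: square-bracketed annotations
#: (silence / laughter / noise) and partial-word tokens ending in "-".
DEFAULT_MARKER_PATTERNS: tuple[str, ...] = (
    r"\[[^\]]*\]",
    r"\S+-(?=\s|$)",
)


class CorpusError(ValueError):
    """Malformed conversation data."""


@dataclass
class Turn:
    """One dialogue turn.

    ``token_count`` is filled by the features module once the turn has been
    tokenized; it is ``None`` before feature extraction.
    """

    conversation_id: str
    index: int
    role: str
    text: str
    token_count: int | None = None


@dataclass
class Conversation:
    id: str
    turns: list[Turn]
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.turns)

    def role_turns(self, role: str) -> list[Turn]:
        return [t for t in self.turns if t.role == role]

    def to_record(self) -> dict:
        return {
            "id": self.id,
            "meta": dict(self.metadata),
            "turns": [{"role": t.role, "text": t.text} for t in self.turns],
        }


def _conversation_from_record(
    record: dict, role_map: Mapping[str, str], lineno: int
) -> Conversation:
    try:
        conv_id = str(record["id"])
        raw_turns = record["turns"]
    except (KeyError, TypeError) as exc:
        raise CorpusError(f"line {lineno}: missing required field: {exc}") from exc
    turns = []
    for i, raw in enumerate(raw_turns):
        role = raw.get("role")
        if role not in role_map:
            raise CorpusError(f"line {lineno}: unknown role {role!r} at turn {i}")
        turns.append(
            Turn(conversation_id=conv_id, index=i, role=role_map[role], text=str(raw.get("text", "")))
        )
    return Conversation(id=conv_id, turns=turns, metadata=dict(record.get("meta", {})))


def read_conversations(
    path, role_map: Mapping[str, str] | None = None
) -> Iterator[Conversation]:
    """Stream conversations from a JSON-lines file in file order.

    Raises :class:`CorpusError` naming the offending line number on a
    malformed line, and naming the role on an unmapped role.
    """
    role_map = dict(role_map or DEFAULT_ROLE_MAP)
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                record = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusError(f"line {lineno}: malformed JSON ({exc.msg})") from exc
            yield _conversation_from_record(record, role_map, lineno)


def write_conversations(convs: Iterable[Conversation], path) -> None:
    """Write conversations to canonical JSON-lines (round-trips with read)."""
    with open(path, "w", encoding="utf-8") as fh:
        for conv in convs:
            fh.write(json.dumps(conv.to_record(), ensure_ascii=False) + "\n")


def clean_transcript_text(
    text: str, marker_patterns: Sequence[str] = DEFAULT_MARKER_PATTERNS
) -> str:
    """Remove non-lexical transcript markers, preserving lexical content.

    Defaults remove square-bracketed annotations (silence, laughter, noise)
    and partial-word tokens marked with a trailing hyphen.  Whitespace left
    behind by removals is collapsed; the result may be empty.
    """
    for pattern in marker_patterns:
        text = re.sub(pattern, " ", text)
    return re.sub(r"\s+", " ", text).strip()


def merge_consecutive_same_speaker(
    utterances: Sequence[tuple[str, float, str]]
) -> list[tuple[str, str]]:
    """Interleave utterances by start time and merge same-speaker runs.

    ``utterances`` are ``(speaker, start_time, text)``.  Ties in start time
    keep input order (stable sort).  Returns ``(speaker, text)`` dialogue
    turns whose speakers strictly alternate.
    """
    ordered = sorted(utterances, key=lambda u: u[1])
    merged: list[tuple[str, list[str]]] = []
    for speaker, _start, text in ordered:
        if merged and merged[-1][0] == speaker:
            merged[-1][1].append(text)
        else:
            merged.append((speaker, [text]))
    return [(speaker, " ".join(parts)) for speaker, parts in merged]


def conversation_from_utterances(
    conv_id: str,
    utterances: Sequence[tuple[str, float, str]],
    role_map: Mapping[str, str] | None = None,
    marker_patterns: Sequence[str] = DEFAULT_MARKER_PATTERNS,
    metadata: dict | None = None,
) -> Conversation:
    """Build a canonical Conversation from timestamped utterances.

    Cleaning runs per utterance; utterances emptied by cleaning are dropped
    before merging so marker-only rows do not break turn alternation.
    """
    role_map = dict(role_map or DEFAULT_ROLE_MAP)
    cleaned = []
    for speaker, start, text in utterances:
        text = clean_transcript_text(text, marker_patterns)
        if text:
            cleaned.append((speaker, start, text))
    turns = []
    for i, (speaker, text) in enumerate(merge_consecutive_same_speaker(cleaned)):
        if speaker not in role_map:
            raise CorpusError(f"conversation {conv_id}: unknown speaker {speaker!r}")
        turns.append(Turn(conversation_id=conv_id, index=i, role=role_map[speaker], text=text))
    return Conversation(id=conv_id, turns=turns, metadata=dict(metadata or {}))


def read_timestamped_utterances(path) -> list[tuple[str, float, str]]:
    """Read a word-aligned transcript: tab-separated (speaker, start, end, word).

    Returns ``(speaker, start_time, word)`` units ready for cleaning and
    same-speaker merging; blank lines are skipped.
    """
    units = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise CorpusError(f"line {lineno}: expected 4 tab-separated fields")
            speaker, start, _end, word = parts
            try:
                units.append((speaker, float(start), word))
            except ValueError as exc:
                raise CorpusError(f"line {lineno}: bad start time {start!r}") from exc
    return units


def count_turn_pairs(conv: Conversation) -> int:
    """Number of complete (user, assistant) adjacent pairs, user first."""
    n = 0
    turns = conv.turns
    i = 0
    while i + 1 < len(turns):
        if turns[i].role == USER and turns[i + 1].role == ASSISTANT:
            n += 1
            i += 2
        else:
            i += 1
    return n


def validate_alternation(conv: Conversation) -> None:
    """Require a user-first, strictly alternating conversation.

    Conversations opening with the assistant role are rejected rather than
    silently re-aligned: the pairing rule (focal turn N with partner turn
    N-1) presumes the user speaks first.
    """
    if not conv.turns:
        return
    if conv.turns[0].role != USER:
        raise CorpusError(f"conversation {conv.id}: first turn is not user-role")
    for prev, cur in zip(conv.turns, conv.turns[1:]):
        if prev.role == cur.role:
            raise CorpusError(
                f"conversation {conv.id}: consecutive turns {prev.index},{cur.index} "
                f"share role {cur.role!r}"
            )


def filter_conversations(
    convs: Iterable[Conversation],
    min_turn_pairs: int = 5,
    predicates: Sequence = (),
) -> list[Conversation]:
    """Keep conversations with >= ``min_turn_pairs`` user-assistant pairs
    that satisfy every metadata predicate."""
    if min_turn_pairs < 1:
        raise ValueError("min_turn_pairs must be >= 1")
    kept = []
    for conv in convs:
        if count_turn_pairs(conv) < min_turn_pairs:
            continue
        if all(pred(conv.metadata) for pred in predicates):
            kept.append(conv)
    return kept


def attrition_table(
    convs: Sequence[Conversation],
    window: tuple[int, int],
    direction,
) -> pd.Series:
    """Conversations contributing an eligible focal turn at each position.

    Counts are indexed by focal-turn position over ``window = (lo, hi)``
    inclusive and are non-increasing for a fixed conversation set.
    """
    from .design import enumerate_focal_turns

    lo, hi = window
    positions = list(range(lo, hi + 1))
    counts = dict.fromkeys(positions, 0)
    for conv in convs:
        eligible = {n for *_ignored, n in enumerate_focal_turns(conv, direction)}
        for pos in positions:
            if pos in eligible:
                counts[pos] += 1
    return pd.Series(counts, name="n_conversations").rename_axis("position")
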