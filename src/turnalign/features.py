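"""Turn-level feature extraction.

Two indicator families are supported:

* **Function-word rate vectors** — the rate of words in each of 10
  closed-class categories per turn (pronoun classes, discourse connectives,
  hedges, articles, prepositions, conjunctions, negations), computed with
  whitespace tokenization, lowercase normalization and punctuation removal.
* **Syntactic pattern sets** — sets of ``(dependency-label, head-POS,
  dependent-POS)`` triples produced by an injectable parser adapter, so the
  analysis is agnostic to the parser actually used (fixtures may supply
  triples directly).
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass
from importlib import resources
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import yaml

#: Canonical category order; every RateVector follows it.
CATEGORIES: tuple[str, ...] = (
    "first_person_sg",
    "first_person_pl",
    "second_person",
    "third_person",
    "discourse_connectives",
    "hedges",
    "articles",
    "prepositions",
    "conjunctions",
    "negations",
)

N_CATEGORIES = len(CATEGORIES)

#: A parser adapter maps raw text to dependency triples.
ParserAdapter = Callable[[str], Sequence[tuple[str, str, str]]]

# Keep alphanumerics and word-internal apostrophes; everything else is
# punctuation.  "don't" must not split (negation lists contain contractions).
_PUNCT_RE = re.compile(r"[^\w']+|_")
_EDGE_APOSTROPHES = re.compile(r"^'+|'+$")


class LexiconError(ValueError):
    """Invalid function-word lexicon."""


class Lexicon:
    """Mapping of the 10 canonical categories to disjoint lowercase word sets.

    Disjointness is enforced because the per-category similarity treats
    category counts as partitioning the function-word mass; a word in two
    categories would be double-counted.
    """

    def __init__(self, categories: Mapping[str, Iterable[str]]):
        missing = set(CATEGORIES) - set(categories)
        extra = set(categories) - set(CATEGORIES)
        if missing or extra:
            raise LexiconError(
                f"lexicon must define exactly the canonical categories; "
                f"missing={sorted(missing)}, unexpected={sorted(extra)}"
            )
        self._sets: dict[str, frozenset[str]] = {}
        seen: dict[str, str] = {}
        for cat in CATEGORIES:
            words = frozenset(categories[cat])
            for w in words:
                if w != w.lower():
                    raise LexiconError(f"word {w!r} in {cat} is not lowercase")
                if w in seen:
                    raise LexiconError(
                        f"word {w!r} appears in both {seen[w]} and {cat}"
                    )
                seen[w] = cat
            self._sets[cat] = words
        # word -> category index, for single-pass counting
        self._index: dict[str, int] = {
            w: k for k, cat in enumerate(CATEGORIES) for w in self._sets[cat]
        }

    def words(self, category: str) -> frozenset[str]:
        return self._sets[category]

    def category_of(self, word: str) -> str | None:
        k = self._index.get(word)
        return CATEGORIES[k] if k is not None else None

    def count(self, tokens: Sequence[str]) -> np.ndarray:
        counts = np.zeros(N_CATEGORIES, dtype=np.int64)
        index = self._index
        for tok, n in Counter(tokens).items():
            k = index.get(tok)
            if k is not None:
                counts[k] += n
        return counts

    @classmethod
    def from_file(cls, path) -> "Lexicon":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        return cls(data)


def default_lexicon() -> Lexicon:
    """The packaged default lexicon (documented approximation of the
    LIWC-tradition lists)."""
    ref = resources.files("turnalign").joinpath("data/function_words.yaml")
    with ref.open("r", encoding="utf-8") as fh:
        return Lexicon(yaml.safe_load(fh))


def tokenize(text: str) -> list[str]:
    """Whitespace-style tokenization: lowercase, punctuation stripped.

    Word-internal apostrophes are retained so contractions survive as single
    tokens; tokens emptied by punctuation stripping are dropped.  Idempotent
    on its own output.
    """
    out = []
    for piece in _PUNCT_RE.split(text.lower()):
        piece = _EDGE_APOSTROPHES.sub("", piece)
        if piece:
            out.append(piece)
    return out


@dataclass(frozen=True)
class RateVector:
    """Per-turn function-word category rates.

    ``rates[k]`` = (count of category-k words) / token_count, in canonical
    category order.  A turn with zero tokens yields an all-zero, degenerate
    vector that downstream similarity computations flag and exclude.
    """

    rates: np.ndarray
    token_count: int

    @property
    def degenerate(self) -> bool:
        return self.token_count == 0

    def rate(self, category: str) -> float:
        return float(self.rates[CATEGORIES.index(category)])


def rate_vector(tokens: Sequence[str], lexicon: Lexicon) -> RateVector:
    n = len(tokens)
    if n == 0:
        return RateVector(rates=np.zeros(N_CATEGORIES), token_count=0)
    counts = lexicon.count(tokens)
    return RateVector(rates=counts / n, token_count=n)


def pattern_set(parse: Iterable[tuple[str, str, str]]) -> frozenset[tuple[str, str, str]]:
    """Collapse a dependency-triple list to its set of distinct
    ``(dep-label, head-POS, dependent-POS)`` patterns."""
    return frozenset(tuple(t) for t in parse)


def spacy_adapter(model: str = "en_core_web_sm") -> ParserAdapter:
    """Parser adapter backed by a spaCy pipeline (NER disabled for speed).

    Requires the optional ``parsing`` extra; raises ImportError otherwise.
    """
    import spacy  # deferred: optional dependency

    nlp = spacy.load(model, disable=["ner"])

    def parse(text: str) -> list[tuple[str, str, str]]:
        doc = nlp(text)
        return [(tok.dep_, tok.head.pos_, tok.pos_) for tok in doc]

    return parse


def annotate_rates(convs, lexicon: Lexicon) -> dict[tuple[str, int], RateVector]:
    """Compute a RateVector per turn and fill ``Turn.token_count``.

    Returns a mapping keyed by ``(conversation_id, turn_index)``.
    """
    table: dict[tuple[str, int], RateVector] = {}
    for conv in convs:
        for turn in conv.turns:
            rv = rate_vector(tokenize(turn.text), lexicon)
            turn.token_count = rv.token_count
            table[(conv.id, turn.index)] = rv
    return table


def rates_frame(rates: Mapping[tuple[str, int], RateVector]):
    """Serialize a rate table to a tidy DataFrame (feature cache format)."""
    import pandas as pd

    rows = []
    for (cid, idx), rv in rates.items():
        row = {"conversation_id": cid, "turn_index": idx, "token_count": rv.token_count}
        row.update({cat: rv.rates[k] for k, cat in enumerate(CATEGORIES)})
        rows.append(row)
    return pd.DataFrame(rows)
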