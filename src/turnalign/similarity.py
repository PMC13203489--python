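"""Turn-pair similarity indicators.

All three indicators are symmetric and bounded in [0, 1]:

* ``cosine_fw`` — cosine similarity of two 10-category function-word rate
  vectors (the aggregate indicator).
* ``category_similarity`` — per-category bounded similarity
  ``1 - |r_focal(k) - r_partner(k)|`` used by the category decomposition.
* ``jaccard_syntax`` — Jaccard overlap of dependency pattern sets.

Degenerate pairs (a zero rate vector, or two empty pattern sets) are flagged
rather than raised; observation-table construction drops them pairwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .features import CATEGORIES, RateVector

COSINE_FW = "cosine_fw"
JACCARD_SYNTAX = "jaccard_syntax"


def category_indicator(category: str) -> str:
    if category not in CATEGORIES:
        raise ValueError(f"unknown category {category!r}")
    return f"category:{category}"


@dataclass(frozen=True)
class SimilarityValue:
    value: float
    kind: str
    degenerate: bool = False


def cosine_fw(a: RateVector, b: RateVector) -> SimilarityValue:
    """Cosine of two rate vectors; degenerate if either is all-zero."""
    na = float(np.dot(a.rates, a.rates))
    nb = float(np.dot(b.rates, b.rates))
    if a.degenerate or b.degenerate or na == 0.0 or nb == 0.0:
        return SimilarityValue(float("nan"), COSINE_FW, degenerate=True)
    value = float(np.dot(a.rates, b.rates)) / math.sqrt(na * nb)
    # guard rounding excursions outside [0, 1]; rates are nonnegative
    return SimilarityValue(min(max(value, 0.0), 1.0), COSINE_FW)


def category_similarity(a: RateVector, b: RateVector, category: str) -> SimilarityValue:
    """Bounded per-category similarity ``1 - |r_a(k) - r_b(k)|``."""
    kind = category_indicator(category)
    if a.degenerate or b.degenerate:
        return SimilarityValue(float("nan"), kind, degenerate=True)
    k = CATEGORIES.index(category)
    return SimilarityValue(1.0 - abs(float(a.rates[k]) - float(b.rates[k])), kind)


def jaccard_syntax(a: frozenset, b: frozenset) -> SimilarityValue:
    """Jaccard overlap |a∩b| / |a∪b|; degenerate when both sets are empty."""
    union = len(a | b)
    if union == 0:
        return SimilarityValue(float("nan"), JACCARD_SYNTAX, degenerate=True)
    return SimilarityValue(len(a & b) / union, JACCARD_SYNTAX)
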