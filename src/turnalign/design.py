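"""Construction of the within-versus-between paired observation table.

For every eligible focal turn N in the analysis window, two rows enter the
design: a *within* row (similarity of focal turn N to the immediately
preceding partner turn in the same conversation) and a *between* row
(similarity of the same focal turn to a randomly sampled partner-role turn
from a different conversation).  The between draw is two-stage uniform —
first a conversation (excluding the focal turn's own), then a partner-role
turn within it — with one draw per within pair, fully determined by the
seed.

Directionality: the *user-side* analysis pairs user turn N with assistant
turn N-1 (first eligible index 1, since the opening user message has no
preceding assistant turn); the *model-side* analysis pairs assistant turn N
with user turn N-1 (first eligible index 0).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .corpus_io import ASSISTANT, USER, Conversation, Turn, validate_alternation
from .features import CATEGORIES, Lexicon, RateVector, annotate_rates, default_lexicon
from .similarity import (
    COSINE_FW,
    JACCARD_SYNTAX,
    SimilarityValue,
    category_similarity,
    cosine_fw,
    jaccard_syntax,
)


@dataclass(frozen=True)
class Direction:
    name: str
    focal_role: str
    partner_role: str
    first_eligible_index: int


USER_SIDE = Direction("user_side", USER, ASSISTANT, 1)
MODEL_SIDE = Direction("model_side", ASSISTANT, USER, 0)

_DIRECTIONS = {d.name: d for d in (USER_SIDE, MODEL_SIDE)}


def get_direction(name) -> Direction:
    if isinstance(name, Direction):
        return name
    try:
        return _DIRECTIONS[name]
    except KeyError:
        raise ValueError(f"unknown direction {name!r}") from None


def enumerate_focal_turns(
    conv: Conversation, direction
) -> list[tuple[Turn, Turn | None, int]]:
    """Eligible focal turns with their preceding partner turn and index N.

    N counts focal-role turns from 0; a focal turn is eligible when a
    preceding partner turn exists, so user-side indices start at 1 and
    model-side indices start at 0.  Requires a user-first alternating
    conversation.
    """
    direction = get_direction(direction)
    validate_alternation(conv)
    out = []
    n = 0
    for i, turn in enumerate(conv.turns):
        if turn.role != direction.focal_role:
            continue
        prev = conv.turns[i - 1] if i > 0 else None
        if prev is not None and prev.role == direction.partner_role:
            out.append((turn, prev, n))
        n += 1
    return out


def sample_between_partner(
    focal_conversation_id: str,
    pool: Sequence[Conversation],
    direction,
    rng: np.random.Generator,
    ordinal_window: tuple[int, int] | None = None,
) -> Turn:
    """Two-stage uniform draw of a partner-role turn from another conversation.

    By default any partner-role turn is eligible; ``ordinal_window``
    restricts the draw to partner turns whose within-role ordinal lies in
    the inclusive range (the window-matched sampling variant).
    """
    direction = get_direction(direction)
    candidates = [c for c in pool if c.id != focal_conversation_id]
    if not candidates:
        raise ValueError("between sampling needs a pool of >= 2 conversations")
    conv = candidates[rng.integers(len(candidates))]
    partner_turns = conv.role_turns(direction.partner_role)
    if ordinal_window is not None:
        lo, hi = ordinal_window
        partner_turns = partner_turns[lo : hi + 1]
    if not partner_turns:
        raise ValueError(f"conversation {conv.id} has no eligible {direction.partner_role} turns")
    return partner_turns[rng.integers(len(partner_turns))]


def _similarity(
    indicator: str,
    focal_key,
    partner_key,
    rates: Mapping,
    patterns: Mapping | None,
) -> SimilarityValue:
    if indicator == JACCARD_SYNTAX:
        if patterns is None:
            raise ValueError("jaccard_syntax requires per-turn pattern sets")
        return jaccard_syntax(patterns[focal_key], patterns[partner_key])
    a: RateVector = rates[focal_key]
    b: RateVector = rates[partner_key]
    if indicator == COSINE_FW:
        return cosine_fw(a, b)
    if indicator.startswith("category:"):
        return category_similarity(a, b, indicator.split(":", 1)[1])
    raise ValueError(f"unknown indicator {indicator!r}")


def build_paired_frame(
    convs: Sequence[Conversation],
    direction,
    window: tuple[int, int],
    indicators: Sequence[str],
    seed: int,
    lexicon: Lexicon | None = None,
    rates: Mapping | None = None,
    patterns: Mapping | None = None,
    between_window_only: bool = False,
) -> pd.DataFrame:
    """Paired observation table with one similarity column per indicator.

    Pairs whose focal or partner turn yields a degenerate similarity for any
    requested indicator are dropped *pairwise* (both rows), keeping the
    design balanced; the count of dropped pairs is stored in
    ``frame.attrs["n_degenerate_pairs"]``.  ``centered_turn`` is the focal
    index N centered at the mean over all retained rows.
    ``between_window_only`` restricts the between draw to partner turns
    whose within-role ordinal lies in the analysis window (variant; the
    default samples any partner-role turn).
    """
    direction = get_direction(direction)
    lo, hi = window
    if lo < 0 or hi < lo:
        raise ValueError(f"invalid window {window!r}")
    needs_rates = any(i != JACCARD_SYNTAX for i in indicators)
    if rates is None and needs_rates:
        rates = annotate_rates(convs, lexicon or default_lexicon())
    rng = np.random.default_rng(seed)

    rows: list[dict] = []
    n_degenerate = 0
    obs_id = 0
    for conv in convs:
        for focal, prev_partner, n_idx in enumerate_focal_turns(conv, direction):
            if not (lo <= n_idx <= hi):
                continue
            between = sample_between_partner(
                conv.id, convs, direction, rng,
                ordinal_window=window if between_window_only else None,
            )
            fkey = (conv.id, focal.index)
            sims_within = {
                ind: _similarity(ind, fkey, (conv.id, prev_partner.index), rates, patterns)
                for ind in indicators
            }
            sims_between = {
                ind: _similarity(
                    ind, fkey, (between.conversation_id, between.index), rates, patterns
                )
                for ind in indicators
            }
            if any(s.degenerate for s in sims_within.values()) or any(
                s.degenerate for s in sims_between.values()
            ):
                n_degenerate += 1
                continue
            base = {
                "conversation_id": conv.id,
                "direction": direction.name,
                "N": n_idx,
                "seed": seed,
            }
            within_row = dict(base, obs_id=obs_id, is_within=1, partner_conversation_id=conv.id)
            between_row = dict(
                base,
                obs_id=obs_id + 1,
                is_within=0,
                partner_conversation_id=between.conversation_id,
            )
            for ind in indicators:
                within_row[f"sim_{ind}"] = sims_within[ind].value
                between_row[f"sim_{ind}"] = sims_between[ind].value
            rows.extend((within_row, between_row))
            obs_id += 2
    if not rows:
        raise ValueError("empty observation table: no eligible pairs in window")
    frame = pd.DataFrame(rows)
    frame["centered_turn"] = frame["N"] - frame["N"].mean()
    frame.attrs["n_degenerate_pairs"] = n_degenerate
    frame.attrs["indicators"] = list(indicators)
    return frame


def build_observation_table(
    convs: Sequence[Conversation],
    direction,
    window: tuple[int, int] = (1, 10),
    indicator: str = COSINE_FW,
    seed: int = 42,
    lexicon: Lexicon | None = None,
    rates: Mapping | None = None,
    patterns: Mapping | None = None,
) -> pd.DataFrame:
    """Single-indicator observation table in the canonical column layout."""
    frame = build_paired_frame(
        convs, direction, window, [indicator], seed, lexicon=lexicon, rates=rates, patterns=patterns
    )
    frame = frame.rename(columns={f"sim_{indicator}": "similarity"})
    frame["indicator"] = indicator
    cols = [
        "obs_id",
        "conversation_id",
        "direction",
        "indicator",
        "N",
        "centered_turn",
        "is_within",
        "similarity",
        "partner_conversation_id",
        "seed",
    ]
    out = frame[cols]
    out.attrs.update(frame.attrs)
    return out


def turn0_gap(
    convs: Sequence[Conversation],
    indicator: str = COSINE_FW,
    seed: int = 42,
    lexicon: Lexicon | None = None,
    rates: Mapping | None = None,
    patterns: Mapping | None = None,
) -> float:
    """Model-side within-minus-between similarity gap at focal index 0.

    Turn 0 is the assistant's first response, conditioned on the user's
    opening message alone; it sits outside the harmonized window and is
    summarized separately as a raw mean gap.
    """
    table = build_observation_table(
        convs, MODEL_SIDE, (0, 0), indicator, seed, lexicon=lexicon, rates=rates, patterns=patterns
    )
    within = table.loc[table["is_within"] == 1, "similarity"].mean()
    between = table.loc[table["is_within"] == 0, "similarity"].mean()
    return float(within - between)


def mean_gap(table: pd.DataFrame) -> float:
    """Mean within-minus-between similarity over an observation table."""
    within = table.loc[table["is_within"] == 1, "similarity"].mean()
    between = table.loc[table["is_within"] == 0, "similarity"].mean()
    return float(within - between)


def category_indicators() -> list[str]:
    return [f"category:{c}" for c in CATEGORIES]
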