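"""Category-level decomposition, topic moderation, and the survivorship check."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .design import build_paired_frame, get_direction
from .features import CATEGORIES, Lexicon
from .model import DissociationModel, DissociationResults


@dataclass(frozen=True)
class CategoryResult:
    category: str
    direction: str
    beta3: float
    p_value: float
    bonferroni_alpha: float
    significant_corrected: bool
    converged: bool


def bonferroni_threshold(alpha: float = 0.05, n_categories: int = len(CATEGORIES), n_directions: int = 2) -> float:
    """Family-wise threshold over the category x direction test family
    (default 0.05 / 20 = 0.0025)."""
    return alpha / (n_categories * n_directions)


def decompose_by_category(
    convs,
    direction,
    seed: int = 42,
    window: tuple[int, int] = (1, 10),
    alpha: float = 0.05,
    lexicon: Lexicon | None = None,
    rates: Mapping | None = None,
) -> list[CategoryResult]:
    """Fit the dissociation model separately for each category's similarity.

    All 10 category models share one paired table (identical between-
    conversation draws), differing only in the similarity column, so the
    decomposition isolates category signal rather than sampling noise.
    Non-converged category fits are propagated with their flag rather than
    dropped.
    """
    direction = get_direction(direction)
    indicators = [f"category:{c}" for c in CATEGORIES]
    frame = build_paired_frame(
        convs, direction, window, indicators, seed, lexicon=lexicon, rates=rates
    )
    threshold = bonferroni_threshold(alpha)
    results = []
    for cat in CATEGORIES:
        fit = DissociationModel(frame, similarity_col=f"sim_category:{cat}").fit()
        p = float(fit.pvalues["is_within:centered_turn"])
        results.append(
            CategoryResult(
                category=cat,
                direction=direction.name,
                beta3=fit.beta3,
                p_value=p,
                bonferroni_alpha=threshold,
                significant_corrected=bool(p < threshold),
                converged=fit.converged,
            )
        )
    return results


@dataclass(frozen=True)
class TopicRule:
    label: str
    keywords: tuple[str, ...]
    priority: int


#: Heuristic first-user-turn topic rules; matching is case-insensitive
#: substring so multiword phrases ("tell me about") match as written.
DEFAULT_TOPIC_RULES: tuple[TopicRule, ...] = (
    TopicRule(
        "coding",
        ("code", "python", "function", "error", "debug", "javascript", "html", "css",
         "sql", "api", "compile", "syntax"),
        1,
    ),
    TopicRule(
        "creative_writing",
        ("write", "story", "poem", "essay", "fiction", "novel", "script", "dialogue",
         "narrative"),
        2,
    ),
    TopicRule(
        "factual_qa",
        ("explain", "what is", "how does", "define", "tell me about", "describe"),
        3,
    ),
    TopicRule(
        "advice",
        ("help me", "advice", "recommend", "suggest", "should i"),
        4,
    ),
)

OTHER_LABEL = "other"


def load_topic_rules(path) -> tuple[TopicRule, ...]:
    """Load topic rules from a YAML/JSON file: a list of mappings with
    ``label``, ``priority`` and ``keywords``."""
    import yaml

    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    rules = tuple(
        TopicRule(label=r["label"], keywords=tuple(r["keywords"]), priority=int(r["priority"]))
        for r in raw
    )
    if len({r.label for r in rules}) != len(rules):
        raise ValueError("topic rule labels must be unique")
    if len({r.priority for r in rules}) != len(rules):
        raise ValueError("topic rule priorities must be unique")
    return rules


def classify_topic(first_focal_text: str, rules: Sequence[TopicRule] = DEFAULT_TOPIC_RULES) -> str:
    """First matching rule by priority wins; no match -> ``other``."""
    if not rules:
        raise ValueError("rules must be nonempty")
    priorities = [r.priority for r in rules]
    if len(set(priorities)) != len(priorities):
        raise ValueError("rule priorities must be unique")
    text = first_focal_text.lower()
    for rule in sorted(rules, key=lambda r: r.priority):
        if any(kw.lower() in text for kw in rule.keywords):
            return rule.label
    return OTHER_LABEL


def label_conversations(convs, rules: Sequence[TopicRule] = DEFAULT_TOPIC_RULES) -> dict[str, str]:
    """Label each conversation from its first user-role turn."""
    labels = {}
    for conv in convs:
        first_user = next((t.text for t in conv.turns if t.role == "user"), "")
        labels[conv.id] = classify_topic(first_user, rules)
    return labels


def topic_moderated_fits(
    convs,
    labels: Mapping[str, str],
    direction,
    seed: int = 42,
    window: tuple[int, int] = (1, 10),
    indicator: str = "cosine_fw",
    min_conversations: int = 25,
    **kwargs,
) -> dict[str, DissociationResults]:
    """Fit the dissociation model within each topic subset.

    Subsets below ``min_conversations`` are fitted but flagged low-n via
    ``results.n_conversations``; subsets with fewer than 2 conversations are
    skipped (a random intercept cannot be estimated).
    """
    by_label: dict[str, list] = {}
    for conv in convs:
        by_label.setdefault(labels[conv.id], []).append(conv)
    out: dict[str, DissociationResults] = {}
    for label, subset in sorted(by_label.items()):
        if len(subset) < 2:
            continue
        out[label] = DissociationModel.from_conversations(
            subset, direction, window=window, indicator=indicator, seed=seed, **kwargs
        ).fit()
    return out


def survivorship_check(convs, mean_similarity: Mapping[str, float]) -> tuple[float, float]:
    """Pearson correlation of conversation length (total turns) with mean
    within-conversation similarity; a near-zero r indicates no survivorship
    bias (longer conversations are not systematically more similar).
    """
    lengths = []
    sims = []
    for conv in convs:
        if conv.id in mean_similarity:
            lengths.append(len(conv.turns))
            sims.append(mean_similarity[conv.id])
    if len(lengths) < 3:
        raise ValueError("survivorship check needs >= 3 conversations")
    lengths_arr = np.asarray(lengths, dtype=float)
    sims_arr = np.asarray(sims, dtype=float)
    if lengths_arr.std() == 0 or sims_arr.std() == 0:
        raise ValueError("zero variance in lengths or similarities")
    r, p = stats.pearsonr(lengths_arr, sims_arr)
    return float(r), float(p)


def mean_within_similarity(table: pd.DataFrame) -> dict[str, float]:
    """Per-conversation mean within similarity from an observation table."""
    within = table[table["is_within"] == 1]
    return within.groupby("conversation_id")["similarity"].mean().to_dict()


def category_results_frame(results: Sequence[CategoryResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])
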