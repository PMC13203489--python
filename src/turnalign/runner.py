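"""End-to-end pipeline runner: configuration, reports, structured logging.

``run_pipeline`` executes read -> features -> paired design -> model fit ->
moderation for each requested direction and indicator, writing plain-CSV
reports plus a JSON log of counts at every stage.  The defaults reproduce
the canonical analysis settings: minimum five user-assistant turn pairs,
harmonized window 1-10, between-sampling seed 42.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import moderation
from .corpus_io import attrition_table, filter_conversations, read_conversations
from .design import (
    build_observation_table,
    get_direction,
    mean_gap,
    turn0_gap,
)
from .features import Lexicon, annotate_rates, default_lexicon
from .model import (
    DissociationModel,
    per_conversation_slopes,
    static_effect_size,
    within_similarity_series,
)


@dataclass
class RunConfig:
    input_path: str | Path
    output_dir: str | Path
    directions: Sequence[str] = ("user_side", "model_side")
    indicators: Sequence[str] = ("cosine_fw",)
    window: tuple[int, int] = (1, 10)
    min_turn_pairs: int = 5
    seed: int = 42
    lexicon_path: str | Path | None = None
    topic_rules: Sequence[moderation.TopicRule] = moderation.DEFAULT_TOPIC_RULES
    decompose: bool = False
    topics: bool = False

    def load_lexicon(self) -> Lexicon:
        if self.lexicon_path is not None:
            return Lexicon.from_file(self.lexicon_path)
        return default_lexicon()


@dataclass
class ReportBundle:
    models: pd.DataFrame
    slopes: pd.DataFrame
    attrition: pd.DataFrame
    survivorship: dict
    log: dict
    categories: pd.DataFrame | None = None
    topics: pd.DataFrame | None = None


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Run the full dissociation analysis and write the report bundle."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {"seed": config.seed, "window": list(config.window)}

    convs = list(read_conversations(config.input_path))
    log["n_conversations_read"] = len(convs)
    convs = filter_conversations(convs, min_turn_pairs=config.min_turn_pairs)
    log["n_conversations_retained"] = len(convs)
    if not convs:
        raise ValueError("no conversations retained after filtering")

    lexicon = config.load_lexicon()
    rates = annotate_rates(convs, lexicon)
    log["n_turns"] = len(rates)

    model_rows = []
    slope_rows = []
    attrition_frames = {}
    survivorship = {}
    gap_summary = {}
    for direction in config.directions:
        dir_obj = get_direction(direction)
        attrition_frames[direction] = attrition_table(convs, config.window, dir_obj)
        for indicator in config.indicators:
            table = build_observation_table(
                convs, dir_obj, config.window, indicator, config.seed, rates=rates
            )
            log[f"n_obs_{direction}_{indicator}"] = len(table)
            log[f"n_degenerate_pairs_{direction}_{indicator}"] = table.attrs[
                "n_degenerate_pairs"
            ]
            fit = DissociationModel(table).fit()
            row = fit.to_row()
            row["d_static"] = static_effect_size(table).d
            row["mean_gap"] = mean_gap(table)
            model_rows.append(row)

            slopes = per_conversation_slopes(within_similarity_series(table))
            slope_rows.append(
                {
                    "direction": direction,
                    "indicator": indicator,
                    "mean_slope": slopes.mean_slope,
                    "t_stat": slopes.t_stat,
                    "df": slopes.df,
                    "p_value": slopes.p_value,
                    "pct_positive": slopes.pct_positive,
                    "n_excluded": slopes.n_excluded,
                }
            )
            if direction == "model_side":
                gap_summary[indicator] = {
                    "turn0_gap": turn0_gap(convs, indicator, config.seed, rates=rates),
                    "mean_gap_1_10": mean_gap(table),
                }
            if direction == "user_side" and indicator == config.indicators[0]:
                mean_sim = moderation.mean_within_similarity(table)
                try:
                    r, p = moderation.survivorship_check(convs, mean_sim)
                    survivorship = {"r": r, "p": p, "n": len(mean_sim)}
                except ValueError as exc:
                    # e.g. all conversations share one length: r undefined
                    survivorship = {"r": None, "p": None, "note": str(exc)}

    models = pd.DataFrame(model_rows)
    if {"user_side", "model_side"} <= set(config.directions):
        by_dir = models[models["indicator"] == config.indicators[0]].set_index("direction")
        log["beta1_ratio_model_over_user"] = float(
            by_dir.loc["model_side", "beta1"] / by_dir.loc["user_side", "beta1"]
        )
    log["turn0_gaps"] = gap_summary

    slopes_frame = pd.DataFrame(slope_rows)
    attrition_frame = pd.DataFrame(attrition_frames)

    categories = None
    if config.decompose:
        cat_rows = []
        for direction in config.directions:
            cat_rows.extend(
                moderation.decompose_by_category(
                    convs, direction, seed=config.seed, window=config.window, rates=rates
                )
            )
        categories = moderation.category_results_frame(cat_rows)
        categories.to_csv(out / "category_decomposition.csv", index=False)

    topics = None
    if config.topics:
        labels = moderation.label_conversations(convs, config.topic_rules)
        topic_rows = []
        for direction in config.directions:
            fits = moderation.topic_moderated_fits(
                convs, labels, direction, seed=config.seed, window=config.window, rates=rates
            )
            for label, fit in fits.items():
                rec = fit.to_row()
                rec["topic"] = label
                rec["direction"] = direction
                topic_rows.append(rec)
        topics = pd.DataFrame(topic_rows)
        topics.to_csv(out / "topic_moderation.csv", index=False)

    models.to_csv(out / "model_results.csv", index=False)
    slopes_frame.to_csv(out / "slope_summaries.csv", index=False)
    attrition_frame.to_csv(out / "attrition.csv")
    log["survivorship"] = survivorship
    with open(out / "run_log.json", "w", encoding="utf-8") as fh:
        json.dump(log, fh, indent=2)

    return ReportBundle(
        models=models,
        slopes=slopes_frame,
        attrition=attrition_frame,
        survivorship=survivorship,
        log=log,
        categories=categories,
        topics=topics,
    )
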