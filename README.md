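# turnalign

Within-versus-between dissociation analysis of linguistic accommodation in
dyadic conversation.

## What problem this solves

When two interlocutors talk — two people on the phone, or a person and a
chat assistant — their linguistic styles tend to align.  The hard part is
showing that an observed rise in similarity reflects adaptation to *this*
partner rather than task-stage effects (everyone drifts toward technical
register as a task progresses) or topic-driven similarity.  `turnalign`
implements the paired design that isolates conversation-specific
adaptation: every *within* observation (similarity of focal turn N to the
immediately preceding partner turn) is matched with a *between*
observation (similarity of the same focal turn to a randomly sampled
partner turn from a different conversation).  Population-level trends move
both rows equally; only conversation-specific adaptation opens a gap.

Both rows enter a multilevel model with a conversation random intercept:

    S_ij = β0 + β1·IsWithin_ij + β2·Turn_ij + β3·IsWithin_ij·Turn_ij + u_0j + ε_ij

* **β1** — the *static* gap: how much more similar you are to your own
  partner than to random partners, on average;
* **β2** — the between-baseline trend (a validity check; should be flat);
* **β3** — the *progressive* gap change per turn: positive means the
  conversation-specific gap widens as the conversation develops;
* **ICC** = σu²/(σu²+σe²) — the share of similarity variance attributable
  to conversation-level differences.

The analysis is symmetric: it runs user-side (user turns focal) and
model-side (assistant turns focal), over a harmonized focal-turn window
1–10, with the assistant's first response (turn 0) summarized separately
because its gap is typically front-loaded.

Intended users: computational psycholinguists and behavioral scientists
studying style matching / accommodation in conversation corpora
(human–human or human–AI), who need the full pipeline — corpus ingestion,
turn-level function-word and syntactic features, seeded between-conversation
baselines, the multilevel fit, category decomposition, topic moderation,
and robustness checks — as tested, reusable parts.

## Worked example

Generate a synthetic corpus with a known accommodation mechanism — gradual
focal drift toward the conversation's partner register on the pronoun
categories — and fit the user-side model:

```python
import turnalign as ta
from turnalign.features import annotate_rates, default_lexicon

lex = default_lexicon()
spec = ta.drift_spec(seed=11, n_conversations=200)   # known ground truth
convs, truth = ta.generate_corpus(spec, lexicon=lex)
rates = annotate_rates(convs, lex)

fit = ta.DissociationModel.from_conversations(
    convs, ta.USER_SIDE, seed=42, rates=rates
).fit()
print(fit.summary().round(4))
```

```
                           coef      se        z       p
intercept                0.6691  0.0074  90.5540  0.0000
is_within                0.0324  0.0054   5.9907  0.0000
centered_turn            0.0009  0.0013   0.6624  0.5077
is_within:centered_turn  0.0068  0.0019   3.6195  0.0003
```

with `sigma_u2=0.0080, sigma_e2=0.0293, ICC=0.21` over 4000 observations
from 200 conversations.  Read: similarity to one's own partner exceeds the
between-conversation baseline by 0.032 on average (β1, p < 0.001); the
baseline itself is flat (β2 ≈ 0, p = 0.51), so the significant positive
interaction (β3 = +0.0068 per turn, p < 0.001) is conversation-specific
progressive convergence — exactly the drift the generator planted, and on
the same scale (the gap widens by ≈ 0.06 over the nine-turn window).

Front-loaded adaptation, the opposite temporal signature, is visible on
the model side of a corpus whose partner mirrors strongly only at its
first response (`ta.front_loaded_spec`): the turn-0 within-versus-between
gap is 0.162 against a turns-1–10 plateau of 0.040 — initial adaptation
followed by stabilization, not progressive change.

Real corpora enter the same way from JSON-lines (one conversation per
line, `{"id": ..., "turns": [{"role": "user|assistant|A|B", "text": ...}]}`)
via `ta.read_conversations`, with timestamped spoken-transcript files
converted through `ta.conversation_from_utterances` (marker cleaning,
same-speaker merging).  A `turnalign` CLI wraps the pipeline
(`turnalign simulate`, `turnalign fit`, `turnalign report`,
`turnalign robustness`).

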