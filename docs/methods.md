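# Methods

## The question and the design

Interlocutors in dyadic conversation tend to align their linguistic style.
Measuring that alignment naively — "does my similarity to my partner rise
over the conversation?" — confounds three things: genuine adaptation to
*this* partner, population-level trends (everyone's language becomes more
task-like as any task progresses), and topic-driven similarity between
adjacent turns.  The within-versus-between dissociation isolates the first:
every *within* observation (similarity of focal turn N to the immediately
preceding partner turn) is paired with a *between* observation (similarity
of the same focal turn to a random partner-role turn drawn from a different
conversation).  Anything that moves similarity to partners *in general*
moves both rows equally; only conversation-specific adaptation opens a gap.

The design is directional.  The *user-side* analysis treats user turns as
focal (first eligible index 1, because the opening user message has no
preceding partner turn); the *model-side* analysis treats assistant turns
as focal (first eligible index 0).  The harmonized analysis window is focal
index 1–10 for both directions, so the model-side turn-0 observation — the
assistant's first response, which empirically carries an outsized gap — is
summarized separately as a raw mean gap and through window-sensitivity
refits over [0, 10].

## The model

For similarity observation i in conversation j:

    S_ij = β0 + β1·IsWithin_ij + β2·Turn_ij + β3·IsWithin_ij·Turn_ij
           + u_0j + ε_ij,    u_0j ~ N(0, σu²),  ε_ij ~ N(0, σe²)

with Turn centered at the pooled sample mean over retained rows (asserted
by the centering identity test).  β1 is the *static* gap, β2 the
between-baseline trend (a validity check: it should be flat), β3 the
*progressive* gap change per turn.  Estimation is REML via statsmodels
MixedLM with a random intercept per conversation; the optimizer chain is
lbfgs → powell → nm, ending in derivative-free methods, with the
convergence flag surfaced on the results object rather than raised.
P-values are two-sided Wald z tests on the fixed effects.  ICC is
σu²/(σu²+σe²).  Optional random slopes for IsWithin and/or Turn are
available as a robustness specification; slope variances are reported
alongside the intercept variance.

Derived statistics: per-conversation OLS slopes of within similarity on
turn with a two-sided one-sample t test; static Cohen's d from the pooled
within/between SD; cumulative progressive d = β3·span/SD_pooled (span 9 for
the 1–10 window); a pairs cluster bootstrap (conversations resampled with
replacement) with a BCa interval for β3 — bias correction from the
bootstrap distribution, acceleration from a leave-one-conversation-out
jackknife; OLS with conversation-clustered sandwich standard errors;
multi-seed reruns that vary only the between-conversation draws; and
window-sensitivity refits.

The bootstrap refits use the OLS fixed-effects estimator by default: the
cluster resampling itself carries the dependence structure, and on balanced
tables the OLS and mixed-model fixed-effect point estimates coincide to
within a GLS reweighting that is negligible here (the two routes are
compared directly in the test suite).  A full REML refit per resample is
available via `refit="mixed"`.

## Indicators

* **Function-word cosine.**  Each turn is a 10-vector of category rates
  (count/token_count) over first/second/third-person and first-person-
  plural pronouns, discourse connectives, hedges, articles, prepositions,
  conjunctions, negations; the indicator is the cosine of the two raw rate
  vectors.  Tokenization is whitespace-style with lowercase normalization
  and punctuation removal; word-internal apostrophes survive so
  contractions ("don't") stay whole.  The packaged lexicon is a documented
  approximation of the closed-class lists in the LIWC tradition; every
  analysis takes the lexicon as an input, so lists can be swapped without
  code changes.  Categories must be disjoint (validated), because the
  per-category similarity treats counts as partitioning function-word mass.
* **Per-category similarity.**  1 − |r_focal(k) − r_partner(k)|, bounded in
  [0, 1]; used by the category decomposition, fitted with the same model.
  The Bonferroni family is the 20 category×direction tests (α/20 = 0.0025).
* **Syntactic overlap.**  Jaccard similarity of (dependency-label,
  head-POS, dependent-POS) triple sets.  Parsing sits behind an injectable
  adapter (text → triples); the default adapter loads spaCy lazily (NER
  disabled) and is an optional extra — pattern sets can equally be supplied
  precomputed, which is how the test fixtures work.

Degenerate pairs — a zero rate vector (empty turn, or no function words at
all) or two empty pattern sets — are dropped *pairwise* (both rows of the
pair), keeping the design balanced; the count is logged on the table.

## The synthetic generator

The generator produces user-first alternating dyads at the level the
pipeline consumes: per-turn category rate vectors realized as multinomial
token draws (category words uniform within category, remaining mass from a
disjoint filler vocabulary), joined so that text → tokenize → rates
round-trips exactly.

Mechanisms, each with a closed-form expected trajectory
(`expected_rate_trajectories`) used as the oracle in recovery tests:

* **Session variation.**  Per-conversation, mean-preserving lognormal
  multipliers on the focal baseline (sd 0.7) and the partner profile
  (sd 1.0) — conversation-level register variation, the larger partner
  value reflecting topic-driven variation in assistant output.  Per-turn
  jitter is also lognormal and role-split: focal 0.2, partner 0.4 (a user's
  function-word register is comparatively stable turn-to-turn; assistant
  responses vary with content).
* **Turn lengths.**  Lognormal per role with the log-variance split into a
  between-conversation component (some conversations run terse, others
  verbose) and a within-conversation component.  Defaults: focal median 18
  with session/turn sigmas 1.5/2.0 (marginal mean ≈ 330, matching the
  heavy-tailed written-chat regime), partner median 271 with 0.4/0.62
  (mean ≈ 355).  Between-conversation length variation is a deliberate,
  realistic driver of the conversation-level intercept variance: short-turn
  conversations have noisier rate vectors and systematically lower cosine
  similarity.  Fitted ICC under the defaults is ≈ 0.17–0.24.
* **Front-loaded partner mirroring.**  The partner's rates are
  profile + λ·(focal session style − profile), with λ0 replacing λ at the
  first response.  λ0 ≫ λ reproduces front-loaded adaptation: a large
  turn-0 within-versus-between gap settling to a stable plateau.  Defaults
  λ = 0.25, λ0 = 0.6.
* **Gradual focal drift.**  From eligible turn N the focal mean moves
  min(γN, 1) of the way toward the conversation's *realized* partner
  register (the mirrored session style), on a masked category subset
  (default: first-person-singular and second-person pronouns, γ = 0.015 —
  per-category rate slopes of order 10⁻³/turn).  The target is
  session-specific by design: drift toward the population-generic profile
  is invisible to the within-versus-between contrast, because the between
  baseline rises at exactly the same rate — that cancellation is the
  design's purpose, and the generator respects it.  When mirroring and
  partner heterogeneity are zero the target reduces to the population
  profile.

Rates leaving the simplex after composition are clipped (nonnegativity;
total capped at 0.97 to preserve filler mass) and the clip count recorded
in the ground truth, which also stores all realized session multipliers.

### What the generator does and does not emulate

It emulates: conversation-level heterogeneity (ICC), heavy-tailed lengths,
a stable assistant register, front-loaded partner adaptation, gradual
focal pronoun drift, and exchangeability of between-conversation draws.
It does not emulate natural-language content, topics, syntax (the
syntactic indicator is exercised with fixture pattern sets), backchannel
dynamics, or autocorrelated residuals.  Passing recovery tests therefore
demonstrates that the *pipeline* measures what it claims under a known
mechanism, not that any particular real corpus contains that mechanism.

## Validation experiments and their sizes

Calibration and recovery experiments use a *validation preset*: the same
generator with verbose written-register lengths for both roles (median 271)
and adaptation off unless the experiment switches a mechanism on.  The
reason is a genuine property of the paired design worth stating plainly:
the two rows of a pair share the focal turn, so with very short focal
turns (median 18) most of the turn-level residual is shared focal sampling
noise, the model-implied SE of β3 overstates its true sampling variance,
and the Wald test becomes conservative (we observe a null z-spread of
≈ 0.5–0.8 and essentially zero rejections in that regime).  With
informative turns the residual is dominated by partner-side variation,
which is independent across the two rows, and the test is near-nominal
(null z-spread ≈ 0.95, type-I ≈ 4%).  The same caveat applies to the
published design itself whenever focal turns are very short; the
cluster bootstrap, which resamples whole conversations and preserves the
pair structure, remains valid in either regime.

Experiment sizes were chosen a priori from power arithmetic and runtime:
type-I calibration uses 200 corpora of 100 conversations × 10 eligible
turns; mechanism recovery uses 100 runs (mirroring λ=0.5 at n=100; drift at
n=200); the category decomposition uses 50 runs at n=200; front-loading 50
runs at n=100; bootstrap coverage 200 replicates with 200 resamples.  The
drift experiments use γ = 0.1 — complete convergence over the ten-turn
window, the upper end of the realistic regime — because at n=200
conversations (an order of magnitude below published corpus sizes)
smaller drift rates are not recoverable with the required reliability;
the resulting aggregate β3 ≈ +0.004/turn.

## Numerical choices and degenerate inputs

* Timestamp ties in transcript interleaving break by input order (stable
  sort); marker-only utterances are cleaned away before merging so they
  cannot break turn alternation.
* Conversations opening with the partner role are rejected, not re-aligned:
  the pairing rule presumes the user speaks first, and silently shifting
  indices would change what "turn N" means.
* Between draws are two-stage uniform (conversation excluding the focal
  turn's own, then any partner-role turn in it), independent across
  observations, one draw per within pair, all funneled through one seeded
  generator per table build; the same seed reproduces the table exactly.
  Restricting draws to partner turns inside the analysis window is
  available as a variant but is not the default.
* All-zero rate vectors make cosine undefined: flagged degenerate, dropped
  pairwise, never raised mid-pipeline.
* The BCa bias-correction proportion is clipped away from 0 and 1 before
  the normal quantile; acceleration falls back to 0 when the jackknife
  spread is exactly zero.
* A conversation with fewer than two distinct turn values has no slope and
  is excluded from the slope distribution with a logged count.

## Known limitations

* The Wald conservativeness under short focal turns, above.  An explicitly
  pair-aware error structure (e.g. a random effect per pair) would address
  it and is out of scope here.
* The model assumes independent residuals within conversation beyond the
  random intercept; autocorrelation across turns is not modeled.
* The shipped lexicon is an approximation of proprietary closed-class
  lists; all rate-level conclusions are lexicon-relative, which is why the
  lexicon is an explicit input everywhere.
* Topic classification is a keyword heuristic over the first user turn,
  priority-ordered, substring-matched; it is deliberately simple and is
  not a topic model.
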