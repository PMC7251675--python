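# Methods

## Text model and candidate definition

Documents follow the PubTator convention: character offsets are global to
`title + " " + abstract`, all intervals 0-based half-open. Linguistic
annotation (sentences, tokens, coarse POS) is a pluggable contract; the
shipped `RuleAnnotator` splits sentences at terminal punctuation followed
by whitespace, tokenizes alphanumeric runs (hyphen/apostrophe-joined)
plus single punctuation marks, and tags verbs from a packaged lexicon
with -s/-es/-ed/-d/-ing inflection stripping. It deliberately trades
linguistic fidelity (no abbreviation handling, no dependency parses) for
determinism and zero model downloads; any external parser can be
injected through the TSV annotation cache. Mentions whose stated surface
disagrees with the text at the stated offsets are dropped, never
repaired — repair would silently corrupt the character positions exported
in predictions. Overlapping chemical annotations keep the longest span
(ties: earliest start), so each surface region yields one mention and
the n(n−1) candidate count stays well defined.

A candidate is an ordered pair of distinct mention *spans* in one
sentence; identical surfaces at different positions still pair, and no
filtering happens at extraction (the definition is deliberately
high-recall; every veto is a labeling function).

## Labeling functions

Nine unipolar LFs ship by default — three positive (keyword-in-between,
verb-in-between, knowledge-base lookup) and six negative (argument
order, "-ase" adjacency, "or" separation, element mentions,
functional-group proximity, treatment vocabulary). "Between" always
means the textual gap between the earlier mention's end and the later
mention's start, independent of which mention is the putative substrate.
A direct consequence is that a positive between-span rule fires on
*both* orders of a pair, so its votes are at most 50% accurate by
construction and conflicts with the order veto are expected, measurable
signal rather than bugs. Keyword matching tolerates inflection (a
trailing *-e* is stemmed; *-s/-es/-d/-ed/-ing* suffixes accepted), so
*oxidize* matches *oxidized* but not *oxidation*, which is a separate
configurable entry. The "-ase" rule inspects only the token immediately
following a mention and requires length ≥ 5 to avoid *base*/*case*. The
functional-group window defaults to 3 tokens on either side of a
mention. The treatment veto is sentence-scoped like every other rule;
abstract scoping would veto whole documents. All lexicons are plain text
files (one term per line, `#` comments) and the registry accepts
user-defined LFs, so the default set can be extended to any corpus.

The packaged knowledge base (`synthetic_reaction_kb.tsv`) is a
hand-written synthetic stand-in of twenty well-known 1:1 microbial
transformations, not an export of any curated database; the loader
applies the documented preprocessing (normalize, drop self-pairs and
water/hydrogen/proton carriers) to any user-supplied pair table.

## Generative label model

Latent label y ∈ {±1} with class prior π; LF j casts a vote with
propensity ρ_j independent of y and matches y with accuracy α_j.
ρ factors out of the posterior, so marginals depend only on α and π.
EM details: ρ̂_j is the observed non-abstain rate (its closed-form MLE);
α is initialized at 0.7 with a small seeded jitter; tol 1e-6 on the
log-likelihood, max 500 iterations, parameters clipped into
[1e-4, 1−1e-4]. When a prior is supplied it is held fixed — the lever
for heavy class imbalance; the pipeline default is 0.5, with a dev-set
positive rate being the natural substitute when gold dev labels exist.

Accuracies are additionally floored at 0.5+1e-3 by default
(`min_accuracy`). This encodes the unipolar reading that a cast vote
never counts *against* its polarity: because between-span positive rules
fire on both orders of a pair, their unconstrained vote accuracy is
≤ 0.5 and unconstrained EM flips them into negative evidence, collapsing
the marginals (observable by passing `min_accuracy=1e-4`). Per column
the expected complete-data log-likelihood is concave in α_j, so clipping
the M-step estimate is the constrained maximizer and the observed
log-likelihood stays non-decreasing (asserted in tests).

A row on which every LF abstained has posterior exactly π. Such rows are
the probabilistic analogue of a majority-vote abstention: generative
"coverage" counts candidates with |marginal − π| ≥ 1e-9, and
thresholded generative predictions abstain on them. For evaluation,
abstentions count as negative predictions, so unrecovered positives are
false negatives.

## Discriminative model

Feature templates (explicit vocabulary, no hashing, frequency floor 2 on
the training split): between-mention lemma n-grams (n ≤ 3), ±3-token
lemma windows around each mention (role-tagged), the argument-order
flag, a token-distance bin, the between-POS sequence (truncated at 8),
an "-ase"-adjacency indicator, and one indicator per reaction keyword
found between the mentions. Soft-target training is exact, not
approximate: each candidate appears as a positive with weight m and a
negative with weight 1−m, which makes the weighted log-loss equal the
sigmoid cross-entropy against the marginal. The optimizer is
scikit-learn's saga with elastic-net penalty; `penalty_strength`
multiplies the penalty relative to the *mean* data loss (so duplicating
examples leaves the optimum unchanged), with defaults l1_ratio 0.5,
penalty 1e-3, tol 1e-6, threshold 0.5 (a score exactly at threshold is
positive). Determinism holds given the seed; on tiny fixtures the
stochastic solver leaves ~1e-3-level noise, which the tests bound
explicitly.

Resampling keeps every candidate with marginal ≥ 0.5 and subsamples the
rest (seeded, uniform) to ≈10% of the pool — negatives in this task are
highly redundant, so little is lost. The end-to-end pipeline first drops
no-signal rows (marginal exactly at the prior): with a 0.5 prior they
would sit exactly at the keep threshold and crowd out informative
examples, and a 0.5 soft target teaches the classifier nothing.

## Evaluation

Gold labels are per ordered candidate, so a correct reaction extracted
backwards scores as FP + FN. Metrics with zero denominators are defined
as 0. Splits are document-level disjoint random partitions with
largest-remainder rounding, deterministic per seed, supporting
train/dev/test plus a held-fixed legacy test set. Grid search is
exhaustive over the Cartesian grid, selects maximal dev F_β (β is a
surfaced config value, default 1), breaking ties by precision then grid
order; failed cells are skipped.

## Synthetic corpus generator

Positive sentence templates assert exactly one substrate→product pair
("X is converted to Y", "conversion of X to Y …", an enzymatic variant,
a three-chemical "in the absence of Z" variant); distractor templates
realize each veto pattern (alternatives with *or*, measurement lists of
0–8 chemicals, clinical-treatment phrasing, "-ase"-adjacent mentions,
element mentions, functional-group contexts). Gold is fixed by template
semantics at generation time — never by running the LFs — so evaluation
is not circular. Chemical names come from a packaged metabolite-style
list, optionally extended with CHEM_0001-style tokens; ~30% of planted
pairs are drawn from the packaged KB so distant supervision fires.

The positive-candidate rate is the configured quantity. With e_pos and
e_neg the expected candidates per positive/distractor sentence under the
template mix, a target rate r is hit by the sentence-level reaction
probability p = r·e_neg / (1 − r·e_pos + r·e_neg). The default
configuration (200 documents, 2–5 sentences each, r = 0.05) emulates a
reaction-enriched corpus; r = 0.015 emulates the general-corpus regime.
The maximum attainable rate is 1/e_pos (≈0.42 under the default mix), so
r = 0.5 saturates near that value — still within the ±20% relative band
asserted for n ≥ 200 documents. What the generator does *not* emulate:
real syntactic variety, tagger errors, nested/overlapping mentions,
cross-sentence coreference, and realistic LF accuracy profiles — so
green tests demonstrate mechanism correctness and calibration, not
real-corpus performance levels.

## Problem sizes and seeds

Default test and example runs use 200-document corpora (~2,700
candidates), 5,000-row simulated label matrices for parameter recovery,
and an 800-document corpus for the 1.5% imbalance check; all randomness
flows from explicit integer seeds (numpy `default_rng`). The acceptance
script generates its corpus from the provided seed (reduced mod 2³¹)
and recomputes the argument-order coverage from scratch each run.

## Known limitations

- The rule annotator mis-splits on abbreviations ("E. coli") and tags
  only a coarse VERB/WORD/PUNCT inventory; inject a real parser via the
  annotation cache for serious corpora.
- The independence assumption of the label model is wrong for correlated
  LFs (e.g. keyword and verb rules fire together); no dependency
  structure is learned.
- Because propensities are label-independent, abstention carries no
  evidence — in particular the *absence* of the order veto is not used
  by the generative model, only by the discriminative features.
- KB lookup is exact string match on normalized surfaces; no synonym or
  identifier resolution.
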