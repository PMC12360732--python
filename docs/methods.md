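# Methods

This note documents the models and procedures implemented in `phenorisk`,
the choices made where the design was genuinely open, and what the
simulation-based tests do and do not establish.

## Problem setting

The package operationalizes a digital-phenotyping analysis for a small
cohort of young sexual- and gender-minority adults: three passively sensed
phone streams — keystroke snapshots (the full contents of the active text
field at every keypress, with the app package or browser URL), GPS fixes
logged only while the phone moves, and periodic wellness-survey answers —
are turned into per-participant behavioral features, which are then used to
predict binary substance-use and sexual-risk outcomes and contrasted
between outcome groups. Participants enter the analysis only if they have
at least 30 distinct days of keystroke data (`min_days`, inclusive
boundary). Day boundaries are fixed UTC calendar days derived from epoch
timestamps; the raw streams carry no timezone, and a fixed convention keeps
every day-based feature reproducible.

## Keystroke deduplication

One typed line arrives as a run of near-duplicate snapshots
(`"H"`, `"He"`, …, `"Hello"`), and autocorrect means an earlier row is not
always a substring of the next. Within each run of consecutive same-app
events, two rules are applied to adjacent rows and iterated to a fixpoint:

1. drop row *i* if its text is a contiguous substring of row *i+1*'s text;
2. drop row *i* if `sim(i, i+1) > 0.6` (strictly greater), where
   `sim(a,b) = 1 − dist(a,b) / max(|a|,|b|)` and `dist` is the unit-cost
   Levenshtein distance, with `sim(∅,∅) = 1` by convention.

The distance is computed by the standard two-row dynamic program and is
verified in tests against the direct recursive definition (all-pairs up to
length 6 over a three-letter alphabet) and against an independent
alignment library. Open choices: comparisons are consecutive-only; runs are
bounded by app-package changes (different text fields should never absorb
each other); the substring check is case-sensitive and not prefix-only
(autocorrect can rewrite earlier characters); empty rows are dropped before
deduplication; the two-rule pass is repeated until no row is removed. A
cheap length-difference bound skips the dynamic program when the similarity
cannot exceed the threshold.

The procedure is intentionally local: a short message whose text happens to
be a substring of the immediately following message in the same app is
absorbed by rule 1. This is inherent to the rules, not a defect of the
implementation, and is rare under realistic message mixes.

## App canonicalization and app-use features

Services reachable as both app and website are merged: the URL's hostname
(lowercased; scheme, credentials, port, path, query stripped; leading
`www.` removed; no eTLD+1 collapsing) is looked up in a curated
domain→package table, falling back to the domain itself; native apps keep
their package name. "Using an app on a day" means producing at least one
deduplicated text line in it that day. Features are day shares:
`freq(app) = (# days using app) / (# days using any app)`, and category
day-fractions aggregate distinct days over the messaging / social-media /
dating categories. The packaged category and domain tables are openly
reconstructed defaults (the original deployment's 68-app list is not
public) and are user-replaceable CSVs.

## Text features

All text features use lines typed in communication apps only (messaging,
social media, dating); other sources are noise (product names, navigation
queries). Tokenization is lowercase, punctuation-stripped with apostrophes
kept inside tokens. Lemmatization is an injected interface whose default is
a deterministic exception table plus regular suffix rules — dependency-free
and reproducible; a corpus-trained lemmatizer can be plugged in.

* **Word frequencies**: `freq(w) = (# days with lemma w) / (# days with
  any text)`. The vocabulary drops stop words (packaged list), known UI
  placeholder strings, and lemmas used by fewer than 5 participants
  (`min_users`, inclusive).
* **Risky phrases**: the same day-share statistic for a lexicon of sex- and
  drug-related phrases, per phrase, per category and per subcategory. A
  phrase matches a day when its full lemmatized token sequence occurs
  contiguously within a single line that day. Matching on lemmatized
  tokens is the default (a config switch matches raw tokens instead — the
  original analysis does not state which it used). The packaged lexicon is
  a small openly reconstructed demonstration; the prior study's list is not
  public.
* **Dictionary scores**: an open JSON format of categories holding
  lowercase word patterns with an optional terminal wildcard stands in for
  proprietary closed-vocabulary scoring software. Daily score = matching
  tokens / total tokens; the participant feature is the unweighted mean
  over days with at least one token. Tokens are matched unlemmatized —
  wildcards absorb inflection. The packaged dictionary demonstrates the
  social / affect / drives / cognitive-processes categories; licensed
  dictionaries drop in as files.
* **Embeddings**: each day's concatenated text is embedded and day vectors
  averaged. The default embedder is a deterministic signed token-hashing
  projection (64 dimensions), which makes embedding features exactly
  reproducible in tests; a transformer sentence encoder plugs in through
  the same `embed(text) → vector` interface. Days with no tokens are
  skipped; a participant with no text days gets a missing embedding.

## Mobility

Because fixes are logged only while moving, a silent gap means time spent
at the last position. Fixes no more than `gap_max` (default 5 min) apart
form one movement episode; the episode's last fix is retained as a stay
point. A speed threshold is available but off by default — the gap rule
alone matches the logger's semantics.

Stay points are clustered with flat-kernel mean shift: every point is
iteratively moved to the mean of the *original* points within radius `r`
until its displacement falls below `r/100` (max 200 iterations); converged
modes closer than `r/2` merge; each point joins its mode's cluster. The
default `r` is 100 m — building-scale place separation; the original
analysis chose its radius by visual inspection, so the parameter is
prominent and configurable. Clustering runs in a local equirectangular
meter frame around the trace centroid (error ≪ r at place scale);
*reported* distances always use the haversine great-circle formula with
Earth radius 3958.8 miles. The most-visited cluster is flagged home (ties
break to the earliest first visit). Features: mean and max distance from
home, share of stay points over 50 miles from home, stay points per day,
mean distinct places per day, total unique places, and share of days with
at least one stay point outside the home cluster.

## Outcome labels and models

Survey answers are decomposed into independent binary questions: the
compound substance-use answer yields methamphetamine-use and
injection-drug-use labels; partner-count bands yield 6-plus and 11-plus
indicators; decline/don't-know answers become missing for the affected
question only, never removing the participant's other answers. The three
headline outcomes are methamphetamine use, ≥6 partners, and condomless
receptive sex.

Two classifiers are evaluated per question × feature-set combination with
leave-one-out cross-validation: L2-regularized logistic regression
(`max_iter=1000`) and an 80-tree gradient-boosting classifier (other
settings at library defaults). Scores are the F1 of the minority class —
the less frequent true answer (ties treat "yes" as positive) — computed on
the pooled out-of-fold predictions. The combination registry holds the 13
evaluated feature sets: the seven single groups and six non-redundant
combinations up to the full set.

Open choices surfaced as flags:

* features are z-scored for the logistic model *inside each training fold*
  (unstated in the original analysis; needed for stable convergence); tree
  models use raw features;
* the word-frequency vocabulary's minimum-user filter is re-applied inside
  each training fold by default, so the held-out participant never
  influences the vocabulary (usage ⇔ nonzero day share, so the filter is
  recomputable from the feature matrix). `paper_faithful` /
  `fold_internal_vocab=False` reproduces the full-corpus vocabulary of the
  original design, which carries a mild leak;
* missing feature values are zero-filled (no fitted imputation statistic —
  nothing to leak across folds).

**Chance bands.** The chance level of each (question, combo, model) cell is
estimated from 200 label permutations scored against the cell's pooled
out-of-fold predictions — the standard permutation null for an association
given fixed prediction margins. Refitting the LOOCV 200 times per cell
(~400k model fits across the grid) would measure the same null at
impractical cost. The dedicated no-leakage check *does* refit: labels are
permuted once, the full LOOCV grid is re-run on the permuted labels, and
every cell's score must fall inside the full range of its 200-permutation
band; a preprocessing leak across folds would push scores above it.

## Group contrasts

Per feature, the "yes" and "no" groups of an outcome are compared with an
independent two-sample t-test — Welch's unequal-variance statistic with
Welch–Satterthwaite degrees of freedom by default (the original analysis
says only "independent t tests"; Welch is the robust common default, and a
`student` flag gives the pooled-variance variant) — two-sided, significant
at P < .05. No multiple-testing correction by default, matching the
exploratory framing; Benjamini–Hochberg is available. `scale_for_display`
divides by the maximum absolute value so features of different scales share
one axis, reproducing the figure convention.

## Synthetic cohort

The generator's defaults are the study conditions: 80 participants × 35
active days (clearing the 30-day filter), outcome prevalences from the
reference cohort (meth 0.183, ≥6 partners 0.50, condomless receptive
0.744, IDU 0.037), 5% missing-answer rate. Planted effects: positives for
meth or ≥6 partners use dating apps on a 2.5× higher share of days and
insert sex-related lexicon phrases at 3× the base rate (drug-related
phrases driven by meth use); ≥6-partner positives travel 2.5× farther.
Condomless receptive sex has deliberately *no* planted channel — it
emulates an outcome the sensed streams carry little signal for, and its
scores should sit at chance. Message text comes from a template grammar
over a neutral vocabulary with lexicon phrases mixed in at class-dependent
rates: controllable and sufficient for frequency-based features; no
natural-language realism is claimed. Typing traces are prefix sequences;
with probability 0.15 a substituted character persists in every later
snapshot until the final row corrects the whole line (how autocorrect
behaves), which provably stays within the dedup rules' reach — the trace
reduces to exactly its final line. GPS days are home→place→home legs of
moving fixes 30 s apart ending at the destination, separated by 1–3 h
dwells, so stay-point detection recovers exactly the visited endpoints and
home is the most-visited place by construction. Each participant's RNG
stream derives from (seed, participant index), so cohorts are byte-identical
across runs and generation order.

What the simulations do **not** show: real typing is bursty, multilingual
and heavily edited; real app mixes are long-tailed; real mobility has
routine structure and GPS noise; real outcome labels are self-reported with
nonrandom missingness. Passing tests establish that the pipeline computes
its quantities correctly and recovers effects of the planted form at the
planted size — not that those effect sizes hold in any real cohort.

## Validation experiments and problem sizes

The validation layer (`phenorisk.validation`) and the acceptance script run:
the two canonical dedup sequences; 10,000-pair edit-distance oracle
agreement; 100 planted-place clustering instances (k ∈ 1..5, separation
~50× r); 1000-rep t-test null calibration with cohort-like 15/65 group
sizes plus a 100-replicate power check of the planted dating-app elevation
(simulated at the day-process level so many replicates stay cheap); a
full-pipeline no-leakage check (one 80×35 cohort, all 13 combos × 2
models refit on permuted labels); and planted-signal recovery over seeded
cohorts (20 in the test suite, 10 in the acceptance script) using the
boosted model on the risky-words group. The end-to-end determinism check
runs the full pipeline twice on a 40-participant × 60-day cohort. These
sizes are the package's chosen validation conditions; raising them is a
config change, not a code change.

## Known limitations

* The packaged lexicon, dictionary, stop-word list and app tables are small
  open reconstructions for demonstration and testing; substantive use
  requires supplying real, validated resources.
* The rule lemmatizer handles regular inflection and common irregulars
  only; out-of-table irregulars pass through unchanged.
* Mean shift is quadratic in stay points per participant; traces with many
  thousands of stay points should be thinned or windowed first.
* LOOCV with n ≈ 80 yields high-variance scores; chance bands are reported
  for exactly this reason, and single-cell F1 differences should not be
  over-read.
* The minority class is defined from the full label vector of each
  question; under heavy missingness the minority can differ between
  questions sharing participants.
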