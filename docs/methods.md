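# Methods

This note documents the models, algorithms and design choices behind
`avspan`, in the spirit of a statistical software methods appendix.  It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Task and design constants

A trial presents five black target digits (1–9) interleaved with five
dark-gray distractor digits; blanks (empty gray circles) are legal
distractors.  Each digit is visible for 200 ms.  Each target owns a
1250 ms window (0.8 Hz); rhythmic conditions lock target onsets to this
grid and precede the sequence with five induction stimuli on the same
grid, non-rhythmic conditions draw the onset uniformly within the window
subject to fitting that window's distractors.  Distractor onsets are
uniform within the residual interval after their target (a sorted-offset
construction that keeps the 200 ms events non-overlapping).  A 7 s answer
window follows the closing fixation.  Time is integer milliseconds from
trial start with half-open event intervals `[onset, onset + duration)`.

**Sequence constraints.**  Exactly five targets with differing neighbours;
five distractors spread over the five post-target gaps with 0–2 per gap,
sampled uniformly from the 51 admissible gap profiles (the maximum-entropy
choice given the totals); distractor values uniform over {1..9, blank}
with blank probability 1/10 (configurable).  Target patterns that read as
obvious are rejection-sampled away: arithmetic progressions of any
constant step, strict two-digit alternations, constant-step ramps after
the first digit (e.g. 1-2-4-6-8), plus an optional user blacklist.  The
excluded families are a judgment call — the task's originators excluded
"recognizable" patterns by hand — so the predicate is deliberately
configurable.

**Schedule constraints.**  Each of the 30 sequences appears once per
condition (120 slots); adjacent slots differ in condition; at least two
other sequences intervene before a sequence repeats.  A randomized greedy
pass with restarts satisfies all three; the restart cap (2000) has never
been approached in testing.  Breaks every 15 trials are metadata, not
timing events.

## Outcome scores

* **PerDigit ∈ [0, 1]**: with equal lengths, the fraction of positions
  where answer and targets agree.  Otherwise exactly `|L| − |S|` dummy
  digits are inserted into the shorter sequence to maximize positional
  matches, which reduces to maximizing matches over order-preserving
  embeddings of the shorter into the longer sequence; solved by dynamic
  programming over (digits consumed, positions consumed) and verified in
  the tests against brute-force enumeration of all dummy placements.
* **Levenshtein ≥ 0**: unit-cost edit distance, verified against a naive
  exponential recursion and against `edlib`.
* **Distraction ∈ [−1, 1]**: all `n − 2` consecutive answer triples are
  tested as *contiguous substrings* of (a) the target sequence and (b) the
  presented stream with blanks removed; the first two answer digits are
  tested as a *prefix* of each reference and the last two as a *suffix*.
  Score = (stream count − target count) / n.  The prefix/suffix reading of
  the edge cases (rather than substring tests) is what reproduces both
  published worked examples exactly; with substring edge tests the first
  example's stream count would be 2, not 1.  The group count is
  `(n − 2) + 2 = n`, which bounds the score to [−1, 1].  For `n = 2` the
  prefix and suffix pairs coincide and are both counted; a single-digit
  answer scores 0 (no groups are defined, and 0 is the neutral value).
  Answers longer than the stream are allowed; the denominator stays `n`.

Transcripts are normalized by keeping digits 1–9 in order; a '0' cannot be
a stimulus and is dropped with a warning.

## Dominance pre-test

Cleaning drops the 12 practice trials, incorrect responses and RTs above
1500 ms, and is idempotent.  Per-participant mean RTs in the Au / Vi / AV
modalities feed a k-means (k = 2, Lloyd, best of 20 restarts) on the raw
millisecond means — the three coordinates share units, so no
standardization is applied.  The cluster whose centroid has the smaller
`mean_vi − mean_au` contrast is labelled VIS (relatively faster visual
responses), the other AUD.  This contrast rule is one concrete encoding of
"shortest RT decides"; it is translation-invariant and symmetric in the
two modalities.

## Ordinal models

The proportional-odds model: `P(Y ≤ k | x) = σ(θ_k − x′β)` with logit link
only (effects are reported as odds ratios).  Thresholds are kept strictly
increasing by optimizing `θ_1` freely and the increments on the log scale.
The fixed-effect likelihood is maximized by L-BFGS with analytic gradients
followed by Newton polishing; convergence requires gradient max-norm
< 1e-6.  Wald covariance comes from a central-difference Hessian at the
optimum (the β block is invariant to the threshold parameterization).

**Mixed models.**  Participant random effects `b_j ~ N(0, Σ)` enter the
linear predictor; Σ is 1×1 (intercept) or an unstructured 2×2 (correlated
intercept + trial-order slope), parameterized by its log-Cholesky factor.
The marginal likelihood integrates `b_j` out per participant via a Laplace
approximation: a damped Newton solve for each participant's mode in
standardized space (vectorized across participants; tolerance 1e-10 with a
roundoff-scaled stall guard) plus the log-determinant correction.
Adaptive Gauss–Hermite quadrature (15 nodes by default, centered and
scaled at the Laplace mode) is available for random-intercept models and
agrees with Laplace to well under 0.5 loglik units at study scale.  The
outer optimization is L-BFGS-B with numerical gradients; modes are warm
started between evaluations.  A variance pinned at the zero boundary is
reported (`boundary` flag), not raised.  AIC = −2·loglik + 2·(number of
free parameters, random-effect parameters included).

Likelihood-ratio comparisons use the naive χ² with df equal to the
parameter-count difference, including for comparisons that add a variance
component — matching common ANOVA-style model-ladder practice; users who
want the conservative boundary mixture can halve the p-value for the
single-variance case.

**Response binning.**  By default every distinct observed score value is
its own ordered category.  Fixed-width alternatives mirror the natural
resolution of each score: PerDigit to the nearest 1/5 (six categories,
exact for five-digit answers, a coarsening only for other lengths) and
Distraction into ten 0.2-wide bins; Levenshtein is already integer.

**Selection ladder.**  X0 fits `~ 1 + (1|Participant) + Order`; X1 adds
Sequence (unordered categorical, first level as reference) and Condition;
X2 forward-selects person-level main effects by LR test at α = 0.05
(sequential, in the order given); X3 does the same for
Condition:covariate (and optionally Sequence:covariate) interactions; X4
switches to a correlated random Order slope, forward-selects
Order:covariate terms, and tries Order² and Order:Condition, keeping them
only if they improve; X5 removes terms backward while the smaller model is
not significantly worse.  Every comparison p-value is recorded.  The
retention criterion (LR at α = 0.05) is one defensible reading of
"removing variables that make no significant improvement"; Wald-based
retention would differ only in edge cases.  Ordinal questionnaire
covariates (six-point scales) enter as numeric per-unit effects,
consistent with odds-ratio-per-unit reporting.

## Nonparametric pipeline

Kruskal–Wallis (tie-corrected, χ²₃ reference) across the four conditions
at trial level; paired Wilcoxon signed-rank post-hoc tests with pairing on
(participant, sequence) — every sequence is seen in every condition —
dropping zero differences, exact null for ≤ 25 non-zero pairs and the
tie-corrected normal approximation otherwise.  No multiplicity correction
by default (raw p-values are reported); Holm adjustment is a flag.
Subgroup contrasts dichotomize perceived-support scales at the scale
midpoint ("disturbing" below vs "supporting" above) and perceived task
difficulty at the upper third ("easy/medium" vs "hard"); between-subgroup
comparisons within a condition use the unpaired rank-sum test.  The
noise-sensitivity covariate is a 2-means clustering of the five 0–10
questionnaire items, the higher-mean cluster labelled "sensitive".

## Synthetic studies

The generator's defaults are the study conditions: 41 participants × 120
trials (30 sequences × 4 conditions), a 108-trial pre-test per
participant, identical sequences across participants in independently
pseudo-randomized orders.

Per-participant latent traits (logit scale): encoding baseline
`N(0.6, 0.7²)` — the 0.7 SD is the random intercept; audio gain
`N(0.3, 0.15²)` — the 0.3 mean is the planted audio log-odds effect;
rhythm gain `N(0.0, 0.10²)` — a null mean effect with mild heterogeneity;
learning slope `N(0.3, 0.15²)` per scaled-order unit (order mapped to
[−1, 1], so ±0.3 logits over the session, negative draws = fatigue);
intrusion logit `logit(0.12) + N(0, 0.3²)`.  Each target is encoded
independently with probability
`σ(base + audio·1[audio] + rhythm·1[rhythm] + slope·order̃)`; each
non-blank distractor intrudes with probability
`σ(intrusion − audio·1[audio])` — audio support helps reject distractors,
the mechanism the Distraction score measures; retained items are emitted
in presentation order, with a 2% digit-substitution rate.  There is no
serial-position or transposition error model: the three scores do not
require one, and adding one would only rescale the planted effects.

Questionnaire covariates are deterministic-plus-noise functions of the
traits (task/memory difficulty fall with encoding ability, perceived
sound/rhythm support rise with the respective gains, tiredness falls with
the learning slope), so subgroup and interaction stages have true signal.
Pre-test RTs are `shift + lognormal`: 150 ms shift, unimodal scales
350/450 ms (dominant modality faster), AV scale 40 ms below the faster
unimodal one (multisensory facilitation), log-SD 0.25, 3% errors and 2%
slow lapses to exercise the cleaning rules.  Marginals: age truncated
normal 23.7 ± 2.7 in [18, 30]; sex balanced; music education ≈ 28/41;
dominance split in half.

What the simulator does *not* emulate — serial-position curves,
RT-accuracy tradeoffs, response-order errors, drifting attention within a
trial — bounds what passing tests show: they validate the analysis
machinery against data satisfying the model's own assumptions, not against
human behavior.

## Problem sizes used in tests

Property tests of the ordinal engine use reduced but structurally
faithful designs (e.g. 12 participants × 32 trials for ladder and
quadrature checks; 40 groups × 60 observations for variance recovery).
The parameter-recovery acceptance check runs 50 seeded studies at the
full 41 × 120 scale with the default planted effects and requires: audio
effect detected (Wald p < 0.05) in ≥ 80% of replicates, rhythm rejections
consistent with the nominal 5% level (exact binomial test), and the same
qualitative pattern from the paired Wilcoxon contrasts (audio contrasts
significant, rhythm contrasts at chance).

## Known limitations

* The CLMM outer optimization uses numerical gradients; fits with many
  Sequence contrasts are accordingly slower than dedicated mixed-model
  software, and very small variance components terminate at the boundary
  rather than testing it.
* Laplace approximation can bias variance estimates downward with few
  observations per participant; the AGQ option mitigates this for
  intercept-only models.
* The pattern-exclusion predicate encodes three recognizable families
  plus a blacklist; "recognizability" has no closed definition.
* `Distraction` for answers of length 1 is defined as 0 by convention;
  length-2 answers count the coinciding prefix/suffix pair twice, which
  matches the group-count identity but is a convention, not a derivation.
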