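# avspan

Simulation and analysis tools for an **audiovisual digit-span experiment**:
a working-memory task in which five black target digits must be recalled
from a stream that interleaves them with five just-noticeably-gray
distractor digits (blanks allowed), under four support conditions —

| code | audio support | rhythmic |
|---|---|---|
| `C_1-NoSupp` | – | – |
| `C_2-VisRhythmSupp` | – | ✓ |
| `C_3-AudSupp` | ✓ | – |
| `C_4-AVRhythmSupp` | ✓ | ✓ |

The scientific question is whether a tone co-presented with each target
(audio support), and whether presenting targets on a strict 0.8 Hz beat
(rhythmic support), improve recall.  The package provides everything needed
to build, simulate and analyze such a study end to end without human data:

* **experiment design** — constrained generation of the 30 digit sequences,
  the pseudo-randomized 120-trial session (every sequence × condition pair
  once, adjacent conditions differ, ≥ 2 other sequences before a repeat),
  per-trial stimulus timelines (200 ms digits, 1.25 s target windows, five
  induction stimuli before rhythmic sequences, 7 s answer window), and the
  108-trial audiovisual-dominance pre-test schedule;
* **scoring** — the three recall scores.  *PerDigit* is the fraction of
  positionally correct digits after inserting `|len difference|` dummy
  digits into the shorter of answer/targets wherever they maximize the
  match.  *Levenshtein* is unit-cost edit distance.  *Distraction* tests
  every answer triple as a substring (plus the first pair as a prefix and
  the last pair as a suffix) against the targets alone and against the full
  presented stream, returning `(stream matches − target matches) / n` in
  [−1, 1] — negative means target-driven recall;
* **dominance pre-test** — RT cleaning (drop practice, errors, > 1500 ms),
  per-modality mean RTs, and 2-means clustering into auditory- vs
  visually-dominant participants;
* **nonparametric pipeline** — Kruskal–Wallis omnibus across conditions,
  paired Wilcoxon post-hoc tests (paired on participant × sequence), and
  questionnaire-based subgroup contrasts;
* **ordinal models** — a cumulative-link (proportional-odds) engine,
  `P(Y ≤ k | x) = logistic(θ_k − x′β)`, with participant random intercepts
  and random trial-order slopes fitted by a Laplace-approximated marginal
  likelihood (adaptive Gauss–Hermite optional), likelihood-ratio and AIC
  comparison, odds-ratio calculus (`OR^k` for k-unit covariate changes),
  and the staged X0→X5 model-selection ladder;
* **synthetic data** — a generator for complete studies (default 41
  participants × 120 trials) with participant-level random intercepts and
  slopes, a planted positive audio effect, a null rhythm effect, learning
  over the session, distractor intrusions, and questionnaire covariates
  linked to the latent traits.

## Worked example

```python
>>> from avspan import per_digit_score, distraction_score, levenshtein
>>> per_digit_score([1, 9, 4, 3, 6], [1, 9, 4, 6])     # "1946" -> "194*6"
0.8
>>> round(per_digit_score([1, 9, 4, 3, 6], [1, 2, 9, 4, 3, 6]), 2)
0.83
>>> levenshtein([1, 9, 4, 3, 6], [1, 9, 4, 6])
1
>>> distraction_score([1, 9, 4, 3, 6], [1, 2, 9, 2, 3, 4, 3, 6, 2], [1, 9, 4, 3, 6])
-0.8
>>> distraction_score([2, 9, 3, 8, 5], [2, 9, 8, 1, 3, 8, 5, 6], [2, 9, 8, 5, 6])
0.6
```

The first distraction example is strongly negative: all five groups of the
answer ("194", "943", "436", prefix "19", suffix "36") occur in the target
sequence but only one in the presented stream, so recall was driven by the
targets.  The second is positive (0.6): four groups trace the full stream
but only one the targets — the participant partly recalled distractors.

A full pipeline from the shell:

```sh
avspan simulate --seed 1 --out study/
avspan score --bundle study/ --out study/scores.csv
avspan pretest-cluster --pretest study/pretest.csv --out study/dominance.csv
avspan analyze --scores study/scores.csv --out study/results/
avspan ladder --scores study/scores.csv --score per_digit --out study/ladder.csv
avspan report --results study/results/
```

On the default simulation the report shows the planted structure: the audio
contrasts (`C_1` vs `C_3`, `C_2` vs `C_4`) come out significant on all
three scores while the rhythm contrasts (`C_1` vs `C_2`, `C_3` vs `C_4`)
do not.

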