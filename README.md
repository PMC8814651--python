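# foodlit

Scoring and personalization toolkit for a 17-item food-literacy screener.
It bundles an instrument of 24 behaviour-change goals (each with a distinct
expert ranking weight from 0.01 to 0.24) linked to 17 items whose answer
options carry two scores: an item overall score (0-6) that is summed and
rescaled to an overall 0-100 food-literacy score, and an item priority score
(0-5) expressing how much the respondent would benefit from focusing on the
linked goal. Adding each goal's priority contribution to its expert weight
yields a tie-free ranking of all 24 goals per respondent; the top 3 is the
personalized guidance view.

The package also ships the validation machinery around such an instrument:

- **content_validity** — item/scale content validity indices from expert
  rating grids (relevance cut-offs 0.78 / 0.9) and the Flesch reading-ease
  formula (with an approximate vowel-group syllable counter for raw text);
- **psychometrics** — Pearson construct validity (good iff 0.4 < r < 0.9),
  Cronbach's alpha, ICC(2,1) absolute-agreement test-retest reliability
  (cut-off 0.7), and independent t-tests;
- **accuracy** — checks whether eat-domain goals assigned to a respondent's
  top 3 match genuinely non-compliant dietary intakes (meat > 100 g/day,
  vegetables < 300 g/day, fruit < 250 g/day, water < 1500 ml/day,
  ultra-processed > 50 g/day; strict inequalities, 0/0 reported as 100% by
  convention);
- **synthetic** — seed-deterministic cohorts whose answers, intakes,
  diet-quality and self-efficacy proxies share a latent trait, plus expert
  panels and retest replicates with known analytic reliability.

## CLI

```bash
# generate a synthetic cohort (responses, intakes, externals, retest wave,
# expert ratings) under out/
foodlit simulate -n 114 --seed 1 --coupling 1.0 --out-dir out/

# overall 0-100 scores
foodlit score out/responses.csv -o out/scores.csv

# full 24-goal ranking + top-3 view
foodlit prioritize out/responses.csv -o out/priorities.csv --top-out out/top3.csv

# validation statistics battery (construct validity, alpha, test-retest, CVI)
foodlit validate out/responses.csv --externals out/externals.csv \
    --retest out/retest_responses.csv --ratings out/expert_ratings.csv \
    -o out/validation.json

# eat-goal assignment accuracy against intake thresholds
foodlit accuracy out/responses.csv --intakes out/intakes.csv -o out/accuracy.json
```

Exit codes: 0 success, 1 computation error, 2 input/validation error.

The bundled instrument lives at `src/foodlit/data/bundled_iflt.yaml`; items
whose option sets are not fully published are marked `reconstructed: true`
and can be overridden by editing a copy of the file and passing it via
`--instrument`.

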