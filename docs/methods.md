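# Methods

## Model and selection procedure

Candidate estimators of whole-liver graft weight are ordinary
least-squares linear models with one or two predictors drawn from six
donor variables: body weight (bw, kg), DuBois BSA and Mosteller BSA
(m²), body height (bh, cm), age (years), and sex (indicator, female = 1).
With all six variables that is 21 candidates (6 univariable, 15
bivariable). Sex coding only matters for the sex-containing candidates and
is symmetric in fit quality.

Accuracy is the root-mean-square error of held-out predictions, in grams,
with divisor n (RMSE is treated as a plain summary of residuals; the n−p
convention is available via `rmse(..., n_params=)` for comparisons).
Complexity is priced by

    C = R · (1 + 0.05 · (N − 1)),

minimized over candidates. For the two-sizes-only candidate set this is a
band rule: the best bivariable candidate displaces the best univariable
one exactly when 1.05 · R₂ < R₁. Note this is *not* identical to
"RMSE at least 5% lower" relative to the univariable value (that would be
R₂ ≤ 0.95 · R₁); the cost function accepts relative reductions down to
1 − 1/1.05 ≈ 4.76%. The cost function is taken as the definition; cost
ties break toward fewer variables, then a fixed variable priority order
(bw, bsa_dubois, bsa_mosteller, bh, age, sex), so selection is fully
deterministic given the CV RMSEs.

Inner CV: repeated k-fold (default 10 folds × 10 repeats), random
unstratified partitions, every record held out exactly once per repeat.
The per-candidate summary is the unweighted mean (and sd) of all
fold-level held-out RMSEs; pooling residuals within repeats before taking
the RMSE is available via `CVConfig(aggregation="pooled")`.

Voting: 100 cycles, each drawing a seeded random subsample of 90% of the
records without replacement (mirroring the size of outer-CV training
sets), running one inner-CV pass plus the parsimony rule, and casting one
vote. The plurality winner is refitted to all records to give the final
formula. Vote ties break by the same fewer-variables/priority rule.

Outer (nested) CV: repeated k-fold (default 10 × 10) around the *entire*
selection. Within each outer training set a single inner-CV pass plus the
parsimony rule selects a candidate (the 100-cycle vote is not nested
inside the outer loop — that would multiply the work by 100 while
estimating the same procedure), the candidate is fitted there, and the
outer test fold is predicted by a model that never saw it. Default
aggregation pools each repeat's held-out residuals into one RMSE and one
R² — with the SStot contribution of each fold computed around that fold's
own mean — and averages across repeats; per-fold averaging is the config
alternative. Both aggregations are exposed because they answer slightly
different questions (typical-fold error vs pooled error) and differ by a
few grams in practice.

Bootstrap: the in-sample R² of a chosen candidate gets a percentile
interval from case resampling (default 2000 replicates, refit per
replicate); degenerate replicates (constant outcome, rank-deficient
design) are skipped and logged. No BCa correction is applied.

## Numerical choices

- Public fits use `numpy.linalg.lstsq`; a candidate is flagged
  rank-deficient (invalid, never silently dropped) when the design's
  singular-value ratio exceeds 1e10 — the guard that handles the
  near-collinear DuBois+Mosteller pair and constant predictors
  deterministically.
- The CV hot path solves per-candidate normal equations with
  cross-product downdating (training Gram matrix = full Gram − fold Gram)
  and batched 2×2/3×3 solves; validity is assessed once per training set
  by SVD. A singular fold-level system falls back to per-candidate solves
  and yields NaN for that fold. This path is cross-checked against
  statsmodels OLS in the tests.
- Fold partitions use `rng.permutation` + `array_split`; folds are then
  iterated in a canonical order (sorted by smallest member) so the unique
  leave-one-out partition gives bit-identical results for any seed.
- All randomness flows from `numpy.random.SeedSequence` spawns of the
  user seed; identical seeds reproduce votes, winners and metrics
  bit-exactly.
- Cohort files are written with 17 significant digits and parsed with
  round-trip float precision, so write/read cycles are bit-exact.

## Synthetic cohort generator

The generator emulates an adult deceased-donor WL cohort: sex ~
Bernoulli(0.434 female); height ~ Normal(159 | 170 cm by sex, sd 6);
weight conditional on height (0.75 kg/cm slope, −63 kg intercept, 9 kg
residual sd, truncated > 35 kg) — the conditional link is what makes BW
and the BSAs strongly collinear (r ≈ 0.9), so BSA candidates genuinely
compete with BW during selection; age ~ Normal(46, 13) truncated to
[18, 80]; graft weight = 439.2 + 14.8·bw (+ optional extra terms) +
Normal(0, 200 g), truncated > 400 g. Defaults reproduce target medians
(~60 kg, ~165 cm, ~1300 g, ~46 y, BSA ~1.67 m²) within 5% and keep the
median-of-medians inside the reference interquartile ranges.

Scenarios: `bw_truth` (the defaults), `bivariable_truth` (adds a −8
g/year age effect, sized so the true bivariable model's expected RMSE
reduction ≈ 11%, comfortably past the 5% rule at large n), and
`null_truth` (no signal; selection still terminates deterministically via
the tie-breaks).

What the generator does *not* emulate: real registry data have
non-Gaussian, possibly heteroscedastic residuals, measurement conventions
that differ by era and site (autopsy vs back-table vs CT volumetry),
donor-selection effects, and unknown joint BH/BW structure beyond the
marginals. Passing tests therefore demonstrate that the *procedure*
(selection, parsimony pricing, nested validation, benchmarking) behaves
correctly under known truth — not that any particular coefficient pair is
correct for a real population. The delimited/spreadsheet reader with a
configurable column mapping exists precisely so a real extracted cohort
can replace the generator.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `CVConfig.n_folds` / `n_repeats` | 10 / 10 | inner and outer CV geometry |
| `CVConfig.rmse_rule_threshold` | 0.05 | complexity surcharge per extra predictor |
| `CVConfig.aggregation` | per_fold (inner), pooled (outer) | RMSE aggregation |
| `fit(n_cycles, subset_fraction)` | 100, 0.9 | voting cycles and subsample size |
| `GeneratorConfig.truth` | 439.2 + 14.8·bw, σ=200 g | generating model |
| `bootstrap_r2_interval(n_boot, level)` | 2000, 0.95 | percentile bootstrap |

## Published-formula registry

Formulas are evaluated exactly as printed; volume outputs (mL) are taken
as grams one-to-one. Assumptions that the sources leave open are fixed and
overridable: Choukèr's sex term uses female = 1 (lowering female
estimates), Chan's uses male = 1 (raising male estimates); Choukèr is
inapplicable under age 16 (records excluded and counted) and its older-age
branch is extended past 70; Yuan's ordinal age factor is 1 for ≤ 40,
2 for 41–60, 3 for > 60. Registry formulas are never refitted.

## Known limitations

- The two BSA estimators differ by up to ~6% at extreme BMIs, so "BSA" is
  not a single quantity; both are carried as separate candidates.
- The voting subsets are 90% subsamples without replacement; other
  reasonable choices (bootstrap resamples, outer-CV training sets) would
  shift vote shares slightly but not the plurality winner in the regimes
  tested.
- Candidates are capped at two predictors and linear form; published
  allometric formulas are evaluated, never fitted.
- Percentile bootstrap only; no bias correction.
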