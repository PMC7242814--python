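# Methods

This note documents the models and procedures `dediff` implements, the
tunable parameters and their defaults, what the synthetic generator does and
does not emulate, and the numerical and design choices made where the
procedure left room for interpretation.

## 1. Experimental design generator (`dediff.design`)

The generator reproduces a two-cycle associative-encoding experiment.
Defaults (all configurable through `DesignParams`):

| parameter | default | meaning |
|---|---|---|
| `n_cycles` × `blocks_per_cycle` | 2 × 2 | four study and four test scanning sessions |
| `critical_per_block` | 48 | word–image pairs per study session, half face / half scene |
| `null_per_sublist` | 24 | fixation-only trials per sub-list |
| `new_words_per_test_sublist` | 24 | recognition lures per test session |
| `fixation_ms` / `stim_ms` / `iti_ms` | 500 / 2000 / 2000 | trial slot = 4.5 s |
| `max_category_run` / `max_null_run` | 3 / 2 | pseudorandomization caps |
| `rest_duration_s` | 30 | mid-session presentation break |
| `fillers_per_segment` | 2 | non-analyzed trials at each segment start |
| `tr_s` | 2.0 | scan repetition time |

Totals per participant: 192 studied pairs (96 per category), 96 new words
(so 288 critical nouns), 96 face and 96 scene images, and 96 null trials per
phase.  Each test sub-list probes exactly the words studied in its paired
study sub-list.

Trial orders are drawn by rejection sampling (retry budget 1,000, failure
names the offending list).  Run-length constraints are enforced on the
*presented* sequence: fillers count by their image category, and runs reset
at presentation breaks (session starts and the 30-s rest), where the filler
block's categories are chosen never to extend the run of the first upcoming
critical trial.  Filler totals per segment are only loosely determined by
the source design, so they are configurable and always excluded from
analysis; they exist so that segment-initial trials have the same local
history as in the real experiment.

## 2. Behavioral generator (`dediff.simulate.BehaviorParams`)

The response model mirrors the task: every test word receives an Old/New
judgment (hit probability `p_hit[category]` for studied words, false-alarm
probability `p_fa` for lures); words endorsed Old receive a source judgment
(correct with `p_source_correct[category]`, don't-know with `p_dk`,
otherwise the wrong source); every study trial receives a 1–3 vividness
rating and an RT.  Group defaults are the published per-cell proportions:
young hits .82/.81 (face/scene), FA .13, source correct .83/.79, don't-know
.14; older hits .70/.66, FA .13, source correct .75/.68, don't-know .13.

Vividness is drawn from a triplet conditioned on the trial's subsequent
source-memory outcome; the default triplets reproduce the observed ordering
(≈2.4 for later source-correct trials, ≈2.15 otherwise, slightly lower in
the older group).  RTs follow a log-normal law parameterized by its median
(young 2350 ms, older 2250 ms) and log-SD 0.35 — right-skewed and
median-friendly, since study RT is summarized by medians.  With probability
`p_invalid` (default 0.02) a response is made invalid, half the time by an
out-of-window RT and half by a double press, exercising the validity
filters.

Subsequent-memory status is binary — `source_correct` versus everything
else (source incorrect, don't-know, item miss, invalid response) — matching
the binning used for all memory-conditioned neural analyses.

## 3. Neural generator (`dediff.simulate.NeuralGenParams`)

For one participant and ROI, the voxel pattern of trial *t* with category
*c* is

```
beta_t = amp[c] · 1 + kappa[c] · T_c + ε_t,   ε_t ~ N(0, σ² I)
```

with `T_c` a unit-norm category template drawn fresh per participant.
`amp` carries the univariate (mean-amplitude) component, `kappa` the
multivariate (pattern-reliability) component; the two are separately
controllable, which is what lets the univariate DI and the similarity index
dissociate.  Useful closed forms: with `kappa = 0` the population DI over
ROI-mean responses is `(amp_pref − amp_nonpref) / (σ/√V)` for V voxels, and
the expected within-category trial correlation is
`kappa² / (kappa² + V σ²)` (helper `pipeline.kappa_for_reliability` inverts
this).

Stated-world defaults (σ = 5 β-units; voxel counts are the published
bilateral ROI sizes):

| ROI | preferred | V | amp pref/nonpref (young) | amp (older) | within-r pref (young → older) |
|---|---|---|---|---|---|
| PPA | scene | 468 | 1.40 / 1.00 | 1.31 / 1.09 | .15 → .07 |
| RSC | scene | 379 | 1.40 / 1.00 | 1.31 / 1.09 | .12 → .06 |
| FFA | face | 44 | 1.90 / 1.00 | same | .12 (both) |
| OFA | face | 122 | 1.55 / 1.00 | same | .12 (both) |

Non-preferred within-r is .03 everywhere.  These values were chosen once to
place young-adult DIs in the 1–2 range the source figures display and to
realize older-group dedifferentiation in scene ROIs as the combination of
preferred-amplitude attenuation, non-preferred broadening, and reduced
preferred-pattern reliability, with face ROIs identical across groups (the
null result).  They were not adjusted after observing test outcomes.

`simulate_bold` reuses the analysis forward model as the generator: each
session's series is the convolved-boxcar design matrix times the true
single-trial amplitudes plus white noise, with scan counts covering the last
event plus the 32-s HRF kernel.  Ground truth is returned for recovery
tests.

**What the generator does not emulate.**  No physiological noise, scanner
drift, spatial autocorrelation, or hemodynamic variability; no
between-subject variance in `amp`/`kappa`/`σ` (subjects differ only through
their templates and noise).  Consequently between-subject spread is much
smaller than in real data — group comparisons on the similarity index in
particular are unrealistically well-powered — and a green pipeline test
establishes correctness of the estimators and inference machinery, not
realistic effect sizes.  Neuropsychological scores are drawn independently
per test from group norms, so factor scores exercise the projection
numerically but not the battery's true correlation structure.

## 4. Single-trial GLM (`dediff.glm`)

Least-squares-all: every modeled trial gets its own regressor — a 2-s boxcar
at the trial onset convolved with the canonical double-gamma HRF (response
gamma delay 6 s, undershoot delay 16 s, unit dispersions, undershoot ratio
1/6, 32-s support, peak-normalized; the convention of the standard SPM-style
toolchain) — built on a 16× oversampled grid and sampled at scan times.
Sessions are concatenated; trial columns are identically zero outside their
session.  Nuisance regressors: six motion parameters, one mean column per
session, and optionally a rest-block boxcar.  Estimation is one ordinary
least-squares solve (no high-pass filter or autocorrelation model — neither
is part of the specified procedure; both are extension points), guarded by a
condition-number check (default 1e8) that fails with advice rather than
returning unstable estimates.

Motion-based trial exclusion flags a trial when any scan from its onset to
onset + duration + HRF-peak lag (default 5 s, configurable — the exact
window is not specified by the source procedure, so a conservative one is
used) strictly exceeds 1 mm translation or 1° rotation on any axis; exactly
threshold-valued displacements do not flag.

ROI definition thresholds a second-level per-voxel t map (paired t on
face−scene difference scores pooled over groups, the desk-scale reduction of
the specified 2 × 2 factorial second level) at one-sided uncorrected
p < .01 in the requested direction and intersects the surviving voxels with
an anatomical mask; an empty result raises `EmptyROIError`.

## 5. Behavioral scoring (`dediff.behavior`)

Validity: exactly one response inside 450–4500 ms (study) or 500–4500 ms
(test), endpoints inclusive ("between X and Y ms" is read inclusively;
configurable).  Item pR = hit rate − FA rate per category (lures carry no
category, so both categories share the participant's FA rate).  pSR uses
the single high-threshold correction, is computed per participant collapsed
across categories (the design makes source judgments span both), and
don't-know responses never count as hits while item misses enter neither
numerator nor denominator.  Participants with pSR < 0.1 are excluded
(strict inequality; 0.10 is retained).  Study summaries report median RT
and mean vividness per participant × category × memory bin over valid trials
only; empty cells are NaN, never zero.

## 6. Selectivity and similarity (`dediff.selectivity`, `dediff.similarity`)

DI is computed from per-trial ROI-mean responses (mean over voxels first);
the axis is not fixed by the published formula, and this reading matches its
"mean response for trials of a preferred class" phrasing.  The pooled
voxel-level alternative is available behind `voxelwise=True`.  SDs use the
n−1 denominator.  Fewer than two trials in either category, or zero pooled
SD, is an error naming the cell.

Similarity uses Pearson correlations (the Fisher transform presupposes
them), unordered pairs counted once, and only cross-session pairs.  The
within-category average pools both categories' same-category pairs by
default (`within_scope="both_categories"`, following the letter of the
procedure, which does not restrict to the preferred category);
`"preferred_only"` is available and reported alongside where relevant.
Degenerate inputs fail loudly: a single represented session
(`NoCrossSessionPairs`), a zero-variance pattern (named trial), or a
|r| = 1 pair (infinite z).

## 7. Inference (`dediff.stats`)

Welch's unequal-variance t with Satterthwaite df is the only two-sample
test; Cohen's d uses the pooled n−1 SD with sign = first sample − second
(group order is stated in every report).  The mixed-design ANOVA supports
balanced split-plot designs with one between factor and one or two within
factors; sums of squares follow the classical decomposition (verified
against base-R `aov` error strata and an independent brute-force oracle).
Nonsphericity correction is Greenhouse–Geisser by default — the epsilon is
computed from the pooled within-group covariance of cell scores under an
orthonormal (Helmert) contrast, the split-plot textbook/SPSS convention;
pingouin's unpooled variant differs slightly, which the cross-check test
tolerates — with Huynh–Feldt as an option.  Epsilon is exactly 1 for
two-level factors.  Effect sizes are partial-η² per error stratum.

Partial correlations residualize both variables on the covariates plus an
intercept and correlate the residuals (df = n − 2 − #covariates).
Regressions that screen an interaction fit
`y ~ x + group + x:group`, drop the interaction when p ≥ .05, and report
the predictor's partial correlation controlling for group from the reduced
model.  No multiple-comparison adjustment is applied by default (pairwise
follow-ups are reported uncorrected in this literature); Holm adjustment is
available to users via `statsmodels` if desired.

Factor scores multiply z-scored test columns (sample mean/SD, n−1) by the
published rotated-component loadings, treated as fixed input weights — the
loadings "applied to scores" reading — rather than Thurstone regression
scores; deriving the loadings themselves is out of scope (they come from a
prior independent dataset).

## 8. Pipeline and reproducibility (`dediff.pipeline`)

`run_synthetic_study` simulates a cohort (default 24 per group), scores
behavior, applies the pSR exclusion, computes DI / mean-beta / similarity
tables for all four ROIs under both memory conditions, runs the ANOVA and
pairwise battery plus the memory partial correlations, validates every
table against its column schema, and writes CSVs plus `manifest.json`
(seed, config hash, versions).  All randomness descends from the master
seed through a fixed SeedSequence spawning order (design, behavior, betas;
then per-ROI × participant children), so any stage is reproducible in
isolation and identical config + seed gives byte-identical outputs.  Plots
are deliberately not part of the contract; the CSVs are.

## 9. Known limitations

- The generative model omits subject-level heterogeneity, so simulated
  group tests overstate attainable power (see §3); calibration tests
  therefore check error rates under the null, not realistic power curves.
- The LSA stage assumes white noise and no temporal filtering.
- Item-level (trial-unique) similarity is intentionally unsupported.
- The mixed ANOVA requires balanced designs and fails otherwise by design;
  unbalanced cohorts (after exclusions) must be handled upstream.
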