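# Methods

## Scope and design

`lcsmed` implements the analysis chain of a two-arm randomized trial of a
text-message CBT program for young-adult depression: instrument scoring,
randomization, latent change score (LCS) efficacy modeling, LCS mediation
with bias-corrected bootstrap inference, and clinical-significance
indices.  Because participant-level data for such trials are typically
not deposited, the package pairs the analysis code with a synthetic trial
generator whose ground truth is known exactly; every estimator is
validated against that truth and against independent arithmetic oracles.

## Instruments

Five sum-score questionnaires are built in (depression inventory `bdi`,
21 items 0–3; depression screen `phq9`, 9 items 0–3 with the eligibility
bar at a total of 10; behavioral activation `bads`, 9 items 0–6;
perseverative thinking `ptq`, 15 items 0–4; cognitive distortions `cds`,
10 items).  Severity bands are closed integer intervals that partition
the total range; boundary membership follows the printed cut-offs exactly
(a depression total of 13 is none-to-minimal, 28 is moderate).

Two deliberately configurable points:

- **`cds` item range.** The instrument's published description ("scored
  0 = never to 7 = all the time" on a "7-point scale") is internally
  inconsistent — 0–7 is eight response options.  The default keeps the
  printed 0–7 range; `InstrumentSpec` accepts any range for sensitivity
  runs.
- **Missing items.** A scale score is missing whenever any item is
  missing (no proration), with an explicit `mean_impute` flag as the
  sensitivity option.  The conservative default avoids inventing a
  proration rule the protocol does not state.

Cronbach's alpha uses the classical formula k/(k−1)·(1 − Σs²ᵢ/s²_total)
on complete-case rows with n−1 variances, matching the covariance
requirements of the formula.

## Synthetic trial generator

The generator emulates the trial design: n = 103 (default), 84.5 %
female, stratified permuted-block randomization by sex with block size
10, four waves, three mediating mechanisms, wave-specific attrition, and
a 474-message / 64-day / every-other-day engagement stream.

Structure of one simulated participant:

1. **Baselines** are drawn normal per scale, clipped to instrument
   bounds, and rounded to integers; the depression baseline is floored at
   20 (the moderate band) to reflect the screened-in sample, and the
   screen score at 10.
2. **Total 0→3-month changes** follow the structural model
   Δmᵢ = driftᵢ + aᵢ·T + εᵢ and Δy = drift_y + Σᵢ bᵢ·Δmᵢ + c′·T + ε_y
   with T the 0/1 arm indicator.  The waitlist drifts are nonzero:
   control participants improve somewhat too.
3. **Apportionment**: each total change is spread over the three monthly
   intervals by wave-profile weights (default 0.55/0.20/0.25 — most
   change in month 1, mirroring the qualitative pattern of this class of
   trials), plus a small sum-preserving measurement wobble (SD 1.5) at
   the interior waves only, so interval-level equations are not
   numerically degenerate while 0→3 totals — and hence the mediation
   ground truth — stay exact.  Scores are clipped and rounded per wave.

**Default parameters.** None of the generative quantities (baseline
means/SDs, residual spreads, drifts) are published for the trial; the
defaults were fixed once at design time: structural paths a = (7, −14,
−10), b = (−0.25, 0.08, 0.22), c′ = −3.5 mirror the sign pattern and
rough magnitude of the trial's fitted simultaneous model, and baseline
means/SDs (bdi 34 ± 7, bads 20 ± 7, cds 44 ± 9, ptq 42 ± 8) with residual
SDs (8, 6, 9, 8) were chosen so that instrument-bound truncation is a
≲ 2 % tail event.  That last constraint matters: a bounded sum score that
frequently hits its floor censors the change distribution and biases
every downstream path estimate, so a generator intended to validate
unbiased recovery must make censoring rare.  Consequently the generator
emulates a trial in which floor effects are negligible; real data with
many participants at the scale floor would violate the linear-change
model here as anywhere.

Attrition is missing-completely-at-random per follow-up wave (default
retention 0.96 per wave, matching the high completion of the emulated
protocol) with an optional monotone-dropout mode.  Informative
missingness is deliberately out of scope.

**Randomization.** Per-stratum permuted blocks: each block is an
independent uniform permutation of block_size/2 copies of each arm.
Guarantees checked by tests: every complete block splits exactly evenly,
and total imbalance can never exceed (number of strata)·block_size/2.

**Engagement.** The 8 weekly message totals (62, 72, 62, 57, 55, 53, 59,
54; sum 474) are placed on every-other-day treatment days (32 days over
64), splitting each week's count across its 4 treatment days by largest
remainder, and the 198 response prompts are apportioned proportionally to
daily message counts.  Per-day responses are binomial in the prompts with
a per-participant propensity (default Beta(1.2, 0.25), mean ≈ 0.83,
matching the emulated protocol's mean response fraction with realistic
dispersion).  The completer rule is total responses ≥ 192; the protocol's
own "≥ 95 %" gloss and its explicit count disagree by a few responses, so
the threshold is an explicit parameter defaulting to the explicit count.

**Seeds.** Every stochastic operation takes a seed; a trial-level seed
derives operation-level streams by fixed offsets, so fixtures are
bit-reproducible.

## The change-score engine

With all loadings and autoregressions fixed at 1 and one indicator per
construct, the latent change equals the observed difference; the engine
therefore solves the regression system directly (SVD least squares with a
condition-number gate at 1e12) rather than running a general SEM
optimizer.  This is exact, transparent, and testable: on every random
complete-data fixture the estimates agree with an explicit
normal-equations solution to below 1e−8.

Conventions:

- **SEs**: residual variance divided by n ("ml", the convention of SEM
  software, default) or by n − p ("ols"); the report labels which is in
  use.
- **Inference**: z = estimate/SE with two-sided standard-normal p-values
  and Wald CIs — matching z-value reporting, not t.
- **Centering**: treatment is centered on its observed mean (e.g. 0.51 /
  −0.49 for a 50 : 53 split) and all outcome levels on the pretreatment
  mean, so intercepts read as the mean change from the previous month for
  an average-baseline participant averaged across arms.  Slopes are
  centering-invariant; tests assert it.
- **Missing data**: listwise deletion per equation (default), a strict
  `complete` policy, or full-information maximum likelihood.  FIML treats
  (response, predictors) as jointly multivariate normal, estimates mean
  and covariance by EM over missing-data patterns, maps the MLE to
  regression coefficients via the conditional-normal identities, and
  takes SEs from a finite-difference observed-information Hessian in a
  Cholesky parametrization.  Per-equation n is always reported.

## Mediation

Single-mediator model (windows 0→3 for both changes): the a-equation
regresses the mediator change on centered treatment plus baseline
mediator and baseline outcome; the outcome equation adds the mediator
change (b) and treatment (c′) over the same baselines.  The simultaneous
model uses one a-equation per mediator and a single outcome equation with
all mediator changes (default windows 0→2 for mediators, 0→3 for the
outcome); each a-equation conditions on that mediator's own baseline plus
the outcome baseline, and the outcome equation on all baselines.
Identities hold exactly by construction: combined indirect = Σ aᵢbᵢ and
total = combined + c′.

**Bias-corrected bootstrap.**  Whole participants are resampled
(preserving within-person correlation; stratified-by-arm resampling is an
option, off by default since the emulated analysis does not state it).
The bias constant z0 is the normal quantile of the fraction of draws
below the point estimate, with ties counting half (mid-p) and the
fraction clamped to [1/(B+1), B/(B+1)] to keep z0 finite; interval
endpoints sit at bootstrap quantiles Φ(2z0 + z_{α/2}) and
Φ(2z0 + z_{1−α/2}).  No acceleration constant is applied — the method is
BC, not BCa, matching the stated analysis.  Failed refits are dropped and
counted.  The estimators carry a vectorized resampling path (batched
normal-equation solves in chunks of 2000 draws) so a 10,000-draw run
takes well under a second at n = 103.

## Clinical significance

- **High-end-state functioning**: fraction of non-missing endpoint
  depression scores in 0–13.
- **RCI**: individual (post − pre)/S_diff values *and* a group
  mean-change RCI are reported, both labeled — published single-number
  RCIs of this design are ambiguous between the two, so the package
  computes both without asserting which a given report used.  The
  reliability input defaults to the baseline item-level Cronbach alpha
  when item data exist, else a supplied constant (0.83 by default in the
  pipeline, the baseline internal consistency of the emulated trial's
  depression instrument).
- **Cohen's d**: between-group d on 0→3-month change scores with pooled
  (n−1-weighted) SD.  A baseline-SD denominator variant is a one-line
  substitution via `sd_pre`; the change-score pooled form is the labeled
  default since the emulated report does not print its formula.

## Validation studies (tests + acceptance script)

- **Arithmetic reproduction**: the published path estimates of the
  emulated trial, stored as inputs in `lcsmed.reference`, reproduce its
  printed indirect/total/percent-mediated values (56.8/41.4/49.7 %
  single-mediator, 63 % combined, 22/12/30 % independent).  Where a
  printed indirect differs in the last digit from the product of rounded
  paths, the printed indirect is used — it carries more precision.
- **Equivalence**: change-model estimates equal explicit normal-equations
  least squares on difference scores (< 1e−8) on random fixtures.
- **Recovery**: 100 simulated trials at n = 103 recover every a/b/c′ path
  within 3 Monte-Carlo SEs of truth.
- **Coverage**: 500 trials × 999 draws give BC interval coverage of the
  true indirect effect within 3 binomial SEs of 95 % (empirically ≈ 94 %,
  the mild undercoverage typical of BC intervals for products of
  coefficients at this sample size).
- **Randomization**: block and imbalance guarantees over 1000 random
  inputs.

Problem sizes (100 recovery trials, 500 coverage trials, 999 draws, 20
equivalence fixtures) are the package's standard validation suite and run
in tens of seconds on one CPU.

## Known limitations

- The generator's between-wave apportionment is a fixed profile plus
  bounded wobble, not a free growth process; it validates the estimators
  but does not emulate individually varying change shapes.
- MCAR attrition only; no mechanism links dropout to symptom level.
- FIML standard errors come from a numerical observed-information
  Hessian; for heavily patterned missingness with many predictors they
  are slower and less polished than the listwise path.
- Passing tests demonstrate correctness of the estimators under the
  generator's assumptions (linear change, rare floor effects, MCAR); they
  are not evidence about any particular real dataset.
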