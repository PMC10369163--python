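# lcsmed

Latent change score (LCS) modeling, longitudinal mediation with
bias-corrected bootstrap inference, and clinical-significance analysis for
two-arm randomized trials whose outcomes are bounded psychometric sum
scores — together with a synthetic trial generator whose ground truth makes
every stage of the pipeline testable.

## Who this is for

Trials of psychological treatments commonly measure depression and its
hypothesized mechanisms (behavioral activation, cognitive distortions,
perseverative thinking) with sum-score questionnaires at a handful of
waves, and ask two questions: *did the treatment reduce symptoms?* and
*through which mechanisms?*  `lcsmed` implements the analytic pipeline for
that design — four assessment waves (baseline, 1, 2, 3 months), stratified
permuted-block randomization, wave-to-wave change modeling, and
mediation — for trial analysts who want the whole chain reproducible from
a seed.

## The model

A latent change score fixes the autoregression between adjacent waves to 1
and attaches a unit-loading latent factor to the later wave; with a single
indicator per construct the latent change equals the observed difference
Δy = y_t − y_{t−1}, so the system is fit exactly by least squares on
difference scores.  The engine fits, with treatment mean-centered and all
outcome levels centered on the pretreatment mean,

    Δy(0→1) = β₀ + β₁·T + β₂·y₀ + ε
    Δy(1→2) = β₀ + β₁·T + β₂·y₁ + β₃·y₀ + ε
    Δy(2→3) = β₀ + β₁·T + β₂·y₂ + β₃·y₀ + ε

plus a baseline-balance equation, reporting estimate, SE (maximum-likelihood
convention by default), z, two-sided normal p, and Wald CI per path.

Mediation uses the standard decomposition: the *a* path (treatment →
mediator change), *b* path (mediator change → outcome change), direct
effect *c′*; indirect = a·b, total = a·b + c′, percent mediated =
100·indirect/total.  Indirect effects are tested with bias-corrected (BC)
bootstrap intervals over whole-participant resamples.  Clinical
significance covers high-end-state functioning (endpoint score 0–13),
Jacobson–Truax reliable change (RCI = (post − pre)/S_diff,
S_diff = √2·sd_pre·√(1−reliability)), severity-band tables and Cohen's *d*
on change scores.

## Worked example

```python
import lcsmed as L

table, truth = L.generate_trial(L.SimulationConfig(seed=7))   # n=103 trial
fit = L.SingleMediatorLCS(mediator="bads", n_boot=2000, seed=7).fit(table)

print(fit.a_["bads"].estimate, fit.b_["bads"].estimate, fit.c_prime_.estimate)
print(fit.indirect_["bads"], fit.bootstrap_["bads"].low, fit.bootstrap_["bads"].high)
```

prints (rounded)

```
a  = 5.46 SE 1.14
b  = -0.29 SE 0.14
c' = -5.39 SE 1.74
indirect = -1.56   95% BC CI (-3.67, -0.17)
total = -6.95      percent mediated = 22.4
```

against a generative truth of a = 7.0, b = −0.25, c′ = −3.5 (indirect
−1.75): at n = 103 a single trial estimates the paths with visible noise,
but the BC interval covers the true indirect effect.  The interval
excluding zero is the mediation test.  Clinical significance on the same
table:

```
high-end state: control 0.06, treatment 0.25
Cohen d: -0.85   group RCI (treatment): -3.84
```

i.e. a quarter of treated participants end in the none-to-minimal band,
the treated–control contrast in 0→3-month change is large, and the
treatment group's mean change exceeds the reliable-change bar (|RCI| >
1.96).

A command-line layer wraps the same calls:

```bash
lcsmed simulate --seed 7 --out trial.csv
lcsmed fit-lcs trial.csv
lcsmed mediate trial.csv --multi --draws 10000
lcsmed clinsig trial.csv
lcsmed reproduce-tables
lcsmed report --seed 7 --out results/
```

## Layout

- `lcsmed.instruments` — questionnaire scoring, severity bands,
  eligibility, Cronbach's alpha, CSV readers/writers.
- `lcsmed.simulate` — stratified block randomization, the structural trial
  generator, attrition, message schedule and engagement streams.
- `lcsmed.lcs` — change scores, centering, the equation fitter and
  `LatentChangeScoreModel`.
- `lcsmed.mediation` — `SingleMediatorLCS`, `MultiMediatorLCS`,
  `indirect_summary`; `lcsmed.bootstrap` for the BC intervals.
- `lcsmed.clinical` — high-end state, RCI, Cohen's d,
  `clinical_significance`.
- `lcsmed.pipeline` / `lcsmed.cli` — the report bundle and shell verbs.
- `docs/methods.md` — modeling assumptions, generator calibration, and
  numerical conventions.

Estimators follow scikit-learn conventions (`fit`, `get_params`, fitted
attributes with trailing underscores) and compose with sklearn tooling.
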