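# nisurv

Design, analysis and simulation of **single-arm time-to-event trials with
joint non-inferiority and superiority hypotheses**.

## The problem

De-escalation and proof-of-concept studies in oncology often cannot
recruit enough patients for a randomized comparison. A single-arm trial
against a historical control can still rank the activity of a regimen if
it pre-specifies *two* ordered hypotheses on the same time-to-event
endpoint (PFS, DFS): a non-inferiority test against the historical control
discounted by a margin, and — only if that succeeds — a superiority test
against the control itself, at the same unadjusted α (a gatekeeping
procedure that controls the overall one-sided type I error). `nisurv` is
for trial statisticians who need to derive the margin, size such a study,
analyse its final data, and verify its operating characteristics by
simulation.

## The model

All calculations use the exponential survival model, under which the
hazard λ, median m and landmark survival S(t) are interchangeable:
λ = ln 2 / m = −ln S(t) / t (months throughout).

* **Non-inferiority margin** (fixed-margin method): given the historical
  active-vs-placebo hazard ratio with confidence bounds (loss direction,
  > 1) and a retention fraction f, NIM = L^(1−f) where L is the CI lower
  bound. The non-inferiority null is the control hazard λ₀·NIM
  (equivalently median m₀/NIM).
* **Sample size**: required events
  d = (z₁₋α + z₁₋β)² / ln(HR)² for planning hazard ratio HR = λ₁/λ₀
  (z₁₋α/2 when two-sided); the probability an enrolled patient yields an
  event under uniform accrual over `ap` months with minimum follow-up
  `fp` is P = 1 − e^(−λ·fp)·(1 − e^(−λ·ap))/(λ·ap); patients =
  ⌈d / P / (1 − dropout)⌉.
* **Final analysis**: exponential MLE λ̂ = d / (total exposure), tested
  one-sided with z = √d·(ln λ_null − ln λ̂), p = 1 − Φ(z), first against
  λ₀·NIM, then (if rejected) against λ₀. A nonparametric path compares
  the Kaplan–Meier median's two-sided CI lower bound against median
  thresholds for the two nulls.
* **Simulation**: patient-level trials (uniform entry, exponential event
  and dropout times, administrative censoring at `ap + fp − entry`) with
  Monte Carlo rejection rates and standard errors.

## Worked example

A metastatic proof-of-concept design: historical median PFS 12 months,
historical HR vs placebo 2.4 (95% CI 1.44–3.56), 50% effect retention,
target median 18 months, one-sided α = 0.10, power 0.90, 12-month
accrual, 24-month minimum follow-up, 10% dropout.

```sh
$ nisurv margin --hr 2.4 --ci 1.44 3.56 --retention 0.5 --control-median 12
NIM = 1.2
non-inferiority null: median 10 mo, hazard 0.0693/mo

$ nisurv design --control-median 12 --alt-median 18 --alpha 0.1 --power 0.9 \
    --accrual 12 --followup 24 --dropout 0.1 --nim 1.2
hazard ratio (alternative/control): 0.667
required events: 39.96 -> 40
event probability: 0.682
patients before dropout: 58.6
patients after dropout inflation: 65.1 -> 66
superiority null: median 12 mo, hazard 0.0578/mo
non-inferiority null: median 10 mo, hazard 0.0693/mo
```

So the study needs 40 events and 66 patients. Suppose at final analysis
the 66 patients yielded 54 events at an observed median of 12 months
(`trial.csv` has columns `patient_id,time,event`):

```sh
$ nisurv analyze trial.csv --control-median 12 --nim 1.2 --alpha 0.1
n=66, events=54, median 12 mo, hazard 0.0578/mo
p(non-inferiority) = 0.09016
p(superiority) = 0.5
conclusion: non_inferior_only
```

The treatment is declared non-inferior (p = 0.090 < 0.10) but not
superior (the gate opens, p = 0.5 ≥ 0.10): exactly the ranked middle
outcome this design exists to distinguish. `nisurv analyze --method km`
runs the nonparametric median-CI rule instead, and `nisurv simulate`
estimates the empirical size and power of the whole decision rule
(a `design --out` JSON report can be fed straight to
`simulate --config`).

The same library API is available in Python
(`nisurv.design_summary`, `nisurv.dual_test`,
`nisurv.operating_characteristics`, …).

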