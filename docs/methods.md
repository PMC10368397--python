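# Methods

## Model and scope

Every parametric calculation assumes exponentially distributed event
times: a constant hazard λ per month, median m = ln 2 / λ, landmark
survival S(t) = e^(−λt). This is the standard planning model for
single-arm time-to-event designs; it buys closed-form sample sizes and a
one-sample test with a simple asymptotic distribution at the cost of a
proportional-hazards-in-the-strong-sense assumption. The nonparametric
Kaplan–Meier path exists precisely for final analyses where the
exponential fit is doubtful or no events were observed.

Time is always months and is carried as a convention, not converted;
hazards are per month.

## Non-inferiority margin

The margin is derived by the fixed-margin method from the historical
active-control-vs-placebo hazard ratio: NIM = L^(1−f), with L the CI
lower bound in the loss direction (> 1) and f the retention fraction
(default 0.5, i.e. retain at least half of the historical effect; common
regulatory practice). Using the CI lower bound rather than the point
estimate is deliberately conservative about the historical evidence.
`HistoricalEffect.from_benefit_ratio` accepts the opposite orientation
(< 1) and inverts point and bounds, swapping the bounds. The historical
HR is taken as given — no meta-analytic synthesis — and the exponential
identity between median ratios and hazard ratios is assumed rather than
reconciled when inputs disagree.

## Sample size

Required events: d = (z₁₋α + z₁₋β)² / ln(HR)², with z₁₋α/2 for a
two-sided α. Event probability under uniform accrual over `ap` and
minimum follow-up `fp` (administrative censoring at `ap + fp − entry`):

    P = 1 − e^(−λ·fp) · (1 − e^(−λ·ap)) / (λ·ap),

evaluated at the alternative hazard λ₁ by default (an option selects λ₀
instead). The `ap → 0` limit is 1 − e^(−λ·fp), implemented with `expm1`
for small λ·ap. Note P is *increasing* in `ap` at fixed `fp`: a longer
accrual gives earlier-enrolled patients more than the minimum follow-up.
Patients: ⌈(d / P) / (1 − dropout)⌉. Events and patients are rounded up
(never down), and the dropout inflation divides patients, not events.
`analytic_power` inverts the events formula,
power = Φ(√d·|ln HR| − z₁₋α), and reproduces the planning power exactly
at the unrounded event count.

## Final analysis

Exponential MLE with right censoring: λ̂ = d / Σtᵢ (events over total
exposure). One-sided test of H₀: λ ≥ λ_null via

    z = √d · (ln λ_null − ln λ̂),    p = 1 − Φ(z),

the asymptotic normal form for the log-hazard with variance 1/d (the
inverse Fisher information given d events). p = 0.5 exactly when
λ̂ = λ_null. Internal computations keep full precision — the worked
p-values only reproduce with exact hazards ln 2 / m, not with
display-rounded ones — and reports round for display only.

The dual decision is a gatekeeping procedure: test the non-inferiority
null λ₀·NIM first; only if p < α, test the superiority null λ₀ at the
same unadjusted α. Since λ₀·NIM ≥ λ₀ implies z_NI ≥ z_sup and hence
p_NI ≤ p_sup for the same data, superiority can never be declared without
non-inferiority, and the hierarchy controls the overall one-sided type I
error without alpha splitting. Conclusions are ranked
superior > non-inferior-only > inconclusive. When no events occurred the
hazard MLE degenerates and the estimator refuses, pointing to the
Kaplan–Meier path.

Effect sizes are reported as signed differences from each null on both
scales (median and hazard). Entry times, when supplied, are used only to
validate that no observation outruns its administrative censoring window.

## Nonparametric path

The Kaplan–Meier median and its two-sided CI (default 90%) come from
lifelines' product-limit estimator with the exponential-Greenwood
(log-minus-log) interval for S(t), inverted at one half in the
Brookmeyer–Crowley manner. Non-inferiority holds when the CI lower bound
exceeds the non-inferiority median threshold m₀/NIM; superiority when it
also exceeds m₀. Ties follow the standard convention (events precede
censorings at equal times). If the lower bound is undefined — the lower
confidence curve never crosses one half within follow-up — the decision
is inconclusive with a diagnostic rather than a guess; this is
conservative for very positive trials with short follow-up.

## Simulator

Each replicate draws entry ~ Uniform(0, ap), event time ~
Exponential(λ_true), dropout time ~ Exponential(λ_drop) (infinite when
the rate is zero; a uniform-over-study alternative is flag-switchable),
and censors administratively at ap + fp − entry. The dropout hazard is
calibrated by root-finding so the expected fraction of patients whose
dropout is observed first equals the design's dropout rate. Replicate r
uses an RNG stream seeded by (seed, r), so results are independent of
execution order and byte-identical across runs. Rejection rates are
reported with Monte Carlo standard errors √(p(1−p)/R); the default is
R = 10,000 replicates. Trials with zero events count as non-rejections
and are tallied separately.

What the generator emulates: the planning model itself (constant hazards,
uniform accrual, administrative censoring, independent dropout). What it
does not: non-uniform or data-dependent accrual, non-exponential event
times, informative dropout, interim looks. Passing simulation checks
therefore validate the internal consistency of the design arithmetic, not
robustness to real-world violations of the exponential model.

## Finite-sample behaviour of the operating characteristics

At the non-inferiority boundary (true hazard λ₀·NIM) the simulated
rejection rate of the d ≈ 40–55-event design is within Monte Carlo noise
of the nominal α = 0.10. Under the alternative, however, the realized
power of the *as-designed* trial exceeds the asymptotic planning value by
two to three percentage points (≈ 0.93 vs 0.90 for the metastatic
design). Three effects compound: ceiling roundings (39.96 → 40 events,
65.1 → 66 patients) add power; the 1/(1 − dropout) patient inflation
over-corrects, because a 10% patient dropout removes only ≈ 7% of
expected events (dropouts contribute partial exposure, and some would
have been administratively censored anyway); and the finite-sample
distribution of the censored log-hazard statistic departs from its
asymptotic normal form (at a fixed d = 40 uncensored events the exact
power is 0.88, while under administrative censoring the simulated power
rises above the asymptotic value). The design is thus conservative in the
direction practitioners want — it delivers at least its nominal power —
and the test suite asserts exactly that, while the equality-to-planning
check is reported at face value.

## Numerical choices and defaults

* Retention fraction default 0.5; margin must not exceed the historical
  CI lower bound.
* Two-sided α uses z₁₋α/2 (the adjuvant landmark example only reproduces
  under this rule).
* KM median CI confidence default 0.90.
* Dropout inflation applies to patients only; events are never inflated.
* Simulation problem sizes in the test suite: 10,000 replicates for
  operating-characteristic checks at the designed n = 66, smaller grids
  (hundreds of replicates) for calibration sweeps — sizes at which the
  Monte Carlo standard errors are small relative to the quantities
  checked.
* Root-finding for dropout calibration: Brent's method on the
  competing-risks identity, xtol 1e-12.

## Known limitations

Historical-control designs inherit the usual biases (population drift,
assay sensitivity); the package computes the pre-specified arithmetic and
cannot adjudicate the quality of the historical anchor. Only exponential
parametric fits are provided (no Weibull/log-normal), no interim or
two-stage machinery, no randomized-comparator sample sizes, and no
covariate adjustment.
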