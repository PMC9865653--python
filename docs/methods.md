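# Methods

`saltckd` is a proportional multistate lifetable (PMSLT) model of the
long-term chronic kidney disease (CKD) impact of population sodium
reduction. Two identical closed cohorts of adults alive in 2019 — one under
business as usual (BAU), one under a sodium-reduction scenario — are
simulated in annual cycles until death or age 100; every reported outcome
is the difference between the arms.

## Model chain

1. **Sodium trajectory.** Each scenario lowers mean daily sodium per
   age-sex stratum linearly: ten equal annual decrements applied at cycle
   starts 2020–2029, then constant. A population-mean sodium target (e.g.
   the 2000 mg/day Suggested Dietary Target, SDT) reduces every stratum by
   the same relative factor so the population-weighted mean lands on the
   target; relative and absolute-salt scenarios apply uniformly per
   stratum. Sodium↔salt conversion uses the NaCl mass fraction
   (22.99/58.44 ≈ 0.3934, so 1 g salt ≈ 393 mg ≈ 390 mg sodium); targets
   stated in sodium are applied in sodium units directly rather than
   through a salt conversion, avoiding compounding of survey roundings
   (the conventional pairing 3700 mg ↔ 9.6 g salt implies a slightly
   different factor).

2. **Blood pressure.** Systolic BP (SBP) in each stratum is normal with
   the survey mean and SD. A sodium reduction Δ (mg/day) shifts the mean
   down by

   (Δ / 1720) × [p·5.39 + (1−p)·2.42] mmHg,

   where p is the mass of the distribution above 140 mmHg. The 5.39
   (95% CI 4.15–6.62) and 2.42 (1.29–3.56) mmHg effects per 4.4 g salt
   (≈1720 mg sodium) reduction are the trial meta-analytic effects in
   hypertensive and normotensive adults. The SD is held fixed: observed
   post-intervention SBP distributions narrow only marginally, and a pure
   location shift keeps the hypertensive-split algebra exact.

3. **Potential impact fraction (PIF).** For each cause d, stratum and
   year, PIF = (E₀[RR(X)] − E₁[RR(X)])/E₀[RR(X)] with expectations over
   baseline and shifted SBP distributions ("distribution shift" method).
   RR(x) is log-linear per 10 mmHg above the theoretical minimum risk
   exposure level (TMREL, 115 mmHg) and clamped to 1 below it — no
   protective extrapolation. The integral is evaluated by adaptive
   quadrature (absolute tolerance 1e-10) on mean ± 10 SD; the constant
   RR = 1 region below TMREL is folded into an analytic normal-CDF term so
   the quadrature only sees the smooth exponential piece. Tests verify
   agreement with a closed-form lognormal-MGF expression to 1e-9 and with
   10⁶-sample Monte Carlo to 1e-3. The PIF scales incidence only;
   mortality responds through prevalence and case fatality.

4. **Disease submodels.** The four CKD causes (hypertensive, diabetic,
   glomerulonephritic, other/unspecified) run as independent illness–death
   Markov submodels with states healthy (S), prevalent (C) and dead from
   the cause (Dc), conditional on surviving other causes, with zero
   remission. Cycles use the exact constant-hazard solution
   S' = S·e⁻ⁱ, C' = C·e⁻ᶠ + iS(e⁻ᶠ − e⁻ⁱ)/(i − f) (limit i·S·e⁻ⁱ when
   |i−f| < 1e-12), so there is no step-size error and S+C+Dc = 1 holds to
   machine precision. Case fatality f is rarely published and is derived
   internally: the default `ode_consistent` method marches the equations
   up the 5-year age bands and solves per band (bisection/Brent to 1e-8)
   for the f that reproduces the observed prevalence at the next band
   entry, falling back to f = mortality/prevalence at the terminal band;
   the `ratio` method uses that quotient everywhere and is the default
   inside the PSA, where thousands of full solves buy no extra insight.
   One free parameter per band can reproduce one constraint; matching
   prevalence was chosen because prevalence drives both morbidity and
   (through f) mortality, and the cause-death fit is checked separately as
   an internal-consistency test (modelled prevalence tracks inputs within
   10% over ages 30–90).

5. **Lifetable.** BAU all-cause mortality is the input rate; the
   intervention rate subtracts the per-cause death-flow differences
   (additive on rates, standard PMSLT practice). Survivorship declines
   exponentially within cycles; person-years use the trapezoid rule.
   Health-adjusted life years (HALYs) weight person-years by
   w = 1 − bYLD + Σ_d dw_d·(C_d,BAU − C_d,arm), where bYLD is the
   all-cause YLD rate (so the BAU weight is 1 − bYLD) and dw_d is the
   per-case disability weight, crude = cause YLD / prevalence, corrected
   multiplicatively for background comorbidity by 1 − (non-CKD YLD). A
   subtractive (uncorrected) switch is provided for comparison. HALY gains
   are decomposed by cause: averted-morbidity terms attribute directly;
   the mortality-driven remainder is allocated proportionally to each
   cause's cumulative death-flow reduction, so components sum exactly.

6. **Costs.** Annual CKD expenditure per stratum and cause divided by
   prevalent cases gives a per-case cost; savings are per-case cost times
   prevented prevalent cases, discounted at 3% (base case; 5% in
   sensitivity) to 2019, with the first discounting applied to 2020.
   Full-year accrual, no mid-year correction, no intervention-delivery
   costs.

7. **Uncertainty.** The PSA perturbs sodium (normal), SBP means (normal),
   the two sodium–BP effects (normal from their CIs), the four relative
   risks (lognormal, σ from the log-CI width so the 2.5/97.5 quantiles
   match) and costs (gamma, mean 1 multiplier with CV 10%). One deviate
   per quantity class scales all strata — fully correlated draws, chosen
   because these inputs come from single national surveys whose error is
   predominantly shared. Draws are a deterministic function of
   (seed, index) and identical across scenarios (common random numbers).
   Intervals are empirical 2.5th/97.5th percentiles; failed draws
   (e.g. a normotensive effect drawn above the hypertensive one) are
   excluded and counted, and more than 1% failures aborts.

## Bookkeeping conventions

- Reporting window "2019–2030" covers the 11 cycles starting 2019–2029,
  so the full ramp plus one year at target; "lifetime" runs to 2094, when
  the youngest 2019 cohort reaches 100.
- Cohorts look up rates, BP and sodium by their *current* age band as they
  age; prevalence among the living is C/(S+C); case counts multiply by the
  lifetable survivorship of the respective arm.
- Incident and death counts use start-of-cycle survivorship. At the hazard
  level a constant PIF of 0.1 cuts incidence by exactly 10%; one-cycle
  case counts follow (1 − e^(−0.9i))/(1 − e^(−i)), marginally above 0.9,
  which the tests assert against the closed form.

## Synthetic inputs

National stratified inputs (GBD-style epidemiology, survey sodium and BP,
health-expenditure totals) are not redistributable, so the generator
fabricates an internally consistent stand-in on the 15 × 2 age-sex grid:

- ~19.3 M adults 25+, flat to age 57 then Gaussian roll-off;
- Gompertz all-cause mortality (doubling ≈ every 8 years; male excess),
  terminal band inflated ×2.2 so survivorship closes by 100;
- per-cause incidence rising log-linearly with age and case fatality
  rising linearly (≈0.003–0.02/yr), with *prevalence generated by forward
  integration of the illness–death equations themselves* — so the
  downstream case-fatality solver can be validated against the truth used
  in construction, and BAU prevalence tracks inputs by design;
- cause YLD = true disability weight (0.08–0.15) × prevalence, background
  YLD well above the CKD share;
- sodium midlife-peaked and ≈40% higher in men (survey-like), rescaled so
  the population-weighted mean is exactly 3700 mg/day;
- baseline SBP means/SDs verbatim from the embedded national-survey
  fixture (10-year bands duplicated onto the 5-year grid; 85+ reused
  above 85);
- expenditure ≈ A$1.9 B/yr from per-case costs of A$540–1150 with a mild
  age gradient.

The `noisy` realism setting jitters the underlying hazards (lognormal,
σ 5–8%) *before* integration, so consistency and monotonicity survive;
monotone gradients are enforced by cumulative maxima afterwards.

What the generator does **not** emulate: survey design effects, secular
sodium trends, CKD staging and dialysis/transplant states, comorbidity
between the four causes, migration and births. Passing tests therefore
demonstrate the correctness and internal coherence of the method, not the
magnitude of any real national estimate: headline outputs have the right
order of magnitude but are not calibrated to any published national total.

## Numerical choices

- Quadrature: absolute tolerance 1e-10, bounds ±10 SD, analytic below
  TMREL (above).
- Case-fatality bisection tolerance 1e-8, bracket [0, 10]/yr; targets
  outside the attainable range clamp to the bracket edge.
- Degenerate hazards (i = f) switch to the analytic limit below |i−f| <
  1e-12; state validation tolerates 1e-9 rounding on entry and conserves
  to 1e-12 per cycle.
- Negative intervention all-cause mortality (impossible under PIF ≥ 0) is
  an error, not a clamp.
- Presentation rounding (cases to 1, % to 0.1) happens only at the
  reporting layer; internals are full precision; bundle CSV round-trips
  use `float_precision="round_trip"`.

## Known limitations

- The additive mortality feedback and the multiplicative background
  disability correction are standard but not unique choices; both are
  isolated behind switches or single functions.
- The `ode_consistent` solver assumes band-constant hazards and the same
  annual discretization as the simulation; it is a stand-in for fuller
  epidemiological calibration tools, not a re-implementation of any of
  them.
- PSA problem sizes in the shipped analysis (200 draws) are chosen for a
  desk-scale workflow; the machinery accepts the conventional 2000.
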