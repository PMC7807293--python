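# Methods

## Model structure and assumptions

`prtcea` is an individual-level (microsimulation) state-transition model of
low-volume metastatic hormone-sensitive prostate cancer with four health
states — stable disease, progression after initial treatment (abiraterone
era), progression after abiraterone (second-line systemic therapy), and
death — on a monthly cycle.  Individual simulation, rather than a cohort
Markov model, is used so that radiation-toxicity events can be followed with
per-patient trackers that permanently modify subsequent utility and add a
one-time cost at onset.

Cycle conventions (shared by every computational path in the package):

* a cycle accrues the cost and utility of the state occupied at its start,
  discounted by `(1 + r)^(-t/12)` with r = 0.03/year;
* toxicity draws occur at the start of each alive cycle in the radiation arm
  and take effect in that same cycle;
* the transition drawn at the end of cycle *t* determines the state of cycle
  *t + 1*; no transition is drawn after the final cycle of the horizon;
* the one-time end-of-life cost is booked at the discount factor of the last
  alive cycle (the cycle whose transition fired);
* no half-cycle correction: with monthly cycles and individual event timing
  the correction is second-order.

The radiation effect enters as a hazard ratio applied on the rate scale,
`p_PRT = 1 − (1 − p_ADT)^HR`, which reproduces the published pair of
progression probabilities (0.035 and 0.020 at HR = 0.59).

Three computational paths implement the same model and are tested against
each other: a scalar per-patient loop (readable reference), a vectorized
cohort simulation (~100× faster; used everywhere), and an exact
Markov-occupancy expectation.  Because toxicity draws are independent of the
disease path, the expectation path folds the trackers in analytically; it is
the smooth objective used for calibration and the oracle for the
microsimulation (checked to 1e-12 against exhaustive 3-cycle enumeration and
within Monte-Carlo error at the full horizon).

## Parameters

All inputs ship in `src/prtcea/data/basecase.yaml` (probabilities per month,
costs in 2020 USD, utilities on [0, 1]).  Each uncertain input carries a
range, read as a central 95% interval and converted to a beta distribution
(probabilities, utilities) or gamma distribution (costs, hazard ratio) by
method of moments with sd = width/(2·1.96); the interval-to-sd divisor can be
overridden per parameter.  Fitted means match the base values to 1e-6.

Choices where the source inputs were ambiguous or incomplete:

* **Stable-state utilities per arm.**  The two stable-state utility rows
  (0.90 and 0.83) are interpreted as arm-specific: 0.90 for ADT alone, 0.83
  persistently for the radiation arm (long-term post-radiation quality of
  life), the default `prt_utility_mode: persistent`.  The alternative
  reading — 0.83 only during the treatment cycle(s) — is available as
  `treatment_only` but overstates the incremental QALY gain roughly
  twofold relative to the published base-case results, so it is not the
  default.
* **Death during the stable state.**  The printed base value (0.0001) lies
  outside its own printed range (0.0008–0.0013); the range midpoint 0.00105
  is used, consistent with background mortality of men around age 68.
* **Death during progression** (0.050/month) applies to both progression
  states and is sampled as a single PSA parameter; per-state overrides
  exist.
* **Progression-1 → progression-2 probability** is not published anywhere.
  It is calibrated so the model's lifetime discounted QALYs match the
  published lifetime values (2.22 and 3.03), giving 0.502/month (an interior
  least-squares optimum; the value is frozen in the fixture with a
  provenance note).  Lifetime *costs* cannot enter this calibration: in this
  model both arms eventually traverse the same progression states, so no
  value of the parameter can produce the published lifetime cost saving —
  see Limitations.
* **Toxicity probability** (0.003 per site) is treated as a per-cycle tracker
  hazard, drawn every alive cycle in the radiation arm until it fires.
* Toxicity and state utilities combine by `min()`, not multiplication,
  because the joint GI+GU value (0.76) is an explicitly elicited weight.
* ADT's monthly drug cost continues in every alive state in both arms;
  progression-state drug costs are additive to it.

## Analyses

* **Base case** — both arms, 37-month horizon (the trial's median follow-up),
  10,000 patients/arm; 95% CIs from trial-level means ± 1.96·SE.  Arms use
  independent random streams by default; a common-random-numbers (CRN) mode
  runs both arms on identical uniform streams, leaving arm means unchanged
  while sharply reducing the variance of the incremental estimates (paired
  per-patient CIs are then available).
* **Lifetime horizon** — the run is extended until all patients die, capped
  at 480 cycles (40 years) with a warning if >0.1% remain alive.
* **One-way sensitivity / thresholds** — each parameter swept over its range
  with a fixed seed per grid point; threshold detection bisects the
  dominance (or incremental-cost-sign) criterion on smoothed evaluations
  (100,000 trials per point, fixed seed, or the exact expectation).  The
  progression hazard ratio is the most influential parameter (widest tornado
  bar); the model stops saving money near HR ≈ 0.81.
* **Scenarios** — `weekly_prt` substitutes the cheap 6-fraction radiation
  cost ($7,243) and a two-cycle treatment period; `upfront_abiraterone` adds
  the abiraterone monthly cost during the stable state in both arms (the
  published analysis does not print the upfront price; the progression-1
  monthly cost is reused); `lifetime` extends the horizon.
* **PSA** — two explicit uncertainty levels: `n_outer` parameter draws ×
  `n_inner` patients/arm per draw (defaults 10,000 × 1,000; the acceptance
  script uses 2,000 × 500 to stay desk-scale).  Parameters are drawn
  independently; utility draws are not constrained by the cross-parameter
  ordering the base case satisfies (transient inversions are sampling noise).
  Scenario rows pin the named parameter and sample the rest.  Summaries use
  percentile (2.5%, 97.5%) intervals across outer draws; the probability of
  cost-effectiveness is the fraction of draws with positive net monetary
  benefit at $100,000/QALY.

## Calibration and synthetic targets

Calibration fits free transition probabilities — optionally
piecewise-constant over user-chosen cycle breakpoints (default: one constant
segment, matching the single published values) — to overall-survival and
failure-free-survival target curves supplied as two-column CSV.  The
objective is an equally weighted SSE over both curve kinds at the target's
monthly time points, evaluated on the exact Markov expectation (smooth and
noise-free); optimization is Nelder–Mead on logit-transformed probabilities,
so fitted values stay in (0, 1).  Fits are validated against the full
microsimulation.

The synthetic-target generator emulates curves digitized from published
Kaplan-Meier figures: exact model curves, optionally perturbed by binomial
sampling noise with a trial-arm-sized denominator (default 410) and restored
to monotonicity by isotonic projection.  It reproduces sampling noise and
digitization-style monotonicity, but not real-world features such as
censoring patterns, delayed treatment effects, or non-Markov dependence of
progression risk on time already survived — parameter-recovery tests
therefore demonstrate the optimizer and model plumbing, not fidelity of the
disease model to any particular trial population.

## Numerical choices

* RNG: `numpy` PCG64 generators seeded through `SeedSequence`; arm streams
  spawned from one master seed; all results bit-reproducible from
  (seed, cohort size).  Cohort draws are generated per cycle across the
  cohort (vectorized) rather than per patient.
* Problem sizes: 10,000 patients/arm for base-case estimates; 100,000 with
  CRN for lifetime incrementals and threshold bisection (tolerance 1e-3 on
  the hazard ratio); PSA 2,000 × 500 in the reproduction script.
* Degenerate inputs: zero-probability models reproduce closed-form geometric
  sums to 1e-9; competing per-cycle probabilities are validated to sum ≤ 1
  per state; `n_trials = 1` runs but yields NaN confidence intervals.
* Ties/edge cases in dominance classification: increments sharing a sign are
  classed by net monetary benefit (for the savings-with-QALY-loss quadrant
  the usual ICER < WTP rule reverses); an exactly zero increment pair is
  "not cost-effective" (no grounds to prefer the intervention).

## Known limitations

* The model cannot reproduce the published *lifetime* cost difference (a
  ~$30k saving): with both arms ultimately traversing the same progression
  states, lifetime costs differ only through the one-time radiation course,
  discounting, and the few extra stable-state deaths in the radiation arm
  (net ≈ +$2k).  37-month absolute costs likewise sit ~$20k above the
  published table at any progression-1→2 rate, although the *incremental*
  results — the decision-relevant quantities — match.  The published PSA
  probabilities of cost-effectiveness at pinned hazard ratios (92% at 0.5,
  79% at 0.75) are mutually inconsistent with the published dominance
  threshold (≈0.79) under any smooth model of the incremental NMB and are
  not reproduced by this implementation (≈100% and ≈70%).
* No background-mortality age dependence, no continuous-time event timing,
  no multi-way (>2 strategy) frontier, no EVPI, and no currency/CPI
  adjustment — inputs are taken as already in 2020 USD.
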