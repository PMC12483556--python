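# Methods

## The model

`gardkit` operationalizes genomically informed radiotherapy dosing for
HPV-positive oropharyngeal cancer. The chain runs:

1. **RSI** — the radiosensitivity index, a rank-based 10-gene expression
   signature interpreted as the tumor's surviving fraction after a single
   2 Gy fraction, RSI ∈ (0, 1].
2. **α_g** — under the linear-quadratic (LQ) cell-survival model
   S = exp(−αD − βD²), RSI back-solves to a patient-specific linear
   coefficient at the reference exposure (n = 1 fraction, d = 2 Gy):

       α_g = −ln(RSI)/(n·d) − β·d = −ln(RSI)/2 − 0.1,

   with β fixed at 0.05 Gy⁻² for every patient. α_g can be negative when
   RSI > e^(−0.2) ≈ 0.819; such values are retained with a warning, never
   clipped, because clipping would silently flatten the resistant tail.
3. **GARD** — for a delivered plan of n_c fractions of d_c Gy,

       GARD = n_c · d_c · (α_g + β·d_c).

   At d_c = 2 Gy this collapses to the exact identity
   GARD = −n_c·ln(RSI), which the test suite enforces to machine
   precision and which anchors everything downstream: de-escalating
   70 → 60 Gy at 2 Gy/fraction rescales GARD by exactly 6/7.
4. **Prescription inversion** — the minimum total dose achieving a target
   GARD at a fixed dose per fraction d is D = target/(α_g + β·d). The
   fraction count is rounded *up* so the achieved GARD never undershoots
   the target, while the reported integer dose is the floor of the
   continuous solution (floor reproduces the published 31 and 113 Gy
   bounds from the cohort's GARD extremes 71.7 and 19.7; nearest-integer
   would report 114 for the upper bound). When α_g + β·d ≤ 0 (RSI = 1
   boundary) the target is unreachable and reported per patient rather
   than raised as a fatal error in cohort-level runs.

EQD2 uses the standard conversion D·(d + α/β)/(2 + α/β) with a default
tumor α/β = 10 Gy (configurable); at d = 2 Gy it is the identity, and for
the common alternative schedule 69.96 Gy/33 fx it gives 70.66 Gy, inside
the 69–71 Gy standard-dosing band used for subset analyses.

## Signature scoring

RSI is a signed linear combination of *within-sample ranks* of ten genes
(AR, JUN, STAT1, PRKCB, RELA, ABL1, SUMO1, PAK2, HDAC1, IRF1). The
packaged coefficients are transcribed from the public rank-based
implementation of the published signature; because different deployments
disagree on whether ranking spans the ten genes or the whole array, the
scope is exposed as `rank_scope` ("signature", the default, or "all")
rather than hard-coded. Ties receive average ranks. Scores outside
(0, 1] — possible on toy or degenerate data — are clipped to [1e−6, 1]
with a warning; scoring is invariant to any strictly increasing
per-sample transform of expression, which the tests verify directly.

## Survival engine

* **Kaplan-Meier and Cox PH** delegate to lifelines (Efron ties); the
  Cox fit is cross-checked in tests against a hand-coded partial-
  likelihood grid maximizer (agreement < 1e−4 on an untied fixture).
* **Log-rank** is computed in-house as the standardized two-sample form
  Z = (O−E)/√V so the cut-point scan can use signed standardized
  statistics; Z² matches lifelines' chi-square to 1e−9.
* **Maximally selected cut-point**: candidate cuts are the observed
  marker values keeping ≥ 10% of the cohort on each side (capped at 256
  quantile-spaced candidates for large n; the scan is rank-based, so the
  selected *split* is invariant under monotone marker transforms). The
  selected cut maximizes |Z| — equivalently minimizes the log-rank
  p-value, the conventional reading of "minimizing the log-rank score",
  since literally minimizing the statistic would return the *worst*
  split. Because the cut is chosen post hoc, the naive p-value is
  anti-conservative; a seeded permutation adjustment (max-|Z| null over
  marker permutations, 1000 permutations by default in the pipeline) is
  reported alongside it.
* **Weibull fitting**: censored MLE by default (lifelines), with an
  alternative least-squares fit to the KM step values at event times;
  the two agree within 5% on clean data. A group with zero events cannot
  identify a proper Weibull and becomes a flagged degenerate plateau
  S(t) = 1 on the observed horizon, with an optional pseudo-event
  fallback (one event at last follow-up).
* **Time-dependent AUC** uses the IPCW cumulative-case/dynamic-control
  estimator: cases (events by the horizon) weighted 1/Ĝ(T⁻), controls
  (at risk past the horizon) weighted 1/Ĝ(t), with Ĝ the Kaplan-Meier
  censoring survival; marker ties count 0.5. Without censoring it reduces
  exactly to pair counting, and it matches scikit-survival's Uno
  estimator to 1e−6 on censored data.

## In silico trials

Virtual patients are drawn by **smoothed bootstrap**: resampling the
source RSI values with replacement and adding Gaussian kernel noise with
bandwidth from R's `nrd0` rule, 0.9·min(sd, IQR/1.34)·m^(−1/5) —
equivalent to sampling the Gaussian KDE of the source. Draws are clipped
into (0.001, 0.999) with the clip count logged (clip mass is negligible
for realistic RSI sources).

Arm outcomes use a **two-group Weibull mixture**: GARD-low and GARD-high
populations are modeled independently and combined by the arm's group
proportions, S(t) = p_low·S_low(t) + p_high·S_high(t). The group models
are fit once on the source cohort and reused across arms and replicates.
A per-patient sampled-event-time mode (administratively censored at 60
months, KM-summarized) exists for generating replicate curve variability;
the analytic mixture is the default. Replicate CIs are 2.5/97.5
percentiles of the 36-month OS over 100 replicates of 200 patients per
arm.

Designs:

* **Unselected de-escalation** — experimental arm uniformly at
  60 Gy/30 fx. GARD falls by 6/7, some patients cross below the cut, the
  high-group count shrinks (about 74 → 32 per 200 under the default
  calibration) and arm survival drops.
* **GARD-selected** — only patients with GARD ≥ cut at *both* doses are
  de-escalated; since GARD₆₀ ≥ 42 implies GARD₇₀ ≥ 42, eligibility is
  P(GARD₆₀ ≥ 42) ≈ 16% under the default calibration, and the
  experimental arm's group composition — hence its predicted survival —
  matches the control arm by construction.
* **Personalized iso-GARD** — every patient receives the minimum
  2 Gy/fraction dose reaching the equipoise target (default GARD 32);
  the report counts fractions spared vs the 35-fraction standard and
  flags patients underdosed by their delivered plan.

The equipoise-threshold search returns the smallest observed GARD value
whose subgroup KM survival at the horizon (default 36 months) is at
least the whole-cohort value. With the "≥" convention the smallest
observed value qualifies trivially (the subgroup is the whole cohort);
`proper_subgroup=True` restricts the scan to strict subsets.

## Synthetic cohort calibration

Real outcomes for the motivating cohort are not public, so the generator
emulates its printed statistical structure. The calibrated quantity is
GARD at 70 Gy/35 fx (all published summaries are on the GARD scale); RSI
follows from the exact identity RSI = exp(−GARD₇₀/35).

* **GARD₇₀ distribution**: lognormal by default (positive support, two
  parameters, flexible tail; gamma selectable), least-squares fitted on
  relative quantile errors to median 39.1, IQR 12.6, P(≥ 42) = 0.37 and
  P(≥ 49) = 0.16 — the tail targets back-derived from mean simulated
  group sizes of 74/200 at 70 Gy and 32/200 at 60 Gy. The fit lands
  within ~1% of every target (the acceptance band is 10%).
* **Schedule mix**: 60% at 70 Gy/35 fx, 30% at 69.96 Gy/33 fx, and a 10%
  tail (66/33, 74/37, 51/17) reproducing EQD2 median 70.0, IQR ≈ 0.7 and
  the 51–74 Gy delivered range.
* **Grouped outcome model** (default): each GARD group gets the unique
  Weibull through two survival anchors. Low group: S(36) = 0.90 (the
  published KM estimate below the cut). High group: S(36) = 0.995 and
  S(60) = 0.99 — a proper-Weibull stand-in for the published "100%",
  which no finite Weibull can represent (the degenerate plateau remains
  available for exact replication). The low group's 60-month anchor is
  solved from the mixture identity so the whole cohort hits the
  published 87.3% at 60 months; the implied 36-month mixture value is
  ~93.6%, inside the (92%, 96%) acceptance window around the published
  94.1%.
* **Continuous outcome model**: Weibull proportional hazards with hazard
  multiplier exp(β_G · GARD); the per-patient scale is
  λ·exp(−β_G·GARD/k). Default planted effect β_G = −0.06 per GARD unit
  (≈ ln 0.941), baseline k = 1.4, λ = 40 months — chosen so a
  median-GARD patient's survival matches the cohort's observed level and
  the event fraction (~14%) matches the real 23/191.
* **Censoring**: administrative at 60 months plus staggered-accrual
  follow-up Uniform(30, 84) months capped at 60, giving a realistic
  censoring mix before the horizon.
* **Covariates** (T4, N2–3, smoking > 10 pack-years, ECOG > 0) are
  independent Bernoulli draws at plausible prevalences; the real joint
  distribution with RSI is unpublished, so synthetic covariates carry no
  association with outcome or GARD. Tests passing on these cohorts
  therefore validate the *machinery*, not any claim about real
  covariate confounding.

What the generator does **not** emulate: correlation between RSI and
clinical covariates, recurrence outcomes, inter-center heterogeneity,
and the discreteness of real follow-up visits. Results on synthetic
cohorts show that the pipeline recovers planted structure, not that the
published clinical estimates generalize.

## Numerical choices and edge cases

* Prescription fraction counts guard floating-point noise with a 1e−12
  tolerance before the ceiling, so exact multiples do not round up.
* The cut-point scan flags zero-variance candidates as NaN and errors
  only if *no* admissible candidate has positive variance.
* IPCW AUC errors (rather than returning NaN) when the censoring
  survival hits zero before the horizon, advising a shorter horizon.
* Calibration with a lone median constraint returns the closed-form
  lognormal location (μ = ln median) with the spread at its initial
  value rather than running an unidentified optimization.
* All randomness flows through `numpy.random.Generator` objects seeded
  from explicit integers; trial runs are bit-for-bit reproducible given
  (spec, seed).

## Problem sizes used in the checks

Acceptance-style checks run at desk scale: 1000-case identity sweeps;
100-seed recovery studies at n = 500 (Cox) and n = 600 (cut-point — the
~191-patient scale yields only ~12 events, far too few to localize a
cut); trials at 200/arm × 100 replicates; calibration checks at
n = 5000. Known limitation: with ~70 events per cohort and a strongly
skewed covariate effect, 95% Cox Wald intervals sit slightly below
nominal coverage (the recovery test measures this directly);
profile-likelihood intervals behave the same, and coverage returns to
nominal as events grow.
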