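# Methods

`lodsim` simulates an aging population in which every individual carries a
fixed polygenic liability for one late-onset disease (LOD), and quantifies
how the risk-allele frequencies of cases and controls diverge — and GWAS
discovery power decays — as study cohorts age.

## Model

**Genetic architecture.** A disease's causal background is modeled as a grid
of independent biallelic SNPs. Minor-allele frequencies and per-allele odds
ratios are each discretized into `grid_points` (default 5) equally spaced
values inside scenario bounds (scenario A, "common low": MAF 0.073–0.500,
OR 1.05–1.15; scenarios B–E move toward rarer, larger-effect alleles), and
the full MAF × OR cross-product forms one 25-variant set. Grid values are
rounded to the scenario's printed precision (3 decimals for A, 4 for B–E),
which makes variant tables byte-reproducible. The liability variance of a
variant list is

    var = 2 Σ_k p_k (1 − p_k) ln(OR_k)²,

and the liability-scale heritability is h² = var / (var + π²/3), π²/3 being
the variance of the standard logistic distribution. Sets are replicated
`n_sets = round(var*(h²) / var(one set))` times (nearest integer); an
explicit `n_sets` override exists because published variant counts for some
diseases exceed nearest rounding by a few sets.

**Individuals.** Allele counts are drawn per variant as Binomial(2, p)
(Hardy–Weinberg). The polygenic risk score (PRS) is β = Σ_k a_k ln(OR_k),
centered by the population offset 2 Σ_k p_k ln(OR_k) so the initial
population mean is zero. Only the scalar PRS and the genotypes of nine
tracked variants (the 3×3 {min, mid, max MAF} × {min, mid, max OR} subgrid
of set 1 — a documented choice, configurable) persist per individual.
Variants sharing identical (p, OR) — the replicated sets — are drawn as one
grouped Binomial(2m, p), which is distributionally identical to summing m
independent Binomial(2, p) genotypes; binomial draws use exact inverse-CDF
table lookup for speed at populations of 10⁶–10⁷.

**Diagnosis.** Each year of age, the expected number of new diagnoses is
N_d(t) = I(t) · N_u(t) (rounded half-to-even, with the fractional remainder
carried to the next year so no incidence mass is lost in small populations).
That many individuals are drawn from the unaffected pool *without
replacement*, with inclusion weight proportional to each individual's hazard
multiplier. The multiplier is exp(PRS) passed through an odds-ratio→hazard
conversion: by default the rate-adjusted form RR = OR / (1 − P0 + P0·OR)
with P0 the current year's incidence (which reduces to the identity as
P0 → 0, the low-incidence regime where OR ≈ HR), or the identity,
selectable via `or_to_hr_mode`. The rate-adjusted form saturates individual
hazards near 1/P0, which visibly compresses the case/control divergence of
the highest-incidence, highest-heritability diseases at old ages — the
mechanism behind their published, anomalously low youngest-cohort MAF
differences.

The weighted draw is implemented as an exponential race (take the n smallest
of E_i / w_i, E_i ~ Exp(1)), a one-pass O(N) equivalent of Gumbel top-k
selection and of the literal cumulative-weight lookup table, which is kept
in `lodsim.oracles` as the correctness reference; the two are statistically
exchangeable but never bit-identical. Race keys are computed in float32 on
the hot path; all count/moment accumulators are float64/int64.

**Study designs.**
*IVA* (individual values analysis) contrasts the newly diagnosed cases of
each 1-year age slice with the currently unaffected population; mortality is
not applied (it removes future cases and controls in equal proportion).
*Cohort* mode staggers `span` (default 10) equal birth cohorts entering one
calendar year apart; cases accumulate (anyone diagnosed at or before their
current age), controls are the currently unaffected survivors, and
statistics are indexed by mid-cohort age (entry age + span/2). Records
require both pools to hold ≥0.25% of the initial population; the youngest
usable cohort is the first mid-cohort age whose cumulative incidence reaches
0.25%. Members of the oldest sub-cohorts who exceed age 100 while the
mid-cohort age is still ≤100 continue under the plateau incidence I(100).

**Mortality.** A Gompertz–Makeham yearly death probability
q(t) = min(1, a + b·e^{t/c}) with a = 2×10⁻⁴, b = 2.4×10⁻⁵, c = 10.2 years
stands in for actuarial life tables; these constants reproduce US unisex
death probabilities within a few percent at ages 60–100 (q(80) ≈ 0.061,
q(90) ≈ 0.163) and leave <1% of a cohort alive at 105. Baseline death ages
are pre-sampled per individual by inverse CDF (distributionally identical to
applying q(t) year by year). Case mortality is q(t) × `case_multiplier`
(1 = equal, 2 = the double-case-mortality stress scenario, 0/`form="none"`
= no deaths); for multipliers ≠ 1 diagnosed individuals switch to yearly
Bernoulli thinning.

## Disease presets

Eight presets (AD, T2D, CAD, stroke, breast, prostate, colorectal, lung)
pair a target heritability with a calibrated incidence curve. Because the
source per-disease curve parameters are not part of this package, each curve
is an exponential I(t) = i0·e^{r(t−t0)} (doubling time ln2/r within
5–8.5 y) that plateaus — via a C¹ saturating approach to `i_max` — at the
published age to which growth is exponential, with i0 fixed (offline, once)
so that the *mortality-adjusted lifetime risk* (cumulative incidence with
death as a competing yearly hazard — the quantity clinical lifetime-risk
tables report) lands inside the published band while the yearly hazard never
exceeds the published maximum. Two calibration notes:

* **breast**: with growth exponential to 72, a <0.5%/y ceiling and the
  unisex mortality stand-in, the achievable lifetime risk tops out near
  9.4%, below the published 12% (a female-mortality figure). The preset is
  pinned at the ceiling; its acceptance band is (8%, 14%).
* **AD**: onset 65, doubling 5.0 y, no cap before 100; yearly incidence
  reaches ≈24% at 100, matching the published ">20%" maximum, with lifetime
  risk 18%.

Shifting a preset's absolute incidence level moves ages, not conclusions:
the validation experiments show the case/control allele distributions depend
on the *cumulative* incidence reached, not on the curve shape that reached
it.

## GWAS power

For one variant in a balanced study of N = cases + controls, the association
test is noncentral F(1, N−4) with λ = N·p₁·p₂·(f_cases − f_controls)²;
power at genome-wide significance is the upper tail beyond the central F
quantile at PSign = 0.99999995 (5×10⁻⁸). `cases_for_power` inverts power =
0.8 for N by monotone bisection to 0.01% relative accuracy. Absolute
cases-needed values follow these equations as published; the cross-age
*multiple* (cases needed at age a vs the youngest cohort) is the primary
reported quantity because it equals (δMAF_young / δMAF_a)² and cancels every
constant in the power model — it is numerically invariant to the
significance level and power target, which the tests assert.

## Validation oracles

* Closed form: the first hazard-weighted draws from an undepleted population
  carry a tracked allele at frequency p·h/(1−p+p·h) (h = per-allele
  multiplier); for p = 0.5, h = 1.15 this gives 0.53488, a case-minus-control
  difference of 0.0349 — the analytic anchor for every low-cumulative-
  incidence youngest cohort.
* The literal per-draw lookup-table sampler must agree with the exponential
  race (equal inclusion probabilities; equal case-MAF trajectories within
  3 Monte-Carlo SE over 50 replicates at n = 10⁴).
* Shape invariance: constant, linear and exponential incidence curves
  calibrated to the same cumulative incidence (5%, 20%, 50%; scenarios A
  and D) must give the same control-pool PRS mean and case/control MAFs at
  the matched cumulative-incidence age within 3 SE. This suite runs with the
  identity OR→HR conversion: the rate-adjusted conversion depends on the
  yearly rate by construction and would re-introduce a small, real shape
  dependence that is not a property of the sampling mechanism under test.
  The matched comparison point for a horizon-calibrated curve is the record
  at horizon − 1 (the record at age h already includes the draws of age h).

## Problem sizes and noise

Default analysis runs use populations of 10⁶–10⁷ with ≥10 replicate seeds;
the acceptance script runs 6×10⁶ × 10 seeds per disease, giving a
Monte-Carlo SE near 10⁻³ on youngest-cohort MAF differences (the reference
analysis used populations ~300× larger; all reported statistics therefore
carry explicit `*_se` columns). The test suite runs the same scale with a
pinned seed so its results are reproducible to the bit; at materially
smaller scales the Monte-Carlo error on the youngest-cohort δMAF exceeds
the 3-decimal precision the published values carry.

## What the generator does and does not emulate

The synthetic populations realize exactly the model above: independent loci
in Hardy–Weinberg proportions, multiplicative per-allele hazards constant
over life, homogeneous environment, no linkage disequilibrium, no secular
trends in incidence or mortality, a single disease at a time with no
comorbidity, and no sex stratification. Passing tests therefore demonstrate
internal consistency of the method and reproduction of the published
simulation statistics — not that any real disease follows the proportional-
hazards polygenic model.

## Known limitations

* The OR→HR conversion of the original analysis is underdetermined; both
  provided modes bracket it. Absolute MAF differences for the two
  highest-incidence diseases (AD, T2D) depend strongly on this choice.
* Within the high-prevalence group the ranking of the age-related decline
  (AD vs CAD vs stroke) is sensitive to the late-age incidence
  approximations; only T2D's top rank and the cancers' bottom ranks are
  robust, and the tests assert exactly that.
* Absolute cases-needed counts implement the published equations verbatim;
  published youngest-cohort counts are internally consistent with a ≈1.33×
  smaller constant, so cross-age ratios are the comparable quantity.
* The unisex mortality stand-in under-serves sex-specific diseases (breast,
  prostate); see the calibration notes.
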