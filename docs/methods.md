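# Methods

## Model overview

The unit of analysis is the national cohort of women aged 15–19, treated as
five equal single-year age classes of size N/5. The model is a deterministic
accounting chain from pregnancy rates to deaths, out-of-pocket (OOP)
spending and impoverishment, decomposed across income quintiles; randomness
enters only through (a) the income draws used by the Monte Carlo
impoverishment path and (b) the probabilistic sensitivity analysis. All
monetary quantities are US$2014.

Key assumptions, stated once:

* **Pregnancies proxy live births.** The maternal mortality ratio (per
  100 000 live births) is applied directly to pregnancy counts; abortion,
  stillbirth and multiple births are not separated.
* **Age-specific risk.** The published 15–49 MMR applies unchanged at ages
  16–19 and is multiplied by the relative risk (4.6 by default) at age 15.
  No renormalization holds the all-age MMR fixed under the age weighting;
  this unrescaled convention is what reproduces the countries' published
  death totals from their published inputs.
* **Mortality is quintile-neutral conditional on pregnancy.** Deaths are
  allocated to quintiles purely by pregnancy shares; no differential case
  fatality by care usage is modelled. The equity decomposition of deaths is
  therefore exactly the normalized per-quintile pregnancy vector — e.g.
  India's bottom-two share is (19+17)/60 = 60% identically.
* **Only care users pay.** κ of pregnancies are complicated; of those, the
  quintile's skilled-birth-attendance coverage u_q reaches care and incurs
  the OOP bill c_q + t_q. Women who forgo care incur zero OOP cost and can
  never appear in the impoverishment counts, even though forgoing care is
  itself a welfare loss — a structural property of OOP-based metrics.
* **No survivorship adjustment.** Deaths do not reduce the cost base; the
  two outcomes are accounted independently.

## Reconciling the two pregnancy parameterizations

The per-age pregnancy percentages and the per-quintile percentages come from
different survey instruments and are inconsistent as absolute rates (India:
mean 6% by age vs 12% by quintile). The package resolves this by contract:
**the per-age profile sets the total count; the per-quintile profile enters
only as normalized shares.** This single choice reproduces the published
death totals and the published bottom-two equity shares simultaneously.
The alternative reading — absolute per-quintile counts (N/5)·p_q, with the
age profile rescaled to match — is available via `quintile_mode="absolute"`
for sensitivity exploration, and is also the convention behind the
*incidence* denominator (cases ÷ pregnant adolescents), where the
per-quintile total is the default because it is the denominator that yields
the published incidence levels (≈0.4% India, ≈1.8% Niger);
`incidence_convention="age"` switches to the per-age denominator.

## Income model

Income is Gamma(k, θ). The Gini of a gamma depends only on the shape,
G(k) = Γ(k+½)/(√π·Γ(k+1)), which is strictly decreasing, so the calibration
is exact and unique: invert G(k) = Gini by Brent's method on k ∈ [10⁻³, 10³]
(tolerance ~10⁻¹²; verified against a numerical Lorenz-curve-integration
oracle to ~3×10⁻⁸), then θ = GDP per capita / k so the mean matches GDP per
capita to machine precision. Matching the *mean* (not the median) is the
standard convention when GDP per capita is the only level anchor. Quintiles
are the population quantile bands at probabilities 0.2/0.4/0.6/0.8 —
deterministic and sample-size-free, never re-ranked from a finite sample.
Income is annual individual income assigned directly to the adolescent; no
household equivalization is attempted.

## Impoverishment counting

A care-using complicated delivery in quintile q is catastrophic when its
bill exceeds τ of the woman's income, i.e. income < (c_q + t_q)/τ. The
default path is **analytic**: the count is u_q·κ·P_q times the conditional
gamma CDF on the quintile band — exact and deterministic, which is what the
test suite and the policy counterfactual build on. The **Monte Carlo** path
draws one income per delivery (inverse-CDF on the band's probability
interval, so draws are exactly conditional) and exists to mirror the
simulation formulation and to cross-check the analytic path; the two agree
within 3 binomial standard errors at the delivery counts involved. The
poverty-headcount variant counts deliveries with income ≥ line before
paying and < line after; a line of zero counts nobody, because post-payment
income is floored at zero. No printed poverty line ships with the fixtures;
the CLI requires `--poverty-line` explicitly.

## Education counterfactual

One additional year of mean female schooling multiplies all pregnancy rates
by (1 − e), uniformly across ages and quintiles (no differential uptake).
Every downstream outcome is homogeneous of degree 1 in the pregnancy rates,
so averted outcomes are exactly e × baseline, quintile by quintile — the
implementation computes baselines once and scales, and the test suite
asserts the linearity rather than re-deriving it. The default e = 18%
(SE 2%) can be replaced by a fitted value: `fit_education_effect` regresses
the adolescent pregnancy rate on mean years of female education (OLS) and
scales the slope by the sample mean rate — an elasticity at the mean —
with the SE scaled identically and confidence intervals using the Student-t
quantile at the fit's residual degrees of freedom. The scaling choice is
isolated in that one function.

Programme cost is (N/5) × annual primary-education cost per pupil: the
entering cohort schooled one extra year. With discounting enabled
(default rate 3%/year), the age-a benefit stream is weighted by
(1+r)^−(a−15) — deaths by their π_a·r_a age profile, cost-linked outcomes by
π_a — while the schooling cost is treated as incurred at the start of the
stream and is therefore not reduced. Discounted benefits are strictly
smaller than undiscounted ones for any positive rate.

## Probabilistic sensitivity analysis

Each trial redraws MMR, the five age relative risks, the ten cost entries
(elementwise, independently) and the education effect, then re-runs the full
deterministic pipeline; 2.5th/97.5th percentiles (linear interpolation
between order statistics, the numpy default — stated so ports can match)
of the 1000-trial outcome samples form the 95% uncertainty ranges.
Distributions are moment-matched to (mean, sd): gamma k = m²/s², θ = s²/m
for non-negative quantities; beta α = mν, β = (1−m)ν with ν = m(1−m)/s² − 1
for proportions (infeasible sd raises an error naming the parameter);
logistic with scale s·√3/π for the education effect. Only the education
effect has a published SE (0.02); all other inputs default to sd = 10% of
the mean, overridable per parameter. GDP per capita and Gini are held fixed
by default (they are not among the varied key parameters); adding them to
the spec makes each trial re-calibrate the income model. Logistic tails are
clipped to [0, 1) for the education effect, a ~10⁻¹⁶-probability event at
the default scale. With these defaults the URs bracket every point estimate
and reproduce the ordering of the published ranges; their exact widths
depend on input SDs that are not published, so the URs are qualitative
diagnostics, not reproduction targets.

## Synthetic data

`generate_education_dataset` emulates the cross-country regression input: 80
countries, education years uniform on 4–10, pregnancy rate linear with slope
−e·(mean rate) plus Gaussian noise (sd 0.035), clipped to [0, 1]. The
defaults put the linear mean ≥ ~2 noise-sd inside the unit interval across
the covariate range, so clipping is rare (<1%) and the OLS recovery
experiment is essentially unbiased; the implied R² ≈ 0.7 sits at the upper
end of a realistic cross-country regime. What the generator does **not**
emulate: heteroscedasticity, country-size weighting, measurement error in
schooling, and reverse causality from pregnancy to dropout — so passing
recovery tests demonstrate correctness of the estimator, not causal validity
of the education effect on real data. `generate_country` produces random
valid parameter sets (usage increasing with income, all invariants holding)
for property-based testing.

## Numerical choices and degenerate inputs

* Gini→shape inversion: Brent on [10⁻³, 10³], xtol 10⁻¹³; Ginis outside the
  gamma family's range on that bracket (< ~0.018) are rejected.
* Conditional band probabilities are clipped into [0, 1] after CDF
  differencing to absorb rounding at band edges.
* An all-zero per-quintile pregnancy vector makes the quintile split
  undefined and raises; an all-zero per-age vector yields a valid all-zero
  ledger.
* τ is required in (0, 1]; τ → 0⁺ counts every care-using delivery.
* `QuintileOutcomes` tolerates −10⁻⁹ of numerical noise and floors at zero.
* Problem sizes are small throughout (5 ages × 5 quintiles; 1000 PSA trials;
  10⁶-draw sampling checks), chosen as the sizes at which every stochastic
  check resolves well inside its tolerance.

## Known limitations

Single-year steady-state model: no cohort dynamics, no morbidity or
sequelae, no lifetime economic consequences of adolescent pregnancy, no
within-country regional variation. The education–fertility relationship is
associational; directionality is assumed. OOP costs are averages over
"complicated delivery" without separating caesarean from assisted vaginal
delivery. Incomes are assigned to adolescents as individuals although they
typically depend on households. The Niger OOP and catastrophic totals are
reproducible from the published input table only to roughly ±15%, so those
outputs carry that structural uncertainty independent of any Monte Carlo
noise.
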