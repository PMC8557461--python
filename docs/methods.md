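# Methods

## The model

`fizsel` models a biallelic SNP (ancestral allele C, derived allele G) at an
X-linked locus in a large *Drosophila melanogaster* population sampled twice
a year (late June and early September). The interval between successive
collections is a "season"; nine seasons connect ten collections over five
years. Within a season the population passes through a fixed number of
discrete generations `g` (default 5 — selection-coefficient estimates
plateau around five generations per season, and two generations a month in
summer plus an overwintering interval is a defensible field guess; `g` is a
configuration knob everywhere).

Each generation consists of

1. **gamete production**: adult females produce eggs with G frequency
   `p_egg = f_GG + f_CG/2`, adult males produce X-bearing sperm with their
   own G frequency `p_m` (males are hemizygous);
2. **random union of gametes**: female zygotes take the product form
   (`f_CC = (1−p_egg)(1−p_sperm)` etc.); male zygotes inherit their single
   X maternally, so the male zygote frequency equals `p_egg` — this is the
   source of the one-generation "male lag" and of the non-monotone
   frequency paths within seasons;
3. **viability selection**: genotype frequencies are reweighted by the
   season's relative viabilities — `v_G` for G males, `w_GG` and `w_GC` for
   GG and GC females — with C males and CC females as the reference fixed
   at 1, then renormalized.

Assumptions: infinite population (deterministic recursions, no drift),
50:50 sex ratio, random mating, no mutation or migration, non-overlapping
generations, viability (not fecundity) selection, and a census at the adult
(post-selection) stage — the stage field traps catch. The state is
`PopulationState` (male G frequency plus the female genotype triple); the
population-wide "weighted allele frequency" `(2·p_egg + p_m)/3` reflects
the 2:1 X-chromosome dosage of females versus males.

Female dominance is summarized by `h` with `w_GC = 1 + h·(w_GG − 1)`:
`h = 0` G recessive, `h = 1` dominant, `h < 0` heterozygote beyond the CC
reference.

## Fitting

Per season, the three fitnesses are estimated by bounded quasi-Newton
(L-BFGS-B, bounds `[1e-4, 10]`) minimization of the sum of squared
*relative* differences between predicted and observed end-of-season
values of the three free observables {male `p_G`, female `f_GG`, female
`f_CC`} (`f_CG` is implied). Observed values are the denominators, floored
at `1e-6` when an observable is zero. Multi-start: the eight corners of
the lattice `{0.5, 1.5}³`, optional warm starts, and seeded log-uniform
random restarts.

Because each season has three free parameters against three observable
degrees of freedom, the optimum on interior data reproduces the endpoint
exactly; the least-squares fit is then simultaneously the maximizer of the
binomial (males) × multinomial (females) count likelihood, and the
full-trajectory fit attains the *saturated* likelihood. The full model fit
(`fit_full_model`: three initial-state frequencies plus 3 fitnesses ×
seasons — 30 parameters for nine seasons) exploits this: the initial state
starts at the first collection's observed frequencies, seasons are fitted
sequentially, and a joint L-BFGS-B pass over all parameters polishes the
trajectory likelihood.

**Uncertainty.** Profile likelihood: one parameter is fixed on a grid, all
others re-optimized (warm-started sequential refit plus optional joint
polish); the 95% interval is `{θ : 2(ℓ_max − ℓ(θ)) ≤ 3.841}` (Wilks χ²₁),
endpoints refined by bisection to 1e-3. Parametric bootstrap: observed
frequencies are treated as the truth, counts are redrawn at the observed
sample sizes, the model is re-fitted, and percentile intervals are taken
(the two approaches should roughly agree, and the test suite checks they
overlap). `profile_curvature` gives a fast observed-information/SE scale
for identifiability screening; near a fixation boundary the quadratic
approximation overstates precision, so sharp identification claims should
be confirmed against the full profile interval.

**Model comparison.** AIC = 2k − 2ℓ over a configurable ladder: neutrality;
constant sexually antagonistic selection with free or fixed dominance;
purely fluctuating selection (the same per-season fitness in both sexes)
with G dominant or recessive; and fluctuating sexually antagonistic
selection with fixed dominance. The ladder is expressed through
`ModelSpec` constraint maps (per-season / constant / tied / fixed), so any
other nesting — and either the `h` or the `w_GC` parameterization, which
give identical AIC on interior data — is expressible.

## Long-term projections

`project` iterates a season cycle (default: seasons 1–8, dropping the last
to balance summers and winters; a 2–9 switch is provided) for hundreds of
seasons. `classify_outcome` calls the polymorphism *maintained* when the
weighted allele frequency at every census of the final cycle stays inside
`[ε, 1−ε]`; otherwise the nearer boundary names the fixing allele. ε
defaults to 1e-3 — far above double-precision underflow and far below any
observed frequency; it is a knob because the maintained/extinct call could
in principle be threshold-sensitive for trajectories that hover.

For *constant* fitnesses an analytic cross-check exists: linearizing the
recursions near each fixation boundary gives a 2×2 matrix per generation
for the rare allele's (heterozygote-frequency, male-frequency) vector —
for rare G, `[[w_GC/2, w_GC], [v_G/2, 0]]`; for rare C the same with
`w_GC/w_GG` and `1/v_G` (selection relative to the resident). A protected
polymorphism requires the leading eigenvalue of the cycle product to
exceed 1 for both alleles. The suite checks long-horizon iteration against
this oracle on hundreds of random draws bounded away from the boundary.

`constant_average_cycle` replaces every fitness by its arithmetic mean
over the cycle (the "no fluctuations" comparison); `override_dominance`
forces `w_GC = 1 + h(w_GG − 1)` in every season, e.g. `h = 0.715`, the
starvation-resistance dominance estimated in the Munich background — an
override that can rescue a polymorphism otherwise lost under a recessive
female-beneficial G.

`sample_parameter_sets` draws fitness sets for an 8-season cycle with each
of the 24 parameters sampled *independently* in proportion to its
discretized profile likelihood. Independence matches the described
construction but ignores parameter correlations, which is documented as a
caveat: correlated draws would concentrate on jointly well-fitting sets.
`uncertainty_sweep` classifies every set over (default) 500 seasons and
reports the fraction maintaining polymorphism and the fraction of those
that still maintain it under the time-averaged constant cycle.

## Frequency tests

All tests work on allele counts (one per male, two per female), because
sample sizes differ by sex, season and year. The CMH test (statsmodels,
continuity correction on by default — the common default of mainstream
statistical software; a flag exposes the uncorrected statistic) stratifies
2×2 G/C tables by collection (sex contrast) or year (season contrast). The
bootstrap test compares the observed cumulative G-frequency difference
(fixed group order: female − male, or September − June) against
randomizations drawn binomially at each stratum's pooled frequency and the
observed sample sizes; `p = #{Δ* ≥ Δ_obs}/n_rep` with ties counted and no
+1 smoothing, so a negative observed difference yields a large p-value and
`p·n_rep` is an integer. Run-to-run variation at 10,000 replicates is on
the order of one percentage point.

Hardy–Weinberg χ² (1 df) compares female genotype counts against
expectations at the all-flies allele frequency by default (females-only is
a flag), Bonferroni-corrected across collections. Binomial CIs are Wilson
by default (Clopper–Pearson selectable). The variance test compares
`var(female frequencies) − var(male frequencies)` across collections
against resampling under per-collection pooled frequencies. The power
simulation plants a constant June→September shift in male frequencies and
reports the detection rate of the chosen seasonal test (bootstrap by
default; CMH selectable — with realistic male sample sizes the power for a
4-point shift is only a few percent, which is why a seasonal signal can be
detectable in females yet invisible in males).

## Dominance from phenotypes and LT50

`h = (X̄_CG − X̄_CC)/(X̄_GG − X̄_CC)` on the transformed trait scale. h is
invariant under affine transforms, so "log square root" (= 0.5·log) is
affinely equivalent to log for every dominance purpose; it is implemented
literally. The bootstrap resamples within genotype classes (preserving
class sizes — the natural reading when class sizes are fixed by design),
10,000 replicates by default, percentile intervals, undefined replicates
(resampled homozygote means colliding) dropped and counted with a flag
above 20%. Per-heterozygote dominance values rescale each heterozygote by
the homozygote class means; their mean equals the point estimate exactly,
which is what lets downstream ANOVAs test dominance differences.
`weighted_genotype_covariate` builds the CC→0 / CG→h / GG→1 covariate (or
canonical class values, or plain categories); the linear-model solve
itself is delegated to standard least-squares machinery.

LT50 is estimated by binomial GLM of the cumulative dead/alive split on
time (logit link), `LT50 = −β₀/β₁`, SE by the delta method from the GLM
covariance. Complete separation (0%→100% in one step) is smoothed by a
half-count continuity correction and flagged. Cox proportional-hazards
modelling of survival is deliberately out of scope: standard tooling
(`lifelines`, R `survival`) covers it, and the package's survival surface
is LT50 plus percent change.

## Synthetic data

`preset_scenarios("field_survey")` rebuilds the survey's sampling frame: 10
collections (June/September 2016–2020), per-collection male sample sizes
drawn uniformly in 22–90 and female sizes in 84–132, rescaled to totals of
exactly 515 males and 1,028 females; truth fitnesses make G
female-beneficial, male-detrimental and mostly recessive in most seasons
with one seasonal reversal (matching the qualitative estimated pattern);
initial state at allele frequency 0.35 (the middle of the observed range);
male counts binomial, female counts multinomial at the forward-simulated
adult frequencies. Phenotype noise is normal on the transformed scale (the
transforms exist to normalize); survival times are logistic around the
target LT50.

What the generator does *not* emulate: genetic drift, bait-attraction or
trapping bias, overlapping generations, migration, linked selection, and
within-season environmental gradation. Passing tests therefore show the
machinery is correct and calibrated under the model's own assumptions, not
that the model is true of wild populations.

## Problem sizes and numerical choices

The test and acceptance runs use deliberately scaled problem sizes chosen
to keep the statistical statements sharp: 20 datasets for the saturation
check; 50 truth schemes at n = 5,000 per collection for recovery; 500
constant-fitness draws for the invasion cross-check; 1,000 null
simulations at 2,000 bootstrap replicates for test calibration (10,000
replicates where run-to-run stability itself is the question); 300
meta-replicates for dominance CI coverage; sweeps of 2,000 parameter sets
× 500 seasons. At n = 5,000 the profile standard errors of season
fitnesses are ~3–8% of the estimate, so single-parameter recovery is
assessed through its own standard errors (calibration) and through median
error rather than as a uniform guarantee; seasons touching a fixation
boundary are excluded from recovery scoring because boundary data carry no
fitness information while local curvature there is misleading.

Other numerical choices: frequencies renormalized after every selection
step (drift tolerance 1e-12); fitness bounds `[1e-4, 10]`; χ²₁ = 3.841 for
95% profiles; bisection tolerance 1e-3; extinction ε = 1e-3; bootstrap
failures tolerated up to 5%; ties in multi-start broken by first-found.

## Known limitations

* Deterministic model: drift in a finite population will widen real
  fluctuations relative to predictions.
* The saturation structure makes the full model's fit a perfect
  interpolation; goodness-of-fit is therefore not testable within the full
  model, only through the AIC ladder of constrained alternatives.
* Independent per-parameter sampling in the uncertainty sweep ignores
  parameter correlations.
* Per-season fitness estimates are weakly identified at realistic field
  sample sizes (hundreds of flies); most 95% intervals straddle 1, and
  conclusions should rest on the model comparison and sweep fractions
  rather than single-season point estimates.
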