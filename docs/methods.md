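# Methods

This note documents the statistical procedures implemented in `matechoice`,
the assumptions they rest on, the tunable parameters and their defaults, and
what the synthetic-data generator does and does not emulate.

## Study structure and units

The unit of competition is the **enclosure-year**: one site in one breeding
season, holding up to 21 adults in a roughly even sex ratio. Individuals may
appear in several enclosure-years. A **successful pair** is a female and
male with at least one offspring surviving to weaning in that
enclosure-year; females carry at most four young, so female offspring counts
are capped at 4, while a male may sire several litters.

## Standardized multilocus heterozygosity

`standardized_heterozygosity` computes, per individual and panel,
`h_std = h_raw / Σ H̄_l` where the sum runs over the loci that individual was
typed at and `H̄_l` is the mean 0/1 heterozygosity indicator among
individuals typed at locus *l*. Standardization is over the whole loaded
panel, not per enclosure. Properties relied on by the tests: with complete
data the population mean is exactly 1 (algebraic identity), and the value is
invariant to allele relabeling and locus order. Degenerate cases: loci typed
in no one are dropped with a warning; an individual whose denominator is
zero (nothing typed, or only loci observed monomorphic) gets `NaN` and is
excluded downstream. Half-calls (one known allele) are treated as missing
throughout — the analysis never uses partial genotypes.

## Pair similarity

`D_AB = 2·F_AB/(F_A + F_B)` uses **set semantics**: a homozygote contributes
one distinct allele to `F_A`, a heterozygote two, and `F_AB` counts shared
distinct alleles per locus. This is the convention that keeps the statistic
in [0, 1] with 1 exactly when the allele sets agree at every shared locus.
The three sums are accumulated across loci before forming one ratio per
pair, so loci are weighted equally regardless of which pairs are missing
where; loci missing in either member contribute nothing. Similarity is
computed separately per panel (genome-wide vs MHC), never mixed. The
minimum shared-locus count for a defined similarity defaults to 1
(`min_shared_loci`, configurable).

## Randomization tests

Per enclosure-year with `k` observed successful pairs, each null draw
selects `k` **distinct pairs** uniformly without replacement from all
defined opposite-sex pairings of that enclosure-year; individuals may recur
across selected pairs, mirroring observed polygamy. The default
`uniform_pairs` scheme is the minimal one consistent with that observation.
An alternative `match_degrees` mode additionally conditions on reproducing
the observed numbers of distinct females and males via rejection sampling;
it is exact but can be slow when the observed degree pattern is rare, and is
provided for sensitivity analysis rather than as the primary scheme.

The test statistic is the mean of the drawn pairs' `D_AB`
(dissimilar-mates hypothesis) or their sample SD (optimum-distance
hypothesis; enclosure-years with a single pair are excluded since no SD
exists). The 95% band is the 2.5/97.5 percentile of the draws — a percentile
interval, not a normal approximation — reported together with the simulated
minimum and maximum. The outcome is categorical (below / within / above the
band) and the empirical p-value is add-one smoothed,
`(1 + #{draws ≤ observed}) / (1 + n_sims)`, so a finite simulation never
reports zero.

The pooled test draws `k_e` pairs independently within every stratum *e*
(per-stratum random streams derived deterministically from the master seed
and the stratum id, so results are independent of processing order and a
single-stratum pooled test reproduces the per-enclosure test bit for bit)
and computes the statistic over the concatenated draws. The pooled SD
includes strata with `k_e = 1`: a single pair has no SD of its own but still
contributes a value to the pooled spread. Mean and SD are computed from
per-draw sums and sums of squares, which is what makes the pooled and
per-stratum code paths numerically identical.

Default `n_sims` is 100,000 per test; a seed is mandatory for any stochastic
analysis. `enumerate_null_exact` provides the exhaustive distribution over
all k-subsets (capped at 10^6 subsets) and serves as the oracle for the
Monte-Carlo machinery in the test suite.

## Breeding-success models

Sexes are modeled separately. Binary success uses a binomial GLM; offspring
counts among breeders use Poisson (males) or a binomial response of
successes out of 4 (females, reflecting the litter cap). Fixed-effects fits
go through iteratively reweighted least squares (statsmodels; relative
deviance change < 1e-8, ≤100 iterations). One random intercept (individual
id, or enclosure-year) can be added; its marginal likelihood is evaluated by
**adaptive Gauss–Hermite quadrature** (15 nodes by default; 1 node is the
Laplace fallback for very large groups), maximized by L-BFGS-B with the SD
bounded at zero, with standard errors from a finite-difference Hessian. The
implementation agrees with `lme4::glmer(nAGQ = 25)` to ~1e-3 on test
problems. Random intercepts are only fitted where the grouping factor
actually repeats ("adequate variation" guard); with singleton groups the
variance is unidentifiable and the pipeline silently falls back to the
fixed-effects model.

Predictors (age, weight, genome-wide and MHC sMLH) are standardized by
centring and dividing by **twice the sample SD** (ddof = 1), putting binary
and continuous effects on one scale. The within-group variant standardizes
inside each enclosure-year × sex cell, turning absolute measures into
competitive ranks; a cell with zero spread maps to 0 (everyone is average
for their group) with a warning.

All 2^p predictor subsets (p ≤ 4) are fitted and ranked by
`AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1)`, where `k` counts the intercept, slopes,
and the random-intercept variance when present. Models with ΔAICc ≤ 2
(configurable) form the top set; Akaike weights are renormalized within it.
The **full average** substitutes zero where a predictor is absent, shrinking
uncertain effects toward zero; unconditional SEs use
`sqrt(Σ w (se² + (β − β̄)²))`. Conditional averaging is available behind a
flag for comparison. **RI** is the unweighted proportion of top-set models
containing the predictor. Back-transformed fitted probabilities use the full
averaged coefficient vector with the stored standardization constants;
predictors with RI < 1 are flagged because their averaged estimates are
shrunken by selection uncertainty, and out-of-range profiles trigger an
extrapolation warning. No multiple-testing correction is applied.

## Synthetic-data generator

Defaults mirror the study conditions the analysis is designed for: 10
enclosure-years (two sites × five seasons) of 10 females and 10 males; ages
uniform on 2–5; weights Normal(7.5, 0.8) kg for females and
Normal(10.0, 1.0) kg for males (typical adult devil masses); 1,948 biallelic
SNPs with minor-allele frequencies uniform on [0.05, 0.5] (the usual
MAF > 5% filter) under Hardy–Weinberg; 12 microsatellites with 2–10 alleles
at Dirichlet(1) frequencies; 5% missing calls; baseline female breeding
probability 0.4 (≈60% of individuals fail to breed); litter sizes 1–4 with
probabilities (0.2, 0.3, 0.3, 0.2) — a symmetric unimodal choice in the
absence of a published litter-size distribution.

Mate choice is modeled as **female choice over enclosure males** (one mate
per litter), a modeling convention rather than a biological claim: each
female's attempt succeeds with probability
`logit⁻¹(α + β_age·z_age + β_wt·z_wt [+ β_het·z_het])`, and a successful
female picks a male with weight ∝ `exp(β_dis·(1 − D_AB))` (dissimilarity
preference), ∝ `exp(−(D_AB − D_opt)²/(2σ_opt²))` (optimum distance), or
uniformly. Effect sizes are stored on the 2-SD logit scale the models
estimate. A master seed expands into independent streams per stage and
enclosure-year.

What the generator does **not** emulate: linkage disequilibrium among SNPs,
pedigree structure across years (individuals are unique to an
enclosure-year), microsatellite mutation, behavioral covariates, or
individual repetition across seasons. Passing tests therefore demonstrate
the correctness and calibration of the statistical machinery under the
stated generative model, not the biological realism of any particular
dataset.

## Validation experiments and problem sizes

Replicated experiments run at a reduced scale chosen to keep the full
validation loop fast while preserving the stratified structure: 4
enclosure-years of 8×8 adults at 200 SNP loci, 1,000–2,000 null draws per
test. Under random mating the pooled below-band rate of both tests stays
within the exact-binomial 99% band around the nominal 2.5% over 1,000
replicate studies. Note the generator and the null are not formally
identical samplers (the generator's breeding females are distinct while the
null may repeat a female across drawn pairs); the calibration experiments
show the resulting dependence difference is immaterial at these scales.

Power experiments use dissimilarity-preference strengths chosen by pilot
simulation at this scale: with genome-wide panels the cross-pair spread of
`D_AB` is only a few hundredths, so preference strengths of 50 (moderate)
and 150 (strong, >80% pooled rejection) in `exp(β_dis(1 − D))` units are
required to produce detectable disassortative pairing. Parameter-recovery
experiments regenerate rosters with a known −1.0 age effect (2-SD logit
scale, n = 400) and recover it with relative bias under 10% and ~95% Wald
coverage.

## Numerical choices and limitations

- Percentiles use linear interpolation (NumPy default); with ≥10^4 draws the
  choice is immaterial.
- Null-draw subsets are generated by partial argsort of uniform variates,
  chunked to bound memory at a few tens of MB regardless of `n_sims`.
- Complete separation in a binomial fit is detected by divergent
  standardized coefficients (|β| > 15) and reported as an error; affected
  subsets are excluded from averaging with a warning.
- AICc requires `n > k + 1`; smaller fits raise rather than silently
  reporting an undefined criterion.
- Conditional R² for averaged mixed models is not implemented; the variance
  decomposition for averaged models is not well defined and is left out
  rather than guessed.
- The `match_degrees` null mode uses rejection sampling and may be slow or
  fail loudly when the observed degree pattern is essentially unreachable
  under uniform pair draws.
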