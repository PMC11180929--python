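# Methods

## Design

`centscan` analyzes a three-cohort extreme-phenotype case-control design:
AD cases, age-matched controls, and cognitively healthy centenarians used
as super-controls, genotyped on a fixed panel of AD-associated SNPs that
carries two published log odds ratios per SNP — a clinical-discovery effect
(`beta_clin`, the yardstick for effect-size change) and a meta-analysis
weight (`beta_meta`, the PRS weight). Genotypes are continuous effect-allele
dosages in [0, 2] (imputed data); hard calls are the integer special case.
Missing dosages are mean-imputed per SNP over the full loaded dataset before
any model fit, preserving sample size in the logistic regressions.

## Association model and the change statistic

Every pairwise contrast is an additive logistic regression of group
membership (case-like group coded 1) on dosage plus the first five principal
components of population stratification. Sex is not a covariate; sex
stratification is offered instead. The effect-size change is the ratio of
the observed to the reference log odds ratio for the same aligned effect
allele, `change = beta_obs / beta_clin` — the only definition consistent
with all three of its bin interpretations (amplified > 1, attenuated in
(0, 1), opposite direction < 0). Bins use a lower-closed boundary
convention (change exactly 1 → the 0–1 bin; exactly 0 → the opposite bin);
these are probability-zero events for continuous estimates.

P-values are two-sided Wald tests on the dosage coefficient (the Wald form
also furnishes the standard error the result schema needs; at these sample
sizes the LRT difference is negligible). Multiplicity is controlled per
scan with Benjamini–Hochberg FDR. Perfect separation, non-convergence, or
constant dosage yield flagged per-SNP results that are excluded from
q-values and summaries but kept in the output table; a scan fails only if
every SNP fails. The amplification sign test is the exact upper-tail
binomial probability P(X ≥ k), X ~ Binomial(n_fit, 1/2).

## PRS

Raw scores are fixed-weight dosage sums (no clumping, shrinkage, or
re-weighting). Standardization computes mean/sd once over the union of all
loaded samples — a single scope keeps the odds ratios of the three pairwise
contrasts on one scale, which their side-by-side interpretation
presupposes; a per-contrast scope is exposed as a sensitivity option.
Because z-scoring absorbs any positive rescaling of the weights, the OR per
SD is invariant to the overall scale of `beta_meta` (property-tested to
1e-6). APOE-free scores drop exactly the two APOE terms. Confidence
intervals are Wald on the log-odds scale.

## Power model

For a SNP with control effect-allele frequency `p0 = maf` and true allelic
log odds ratio `beta`, the case frequency is the odds-ratio inversion
`p1 = e^beta p0 / (1 + p0 (e^beta - 1))` and genotypes are Hardy–Weinberg
within each group. With expected genotype counts `w_yg = n_y · HWE_y(g)`,
the additive logistic likelihood-ratio statistic has approximate
non-centrality

    ncp = 2 [ L(b0*, b1*) - L0 ],

where `(b0*, b1*)` maximize the expected log-likelihood (a two-parameter
Newton iteration on the 2×3 expected table; for exact-HWE cells the
additive model reproduces the table and `b1*` equals the allelic log odds
ratio) and `L0` is the intercept-only likelihood at the design's fixed
case:control margin. Power is `P(chi²₁(ncp) > chi²₁ critical at alpha)`;
at `beta = 0` the non-centrality vanishes and the power equals the test
size exactly. Power is *not* symmetric in the sign of `beta` at fixed
`maf` — flipping the sign changes the implied case frequency and hence the
information; the exact invariance is the allele relabeling
(`maf → 1 − maf`, `beta → −beta`), which is property-tested. The same
Newton solver applied to observed multinomial genotype counts provides a
vectorized Monte-Carlo likelihood-ratio test, the independent oracle for
the analytic formula (agreement within 0.007 over a
maf × OR × sample-size grid at 20 000 replicates per cell).

Tables with no genotype variation (possible in Monte-Carlo draws at rare
alleles) collapse to the null fit, so their LRT is zero rather than NaN.

## Escalation and equivalence

`controls_needed` scans control counts 200, 400, … up to a cap of twice the
assumed case count (defaults: 8000 cases, alpha 0.05, target power 0.8) and
returns the first count reaching the target, or the cap as sentinel when
none does. The assumed per-arm effect is the *observed* log odds ratio from
the corresponding contrast, not the reference effect. Eligibility requires
`maf_ref > 1%` and an observed effect direction matching the reference in
both contrasts (the "either" reading of direction consistency is exposed as
an option). In the equivalence ratio the cap substitutes for a single
non-converged arm; SNPs converging in neither arm are excluded from all
summaries. The functional shortlist keeps SNPs with ratio > 2 (one
super-control worth more than two ordinary controls). Two-sided alpha is
used throughout, matching the Wald/LRT tests of the association stage.

## Synthetic-data generator

The generator is allelic with HWE inside each cohort, matching the additive
analysis model and keeping the truth analytically available: controls draw
at `maf_ref`; cases at the frequency whose allelic OR versus controls is
`exp(beta_clin) · case_or_multiplier`; centenarians at the frequency that
makes the case-vs-centenarian log OR equal `centenarian_change · beta_clin`
— i.e. the generator is parameterized directly through the statistic the
scan estimates, so recovery tests are self-calibrating. A null
configuration (all group frequencies equal) is expressed through the same
knobs: `case_or_multiplier = exp(-beta_clin)` per SNP and
`centenarian_change = 0`.

Default margins: 2281 cases / 3165 age-matched controls / 346 centenarians;
female fractions 55/48/71%; 971/2281 early-onset cases with onset ages
uniform within the early (≤ 65) and late windows — only the ≤ 65 dichotomy
matters downstream. PCs are standard normal and carry no group signal by
default (a homogeneous population); an optional confounding knob shifts PC1
by cohort (+δ cases, −δ centenarians) to exercise covariate adjustment.

The default 86-SNP panel is synthetic (no published supplementary table is
redistributed). Its two APOE SNPs are calibrated so the generator
reproduces realistic carrier fractions — e4 43/17/7% and e2 3/9/13% across
cases/controls/centenarians — via `maf_ref` 0.0890 / 0.0461, `beta_clin`
+1.1944 / −1.1463, and the exposed centenarian change factors 1.8192 /
1.3499. The remaining 84 SNPs draw MAFs of 0.05–0.5 (85%) or 0.01–0.05
(15%) with clinical ORs of 1.08–1.30 (common) or 1.25–1.9 (low-frequency),
mixed effect directions, and `beta_meta` a 0.6–0.9 attenuation of
`beta_clin` (proxy-phenotype dilution). These values were chosen once as
field-typical and are fixed.

What the generator does *not* emulate — and hence what passing tests do not
establish about real data: linkage disequilibrium between panel SNPs
(treated as independent loci, consistent with their use as independent GWAS
hits), age-dependent survival effects on allele frequencies, genotyping or
imputation error (dosages are exact hard calls), cohort-specific inclusion
biases, and any liability-scale architecture shared across SNPs. Recovery
of the change statistic and the PRS ordering on these data validates the
estimators, not the biological claims.

## Numerical and I/O choices

* Allele alignment is exact string matching in either orientation (swap ⇒
  dosage 2 − d); no reverse-complement rescue, because in a closed exchange
  silent strand flips are the dominant corruption risk. Unalignable SNPs
  are dropped loudly.
* Coordinates are 1-based (VCF convention). VCF output stores the effect
  allele as ALT with a DS FORMAT field; TSV dosage matrices are declared
  pre-aligned.
* Result tables are written with fixed `%.10g` float formatting, so
  identical inputs reproduce byte-identical files; the run manifest records
  the config, a config hash, the seed, and per-file sha256 checksums.
* The pipeline expands one global seed into independent per-stage
  substreams (`numpy.random.SeedSequence.spawn`), so toggling one stage
  does not perturb another's draws.
* Newton iterations for the expected-count logistic use analytic gradients
  and Hessians with a 1e-12 step tolerance; degenerate (singular) updates
  are zeroed, which collapses uninformative tables to the null.

## Problem sizes

The validation suite runs the Monte-Carlo power grid at 20 000 replicates
per cell, change-statistic recovery over 20 seeded replicates at the full
default cohort sizes, escalation checks against a dense step-1 grid oracle
over 50 random (maf, beta) draws, and type-I error over 200 replicate null
scans of a 12-SNP panel at 300/300/50 per cohort — sizes at which the
binomial/Monte-Carlo error bounds quoted in the tests are decisive.

## Known limitations

* The expected-LRT non-centrality is an asymptotic approximation; at very
  small control counts (first escalation steps) with rare alleles its error
  is largest, though still within the validated 0.02 band at the grid
  extremes tested.
* The change statistic divides by `beta_clin`; SNPs with near-zero
  reference effects have heavy-tailed change estimates, which is why scan
  summaries are median/IQR-based and the sign test is the inferential
  anchor.
* PRS contrasts assume the logistic model's linearity in the z-scored
  score; no calibration beyond PC adjustment is attempted.
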