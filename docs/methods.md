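# Methods

This note records the statistical conventions, default parameters and
design choices behind `crediblemap`, in the spirit of a model-description
appendix. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Synthetic cohorts

The generator produces the inputs the analysis chain consumes with the
statistical structure those analyses assume; it is not a demographic or
coalescent simulator.

**Haplotypes.** Each haplotype is a latent stationary Gaussian AR(1)
series with lag-1 correlation `ld_rho` ∈ [0, 1) and standard normal
marginals, thresholded per site at Φ⁻¹(1 − alt_freq) so that per-site
alternate-allele frequencies match the target in expectation while
adjacent-site allelic correlation increases monotonically with `ld_rho`.
This creates the multi-variant "shadow" associations that fine-mapping
must resolve, which is all the downstream methods require. It does not
produce realistic decay of LD with distance, recombination hotspots,
allele-frequency spectra, or population divergence; conclusions about
real-data performance should not be read off these simulations.

**Disease model.** Individuals are formed by drawing haplotype pairs with
replacement from the panel; case status is Bernoulli with
logit P(case) = logit(base_rate) + ln(OR)·g_causal + aᵀ·admixture, and
sampling continues until the case and control quotas are filled. A
logistic (rather than liability-threshold) model is used deliberately so
that the simulated per-allele odds ratio is exactly the estimand of the
downstream logistic regression — parameter-recovery tests then have an
exact target. Defaults: per-allele OR 1.35 (the middle of the 1.18–1.51
range typical of common autoimmune risk alleles), base rate 0.2–0.3 in
tests, missingness 0.02 completely at random. Admixture covariates are
drawn from a symmetric 4-component Dirichlet with the first three
components retained, mirroring the convention of using three of four
admixture proportions as stratification covariates. Case:control ratios
are configurable per ancestry; 1:1 is the default since typical ratios
vary by cohort and no single value is canonical.

Because individuals are drawn from a finite haplotype panel, two
individuals can share haplotypes; with panels much larger than the cohort
(the default is 8 haplotypes per sampled individual) this sharing is
negligible, and the null-calibration test sizes its panel accordingly.

**Bench-assay inputs.** The IFN panel draws NC samples from
N(μ_g, σ_g²) per gene and treated samples from the same law shifted by a
per-gene offset. T7EI band triples put (1−f) of the signal in the
substrate band and split f across the two cleavage products, with
multiplicative log-normal noise of a given coefficient of variation.

All generator randomness in a call flows from one integer seed through a
single `numpy.random.Generator`; identical configuration and seed give
bit-identical output.

## Quality control

Filter order follows the dependency between the rules: imputation-quality
filter → per-group MAF and variant call-rate filters → sample call-rate
filter (computed on surviving variants) → relatedness pruning. All
frequency/call-rate filters are strict `<` comparisons, so a variant or
sample sitting exactly at a threshold is kept. Defaults: MAF < 0.01 in
any group removes the variant; variant call rate < 0.90; sample call rate
< 0.95; imputation r² < 0.8 (imputed variants only, identified by a
non-missing r² score); π̂ > 0.4 flags duplicate/first-degree pairs.

The sample call-rate rule is sometimes stated in the literature with the
inequality inverted ("samples with genotyping rates > 95% were excluded"),
which as written would discard the best-genotyped samples; this package
implements the conventional direction and logs the threshold it applied.

**Relatedness.** π̂ = P(IBD=1)/2 + P(IBD=2) is estimated by method of
moments from IBS0/IBS1/IBS2 counts and study allele frequencies (the
standard GWAS-toolkit estimator, without finite-sample bias-correction
terms). Raw moment estimates are projected onto the probability simplex:
a pair whose raw P(IBD=0) exceeds 1 is called unrelated outright, negative
components are floored at zero, and the triple renormalized. Pairs with
fewer than 50 overlapping non-missing genotypes are flagged unreliable.
Pruning is greedy over pairs in descending π̂; the lower-call-rate member
of each pair is removed. The test suite checks the estimator against an
independent brute-force maximum-likelihood estimate of the IBD-state
proportions (grid search over the simplex on the per-site IBS likelihood)
at 20,000 markers, where the two agree within 0.02.

## Association

Per-variant logistic regressions are fitted by IRLS: at most 50
iterations, convergence when the largest coefficient update falls below
1e-8. Separation is detected as any |coefficient| exceeding 15 on the
log-odds scale during iteration; such fits are flagged unconverged and
carry no p-value rather than a silently unstable number. No Firth
correction is applied, keeping the estimand identical to a standard scan.
Missing genotypes are handled per variant by complete-case analysis (not
mean imputation), matching standard GWAS-toolkit behaviour; β is reported
per alternate allele as coded in the VCF. Two-sided p-values use the
normal reference for logistic Wald tests and the Student-t reference for
OLS eQTL slope tests; no genomic control is applied.

**Stepwise conditioning.** The scan's top variant — lowest p, ties broken
by lowest genomic position (a convention of this package) — is added as a
model covariate and the region re-scanned; iteration stops when no variant
remains below `p_stop` (default 1e-4). Variants with residual evidence in
the window 1e-4 < p < 1e-2 are reported at each step. Conditioning
genotypes are mean-imputed where missing so the complete-case sample does
not shrink with every step; a variant collinear with the conditioning set
(including a conditioned variant scanned against itself) is reported as
aliased and skipped.

**eQTL scans.** Ordinary least squares of expression on genotype over the
intersection of sample ids, with optional conditioning genotypes as
covariates. Constant-genotype fits are flagged non-estimable. The
conventional genome-wide reporting threshold for trans scans is p < 1e-4.

## Fine-mapping

The Wakefield approximate Bayes factor is used with prior effect variance
W = 0.04 (prior SD 0.2 on the log-odds scale), the de facto standard for
binary-trait fine-mapping. Where a published analysis computed Bayes
factors with tools whose priors are undocumented, results are comparable
in structure but not numerically identical; posterior probabilities are
only approximately invariant to W, so W is a configurable parameter and
its default is stated wherever output is written.

Posterior probabilities are computed with log-sum-exp, keeping Σ PP = 1
to 1e-12 even when log Bayes factors span hundreds of nats across
10,000-variant regions. The p-value route recovers z = Φ⁻¹(1 − p/2) from
log(p) (`scipy.special.ndtri_exp`), so p-values below the double
underflow limit (p < 1e-300, supplied as log p) never produce an infinite
z, and approximates V = 1/(2·N·MAF·(1−MAF)).

**Credible sets.** Variants are ranked by descending PP (ties broken by
input order) and accumulated until the cumulative PP reaches the level;
the set is therefore minimal by construction — removing its weakest
member drops below the level. An optional tie-inclusive mode adds every
variant tied with the boundary member, yielding a conservative superset;
it is off by default because minimality is the property downstream
consumers rely on. The single-causal-variant assumption is explicit: with
multiple causal variants in strong LD the credible set covers the leading
signal only, and multi-causal methods (stochastic search, LD-aware
fine-mapping) are out of scope. The trans-ancestral credible set for a
meta-analysis is computed from meta p-values via the p-value route, with
per-variant MAF averaged across contributing ancestries.

## Meta-analysis

The sample-size-weighted Z scheme only: zᵢ = Φ⁻¹(1 − pᵢ/2)·sign(effect),
Z = Σ wᵢzᵢ/√(Σ wᵢ²), wᵢ = √Nᵢ. Effect direction comes from the beta sign
when present, else an explicit direction column; p-only input without
direction is rejected because the signed scheme is meaningless without
it. The first study in which a variant appears fixes the reference allele
orientation; later studies are aligned by allele match, ref/alt swap
(sign flip) or strand complement. Palindromic A/T and C/G variants are
excluded by default since strand cannot be resolved without allele
frequencies (`keep_ambiguous` overrides, treating the alleles as given).
No heterogeneity statistics and no inverse-variance or random-effects
models are provided.

## Bench statistics

**IFN score.** Per gene: subtract the negative-control group's mean and
divide by its SD (sample SD, n−1 denominator; configurable since the
population convention is equally defensible and published descriptions
are often silent); sum the four standardized values per sample. All four
signature genes are standardized identically. The NC-group mean score is
0 by construction, and the score is invariant to affine rescaling of any
gene's raw units. At least two NC samples are required, and a zero NC SD
is an error naming the offending gene.

**T7EI efficiency.** The printed form of this assay's formula is often
typeset ambiguously; it is read here as the cleaved fraction
f = (b+c)/(a+b+c), the standard interpretation — the literal left-to-right
reading produces fractions outside [0, 1]. Efficiency = 100·(1 − √(1−f)),
which is strictly increasing in f, invariant to rescaling all bands by a
positive constant, and bounded in [0, 100]. Samples above 40% efficiency
are flagged usable.

**Fold enrichment.** Linear mode divides raw qPCR signals (ChIP target
over IgG; FAIRE over input). Ct mode computes efficiency^(Ct_control −
Ct_target) with amplification efficiency 2 by default; the two modes agree
on signals 2^(−Ct).

**Allelic imbalance.** Exact two-sided binomial test of ref vs alt read
counts against 0.5, using the minimum-likelihood definition of
two-sidedness (the p-value sums probabilities of all outcomes no more
likely than the one observed). This is a deliberately simple single-site
test; pipeline-level allelic-bias analysis with read-level filters is out
of scope.

## Pipeline and problem sizes

`run_pipeline` chains simulate → QC → scan → conditional → per-ancestry
fine-mapping → credible-set intersection → weighted-Z meta-analysis →
fine-mapping of the meta p-values, writing one TSV per stage with the
seed stamped in a header line, and is byte-identical across reruns with
the same configuration and seed. Defaults (4 ancestries × 500/500
samples × 60 variants) were chosen so a full replay takes under a second
while still exhibiting the cross-ancestry behaviour of interest; the
test suite uses replicate counts of 50–200 and cohorts up to 2,000/2,000
for parameter-recovery and calibration checks, sizes at which the
Monte-Carlo acceptance properties hold with margin. Relatedness pruning
is skipped by default inside the synthetic pipeline (individuals are
generated unrelated); it is enabled when QC-ing external data.

## Known limitations

- Single-causal fine-mapping only; no colocalization, no LD-matrix-based
  multi-signal methods.
- The LD model is first-order (adjacent-site correlation); long-range LD
  and realistic haplotype structure are not simulated, so calibration
  results on synthetic data bound, but do not establish, real-data
  behaviour.
- π̂ assumes Hardy-Weinberg proportions and a homogeneous sample when
  converting IBS to IBD; admixed samples inflate π̂ for unrelated pairs.
- Imputation itself (phasing, reference panels) is out of scope; only the
  post-imputation r² filter is implemented.
- No mixed models or genomic relatedness matrices; admixture proportions
  are taken as given covariates, never estimated.
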