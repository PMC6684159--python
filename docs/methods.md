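# Methods

`pleioaudit` quantifies the phenome-wide consequences of substituting a
single allele — the situation faced when a variant such as the CCR5Δ32
deletion is proposed as a gene-editing target — from public GWAS summary
statistics over a panel of binary disease phenotypes. This note documents
the statistical model, the estimators, the numerical choices, and what the
synthetic data used by the test suite does and does not establish.

## From observed-scale effects to odds ratios

Biobank-scale GWAS of binary traits are usually run as linear regressions of
the 0/1 disease indicator on allele dosage, giving an "observed-scale"
effect β_obs whose magnitude depends on disease prevalence K and is
therefore not comparable across diseases. When the variant explains a small
fraction of phenotypic variance, (β_obs, K, f) — with f the effect-allele
frequency — suffice to recover the allelic odds ratio. `scale.obs_beta_to_logor`
reconstructs the expected allele-by-status 2×2 table under Hardy–Weinberg
genotype frequencies and the linear risk model P(case | dose g) = μ + β_obs·g
with marginal prevalence K (so μ = K − 2f·β_obs). The per-allele case
probabilities are

    p1 = K + β_obs (1 − f),   p0 = K − β_obs f,

and log OR = log[p1(1−p0)] − log[p0(1−p1)]. This is exact for the expected
table (the unit tests verify ≥10-digit agreement with an independent
genotype-level reconstruction) and reduces to β_obs / (K(1−K)) for small
effects. The delta-method SE propagates se_obs through the analytic
derivative (1−f)/(p1(1−p1)) + f/(p0(1−p0)), which equals 1/(K(1−K)) at
β_obs = 0. Z scores are β_obs/se_obs on the observed scale, and GWAS
p-values are carried through unchanged; K is the marginal case fraction from
the manifest, never re-estimated. Effects whose implied p1 or p0 leave (0,1)
raise a domain error rather than being silently truncated.

## The effect-size mixture

Across n diseases the variant's Z scores are modeled as i.i.d. draws from

    π₋ N(−μZ, 1) + π₀ N(0, 1) + π₊ N(+μZ, 1),   μZ ≥ 0,

with unit component variances (the sampling variance of a Z score) and
weights on the simplex. π₊ is the proportion of diseases whose risk the
target allele truly raises; π₊ · n is the expected number of affected
diseases. Treating diseases as independent is a simplification — comorbidity
and shared etiology induce correlated Z scores, and the likelihood ignores
that.

**Why the fit is penalized.** The components overlap heavily when μZ is of
order 1, and at μZ = 0 the weights are entirely unidentified. In finite
samples the likelihood develops a ridge of spurious maxima on which π₀ → 0,
μ̂Z is small, and the "mixture" is just a slightly shifted normal; plain
maximum likelihood lands there for a substantial fraction of panel-sized
(n ≈ 131) samples, destroying the interpretability of the weights even
though the fitted density is fine. `SymmetricZMixture` therefore maximizes

    ℓ(π, μZ) + (null_bias − 1) · log π₀,

a Dirichlet pseudo-count on the null weight exactly as used by
adaptive-shrinkage effect-size mixture methods. The default `null_bias = 2`
(one pseudo-observation) is the minimal choice that makes the π₀ → 0
boundary inadmissible; its influence vanishes as O(1/n). Simulation at the
design scale (200 panels of n = 131 drawn from π = (0, 0.769, 0.231),
μZ = 1.003) recovers mean π̂₊ ≈ 0.25 and mean μ̂Z ≈ 1.13; the residual upward
dispersion of μ̂Z reflects genuine weak identifiability at this n, not an
optimizer artifact. The reported log-likelihood is always the unpenalized
one, and it never falls below the one-component N(0,1) null model (the null
is one of the EM starts and a fixed point of the iteration).

**Optimization.** EM with multiple restarts: the null model, a moment-based
start from the tail fractions beyond |z| = 1, and Dirichlet-random starts
(20 restarts by default, seeded). The M-step for the shared shift pools the
outer components, μ = (Σr₊z − Σr₋z)/(Σr₊ + Σr₋), clamped to a 1e−6 floor to
stay off the μ = 0 ridge. Convergence is a per-iteration objective gain
below `tol` (1e−8); the iteration cap is 10000 because EM is sublinear on
the flat ridge. Weights within 1e−6 of the simplex boundary are snapped for
reporting (hence exact zeros in output). Fits are deterministic given the
seed.

**Bootstrap.** Nonparametric case resampling (same n, default B = 1000),
each replicate refit by EM warm-started just inside the simplex at the point
estimate. Reported per quantity: the standard deviation across replicates
(bootstrap SE) and a two-sided Wald p-value 2Φ(−|θ̂|/se) against θ = 0, with
p = 1 reported for estimates exactly at 0. Besides the four parameters, the
mixture mean shift (π₊−π₋)·μZ is summarized: it is the smooth functional
that carries the directional signal, and its bootstrap SE scales as 1/√n
even at sizes where μ̂Z alone is non-regular (its SE shrinks much more
slowly). Wald p-values from a bootstrap SE are a convention, not an exact
tail probability; at panel scale the SEs on π̂₊ are large (≈ 0.17 in the
README example) and single-panel point estimates should be read accordingly.

## Enrichment summaries

Direction counts classify diseases by the sign of the fitted log OR,
regardless of significance. The symmetry of the signed log ORs around zero
is tested with the one-sample Wilcoxon signed-rank test (zeros dropped, ties
average-ranked, normal approximation with ±0.5 continuity correction,
two-sided). The normal approximation tracks the exact 2ⁿ permutation
distribution to about two significant figures when the exact p ≥ 0.05; in
the far tail at small n the exact null is too discrete for any continuous
approximation, so only the rejection decision is meaningful there. Whether
the test is applied to ORs, log ORs or Z scores changes magnitudes but not
signs; this package applies it to log ORs. FDR labeling is
Benjamini–Hochberg step-up at q = 0.05 over the analyzed disease set, with
an option to include externally derived p-values (e.g. a disease studied
outside the biobank) in the FDR set only. QQ coordinates use the
−log10((i − ½)/m) expected quantiles; no genomic-control λ is computed.

## Genotype-table odds ratios

For published case/control genotype counts, the per-allele OR is estimated
by maximum-likelihood logistic regression of status on allele dose
g ∈ {0, 1, 2} using the grouped counts (binomial GLM). Additive dose coding
matches the "per-substitution" interpretation; empty genotype classes are
simply absent rows, so a table with zero variant homozygote cases — the
signature of a strongly protective allele — remains estimable. Complete
separation along the dose gradient is detected and surfaced as an error; a
hand-implemented Jeffreys-penalized (Firth) fit is available as the
separation-robust option. Wald p-values and normal-theory 95% CIs on the log
scale accompany the OR. The allele-counting 2×2 collapse (homozygotes
contribute two alleles) is provided as a cross-check; under HWE it agrees
with the dose model to within ~2% on non-degenerate tables.

## Pleiotropy counts

Pleiotropy is measured PheWAS-style: for each SNP, the number of phenotypes
with association p strictly below 5×10⁻⁴ across a SNP × phenotype p-value
matrix; missing entries never count. Background summaries are the mean and
median count over all SNPs and over the common stratum (MAF strictly above
0.3). Disease locus sets — each locus operationalized as its reported lead
SNP, with no LD clumping — are summarized by the mean and standard error
(sd/√k) of their members' counts and flagged when the set mean strictly
exceeds the genome mean. The published genome-wide background values for
this statistic come from a full biobank GWAS release at terabyte scale and
are not reproducible at desk scale; the counter is instead validated by
brute-force oracle equivalence and binomial calibration on synthetic
matrices.

## Synthetic data: what it emulates and what it does not

`synthetic.gen_phenotype_panel` emulates the summary statistics of one
variant GWASed across a curated panel: 131 phenotypes, a 361,194-sample
cohort, effect-allele frequency 0.092, prevalences uniform on (0.003, 0.2)
(floor = the 1000-case curation threshold over the cohort; ceiling typical
of common curated diseases). The observed-scale SE follows the
linear-dosage design, se = √(K(1−K)/(n·2f(1−f))); the true standardized
effect is drawn from the mixture (defaults (0, 0.769, 0.231, 1.003)) and
β_obs = Z·se, so the GWAS sampling noise is embodied in the unit component
variance. Not emulated: covariate adjustment (absorbed into the SE),
imputation uncertainty, LD between variants, correlation between diseases,
case/control overlap across phenotypes. Passing recovery tests on these
panels therefore demonstrates the estimator's behavior under the stated
sampling model, not robustness to the correlation structure of real biobank
panels. `gen_pvalue_matrix` draws each SNP × phenotype entry as associated
with a controllable rate (p uniform below the threshold) or null (uniform
above), with optional enriched locus sets; `gen_genotype_table` draws
multinomial genotype counts with HWE controls and case probabilities tilted
by OR^dose. All generators are bit-reproducible given their seed.

## Pipeline and reproducibility

`pipeline.run_audit` chains ingest → orientation to the target allele →
curation filter (≥1000 cases) → scale transform → mixture fit + bootstrap →
enrichment report, writing TSV/JSON only. Analytical outputs contain no
timestamps and embed the seed and a configuration hash, so reruns with the
same configuration are byte-identical. All randomness flows through
explicit seeds.

## Known limitations

- Independence of diseases is assumed throughout the likelihood and the
  signed-rank test; both overstate precision under positive correlation.
- π̂₊ and μ̂Z are weakly identified at n ≈ 131: single-panel point estimates
  are dispersed (bootstrap SEs ≈ 0.1–0.2) even though panel-averaged
  recovery is accurate. The mean shift (π₊−π₋)μZ is the well-identified
  summary.
- The scale transformation assumes the variant explains a small fraction of
  variance and HWE at the locus; it is exact only for the expected table.
- The null-weight pseudo-count introduces an O(1/n) shrinkage toward the
  null; with very small panels (n ≲ 20) it is material.
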