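# Methods

## Grantham distance and HED

The amino-acid distance is
D(i,j) = ρ·[α(cᵢ−cⱼ)² + β(pᵢ−pⱼ)² + γ(vᵢ−vⱼ)²]^½ over side-chain
composition (c), polarity (p) and molecular volume (v), with the classic
weights α=1.833, β=0.1018, γ=0.000399. The property table and weights are
embedded as a versioned fixture so no network access is needed.

**Scale factor ρ.** The constant usually quoted for this metric, 50.723,
does *not* reproduce the classic integer table when the formula is
re-evaluated at full precision: it yields W↔C = 214.36, which rounds to
214 rather than the published 215. Calibrating ρ so the mean over the 190
unordered residue pairs is exactly 100 (ρ ≈ 50.78988) reproduces both
landmark entries (D(L,I)=5, D(W,C)=215, the matrix maximum) and is
therefore the package default. Any ρ can be supplied via
`GranthamParams(rho=...)`, and `calibrate_rho()` exposes the calibration.
Two matrix modes exist: `published-integer` (default; continuous value
rounded half-up, matching the table historically used for HED) and
`continuous` for sensitivity analysis.

**HED.** For one locus, HED is the mean per-site distance between the two
allele protein sequences over the concatenated exon-2 (≈90 aa) and exon-3
(≈92 aa) segments — the variable peptide-binding region. Alleles are
resolved at two-field resolution (`B*15:01:01:02N` → `B*15:01`);
intra-two-field protein variation is ignored because the analysis operates
at genotype resolution. Homozygosity means identical two-field names, and
a homozygous locus scores 0 without a sequence lookup; sequence-identical
but differently named alleles count as heterozygous with HED 0. Sites
where either sequence carries an alignment gap are excluded from both the
numerator and the denominator, with a warning when more than 5% of sites
drop out. Mean HED is the arithmetic mean of the three locus values,
including homozygous zeros — the natural reading of "mean divergence at
HLA-A, HLA-B and HLA-C"; computing it over heterozygous loci only is a
plausible alternative the package deliberately does not adopt.

## Somatic features

A somatic SNV counts toward TMB iff it is exonic, nonsynonymous or
stopgain, covered at depth ≥ 40, has sample variant-allele fraction
≥ 0.03, and has population allele frequency ≤ 0.002 in every database
(ExAC, gnomAD, 1000 Genomes) where a value is present. All five boundaries
are inclusive. The two "allele frequency" filters are distinct: one is the
sample VAF, the other the population AF. A missing population frequency
means "not observed" and passes that sub-filter — the usual annotation
convention. The passing set is a pure conjunction (order-independent); the
per-filter rejection tally attributes each rejected record to the first
failing predicate in the documented order (region, effect, depth, VAF,
population AF). TMB = passing count × 10⁶ / callable bases, where callable
means exonic positions at ≥ 40×. Indels are excluded. CNA burden counts
genes with a gain or loss call; the MSI call is MSI-H iff ≥ 2 of the five
PCR loci (BAT-25, BAT-26, D2S123, D5S346, D17S250) are unstable. DCB means
CR, PR, or SD lasting ≥ 24 weeks (inclusive).

## Cutpoints and group tests

`maxstat_cutpoint` scans every distinct marker value whose split
(value > c vs ≤ c) leaves at least ⌈minprop·n⌉ patients per side
(minprop default 0.1, the convention of the standard cutpoint tools) and
returns the candidate maximizing the standardized log-rank |Z|, breaking
ties toward the smallest candidate. No selection-adjusted p-value is
attached: the cutpoint is used for stratification, with significance
assessed downstream by KM/log-rank/Cox. Note that maximally selected
statistics drift toward the admissible boundary on strongly separated
data; minprop is the only guard, by design.

`youden_cutpoint` maximizes J = sensitivity + specificity − 1 over the
distinct observed scores, calling positive when the score is strictly
above the threshold. Higher score is assumed to predict the positive
outcome; if the empirical AUC is below 0.5 the direction flips with a
warning (disable with `auto_flip=False`).

Joint HED×TMB groups use strict inequalities: a value equal to the
cutpoint is "low". DCB contrasts use the two-sided Fisher exact test
(hypergeometric enumeration; note that in a perfectly separated 2×2 table
both extreme tables are equally probable, so the two-sided p is twice the
single-tail mass) or the Pearson chi-square without continuity correction;
`method="auto"` picks Fisher when any expected cell is below 5. Spearman
correlations use midranks with the t-approximation p-value. Per-gene
mutation-frequency comparisons are per-gene Fisher tests with no
multiplicity adjustment, matching the convention of reporting unadjusted
p < 0.2 / p < 0.05 tiers. Kruskal–Wallis handles the all-identical
degenerate case as H = 0, p = 1.

## Survival

Time is months; event = 1 is death/progression. KM is the product-limit
estimator with Greenwood variance; the median is the first time S(t) ≤ 0.5
(NaN if never reached, no CI by default). Log-rank is the
observed-minus-expected chi-square with hypergeometric variance (df 1).
Cox PH uses Efron tie handling (better small-sample behavior than Breslow)
via lifelines, with Wald 95% CIs; constant covariates and fits with fewer
events than covariates + 1 are rejected up front. The cutpoint scan's
internal standardized Z is an independent in-package implementation, so
the squared-Z/log-rank identity can be (and is) cross-checked between the
two code paths.

## Expression

Counts are assumed background-subtracted. RPM = counts × 10⁶ / sample
total over the panel. The housekeeping ratio uses **geometric** means
(robust to one dominant housekeeping gene; arithmetic means are the
undocumented alternative): ratio = geomean(control HK RPM) /
geomean(sample HK RPM), so after scaling each sample's housekeeping
geometric mean equals the control's exactly. Zero housekeeping values are
excluded from the geometric mean with a warning. The log layer is
log2(nRPM + 1); the pseudocount of 1 keeps zeros at zero.

Differential expression defaults to a moderated t: per-gene pooled
variances are shrunk toward a scaled inverse-chi-square prior fitted by
moment matching on the log variances (the prior degrees of freedom come
from inverting the trigamma function; infinite prior df degenerates to a
common variance and a normal reference). The simpler Welch t is available
because the exact prior of any particular external fit is not
reproducible. A gene passes iff |log2FC| > 0.5849 — log2 of a 1.5-fold
change, truncated at four decimals — **and** raw p < 0.05; no multiplicity
adjustment at this step. Over-representation of the passing genes in
user-supplied GMT sets uses the upper hypergeometric tail with
Benjamini–Hochberg adjustment across sets; bundling a pathway database is
out of scope, so sets are always user-supplied.

## Synthetic cohorts

The generator's defaults mirror the study conditions: 84 patients, tumor
profiling for the first 76, marker cutpoints 8.61 (HLA-B HED) and
5.22 mut/Mb (TMB). Per locus it derives an allele pool from an ancestral
182-aa binding region by random substitutions, rescaling the substitution
count until the realized mean pairwise divergence is within ±20% of the
target (defaults 6.5 / 9.0 / 3.0 for A/B/C, ordered like the observed
locus divergences; HLA-C lowest). Homozygosity rates default to
0.12/0.07/0.15. Survival is exponential proportional hazards
(baseline 0.05/month, log-HR −log 2 for each of HED-high and TMB-high,
exponential censoring at 0.02/month ⇒ roughly a quarter to a third
censored); PFS uses a doubled hazard. DCB is logistic on the same flags
(intercept −0.85 ⇒ ~30% benefit at both-low). Per-sample TMB is lognormal
(median 4.5 mut/Mb, σ = 0.8 — half the cohort lands near the 5.22 cut);
passing variant counts are Poisson at TMB × callable/10⁶ with callable
bases near 2 Mb, and each filter branch receives a configured fraction of
deliberately failing records so the cascade is always exercised.
Population AFs have a point mass at "missing" plus a tail crossing 0.002.
Expression is gamma-Poisson (negative binomial, dispersion 0.15) over
1–2 M reads/sample with flat high housekeeping genes and a 10% fraction of
panel genes up-regulated 1.5–3× in the HED-high group (up-only, matching
the inflamed-phenotype structure). Everything flows from a single
`default_rng(seed)`; a fixed seed gives byte-identical files.

What the generator does **not** emulate: real HLA allele/haplotype
frequencies and linkage, locus-specific sequence constraints, indels and
CNV segmentation noise, batch effects in the panel counts, or correlated
censoring. Passing tests therefore demonstrate correctness of the
computational chain under the stated generative model, not clinical
validity on real cohorts — in particular the study's cohort-level numbers
(cutpoints 8.61/5.22, published hazard ratios and correlations) depend on
the deposited patient data, which are controlled-access; the pipeline
reproduces them only when pointed at those tables.

## Problem sizes and numerical choices

Simulation studies in the tests and the acceptance script use: Cox
recovery with 3 cohorts of n=500 (true HR 2, ~30% censoring); log-rank
null calibration with 2,000 replicates at n=84; cutpoint-oracle
equivalence on 50 random cohorts with n ∈ [30, 200]; expression power on
300 true and 700 null genes at 25 samples/group with σ = 0.5 on the log2
scale. These sizes give stable estimates at interactive runtimes.
Convergence and ties: Cox stops on lifelines' default relative-likelihood
criterion; cutpoint ties break toward the smallest candidate; rounding in
the integer matrix is half-up; HED brute-force equivalence is asserted to
1e−12 and normalization identities to 1e−9.

## Known limitations

No HLA genotyping from reads, no class II, no neoantigen prediction (TNB
is consumed as a column), no CNV calling, no time-dependent ROC or
bootstrap cutpoint CIs, no pathway-topology analysis. The maxstat scan
reports the maximizing split without a selection-corrected p-value, and
the moderated-t prior is fitted per run rather than imported from any
external fit.
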