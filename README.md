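# hedstrat

Biomarker analysis of **germline HLA class I evolutionary divergence (HED)**
for immune-checkpoint-blockade (ICB) cohorts, with a focus on
gastrointestinal cancer.

Patients inherit two alleles at each HLA class I locus (HLA-A, -B, -C).
The more physicochemically divergent the two alleles are across the
peptide-binding region, the broader the repertoire of tumor peptides they
can present to cytotoxic T cells — which is why HED has been proposed as a
germline determinant of ICB response. This package implements that analysis
chain end to end:

- **Grantham distance matrix** built from first principles. For residues
  *i*, *j* with side-chain composition *c*, polarity *p* and molecular
  volume *v*:

  D(i,j) = ρ·[α(cᵢ−cⱼ)² + β(pᵢ−pⱼ)² + γ(vᵢ−vⱼ)²]^½,

  with α=1.833, β=0.1018, γ=0.000399 and ρ calibrated so the mean over the
  190 residue pairs is 100. The default "published-integer" mode rounds to
  the classic integer table (D(L,I)=5, max D(W,C)=215).
- **HED**: mean per-site Grantham distance between a patient's two allele
  sequences over the concatenated exon-2/exon-3 protein segments (the
  peptide-binding groove); 0 for homozygotes; mean HED averages the three
  loci.
- **Tumor genomic features**: TMB (filtered nonsynonymous/stopgain SNVs per
  megabase of ≥40× exonic sequence, with the depth ≥ 40 / VAF ≥ 0.03 /
  population-AF ≤ 0.002 filter cascade), gene-level CNA burden, and the
  five-locus PCR MSI call (MSI-H iff ≥ 2 unstable loci).
- **Stratification**: maximally-selected-rank-statistics cutpoints for
  survival markers, Youden-index cutpoint for durable clinical benefit
  (DCB: CR/PR or SD ≥ 24 weeks), and the joint HED×TMB grouping
  (both high / single high / both low with strict `>` cutoffs, defaults
  8.61 and 5.22 mut/Mb).
- **Survival analysis**: Kaplan–Meier, log-rank and multivariable Cox PH
  (via lifelines), plus contingency, Spearman, Kruskal–Wallis and per-gene
  mutation-frequency tests.
- **Immune-panel expression**: RPM → housekeeping-ratio normalization
  against an internal control → log2, moderated-t differential expression
  (|log2FC| > 0.5849, p < 0.05) and hypergeometric gene-set
  over-representation with BH adjustment.
- **Synthetic cohort generator**: a reproducible bundle with the same
  structure as the real inputs (84 patients, tumor profiling for 76,
  395-gene panel with 10 housekeeping genes), with survival hazards,
  benefit rates, variant tables and expression tied to the marker groups.

## Worked example

```
$ hedstrat simulate --out-dir cohort --seed 1
wrote synthetic bundle to cohort
$ hedstrat run --input-dir cohort --out-dir out
hed: ok
features: ok
stratify: ok
survive: ok
deg: ok
```

`out/report.json` from this run contains (excerpt):

```
"youden_tmb": {"threshold": 3.036, "j": 0.4056, "sensitivity": 0.85, "specificity": 0.556}
"dcb_by_hed_b": {"table": [[20, 3], [25, 36]], "method": "chi2", "p": 0.000165}
"cox_os": {"hed_b_high": {"hr": 0.848, ...}, "tmb_high": {"hr": 0.592, ...}}
"deg": {"n_genes": 395, "n_pass": 39}
```

Reading: dichotomizing this synthetic cohort by HLA-B HED puts 20/23
benefiting patients in the high group versus 25/61 in the low group
(chi-square p = 1.7e-4); the Youden scan places the TMB threshold at
3.04 mut/Mb for this replicate; the Cox hazard ratios below 1 reflect the
protective marker effects built into the generator; 39 of 395 panel genes
pass the differential-expression thresholds. Stage tables (HED profiles,
TMB, KM curves, DEG, ORA, ...) are written next to the report as TSV.

The same is available as a library:

```python
from hedstrat import build_grantham_matrix, grantham_distance
m = build_grantham_matrix()            # published-integer mode
grantham_distance("L", "I", m)         # 5.0
grantham_distance("W", "C", m)         # 215.0 (the matrix maximum)
```

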