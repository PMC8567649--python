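"""End-to-end orchestration: load a cohort input bundle, compute HED
profiles and tumor features, stratify, run the survival and expression
analyses, and write a machine-readable run report.

Every stage writes its table(s) under the output directory and appends a
status entry (row counts, key results) to ``report.json``.  The report
echoes the effective configuration so a run is reproducible from the
report alone; it contains no timestamps, so re-running an identical
bundle yields byte-identical output.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import pandas as pd

from . import expression, hed, somatic, stratify, survival
from .config import AnalysisConfig
from .errors import DegenerateInputError, HedstratError, InputError
from .grantham import build_grantham_matrix

REQUIRED_INPUTS = {
    "alleles.fasta": "allele protein FASTA (header = allele name)",
    "exon_annotation.tsv": "locus, exon, start, end (1-based inclusive)",
    "genotypes.tsv": "patient_id, A1, A2, B1, B2, C1, C2",
    "clinical.tsv": ("patient_id, os_months, os_event, pfs_months, pfs_event, "
                     "response, sd_duration_weeks, msi_status, tnb"),
    "variants.tsv": "sample_id, gene, region_class, effect, depth, vaf, pop_af_*",
    "callable.tsv": "sample_id, callable_bases",
    "cna.tsv": "sample_id, gene, state",
    "msi.tsv": "sample_id plus one column per panel locus",
}

OPTIONAL_INPUTS = ("counts.tsv", "control_profile.tsv", "hk_genes.txt",
                   "gene_sets.gmt", "driver_mutations.tsv")


def check_inputs(input_dir: Path) -> None:
    missing = [(name, schema) for name, schema in REQUIRED_INPUTS.items()
               if not (input_dir / name).exists()]
    if missing:
        lines = "; ".join(f"{name} ({schema})" for name, schema in missing)
        raise InputError(f"missing required input(s) in {input_dir}: {lines}")


def run_pipeline(config: AnalysisConfig, input_dir, out_dir) -> dict:
    """Run every stage; returns the report dict (also written as JSON)."""
    input_dir, out_dir = Path(input_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    check_inputs(input_dir)
    report: dict = {"config": config.to_dict(), "input_dir": str(input_dir),
                    "stages": {}}

    def stage(name: str):
        def mark(status: str, **info):
            report["stages"][name] = {"status": status, **info}
        return mark

    matrix = build_grantham_matrix(mode=config.matrix_mode)
    matrix.to_tsv(out_dir / "grantham_matrix.tsv")

    # --- HED profiles -------------------------------------------------
    mark = stage("hed")
    library = hed.load_allele_library(input_dir / "alleles.fasta",
                                      input_dir / "exon_annotation.tsv")
    genotypes = hed.read_genotypes(input_dir / "genotypes.tsv")
    profiles = hed.profile_cohort(genotypes, library, matrix)
    profiles.to_csv(out_dir / "hed_profiles.tsv", sep="\t", index=False)
    mark("ok", n_patients=len(profiles), n_alleles=len(library))

    # --- tumor features -----------------------------------------------
    mark = stage("features")
    variants = pd.read_csv(input_dir / "variants.tsv", sep="\t")
    callable_summary = pd.read_csv(input_dir / "callable.tsv", sep="\t")
    _, tally = somatic.filter_somatic_snvs(variants)
    tmb_table = somatic.compute_tmb_table(variants, callable_summary)
    tmb_table.to_csv(out_dir / "tmb.tsv", sep="\t", index=False)
    cna_burden = somatic.compute_cna_burden(pd.read_csv(input_dir / "cna.tsv", sep="\t"))
    cna_burden.to_csv(out_dir / "cna_burden.tsv", sep="\t", index=False)
    msi_calls = somatic.call_msi_table(pd.read_csv(input_dir / "msi.tsv", sep="\t"))
    msi_calls.to_csv(out_dir / "msi_calls.tsv", sep="\t", index=False)
    mark("ok", n_variants=int(len(variants)), filter_tally=tally,
         n_tumor_samples=int(len(tmb_table)))

    # --- cohort table --------------------------------------------------
    clinical = pd.read_csv(input_dir / "clinical.tsv", sep="\t")
    clinical["dcb"] = somatic.derive_dcb_table(clinical)
    # the PCR-panel call supersedes any clinical-table MSI annotation
    clinical = clinical.rename(columns={"msi_status": "msi_status_clinical"})
    cohort = (clinical.merge(profiles, on="patient_id", how="left")
              .merge(tmb_table.rename(columns={"sample_id": "patient_id"}),
                     on="patient_id", how="left")
              .merge(cna_burden.rename(columns={"sample_id": "patient_id"}),
                     on="patient_id", how="left")
              .merge(msi_calls.rename(columns={"sample_id": "patient_id"}),
                     on="patient_id", how="left"))
    cohort.to_csv(out_dir / "cohort.tsv", sep="\t", index=False)

    # --- stratification -----------------------------------------------
    mark = stage("stratify")
    cutpoints = {}
    for locus, col in (("A", "hed_a"), ("B", "hed_b"), ("C", "hed_c"),
                       ("mean", "mean_hed")):
        try:
            res = stratify.maxstat_cutpoint(cohort[col], cohort["os_months"],
                                            cohort["os_event"],
                                            minprop=config.minprop, variable=col)
            cutpoints[locus] = {"cutpoint": res.cutpoint, "abs_z": res.statistic,
                                "n_high": res.n_high, "n_low": res.n_low}
        except DegenerateInputError as exc:
            cutpoints[locus] = {"error": str(exc)}
    tumor = cohort[cohort["tmb"].notna()].copy()
    youden = stratify.youden_cutpoint(tumor["tmb"], (tumor["dcb"] == "DCB").astype(int))
    tumor["joint_group"] = stratify.assign_joint_groups(
        tumor, hed_col="hed_b", tmb_col="tmb",
        hed_cut=config.hed_cuts["B"], tmb_cut=config.tmb_cut)
    tumor[["patient_id", "joint_group"]].to_csv(out_dir / "joint_groups.tsv",
                                                sep="\t", index=False)
    hed_b_group = hed.dichotomize(cohort["hed_b"], config.hed_cuts["B"])
    dcb_test = stratify.dcb_contingency_test(hed_b_group, cohort["dcb"], method="auto")
    bh = tumor[tumor["joint_group"] == "both_high"]
    bl = tumor[tumor["joint_group"] == "both_low"]
    joint_test = None
    if len(bh) and len(bl):
        sub = pd.concat([bh, bl])
        joint_test = stratify.dcb_contingency_test(
            sub["joint_group"].astype(str), sub["dcb"], method="fisher")
    correlations = {}
    het_b = tumor[tumor["het_b"] == True]  # noqa: E712 (column is boolean)
    for msi_group in ("MSI-H", "MSS"):
        sub = het_b[het_b["msi_status"] == msi_group]
        for feat in ("tmb", "cna_burden", "tnb"):
            key = f"hed_b_vs_{feat}_{msi_group}"
            try:
                a = stratify.spearman_assoc(sub["hed_b"], sub[feat])
                correlations[key] = {"rho": a.rho, "p": a.p, "n": a.n}
            except (InputError, DegenerateInputError) as exc:
                correlations[key] = {"error": str(exc)}
    gene_comparison = None
    driver_path = input_dir / "driver_mutations.tsv"
    if driver_path.exists():
        flags = pd.read_csv(driver_path, sep="\t", index_col="gene")
        labels = hed.dichotomize(
            cohort.set_index("patient_id")["hed_b"], config.hed_cuts["B"])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gene_comparison = stratify.compare_driver_genes(flags, labels.astype(str))
        gene_comparison.to_csv(out_dir / "driver_gene_comparison.tsv",
                               sep="\t", index=False)
    kw = stratify.kruskal_test(
        *[cohort.loc[cohort[f"het_{l}"], f"hed_{l}"].to_numpy()
          for l in ("a", "b", "c")])
    mark("ok", maxstat_cutpoints=cutpoints,
         youden_tmb={"threshold": youden.threshold, "j": youden.youden_j,
                     "sensitivity": youden.sensitivity,
                     "specificity": youden.specificity},
         dcb_by_hed_b={"table": dcb_test.table, "method": dcb_test.method,
                       "p": dcb_test.p, "proportions": dcb_test.proportions},
         dcb_both_high_vs_both_low=(
             None if joint_test is None else
             {"table": joint_test.table, "p": joint_test.p}),
         spearman=correlations,
         kruskal_het_hed={"h": kw.statistic, "df": kw.df, "p": kw.p})

    # --- survival ------------------------------------------------------
    mark = stage("survive")
    surv_info = {}
    km_rows = []
    for endpoint, (tcol, ecol) in (("os", ("os_months", "os_event")),
                                   ("pfs", ("pfs_months", "pfs_event"))):
        sub = cohort[cohort[tcol].notna()]
        grp = hed.dichotomize(sub["hed_b"], config.hed_cuts["B"])
        high = grp == "high"
        lr = survival.logrank_test(sub.loc[high, tcol], sub.loc[high, ecol],
                                   sub.loc[~high, tcol], sub.loc[~high, ecol])
        for label, m in (("high", high), ("low", ~high)):
            est = survival.km_fit(sub.loc[m, tcol], sub.loc[m, ecol])
            frame = survival.km_curve_frame(est)
            frame.insert(0, "endpoint", endpoint)
            frame.insert(1, "hed_b_group", label)
            km_rows.append(frame)
            surv_info[f"{endpoint}_median_{label}"] = est.median
        surv_info[f"{endpoint}_logrank_p"] = lr.p
    pd.concat(km_rows).to_csv(out_dir / "km_curves.tsv", sep="\t", index=False)
    cox_sub = tumor[tumor["os_months"].notna() & tumor["msi_status"].notna()].copy()
    covariates = pd.DataFrame({
        "hed_b_high": (cox_sub["hed_b"] > config.hed_cuts["B"]).astype(int),
        "tmb_high": (cox_sub["tmb"] > config.tmb_cut).astype(int),
        "msi_h": (cox_sub["msi_status"] == "MSI-H").astype(int),
    })
    try:
        cox = survival.cox_fit(covariates, cox_sub["os_months"], cox_sub["os_event"])
        survival.forest_table(cox).to_csv(out_dir / "cox_forest.tsv",
                                          sep="\t", index=False)
        surv_info["cox_os"] = {
            row.covariate: {"hr": row.hr, "ci": [row.ci_low, row.ci_high], "p": row.p}
            for row in cox.summary.itertuples()}
    except HedstratError as exc:
        surv_info["cox_os"] = {"error": str(exc)}
    mark("ok", **surv_info)

    # --- expression ----------------------------------------------------
    mark = stage("deg")
    counts_path = input_dir / "counts.tsv"
    if not counts_path.exists():
        mark("skipped", reason="no counts.tsv in input bundle")
    else:
        counts = pd.read_csv(counts_path, sep="\t", index_col="gene")
        hk_genes = [l.strip() for l in
                    (input_dir / "hk_genes.txt").read_text().splitlines() if l.strip()]
        control = pd.read_csv(input_dir / "control_profile.tsv", sep="\t",
                              index_col="gene")["rpm"]
        rpm = expression.rpm_normalize(counts)
        nrpm = expression.hk_normalize(rpm, hk_genes, control)
        logm = expression.log_transform(nrpm)
        labels = hed.dichotomize(
            cohort.set_index("patient_id")["hed_b"], config.hed_cuts["B"]).astype(str)
        deg = expression.differential_expression(
            logm, labels, method=config.deg_method,
            lfc_threshold=config.deg_lfc, p_threshold=config.deg_p)
        deg.table.to_csv(out_dir / "deg.tsv", sep="\t", index=False)
        deg_info = {"n_genes": int(len(deg.table)),
                    "n_pass": int(deg.table["passes"].sum()),
                    "method": deg.method}
        gmt_path = input_dir / "gene_sets.gmt"
        if gmt_path.exists():
            sets = expression.read_gmt(gmt_path)
            deg_genes = deg.table.loc[deg.table["passes"], "gene"]
            ora = expression.ora_test(deg_genes, counts.index, sets)
            ora.to_csv(out_dir / "ora.tsv", sep="\t", index=False)
            deg_info["n_sets_tested"] = int(len(ora))
        mark("ok", **deg_info)

    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=float)
    return report
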