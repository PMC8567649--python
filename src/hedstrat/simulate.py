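"""Synthetic cohort generator.

Produces a complete, reproducible input bundle with the statistical
structure the downstream analyses assume: an HLA allele library with
tunable per-locus divergence, per-patient genotypes with configurable
homozygosity, survival times whose hazard depends on the HED-high and
TMB-high flags (exponential baseline, proportional hazards), durable
clinical benefit from a logistic model on the same flags, somatic variant
tables that exercise every filter branch, gene-level CNA calls, the
five-locus MSI panel, and a negative-binomial immune-panel count matrix
with stable housekeeping genes and a configurable up-regulated fraction
in the HED-high group.

The default shape mirrors the study conditions: 84 patients with
germline genotypes, tumor profiling for 76 of them, a 395-gene panel with
10 housekeeping genes, marker cutpoints 8.61 (HLA-B HED) and 5.22 mut/Mb
(TMB), and protective hazard ratios for both marker-high flags.  All
randomness flows from one integer seed through ``numpy.random.default_rng``;
a fixed seed yields byte-identical files.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .grantham import RESIDUES, build_grantham_matrix
from .hed import (AlleleName, AlleleSequence, GenotypeRecord, pairwise_hed,
                  profile_cohort)
from .somatic import MSI_LOCI

# full-protein layout used for every synthetic allele: a leader peptide,
# then exon 2 (90 aa) + exon 3 (92 aa) forming the 182-aa binding region,
# then a C-terminal remainder.
LEADER_LEN = 24
EXON2_LEN = 90
EXON3_LEN = 92
PBR_LEN = EXON2_LEN + EXON3_LEN
TAIL_LEN = 140

DRIVER_GENES = ("TP53", "KMT2D", "ARID1A", "NOTCH1", "PIK3CA", "SMAD4",
                "KRAS", "APC", "ERBB2", "CDKN2A")
#: mutation probability in the HED-low vs HED-high group
DRIVER_PREVALENCE = {
    "TP53": (0.55, 0.30), "KMT2D": (0.30, 0.05), "ARID1A": (0.28, 0.10),
    "NOTCH1": (0.20, 0.05), "PIK3CA": (0.18, 0.15), "SMAD4": (0.15, 0.12),
    "KRAS": (0.30, 0.28), "APC": (0.25, 0.22), "ERBB2": (0.10, 0.10),
    "CDKN2A": (0.12, 0.10),
}


@dataclass
class SimulationConfig:
    seed: int = 0
    n_patients: int = 84
    n_tumor: int = 76
    # allele library
    pool_sizes: dict = field(default_factory=lambda: {"A": 10, "B": 12, "C": 8})
    divergence_targets: dict = field(default_factory=lambda: {"A": 6.5, "B": 9.0, "C": 3.0})
    divergence_tolerance: float = 0.20
    homozygosity_rates: dict = field(default_factory=lambda: {"A": 0.12, "B": 0.07, "C": 0.15})
    # survival model (time in months)
    baseline_hazard: float = 0.05
    log_hr_hed_high: float = -math.log(2)
    log_hr_tmb_high: float = -math.log(2)
    censoring_rate: float = 0.02
    pfs_hazard_multiplier: float = 2.0
    # DCB logistic model
    dcb_intercept: float = -0.85
    dcb_coef_hed: float = 1.0
    dcb_coef_tmb: float = 1.0
    # marker cutpoints that the generator conditions on
    hed_cut: float = 8.61
    tmb_cut: float = 5.22
    # variant table
    callable_bases_mean: float = 2_000_000.0
    callable_bases_sd: float = 50_000.0
    tmb_log_mean: float = math.log(4.5)
    tmb_log_sigma: float = 0.8
    filter_fail_fractions: dict = field(default_factory=lambda: {
        "region": 0.15, "effect": 0.30, "depth": 0.05, "vaf": 0.05, "pop_af": 0.05})
    msi_h_rate: float = 0.20
    # expression panel
    n_genes: int = 395
    n_hk: int = 10
    de_fraction: float = 0.10
    fc_range: tuple = (1.5, 3.0)
    nb_dispersion: float = 0.15
    library_size_range: tuple = (1_000_000, 2_000_000)

    def __post_init__(self) -> None:
        for locus, k in self.pool_sizes.items():
            if k < 2:
                raise ConfigurationError(f"allele pool at locus {locus} must have >= 2 alleles")
        for name in ("baseline_hazard", "censoring_rate"):
            if not getattr(self, name) > 0:
                raise ConfigurationError(f"{name} must be positive")
        for name, v in (("msi_h_rate", self.msi_h_rate), ("de_fraction", self.de_fraction)):
            if not 0 <= v <= 1:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if self.n_tumor > self.n_patients:
            raise ConfigurationError("n_tumor cannot exceed n_patients")


@dataclass
class AlleleLibraryBundle:
    library: dict                      # AlleleName -> AlleleSequence
    fasta_text: str
    annotation: pd.DataFrame           # locus, exon, start, end (1-based inclusive)


@dataclass
class CohortBundle:
    genotypes: pd.DataFrame
    clinical: pd.DataFrame
    variants: pd.DataFrame
    callable_summary: pd.DataFrame
    cna: pd.DataFrame
    msi: pd.DataFrame
    driver_mutations: pd.DataFrame     # genes x patients boolean
    counts: pd.DataFrame               # genes x samples
    control_profile: pd.DataFrame      # gene, rpm (housekeeping control sample)
    hk_genes: list
    gene_sets: dict
    hed_profiles: pd.DataFrame         # ground truth used by the generator


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(RESIDUES), size=length))


def _exon_intervals() -> dict[int, tuple[int, int]]:
    e2 = (LEADER_LEN + 1, LEADER_LEN + EXON2_LEN)
    e3 = (e2[1] + 1, e2[1] + EXON3_LEN)
    return {2: e2, 3: e3}


def default_annotation() -> pd.DataFrame:
    rows = []
    for locus in ("A", "B", "C"):
        for exon, (start, end) in _exon_intervals().items():
            rows.append({"locus": locus, "exon": exon, "start": start, "end": end})
    return pd.DataFrame(rows)


def _mutate(rng: np.random.Generator, seq: list, n_sub: int) -> list:
    sites = rng.choice(len(seq), size=min(n_sub, len(seq)), replace=False)
    out = list(seq)
    for s in sites:
        choices = [r for r in RESIDUES if r != out[s]]
        out[s] = choices[rng.integers(len(choices))]
    return out


def simulate_allele_library(cfg: SimulationConfig,
                            rng: np.random.Generator | None = None) -> AlleleLibraryBundle:
    """Build a per-locus allele pool hitting the target mean pairwise
    divergence within the configured tolerance.

    Each locus starts from an ancestral binding-region sequence; alleles
    are derived by seeded random substitutions, and the substitution count
    is rescaled until the realized mean pairwise divergence is within
    ±tolerance of the target.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    matrix = build_grantham_matrix()
    mean_dist = matrix.off_diagonal_mean()
    intervals = _exon_intervals()
    library: dict[AlleleName, AlleleSequence] = {}
    fasta_lines: list[str] = []
    for locus in ("A", "B", "C"):
        k = cfg.pool_sizes[locus]
        target = float(cfg.divergence_targets[locus])
        ancestor_pbr = list(_random_protein(rng, PBR_LEN))
        # two alleles differing at n sites diverge by ~ 2n * mean_dist / L
        scale = 1.0
        for attempt in range(25):
            n_sub = max(1, round(scale * target * PBR_LEN / (2 * mean_dist)))
            pbrs = [_mutate(rng, ancestor_pbr, n_sub) for _ in range(k)]
            seqs = []
            for i, pbr in enumerate(pbrs):
                name = AlleleName(locus=locus, field1=f"{i + 1:02d}", field2="01")
                seqs.append(AlleleSequence(name=name, pbr_seq="".join(pbr),
                                           source_len=LEADER_LEN + PBR_LEN + TAIL_LEN))
            heds = [pairwise_hed(a, b, matrix)
                    for i, a in enumerate(seqs) for b in seqs[i + 1:]]
            realized = float(np.mean(heds))
            if realized > 0 and abs(realized - target) / target <= cfg.divergence_tolerance:
                break
            scale *= target / max(realized, 1e-9)
        else:
            raise ConfigurationError(
                f"cannot reach divergence target {target} at locus {locus} "
                f"(last realized {realized:.3g}); adjust pool or target")
        leader = _random_protein(rng, LEADER_LEN)
        tail = _random_protein(rng, TAIL_LEN)
        for seq in seqs:
            library[seq.name] = seq
            full = leader + seq.pbr_seq + tail
            assert full[intervals[2][0] - 1:intervals[3][1]] == seq.pbr_seq
            fasta_lines.append(f">{seq.name}\n{full}")
    return AlleleLibraryBundle(library=library,
                               fasta_text="\n".join(fasta_lines) + "\n",
                               annotation=default_annotation())


def build_pair_library(locus: str = "B",
                       substitutions: dict[int, tuple[str, str]] | None = None
                       ) -> dict[AlleleName, AlleleSequence]:
    """Deterministic two-allele library for oracle tests: allele 2 differs
    from allele 1 by exactly the given {site: (from, to)} substitutions
    over a fixed 182-residue background."""
    base = list((RESIDUES * ((PBR_LEN // len(RESIDUES)) + 1))[:PBR_LEN])
    other = list(base)
    for site, (src, dst) in (substitutions or {}).items():
        base[site] = src
        other[site] = dst
    n1 = AlleleName(locus=locus, field1="90", field2="01")
    n2 = AlleleName(locus=locus, field1="90", field2="02")
    return {n1: AlleleSequence(n1, "".join(base), PBR_LEN),
            n2: AlleleSequence(n2, "".join(other), PBR_LEN)}


def draw_survival(cfg: SimulationConfig, hed_high, tmb_high,
                  rng: np.random.Generator,
                  hazard_multiplier: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Draw one replicate of (time, event) under the proportional-hazards
    model: exponential baseline, log-hazard shifts for the HED-high and
    TMB-high flags, independent exponential censoring."""
    hed_high = np.asarray(hed_high, dtype=float)
    tmb_high = np.asarray(tmb_high, dtype=float)
    log_hr = cfg.log_hr_hed_high * hed_high + cfg.log_hr_tmb_high * tmb_high
    hazard = cfg.baseline_hazard * np.exp(log_hr) * hazard_multiplier
    t_event = rng.exponential(1 / hazard)
    t_cens = rng.exponential(1 / cfg.censoring_rate, size=len(hed_high))
    time = np.round(np.minimum(t_event, t_cens), 2).clip(min=0.03)
    event = (t_event <= t_cens).astype(int)
    return time, event


def _simulate_genotypes(cfg: SimulationConfig, library: dict,
                        rng: np.random.Generator) -> list[GenotypeRecord]:
    by_locus = {locus: sorted([n for n in library if n.locus == locus])
                for locus in ("A", "B", "C")}
    records = []
    for i in range(cfg.n_patients):
        alleles = {}
        for locus in ("A", "B", "C"):
            pool = by_locus[locus]
            a1 = pool[rng.integers(len(pool))]
            if rng.random() < cfg.homozygosity_rates[locus]:
                a2 = a1
            else:
                a2 = pool[rng.integers(len(pool))]  # chance collision still allowed
            alleles[locus] = (a1, a2)
        records.append(GenotypeRecord(patient_id=f"P{i + 1:03d}", alleles=alleles))
    return records


def _simulate_variants(cfg: SimulationConfig, sample_ids, tmb_values,
                       callable_bases, rng: np.random.Generator) -> pd.DataFrame:
    gene_pool = [f"GENE{i:03d}" for i in range(1, 201)]
    rows = []
    for sid, tmb, cb in zip(sample_ids, tmb_values, callable_bases):
        n_pass = rng.poisson(tmb * cb / 1e6)
        n_fail = {name: rng.poisson(frac * max(n_pass, 1))
                  for name, frac in cfg.filter_fail_fractions.items()}
        for kind, count in [("pass", n_pass)] + list(n_fail.items()):
            for _ in range(count):
                region = "exonic"
                effect = "nonsynonymous SNV" if rng.random() < 0.9 else "stopgain"
                depth = int(40 + rng.poisson(80))
                vaf = float(np.round(0.03 + 0.5 * rng.beta(2, 8), 4))
                pop = [np.nan if rng.random() < 0.7
                       else float(np.round(rng.uniform(0, 0.002), 6)) for _ in range(3)]
                if kind == "region":
                    region = "intronic" if rng.random() < 0.5 else "UTR3"
                elif kind == "effect":
                    effect = "synonymous SNV"
                elif kind == "depth":
                    depth = int(rng.integers(5, 40))
                elif kind == "vaf":
                    vaf = float(np.round(rng.uniform(0.001, 0.029), 4))
                elif kind == "pop_af":
                    pop[int(rng.integers(3))] = float(np.round(rng.uniform(0.003, 0.05), 6))
                rows.append({"sample_id": sid,
                             "chrom": f"chr{rng.integers(1, 23)}",
                             "pos": int(rng.integers(1, 2_000_000)),
                             "ref": "ACGT"[rng.integers(4)],
                             "alt": "ACGT"[rng.integers(4)],
                             "gene": gene_pool[rng.integers(len(gene_pool))],
                             "region_class": region, "effect": effect,
                             "depth": depth, "vaf": vaf,
                             "pop_af_exac": pop[0], "pop_af_gnomad": pop[1],
                             "pop_af_1kg": pop[2]})
    return pd.DataFrame(rows)


def _simulate_counts(cfg: SimulationConfig, sample_ids, hed_high,
                     rng: np.random.Generator):
    n_panel = cfg.n_genes - cfg.n_hk
    genes = [f"IO{i:03d}" for i in range(1, n_panel + 1)]
    hk_genes = [f"HK{i:02d}" for i in range(1, cfg.n_hk + 1)]
    all_genes = genes + hk_genes
    # relative expression on the log scale; housekeeping genes sit high and flat
    base_log = np.concatenate([rng.normal(4.0, 1.6, size=n_panel),
                               rng.normal(8.0, 0.3, size=cfg.n_hk)])
    rel = np.exp2(base_log)
    n_de = int(round(cfg.de_fraction * n_panel))
    de_idx = rng.choice(n_panel, size=n_de, replace=False)
    fold = rng.uniform(*cfg.fc_range, size=n_de)  # up-regulated in HED-high only
    counts = np.zeros((cfg.n_genes, len(sample_ids)), dtype=int)
    disp = cfg.nb_dispersion
    for j, high in enumerate(hed_high):
        mu_rel = rel.copy()
        if high:
            mu_rel[de_idx] *= fold
        lib = rng.integers(cfg.library_size_range[0], cfg.library_size_range[1] + 1)
        mu = mu_rel / mu_rel.sum() * lib
        # NB via gamma-Poisson; dispersion only where mu is appreciable
        shape = 1.0 / disp
        lam = rng.gamma(shape, mu / shape)
        counts[:, j] = rng.poisson(lam)
    counts_df = pd.DataFrame(counts, index=all_genes, columns=sample_ids)
    # internal control sample: expectation of the null profile, as RPM
    control_rpm = pd.DataFrame({"gene": all_genes,
                                "rpm": rel / rel.sum() * 1e6})
    de_genes = [genes[i] for i in sorted(de_idx)]
    gene_sets = {
        "SYNTH_UPREGULATED_PROGRAM": set(de_genes[: max(5, len(de_genes) // 2)]),
        "SYNTH_RANDOM_SET_A": set(rng.choice(genes, size=25, replace=False)),
        "SYNTH_RANDOM_SET_B": set(rng.choice(genes, size=40, replace=False)),
        "SYNTH_HOUSEKEEPING": set(hk_genes),
    }
    return counts_df, control_rpm, hk_genes, gene_sets, de_genes


def simulate_cohort(cfg: SimulationConfig,
                    library_bundle: AlleleLibraryBundle | None = None) -> CohortBundle:
    """Generate the full input bundle for one synthetic cohort."""
    rng = np.random.default_rng(cfg.seed)
    if library_bundle is None:
        library_bundle = simulate_allele_library(cfg, rng)
    library = library_bundle.library
    genotypes = _simulate_genotypes(cfg, library, rng)
    matrix = build_grantham_matrix()
    profiles = profile_cohort(genotypes, library, matrix)

    patient_ids = profiles["patient_id"].tolist()
    tumor_ids = patient_ids[:cfg.n_tumor]
    hed_high = (profiles["hed_b"] > cfg.hed_cut).to_numpy()

    # tumor genomic features
    tmb_true = np.exp(rng.normal(cfg.tmb_log_mean, cfg.tmb_log_sigma, size=cfg.n_tumor))
    callable_bases = np.maximum(
        rng.normal(cfg.callable_bases_mean, cfg.callable_bases_sd, size=cfg.n_tumor),
        1e5).astype(int)
    variants = _simulate_variants(cfg, tumor_ids, tmb_true, callable_bases, rng)
    callable_summary = pd.DataFrame({"sample_id": tumor_ids,
                                     "callable_bases": callable_bases})
    tmb_high = np.zeros(cfg.n_patients, dtype=bool)
    tmb_high[:cfg.n_tumor] = tmb_true > cfg.tmb_cut

    # CNA states over a fixed 100-gene panel
    cna_genes = [f"CN{i:03d}" for i in range(1, 101)]
    cna_rows = []
    for sid in tumor_ids:
        aneuploidy = rng.beta(1.5, 6)
        states = rng.choice(["neutral", "gain", "loss"], size=len(cna_genes),
                            p=[1 - aneuploidy, aneuploidy / 2, aneuploidy / 2])
        cna_rows.extend({"sample_id": sid, "gene": g, "state": s}
                        for g, s in zip(cna_genes, states))
    cna = pd.DataFrame(cna_rows)

    # five-locus MSI panel
    msi_rows = []
    for sid in tumor_ids:
        is_high = rng.random() < cfg.msi_h_rate
        n_unstable = int(rng.integers(2, 6)) if is_high else int(rng.integers(0, 2))
        unstable = set(rng.choice(MSI_LOCI, size=n_unstable, replace=False))
        msi_rows.append({"sample_id": sid,
                         **{locus: locus in unstable for locus in MSI_LOCI}})
    msi = pd.DataFrame(msi_rows)

    # driver-gene mutation flags, enriched in the HED-low group
    flags = {}
    hed_high_by_id = dict(zip(patient_ids, hed_high))
    for gene in DRIVER_GENES:
        p_low, p_high = DRIVER_PREVALENCE[gene]
        flags[gene] = [rng.random() < (p_high if hed_high_by_id[s] else p_low)
                       for s in tumor_ids]
    driver_mutations = pd.DataFrame(flags, index=tumor_ids).T

    # clinical outcomes under proportional hazards
    os_time, os_event = draw_survival(cfg, hed_high, tmb_high, rng)
    pfs_time, pfs_event = draw_survival(cfg, hed_high, tmb_high, rng,
                                        hazard_multiplier=cfg.pfs_hazard_multiplier)

    lin = (cfg.dcb_intercept + cfg.dcb_coef_hed * hed_high.astype(float)
           + cfg.dcb_coef_tmb * tmb_high.astype(float))
    dcb = rng.random(cfg.n_patients) < 1 / (1 + np.exp(-lin))
    responses, sd_weeks = [], []
    for benefit in dcb:
        if benefit:
            r = rng.choice(["CR", "PR", "SD"], p=[0.1, 0.5, 0.4])
            sd_weeks.append(float(np.round(rng.uniform(24, 80), 1)) if r == "SD" else np.nan)
        else:
            r = rng.choice(["PD", "SD"], p=[0.7, 0.3])
            sd_weeks.append(float(np.round(rng.uniform(4, 23.9), 1)) if r == "SD" else np.nan)
        responses.append(r)

    msi_status = {r["sample_id"]: ("MSI-H" if sum(r[l] for l in MSI_LOCI) >= 2 else "MSS")
                  for r in msi_rows}
    tnb = np.full(cfg.n_patients, np.nan)
    tnb[:cfg.n_tumor] = rng.poisson(np.maximum(tmb_true * 12, 0.5))

    clinical = pd.DataFrame({
        "patient_id": patient_ids,
        "os_months": os_time, "os_event": os_event,
        "pfs_months": pfs_time, "pfs_event": pfs_event,
        "response": responses, "sd_duration_weeks": sd_weeks,
        "msi_status": [msi_status.get(p, "") for p in patient_ids],
        "tnb": tnb,
    })

    counts, control_rpm, hk_genes, gene_sets, _ = _simulate_counts(
        cfg, tumor_ids, hed_high[:cfg.n_tumor], rng)

    geno_rows = []
    for g in genotypes:
        row = {"patient_id": g.patient_id}
        for locus in ("A", "B", "C"):
            row[f"{locus}1"], row[f"{locus}2"] = (str(a) for a in g.alleles[locus])
        geno_rows.append(row)

    return CohortBundle(genotypes=pd.DataFrame(geno_rows), clinical=clinical,
                        variants=variants, callable_summary=callable_summary,
                        cna=cna, msi=msi, driver_mutations=driver_mutations,
                        counts=counts, control_profile=control_rpm,
                        hk_genes=hk_genes, gene_sets=gene_sets,
                        hed_profiles=profiles)


def write_bundle(cfg: SimulationConfig, out_dir) -> Path:
    """Emit the complete input bundle (plus the allele library) into a
    directory; returns the directory path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    lib = simulate_allele_library(cfg, rng)
    bundle = simulate_cohort(cfg, lib)
    (out / "alleles.fasta").write_text(lib.fasta_text)
    header = "# 1-based inclusive protein coordinates of the binding-region exons\n"
    (out / "exon_annotation.tsv").write_text(
        header + lib.annotation.to_csv(sep="\t", index=False))
    bundle.genotypes.to_csv(out / "genotypes.tsv", sep="\t", index=False)
    bundle.clinical.to_csv(out / "clinical.tsv", sep="\t", index=False)
    bundle.variants.to_csv(out / "variants.tsv", sep="\t", index=False)
    bundle.callable_summary.to_csv(out / "callable.tsv", sep="\t", index=False)
    bundle.cna.to_csv(out / "cna.tsv", sep="\t", index=False)
    bundle.msi.to_csv(out / "msi.tsv", sep="\t", index=False)
    bundle.driver_mutations.to_csv(out / "driver_mutations.tsv", sep="\t",
                                   index_label="gene")
    bundle.counts.to_csv(out / "counts.tsv", sep="\t", index_label="gene")
    bundle.control_profile.to_csv(out / "control_profile.tsv", sep="\t", index=False)
    (out / "hk_genes.txt").write_text("\n".join(bundle.hk_genes) + "\n")
    with open(out / "gene_sets.gmt", "w") as fh:
        for name, members in bundle.gene_sets.items():
            fh.write(name + "\tsynthetic\t" + "\t".join(sorted(members)) + "\n")
    with open(out / "sim_config.json", "w") as fh:
        json.dump(asdict(cfg), fh, indent=2, sort_keys=True, default=list)
    return out
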