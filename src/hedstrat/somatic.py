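"""Somatic-variant filtering, TMB, CNA burden, MSI panel call and DCB labels.

TMB is the count of somatic SNVs surviving a five-predicate filter
cascade, scaled to mutations per megabase of callable exonic sequence
(bases covered at depth >= 40):

    TMB = passing_mutations * 1e6 / callable_bases

Filters (all boundaries inclusive): exonic region; nonsynonymous-SNV or
stopgain effect; site depth >= 40; sample variant-allele fraction >= 0.03;
population allele frequency <= 0.002 in each of ExAC, gnomAD and 1000
Genomes where a value is available (a missing population frequency means
"not observed" and passes that sub-filter).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, InputError, ValidationError

MIN_DEPTH = 40
MIN_VAF = 0.03
MAX_POP_AF = 0.002
PASSING_REGION = "exonic"
PASSING_EFFECTS = frozenset({"nonsynonymous SNV", "stopgain"})
POP_AF_COLUMNS = ("pop_af_exac", "pop_af_gnomad", "pop_af_1kg")

#: Documented attribution order: a rejected record is tallied under the
#: first failing predicate in this order.  The passing set itself is
#: order-independent (conjunction of predicates).
FILTER_ORDER = ("region", "effect", "depth", "vaf", "pop_af")

MSI_LOCI = ("BAT-25", "BAT-26", "D2S123", "D5S346", "D17S250")

VARIANT_COLUMNS = ("sample_id", "chrom", "pos", "ref", "alt", "gene",
                   "region_class", "effect", "depth", "vaf") + POP_AF_COLUMNS


@dataclass(frozen=True)
class TMBResult:
    sample_id: str
    mutation_count: int
    callable_bases: int
    tmb: float


@dataclass(frozen=True)
class MSIPanelResult:
    sample_id: str
    unstable_loci: tuple[str, ...]
    call: str  # "MSI-H" | "MSS"


def _filter_masks(records: pd.DataFrame) -> dict[str, pd.Series]:
    pop_ok = pd.Series(True, index=records.index)
    for col in POP_AF_COLUMNS:
        if col in records.columns:
            vals = pd.to_numeric(records[col], errors="coerce")
            pop_ok &= vals.isna() | (vals <= MAX_POP_AF)
    return {
        "region": records["region_class"].astype(str).eq(PASSING_REGION),
        "effect": records["effect"].astype(str).isin(PASSING_EFFECTS),
        "depth": pd.to_numeric(records["depth"]) >= MIN_DEPTH,
        "vaf": pd.to_numeric(records["vaf"]) >= MIN_VAF,
        "pop_af": pop_ok,
    }


def filter_somatic_snvs(records: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the SNV filter cascade.

    Returns the passing records and a per-filter rejection tally (first
    failing predicate in the documented order).  The tally sums to the
    rejected count.
    """
    missing = [c for c in ("region_class", "effect", "depth", "vaf")
               if c not in records.columns]
    if missing:
        raise InputError(f"variant table is missing column(s) {missing}")
    depth = pd.to_numeric(records["depth"], errors="coerce")
    vaf = pd.to_numeric(records["vaf"], errors="coerce")
    bad = records.index[depth.isna() | vaf.isna() | (depth < 0) | (vaf < 0) | (vaf > 1)]
    if len(bad):
        raise ValidationError(f"malformed depth/vaf at row(s) {list(bad[:5])}")

    masks = _filter_masks(records)
    passing_mask = pd.Series(True, index=records.index)
    for m in masks.values():
        passing_mask &= m
    tally = {name: 0 for name in FILTER_ORDER}
    remaining = ~passing_mask
    undecided = remaining.copy()
    for name in FILTER_ORDER:
        fails_here = undecided & ~masks[name]
        tally[name] = int(fails_here.sum())
        undecided &= ~fails_here
    return records[passing_mask].copy(), tally


def compute_tmb(passing_count: int, callable_bases: int, sample_id: str = "") -> TMBResult:
    """Mutations per megabase over callable exonic sequence."""
    if callable_bases <= 0:
        raise DegenerateInputError("callable_bases must be positive to compute TMB")
    if passing_count < 0:
        raise InputError("mutation count cannot be negative")
    return TMBResult(sample_id=sample_id, mutation_count=int(passing_count),
                     callable_bases=int(callable_bases),
                     tmb=passing_count * 1e6 / callable_bases)


def compute_tmb_table(variants: pd.DataFrame, callable_summary: pd.DataFrame) -> pd.DataFrame:
    """Per-sample TMB from a variant table and callable-bases table.

    ``callable_summary`` needs columns sample_id and callable_bases; samples
    present there but absent from the (filtered) variant table get TMB 0.
    """
    passing, _ = filter_somatic_snvs(variants)
    counts = passing.groupby("sample_id").size()
    rows = []
    for row in callable_summary.itertuples():
        n = int(counts.get(str(row.sample_id), counts.get(row.sample_id, 0)))
        res = compute_tmb(n, int(row.callable_bases), sample_id=str(row.sample_id))
        rows.append({"sample_id": res.sample_id, "mutation_count": res.mutation_count,
                     "callable_bases": res.callable_bases, "tmb": res.tmb})
    return pd.DataFrame(rows)


def compute_cna_burden(cna_records: pd.DataFrame) -> pd.DataFrame:
    """Count, per sample, the genes with a copy-number gain or loss.

    One state per gene per sample; duplicated gene entries raise.
    """
    required = {"sample_id", "gene", "state"}
    if not required.issubset(cna_records.columns):
        raise InputError(f"CNA table must have columns {sorted(required)}")
    bad_states = set(cna_records["state"]) - {"gain", "loss", "neutral"}
    if bad_states:
        raise ValidationError(f"unknown CNA state(s): {sorted(bad_states)}")
    dup = cna_records.duplicated(subset=["sample_id", "gene"], keep=False)
    if dup.any():
        genes = cna_records.loc[dup, ["sample_id", "gene"]].drop_duplicates()
        raise ValidationError(
            "duplicate CNA entries for " +
            "; ".join(f"{r.sample_id}:{r.gene}" for r in genes.itertuples()))
    altered = cna_records["state"].isin(["gain", "loss"])
    burden = (cna_records.assign(altered=altered)
              .groupby("sample_id")["altered"].sum().astype(int)
              .rename("cna_burden").reset_index())
    return burden


def call_msi(flags: Mapping[str, bool], sample_id: str = "") -> MSIPanelResult:
    """Five-locus PCR panel call: MSI-H iff >= 2 unstable loci, else MSS."""
    missing = [l for l in MSI_LOCI if l not in flags]
    if missing:
        raise InputError(f"MSI panel is missing locus/loci: {missing}")
    unstable = tuple(l for l in MSI_LOCI if flags[l])
    call = "MSI-H" if len(unstable) >= 2 else "MSS"
    return MSIPanelResult(sample_id=sample_id, unstable_loci=unstable, call=call)


def call_msi_table(msi_records: pd.DataFrame) -> pd.DataFrame:
    """Vector form of :func:`call_msi` over a TSV with one column per locus."""
    missing = [l for l in MSI_LOCI if l not in msi_records.columns]
    if missing:
        raise InputError(f"MSI panel table is missing locus column(s): {missing}")
    rows = []
    for idx, row in msi_records.iterrows():
        flags = {locus: bool(row[locus]) for locus in MSI_LOCI}
        res = call_msi(flags, sample_id=str(row["sample_id"]))
        rows.append({"sample_id": res.sample_id,
                     "unstable_count": len(res.unstable_loci), "msi_status": res.call})
    return pd.DataFrame(rows)


def derive_dcb(response: str, sd_duration_weeks: float | None = None) -> str:
    """Durable clinical benefit from RECIST response.

    CR/PR always qualify; SD qualifies when it lasted >= 24 weeks
    (boundary inclusive); PD and shorter SD are no-durable-benefit.
    """
    if response not in {"CR", "PR", "SD", "PD"}:
        raise InputError(f"unknown RECIST response {response!r}")
    if response in ("CR", "PR"):
        return "DCB"
    if response == "PD":
        return "NDB"
    if sd_duration_weeks is None or not np.isfinite(sd_duration_weeks):
        raise InputError("SD response requires sd_duration_weeks")
    return "DCB" if sd_duration_weeks >= 24 else "NDB"


def derive_dcb_table(clinical: pd.DataFrame) -> pd.Series:
    """DCB/NDB labels for a clinical table with columns response and
    (for SD rows) sd_duration_weeks."""
    durations: Sequence = (clinical["sd_duration_weeks"]
                           if "sd_duration_weeks" in clinical.columns
                           else [None] * len(clinical))
    labels = [derive_dcb(r, None if pd.isna(d) else float(d))
              for r, d in zip(clinical["response"], durations)]
    return pd.Series(labels, index=clinical.index, name="dcb")
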