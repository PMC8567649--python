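"""HLA class I allele handling and evolutionary-divergence (HED) computation.

The divergence between a patient's two alleles at one locus is the mean
per-site Grantham distance over the peptide-binding region (the
concatenated exon-2 and exon-3 protein segments, the variable part of the
peptide-binding groove).  Homozygotes have divergence 0 by definition.
The per-patient mean HED averages the HLA-A, -B and -C values.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

from .errors import DegenerateInputError, InputError, ValidationError
from .grantham import GranthamMatrix

LOCI = ("A", "B", "C")
GAP = "-"

_ALLELE_RE = re.compile(r"^(?:HLA-)?([ABC])\*(\d+):(\d+)")


@dataclass(frozen=True, order=True)
class AlleleName:
    """Two-field HLA allele designation, e.g. B*15:01.

    Higher-resolution fields (synonymous / non-coding suffixes such as
    B*15:01:01:02N) are truncated on parse: the analysis operates at
    genotype (two-field) resolution.
    """

    locus: str
    field1: str
    field2: str

    @classmethod
    def parse(cls, text: str) -> "AlleleName":
        m = _ALLELE_RE.match(text.strip())
        if not m:
            raise InputError(f"cannot parse HLA allele name {text!r} "
                             "(expected e.g. B*15:01)")
        return cls(locus=m.group(1), field1=m.group(2), field2=m.group(3))

    def __str__(self) -> str:
        return f"{self.locus}*{self.field1}:{self.field2}"


@dataclass(frozen=True)
class AlleleSequence:
    """Peptide-binding-region protein sequence of one allele."""

    name: AlleleName
    pbr_seq: str
    source_len: int

    def __post_init__(self) -> None:
        bad = set(self.pbr_seq) - set("ACDEFGHIKLMNPQRSTVWY" + GAP)
        if bad:
            raise ValidationError(
                f"{self.name}: non-canonical residue(s) {sorted(bad)} in PBR sequence")


@dataclass(frozen=True)
class GenotypeRecord:
    """Two alleles per locus (unordered pairs) for one patient."""

    patient_id: str
    alleles: Mapping[str, tuple[AlleleName, AlleleName]]

    def __post_init__(self) -> None:
        for locus in LOCI:
            if locus not in self.alleles:
                raise ValidationError(f"{self.patient_id}: locus {locus} missing from genotype")
            a1, a2 = self.alleles[locus]
            if a1.locus != locus or a2.locus != locus:
                raise ValidationError(
                    f"{self.patient_id}: allele pair {a1}/{a2} does not match locus {locus}")


@dataclass(frozen=True)
class HEDProfile:
    """Per-locus HED, mean HED and zygosity flags for one patient."""

    patient_id: str
    hed_a: float
    hed_b: float
    hed_c: float
    mean_hed: float
    het_a: bool
    het_b: bool
    het_c: bool


def read_exon_annotation(path) -> dict[str, dict[int, tuple[int, int]]]:
    """Read the sidecar TSV of 1-based inclusive protein coordinates.

    Columns: locus, exon, start, end.  Returns {locus: {exon: (start, end)}}.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"locus", "exon", "start", "end"}
    if not required.issubset(df.columns):
        raise InputError(f"exon annotation must have columns {sorted(required)}")
    ann: dict[str, dict[int, tuple[int, int]]] = {}
    for row in df.itertuples():
        ann.setdefault(str(row.locus), {})[int(row.exon)] = (int(row.start), int(row.end))
    for locus, exons in ann.items():
        for ex in (2, 3):
            if ex not in exons:
                raise InputError(f"exon annotation for locus {locus} lacks exon {ex}")
    return ann


def extract_pbr(full_seq: str, exon2: tuple[int, int], exon3: tuple[int, int]) -> str:
    """Concatenate the exon-2 and exon-3 intervals (1-based inclusive)."""
    for label, (start, end) in (("exon 2", exon2), ("exon 3", exon3)):
        if start < 1 or end > len(full_seq) or start > end:
            raise InputError(
                f"{label} interval [{start},{end}] exceeds protein of length {len(full_seq)}")
    return full_seq[exon2[0] - 1:exon2[1]] + full_seq[exon3[0] - 1:exon3[1]]


def load_allele_library(fasta_path, exon_annotation_path) -> dict[AlleleName, AlleleSequence]:
    """Parse an allele-protein FASTA plus its exon-coordinate sidecar.

    FASTA headers must be parseable allele names; names are truncated to
    two-field resolution (first record wins on duplicates).  All alleles of
    one locus must yield equal-length binding-region sequences.
    """
    annotation = read_exon_annotation(exon_annotation_path)
    library: dict[AlleleName, AlleleSequence] = {}
    for record in SeqIO.parse(str(fasta_path), "fasta"):
        name = AlleleName.parse(record.id)
        if name.locus not in annotation:
            raise InputError(f"no exon annotation for locus {name.locus}")
        seq = str(record.seq).upper()
        pbr = extract_pbr(seq, annotation[name.locus][2], annotation[name.locus][3])
        library.setdefault(name, AlleleSequence(name=name, pbr_seq=pbr, source_len=len(seq)))
    # per-locus length uniformity (alignment precondition for per-site distances)
    for locus in LOCI:
        lengths = {str(a.name): len(a.pbr_seq) for a in library.values()
                   if a.name.locus == locus}
        if len(set(lengths.values())) > 1:
            raise ValidationError(
                f"unequal PBR lengths at locus {locus}: {sorted(lengths.items())}")
    return library


def pairwise_hed(a1: AlleleSequence, a2: AlleleSequence, matrix: GranthamMatrix) -> float:
    """Mean per-site Grantham distance between two aligned allele sequences.

    Sites where either sequence carries a gap are excluded from both the
    numerator and the denominator; a warning is emitted when more than 5%
    of sites are excluded.
    """
    if a1.name.locus != a2.name.locus:
        raise InputError(f"alleles {a1.name} and {a2.name} are from different loci")
    if len(a1.pbr_seq) != len(a2.pbr_seq):
        raise InputError(f"{a1.name} and {a2.name} have unequal PBR lengths "
                         f"({len(a1.pbr_seq)} vs {len(a2.pbr_seq)})")
    total = 0.0
    compared = 0
    for x, y in zip(a1.pbr_seq, a2.pbr_seq):
        if x == GAP or y == GAP:
            continue
        total += matrix.distance(x, y)
        compared += 1
    n = len(a1.pbr_seq)
    if compared == 0:
        raise DegenerateInputError(
            f"no comparable (gap-free) sites between {a1.name} and {a2.name}")
    if n and (n - compared) / n > 0.05:
        warnings.warn(f"{a1.name}/{a2.name}: {n - compared} of {n} sites excluded as gaps",
                      stacklevel=2)
    return total / compared


def classify_zygosity(genotype: GenotypeRecord) -> dict[str, bool]:
    """Heterozygosity flags per locus: homozygous iff the two two-field
    allele names are identical."""
    return {locus: genotype.alleles[locus][0] != genotype.alleles[locus][1]
            for locus in LOCI}


def profile_patient(genotype: GenotypeRecord,
                    library: Mapping[AlleleName, AlleleSequence],
                    matrix: GranthamMatrix) -> HEDProfile:
    """Per-locus and mean HED for one patient.

    Homozygous loci score 0 without requiring a sequence lookup; for
    heterozygous loci both alleles must resolve in the library.
    """
    het = classify_zygosity(genotype)
    hed: dict[str, float] = {}
    for locus in LOCI:
        a1, a2 = genotype.alleles[locus]
        if not het[locus]:
            hed[locus] = 0.0
            continue
        try:
            s1, s2 = library[a1], library[a2]
        except KeyError as exc:
            raise InputError(f"allele {exc.args[0]} not found in allele library") from None
        hed[locus] = pairwise_hed(s1, s2, matrix)
    mean_hed = (hed["A"] + hed["B"] + hed["C"]) / 3
    return HEDProfile(patient_id=genotype.patient_id,
                      hed_a=hed["A"], hed_b=hed["B"], hed_c=hed["C"],
                      mean_hed=mean_hed,
                      het_a=het["A"], het_b=het["B"], het_c=het["C"])


def read_genotypes(path) -> list[GenotypeRecord]:
    """Genotype TSV with columns patient_id, A1, A2, B1, B2, C1, C2."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"patient_id", "A1", "A2", "B1", "B2", "C1", "C2"}
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"genotype table is missing column(s) {sorted(missing)}")
    records = []
    for row in df.itertuples():
        alleles = {locus: (AlleleName.parse(getattr(row, f"{locus}1")),
                           AlleleName.parse(getattr(row, f"{locus}2")))
                   for locus in LOCI}
        records.append(GenotypeRecord(patient_id=str(row.patient_id), alleles=alleles))
    return records


def profile_cohort(genotypes: Iterable[GenotypeRecord],
                   library: Mapping[AlleleName, AlleleSequence],
                   matrix: GranthamMatrix) -> pd.DataFrame:
    """HEDProfile table (one row per patient) for a whole cohort."""
    rows = [profile_patient(g, library, matrix).__dict__ for g in genotypes]
    return pd.DataFrame(rows)


def dichotomize(values: pd.Series, cutpoint: float) -> pd.Series:
    """Label 'high' iff value > cutpoint (strict), 'low' iff value <= cutpoint.

    Missing values are excluded from the output with a warning, never
    silently dropped.
    """
    if not pd.notna(cutpoint):
        raise InputError("cutpoint must be finite")
    values = pd.Series(values)
    missing = values.isna()
    if missing.any():
        warnings.warn(f"{int(missing.sum())} missing value(s) excluded from dichotomization",
                      stacklevel=2)
        values = values[~missing]
    return pd.Series(pd.Categorical(
        ["high" if v > cutpoint else "low" for v in values],
        categories=["low", "high"]), index=values.index, name=values.name)
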