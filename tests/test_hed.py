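"""Allele parsing, binding-region extraction and HED computation."""

import numpy as np
import pytest

from hedstrat.errors import DegenerateInputError, InputError, ValidationError
from hedstrat.grantham import RESIDUES
from hedstrat.hed import (AlleleName, AlleleSequence, GenotypeRecord,
                          classify_zygosity, dichotomize, extract_pbr,
                          load_allele_library, pairwise_hed, profile_patient)

PBR_LEN = 182


def make_allele(locus, f1, f2, seq):
    name = AlleleName(locus=locus, field1=f1, field2=f2)
    return AlleleSequence(name=name, pbr_seq=seq, source_len=len(seq))


def background(length=PBR_LEN):
    return (RESIDUES * (length // len(RESIDUES) + 1))[:length]


@pytest.mark.parametrize("text,expected", [
    ("B*15:01", "B*15:01"),
    ("B*15:01:01:02N", "B*15:01"),       # truncation to two-field resolution
    ("HLA-A*02:01", "A*02:01"),
    ("C*03:04:01", "C*03:04"),
])
def test_allele_name_truncation(text, expected):
    assert str(AlleleName.parse(text)) == expected


def test_unparseable_allele_name():
    with pytest.raises(InputError):
        AlleleName.parse("B15:01")


def test_extract_pbr_coordinates():
    assert extract_pbr("MKTAYIAKQR", (2, 4), (5, 7)) == "KTAYIA"


def test_extract_pbr_out_of_range():
    with pytest.raises(InputError):
        extract_pbr("MKTAY", (2, 4), (5, 7))


def test_load_allele_library_round_trip(tmp_path):
    fasta = tmp_path / "alleles.fasta"
    ann = tmp_path / "ann.tsv"
    seq1 = "M" * 4 + "A" * 6 + "W" * 6 + "K" * 4
    seq2 = "M" * 4 + "C" * 6 + "W" * 6 + "K" * 4
    fasta.write_text(f">B*15:01:01:02N\n{seq1}\n>B*40:01\n{seq2}\n")
    ann.write_text("locus\texon\tstart\tend\nB\t2\t5\t10\nB\t3\t11\t16\n")
    lib = load_allele_library(fasta, ann)
    assert set(map(str, lib)) == {"B*15:01", "B*40:01"}
    assert lib[AlleleName.parse("B*15:01")].pbr_seq == "A" * 6 + "W" * 6


def test_library_length_mismatch_raises(tmp_path):
    fasta = tmp_path / "alleles.fasta"
    ann = tmp_path / "ann.tsv"
    fasta.write_text(">B*15:01\nAAAAWWWW\n>B*40:01\nAAAWWWW\n")
    # second allele too short for the exon-3 interval
    ann.write_text("locus\texon\tstart\tend\nB\t2\t1\t4\nB\t3\t5\t8\n")
    with pytest.raises((InputError, ValidationError)):
        load_allele_library(fasta, ann)


def test_pairwise_hed_single_substitution(integer_matrix):
    base = background()
    other = list(base)
    base = list(base)
    base[10], other[10] = "L", "I"
    a = make_allele("B", "01", "01", "".join(base))
    b = make_allele("B", "01", "02", "".join(other))
    assert pairwise_hed(a, b, integer_matrix) == pytest.approx(5 / 182)


def test_pairwise_hed_two_substitutions(integer_matrix):
    base, other = list(background()), list(background())
    base[0], other[0] = "L", "I"
    base[50], other[50] = "W", "C"
    a = make_allele("B", "01", "01", "".join(base))
    b = make_allele("B", "01", "02", "".join(other))
    assert pairwise_hed(a, b, integer_matrix) == pytest.approx((5 + 215) / 182)


def test_pairwise_hed_identical_is_zero(integer_matrix):
    a = make_allele("A", "01", "01", background())
    b = make_allele("A", "01", "02", background())
    assert pairwise_hed(a, b, integer_matrix) == 0.0


def test_pairwise_hed_gap_sites_excluded(integer_matrix):
    base, other = list(background(20)), list(background(20))
    base[0], other[0] = "L", "I"
    other[5] = other[6] = "-"  # 10% of sites gapped -> warning threshold crossed
    a = make_allele("B", "01", "01", "".join(base))
    b = make_allele("B", "01", "02", "".join(other))
    with pytest.warns(UserWarning, match="gap"):
        assert pairwise_hed(a, b, integer_matrix) == pytest.approx(5 / 18)


def test_pairwise_hed_different_loci_rejected(integer_matrix):
    a = make_allele("A", "01", "01", background())
    b = make_allele("B", "01", "01", background())
    with pytest.raises(InputError):
        pairwise_hed(a, b, integer_matrix)


def test_pairwise_hed_all_gaps_degenerate(integer_matrix):
    a = make_allele("B", "01", "01", "-" * 10)
    b = make_allele("B", "01", "02", background(10))
    with pytest.raises(DegenerateInputError):
        pairwise_hed(a, b, integer_matrix)


def test_pairwise_hed_matches_bruteforce_on_random_pairs(integer_matrix, rng):
    """Per-site loop oracle over random gap-free pairs, 1e-12 agreement."""
    residues = list(RESIDUES)
    for _ in range(200):
        length = int(rng.integers(30, 200))
        s1 = rng.choice(residues, size=length)
        s2 = rng.choice(residues, size=length)
        a = make_allele("C", "01", "01", "".join(s1))
        b = make_allele("C", "01", "02", "".join(s2))
        expected = sum(integer_matrix.distance(x, y) for x, y in zip(s1, s2)) / length
        assert pairwise_hed(a, b, integer_matrix) == pytest.approx(expected, abs=1e-12)
        assert pairwise_hed(b, a, integer_matrix) == pytest.approx(expected, abs=1e-12)


def test_single_site_edit_strictly_increases_hed(integer_matrix, rng):
    base = rng.choice(list(RESIDUES), size=100)
    other = base.copy()
    a = make_allele("B", "01", "01", "".join(base))
    prev = 0.0
    sites = rng.choice(100, size=10, replace=False)
    for site in sites:
        other[site] = "W" if base[site] != "W" else "C"
        b = make_allele("B", "01", "02", "".join(other))
        cur = pairwise_hed(a, b, integer_matrix)
        assert cur > prev
        prev = cur


def genotype(a1, a2, b1, b2, c1, c2):
    return GenotypeRecord(patient_id="P1", alleles={
        "A": (AlleleName.parse(a1), AlleleName.parse(a2)),
        "B": (AlleleName.parse(b1), AlleleName.parse(b2)),
        "C": (AlleleName.parse(c1), AlleleName.parse(c2))})


def test_classify_zygosity():
    g = genotype("A*02:01", "A*02:01", "B*15:01", "B*40:01", "C*03:04", "C*03:04")
    assert classify_zygosity(g) == {"A": False, "B": True, "C": False}


def test_homozygous_profile_is_zero_without_library(integer_matrix):
    g = genotype("A*02:01", "A*02:01", "B*15:01", "B*15:01", "C*03:04", "C*03:04")
    profile = profile_patient(g, library={}, matrix=integer_matrix)
    assert (profile.hed_a, profile.hed_b, profile.hed_c, profile.mean_hed) == (0, 0, 0, 0)
    assert not (profile.het_a or profile.het_b or profile.het_c)


def test_mean_hed_is_exact_three_locus_mean(integer_matrix):
    base, other = list(background()), list(background())
    base[3], other[3] = "L", "I"
    lib = {}
    for locus in "ABC":
        for f2, seq in (("01", base), ("02", other)):
            al = make_allele(locus, "07", f2, "".join(seq))
            lib[al.name] = al
    g = genotype("A*07:01", "A*07:02", "B*07:01", "B*07:02", "C*07:01", "C*07:01")
    p = profile_patient(g, lib, integer_matrix)
    d = 5 / 182
    assert p.hed_a == pytest.approx(d)
    assert p.hed_b == pytest.approx(d)
    assert p.hed_c == 0.0
    assert p.mean_hed == (p.hed_a + p.hed_b + p.hed_c) / 3


def test_unresolvable_allele_named_in_error(integer_matrix):
    g = genotype("A*02:01", "A*68:01", "B*15:01", "B*15:01", "C*03:04", "C*03:04")
    with pytest.raises(InputError, match="A"):
        profile_patient(g, {}, integer_matrix)


def test_dichotomize_strict_boundary():
    import pandas as pd
    labels = dichotomize(pd.Series([8.62, 8.61, 8.60]), 8.61)
    assert list(labels) == ["high", "low", "low"]


def test_dichotomize_excludes_missing_with_warning():
    import pandas as pd
    with pytest.warns(UserWarning, match="missing"):
        labels = dichotomize(pd.Series([1.0, np.nan, 9.0]), 5.0)
    assert list(labels) == ["low", "high"]
    assert len(labels) == 2


def test_dichotomize_empty_input():
    import pandas as pd
    assert len(dichotomize(pd.Series([], dtype=float), 1.0)) == 0


from hypothesis import given, settings
from hypothesis import strategies as st

_residue_or_gap = st.sampled_from(RESIDUES + "-")


@given(st.lists(st.tuples(_residue_or_gap, _residue_or_gap),
                min_size=5, max_size=60))
@settings(deadline=None, derandomize=True, max_examples=100)
def test_pairwise_hed_symmetry_and_zero_iff_identical(pairs):
    from hedstrat.grantham import build_grantham_matrix
    matrix = build_grantham_matrix()
    s1 = "".join(p[0] for p in pairs)
    s2 = "".join(p[1] for p in pairs)
    a = make_allele("A", "01", "01", s1)
    b = make_allele("A", "01", "02", s2)
    compared = [(x, y) for x, y in zip(s1, s2) if "-" not in (x, y)]
    import warnings as _w
    with _w.catch_warnings():
        _w.simplefilter("ignore")
        if not compared:
            with pytest.raises(DegenerateInputError):
                pairwise_hed(a, b, matrix)
            return
        d_ab = pairwise_hed(a, b, matrix)
        d_ba = pairwise_hed(b, a, matrix)
    assert d_ab == d_ba >= 0
    assert (d_ab == 0) == all(x == y for x, y in compared)
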