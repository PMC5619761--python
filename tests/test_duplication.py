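"""Global alignment and the coverage/identity duplication criteria."""

import numpy as np
import pytest
from Bio import Align

from zmgras.census import CensusEntry
from zmgras.duplication import (
    chromosome_distribution,
    classify_duplication,
    find_duplicate_pairs,
    global_align,
    DuplicatePair,
)
from zmgras.errors import MissingRecordError, ValidationError
from zmgras.io_formats import ProteinRecord
from zmgras.pipeline import table1_fixture

from oracles import gotoh_global_score

AA20 = list("ACDEFGHIKLMNPQRSTVWY")


# ---------------------------------------------------------------------------
# Global alignment


def test_self_alignment_identity_and_coverage():
    aln = global_align("HEAGAWGHEE", "HEAGAWGHEE")
    assert aln.identity == 1.0
    assert aln.coverage == 1.0


def test_single_mismatch_identity():
    aln = global_align("AAAA", "AATA")
    assert aln.identity == pytest.approx(0.75)


def test_empty_sequence_rejected():
    with pytest.raises(ValidationError):
        global_align("", "MKV")


def test_alignment_symmetric_under_swap():
    rng = np.random.default_rng(2)
    for _ in range(10):
        a = "".join(rng.choice(AA20, 40))
        b = "".join(rng.choice(AA20, 50))
        fwd = global_align(a, b)
        rev = global_align(b, a)
        assert fwd.identity == pytest.approx(rev.identity)
        assert fwd.coverage == pytest.approx(rev.coverage)
        assert fwd.score == pytest.approx(rev.score)


def test_alignment_score_matches_textbook_dp_oracle():
    submat = Align.substitution_matrices.load("BLOSUM62")
    rng = np.random.default_rng(42)
    for _ in range(60):
        a = "".join(rng.choice(AA20, int(rng.integers(3, 61))))
        b = "".join(rng.choice(AA20, int(rng.integers(3, 61))))
        aln = global_align(a, b)
        assert aln.score == pytest.approx(
            gotoh_global_score(a, b, submat, 10.0, 0.5), abs=1e-6
        )


def test_coverage_bounded_by_length_ratio():
    rng = np.random.default_rng(8)
    for _ in range(10):
        a = "".join(rng.choice(AA20, int(rng.integers(20, 60))))
        b = "".join(rng.choice(AA20, int(rng.integers(20, 60))))
        aln = global_align(a, b)
        assert aln.coverage <= min(len(a), len(b)) / max(len(a), len(b)) + 1e-12


# ---------------------------------------------------------------------------
# Duplication criteria


def _entry(locus, chrom, start, end):
    return CensusEntry(
        gene_name=locus, gene_locus=locus, chromosome=chrom,
        start=start, end=end, length_aa=100, mw_da=11000.0, pi=6.0,
    )


def _census_pair(seq_a, seq_b, chrom_b="chr2"):
    census = [
        _entry("gA", "chr1", 1000, 2000),
        _entry("gB", chrom_b, 500_000, 501_000),
    ]
    proteins = {
        "gA": ProteinRecord("gA_P01", "gA", seq_a),
        "gB": ProteinRecord("gB_P01", "gB", seq_b),
    }
    return census, proteins


def test_pair_above_both_thresholds_reported():
    seq = "".join(np.random.default_rng(1).choice(AA20, 100))
    variant = seq[:90] + "W" * 10 if seq[90:] != "W" * 10 else seq[:90] + "Y" * 10
    census, proteins = _census_pair(seq, variant)
    pairs = find_duplicate_pairs(census, proteins)
    assert len(pairs) == 1
    assert pairs[0].identity >= 0.9 and pairs[0].coverage == pytest.approx(1.0)


def test_low_coverage_rejected_before_alignment():
    seq = "".join(np.random.default_rng(3).choice(AA20, 100))
    census, proteins = _census_pair(seq, seq[:50])  # coverage can be at most 0.5
    assert find_duplicate_pairs(census, proteins) == []


def test_boundary_identity_exactly_080_rejected():
    """identity must be strictly greater than the threshold."""
    rng = np.random.default_rng(4)
    seq = "".join(rng.choice(AA20, 100))
    # mutate exactly 20 positions -> identity exactly 0.80
    mutated = list(seq)
    for i in range(20):
        mutated[i] = next(c for c in AA20 if c != seq[i])
    census, proteins = _census_pair(seq, "".join(mutated))
    aln = global_align(seq, "".join(mutated))
    assert aln.identity == pytest.approx(0.80)
    assert find_duplicate_pairs(census, proteins) == []


def test_boundary_coverage_exactly_080_rejected():
    census = [_entry("gA", "chr1", 1000, 2000), _entry("gB", "chr2", 1000, 2000)]
    proteins = {
        "gA": ProteinRecord("gA_P01", "gA", "M" * 100),
        "gB": ProteinRecord("gB_P01", "gB", "M" * 80),  # coverage exactly 0.80
    }
    assert find_duplicate_pairs(census, proteins) == []


def test_planted_pairs_recovered_exactly(family, family_census):
    """Precision = recall = 1.0 on the planted duplicate pairs."""
    entries, genes = family_census
    pairs = find_duplicate_pairs(entries, genes)
    found = {frozenset((p.gene_a, p.gene_b)) for p in pairs}
    truth = {frozenset(p[:2]) for p in family.truth.duplicate_pairs}
    assert found == truth
    truth_class = {frozenset(p[:2]): p[2] for p in family.truth.duplicate_pairs}
    for p in pairs:
        assert truth_class[frozenset((p.gene_a, p.gene_b))] == p.dup_class


def test_find_pairs_invariant_to_protein_ordering(family_census):
    entries, genes = family_census
    reversed_entries = list(reversed(entries))
    p1 = find_duplicate_pairs(entries, genes)
    p2 = find_duplicate_pairs(reversed_entries, genes)
    assert [(p.gene_a, p.gene_b) for p in p1] == [(p.gene_a, p.gene_b) for p in p2]


def test_tightly_linked_cluster_counts_one_event():
    """Three mutually duplicated adjacent genes yield a single event."""
    rng = np.random.default_rng(9)
    seq = "".join(rng.choice(AA20, 100))
    mut1 = "W" + seq[1:]
    mut2 = "Y" + seq[1:]
    census = [
        _entry("g1", "chr1", 1_000, 2_000),
        _entry("g2", "chr1", 10_000, 11_000),
        _entry("g3", "chr1", 20_000, 21_000),
    ]
    proteins = {
        "g1": ProteinRecord("g1_P01", "g1", seq),
        "g2": ProteinRecord("g2_P01", "g2", mut1),
        "g3": ProteinRecord("g3_P01", "g3", mut2),
    }
    pairs = find_duplicate_pairs(census, proteins)
    assert len(pairs) == 1


# ---------------------------------------------------------------------------
# Tandem / segmental classification


def _pair(gene_a, gene_b):
    return DuplicatePair(gene_a, gene_b, 0.9, 0.95, True, None)


def test_classify_close_same_chromosome_tandem():
    census = [
        _entry("gA", "chr3", 100_000, 105_000),
        _entry("gB", "chr3", 135_000, 140_000),  # 30 kb gap
        _entry("mid", "chr3", 110_000, 120_000),  # 1 intervening gene
    ]
    assert classify_duplication(_pair("gA", "gB"), census) == "tandem"


def test_classify_different_chromosomes_segmental():
    census = [_entry("gA", "chr2", 1, 1000), _entry("gB", "chr7", 1, 1000)]
    assert classify_duplication(_pair("gA", "gB"), census) == "segmental"


def test_classify_distant_same_chromosome_segmental():
    census = [_entry("gA", "chr1", 1, 1000), _entry("gB", "chr1", 80_000_000, 80_001_000)]
    census += [
        _entry(f"bg{i}", "chr1", 10_000 + 100_000 * i, 10_500 + 100_000 * i)
        for i in range(500)
    ]
    assert classify_duplication(_pair("gA", "gB"), census) == "segmental"


def test_classify_unknown_gene_raises():
    with pytest.raises(MissingRecordError):
        classify_duplication(_pair("gA", "ghost"), [_entry("gA", "chr1", 1, 10)])


# ---------------------------------------------------------------------------
# Chromosome distribution


def test_chromosome_distribution_matches_published_counts():
    dist = chromosome_distribution(table1_fixture())
    assert dist["chr1"] == (13, 15.12)
    assert dist["chr4"] == (17, 19.77)
    assert dist["chr8"] == (3, 3.49)


def test_chromosome_distribution_single_gene():
    dist = chromosome_distribution([_entry("g", "chr5", 1, 10)])
    assert dist == {"chr5": (1, 100.0)}
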