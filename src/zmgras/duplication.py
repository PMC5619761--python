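"""Paralog detection by coverage/identity criteria and chromosome maps.

A gene pair is called a duplication event when a full-length global
protein alignment covers more than 80% of the longer protein and the
aligned region exceeds 80% identity; clusters of tightly linked genes
contribute a single event (the highest-identity pair is retained).
Events are classed as tandem (same chromosome, small gap or few
intervening genes) or segmental.

Global alignment is Needleman-Wunsch with affine gaps (BLOSUM62,
gap open 10, gap extend 0.5 by default; a gap of length k costs
open + k*extend), executed through Biopython's PairwiseAligner.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from typing import Mapping, Optional

from Bio import Align

from .census import CensusEntry
from .errors import MissingRecordError, ValidationError
from .io_formats import ProteinRecord

DEFAULT_GAP_OPEN = 10.0
DEFAULT_GAP_EXTEND = 0.5
DEFAULT_MATRIX = "BLOSUM62"


@dataclass(frozen=True)
class AlignmentScoring:
    """Substitution matrix and affine gap costs (open + k*extend for k gaps)."""

    matrix: str = DEFAULT_MATRIX
    gap_open: float = DEFAULT_GAP_OPEN
    gap_extend: float = DEFAULT_GAP_EXTEND


@dataclass(frozen=True)
class PairwiseAlignment:
    """A global alignment with identity and coverage fractions.

    identity = identical columns / columns where both sequences carry a
    residue; coverage = both-residue columns / length of the longer input.
    """

    id_a: str
    id_b: str
    aligned_a: str
    aligned_b: str
    score: float
    identity: float
    coverage: float


@dataclass(frozen=True)
class DuplicatePair:
    gene_a: str
    gene_b: str
    identity: float
    coverage: float
    same_chromosome: bool
    genomic_gap_bp: Optional[int]
    dup_class: Optional[str] = None  # "tandem" | "segmental"


def _make_aligner(scoring: AlignmentScoring) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = Align.substitution_matrices.load(scoring.matrix)
    # Biopython charges open_gap_score for the first gapped position, so a
    # k-long gap costs open+k*extend when open_gap_score = -(open+extend)
    aligner.open_gap_score = -(scoring.gap_open + scoring.gap_extend)
    aligner.extend_gap_score = -scoring.gap_extend
    return aligner


def global_align(
    seq_a: str, seq_b: str, scoring: AlignmentScoring = AlignmentScoring(),
    id_a: str = "a", id_b: str = "b",
) -> PairwiseAlignment:
    """Optimal global alignment of two protein sequences."""
    if not seq_a or not seq_b:
        raise ValidationError("cannot align an empty sequence")
    aligner = _make_aligner(scoring)
    alignment = aligner.align(seq_a, seq_b)[0]
    aligned_a, aligned_b = alignment[0], alignment[1]
    both = ident = 0
    for ca, cb in zip(aligned_a, aligned_b):
        if ca != "-" and cb != "-":
            both += 1
            if ca == cb:
                ident += 1
    if both == 0:
        raise ValidationError(f"no aligned residue columns for {id_a}/{id_b}")
    return PairwiseAlignment(
        id_a=id_a,
        id_b=id_b,
        aligned_a=aligned_a,
        aligned_b=aligned_b,
        score=float(alignment.score),
        identity=ident / both,
        coverage=both / max(len(seq_a), len(seq_b)),
    )


# ---------------------------------------------------------------------------
# Duplication criteria


def _gap_bp(a: CensusEntry, b: CensusEntry) -> Optional[int]:
    if a.chromosome != b.chromosome:
        return None
    first, second = (a, b) if a.start <= b.start else (b, a)
    return max(0, second.start - first.end - 1)


def _intervening_genes(a: CensusEntry, b: CensusEntry, census: list[CensusEntry]) -> int:
    lo, hi = sorted((min(a.end, b.end), max(a.start, b.start)))
    return sum(
        1
        for e in census
        if e.chromosome == a.chromosome
        and e.gene_locus not in (a.gene_locus, b.gene_locus)
        and e.start > lo
        and e.end < hi
    )


def _tightly_linked(
    a: CensusEntry,
    b: CensusEntry,
    census: list[CensusEntry],
    window_bp: int,
    max_intervening: int,
) -> bool:
    gap = _gap_bp(a, b)
    if gap is None:
        return False
    return gap <= window_bp or _intervening_genes(a, b, census) <= max_intervening


def find_duplicate_pairs(
    census: list[CensusEntry],
    proteins: Mapping[str, ProteinRecord],
    id_threshold: float = 0.80,
    cov_threshold: float = 0.80,
    scoring: AlignmentScoring = AlignmentScoring(),
    linked_window_bp: int = 200_000,
    linked_max_intervening: int = 5,
    classify: bool = True,
) -> list[DuplicatePair]:
    """All gene pairs passing identity > and coverage > their thresholds.

    Tightly-linked clusters (same chromosome, gap <= window or few
    intervening census genes) contribute one event each: the
    highest-identity pair of the cluster.  ``proteins`` maps gene locus to
    its representative protein.  Pairs whose length ratio already bounds
    coverage at or below the threshold are skipped without aligning, which
    cannot change the result (coverage <= shorter/longer length).
    """
    if not (0 < id_threshold < 1 and 0 < cov_threshold < 1):
        raise ValidationError("thresholds must lie in (0, 1)")
    entries = {e.gene_locus: e for e in census}
    missing = [loc for loc in entries if loc not in proteins]
    if missing:
        raise MissingRecordError(f"no representative protein for {missing}")

    passing: list[DuplicatePair] = []
    for loc_a, loc_b in itertools.combinations(sorted(entries), 2):
        rec_a, rec_b = proteins[loc_a], proteins[loc_b]
        ratio = min(len(rec_a), len(rec_b)) / max(len(rec_a), len(rec_b))
        if ratio <= cov_threshold:
            continue
        aln = global_align(
            rec_a.sequence, rec_b.sequence, scoring, id_a=loc_a, id_b=loc_b
        )
        if aln.identity > id_threshold and aln.coverage > cov_threshold:
            a, b = entries[loc_a], entries[loc_b]
            passing.append(
                DuplicatePair(
                    gene_a=loc_a,
                    gene_b=loc_b,
                    identity=aln.identity,
                    coverage=aln.coverage,
                    same_chromosome=a.chromosome == b.chromosome,
                    genomic_gap_bp=_gap_bp(a, b),
                )
            )

    # one event per tightly-linked cluster: union-find over the genes of
    # passing pairs, then keep the best pair per cluster pair
    parent: dict[str, str] = {}

    def find(x: str) -> str:
        parent.setdefault(x, x)
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: str, y: str) -> None:
        parent[find(x)] = find(y)

    genes_in_pairs = sorted({g for p in passing for g in (p.gene_a, p.gene_b)})
    for ga, gb in itertools.combinations(genes_in_pairs, 2):
        if _tightly_linked(
            entries[ga], entries[gb], census, linked_window_bp, linked_max_intervening
        ):
            union(ga, gb)

    best: dict[frozenset, DuplicatePair] = {}
    for pair in passing:
        key = frozenset((find(pair.gene_a), find(pair.gene_b)))
        cur = best.get(key)
        if cur is None or pair.identity > cur.identity:
            best[key] = pair

    result = sorted(
        best.values(),
        key=lambda p: (
            _chrom_key(entries[p.gene_a].chromosome),
            entries[p.gene_a].start,
            p.gene_a,
            p.gene_b,
        ),
    )
    if classify:
        result = [
            replace(
                p,
                dup_class=classify_duplication(
                    p, census, linked_window_bp, linked_max_intervening
                ),
            )
            for p in result
        ]
    return result


def classify_duplication(
    pair: DuplicatePair,
    census: list[CensusEntry],
    tandem_window_bp: int = 200_000,
    tandem_max_intervening: int = 5,
) -> str:
    """'tandem' for close same-chromosome pairs, else 'segmental'."""
    entries = {e.gene_locus: e for e in census}
    try:
        a, b = entries[pair.gene_a], entries[pair.gene_b]
    except KeyError as exc:
        raise MissingRecordError(f"gene {exc.args[0]!r} not in census") from None
    if a.chromosome != b.chromosome:
        return "segmental"
    gap = _gap_bp(a, b)
    if gap <= tandem_window_bp:
        return "tandem"
    if _intervening_genes(a, b, census) <= tandem_max_intervening:
        return "tandem"
    return "segmental"


# ---------------------------------------------------------------------------
# Chromosome distribution


def _chrom_key(chrom: str):
    digits = "".join(c for c in chrom if c.isdigit())
    return (0, int(digits)) if digits else (1, chrom)


def chromosome_distribution(census: list[CensusEntry]) -> dict[str, tuple[int, float]]:
    """Per-chromosome gene count and percentage (2 decimals)."""
    if not census:
        return {}
    counts: dict[str, int] = {}
    for e in census:
        counts[e.chromosome] = counts.get(e.chromosome, 0) + 1
    total = len(census)
    return {
        c: (k, round(k / total * 100, 2))
        for c, k in sorted(counts.items(), key=lambda kv: _chrom_key(kv[0]))
    }
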