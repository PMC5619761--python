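"""Exon-intron structure statistics and motif-occurrence matrices.

Motif discovery itself (MEME-style EM) is out of scope; occurrences are
consumed as a table and summarised into presence/absence matrices, from
which subfamily-specific motifs are called by an in-rate / out-rate rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional

import pandas as pd

from .errors import MissingRecordError, ValidationError
from .io_formats import GeneModel, MotifOccurrence


@dataclass
class GeneStructure:
    gene_id: str
    n_exons: int
    exon_lengths: list[int] = field(default_factory=list)

    @property
    def n_introns(self) -> int:
        return self.n_exons - 1


@dataclass
class MotifMatrix:
    """Genes x motifs presence matrix with per-occurrence detail retained."""

    presence: pd.DataFrame  # bool, genes x motif ids
    occurrences: dict[str, list[MotifOccurrence]]

    def ordered_motifs(self, gene: str) -> list[int]:
        """Motif ids of a gene ordered by start position."""
        return [o.motif_id for o in sorted(self.occurrences.get(gene, []),
                                           key=lambda o: (o.start, o.motif_id))]


def gene_structures(
    models: list[GeneModel], representative: Mapping[str, str]
) -> list[GeneStructure]:
    """Exon counts and lengths of each gene's representative transcript."""
    out = []
    for model in models:
        tid = representative.get(model.gene_id)
        if tid is None:
            raise MissingRecordError(f"no representative transcript for {model.gene_id}")
        exons = dict(model.transcripts).get(tid)
        if exons is None:
            raise MissingRecordError(f"{model.gene_id}: transcript {tid!r} not found")
        out.append(
            GeneStructure(
                gene_id=model.gene_id,
                n_exons=len(exons),
                exon_lengths=[e - s + 1 for s, e in exons],
            )
        )
    return out


def intron_statistics(
    models: list[GeneModel], representative: Mapping[str, str]
) -> tuple[dict[int, int], dict[int, float]]:
    """Histogram of intron counts over genes, with percentages (2 decimals)."""
    structures = gene_structures(models, representative)
    hist: dict[int, int] = {}
    for s in structures:
        hist[s.n_introns] = hist.get(s.n_introns, 0) + 1
    total = len(structures)
    percent = {k: round(v / total * 100, 2) for k, v in hist.items()}
    return dict(sorted(hist.items())), dict(sorted(percent.items()))


def build_motif_matrix(
    occurrences: list[MotifOccurrence], genes: list[str]
) -> MotifMatrix:
    """Presence/absence matrix over the given genes and all seen motif ids."""
    gene_set = set(genes)
    per_gene: dict[str, list[MotifOccurrence]] = {g: [] for g in genes}
    for occ in occurrences:
        if occ.protein_id not in gene_set:
            raise ValidationError(f"occurrence for unknown gene {occ.protein_id!r}")
        per_gene[occ.protein_id].append(occ)
    motif_ids = sorted({o.motif_id for o in occurrences})
    presence = pd.DataFrame(False, index=list(genes), columns=motif_ids, dtype=bool)
    for gene, occs in per_gene.items():
        for occ in occs:
            presence.at[gene, occ.motif_id] = True
    return MotifMatrix(presence=presence, occurrences=per_gene)


def subfamily_specific_motifs(
    matrix: MotifMatrix,
    assignment: Mapping[str, str],
    in_frac: float = 0.7,
    out_frac: float = 0.2,
) -> dict[str, list[int]]:
    """Motifs present in >= ``in_frac`` of a subfamily and <= ``out_frac`` outside.

    Empty subfamilies are skipped with a warning.  The result is invariant
    to gene ordering and equivariant under motif relabelling.
    """
    unlabeled = [g for g in matrix.presence.index if g not in assignment]
    if unlabeled:
        raise ValidationError(f"genes without subfamily label: {unlabeled[:5]}")
    subfamilies = sorted(set(assignment[g] for g in matrix.presence.index))
    out: dict[str, list[int]] = {}
    for sub in subfamilies:
        members = [g for g in matrix.presence.index if assignment[g] == sub]
        others = [g for g in matrix.presence.index if assignment[g] != sub]
        if not members:
            warnings.warn(f"subfamily {sub!r} has no genes; skipped", stacklevel=2)
            continue
        specific = []
        for motif in matrix.presence.columns:
            rate_in = matrix.presence.loc[members, motif].mean()
            rate_out = matrix.presence.loc[others, motif].mean() if others else 0.0
            if rate_in >= in_frac and rate_out <= out_frac:
                specific.append(int(motif))
        out[sub] = specific
    return out


def write_structure_tsv(structures: list[GeneStructure], path) -> None:
    pd.DataFrame(
        [
            (s.gene_id, s.n_exons, s.n_introns, ",".join(map(str, s.exon_lengths)))
            for s in structures
        ],
        columns=["gene_id", "n_exons", "n_introns", "exon_lengths"],
    ).to_csv(path, sep="\t", index=False)


def write_motif_matrix_tsv(matrix: MotifMatrix, path) -> None:
    df = matrix.presence.astype(int).copy()
    df.insert(
        0, "motif_order",
        [",".join(map(str, matrix.ordered_motifs(g))) for g in df.index],
    )
    df.to_csv(path, sep="\t", index_label="gene")
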