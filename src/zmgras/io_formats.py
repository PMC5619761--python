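"""Readers and writers for every external format the pipeline touches.

All coordinates crossing this API are 1-based inclusive (the GFF3
convention); no half-open intervals are exposed.  Parsing of FASTA goes
through Biopython, GFF3 assembly is validated against the gene/mRNA/exon
hierarchy, and HMMER per-domain tables are read in a tolerant
whitespace-delimited dialect (only the target name, full-sequence E-value
and alignment coordinates are required; extra columns are ignored).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Callable, Optional, Union

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import FormatError, ValidationError
from .tree import PhyloTree, read_newick, write_newick  # noqa: F401  (re-export)

AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")

#: default rule for deriving a gene locus from a protein/transcript id:
#: strip common transcript/protein suffixes such as _P01, _T01, -T001, .1
DEFAULT_LOCUS_SUFFIX = re.compile(r"(?:_P\d+|_T\d+|-T\d+|_FGT\d+|\.\d+)$")


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence together with the gene locus it belongs to."""

    protein_id: str
    gene_locus: str
    sequence: str

    def __post_init__(self):
        if not self.sequence:
            raise ValidationError(f"empty sequence for {self.protein_id!r}")
        bad = set(self.sequence) - AA_ALPHABET
        if bad:
            raise ValidationError(
                f"illegal residue(s) {sorted(bad)} in record {self.protein_id!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class DomainHit:
    """One row of a per-domain table: a domain model aligned to a protein."""

    protein_id: str
    model_name: str
    full_sequence_evalue: float
    ali_from: int
    ali_to: int

    def __post_init__(self):
        if self.full_sequence_evalue <= 0:
            raise ValidationError(
                f"E-value must be positive, got {self.full_sequence_evalue} "
                f"for {self.protein_id}"
            )
        if not (1 <= self.ali_from <= self.ali_to):
            raise ValidationError(
                f"bad alignment coordinates {self.ali_from}..{self.ali_to} "
                f"for {self.protein_id}"
            )


@dataclass(frozen=True)
class MotifOccurrence:
    """A conserved-motif occurrence on a protein (1-based inclusive)."""

    protein_id: str
    motif_id: int
    start: int
    end: int
    p_value: float

    def __post_init__(self):
        if self.motif_id < 1:
            raise ValidationError(f"motif_id must be >= 1, got {self.motif_id}")
        if self.start > self.end:
            raise ValidationError(
                f"motif start {self.start} > end {self.end} on {self.protein_id}"
            )
        if not (0 < self.p_value <= 1):
            raise ValidationError(f"p-value out of (0,1]: {self.p_value}")


@dataclass
class GeneModel:
    """A gene with its transcripts and exon intervals, 1-based inclusive."""

    gene_id: str
    chromosome: str
    strand: str
    start: int
    end: int
    #: list of (transcript_id, [(exon_start, exon_end), ...]) sorted 5'->3'
    #: in genome coordinates
    transcripts: list[tuple[str, list[tuple[int, int]]]] = field(default_factory=list)

    def __post_init__(self):
        if self.start > self.end:
            raise ValidationError(f"gene {self.gene_id}: start > end")
        if not self.transcripts:
            raise ValidationError(f"gene {self.gene_id}: no transcripts")
        for tid, exons in self.transcripts:
            if not exons:
                raise ValidationError(f"transcript {tid}: no exons")
            prev_end = None
            for (s, e) in exons:
                if s > e:
                    raise ValidationError(f"transcript {tid}: exon start {s} > end {e}")
                if not (self.start <= s and e <= self.end):
                    raise ValidationError(
                        f"transcript {tid}: exon {s}..{e} outside gene bounds"
                    )
                if prev_end is not None and s <= prev_end:
                    raise ValidationError(
                        f"transcript {tid}: exons overlap or are unsorted at {s}"
                    )
                prev_end = e

    def introns(self, transcript_id: str) -> list[tuple[int, int]]:
        """Intron intervals (1-based inclusive) of one transcript."""
        for tid, exons in self.transcripts:
            if tid == transcript_id:
                return [
                    (exons[i][1] + 1, exons[i + 1][0] - 1)
                    for i in range(len(exons) - 1)
                ]
        raise ValidationError(f"gene {self.gene_id}: no transcript {transcript_id!r}")


# ---------------------------------------------------------------------------
# FASTA


def default_locus_rule(protein_id: str) -> str:
    return DEFAULT_LOCUS_SUFFIX.sub("", protein_id)


def read_fasta(
    path, locus_rule: Union[Callable[[str], str], str, None] = None
) -> list[ProteinRecord]:
    """Read a protein FASTA into validated records.

    ``locus_rule`` maps a protein id to its gene locus; it may be a callable,
    a regex string whose match is stripped from the id, or None for the
    default transcript-suffix stripping rule.
    """
    if locus_rule is None:
        rule = default_locus_rule
    elif isinstance(locus_rule, str):
        pattern = re.compile(locus_rule)
        rule = lambda pid: pattern.sub("", pid)  # noqa: E731
    else:
        rule = locus_rule

    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        pid = rec.id
        if pid in seen:
            raise ValidationError(f"duplicate protein_id {pid!r} in {path}")
        seen.add(pid)
        seq = str(rec.seq).upper()
        if seq.endswith("*"):
            seq = seq[:-1]
        records.append(ProteinRecord(protein_id=pid, gene_locus=rule(pid), sequence=seq))
    if not records:
        raise FormatError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: list[ProteinRecord], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.protein_id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3

_GFF_COLS = 9


def _gff_attributes(text: str) -> dict[str, str]:
    out = {}
    for item in text.strip().split(";"):
        if not item:
            continue
        if "=" not in item:
            raise FormatError(f"malformed GFF3 attribute {item!r}")
        key, value = item.split("=", 1)
        out[key.strip()] = value.strip()
    return out


def read_gff3(path) -> list[GeneModel]:
    """Assemble gene/mRNA/exon features linked by ID/Parent into gene models.

    Raises a validation error for exons whose Parent is not a known mRNA,
    for mRNAs without exons, and for any interval with end < start.
    """
    genes: dict[str, dict] = {}
    mrna_parent: dict[str, str] = {}
    mrna_exons: dict[str, list[tuple[int, int]]] = {}
    order: list[str] = []

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != _GFF_COLS:
                raise FormatError(f"{path}:{lineno}: expected 9 columns, got {len(cols)}")
            seqid, _source, ftype, start_s, end_s, _score, strand, _phase, attrs_s = cols
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if end < start:
                raise ValidationError(f"{path}:{lineno}: end {end} < start {start}")
            attrs = _gff_attributes(attrs_s)
            if ftype == "gene":
                gid = attrs.get("ID")
                if gid is None:
                    raise ValidationError(f"{path}:{lineno}: gene without ID")
                genes[gid] = dict(chromosome=seqid, strand=strand, start=start, end=end)
                order.append(gid)
            elif ftype == "mRNA":
                tid, parent = attrs.get("ID"), attrs.get("Parent")
                if tid is None or parent is None:
                    raise ValidationError(f"{path}:{lineno}: mRNA needs ID and Parent")
                mrna_parent[tid] = parent
                mrna_exons.setdefault(tid, [])
            elif ftype == "exon":
                parent = attrs.get("Parent")
                if parent is None:
                    raise ValidationError(f"{path}:{lineno}: exon without Parent")
                for p in parent.split(","):
                    if p not in mrna_exons:
                        raise ValidationError(
                            f"{path}:{lineno}: exon Parent {p!r} matches no mRNA"
                        )
                    mrna_exons[p].append((start, end))

    models: list[GeneModel] = []
    for gid in order:
        info = genes[gid]
        transcripts = []
        for tid, parent in mrna_parent.items():
            if parent != gid:
                continue
            exons = sorted(mrna_exons[tid])
            if not exons:
                raise ValidationError(f"mRNA {tid!r} has no exons")
            transcripts.append((tid, exons))
        transcripts.sort(key=lambda t: t[0])
        models.append(GeneModel(gene_id=gid, transcripts=transcripts, **info))
    return models


def write_gff3(models: list[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in models:
            fh.write(
                f"{g.chromosome}\tzmgras\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
            for tid, exons in g.transcripts:
                fh.write(
                    f"{g.chromosome}\tzmgras\tmRNA\t{exons[0][0]}\t{exons[-1][1]}\t.\t"
                    f"{g.strand}\t.\tID={tid};Parent={g.gene_id}\n"
                )
                for (s, e) in exons:
                    fh.write(
                        f"{g.chromosome}\tzmgras\texon\t{s}\t{e}\t.\t{g.strand}\t.\t"
                        f"Parent={tid}\n"
                    )


# ---------------------------------------------------------------------------
# HMMER per-domain table

_DOMTBL_MIN_COLS = 19
_COL_TARGET, _COL_QUERY, _COL_EVALUE = 0, 3, 6
_COL_ALI_FROM, _COL_ALI_TO = 17, 18


def read_domtbl(path) -> list[DomainHit]:
    """Read a HMMER per-domain table ('domtblout' dialect), unfiltered."""
    hits: list[DomainHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split()
            if len(cols) < _DOMTBL_MIN_COLS:
                raise FormatError(
                    f"{path}:{lineno}: expected >= {_DOMTBL_MIN_COLS} columns, "
                    f"got {len(cols)}"
                )
            try:
                evalue = float(cols[_COL_EVALUE])
            except ValueError as exc:
                raise ValidationError(
                    f"{path}:{lineno}: unparseable E-value {cols[_COL_EVALUE]!r}"
                ) from exc
            try:
                ali_from, ali_to = int(cols[_COL_ALI_FROM]), int(cols[_COL_ALI_TO])
            except ValueError as exc:
                raise ValidationError(
                    f"{path}:{lineno}: unparseable alignment coordinates"
                ) from exc
            hits.append(
                DomainHit(
                    protein_id=cols[_COL_TARGET],
                    model_name=cols[_COL_QUERY],
                    full_sequence_evalue=evalue,
                    ali_from=ali_from,
                    ali_to=ali_to,
                )
            )
    return hits


def write_domtbl(hits: list[DomainHit], path) -> None:
    """Emit hits in the 22-column per-domain layout HMMER prints."""
    with open(path, "w") as fh:
        fh.write(
            "#" + " ".join(
                ["target", "acc", "tlen", "query", "acc", "qlen", "E-value", "score",
                 "bias", "#", "of", "c-Evalue", "i-Evalue", "score", "bias",
                 "hmm_from", "hmm_to", "ali_from", "ali_to", "env_from", "env_to",
                 "acc"]
            ) + "\n"
        )
        for h in hits:
            row = [
                h.protein_id, "-", "0", h.model_name, "-", "0",
                f"{h.full_sequence_evalue:.2g}", "0.0", "0.0", "1", "1",
                f"{h.full_sequence_evalue:.2g}", f"{h.full_sequence_evalue:.2g}",
                "0.0", "0.0", "1", str(h.ali_to - h.ali_from + 1),
                str(h.ali_from), str(h.ali_to), str(h.ali_from), str(h.ali_to), "0.90",
            ]
            fh.write(" ".join(row) + "\n")


# ---------------------------------------------------------------------------
# Motif-occurrence, expression and Ct tables


def read_motifs_tsv(path) -> list[MotifOccurrence]:
    """Read a motif-occurrence table: gene, motif_id, start, end, p_value."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene", "motif_id", "start", "end", "p_value"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    return [
        MotifOccurrence(
            protein_id=str(r.gene),
            motif_id=int(r.motif_id),
            start=int(r.start),
            end=int(r.end),
            p_value=float(r.p_value),
        )
        for r in df.itertuples()
    ]


def write_motifs_tsv(occurrences: list[MotifOccurrence], path) -> None:
    pd.DataFrame(
        [(o.protein_id, o.motif_id, o.start, o.end, o.p_value) for o in occurrences],
        columns=["gene", "motif_id", "start", "end", "p_value"],
    ).to_csv(path, sep="\t", index=False)


def read_expression_tsv(path) -> "pd.DataFrame":
    """Read a genes x tissues expression table.

    First row holds tissue names, first column gene ids; empty cells become
    NA; any other non-numeric cell raises a validation error naming its
    coordinates.  Returns a float DataFrame (genes as index).
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if raw.index.has_duplicates:
        dupes = raw.index[raw.index.duplicated()].unique().tolist()
        raise ValidationError(f"{path}: duplicated gene id rows {dupes}")
    converted = raw.apply(lambda col: pd.to_numeric(col, errors="coerce"))
    bad = converted.isna() & raw.notna() & (raw.apply(lambda c: c.str.strip()) != "")
    if bad.to_numpy().any():
        gi, ti = np.argwhere(bad.to_numpy())[0]
        raise ValidationError(
            f"{path}: non-numeric cell at gene {raw.index[gi]!r}, "
            f"tissue {raw.columns[ti]!r}: {raw.iat[gi, ti]!r}"
        )
    return converted.astype(float)


def read_ct_tsv(path) -> pd.DataFrame:
    """Read a qPCR Ct table with columns sample, gene, replicate, ct."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample", "gene", "replicate", "ct"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    if (df["ct"] <= 0).any():
        raise ValidationError(f"{path}: Ct values must be positive")
    return df
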