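"""Family-member nomination and per-gene characterization.

The census pipeline is: keep proteins with a domain hit at or below the
E-value cutoff (1e-5 by default), collapse splice variants to gene loci
(representative isoform = longest protein), compute sequence length,
average molecular weight and isoelectric point, and emit one row per gene
in locus order, named ``<prefix>1..<prefix>N``.

Molecular weight is the sum of average residue masses plus one water.
The isoelectric point is the zero of the Henderson-Hasselbalch net-charge
function over the ionizable groups (N-terminus, K, R, H positive;
C-terminus, D, E, C, Y negative), found by bisection on pH in [0, 14].
The pKa set defaults to the EMBOSS values and is configurable; different
tools use different sets, so published pI values are only comparable
within one set.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional

import pandas as pd

from .errors import MissingRecordError, ValidationError
from .io_formats import DomainHit, GeneModel, ProteinRecord

logger = logging.getLogger(__name__)

WATER_MW = 18.01524

#: average (isotope-abundance weighted) residue masses, Da
RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886, "C": 103.1388,
    "E": 129.1155, "Q": 128.1307, "G": 57.0519, "H": 137.1411, "I": 113.1594,
    "L": 113.1594, "K": 128.1741, "M": 131.1926, "F": 147.1766, "P": 97.1167,
    "S": 87.0782, "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}

#: EMBOSS pKa values for the ionizable groups
EMBOSS_PKA = {
    "Nterm": 8.6, "Cterm": 3.6,
    "K": 10.8, "R": 12.5, "H": 6.5,
    "D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1,
}

_BASIC = ("K", "R", "H")
_ACIDIC = ("D", "E", "C", "Y")


@dataclass
class CensusEntry:
    """One row of the family census (the published-table analog)."""

    gene_name: str
    gene_locus: str
    chromosome: str
    start: int
    end: int
    length_aa: int
    mw_da: Optional[float]
    pi: Optional[float]
    n_splice_forms: int = 1
    subgroup: Optional[str] = None

    def __post_init__(self):
        if self.length_aa <= 0:
            raise ValidationError(f"{self.gene_name}: non-positive length")
        if self.mw_da is not None and self.mw_da <= 18.0:
            raise ValidationError(f"{self.gene_name}: implausible MW {self.mw_da}")
        if self.pi is not None and not (0 < self.pi < 14):
            raise ValidationError(f"{self.gene_name}: pI out of range {self.pi}")
        if self.n_splice_forms < 1:
            raise ValidationError(f"{self.gene_name}: n_splice_forms < 1")


@dataclass
class CensusSummary:
    """Counts and descriptive statistics over a census."""

    n_genes: int
    per_chromosome_counts: dict[str, int]
    per_chromosome_percent: dict[str, float]
    stats: dict[str, dict[str, float]] = field(default_factory=dict)


def filter_family_hits(hits: list[DomainHit], evalue_cutoff: float = 1e-5) -> set[str]:
    """Protein ids with at least one hit at E-value <= cutoff (set semantics)."""
    if evalue_cutoff <= 0:
        raise ValidationError(f"E-value cutoff must be positive, got {evalue_cutoff}")
    return {h.protein_id for h in hits if h.full_sequence_evalue <= evalue_cutoff}


def collapse_to_genes(
    members: set[str], records: list[ProteinRecord]
) -> dict[str, ProteinRecord]:
    """Collapse member transcripts to gene loci.

    Returns one representative record per locus: the longest member protein,
    ties broken by lexicographically smallest protein id.  The number of
    member isoforms per locus is available via :func:`splice_form_counts`.
    """
    by_id = {r.protein_id: r for r in records}
    absent = members - by_id.keys()
    if absent:
        raise MissingRecordError(f"member ids absent from records: {sorted(absent)}")
    best: dict[str, ProteinRecord] = {}
    # iterate in sorted id order with strict '>' so that among equally long
    # isoforms the lexicographically smallest protein_id is kept
    for pid in sorted(members):
        rec = by_id[pid]
        cur = best.get(rec.gene_locus)
        if cur is None or len(rec) > len(cur):
            best[rec.gene_locus] = rec
    return best


def splice_form_counts(members: set[str], records: list[ProteinRecord]) -> dict[str, int]:
    """Number of member isoforms per gene locus."""
    by_id = {r.protein_id: r for r in records}
    counts: dict[str, int] = {}
    for pid in members:
        if pid not in by_id:
            raise MissingRecordError(f"member id {pid!r} absent from records")
        locus = by_id[pid].gene_locus
        counts[locus] = counts.get(locus, 0) + 1
    return counts


def protein_mw(sequence: str) -> float:
    """Average molecular weight in Daltons: residue masses plus one water."""
    if not sequence:
        raise ValidationError("empty sequence has no molecular weight")
    try:
        return sum(RESIDUE_MASS[aa] for aa in sequence) + WATER_MW
    except KeyError as exc:
        raise ValidationError(
            f"residue {exc.args[0]!r} has no defined average mass"
        ) from None


def net_charge(sequence: str, ph: float, pka: Mapping[str, float] = EMBOSS_PKA) -> float:
    """Net protein charge at a given pH (Henderson-Hasselbalch terms)."""
    if not sequence:
        raise ValidationError("empty sequence has no charge")
    positive = 1.0 / (1.0 + 10 ** (ph - pka["Nterm"]))
    for aa in _BASIC:
        positive += sequence.count(aa) / (1.0 + 10 ** (ph - pka[aa]))
    negative = 1.0 / (1.0 + 10 ** (pka["Cterm"] - ph))
    for aa in _ACIDIC:
        negative += sequence.count(aa) / (1.0 + 10 ** (pka[aa] - ph))
    return positive - negative


def protein_pi(
    sequence: str,
    pka: Mapping[str, float] = EMBOSS_PKA,
    tol: float = 1e-4,
    max_iter: int = 100,
) -> float:
    """Isoelectric point by bisection on pH in [0, 14].

    Stops when |net charge| < ``tol`` or after ``max_iter`` bisections.
    """
    if not sequence:
        raise ValidationError("empty sequence has no pI")
    lo, hi = 0.0, 14.0
    mid = 7.0
    for _ in range(max_iter):
        mid = (lo + hi) / 2.0
        q = net_charge(sequence, mid, pka)
        if abs(q) < tol:
            break
        if q > 0:
            lo = mid
        else:
            hi = mid
    return mid


def build_census(
    genes: Mapping[str, ProteinRecord],
    models: list[GeneModel],
    naming_prefix: str = "ZmGRAS",
    splice_forms: Optional[Mapping[str, int]] = None,
    subgroups: Optional[Mapping[str, str]] = None,
) -> list[CensusEntry]:
    """Assemble census entries, one per locus, in ascending locus order.

    Proteins containing X are kept in the census but get no MW/pI
    (reported as missing, with a warning).
    """
    by_gene = {m.gene_id: m for m in models}
    entries = []
    for i, locus in enumerate(sorted(genes), start=1):
        rec = genes[locus]
        model = by_gene.get(locus)
        if model is None:
            raise MissingRecordError(f"no gene model for locus {locus!r}")
        if "X" in rec.sequence:
            warnings.warn(
                f"{locus}: sequence contains X; MW/pI not computed", stacklevel=2
            )
            mw = pi = None
        else:
            mw = protein_mw(rec.sequence)
            pi = protein_pi(rec.sequence)
        entries.append(
            CensusEntry(
                gene_name=f"{naming_prefix}{i}",
                gene_locus=locus,
                chromosome=model.chromosome,
                start=model.start,
                end=model.end,
                length_aa=len(rec),
                mw_da=mw,
                pi=pi,
                n_splice_forms=(splice_forms or {}).get(locus, 1),
                subgroup=(subgroups or {}).get(locus),
            )
        )
    return entries


def summarize_census(entries: list[CensusEntry]) -> CensusSummary:
    """Per-chromosome counts and min/max/mean of length, MW and pI."""
    if not entries:
        raise ValidationError("cannot summarize an empty census")
    counts: dict[str, int] = {}
    for e in entries:
        counts[e.chromosome] = counts.get(e.chromosome, 0) + 1
    n = len(entries)
    percent = {c: round(k / n * 100, 2) for c, k in counts.items()}
    stats = {}
    for col in ("length_aa", "mw_da", "pi"):
        values = [getattr(e, col) for e in entries if getattr(e, col) is not None]
        if values:
            stats[col] = {
                "min": min(values),
                "max": max(values),
                "mean": sum(values) / len(values),
            }
    return CensusSummary(
        n_genes=n,
        per_chromosome_counts=counts,
        per_chromosome_percent=percent,
        stats=stats,
    )


# ---------------------------------------------------------------------------
# Census TSV / summary JSON

CENSUS_COLUMNS = [
    "gene_name", "gene_locus", "chromosome", "start", "end",
    "length_aa", "mw_da", "pi", "n_splice_forms", "subgroup",
]


def write_census_tsv(entries: list[CensusEntry], path) -> None:
    pd.DataFrame(
        [[getattr(e, c) for c in CENSUS_COLUMNS] for e in entries],
        columns=CENSUS_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def read_census_tsv(path) -> list[CensusEntry]:
    df = pd.read_csv(path, sep="\t")
    entries = []
    for r in df.itertuples():
        entries.append(
            CensusEntry(
                gene_name=str(r.gene_name),
                gene_locus=str(r.gene_locus),
                chromosome=str(r.chromosome),
                start=int(r.start),
                end=int(r.end),
                length_aa=int(r.length_aa),
                mw_da=None if pd.isna(r.mw_da) else float(r.mw_da),
                pi=None if pd.isna(r.pi) else float(r.pi),
                n_splice_forms=(
                    1
                    if pd.isna(getattr(r, "n_splice_forms", 1))
                    else int(getattr(r, "n_splice_forms", 1))
                ),
                subgroup=None if pd.isna(getattr(r, "subgroup", None)) else str(r.subgroup),
            )
        )
    return entries


def write_summary_json(summary: CensusSummary, path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "n_genes": summary.n_genes,
                "per_chromosome_counts": summary.per_chromosome_counts,
                "per_chromosome_percent": summary.per_chromosome_percent,
                "stats": summary.stats,
            },
            fh,
            indent=2,
            sort_keys=True,
        )
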