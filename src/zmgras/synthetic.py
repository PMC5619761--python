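"""Planted-truth synthetic genome emulating a GRAS-like gene family.

The generator produces a toy proteome whose members share an ordered
C-terminal block architecture (LHRI, VHIID, LHRII, PFYRE, SAW analogs)
on top of subfamily-specific N-terminal blocks, together with gene models,
a per-domain hit table, motif occurrences, an expression matrix and a
replicate Ct table.  Every planted property (subfamily membership,
duplicate pairs and their classes, intron counts, expression clusters,
subfamily-specific motifs, a known fold change) is serialised alongside
the data so each pipeline stage can be scored against the truth.

The mutation model is deliberately simple: per-site substitution with
uniform replacement over the 19 alternative residues and no indels inside
planted duplicates, which keeps identity targets analytic (a duplicate
mutated at a fraction 1-t of its sites has global-alignment identity t).
The default magnitudes mirror the maize study: 86 genes in 8 subfamilies,
104 transcripts over 86 loci, 11 duplicate pairs, 80% intronless genes,
13 tissues, and 9 of 11 duplicate pairs with concordant expression.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io_formats import (
    DomainHit,
    GeneModel,
    MotifOccurrence,
    ProteinRecord,
    write_domtbl,
    write_fasta,
    write_gff3,
    write_motifs_tsv,
)

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

#: ordered shared C-terminal blocks and their lengths (aa)
CTERM_BLOCKS = (("LHRI", 30), ("VHIID", 40), ("LHRII", 30), ("PFYRE", 40), ("SAW", 40))
CTERM_LEN = sum(length for _, length in CTERM_BLOCKS)

DEFAULT_SUBFAMILY_SIZES = {
    "SCL3": 10, "HAM": 10, "LS": 4, "SCR": 4,
    "DELLA": 10, "SHR": 10, "PAT1": 10, "LISCL": 28,
}

#: subfamily of each planted duplicate pair (paper-like multiplicities)
DEFAULT_PAIR_SUBFAMILIES = (
    "SHR", "SHR", "SHR", "PAT1", "PAT1", "PAT1",
    "LISCL", "LISCL", "DELLA", "SCL3", "LS",
)

TISSUES_13 = (
    "seedling", "coleoptile", "radicle", "stem_SAM", "first_internode",
    "immature_tassel", "meiotic_tassel", "anthers", "primary_root",
    "pooled_leaves", "silks", "adult_leaf", "embryo_24DAP",
)

WIDESPREAD_MOTIFS = (1, 2, 3, 4, 5, 6, 9, 11)
SPECIFIC_MOTIFS = (15, 16, 17)  # planted only in the LISCL analog


@dataclass(frozen=True)
class SyntheticFamilySpec:
    """Parameters of the planted-truth genome."""

    seed: int
    subfamily_sizes: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_SUBFAMILY_SIZES)
    )
    pair_subfamilies: tuple[str, ...] = DEFAULT_PAIR_SUBFAMILIES
    n_tandem_pairs: int = 4
    duplicate_identity_target: float = 0.92
    background_max_identity: float = 0.5
    intronless_fraction: float = 0.80
    n_chromosomes: int = 10
    n_tissues: int = 13
    n_similar_pairs: int = 9
    n_splice_variant_genes: int = 18
    n_decoys: int = 40
    n_anchors_per_subfamily: int = 2
    n_motifs: int = 20
    nterm_len: int = 120
    subfamily_divergence: float = 0.15
    planted_fold_change: float = 4.0

    @property
    def n_duplicate_pairs(self) -> int:
        return len(self.pair_subfamilies)

    @property
    def n_genes(self) -> int:
        return sum(self.subfamily_sizes.values())

    @property
    def gene_divergence(self) -> float:
        """Per-gene mutation rate targeting the background identity ceiling."""
        return 1.0 - self.background_max_identity ** 0.5

    def validate(self) -> None:
        if self.duplicate_identity_target <= self.background_max_identity:
            raise ValidationError(
                "duplicate identity target must exceed background identity"
            )
        for name, value in (
            ("duplicate_identity_target", self.duplicate_identity_target),
            ("background_max_identity", self.background_max_identity),
            ("intronless_fraction", self.intronless_fraction),
        ):
            if not (0 <= value <= 1):
                raise ValidationError(f"{name} must lie in [0, 1], got {value}")
        if self.n_similar_pairs > self.n_duplicate_pairs:
            raise ValidationError("n_similar_pairs exceeds n_duplicate_pairs")
        if self.n_tandem_pairs > self.n_duplicate_pairs:
            raise ValidationError("n_tandem_pairs exceeds n_duplicate_pairs")
        for sub, n_pairs in _pairs_per_subfamily(self.pair_subfamilies).items():
            if self.subfamily_sizes.get(sub, 0) < 2 * n_pairs:
                raise ValidationError(
                    f"subfamily {sub} too small for {n_pairs} duplicate pairs"
                )


def _pairs_per_subfamily(pair_subfamilies) -> dict[str, int]:
    out: dict[str, int] = {}
    for sub in pair_subfamilies:
        out[sub] = out.get(sub, 0) + 1
    return out


@dataclass
class PlantedTruth:
    """Ground truth serialised next to the generated files."""

    subfamily: dict[str, str]
    anchor_labels: dict[str, str]
    duplicate_pairs: list[tuple[str, str, str]]  # (gene_a, gene_b, class)
    intron_counts: dict[str, int]
    expression_clusters: dict[str, int]
    similar_pairs: list[tuple[str, str]]
    divergent_pairs: list[tuple[str, str]]
    specific_motifs: dict[str, list[int]]
    splice_variant_genes: list[str]
    fold_change: dict

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "PlantedTruth":
        with open(path) as fh:
            raw = json.load(fh)
        raw["duplicate_pairs"] = [tuple(p) for p in raw["duplicate_pairs"]]
        raw["similar_pairs"] = [tuple(p) for p in raw["similar_pairs"]]
        raw["divergent_pairs"] = [tuple(p) for p in raw["divergent_pairs"]]
        return cls(**raw)


@dataclass
class SyntheticFamily:
    """In-memory bundle of everything :func:`generate_family` produces."""

    spec: SyntheticFamilySpec
    proteins: list[ProteinRecord]  # family members incl. splice variants
    decoys: list[ProteinRecord]
    anchors: list[ProteinRecord]
    gene_models: list[GeneModel]
    domain_hits: list[DomainHit]
    motif_occurrences: list[MotifOccurrence]
    truth: PlantedTruth

    @property
    def representative(self) -> dict[str, str]:
        """gene locus -> representative transcript id."""
        return {m.gene_id: f"{m.gene_id}_T01" for m in self.gene_models}

    def write(self, outdir) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "proteome": outdir / "proteome.fasta",
            "anchors_fasta": outdir / "anchors.fasta",
            "gff3": outdir / "genes.gff3",
            "domtbl": outdir / "domains.domtbl",
            "motifs": outdir / "motifs.tsv",
            "anchors_tsv": outdir / "anchors.tsv",
            "truth": outdir / "truth.json",
        }
        write_fasta(self.proteins + self.decoys, paths["proteome"])
        write_fasta(self.anchors, paths["anchors_fasta"])
        write_gff3(self.gene_models, paths["gff3"])
        write_domtbl(self.domain_hits, paths["domtbl"])
        write_motifs_tsv(self.motif_occurrences, paths["motifs"])
        pd.DataFrame(
            sorted(self.truth.anchor_labels.items()), columns=["leaf_id", "label"]
        ).to_csv(paths["anchors_tsv"], sep="\t", index=False)
        self.truth.to_json(paths["truth"])
        return paths


# ---------------------------------------------------------------------------
# Sequence helpers


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.choice(AMINO_ACIDS, size=length)


def _mutate_rate(rng: np.random.Generator, seq: np.ndarray, rate: float) -> np.ndarray:
    out = seq.copy()
    hits = np.flatnonzero(rng.random(len(seq)) < rate)
    for i in hits:
        choices = AMINO_ACIDS[AMINO_ACIDS != out[i]]
        out[i] = rng.choice(choices)
    return out


def _mutate_count(rng: np.random.Generator, seq: np.ndarray, count: int) -> np.ndarray:
    out = seq.copy()
    for i in rng.choice(len(seq), size=count, replace=False):
        choices = AMINO_ACIDS[AMINO_ACIDS != out[i]]
        out[i] = rng.choice(choices)
    return out


# ---------------------------------------------------------------------------
# Family generation


def generate_family(spec: SyntheticFamilySpec) -> SyntheticFamily:
    """Generate the proteome, gene models, domain hits, motifs and truth."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    subfamilies = list(spec.subfamily_sizes)

    # subfamily consensus sequences: unique N-terminal block + shared
    # C-terminal block architecture mutated per subfamily
    root_cterm = _random_seq(rng, CTERM_LEN)
    consensus: dict[str, np.ndarray] = {}
    for sub in subfamilies:
        nterm = _random_seq(rng, spec.nterm_len)
        cterm = _mutate_rate(rng, root_cterm, spec.subfamily_divergence)
        consensus[sub] = np.concatenate([nterm, cterm])

    # gene plan: per subfamily the last d genes are duplicates of the first d
    pairs_per_sub = _pairs_per_subfamily(spec.pair_subfamilies)
    gene_subfamily: dict[str, str] = {}
    gene_seq: dict[str, np.ndarray] = {}
    duplicate_of: dict[str, str] = {}
    counter = 0
    for sub in subfamilies:
        n_total = spec.subfamily_sizes[sub]
        n_dup = pairs_per_sub.get(sub, 0)
        originals = []
        for _ in range(n_total - n_dup):
            counter += 1
            locus = f"SYNG{counter:03d}"
            gene_subfamily[locus] = sub
            gene_seq[locus] = _mutate_rate(rng, consensus[sub], spec.gene_divergence)
            originals.append(locus)
        for k in range(n_dup):
            counter += 1
            locus = f"SYNG{counter:03d}"
            source = originals[k]
            gene_subfamily[locus] = sub
            n_mut = int(round((1.0 - spec.duplicate_identity_target) * len(gene_seq[source])))
            gene_seq[locus] = _mutate_count(rng, gene_seq[source], n_mut)
            duplicate_of[locus] = source

    # ordered duplicate pairs in spec order, first n_tandem_pairs tandem
    pair_list: list[tuple[str, str, str]] = []
    seen_per_sub: dict[str, int] = {}
    for idx, sub in enumerate(spec.pair_subfamilies):
        k = seen_per_sub.get(sub, 0)
        seen_per_sub[sub] = k + 1
        copies = [loc for loc, src in duplicate_of.items() if gene_subfamily[loc] == sub]
        copy = sorted(copies)[k]
        source = duplicate_of[copy]
        dup_class = "tandem" if idx < spec.n_tandem_pairs else "segmental"
        pair_list.append((source, copy, dup_class))

    # chromosome placement: tandem pairs adjacent on their own chromosome,
    # segmental pairs forced onto two different chromosomes
    chrom_genes: dict[int, list] = {c: [] for c in range(spec.n_chromosomes)}
    placed: set[str] = set()
    tandem_idx = segmental_idx = 0
    for source, copy, dup_class in pair_list:
        if dup_class == "tandem":
            c = tandem_idx % spec.n_chromosomes
            chrom_genes[c].append(("tandem_unit", source, copy))
            tandem_idx += 1
        else:
            c1 = segmental_idx % spec.n_chromosomes
            c2 = (segmental_idx + 3) % spec.n_chromosomes
            chrom_genes[c1].append(("gene", source))
            chrom_genes[c2].append(("gene", copy))
            segmental_idx += 1
        placed.update((source, copy))
    background = [loc for loc in sorted(gene_seq) if loc not in placed]
    for i, locus in enumerate(background):
        chrom_genes[i % spec.n_chromosomes].append(("gene", locus))

    # splice variants on non-duplicate background genes
    variant_loci = sorted(
        rng.choice(background, size=min(spec.n_splice_variant_genes, len(background)),
                   replace=False).tolist()
    )

    # intron counts are drawn to hit intronless_fraction exactly over the
    # final gene set: original loci are sampled (without replacement) into
    # the intronless class until round(fraction * n_genes) genes are
    # covered, with a duplicate inheriting its source's structure (so a
    # duplicated source counts for two genes)
    intron_weights = np.array([9.0, 5.0, 2.0, 0.5, 1.0])
    dup_sources = set(duplicate_of.values())
    originals = [loc for loc in sorted(gene_seq) if loc not in duplicate_of]
    target_intronless = int(round(spec.intronless_fraction * len(gene_seq)))
    covered = 0
    intronless: set[str] = set()
    for idx in rng.permutation(len(originals)):
        locus = originals[int(idx)]
        weight = 2 if locus in dup_sources else 1
        if covered + weight <= target_intronless:
            intronless.add(locus)
            covered += weight
    intron_counts: dict[str, int] = {}
    for locus in originals:
        if locus in intronless:
            intron_counts[locus] = 0
        else:
            intron_counts[locus] = int(
                rng.choice(np.arange(1, 6), p=intron_weights / intron_weights.sum())
            )
    for locus, source in duplicate_of.items():
        intron_counts[locus] = intron_counts[source]

    # build gene models chromosome by chromosome
    gene_models: list[GeneModel] = []
    for c in range(spec.n_chromosomes):
        pos = int(rng.integers(50_000, 500_000))
        entries = chrom_genes[c]
        order = rng.permutation(len(entries))
        for k in order:
            entry = entries[int(k)]
            loci = list(entry[1:])
            for li, locus in enumerate(loci):
                if li > 0:  # tandem partner: small gap
                    pos += int(np.exp(rng.uniform(np.log(2_000), np.log(50_000))))
                model = _build_gene_model(
                    rng, locus, f"chr{c + 1}",
                    start=pos,
                    aa_len=len(gene_seq[locus]),
                    n_introns=intron_counts[locus],
                    with_variant=locus in variant_loci,
                )
                gene_models.append(model)
                pos = model.end
                if li == len(loci) - 1:  # intergenic gap floor 300 kb
                    pos += int(np.exp(rng.uniform(np.log(300_000), np.log(2_000_000))))
    gene_models.sort(key=lambda m: m.gene_id)

    # protein records (representative _P01 plus _P02 truncations)
    proteins: list[ProteinRecord] = []
    for locus in sorted(gene_seq):
        seq = "".join(gene_seq[locus])
        proteins.append(ProteinRecord(f"{locus}_P01", locus, seq))
        if locus in variant_loci:
            cut = max(30, int(0.7 * len(seq)))
            proteins.append(ProteinRecord(f"{locus}_P02", locus, seq[:cut]))

    # decoys: unrelated proteins that must fail the E-value filter
    decoys = [
        ProteinRecord(
            f"DECOY{i + 1:03d}_P01",
            f"DECOY{i + 1:03d}",
            "".join(_random_seq(rng, int(rng.integers(150, 600)))),
        )
        for i in range(spec.n_decoys)
    ]

    # per-domain table: members pass (E in [1e-30, 1e-6]), decoys fail
    domain_hits: list[DomainHit] = []
    for rec in proteins:
        evalue = 10.0 ** rng.uniform(-30, -6)
        ali_to = len(rec.sequence)
        ali_from = max(1, ali_to - CTERM_LEN + 1)
        domain_hits.append(DomainHit(rec.protein_id, "GRAS_domain", evalue, ali_from, ali_to))
    for rec in decoys:
        evalue = 10.0 ** rng.uniform(-4, 0)
        domain_hits.append(
            DomainHit(rec.protein_id, "GRAS_domain", evalue, 1, len(rec.sequence))
        )

    # anchors: reference-species proteins drawn from each consensus
    anchors: list[ProteinRecord] = []
    anchor_labels: dict[str, str] = {}
    for sub in subfamilies:
        for k in range(spec.n_anchors_per_subfamily):
            pid = f"ANCHOR_{sub}_{k + 1}"
            seq = _mutate_rate(rng, consensus[sub], spec.gene_divergence)
            anchors.append(ProteinRecord(pid, pid, "".join(seq)))
            anchor_labels[pid] = sub

    motif_occurrences = _generate_motifs(spec, rng, gene_subfamily, gene_seq)

    truth = PlantedTruth(
        subfamily=dict(sorted(gene_subfamily.items())),
        anchor_labels=anchor_labels,
        duplicate_pairs=pair_list,
        intron_counts=dict(sorted(intron_counts.items())),
        expression_clusters={},  # filled by generate_expression
        similar_pairs=[],
        divergent_pairs=[],
        specific_motifs={"LISCL": list(SPECIFIC_MOTIFS)},
        splice_variant_genes=variant_loci,
        fold_change={},
    )
    return SyntheticFamily(
        spec=spec,
        proteins=proteins,
        decoys=decoys,
        anchors=anchors,
        gene_models=gene_models,
        domain_hits=domain_hits,
        motif_occurrences=motif_occurrences,
        truth=truth,
    )


def _build_gene_model(
    rng: np.random.Generator,
    locus: str,
    chromosome: str,
    start: int,
    aa_len: int,
    n_introns: int,
    with_variant: bool,
) -> GeneModel:
    cds_len = 3 * aa_len + 3
    n_exons = n_introns + 1
    # split the CDS into n_exons parts of at least 30 bp
    cuts = sorted(rng.choice(np.arange(30, cds_len - 30), size=n_exons - 1,
                             replace=False)) if n_exons > 1 else []
    bounds = [0] + [int(c) for c in cuts] + [cds_len]
    exon_lens = [bounds[i + 1] - bounds[i] for i in range(n_exons)]
    intron_lens = [int(rng.integers(100, 2000)) for _ in range(n_introns)]
    exons = []
    pos = start
    for i, elen in enumerate(exon_lens):
        exons.append((pos, pos + elen - 1))
        pos += elen
        if i < n_introns:
            pos += intron_lens[i]
    end = exons[-1][1]
    transcripts = [(f"{locus}_T01", exons)]
    if with_variant:
        cut = max(90, int(0.7 * cds_len))
        transcripts.append((f"{locus}_T02", [(start, start + cut - 1)]))
        # the variant must stay inside the gene span
        if start + cut - 1 > end:
            end = start + cut - 1
    strand = "+" if rng.random() < 0.5 else "-"
    return GeneModel(
        gene_id=locus, chromosome=chromosome, strand=strand,
        start=start, end=end, transcripts=transcripts,
    )


def _generate_motifs(
    spec: SyntheticFamilySpec,
    rng: np.random.Generator,
    gene_subfamily: dict[str, str],
    gene_seq: dict[str, np.ndarray],
) -> list[MotifOccurrence]:
    """Plant motif occurrences: widespread, LISCL-specific, and scattered."""
    occurrences: list[MotifOccurrence] = []
    loci = sorted(gene_seq)
    other_motifs = [
        m for m in range(1, spec.n_motifs + 1)
        if m not in WIDESPREAD_MOTIFS and m not in SPECIFIC_MOTIFS
    ]
    non_liscl = sorted(set(gene_subfamily.values()) - {"LISCL"})
    home = {m: non_liscl[i % len(non_liscl)] for i, m in enumerate(other_motifs)}

    for locus in loci:
        sub = gene_subfamily[locus]
        length = len(gene_seq[locus])
        offset = length - CTERM_LEN
        for rank, motif in enumerate(WIDESPREAD_MOTIFS):
            if rng.random() < 0.95:
                start = offset + 1 + rank * 20
                occurrences.append(
                    MotifOccurrence(locus, motif, start, min(start + 14, length),
                                    10.0 ** rng.uniform(-30, -5))
                )
        if sub == "LISCL":
            for rank, motif in enumerate(SPECIFIC_MOTIFS):
                if rng.random() < 0.95:
                    start = offset + 30 + rank * 25
                    occurrences.append(
                        MotifOccurrence(locus, motif, start, min(start + 19, length),
                                        10.0 ** rng.uniform(-30, -5))
                    )
        for motif in other_motifs:
            rate = 0.85 if home[motif] == sub else 0.05
            if rng.random() < rate:
                start = int(rng.integers(1, max(2, offset)))
                occurrences.append(
                    MotifOccurrence(locus, motif, start, min(start + 14, length),
                                    10.0 ** rng.uniform(-20, -3))
                )
    return occurrences


# ---------------------------------------------------------------------------
# Expression and Ct generation


def generate_expression(
    spec: SyntheticFamilySpec,
    truth: PlantedTruth,
    noise_sd: float = 0.2,
    ct_intercept: float = 28.0,
    ct_slope: float = 1.0,
    ct_noise_sd: float = 0.1,
    reference_gene: str = "ACTIN",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Expression matrix and replicate Ct table from subfamily archetypes.

    Each subfamily gets an archetype tissue profile; genes multiply it by
    per-cell lognormal noise (sd ``noise_sd`` in log2 units).  Of the
    planted duplicate pairs, the first ``n_similar_pairs`` share their
    archetype (target r >= 0.9) and the remaining pairs have the copy
    reassigned to a different archetype.  Ct values follow
    ``Ct = a - b*log2(expr)`` plus Gaussian noise, with three replicates
    and a constant reference gene.  Updates ``truth`` in place
    (expression_clusters, similar/divergent pairs, fold_change).
    """
    rng = np.random.default_rng(spec.seed + 1)
    tissues = list(TISSUES_13[: spec.n_tissues])
    if len(tissues) < spec.n_tissues:
        tissues += [f"tissue_{i}" for i in range(len(tissues), spec.n_tissues)]
    subfamilies = sorted(set(truth.subfamily.values()))
    # archetypes are drawn with pairwise log-correlation bounded away from 1
    # so the planted clusters are separable by construction
    profiles: list[np.ndarray] = []
    while len(profiles) < len(subfamilies):
        candidate = rng.normal(5.0, 2.0, size=spec.n_tissues)
        if all(abs(np.corrcoef(candidate, p)[0, 1]) <= 0.3 for p in profiles):
            profiles.append(candidate)
    archetype = {sub: 2.0 ** profiles[i] for i, sub in enumerate(subfamilies)}
    cluster_index = {sub: i for i, sub in enumerate(subfamilies)}

    gene_archetype = {
        locus: truth.subfamily[locus] for locus in truth.subfamily
    }
    similar = [tuple(p[:2]) for p in truth.duplicate_pairs[: spec.n_similar_pairs]]
    divergent = []
    for source, copy, _cls in truth.duplicate_pairs[spec.n_similar_pairs:]:
        own = truth.subfamily[copy]
        # reassign the copy to the archetype least correlated (raw scale)
        # with its source's, so the pair is divergent by construction
        gene_archetype[copy] = min(
            (s for s in subfamilies if s != own),
            key=lambda s: abs(np.corrcoef(archetype[own], archetype[s])[0, 1]),
        )
        divergent.append((source, copy))

    loci = sorted(truth.subfamily)
    values = np.empty((len(loci), spec.n_tissues))
    for i, locus in enumerate(loci):
        base = archetype[gene_archetype[locus]]
        values[i] = base * 2.0 ** rng.normal(0.0, noise_sd, size=spec.n_tissues)

    expr = pd.DataFrame(values, index=loci, columns=tissues)

    # plant a known fold change on a non-duplicate gene for Ct recovery
    dup_genes = {g for p in truth.duplicate_pairs for g in p[:2]}
    fold_gene = next(g for g in loci if g not in dup_genes)
    calibrator, fold_tissue = tissues[0], tissues[1]
    expr.loc[fold_gene, fold_tissue] = (
        spec.planted_fold_change * expr.loc[fold_gene, calibrator]
    )

    truth.expression_clusters = {
        locus: cluster_index[gene_archetype[locus]] for locus in loci
    }
    truth.similar_pairs = similar
    truth.divergent_pairs = divergent
    truth.fold_change = {
        "gene": fold_gene,
        "tissue": fold_tissue,
        "calibrator": calibrator,
        "ratio": spec.planted_fold_change,
    }

    # Ct table over the qPCR panel: one gene per duplicate pair, the
    # fold-change gene, and a constant reference gene; 9 sampled tissues
    panel = [p[0] for p in truth.duplicate_pairs] + [fold_gene]
    samples = tissues[: min(9, len(tissues))]
    rows = []
    for sample in samples:
        for gene in panel:
            true_ct = ct_intercept - ct_slope * np.log2(expr.loc[gene, sample])
            for rep in range(1, 4):
                rows.append(
                    (sample, gene, rep, round(true_ct + rng.normal(0, ct_noise_sd), 4))
                )
        for rep in range(1, 4):
            rows.append(
                (sample, reference_gene, rep, round(20.0 + rng.normal(0, 0.04), 4))
            )
    ct = pd.DataFrame(rows, columns=["sample", "gene", "replicate", "ct"])
    return expr, ct


def write_expression(expr: pd.DataFrame, ct: pd.DataFrame, outdir) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"expression": outdir / "expression.tsv", "ct": outdir / "ct.tsv"}
    expr.to_csv(paths["expression"], sep="\t", index_label="gene", float_format="%.6f")
    ct.to_csv(paths["ct"], sep="\t", index=False)
    return paths
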