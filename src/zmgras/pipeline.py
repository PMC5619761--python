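"""Run-level orchestration: config, stage sequencing, manifest, fixtures.

``run_pipeline`` wires the stages census -> phylogeny -> duplication ->
structure/motifs -> expression -> qPCR over a directory of input files,
writing each stage's outputs under ``<run>/<stage>/`` and a manifest
recording the config, seed and input checksums.  Stages whose inputs are
absent are skipped cleanly.

``table1_fixture`` ships the published 86-gene maize census table
(gene name, locus, coordinates, length, MW, pI, subgroup) as packaged
data.  The source table prints molecular weight under a kDa header while
the values are plainly Daltons (e.g. 55337.9); the fixture stores them in
Daltons as printed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import census as census_mod
from . import duplication as dup_mod
from . import expression as expr_mod
from . import phylogeny as phylo_mod
from . import structure_motifs as struct_mod
from .census import CensusEntry
from .errors import PackagingError, ValidationError, ZmGrasError
from .io_formats import (
    read_ct_tsv,
    read_domtbl,
    read_expression_tsv,
    read_fasta,
    read_gff3,
    read_motifs_tsv,
    write_newick,
)

logger = logging.getLogger(__name__)

TABLE1_SHA256 = "24c74069613453c295b5a02c393e990bd45566867bc771db76941489a2502abd"
_TABLE1_RESOURCE = "maize_gras_table1.tsv"


def table1_fixture() -> list[CensusEntry]:
    """The published 86-row maize GRAS census table as census entries."""
    ref = resources.files("zmgras.data").joinpath(_TABLE1_RESOURCE)
    try:
        raw = ref.read_bytes()
    except FileNotFoundError as exc:
        raise PackagingError(f"packaged fixture {_TABLE1_RESOURCE} missing") from exc
    digest = hashlib.sha256(raw).hexdigest()
    if TABLE1_SHA256 is not None and digest != TABLE1_SHA256:
        raise PackagingError(
            f"packaged fixture checksum mismatch: {digest} != {TABLE1_SHA256}"
        )
    df = pd.read_csv(ref.open("r"), sep="\t")
    if len(df) != 86:
        raise PackagingError(f"expected 86 fixture rows, found {len(df)}")
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
                mw_da=float(r.mw_da),
                pi=float(r.pi),
                subgroup=None if pd.isna(r.subgroup) else str(r.subgroup),
            )
        )
    return entries


@dataclass
class RunConfig:
    """Validated run-level configuration for the full pipeline."""

    fasta: Optional[str] = None
    gff3: Optional[str] = None
    domtbl: Optional[str] = None
    anchors_fasta: Optional[str] = None
    anchors_tsv: Optional[str] = None
    motifs: Optional[str] = None
    expression: Optional[str] = None
    ct: Optional[str] = None
    evalue_cutoff: float = 1e-5
    id_threshold: float = 0.80
    cov_threshold: float = 0.80
    tandem_window_bp: int = 200_000
    tandem_max_intervening: int = 5
    bootstrap_replicates: int = 1000
    distance_mode: str = "msa_pdist"
    scale_method: str = "zscore"
    cluster_distance: str = "pearson"
    cluster_linkage: str = "average"
    reference_gene: str = "ACTIN"
    calibrator_sample: Optional[str] = None
    naming_prefix: str = "GENE"
    seed: int = 0

    def validate(self) -> None:
        if self.evalue_cutoff <= 0:
            raise ValidationError("evalue_cutoff must be positive")
        for name in ("id_threshold", "cov_threshold"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValidationError(f"{name} must lie in (0, 1), got {v}")
        if self.bootstrap_replicates < 0:
            raise ValidationError("bootstrap_replicates must be >= 0")
        for name in ("fasta", "gff3", "domtbl", "anchors_fasta", "anchors_tsv",
                     "motifs", "expression", "ct"):
            path = getattr(self, name)
            if path is not None and not Path(path).exists():
                raise ValidationError(f"config path {name}={path!r} does not exist")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        config = cls(**raw)
        config.validate()
        return config


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig, run_dir) -> dict:
    """Execute all stages whose inputs are available; return the manifest."""
    config.validate()
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": dataclasses.asdict(config),
        "seed": config.seed,
        "inputs": {},
        "stages": {},
    }
    for name in ("fasta", "gff3", "domtbl", "anchors_fasta", "anchors_tsv",
                 "motifs", "expression", "ct"):
        path = getattr(config, name)
        if path is not None:
            manifest["inputs"][name] = {"path": str(path), "sha256": _sha256(path)}

    state: dict = {}
    stages = [
        ("census", _stage_census),
        ("phylogeny", _stage_phylogeny),
        ("duplication", _stage_duplication),
        ("structure", _stage_structure),
        ("expression", _stage_expression),
        ("qpcr", _stage_qpcr),
    ]
    for stage_name, stage_fn in stages:
        stage_dir = run_dir / stage_name
        try:
            outputs = stage_fn(config, state, stage_dir)
        except ZmGrasError as exc:
            logger.error("[%s] failed: %s", stage_name, exc)
            raise ZmGrasError(f"[{stage_name}] {exc}") from exc
        if outputs is None:
            logger.info("[%s] skipped (inputs absent)", stage_name)
            manifest["stages"][stage_name] = {"status": "skipped"}
        else:
            logger.info("[%s] completed: %d outputs", stage_name, len(outputs))
            manifest["stages"][stage_name] = {
                "status": "completed",
                "outputs": [str(p) for p in outputs],
            }
    with open(run_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


# ---------------------------------------------------------------------------
# Stages


def _stage_census(config: RunConfig, state: dict, outdir: Path):
    if not (config.fasta and config.domtbl and config.gff3):
        return None
    outdir.mkdir(parents=True, exist_ok=True)
    records = read_fasta(config.fasta)
    hits = read_domtbl(config.domtbl)
    models = read_gff3(config.gff3)
    members = census_mod.filter_family_hits(hits, config.evalue_cutoff)
    genes = census_mod.collapse_to_genes(members, records)
    splice = census_mod.splice_form_counts(members, records)
    entries = census_mod.build_census(
        genes, models, naming_prefix=config.naming_prefix, splice_forms=splice
    )
    summary = census_mod.summarize_census(entries)
    census_path = outdir / "census.tsv"
    summary_path = outdir / "summary.json"
    census_mod.write_census_tsv(entries, census_path)
    census_mod.write_summary_json(summary, summary_path)
    state.update(records=records, genes=genes, census=entries, models=models)
    return [census_path, summary_path]


def _stage_phylogeny(config: RunConfig, state: dict, outdir: Path):
    if "genes" not in state:
        return None
    outdir.mkdir(parents=True, exist_ok=True)
    items = [(locus, rec.sequence) for locus, rec in sorted(state["genes"].items())]
    anchors: dict[str, str] = {}
    if config.anchors_fasta and config.anchors_tsv:
        anchor_records = read_fasta(config.anchors_fasta)
        labels = pd.read_csv(config.anchors_tsv, sep="\t")
        anchors = dict(zip(labels["leaf_id"].astype(str), labels["label"].astype(str)))
        items += [(r.protein_id, r.sequence) for r in anchor_records]

    mode = config.distance_mode
    if mode == "msa_pdist" and len({len(s) for _, s in items}) != 1:
        logger.info("[phylogeny] sequences not equal length; using pairwise_global")
        mode = "pairwise_global"

    outputs = []
    if mode == "msa_pdist" and config.bootstrap_replicates > 0:
        tree = phylo_mod.bootstrap_support(
            items, config.bootstrap_replicates, seed=config.seed
        )
    else:
        dm = phylo_mod.pairwise_distance_matrix(items, mode)
        tree = phylo_mod.nj_tree(dm)
    tree_path = outdir / "tree.nwk"
    write_newick(tree, tree_path)
    outputs.append(tree_path)

    if anchors:
        assignment = phylo_mod.assign_subfamilies(tree, anchors)
        assign_path = outdir / "subfamilies.tsv"
        pd.DataFrame(
            sorted(assignment.items()), columns=["gene", "subfamily"]
        ).to_csv(assign_path, sep="\t", index=False)
        state["assignment"] = assignment
        outputs.append(assign_path)
    return outputs


def _stage_duplication(config: RunConfig, state: dict, outdir: Path):
    if "census" not in state or "genes" not in state:
        return None
    outdir.mkdir(parents=True, exist_ok=True)
    pairs = dup_mod.find_duplicate_pairs(
        state["census"],
        state["genes"],
        id_threshold=config.id_threshold,
        cov_threshold=config.cov_threshold,
        linked_window_bp=config.tandem_window_bp,
        linked_max_intervening=config.tandem_max_intervening,
    )
    pairs_path = outdir / "duplicate_pairs.tsv"
    pd.DataFrame(
        [
            (p.gene_a, p.gene_b, round(p.identity, 4), round(p.coverage, 4),
             p.dup_class, p.genomic_gap_bp)
            for p in pairs
        ],
        columns=["gene_a", "gene_b", "identity", "coverage", "dup_class", "gap_bp"],
    ).to_csv(pairs_path, sep="\t", index=False)
    dist = dup_mod.chromosome_distribution(state["census"])
    map_path = outdir / "chromosome_map.tsv"
    pd.DataFrame(
        [(c, k, pct) for c, (k, pct) in dist.items()],
        columns=["chromosome", "n_genes", "percent"],
    ).to_csv(map_path, sep="\t", index=False)
    state["pairs"] = pairs
    return [pairs_path, map_path]


def _stage_structure(config: RunConfig, state: dict, outdir: Path):
    if "models" not in state or "genes" not in state:
        return None
    outdir.mkdir(parents=True, exist_ok=True)
    family_loci = set(state["genes"])
    models = [m for m in state["models"] if m.gene_id in family_loci]
    representative = {}
    for m in models:
        # representative transcript: same isoform the census used
        rep_pid = state["genes"][m.gene_id].protein_id
        tids = [tid for tid, _ in m.transcripts]
        rep_tid = rep_pid.replace("_P", "_T")
        representative[m.gene_id] = rep_tid if rep_tid in tids else tids[0]
    structures = struct_mod.gene_structures(models, representative)
    hist, percent = struct_mod.intron_statistics(models, representative)
    struct_path = outdir / "structure.tsv"
    struct_mod.write_structure_tsv(structures, struct_path)
    hist_path = outdir / "intron_histogram.json"
    with open(hist_path, "w") as fh:
        json.dump({"counts": hist, "percent": percent}, fh, indent=2)
    outputs = [struct_path, hist_path]

    if config.motifs:
        occurrences = read_motifs_tsv(config.motifs)
        matrix = struct_mod.build_motif_matrix(occurrences, sorted(family_loci))
        matrix_path = outdir / "motif_matrix.tsv"
        struct_mod.write_motif_matrix_tsv(matrix, matrix_path)
        outputs.append(matrix_path)
        if "assignment" in state:
            specific = struct_mod.subfamily_specific_motifs(
                matrix, state["assignment"]
            )
            spec_path = outdir / "specific_motifs.json"
            with open(spec_path, "w") as fh:
                json.dump(specific, fh, indent=2, sort_keys=True)
            outputs.append(spec_path)
    return outputs


def _stage_expression(config: RunConfig, state: dict, outdir: Path):
    if not config.expression:
        return None
    outdir.mkdir(parents=True, exist_ok=True)
    matrix = expr_mod.ExpressionMatrix(read_expression_tsv(config.expression))
    scaled = expr_mod.scale_rows(matrix, config.scale_method)
    dendro = expr_mod.hierarchical_cluster(
        scaled, "genes", config.cluster_distance, config.cluster_linkage
    )
    order_path = outdir / "clustered_order.tsv"
    pd.DataFrame({"gene": dendro.leaf_order()}).to_csv(
        order_path, sep="\t", index=False
    )
    scaled_path = outdir / "scaled_matrix.tsv"
    scaled.values.to_csv(scaled_path, sep="\t", index_label="gene")
    outputs = [order_path, scaled_path]
    if "pairs" in state:
        pair_ids = [(p.gene_a, p.gene_b) for p in state["pairs"]]
        pair_ids = [
            (a, b) for a, b in pair_ids
            if a in matrix.values.index and b in matrix.values.index
        ]
        if pair_ids:
            calls = expr_mod.pair_expression_similarity(matrix, pair_ids)
            sim_path = outdir / "pair_similarity.tsv"
            pd.DataFrame(
                [(a, b, call) for (a, b), call in calls.items()],
                columns=["gene_a", "gene_b", "call"],
            ).to_csv(sim_path, sep="\t", index=False)
            outputs.append(sim_path)
    state["expression"] = matrix
    return outputs


def _stage_qpcr(config: RunConfig, state: dict, outdir: Path):
    if not config.ct:
        return None
    outdir.mkdir(parents=True, exist_ok=True)
    data = read_ct_tsv(config.ct)
    calibrator = config.calibrator_sample or sorted(data["sample"].unique())[0]
    table = expr_mod.QpcrTable(
        data=data,
        reference_gene=config.reference_gene,
        calibrator_sample=calibrator,
    )
    rows = []
    genes = sorted(g for g in data["gene"].unique() if g != config.reference_gene)
    for gene in genes:
        for sample in sorted(data["sample"].unique()):
            result = expr_mod.ddct(table, gene, sample)
            rows.append(
                (gene, sample, round(result.relative_expression, 6),
                 round(result.ddct, 6))
            )
    rel_path = outdir / "relative_expression.tsv"
    pd.DataFrame(
        rows, columns=["gene", "sample", "relative_expression", "ddct"]
    ).to_csv(rel_path, sep="\t", index=False)
    return [rel_path]
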