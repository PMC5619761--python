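"""Distance estimation, neighbor-joining trees, bootstrap and subfamily calls.

Distances are protein p-distances (mismatches over columns where both
sequences carry a residue; gapped columns are excluded pairwise), with an
optional Kimura correction d = -ln(1 - p - 0.2 p^2).  Trees are built by
the canonical neighbor-joining algorithm: at each step join the pair
minimising

    Q(i,j) = (r - 2) d(i,j) - sum_k d(i,k) - sum_k d(j,k)

with branch lengths v_i = d(i,j)/2 + (R_i - R_j)/(2(r-2)) and reduced
distances d(u,m) = (d(i,m) + d(j,m) - d(i,j)) / 2.  Negative branch
lengths are clamped to zero with the deficit moved to the sibling edge.
Bootstrap supports are bipartition frequencies over column-resampled
replicates.  Subfamily labels propagate from reference anchors: each query
leaf takes the majority anchor label of the smallest clade (after midpoint
rooting) that contains it together with at least one anchor.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping, Optional, Union

import numpy as np
from skbio import DistanceMatrix

from .duplication import AlignmentScoring, global_align
from .errors import ValidationError
from .io_formats import ProteinRecord
from .tree import Clade, PhyloTree

UNASSIGNED = "UNASSIGNED"
SUBFAMILIES = ("SCL3", "HAM", "LS", "SCR", "DELLA", "SHR", "PAT1", "LISCL")

#: p beyond which the Kimura correction is undefined
KIMURA_MAX_P = 0.854
DEFAULT_KIMURA_CEILING = 10.0

SeqInput = Union[Iterable[ProteinRecord], Iterable[tuple[str, str]], Mapping[str, str]]


def _as_label_seq(records: SeqInput) -> list[tuple[str, str]]:
    if isinstance(records, Mapping):
        return [(str(k), str(v)) for k, v in records.items()]
    out = []
    for item in records:
        if isinstance(item, ProteinRecord):
            out.append((item.protein_id, item.sequence))
        else:
            label, seq = item
            out.append((str(label), str(seq)))
    return out


def p_distance(seq_a: str, seq_b: str, pair: tuple[str, str] = ("a", "b")) -> float:
    """Mismatch fraction over columns where both sequences have residues."""
    if len(seq_a) != len(seq_b):
        raise ValidationError(f"sequences {pair} are not aligned (unequal lengths)")
    comparable = mismatches = 0
    for ca, cb in zip(seq_a, seq_b):
        if ca != "-" and cb != "-":
            comparable += 1
            if ca != cb:
                mismatches += 1
    if comparable == 0:
        raise ValidationError(f"pair {pair} shares no comparable columns")
    return mismatches / comparable


def kimura_correction(p: float, ceiling: float = DEFAULT_KIMURA_CEILING) -> float:
    if p >= KIMURA_MAX_P:
        return ceiling
    return -math.log(1.0 - p - 0.2 * p * p)


def pairwise_distance_matrix(
    records: SeqInput,
    mode: str = "msa_pdist",
    correction: Optional[str] = None,
    kimura_ceiling: float = DEFAULT_KIMURA_CEILING,
    scoring: AlignmentScoring = AlignmentScoring(),
) -> DistanceMatrix:
    """Pairwise p-distance matrix from aligned or unaligned proteins.

    ``mode='msa_pdist'`` expects pre-aligned (equal-length) sequences;
    ``mode='pairwise_global'`` aligns each pair globally first.
    """
    items = _as_label_seq(records)
    if len(items) < 3:
        raise ValidationError("need at least 3 sequences for a distance matrix")
    if mode not in ("msa_pdist", "pairwise_global"):
        raise ValidationError(f"unknown mode {mode!r}")
    labels = [label for label, _ in items]
    if len(set(labels)) != len(labels):
        raise ValidationError("duplicate sequence labels")
    n = len(items)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            (la, sa), (lb, sb) = items[i], items[j]
            if mode == "msa_pdist":
                p = p_distance(sa, sb, (la, lb))
            else:
                aln = global_align(sa, sb, scoring, id_a=la, id_b=lb)
                p = p_distance(aln.aligned_a, aln.aligned_b, (la, lb))
            if correction == "kimura":
                p = kimura_correction(p, kimura_ceiling)
            d[i, j] = d[j, i] = p
    return DistanceMatrix(d, ids=labels)


# ---------------------------------------------------------------------------
# Neighbor joining


def nj_tree(dm: DistanceMatrix) -> PhyloTree:
    """Neighbor-joining tree (unrooted, trifurcating root) from a distance matrix.

    Q-ties are broken towards the lexicographically smallest pair of
    subtree labels (a subtree is labelled by its smallest leaf) so the
    result is deterministic and independent of input order.
    """
    labels = list(dm.ids)
    if len(labels) < 3:
        raise ValidationError("neighbor joining needs at least 3 taxa")
    d = np.array(dm.data, dtype=float)
    nodes = [Clade(name=label) for label in labels]
    reps = list(labels)  # smallest leaf label per active subtree

    while len(nodes) > 3:
        r = len(nodes)
        row_sums = d.sum(axis=1)
        q = (r - 2) * d - row_sums[:, None] - row_sums[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        candidates = np.argwhere(q <= qmin + 1e-12)
        i, j = min(
            ((int(a), int(b)) for a, b in candidates if a < b),
            key=lambda ij: tuple(sorted((reps[ij[0]], reps[ij[1]]))),
        )
        dij = d[i, j]
        vi = dij / 2.0 + (row_sums[i] - row_sums[j]) / (2.0 * (r - 2))
        vj = dij - vi
        # PHYLIP-style clamping: negative edge -> 0, deficit to the sibling
        if vi < 0:
            vj += vi
            vi = 0.0
        if vj < 0:
            vi += vj
            vj = 0.0
        vi, vj = max(vi, 0.0), max(vj, 0.0)
        nodes[i].branch_length = vi
        nodes[j].branch_length = vj
        new = Clade(children=[nodes[i], nodes[j]])
        new_dist = (d[i, :] + d[j, :] - dij) / 2.0

        keep = [k for k in range(r) if k not in (i, j)]
        d = np.vstack([d[keep][:, keep], new_dist[keep]])
        d = np.hstack([d, np.append(new_dist[keep], 0.0)[:, None]])
        nodes = [nodes[k] for k in keep] + [new]
        reps = [reps[k] for k in keep] + [min(reps[i], reps[j])]

    # final trifurcation: closed-form lengths a=(d01+d02-d12)/2 etc.
    d01, d02, d12 = d[0, 1], d[0, 2], d[1, 2]
    lengths = [
        (d01 + d02 - d12) / 2.0,
        (d01 + d12 - d02) / 2.0,
        (d02 + d12 - d01) / 2.0,
    ]
    for node, length in zip(nodes, lengths):
        node.branch_length = max(length, 0.0)
    return PhyloTree(root=Clade(children=nodes))


# ---------------------------------------------------------------------------
# Bootstrap


def bootstrap_support(
    alignment: SeqInput,
    n_replicates: int,
    seed: int,
    correction: Optional[str] = None,
) -> PhyloTree:
    """NJ tree with bipartition bootstrap supports (percent, integer).

    Replicate r resamples alignment columns with an RNG seeded ``seed + r``,
    so runs are reproducible and trivially parallelisable.
    """
    items = _as_label_seq(alignment)
    if n_replicates < 1:
        raise ValidationError("need at least one bootstrap replicate")
    lengths = {len(seq) for _, seq in items}
    if len(lengths) != 1:
        raise ValidationError("bootstrap requires aligned, equal-length sequences")
    n_cols = lengths.pop()
    labels = [label for label, _ in items]
    seqs = [seq for _, seq in items]

    base = nj_tree(pairwise_distance_matrix(items, "msa_pdist", correction))
    counts: dict[frozenset, int] = {part: 0 for part in base.bipartitions()}

    arr = np.array([list(s) for s in seqs])
    for rep in range(n_replicates):
        rng = np.random.default_rng(seed + rep)
        cols = rng.integers(0, n_cols, size=n_cols)
        resampled = ["".join(row) for row in arr[:, cols]]
        rep_tree = nj_tree(
            pairwise_distance_matrix(list(zip(labels, resampled)), "msa_pdist", correction)
        )
        for part in rep_tree.bipartitions():
            if part in counts:
                counts[part] += 1

    all_leaves = frozenset(labels)
    anchor = min(all_leaves)
    for node in base.root.walk():
        if node is base.root or node.is_leaf:
            continue
        side = frozenset(leaf.name for leaf in node.walk() if leaf.is_leaf)
        if anchor in side:
            side = all_leaves - side
        if side in counts:
            node.support = int(round(100.0 * counts[side] / n_replicates))
    return base


# ---------------------------------------------------------------------------
# Subfamily assignment


def assign_subfamilies(
    tree: PhyloTree, anchors: Mapping[str, str]
) -> dict[str, str]:
    """Propagate anchor subfamily labels to query leaves.

    The tree is midpoint rooted; each non-anchor leaf takes the majority
    anchor label of its smallest proper ancestor clade that contains at
    least one anchor.  Majority ties, or no anchor outside the root clade,
    yield ``UNASSIGNED``.
    """
    if not anchors:
        raise ValidationError("anchor set is empty")
    missing = set(anchors) - set(tree.leaf_names())
    if missing:
        raise ValidationError(f"anchors not in tree: {sorted(missing)}")

    rooted = tree.midpoint_rooted()
    parents: dict[int, Clade] = {}
    for node in rooted.root.walk():
        for child in node.children:
            parents[id(child)] = node
    leaf_nodes = {leaf.name: leaf for leaf in rooted.leaves()}

    anchor_sets: dict[int, list[str]] = {}

    def collect(node: Clade) -> list[str]:
        if node.is_leaf:
            found = [anchors[node.name]] if node.name in anchors else []
        else:
            found = [lab for c in node.children for lab in collect(c)]
        anchor_sets[id(node)] = found
        return found

    collect(rooted.root)

    assignment: dict[str, str] = {}
    for name, leaf in leaf_nodes.items():
        if name in anchors:
            continue
        label = UNASSIGNED
        node = parents.get(id(leaf))
        while node is not None and node is not rooted.root:
            found = anchor_sets[id(node)]
            if found:
                tally: dict[str, int] = {}
                for lab in found:
                    tally[lab] = tally.get(lab, 0) + 1
                ranked = sorted(tally.items(), key=lambda kv: (-kv[1], kv[0]))
                if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
                    label = UNASSIGNED
                else:
                    label = ranked[0][0]
                break
            node = parents.get(id(node))
        assignment[name] = label
    return assignment
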