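"""Distances, neighbor joining, bootstrap and subfamily propagation."""

import numpy as np
import pytest
from skbio import DistanceMatrix

from zmgras.errors import ValidationError
from zmgras.phylogeny import (
    UNASSIGNED,
    assign_subfamilies,
    bootstrap_support,
    kimura_correction,
    nj_tree,
    p_distance,
    pairwise_distance_matrix,
)
from zmgras.tree import Clade, PhyloTree

from oracles import ls_best_topology, random_additive_tree


# ---------------------------------------------------------------------------
# p-distance


def test_p_distance_basic_and_identity():
    assert p_distance("AAAA", "AAAT") == pytest.approx(0.25)
    assert p_distance("MKVL", "MKVL") == 0.0


def test_p_distance_excludes_gap_columns_pairwise():
    # comparable columns: positions 1, 2, 4 (0-based 0,1,3); one mismatch
    assert p_distance("AA-A", "AATA") == pytest.approx(0.0)
    assert p_distance("AC-A", "AATG") == pytest.approx(2 / 3)


def test_p_distance_no_comparable_columns_raises():
    with pytest.raises(ValidationError, match="x.*y"):
        p_distance("A-", "-A", ("x", "y"))


def test_kimura_correction_behaviour():
    assert kimura_correction(0.0) == pytest.approx(0.0)
    assert kimura_correction(0.3) == pytest.approx(-np.log(1 - 0.3 - 0.2 * 0.09))
    assert kimura_correction(0.9, ceiling=7.5) == 7.5


def test_distance_matrix_modes_agree_on_equal_length_sequences():
    items = [("a", "MKVLAT"), ("b", "MKVLAG"), ("c", "MKIWAT")]
    msa = pairwise_distance_matrix(items, "msa_pdist")
    glob = pairwise_distance_matrix(items, "pairwise_global")
    assert np.allclose(msa.data, glob.data)


# ---------------------------------------------------------------------------
# Neighbor joining


def test_nj_three_taxa_closed_form():
    d = np.array([[0.0, 0.3, 0.5], [0.3, 0.0, 0.6], [0.5, 0.6, 0.0]])
    tree = nj_tree(DistanceMatrix(d, ids=["A", "B", "C"]))
    lengths = {leaf.name: leaf.branch_length for leaf in tree.leaves()}
    assert lengths["A"] == pytest.approx((0.3 + 0.5 - 0.6) / 2, abs=1e-9)
    assert lengths["B"] == pytest.approx((0.3 + 0.6 - 0.5) / 2, abs=1e-9)
    assert lengths["C"] == pytest.approx((0.5 + 0.6 - 0.3) / 2, abs=1e-9)
    # the two closed-form branch lengths at a join sum to d(i,j)
    assert lengths["A"] + lengths["B"] == pytest.approx(0.3, abs=1e-12)


def _index_bipartitions(tree: PhyloTree, n: int) -> set:
    got = set()
    for side in tree.bipartitions():
        idx = frozenset(int(name[1:]) for name in side)
        if 0 in idx:
            idx = frozenset(range(n)) - idx
        got.add(idx)
    return got


def test_nj_recovers_additive_trees_against_ls_oracle():
    """On additive matrices NJ must match the exhaustive least-squares
    topology and reproduce the generating branch lengths through path
    distances."""
    rng = np.random.default_rng(123)
    for _ in range(30):
        n = int(rng.integers(4, 9))
        dist, true_parts = random_additive_tree(rng, n)
        labels = [f"L{i:02d}" for i in range(n)]
        tree = nj_tree(DistanceMatrix(dist, ids=labels))
        assert _index_bipartitions(tree, n) == set(true_parts)
        assert _index_bipartitions(tree, n) == set(ls_best_topology(dist))


def test_nj_path_distances_reproduce_additive_input():
    rng = np.random.default_rng(7)
    dist, _ = random_additive_tree(rng, 6)
    labels = [f"L{i:02d}" for i in range(6)]
    tree = nj_tree(DistanceMatrix(dist, ids=labels))
    tip_dists = tree.to_skbio().tip_tip_distances()
    for i in range(6):
        for j in range(i + 1, 6):
            assert tip_dists[labels[i], labels[j]] == pytest.approx(
                dist[i, j], abs=1e-9
            )


def test_nj_label_permutation_gives_isomorphic_tree():
    rng = np.random.default_rng(5)
    dist, _ = random_additive_tree(rng, 7)
    labels = [f"L{i:02d}" for i in range(7)]
    tree = nj_tree(DistanceMatrix(dist, ids=labels))
    perm = rng.permutation(7)
    permuted = dist[np.ix_(perm, perm)]
    tree2 = nj_tree(
        DistanceMatrix(permuted, ids=[labels[i] for i in perm])
    )
    assert tree.bipartitions() == tree2.bipartitions()


def test_nj_matches_scikit_bio_on_random_matrix():
    """Cross-check against an independent NJ implementation."""
    import skbio.tree

    rng = np.random.default_rng(11)
    dist, _ = random_additive_tree(rng, 8)
    dist += rng.uniform(0, 0.01, dist.shape)  # break exact additivity
    dist = (dist + dist.T) / 2
    np.fill_diagonal(dist, 0.0)
    labels = [f"L{i:02d}" for i in range(8)]
    ours = nj_tree(DistanceMatrix(dist, ids=labels))
    theirs = PhyloTree.from_skbio(skbio.tree.nj(DistanceMatrix(dist, ids=labels)))
    assert ours.bipartitions() == theirs.bipartitions()


def test_nj_requires_three_taxa():
    with pytest.raises(ValidationError):
        nj_tree(DistanceMatrix(np.array([[0.0, 1.0], [1.0, 0.0]]), ids=["a", "b"]))


# ---------------------------------------------------------------------------
# Bootstrap


def test_bootstrap_uniform_alignment_gives_full_support():
    items = [("a", "ACAA"), ("b", "ACAA"), ("c", "GTGG"), ("d", "GTGG")]
    # every column supports the split {a,b}|{c,d}; all supports must be 100
    tree = bootstrap_support(items, n_replicates=20, seed=3)
    supports = [n.support for n in tree.root.walk() if n.support is not None]
    assert supports and all(s == 100 for s in supports)


def test_bootstrap_supports_in_range_and_deterministic(family):
    items = [(r.gene_locus, r.sequence) for r in family.proteins[:12]
             if r.protein_id.endswith("_P01")]
    t1 = bootstrap_support(items, n_replicates=25, seed=9)
    t2 = bootstrap_support(items, n_replicates=25, seed=9)
    s1 = [n.support for n in t1.root.walk() if n.support is not None]
    s2 = [n.support for n in t2.root.walk() if n.support is not None]
    assert s1 == s2
    assert all(0 <= s <= 100 for s in s1)


def test_bootstrap_rejects_unaligned_input():
    with pytest.raises(ValidationError):
        bootstrap_support([("a", "AA"), ("b", "AAA"), ("c", "AA")], 5, seed=0)


# ---------------------------------------------------------------------------
# Subfamily assignment


def _leaf(name, length=0.1):
    return Clade(name=name, branch_length=length)


def test_query_sister_to_single_anchor():
    inner = Clade(children=[_leaf("q"), _leaf("DELLA_anchor")], branch_length=0.1)
    root = Clade(children=[inner, _leaf("far", 2.0), _leaf("far2", 2.1)])
    tree = PhyloTree(root=root)
    result = assign_subfamilies(tree, {"DELLA_anchor": "DELLA"})
    assert result["q"] == "DELLA"


def test_majority_rule_in_mixed_clade():
    clade = Clade(
        children=[
            _leaf("q"),
            Clade(
                children=[
                    _leaf("p1"), _leaf("p2"), _leaf("s1"),
                ],
                branch_length=0.05,
            ),
        ],
        branch_length=0.1,
    )
    root = Clade(children=[clade, _leaf("out", 3.0), _leaf("out2", 3.1)])
    tree = PhyloTree(root=root)
    result = assign_subfamilies(
        tree, {"p1": "PAT1", "p2": "PAT1", "s1": "SHR"}
    )
    assert result["q"] == "PAT1"


def test_tie_yields_unassigned():
    clade = Clade(
        children=[
            _leaf("q"),
            Clade(children=[_leaf("p1"), _leaf("s1")], branch_length=0.05),
        ],
        branch_length=0.1,
    )
    root = Clade(children=[clade, _leaf("out", 3.0), _leaf("out2", 3.1)])
    result = assign_subfamilies(
        PhyloTree(root=root), {"p1": "PAT1", "s1": "SHR"}
    )
    assert result["q"] == UNASSIGNED


def test_empty_anchor_set_raises(family):
    items = [(r.gene_locus, r.sequence) for r in family.proteins[:6]]
    tree = nj_tree(pairwise_distance_matrix(items, "msa_pdist"))
    with pytest.raises(ValidationError):
        assign_subfamilies(tree, {})


def test_planted_subfamilies_recovered(family):
    """>= 95% of genes recover their planted subfamily from anchors."""
    items = [(r.gene_locus, r.sequence) for r in family.proteins
             if r.protein_id.endswith("_P01")]
    items += [(a.protein_id, a.sequence) for a in family.anchors]
    tree = nj_tree(pairwise_distance_matrix(items, "msa_pdist"))
    assignment = assign_subfamilies(tree, family.truth.anchor_labels)
    truth = family.truth.subfamily
    labels_used = set(assignment.values()) - {UNASSIGNED}
    assert labels_used <= set(family.truth.anchor_labels.values())
    recovered = sum(assignment[g] == truth[g] for g in truth) / len(truth)
    assert recovered >= 0.95
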