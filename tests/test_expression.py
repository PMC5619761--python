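"""Scaling, hierarchical clustering, pair similarity and comparative Ct."""

import numpy as np
import pandas as pd
import pytest

from zmgras.errors import ValidationError
from zmgras.expression import (
    DdctResult,
    ExpressionMatrix,
    QpcrTable,
    ddct,
    hierarchical_cluster,
    pair_expression_similarity,
    pearson_distance,
    scale_rows,
)

from oracles import naive_agglomeration


def _matrix(rows, genes=None, tissues=None):
    arr = np.array(rows, dtype=float)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    tissues = tissues or [f"t{j}" for j in range(arr.shape[1])]
    return ExpressionMatrix(pd.DataFrame(arr, index=genes, columns=tissues))


# ---------------------------------------------------------------------------
# Scaling


def test_unit_max_scaling():
    scaled = scale_rows(_matrix([[1, 2, 3]]), "unit_max")
    assert np.allclose(scaled.values.to_numpy(), [[1 / 3, 2 / 3, 1.0]])


def test_zscore_constant_row_maps_to_zeros():
    scaled = scale_rows(_matrix([[5, 5, 5], [1, 2, 3]]), "zscore")
    assert np.allclose(scaled.values.loc["g0"].to_numpy(), 0.0)


def test_zscore_rows_standardized():
    scaled = scale_rows(_matrix([[1, 2, 3, 10], [4, 0, 8, 2]]), "zscore")
    out = scaled.values.to_numpy()
    assert np.allclose(out.mean(axis=1), 0.0, atol=1e-12)
    assert np.allclose(out.std(axis=1), 1.0, atol=1e-12)


def test_all_na_row_rejected():
    df = pd.DataFrame([[np.nan, np.nan]], index=["g"], columns=["a", "b"])
    with pytest.raises(ValidationError):
        ExpressionMatrix(df)


# ---------------------------------------------------------------------------
# Clustering


def test_identical_rows_merge_first_at_zero_height():
    matrix = _matrix([[1, 2, 3], [1, 2, 3], [9, 1, 4]])
    dendro = hierarchical_cluster(matrix, "genes", "pearson", "average")
    first = dendro.merges[0]
    assert {first[0], first[1]} == {0, 1}
    assert first[2] == pytest.approx(0.0, abs=1e-12)


def test_anticorrelated_rows_pearson_distance_two():
    x = np.array([1.0, 2.0, 3.0])
    assert pearson_distance(x, -x) == pytest.approx(2.0)
    assert pearson_distance(x, x) == pytest.approx(0.0)


@pytest.mark.parametrize("linkage", ["average", "complete", "single"])
def test_merge_order_matches_naive_agglomeration_oracle(linkage):
    rng = np.random.default_rng(21)
    data = rng.random((6, 5)) * 10
    matrix = _matrix(data)
    dendro = hierarchical_cluster(matrix, "genes", "euclidean", linkage)
    # oracle on the same item-level distances
    dmat = np.zeros((6, 6))
    for i in range(6):
        for j in range(6):
            dmat[i, j] = np.sqrt(((data[i] - data[j]) ** 2).sum())
    expected = naive_agglomeration(dmat, linkage)
    got = [(i, j, h) for i, j, h, _size in dendro.merges]
    for (gi, gj, gh), (ei, ej, eh) in zip(got, expected):
        assert {gi, gj} == {ei, ej}
        assert gh == pytest.approx(eh, abs=1e-12)


def test_average_linkage_matches_scipy_on_complete_data():
    from scipy.cluster.hierarchy import linkage as scipy_linkage

    rng = np.random.default_rng(5)
    data = rng.random((8, 6))
    dendro = hierarchical_cluster(_matrix(data), "genes", "euclidean", "average")
    Z = scipy_linkage(data, method="average", metric="euclidean")
    assert np.allclose(sorted(dendro.heights()), sorted(Z[:, 2]), atol=1e-10)


def test_average_linkage_heights_monotone(family, expression_bundle):
    expr, _ct = expression_bundle
    matrix = ExpressionMatrix(expr)
    dendro = hierarchical_cluster(scale_rows(matrix, "zscore"), "genes")
    heights = dendro.heights()
    assert all(b >= a - 1e-9 for a, b in zip(heights, heights[1:]))
    assert all(0.0 <= h <= 2.0 + 1e-9 for h in heights)  # pearson range


def test_clustering_invariant_to_row_permutation():
    rng = np.random.default_rng(13)
    data = rng.random((7, 5))
    genes = [f"g{i}" for i in range(7)]
    d1 = hierarchical_cluster(_matrix(data, genes), "genes", "euclidean", "average")
    perm = rng.permutation(7)
    d2 = hierarchical_cluster(
        _matrix(data[perm], [genes[i] for i in perm]), "genes", "euclidean", "average"
    )
    def merged_sets(dendro):
        n = len(dendro.labels)
        sets = {i: frozenset([dendro.labels[i]]) for i in range(n)}
        out = []
        for k, (i, j, h, _s) in enumerate(dendro.merges):
            sets[n + k] = sets[i] | sets[j]
            out.append((sets[n + k], round(h, 10)))
        return out
    assert merged_sets(d1) == merged_sets(d2)


def test_planted_expression_clusters_recovered(family, expression_bundle):
    """Cutting the dendrogram at the planted cluster count gives ARI >= 0.9."""
    from sklearn.metrics import adjusted_rand_score

    expr, _ct = expression_bundle
    matrix = ExpressionMatrix(expr)
    dendro = hierarchical_cluster(scale_rows(matrix, "zscore"), "genes")
    k = len(set(family.truth.expression_clusters.values()))
    cut = dendro.cut(k)
    truth = [family.truth.expression_clusters[g] for g in dendro.labels]
    pred = [cut[g] for g in dendro.labels]
    assert adjusted_rand_score(truth, pred) >= 0.9


def test_cluster_needs_two_items():
    with pytest.raises(ValidationError):
        hierarchical_cluster(_matrix([[1, 2, 3]]), "genes")


# ---------------------------------------------------------------------------
# Pair similarity


def test_identical_profiles_similar_and_anticorrelated_divergent():
    matrix = _matrix([[1, 5, 2, 8], [1, 5, 2, 8], [8, 2, 5, 1]],
                     genes=["a", "b", "c"])
    calls = pair_expression_similarity(matrix, [("a", "b"), ("a", "c")])
    assert calls[("a", "b")] == "similar"
    assert calls[("a", "c")] == "divergent"


def test_pair_with_too_few_shared_tissues_undeterminable():
    df = pd.DataFrame(
        [[1.0, np.nan, np.nan, 2.0], [np.nan, 1.0, 2.0, 3.0]],
        index=["a", "b"], columns=list("wxyz"),
    )
    calls = pair_expression_similarity(ExpressionMatrix(df), [("a", "b")])
    assert calls[("a", "b")] == "undeterminable"


def test_planted_similar_fraction_reproduced(family, expression_bundle):
    """9 of 11 planted pairs concordant: 81.82% similar calls."""
    expr, _ct = expression_bundle
    matrix = ExpressionMatrix(expr)
    pairs = [tuple(p[:2]) for p in family.truth.duplicate_pairs]
    calls = pair_expression_similarity(matrix, pairs)
    n_similar = sum(1 for v in calls.values() if v == "similar")
    assert n_similar == len(family.truth.similar_pairs) == 9
    assert round(100 * n_similar / len(pairs), 2) == 81.82
    for pair in family.truth.divergent_pairs:
        assert calls[tuple(pair)] == "divergent"


# ---------------------------------------------------------------------------
# Comparative Ct


def _ct_table(rows, calibrator="cal"):
    df = pd.DataFrame(rows, columns=["sample", "gene", "replicate", "ct"])
    return QpcrTable(df, reference_gene="REF", calibrator_sample=calibrator)


def test_ddct_closed_form_quarter():
    table = _ct_table([
        ("s", "T", 1, 24.0), ("s", "REF", 1, 20.0),
        ("cal", "T", 1, 22.0), ("cal", "REF", 1, 20.0),
    ])
    result = ddct(table, "T", "s")
    assert result.ddct == pytest.approx(2.0)
    assert result.relative_expression == pytest.approx(0.25)


def test_ddct_calibrator_identity():
    table = _ct_table([
        ("cal", "T", 1, 22.0), ("cal", "REF", 1, 20.0),
        ("s", "T", 1, 24.0), ("s", "REF", 1, 20.0),
    ])
    assert ddct(table, "T", "cal").relative_expression == pytest.approx(1.0)


def test_ddct_replicates_averaged_before_dct():
    table = _ct_table([
        ("s", "T", 1, 24.0), ("s", "T", 2, 24.2), ("s", "T", 3, 23.8),
        ("s", "REF", 1, 20.0),
        ("cal", "T", 1, 22.0), ("cal", "REF", 1, 20.0),
    ])
    result = ddct(table, "T", "s")
    assert result.dct_sample == pytest.approx(4.0)
    assert result.relative_expression == pytest.approx(0.25)
    assert len(result.per_replicate) == 3


def test_ddct_reciprocal_property():
    table = _ct_table([
        ("s", "T", 1, 23.5), ("s", "REF", 1, 19.5),
        ("cal", "T", 1, 22.0), ("cal", "REF", 1, 20.0),
    ])
    fwd = ddct(table, "T", "s", "cal").relative_expression
    rev = ddct(table, "T", "cal", "s").relative_expression
    assert fwd * rev == pytest.approx(1.0)


def test_ddct_missing_reference_rejected():
    df = pd.DataFrame(
        [("s", "T", 1, 24.0), ("cal", "T", 1, 22.0), ("cal", "REF", 1, 20.0)],
        columns=["sample", "gene", "replicate", "ct"],
    )
    with pytest.raises(ValidationError):
        QpcrTable(df, reference_gene="REF", calibrator_sample="cal")


def test_generator_ct_model_recovers_planted_fold_change(family, expression_bundle):
    """The planted 4-fold ratio is recovered within the replicate-noise
    bound (3 sigma of ddCt ~ 0.35 in log2 units)."""
    _expr, ct = expression_bundle
    fc = family.truth.fold_change
    table = QpcrTable(ct, reference_gene="ACTIN",
                      calibrator_sample=fc["calibrator"])
    result = ddct(table, fc["gene"], fc["tissue"])
    assert abs(np.log2(result.relative_expression) - np.log2(fc["ratio"])) <= 0.35


def test_generator_reference_gene_stable(expression_bundle):
    _expr, ct = expression_bundle
    ref = ct[ct["gene"] == "ACTIN"].groupby("sample")["ct"].mean()
    assert 100 * ref.std() / ref.mean() < 2.0
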