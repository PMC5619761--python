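"""Expression-matrix scaling, hierarchical clustering and qPCR quantification.

The clustering mirrors the Cluster 3.0 workflow used for expression
heatmaps: per-gene scaling, a Pearson (1 - r) or Euclidean distance over
pairwise-complete observations, and agglomerative average/complete/single
linkage with a deterministic tie-break (the merge joining the smallest
original indices wins among equal-distance candidates).

Relative qPCR quantification uses the comparative Ct method:

    dCt(s)  = mean Ct(target, s) - mean Ct(reference, s)
    ddCt    = dCt(sample) - dCt(calibrator)
    ratio   = 2 ** (-ddCt)

Replicate Ct values are averaged before dCt; the per-replicate spread is
reported separately for error bars.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ValidationError


@dataclass
class ExpressionMatrix:
    """A genes x tissues abundance table (non-negative, NA allowed)."""

    values: pd.DataFrame

    def __post_init__(self):
        all_na = self.values.isna().all(axis=1)
        if all_na.any():
            raise ValidationError(
                f"all-NA expression rows: {list(self.values.index[all_na])}"
            )
        if (self.values < 0).any().any():
            raise ValidationError("expression values must be non-negative")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def tissues(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class Dendrogram:
    """Binary merge tree in scipy-linkage-like encoding.

    ``merges[k] = (i, j, height, size)`` joins clusters i and j into
    cluster ``n + k`` (original items are clusters ``0..n-1``).
    """

    labels: list[str]
    merges: list[tuple[int, int, float, int]]

    def heights(self) -> list[float]:
        return [m[2] for m in self.merges]

    def cut(self, k: int) -> dict[str, int]:
        """Memberships after cutting into ``k`` clusters."""
        n = len(self.labels)
        if not (1 <= k <= n):
            raise ValidationError(f"cannot cut {n} items into {k} clusters")
        parent = list(range(n + len(self.merges)))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for idx, (i, j, _h, _s) in enumerate(self.merges[: n - k]):
            parent[find(i)] = parent[find(j)] = n + idx
        roots: dict[int, int] = {}
        out = {}
        for item in range(n):
            root = find(item)
            out[self.labels[item]] = roots.setdefault(root, len(roots))
        return out

    def leaf_order(self) -> list[str]:
        """Left-to-right leaf order of the merge tree."""
        n = len(self.labels)
        children: dict[int, tuple[int, int]] = {
            n + k: (i, j) for k, (i, j, _h, _s) in enumerate(self.merges)
        }

        def expand(node: int) -> list[int]:
            if node < n:
                return [node]
            i, j = children[node]
            return expand(i) + expand(j)

        return [self.labels[i] for i in expand(n + len(self.merges) - 1)]


# ---------------------------------------------------------------------------
# Scaling


def scale_rows(matrix: ExpressionMatrix, method: str = "zscore") -> ExpressionMatrix:
    """Per-gene scaling: 'zscore', 'unit_max' or 'none' (NA skipped)."""
    df = matrix.values
    if method == "none":
        return ExpressionMatrix(df.copy())
    if method == "unit_max":
        scaled = df.div(df.max(axis=1, skipna=True), axis=0)
        return ExpressionMatrix(scaled.fillna(df * 0).where(df.notna()))
    if method == "zscore":
        mean = df.mean(axis=1, skipna=True)
        sd = df.std(axis=1, ddof=0, skipna=True)
        centered = df.sub(mean, axis=0)
        scaled = centered.div(sd.replace(0.0, np.nan), axis=0)
        # constant rows (sd == 0) map to all-zeros
        scaled = scaled.where(~(sd == 0), 0.0).where(df.notna())
        out = ExpressionMatrix.__new__(ExpressionMatrix)
        out.values = scaled
        return out
    raise ValidationError(f"unknown scaling method {method!r}")


# ---------------------------------------------------------------------------
# Distances and clustering


def pearson_distance(x: np.ndarray, y: np.ndarray) -> float:
    """1 - centered Pearson correlation over pairwise-complete observations."""
    mask = ~(np.isnan(x) | np.isnan(y))
    if mask.sum() < 2:
        raise ValidationError("fewer than 2 shared observations for correlation")
    xv, yv = x[mask], y[mask]
    xc, yc = xv - xv.mean(), yv - yv.mean()
    denom = np.sqrt((xc ** 2).sum() * (yc ** 2).sum())
    if denom == 0:
        return 1.0  # a flat profile is uncorrelated with anything
    return float(1.0 - (xc * yc).sum() / denom)


def euclidean_distance(x: np.ndarray, y: np.ndarray) -> float:
    mask = ~(np.isnan(x) | np.isnan(y))
    if mask.sum() < 1:
        raise ValidationError("no shared observations for distance")
    return float(np.sqrt(((x[mask] - y[mask]) ** 2).sum()))


_DISTANCES = {"pearson": pearson_distance, "euclidean": euclidean_distance}


def hierarchical_cluster(
    matrix: ExpressionMatrix,
    axis: str = "genes",
    distance: str = "pearson",
    linkage: str = "average",
    min_observed_frac: float = 0.5,
) -> Dendrogram:
    """Agglomerative clustering of genes (or tissues) of an expression matrix.

    NA cells are handled by pairwise-complete observations; genes observed
    in fewer than ``min_observed_frac`` of tissues are excluded with a
    warning.  Ties in the merge distance are broken towards the pair whose
    (sorted) original cluster indices are smallest.
    """
    if axis not in ("genes", "tissues"):
        raise ValidationError(f"unknown axis {axis!r}")
    df = matrix.values if axis == "genes" else matrix.values.T
    observed = df.notna().mean(axis=1)
    dropped = list(df.index[observed < min_observed_frac])
    if dropped:
        warnings.warn(
            f"excluded from clustering (<{min_observed_frac:.0%} observed): {dropped}",
            stacklevel=2,
        )
        df = df.drop(index=dropped)
    if len(df) < 2:
        raise ValidationError("need at least 2 items to cluster")
    if distance not in _DISTANCES:
        raise ValidationError(f"unknown distance {distance!r}")
    if linkage not in ("average", "complete", "single"):
        raise ValidationError(f"unknown linkage {linkage!r}")

    dist = _DISTANCES[distance]
    data = df.to_numpy(dtype=float)
    n = len(df)
    # pairwise item distances once; cluster distances reduce over members
    dmat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dmat[i, j] = dmat[j, i] = dist(data[i], data[j])

    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    active = sorted(members)
    merges: list[tuple[int, int, float, int]] = []
    reduce = {"average": np.mean, "complete": np.max, "single": np.min}[linkage]

    while len(active) > 1:
        best: Optional[tuple[float, int, int]] = None
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                ci, cj = active[ai], active[aj]
                block = dmat[np.ix_(members[ci], members[cj])]
                h = float(reduce(block))
                key = (h, *sorted((ci, cj)))
                if best is None or key < best:
                    best = key
        h, ci, cj = best
        new_id = n + len(merges)
        members[new_id] = members.pop(ci) + members.pop(cj)
        merges.append((ci, cj, h, len(members[new_id])))
        active = sorted(members)

    return Dendrogram(labels=list(df.index), merges=merges)


# ---------------------------------------------------------------------------
# Duplicate-pair expression similarity


def pair_expression_similarity(
    matrix: ExpressionMatrix,
    pairs: list[tuple[str, str]],
    r_threshold: float = 0.8,
) -> dict[tuple[str, str], str]:
    """Classify gene pairs as 'similar' (Pearson r >= threshold) or 'divergent'.

    Pairs sharing fewer than 3 observed tissues are 'undeterminable'.
    """
    out = {}
    for a, b in pairs:
        for gene in (a, b):
            if gene not in matrix.values.index:
                raise ValidationError(f"gene {gene!r} not in expression matrix")
        x = matrix.values.loc[a].to_numpy(dtype=float)
        y = matrix.values.loc[b].to_numpy(dtype=float)
        mask = ~(np.isnan(x) | np.isnan(y))
        if mask.sum() < 3:
            out[(a, b)] = "undeterminable"
            continue
        r = 1.0 - pearson_distance(x, y)
        out[(a, b)] = "similar" if r >= r_threshold else "divergent"
    return out


# ---------------------------------------------------------------------------
# Comparative Ct quantification


@dataclass
class QpcrTable:
    """Replicate Ct measurements with a reference gene and calibrator sample."""

    data: pd.DataFrame  # columns: sample, gene, replicate, ct
    reference_gene: str
    calibrator_sample: str

    def __post_init__(self):
        required = {"sample", "gene", "replicate", "ct"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValidationError(f"Ct table missing columns {sorted(missing)}")
        if (self.data["ct"] <= 0).any():
            raise ValidationError("Ct values must be positive")
        samples = set(self.data["sample"])
        ref_samples = set(self.data.loc[self.data["gene"] == self.reference_gene, "sample"])
        if samples - ref_samples:
            raise ValidationError(
                f"reference gene {self.reference_gene!r} missing in samples "
                f"{sorted(samples - ref_samples)}"
            )

    def mean_ct(self, gene: str, sample: str) -> float:
        sel = self.data[(self.data["gene"] == gene) & (self.data["sample"] == sample)]
        if sel.empty:
            raise ValidationError(f"no Ct for gene {gene!r} in sample {sample!r}")
        return float(sel["ct"].mean())

    def replicate_cts(self, gene: str, sample: str) -> list[float]:
        sel = self.data[(self.data["gene"] == gene) & (self.data["sample"] == sample)]
        return [float(v) for v in sel["ct"]]


@dataclass
class DdctResult:
    relative_expression: float
    ddct: float
    dct_sample: float
    dct_calibrator: float
    #: per-replicate 2^-ddCt values (replicate target Ct against mean
    #: reference Ct), reported for error bars
    per_replicate: list[float] = field(default_factory=list)


def ddct(
    table: QpcrTable,
    target_gene: str,
    sample: str,
    calibrator: Optional[str] = None,
) -> DdctResult:
    """Relative expression of ``target_gene`` in ``sample`` by 2^-ddCt."""
    calibrator = calibrator or table.calibrator_sample
    ref = table.reference_gene
    dct_sample = table.mean_ct(target_gene, sample) - table.mean_ct(ref, sample)
    dct_cal = table.mean_ct(target_gene, calibrator) - table.mean_ct(ref, calibrator)
    delta_delta = dct_sample - dct_cal
    per_rep = [
        2.0 ** -((ct - table.mean_ct(ref, sample)) - dct_cal)
        for ct in table.replicate_cts(target_gene, sample)
    ]
    return DdctResult(
        relative_expression=2.0 ** -delta_delta,
        ddct=delta_delta,
        dct_sample=dct_sample,
        dct_calibrator=dct_cal,
        per_replicate=per_rep,
    )
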