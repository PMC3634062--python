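"""Replicate QC, cross-platform correlations, tissue clustering and ordination.

All correlations are Pearson coefficients computed on log-scale values, the
convention for comparing expression profiles with very different dynamic
ranges.  Tissue clustering is agglomerative with complete linkage on the
distance 1 - r between tissue columns; ordination summarizes genes into
k-means clusters first and then runs PCA on the tissue x centroid matrix, so
tissues (not genes) are the observations being ordinated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .matrix import ExpressionMatrix, ExpressionError
from .transforms import transform_log2_floor


@dataclass
class CorrelationReport:
    """Per-tissue Pearson correlations with summary statistics."""

    per_tissue_r: pd.Series
    mean_r: float
    sd_r: float
    fraction_above: dict          # cutoff -> fraction of correlations above it
    pairwise: pd.DataFrame | None = None   # replicate QC detail (tissue, i, j, r)
    excluded: list = field(default_factory=list)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = np.std(x), np.std(y)
    if sx == 0 or sy == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def _log_values(m: ExpressionMatrix) -> pd.DataFrame:
    """Log2-floored values for correlation; pass transformed data through."""
    if m.units in ("log2", "asinh", "zscore"):
        return m.values
    return transform_log2_floor(m).values


def replicate_correlations(m: ExpressionMatrix,
                           cutoff: float = 0.95) -> CorrelationReport:
    """All pairwise Pearson correlations between replicates of each tissue.

    Computed on log2-floored values across genes.  Pairs involving a constant
    column have undefined r; they are excluded from the summaries and listed
    in ``excluded``.
    """
    if not m.has_replicates:
        raise ExpressionError("replicate correlations need replicate columns")
    vals = _log_values(m)
    rows, excluded = [], []
    for tissue in m.tissue_ids:
        block = vals[tissue]
        reps = list(block.columns)
        for i, j in combinations(reps, 2):
            r = _pearson(block[i].to_numpy(), block[j].to_numpy())
            if np.isnan(r):
                excluded.append((tissue, i, j))
            else:
                rows.append({"tissue": tissue, "rep_i": i, "rep_j": j, "r": r})
    pairwise = pd.DataFrame(rows)
    if pairwise.empty:
        raise ExpressionError("no replicate pair had a defined correlation")
    per_tissue = pairwise.groupby("tissue", sort=False)["r"].mean()
    rs = pairwise["r"].to_numpy()
    return CorrelationReport(
        per_tissue_r=per_tissue, mean_r=float(rs.mean()),
        sd_r=float(rs.std(ddof=1)) if len(rs) > 1 else 0.0,
        fraction_above={cutoff: float((rs > cutoff).mean())},
        pairwise=pairwise, excluded=excluded)


def cross_platform_correlations(a: ExpressionMatrix, b: ExpressionMatrix,
                                cutoff: float = 0.7) -> CorrelationReport:
    """Per-tissue Pearson r between the two platforms over genes.

    Expects replicate-collapsed matrices aligned on genes and tissues;
    correlations are computed on log2-floored values (already-transformed
    inputs are used as given).
    """
    if list(a.gene_ids) != list(b.gene_ids):
        raise ExpressionError("matrices must be aligned on the same genes")
    if a.tissue_ids != b.tissue_ids:
        raise ExpressionError("matrices must cover the same tissues")
    if a.n_genes < 3:
        raise ExpressionError("need at least 3 genes for a correlation")
    va, vb = _log_values(a), _log_values(b)
    per_tissue = pd.Series(
        {t: _pearson(va[t].to_numpy(), vb[t].to_numpy()) for t in a.tissue_ids})
    rs = per_tissue.dropna().to_numpy()
    return CorrelationReport(
        per_tissue_r=per_tissue, mean_r=float(rs.mean()),
        sd_r=float(rs.std(ddof=1)) if len(rs) > 1 else 0.0,
        fraction_above={cutoff: float((rs > cutoff).mean())},
        excluded=[t for t in per_tissue.index if np.isnan(per_tissue[t])])


# ---------------------------------------------------------------------------
# hierarchical clustering of tissues


@dataclass
class Dendrogram:
    """Complete-linkage merge history over tissue leaves.

    ``merges`` lists ``(members_left, members_right, height)`` in merge order,
    each members tuple sorted lexicographically.
    """

    merges: list
    leaves: list

    @property
    def heights(self) -> list:
        return [h for _, _, h in self.merges]

    def cut(self, k: int) -> list:
        """Cluster memberships after stopping at ``k`` clusters."""
        if not 1 <= k <= len(self.leaves):
            raise ValueError(f"k must be in [1, {len(self.leaves)}]")
        clusters = {(l,): frozenset([l]) for l in self.leaves}
        for left, right, _ in self.merges[:len(self.leaves) - k]:
            merged = clusters.pop(left) | clusters.pop(right)
            clusters[tuple(sorted(merged))] = merged
        return sorted(clusters.values(), key=lambda s: sorted(s)[0])

    def to_newick(self) -> str:
        node = {(l,): l for l in self.leaves}
        height = {(l,): 0.0 for l in self.leaves}
        key = None
        for left, right, h in self.merges:
            nl, nr = node.pop(left), node.pop(right)
            bl, br = h - height.pop(left), h - height.pop(right)
            key = tuple(sorted(left + right))
            node[key] = f"({nl}:{bl:.6g},{nr}:{br:.6g})"
            height[key] = h
        (root,) = node.values()
        return root + ";"


def cluster_tissues(m: ExpressionMatrix) -> Dendrogram:
    """Agglomerate tissues by complete linkage on 1 - Pearson r distance.

    Ties between candidate merges are broken deterministically by the
    lexicographically smallest member labels of the competing pairs.
    """
    if m.has_replicates:
        raise ExpressionError("collapse replicates before clustering tissues")
    if m.n_tissues < 2:
        raise ExpressionError("need at least 2 tissues to cluster")
    vals = m.values
    sd = vals.std(axis=0, ddof=0)
    if (sd == 0).any():
        bad = sd.index[sd == 0].tolist()
        raise ExpressionError(f"constant tissue column(s): {bad}")
    labels = list(vals.columns)
    D = 1.0 - np.corrcoef(vals.to_numpy().T)
    np.fill_diagonal(D, 0.0)
    idx_of = {l: i for i, l in enumerate(labels)}

    clusters = {(l,): [l] for l in labels}
    merges = []
    while len(clusters) > 1:
        best = None
        for ka, kb in combinations(sorted(clusters), 2):
            d = max(D[idx_of[x], idx_of[y]]
                    for x in clusters[ka] for y in clusters[kb])
            cand = (d, min(ka[0], kb[0]), max(ka[0], kb[0]), ka, kb)
            if best is None or cand[:3] < best[:3]:
                best = cand
        d, _, _, ka, kb = best
        members = sorted(clusters.pop(ka) + clusters.pop(kb))
        clusters[tuple(members)] = members
        merges.append((ka, kb, float(d)))
    return Dendrogram(merges=merges, leaves=labels)


# ---------------------------------------------------------------------------
# k-means + PCA ordination


@dataclass
class PCAOrdination:
    coordinates: pd.DataFrame          # tissues x PCs
    explained_variance_ratio: np.ndarray
    k_used: int


def pca_tissues(m: ExpressionMatrix, k: int = 1000, seed: int = 0,
                n_restarts: int = 10, scale: bool = False) -> PCAOrdination:
    """Summarize genes into ``k`` k-means clusters, then PCA the tissues.

    The cluster centroids (k x tissues) become the feature matrix: tissues
    are observations, centroid profiles are variables.  Variables are
    centered (and optionally unit-scaled); components are ordered by
    decreasing explained variance.
    """
    if m.has_replicates:
        raise ExpressionError("collapse replicates before ordination")
    X = m.values.to_numpy()
    n_genes = X.shape[0]
    if k > n_genes:
        warnings.warn(f"k={k} exceeds the {n_genes} genes; reducing k")
        k = n_genes
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    km.fit(X)
    Y = km.cluster_centers_.T            # tissues x k
    Y = Y - Y.mean(axis=0, keepdims=True)
    if scale:
        s = Y.std(axis=0, ddof=0)
        Y = Y / np.where(s == 0, 1.0, s)
    pca = PCA()
    coords = pca.fit_transform(Y)
    cols = [f"PC{i + 1}" for i in range(coords.shape[1])]
    return PCAOrdination(
        coordinates=pd.DataFrame(coords, index=m.values.columns, columns=cols),
        explained_variance_ratio=pca.explained_variance_ratio_,
        k_used=k)


def top_expressed_genes(m: ExpressionMatrix, n: int = 10) -> pd.DataFrame:
    """Per-tissue descending ranking of the ``n`` highest-expressed genes.

    Ties are broken by lexicographically smaller gene id.  Returns a long
    DataFrame with columns tissue, rank, gene, value.
    """
    if m.has_replicates:
        raise ExpressionError("collapse replicates before ranking genes")
    if n > m.n_genes:
        warnings.warn(f"n={n} exceeds the {m.n_genes} genes; full ranking returned")
        n = m.n_genes
    rows = []
    for tissue in m.values.columns:
        col = m.values[tissue]
        ordered = sorted(col.items(), key=lambda kv: (-kv[1], kv[0]))[:n]
        for rank, (gene, value) in enumerate(ordered, start=1):
            rows.append({"tissue": tissue, "rank": rank,
                         "gene": gene, "value": float(value)})
    return pd.DataFrame(rows)
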