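"""Co-expression networks, Fisher-z normalization and the mixed-platform null.

A co-expression network is the complete weighted graph over genes whose edge
(i, j) is the Pearson correlation of the two genes' transformed tissue
profiles.  Edges are variance-stabilized with the Fisher transformation
z = atanh(r) and standardized to mean 0 / SD 1 over the upper triangle, which
makes edge weights comparable between networks built from different inputs.

The mixed-platform bootstrap builds a null for cross-network similarity:
per replicate, a fair coin decides for every tissue which platform's profile
enters pseudo-network 1 (the other platform's goes into pseudo-network 2), so
each pseudo-dataset is a random platform mixture over the same 18 tissues.
If the two platforms are interchangeable measurements, the observed
single-platform similarity is just one more draw from this null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix, ExpressionError

ATANH_EPS = 1e-7
DEFAULT_MAX_GENES = 5000


@dataclass
class CoexpressionNetwork:
    """Symmetric gene x gene edge-weight matrix (diagonal excluded from all
    statistics)."""

    gene_ids: pd.Index
    edges: np.ndarray
    stage: str                 # raw_r | fisher_z | normalized
    source: str = ""

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def upper_triangle(self) -> np.ndarray:
        iu = np.triu_indices(self.n_genes, k=1)
        return self.edges[iu]


def remove_constant_genes(m: ExpressionMatrix):
    """Split off genes whose profile is constant across tissues (their
    correlation with anything is undefined).  Returns (filtered, dropped)."""
    sd = m.values.std(axis=1, ddof=0)
    dropped = sd.index[sd == 0].tolist()
    if dropped:
        kept = m.with_values(m.values.loc[sd > 0])
        return kept, dropped
    return m, []


def build_network(m: ExpressionMatrix,
                  max_genes: int = DEFAULT_MAX_GENES) -> CoexpressionNetwork:
    """All-pairs Pearson correlation of gene profiles across tissues.

    Expects a replicate-collapsed, transformed matrix with at least 4 tissues
    and no constant gene profiles (use :func:`remove_constant_genes` first).
    Dense storage grows quadratically, so gene count is capped.
    """
    if m.has_replicates:
        raise ExpressionError("collapse replicates before building a network")
    if m.n_tissues < 4:
        raise ExpressionError("need at least 4 tissues for a co-expression network")
    if m.n_genes > max_genes:
        raise ExpressionError(
            f"{m.n_genes} genes exceeds the dense-network cap of {max_genes}")
    sd = m.values.std(axis=1, ddof=0)
    if (sd == 0).any():
        bad = sd.index[sd == 0][0]
        raise ExpressionError(f"constant gene profile: {bad!r}")
    edges = np.corrcoef(m.values.to_numpy())
    edges = np.clip(edges, -1.0, 1.0)
    return CoexpressionNetwork(gene_ids=m.gene_ids, edges=edges,
                               stage="raw_r", source=m.platform)


def fisher_normalize(net: CoexpressionNetwork, eps: float = ATANH_EPS,
                     method: str = "zscore") -> CoexpressionNetwork:
    """Fisher z-transform the edges and standardize over the upper triangle.

    r is clamped to +/-(1 - eps) before atanh so perfect correlations stay
    finite.  ``method="zscore"`` (default) standardizes to mean 0 / SD 1;
    ``"minmax"`` rescales to [0, 1] instead.
    """
    if net.stage != "raw_r":
        raise ExpressionError(f"expected a raw_r network, got stage {net.stage!r}")
    n = net.n_genes
    if n * (n - 1) // 2 < 2:
        raise ExpressionError("need at least 2 edges to normalize")
    z = np.arctanh(np.clip(net.edges, -1.0 + eps, 1.0 - eps))
    iu = np.triu_indices(n, k=1)
    vals = z[iu]
    if method == "zscore":
        mu, sd = vals.mean(), vals.std(ddof=1)
        if sd == 0:
            raise ExpressionError("all edges identical; cannot standardize")
        norm = (z - mu) / sd
    elif method == "minmax":
        lo, hi = vals.min(), vals.max()
        if hi == lo:
            raise ExpressionError("all edges identical; cannot rescale")
        norm = (z - lo) / (hi - lo)
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    np.fill_diagonal(norm, 0.0)
    return CoexpressionNetwork(gene_ids=net.gene_ids, edges=norm,
                               stage="normalized", source=net.source)


def network_similarity(a: CoexpressionNetwork, b: CoexpressionNetwork) -> float:
    """Pearson correlation between the two networks' upper-triangle edges."""
    if list(a.gene_ids) != list(b.gene_ids):
        raise ExpressionError("networks must share the same genes in the same order")
    if a.stage != "normalized" or b.stage != "normalized":
        raise ExpressionError("normalize both networks before comparing them")
    ua, ub = a.upper_triangle(), b.upper_triangle()
    return float(np.corrcoef(ua, ub)[0, 1])


# ---------------------------------------------------------------------------
# mixed-platform bootstrap


@dataclass
class MixedBootstrapResult:
    observed_similarity: float
    null_similarities: np.ndarray
    B: int
    percentile_of_observed: float     # fraction of null <= observed
    assignments: np.ndarray           # B x n_tissues booleans (True: A -> net1)


def standardize_columns(m: ExpressionMatrix) -> ExpressionMatrix:
    """Z-score each tissue column over genes (mean 0, SD 1).

    Puts the two platforms' transformed values on a common per-tissue scale
    so a mixed 18-tissue profile is not dominated by platform units.
    """
    vals = m.values
    sd = vals.std(axis=0, ddof=0)
    if (sd == 0).any():
        bad = sd.index[sd == 0].tolist()
        raise ExpressionError(f"constant tissue column(s): {bad}")
    return m.with_values((vals - vals.mean(axis=0)) / sd, units="zscore")


def _net_similarity_from_values(va: np.ndarray, vb: np.ndarray) -> float:
    ra = np.corrcoef(va)
    rb = np.corrcoef(vb)
    n = va.shape[0]
    iu = np.triu_indices(n, k=1)
    za = np.arctanh(np.clip(ra[iu], -1 + ATANH_EPS, 1 - ATANH_EPS))
    zb = np.arctanh(np.clip(rb[iu], -1 + ATANH_EPS, 1 - ATANH_EPS))
    za = (za - za.mean()) / za.std(ddof=1)
    zb = (zb - zb.mean()) / zb.std(ddof=1)
    return float(np.corrcoef(za, zb)[0, 1])


def mixed_bootstrap(tA: ExpressionMatrix, tB: ExpressionMatrix, B: int = 1000,
                    seed: int = 0, standardize: bool = True,
                    complementary: bool = True) -> MixedBootstrapResult:
    """Null distribution of network similarity under platform mixing.

    ``tA`` and ``tB`` are transformed, replicate-collapsed matrices aligned on
    genes and tissues.  Per replicate, each tissue's platform-A profile goes
    into pseudo-network 1 and its platform-B profile into pseudo-network 2, or
    the swap, by a fair coin (``complementary=True``, the default, keeps the
    two pseudo-datasets complementary; ``False`` draws the two assignments
    independently).  The observed similarity comes from the unmixed pair,
    processed identically.
    """
    if list(tA.gene_ids) != list(tB.gene_ids):
        raise ExpressionError("matrices must be aligned on the same genes")
    if tA.tissue_ids != tB.tissue_ids:
        raise ExpressionError("matrices must cover the same tissues")
    if B < 100:
        warnings.warn(f"B={B} bootstrap replicates give a coarse null")
    if standardize:
        tA, tB = standardize_columns(tA), standardize_columns(tB)
    va, vb = tA.values.to_numpy(), tB.values.to_numpy()
    n_tissues = va.shape[1]
    observed = _net_similarity_from_values(va, vb)

    rng = np.random.default_rng(seed)
    nulls = np.empty(B)
    assignments = np.empty((B, n_tissues), dtype=bool)
    for b in range(B):
        coin1 = rng.integers(0, 2, n_tissues).astype(bool)
        m1 = np.where(coin1[None, :], va, vb)
        if complementary:
            m2 = np.where(coin1[None, :], vb, va)
        else:
            coin2 = rng.integers(0, 2, n_tissues).astype(bool)
            m2 = np.where(coin2[None, :], va, vb)
        assignments[b] = coin1
        nulls[b] = _net_similarity_from_values(m1, m2)
    percentile = float((nulls <= observed).mean())
    return MixedBootstrapResult(observed_similarity=observed,
                                null_similarities=nulls, B=B,
                                percentile_of_observed=percentile,
                                assignments=assignments)


def stringent_expression_filter(m: ExpressionMatrix, cutoff: float = 5.0):
    """Genes whose maximum tissue FPKM strictly exceeds ``cutoff``.

    Returns (kept gene list, removed gene list) for a replicate-collapsed
    RNA-Seq matrix on the linear scale.
    """
    if m.has_replicates:
        raise ExpressionError("collapse replicates before filtering")
    maxima = m.values.max(axis=1)
    kept = maxima.index[maxima > cutoff].tolist()
    removed = maxima.index[maxima <= cutoff].tolist()
    return kept, removed
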