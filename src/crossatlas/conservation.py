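"""Per-gene expression-conservation (EC) scores between two networks.

The EC score of gene g is the Pearson correlation between g's edge-weight
vector (its co-expression neighborhood, diagonal excluded) in network A and
in network B: EC near 1 means the gene keeps the same neighbors on both
platforms, low EC means its co-expression relationships diverge.

Significance is assessed against a null built by the mixed-platform
bootstrap: each replicate reassigns, tissue by tissue, which platform's
profile enters each of two pseudo-networks, and EC per gene between the
pseudo-networks is recorded.  By default the null draws of all genes are
pooled into one reference distribution: a gene is divergent when its
observed EC sits in the far left tail of what mixing produces anywhere in
the network.  Pooling is what gives the test workable resolution -- a
single gene's B mixing draws include assignments arbitrarily close to the
observed pure split, so the per-gene empirical p (available via
``pooled_null=False``) has an effective floor near the probability of a
near-pure coin sequence and cannot reliably resolve below alpha = 0.01 at
moderate B.  The empirical one-sided p-value uses the standard +1
Monte-Carlo correction, so it is never exactly zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import ExpressionMatrix, ExpressionError
from .network import (CoexpressionNetwork, build_network, fisher_normalize,
                      standardize_columns, ATANH_EPS)

DEFAULT_TAU = 2.0
DEGREE_DOMINANCE_FACTOR = 2
DEGREE_DOMINANCE_OFFSET = 5


@dataclass
class ECResult:
    per_gene_ec: pd.Series
    per_gene_p: pd.Series
    flagged: set                      # p < alpha
    degree_a: pd.Series
    degree_b: pd.Series
    alpha: float
    n_boot: int
    divergence_class: pd.Series | None = None

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({
            "ec": self.per_gene_ec,
            "p": self.per_gene_p,
            "flagged": self.per_gene_ec.index.isin(self.flagged),
            "degree_a": self.degree_a,
            "degree_b": self.degree_b,
        })
        if self.divergence_class is not None:
            out["class"] = self.divergence_class.reindex(out.index)
        return out


def _rowwise_pearson(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Pearson r between matching rows of X and Y (vectorized)."""
    Xc = X - X.mean(axis=1, keepdims=True)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    num = (Xc * Yc).sum(axis=1)
    den = np.sqrt((Xc ** 2).sum(axis=1) * (Yc ** 2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = num / den
    r[den == 0] = np.nan
    return r


def _ec_from_edges(ea: np.ndarray, eb: np.ndarray) -> np.ndarray:
    n = ea.shape[0]
    off = ~np.eye(n, dtype=bool)
    A = ea[off].reshape(n, n - 1)
    B = eb[off].reshape(n, n - 1)
    return _rowwise_pearson(A, B)


def ec_scores(a: CoexpressionNetwork, b: CoexpressionNetwork) -> pd.Series:
    """EC per gene: correlation of its neighborhood vectors in a and b.

    Both networks must be normalized and share the same gene order; the
    self-edge is excluded from both vectors.  Genes with a constant row get
    NaN (undefined EC) and are reported as missing.
    """
    if list(a.gene_ids) != list(b.gene_ids):
        raise ExpressionError("networks must share the same genes in the same order")
    if a.stage != "normalized" or b.stage != "normalized":
        raise ExpressionError("normalize both networks before EC scoring")
    return pd.Series(_ec_from_edges(a.edges, b.edges), index=a.gene_ids)


def connectivity(net: CoexpressionNetwork, tau: float = DEFAULT_TAU) -> pd.Series:
    """Degree per gene: off-diagonal edges with normalized weight >= tau."""
    if net.stage != "normalized":
        raise ExpressionError("connectivity is defined on a normalized network")
    n = net.n_genes
    strong = net.edges >= tau
    np.fill_diagonal(strong, False)
    return pd.Series(strong.sum(axis=1), index=net.gene_ids)


def _normalized_edges(values: np.ndarray) -> np.ndarray:
    r = np.corrcoef(values)
    z = np.arctanh(np.clip(r, -1 + ATANH_EPS, 1 - ATANH_EPS))
    iu = np.triu_indices(values.shape[0], k=1)
    vals = z[iu]
    z = (z - vals.mean()) / vals.std(ddof=1)
    np.fill_diagonal(z, 0.0)
    return z


def ec_significance(tA: ExpressionMatrix, tB: ExpressionMatrix, B: int = 1000,
                    seed: int = 0, alpha: float = 0.01,
                    tau: float = DEFAULT_TAU, standardize: bool = True,
                    complementary: bool = True, two_sided: bool = False,
                    pooled_null: bool = True) -> ECResult:
    """Observed EC per gene plus an empirical p-value from platform mixing.

    ``tA`` / ``tB`` are transformed, replicate-collapsed matrices aligned on
    genes and tissues.  Per bootstrap replicate, a fair coin per tissue
    assigns the two platforms' profiles to two pseudo-networks (complementary
    by default) and EC per gene between them is recorded.  One-sided p =
    (1 + #{null EC <= observed EC}) / (#null + 1); low EC (divergent
    neighbors) gives a small p.  With ``pooled_null=True`` (default) each
    observed EC is compared against the null draws of all genes pooled
    together; ``False`` uses the gene's own B draws only (coarse resolution,
    see the module docstring).
    """
    if list(tA.gene_ids) != list(tB.gene_ids):
        raise ExpressionError("matrices must be aligned on the same genes")
    if tA.tissue_ids != tB.tissue_ids:
        raise ExpressionError("matrices must cover the same tissues")
    if B < 100:
        warnings.warn(
            f"B={B}: empirical p-value resolution 1/(B+1) = {1 / (B + 1):.3g} "
            f"is coarser than alpha = {alpha}")
    if standardize:
        tA, tB = standardize_columns(tA), standardize_columns(tB)
    va, vb = tA.values.to_numpy(), tB.values.to_numpy()
    n_genes, n_tissues = va.shape

    ea, eb = _normalized_edges(va), _normalized_edges(vb)
    observed = _ec_from_edges(ea, eb)
    degree_a = (ea >= tau).sum(axis=1) - (np.diag(ea) >= tau).astype(int)
    degree_b = (eb >= tau).sum(axis=1) - (np.diag(eb) >= tau).astype(int)

    rng = np.random.default_rng(seed)
    count_leq = np.zeros(n_genes)
    count_geq = np.zeros(n_genes)
    pooled = [] if pooled_null else None
    for _ in range(B):
        coin = rng.integers(0, 2, n_tissues).astype(bool)
        m1 = np.where(coin[None, :], va, vb)
        if complementary:
            m2 = np.where(coin[None, :], vb, va)
        else:
            coin2 = rng.integers(0, 2, n_tissues).astype(bool)
            m2 = np.where(coin2[None, :], va, vb)
        null_ec = _ec_from_edges(_normalized_edges(m1), _normalized_edges(m2))
        count_leq += (null_ec <= observed)
        count_geq += (null_ec >= observed)
        if pooled is not None:
            pooled.append(null_ec)

    if pooled is not None:
        allnull = np.concatenate(pooled)
        allnull = allnull[~np.isnan(allnull)]
        count_leq = np.array([(allnull <= o).sum() for o in observed], dtype=float)
        count_geq = np.array([(allnull >= o).sum() for o in observed], dtype=float)
        denom = len(allnull) + 1
    else:
        denom = B + 1

    p_low = (1.0 + count_leq) / denom
    if two_sided:
        p_high = (1.0 + count_geq) / denom
        p = np.minimum(1.0, 2.0 * np.minimum(p_low, p_high))
    else:
        p = p_low
    p = np.where(np.isnan(observed), np.nan, p)

    per_gene_ec = pd.Series(observed, index=tA.gene_ids)
    per_gene_p = pd.Series(p, index=tA.gene_ids)
    flagged = set(per_gene_p.index[(per_gene_p < alpha).fillna(False)])
    return ECResult(per_gene_ec=per_gene_ec, per_gene_p=per_gene_p,
                    flagged=flagged,
                    degree_a=pd.Series(degree_a, index=tA.gene_ids),
                    degree_b=pd.Series(degree_b, index=tA.gene_ids),
                    alpha=alpha, n_boot=B)


def classify_divergent(ec: ECResult, expr_a: ExpressionMatrix,
                       expr_b: ExpressionMatrix,
                       saturation_quantile: float = 0.99,
                       factor: int = DEGREE_DOMINANCE_FACTOR,
                       offset: int = DEGREE_DOMINANCE_OFFSET):
    """Connectivity class per flagged gene plus expression-defined clusters.

    A flagged gene is ``more_in_a`` when degree_a >= factor * degree_b +
    offset, ``more_in_b`` symmetrically, else ``similar``.  Two clusters of
    divergent genes are also reported from replicate-collapsed linear
    expression: (i) genes high on both platforms whose platform-A (microarray)
    mean sits at or above the saturation quantile of all platform-A means --
    candidates clipped by the array ceiling; (ii) genes whose platform-B
    (RNA-Seq) median expression is exactly zero -- barely-detected genes whose
    RNA-Seq correlations are count-noise artifacts.

    Returns (classes Series over flagged genes, summary dict); the classes are
    also stored on ``ec.divergence_class``.
    """
    flagged = sorted(ec.flagged)
    classes = {}
    for g in flagged:
        da, db = ec.degree_a[g], ec.degree_b[g]
        if da >= factor * db + offset:
            classes[g] = "more_in_a"
        elif db >= factor * da + offset:
            classes[g] = "more_in_b"
        else:
            classes[g] = "similar"
    classes = pd.Series(classes, dtype=object)

    mean_a = expr_a.values.mean(axis=1)
    mean_b = expr_b.values.mean(axis=1)
    median_b = expr_b.values.median(axis=1)
    sat_cut = float(mean_a.quantile(saturation_quantile))
    high_b = float(mean_b.median())
    cluster_saturated = [g for g in flagged
                         if mean_a[g] >= sat_cut and mean_b[g] >= high_b]
    cluster_low = [g for g in flagged if median_b[g] == 0]
    summary = {
        "counts": {c: int((classes == c).sum())
                   for c in ("more_in_a", "more_in_b", "similar")},
        "saturated_cluster": cluster_saturated,
        "low_expression_cluster": cluster_low,
        "saturation_cutoff": sat_cut,
    }
    ec.divergence_class = classes
    return classes, summary


def enrichment_test(flagged, annotated, universe) -> float:
    """Upper-tail hypergeometric p for overlap of flagged and annotated genes.

    P(X >= observed overlap) when drawing |flagged| genes without replacement
    from a universe containing |annotated| annotated genes.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty gene universe")
    flagged = set(flagged) & universe
    annotated = set(annotated) & universe
    overlap = len(flagged & annotated)
    M, K, n = len(universe), len(annotated), len(flagged)
    return float(stats.hypergeom.sf(overlap - 1, M, K, n))


@dataclass
class LowExpressionDiagnostic:
    statistic: float
    p_value: float             # one-sided: set has lower mean expression
    median_set: float
    median_rest: float
    n_set: int
    n_rest: int


def low_expression_diagnostic(gene_set, m: ExpressionMatrix) -> LowExpressionDiagnostic:
    """Rank-sum test that a gene set has lower mean expression than the rest.

    ``m`` is a replicate-collapsed linear RNA-Seq matrix; the statistic is a
    one-sided Mann-Whitney U on per-gene means (alternative: the set is
    lower).
    """
    genes = set(gene_set)
    means = m.values.mean(axis=1)
    in_set = means.index.isin(genes)
    if not in_set.any():
        raise ValueError("gene set is empty or absent from the matrix")
    if in_set.all():
        raise ValueError("gene set must be a strict subset of the matrix genes")
    x = means[in_set].to_numpy()
    y = means[~in_set].to_numpy()
    if len(x) + len(y) <= 20 and len(np.unique(np.concatenate([x, y]))) \
            == len(x) + len(y):
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="less", method=method)
    return LowExpressionDiagnostic(
        statistic=float(res.statistic), p_value=float(res.pvalue),
        median_set=float(np.median(x)), median_rest=float(np.median(y)),
        n_set=len(x), n_rest=len(y))
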