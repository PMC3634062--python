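"""Shannon-entropy tissue specificity and paralog-pair correlation analysis.

Tissue specificity of a gene is quantified by the Shannon entropy of its
normalized expression profile p_t = x_t / sum(x): H = -sum p_t log2 p_t, in
bits.  H = 0 for expression confined to one tissue and log2(T) for a uniform
profile, so lower entropy means more tissue-specific expression.  Entropy is
computed on linear (untransformed) replicate-averaged values by default.

Paralog analysis correlates the tissue profiles of the two members of each
duplicate pair within one platform and contrasts the pair correlations with a
null of randomly drawn gene pairs; a pair counts as "highly correlated" when
its r exceeds the null mean by more than two null standard deviations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import ExpressionMatrix, ExpressionError


@dataclass
class EntropyResult:
    per_gene_entropy: pd.Series   # bits
    platform: str
    excluded: list = field(default_factory=list)   # all-zero profiles


def shannon_entropy(profile) -> float:
    """Entropy in bits of a nonnegative per-tissue expression vector."""
    x = np.asarray(profile, dtype=float)
    if (x < 0).any():
        raise ValueError("expression profile must be nonnegative")
    total = x.sum()
    if total == 0:
        raise ValueError("all-zero profile has undefined entropy")
    p = x / total
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def expression_entropy(m: ExpressionMatrix, detection=None) -> EntropyResult:
    """Per-gene entropy over tissues for a replicate-collapsed linear matrix.

    Genes with an all-zero profile are excluded and recorded; when a
    :class:`~crossatlas.detection.DetectionResult` is supplied only its
    expressed genes enter the sample.
    """
    if m.has_replicates:
        raise ExpressionError("collapse replicates before computing entropy")
    vals = m.values
    if detection is not None:
        keep = detection.expressed[detection.expressed].index
        vals = vals.loc[vals.index.intersection(keep)]
    totals = vals.sum(axis=1)
    excluded = totals.index[totals == 0].tolist()
    usable = vals.loc[totals > 0]
    p = usable.div(usable.sum(axis=1), axis=0).to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log2(p), 0.0)
    ent = pd.Series(-terms.sum(axis=1), index=usable.index)
    return EntropyResult(per_gene_entropy=ent, platform=m.platform,
                         excluded=excluded)


@dataclass
class EntropyComparison:
    statistic: float          # Mann-Whitney U for sample a
    p_value: float            # two-sided
    n_a: int
    n_b: int
    median_a: float
    median_b: float
    more_specific: str        # platform with the lower median entropy


def compare_entropy_distributions(a: EntropyResult,
                                  b: EntropyResult) -> EntropyComparison:
    """Mann-Whitney U test between the two platforms' entropy samples.

    Both samples are restricted to the shared gene universe.  The exact null
    distribution is used for combined n <= 20 (requires no ties); otherwise
    the tie-corrected normal approximation.
    """
    shared = a.per_gene_entropy.index.intersection(b.per_gene_entropy.index)
    xa = a.per_gene_entropy.loc[shared].to_numpy()
    xb = b.per_gene_entropy.loc[shared].to_numpy()
    if len(xa) < 3 or len(xb) < 3:
        raise ValueError("need at least 3 genes per platform")
    if len(xa) + len(xb) <= 20 and len(np.unique(np.concatenate([xa, xb]))) \
            == len(xa) + len(xb):
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(xa, xb, alternative="two-sided", method=method)
    med_a, med_b = float(np.median(xa)), float(np.median(xb))
    more_specific = a.platform if med_a < med_b else b.platform
    return EntropyComparison(statistic=float(res.statistic),
                             p_value=float(res.pvalue),
                             n_a=len(xa), n_b=len(xb),
                             median_a=med_a, median_b=med_b,
                             more_specific=more_specific)


# ---------------------------------------------------------------------------
# paralog-pair correlations against a random-pair null


@dataclass
class ParalogReport:
    pair_r: pd.DataFrame                     # gene_a, gene_b, mismatch_class, r
    skipped: list = field(default_factory=list)
    null_mean: float | None = None
    null_sd: float | None = None
    null_n: int | None = None
    fraction_high: float | None = None
    threshold_rule: str = "r > null_mean + 2 * null_sd"


@dataclass
class RandomPairNull:
    mean: float
    sd: float
    sample: np.ndarray


def read_paralog_pairs(path) -> list:
    """Two- or three-column TSV: gene_a, gene_b[, mismatch_class]."""
    pairs = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            parts = line.rstrip("\n").split("\t")
            if i == 0 and parts[0].lower() in ("gene_a", "gene1", "gene"):
                continue
            if len(parts) < 2:
                raise ValueError(f"line {i + 1}: expected >= 2 columns")
            cls = parts[2] if len(parts) > 2 else ""
            pairs.append((parts[0], parts[1], cls))
    return pairs


def _profile_r(vals: pd.DataFrame, g1: str, g2: str) -> float:
    x, y = vals.loc[g1].to_numpy(), vals.loc[g2].to_numpy()
    if np.std(x) == 0 or np.std(y) == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def paralog_correlations(m: ExpressionMatrix, pairs) -> ParalogReport:
    """Pearson r across tissues for each paralog pair within one platform.

    Expects a replicate-collapsed, platform-transformed matrix.  Pairs with a
    missing or constant-profile member are skipped and logged.
    """
    if m.has_replicates:
        raise ExpressionError("collapse replicates before paralog analysis")
    vals = m.values
    present = set(vals.index)
    rows, skipped = [], []
    for entry in pairs:
        g1, g2 = entry[0], entry[1]
        cls = entry[2] if len(entry) > 2 else ""
        if g1 not in present or g2 not in present:
            skipped.append((g1, g2, "missing"))
            continue
        r = _profile_r(vals, g1, g2)
        if np.isnan(r):
            skipped.append((g1, g2, "constant"))
            continue
        rows.append({"gene_a": g1, "gene_b": g2, "mismatch_class": cls, "r": r})
    if not rows:
        raise ValueError("no usable paralog pair (all missing or constant)")
    return ParalogReport(pair_r=pd.DataFrame(rows), skipped=skipped)


def random_pair_null(m: ExpressionMatrix, n_pairs: int, seed: int,
                     exclude_pairs=()) -> RandomPairNull:
    """Null distribution of r over uniformly sampled unordered gene pairs.

    Self-pairs and any pair in ``exclude_pairs`` (e.g. the paralog list) are
    never drawn; pairs with a constant member are resampled.  Deterministic
    given ``seed``.
    """
    if n_pairs < 100:
        raise ValueError("need n_pairs >= 100 for a stable null")
    vals = m.values
    genes = list(vals.index)
    if len(genes) < 20:
        raise ValueError("gene universe too small (< 20) for a random-pair null")
    forbidden = {frozenset((p[0], p[1])) for p in exclude_pairs}
    rng = np.random.default_rng(seed)
    sample = []
    attempts = 0
    while len(sample) < n_pairs:
        attempts += 1
        if attempts > 100 * n_pairs:
            raise RuntimeError("could not sample enough valid random pairs")
        i, j = rng.integers(0, len(genes), 2)
        if i == j or frozenset((genes[i], genes[j])) in forbidden:
            continue
        r = _profile_r(vals, genes[i], genes[j])
        if np.isnan(r):
            continue
        sample.append(r)
    arr = np.asarray(sample)
    return RandomPairNull(mean=float(arr.mean()), sd=float(arr.std(ddof=1)),
                          sample=arr)


def attach_null(report: ParalogReport, null: RandomPairNull) -> ParalogReport:
    report.null_mean, report.null_sd = null.mean, null.sd
    report.null_n = len(null.sample)
    return report


def fraction_highly_correlated(report: ParalogReport) -> float:
    """Fraction of pairs with r above the 2-SD random-pair cutoff."""
    if report.null_mean is None or report.null_sd is None:
        raise ValueError("attach a random-pair null before applying the rule")
    cutoff = report.null_mean + 2.0 * report.null_sd
    frac = float((report.pair_r["r"] > cutoff).mean())
    report.fraction_high = frac
    return frac


def paralog_analysis(m: ExpressionMatrix, pairs, n_null: int | None = None,
                     seed: int = 0) -> ParalogReport:
    """Pair correlations, random-pair null and the 2-SD fraction in one call.

    The null defaults to 10x the number of usable pairs (minimum 100).
    """
    report = paralog_correlations(m, pairs)
    if n_null is None:
        n_null = max(100, 10 * len(report.pair_r))
    null = random_pair_null(m, n_null, seed, exclude_pairs=pairs)
    attach_null(report, null)
    fraction_highly_correlated(report)
    return report
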