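"""Expression detection filters and expression-level binning.

Two platform-specific detection rules:

* RNA-Seq: a gene is expressed in a tissue when the lower bound of the
  two-sided t confidence interval (default 95%) for its mean replicate FPKM
  exceeds zero.  A gene is expressed overall when that holds in at least one
  tissue.
* Microarray: a gene is expressed when its replicate-averaged intensity
  exceeds a fixed threshold (default 200) in at least one tissue; the
  comparison is strict by default.

Expression levels partition [0, inf) into none (0), low (0, 5], medium
(5, 200] and high (200, inf); the default cut points are FPKM-scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import ExpressionMatrix, ExpressionError

LEVELS = ("none", "low", "medium", "high")
DEFAULT_BINS = (0.0, 5.0, 200.0)


class ConfigurationError(ValueError):
    """Detection rule cannot be applied to the supplied matrix."""


@dataclass
class DetectionResult:
    """Per-gene detection flags and per-(gene, tissue) expression bins."""

    expressed: pd.Series           # gene -> bool
    level_by_tissue: pd.DataFrame  # gene x tissue -> level name
    criterion: str

    def to_frame(self) -> pd.DataFrame:
        out = self.level_by_tissue.copy()
        out.insert(0, "expressed", self.expressed)
        return out


def classify_expression_level(value: float, bins=DEFAULT_BINS) -> str:
    """Bin a single nonnegative expression value.

    ``0 -> none``, ``(0, b1] -> low``, ``(b1, b2] -> medium``,
    ``(b2, inf) -> high``; all boundaries half-open so every value lands in
    exactly one bin.
    """
    if value < 0:
        raise ValueError(f"negative expression value {value}")
    zero, lo, hi = bins
    if value <= zero:
        return "none"
    if value <= lo:
        return "low"
    if value <= hi:
        return "medium"
    return "high"


def _bin_frame(values: pd.DataFrame, bins=DEFAULT_BINS) -> pd.DataFrame:
    zero, lo, hi = bins
    arr = values.to_numpy(dtype=float)
    out = np.full(arr.shape, "none", dtype=object)
    out[(arr > zero) & (arr <= lo)] = "low"
    out[(arr > lo) & (arr <= hi)] = "medium"
    out[arr > hi] = "high"
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def detect_expressed_rnaseq(m: ExpressionMatrix, confidence: float = 0.95,
                            bins=DEFAULT_BINS) -> DetectionResult:
    """Flag genes whose mean-FPKM t-interval lower bound exceeds zero.

    Requires at least two replicates per tissue; the interval is the two-sided
    t interval on the replicate mean (df = n_rep - 1).  Constant replicates
    give SD = 0, so any all-positive constant profile is detected, while an
    all-zero one is not (lower bound exactly 0, and the rule is strict).
    """
    if not m.has_replicates:
        raise ConfigurationError(
            "RNA-Seq detection needs replicate columns; supply a precomputed "
            "confidence-interval lower bound instead for collapsed data")
    grouped = m.values.T.groupby(level=0, sort=False)
    n = grouped.size()
    if (n < 2).any():
        bad = n[n < 2].index.tolist()
        raise ConfigurationError(
            f"tissues with <2 replicates (cannot form a t interval): {bad}")
    mean = grouped.mean().T
    sd = grouped.std(ddof=1).T
    alpha = 1.0 - confidence
    tcrit = pd.Series(stats.t.ppf(1 - alpha / 2, df=n - 1), index=n.index)
    lower = mean - sd * tcrit / np.sqrt(n)
    detected = lower > 0
    levels = _bin_frame(mean, bins)
    levels = levels.where(detected, "none")
    expressed = detected.any(axis=1)
    return DetectionResult(
        expressed=expressed, level_by_tissue=levels,
        criterion=f"FPKM {confidence:.0%} CI lower bound > 0 in >=1 tissue")


def detect_expressed_microarray(m: ExpressionMatrix, threshold: float = 200.0,
                                strict: bool = True,
                                bins=DEFAULT_BINS) -> DetectionResult:
    """Flag genes with mean intensity above ``threshold`` in >=1 tissue.

    Expects a replicate-collapsed matrix.  ``strict`` selects ``>`` (default)
    versus ``>=``.  Per-tissue levels are binned only where the tissue itself
    clears the threshold, so the overall flag and the per-tissue levels agree.
    The default bins are FPKM-scale; pass intensity-appropriate ``bins`` when
    the binning (rather than the flag) matters for microarray data.
    """
    if m.has_replicates:
        raise ConfigurationError("collapse replicates before microarray detection")
    vals = m.values
    detected = vals > threshold if strict else vals >= threshold
    levels = _bin_frame(vals, bins).where(detected, "none")
    op = ">" if strict else ">="
    return DetectionResult(
        expressed=detected.any(axis=1), level_by_tissue=levels,
        criterion=f"mean intensity {op} {threshold:g} in >=1 tissue")


def write_detection_table(result: DetectionResult, path) -> None:
    result.to_frame().to_csv(path, sep="\t")
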