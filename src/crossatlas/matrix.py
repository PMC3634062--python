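"""Expression-matrix data model and tab-delimited I/O.

The central container is :class:`ExpressionMatrix`: a genes x samples table of
nonnegative expression values tagged with the measurement platform (``rnaseq``
or ``microarray``) and its units.  Samples are either per-tissue columns or
(tissue, replicate) pairs; replicate structure is carried as a pandas
``MultiIndex`` and inferred from ``<tissue>__rep<k>`` column headers on read.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

PLATFORMS = ("rnaseq", "microarray")
#: linear (pre-transform) units; log-like units may hold negative values
LINEAR_UNITS = ("FPKM", "intensity")
TRANSFORMED_UNITS = ("log2", "asinh", "zscore")
REPLICATE_SEP = "__rep"


class ExpressionError(ValueError):
    """Invalid expression-matrix content (negative values, duplicates, NaN)."""


class ParseError(ExpressionError):
    """Malformed expression table on disk."""


class AlignmentError(ExpressionError):
    """Two matrices cannot be aligned on a shared gene set."""


@dataclass
class ExpressionMatrix:
    """Genes x (tissue[, replicate]) expression values with platform metadata.

    Parameters
    ----------
    values
        DataFrame indexed by gene id.  Columns are either a plain ``Index`` of
        tissue ids (replicate-collapsed) or a ``MultiIndex`` of
        ``(tissue, replicate)`` pairs.
    platform
        ``"rnaseq"`` or ``"microarray"``.
    units
        ``"FPKM"`` or ``"intensity"`` for linear data; ``"log2"`` / ``"asinh"``
        / ``"zscore"`` after a transform.
    """

    values: pd.DataFrame
    platform: str
    units: str

    def __post_init__(self) -> None:
        if self.platform not in PLATFORMS:
            raise ExpressionError(f"unknown platform {self.platform!r}")
        if self.units not in LINEAR_UNITS + TRANSFORMED_UNITS:
            raise ExpressionError(f"unknown units {self.units!r}")
        idx = self.values.index
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise ParseError(f"duplicate gene ids: {dups}")
        if self.values.shape[1] == 0:
            raise ExpressionError("matrix has no sample columns")
        arr = self.values.to_numpy(dtype=float)
        if np.isnan(arr).any():
            raise ExpressionError("missing values are not allowed")
        if self.units in LINEAR_UNITS and (arr < 0).any():
            gene = self.values.index[np.where(arr < 0)[0][0]]
            raise ExpressionError(f"negative value for gene {gene!r}")

    # -- structure ---------------------------------------------------------

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def has_replicates(self) -> bool:
        return isinstance(self.values.columns, pd.MultiIndex)

    @property
    def tissue_ids(self) -> list[str]:
        if self.has_replicates:
            return list(self.values.columns.get_level_values(0).unique())
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_tissues(self) -> int:
        return len(self.tissue_ids)

    def subset_genes(self, genes) -> "ExpressionMatrix":
        missing = [g for g in genes if g not in self.values.index]
        if missing:
            raise ExpressionError(f"genes absent from matrix: {missing[:5]}")
        return replace(self, values=self.values.loc[list(genes)])

    def with_values(self, values: pd.DataFrame, units: str | None = None) -> "ExpressionMatrix":
        return ExpressionMatrix(values=values, platform=self.platform,
                                units=units or self.units)


def _default_units(platform: str) -> str:
    return "FPKM" if platform == "rnaseq" else "intensity"


def read_expression_table(path, platform: str, units: str | None = None) -> ExpressionMatrix:
    """Read a tab-delimited expression table.

    The first column holds gene ids; remaining column headers are either bare
    tissue names or ``<tissue>__rep<k>``.  Ragged rows, duplicate gene ids and
    negative values are rejected.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except pd.errors.ParserError as exc:  # pragma: no cover - pandas message
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ParseError(f"duplicate gene ids in {path.name}: {dups}")
    if df.isna().any().any():
        raise ParseError(f"ragged or missing entries in {path.name}")
    try:
        vals = df.astype(float)
    except ValueError as exc:
        raise ParseError(f"non-numeric entry in {path.name}: {exc}") from exc
    cols = list(vals.columns)
    if any(REPLICATE_SEP in c for c in cols):
        tuples = []
        for c in cols:
            if REPLICATE_SEP in c:
                tissue, rep = c.rsplit(REPLICATE_SEP, 1)
                try:
                    rep_i = int(rep)
                except ValueError as exc:
                    raise ParseError(f"bad replicate label in column {c!r}") from exc
            else:
                tissue, rep_i = c, 1
            tuples.append((tissue, rep_i))
        vals.columns = pd.MultiIndex.from_tuples(tuples, names=["tissue", "replicate"])
    return ExpressionMatrix(values=vals, platform=platform,
                            units=units or _default_units(platform))


def write_expression_table(m: ExpressionMatrix, path) -> Path:
    """Write a matrix as TSV with ``<tissue>__rep<k>`` headers (round-trips
    values to at least 6 significant digits)."""
    path = Path(path)
    out = m.values.copy()
    if m.has_replicates:
        out.columns = [f"{t}{REPLICATE_SEP}{r}" for t, r in m.values.columns]
    out.index.name = "gene"
    out.to_csv(path, sep="\t", float_format="%.8g")
    return path


def collapse_replicates(m: ExpressionMatrix) -> ExpressionMatrix:
    """Average replicates within each tissue (arithmetic mean).

    A tissue with fewer replicates than its siblings is averaged over the
    replicates it has.  Replicate structure is dropped from the result.
    """
    if not m.has_replicates:
        raise ExpressionError("matrix has no replicate structure to collapse")
    collapsed = m.values.T.groupby(level=0, sort=False).mean().T
    return m.with_values(collapsed)


def align_common_genes(a: ExpressionMatrix, b: ExpressionMatrix,
                       mode: str = "all_common",
                       detections: tuple | None = None):
    """Restrict two matrices to a shared gene set, in ``a``'s gene order.

    ``mode="all_common"`` keeps every gene present in both; ``"expressed_both"``
    additionally requires the gene to be flagged expressed by both entries of
    ``detections`` (a pair of :class:`~crossatlas.detection.DetectionResult`).
    """
    if mode not in ("all_common", "expressed_both"):
        raise ValueError(f"unknown mode {mode!r}")
    common = [g for g in a.gene_ids if g in set(b.gene_ids)]
    if mode == "expressed_both":
        if detections is None:
            raise ValueError("mode 'expressed_both' requires detection results")
        det_a, det_b = detections
        keep = set(det_a.expressed[det_a.expressed].index) & \
            set(det_b.expressed[det_b.expressed].index)
        common = [g for g in common if g in keep]
    if not common:
        raise AlignmentError("no genes shared between the two matrices")
    return a.subset_genes(common), b.subset_genes(common)
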