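"""Variance-compressing transforms for the two platforms.

Microarray intensities are log2 transformed with a floor of 1 (values below 1
are replaced by 1 so the log is never negative); RNA-Seq FPKM values get the
inverse hyperbolic sine, asinh(x) = ln(x + sqrt(x^2 + 1)), which behaves like
ln(2x) for large x but stays well defined (and nearly linear) near zero.
Double transformation is refused via the units tag.
"""

from __future__ import annotations

import numpy as np

from .matrix import ExpressionMatrix, ExpressionError, LINEAR_UNITS


def _require_linear(m: ExpressionMatrix) -> None:
    if m.units not in LINEAR_UNITS:
        raise ExpressionError(
            f"matrix already transformed (units={m.units!r}); refusing to re-transform")


def transform_log2_floor(m: ExpressionMatrix, floor: float = 1.0) -> ExpressionMatrix:
    """log2 with values below ``floor`` replaced by ``floor`` (so x<1 -> 0)."""
    _require_linear(m)
    vals = np.log2(m.values.clip(lower=floor))
    return m.with_values(vals, units="log2")


def transform_asinh(m: ExpressionMatrix) -> ExpressionMatrix:
    """Inverse hyperbolic sine transform, elementwise."""
    _require_linear(m)
    return m.with_values(np.arcsinh(m.values), units="asinh")


def platform_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """The conventional transform for each platform: asinh for RNA-Seq
    (heavier compression of its larger dynamic range), log2-floor for
    microarray."""
    return transform_asinh(m) if m.platform == "rnaseq" else transform_log2_floor(m)
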