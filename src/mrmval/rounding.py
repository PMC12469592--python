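"""Reporting-rounding helpers.

Validation tables report matrix factors, CVs, accuracies and precisions as
integers (half-up, the convention of chromatography data systems), and study
concentrations to three significant figures. Internal computation always runs
at full precision; these helpers are applied only when rendering output.
"""

from __future__ import annotations

import math
from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero at ``ndigits`` decimals (half-up)."""
    x = float(x)
    if not math.isfinite(x):
        return x
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def round_sigfig(x: float, sig: int = 3) -> float:
    """Round to ``sig`` significant figures (half-up)."""
    if x == 0 or not math.isfinite(x):
        return x
    exponent = math.floor(math.log10(abs(x)))
    return round_half_up(x, sig - 1 - exponent)
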