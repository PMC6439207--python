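"""Half-up rounding helpers for reproducing printed table values.

All model arithmetic runs at full floating precision; these helpers exist
only at presentation boundaries (reports, regression comparisons against
published tables that round half-up).
"""

from __future__ import annotations

import math
from decimal import ROUND_HALF_UP, Decimal

__all__ = ["round_half_up", "round_sig"]


def round_half_up(x: float, ndigits: int) -> float:
    """Round to ``ndigits`` decimals with ties away from zero (half-up)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def round_sig(x: float, sig: int) -> float:
    """Round to ``sig`` significant figures, half-up."""
    if x == 0:
        return 0.0
    exponent = math.floor(math.log10(abs(x)))
    return round_half_up(x, sig - 1 - exponent)
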