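"""Small numeric helpers used at report boundaries."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round to ``ndigits`` decimals with ties going away from zero.

    Python's built-in ``round`` uses banker's rounding; published summary
    tables in this field round half away from zero, so report serialization
    goes through this helper instead.
    """
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(quantum, rounding=ROUND_HALF_UP))
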