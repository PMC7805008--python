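"""Half-up decimal rounding used only at the reporting layer."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round to ``ndigits`` decimals with ties going away from zero.

    Matches the convention of printed epidemiological tables (2.5 → 3, not 2).
    """
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(quantum, rounding=ROUND_HALF_UP))
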