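"""Report-time rounding: half-away-from-zero, matching printed tables."""

from decimal import ROUND_HALF_UP, Decimal

__all__ = ["round_half_away"]


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero (unlike Python's banker's rounding)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))
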