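"""Small shared helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero, as printed report tables do.

    Python's built-in ``round`` uses banker's rounding; report tables in
    this field round 0.375 -> 0.38, so serialization goes through here.
    """
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def stars(p: float, alpha1: float = 0.05, alpha2: float = 0.01) -> str:
    """Significance flag vocabulary: '' / '*' / '**' at 0.05 and 0.01."""
    if p <= alpha2:
        return "**"
    if p <= alpha1:
        return "*"
    return ""
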