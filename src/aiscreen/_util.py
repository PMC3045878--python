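"""Small shared helpers: display rounding and formatting conventions."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (0.5 -> 1, -0.5 -> -1), unlike banker's round.

    Used wherever a displayed value must match conventional hand-rounding of
    printed tables (percentages, reconstructed allele counts).
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def fmt_p(p: float) -> str:
    """P-value at display precision: 2 decimals, half away from zero."""
    return f"{round_half_away(p, 2):.2f}"


def fmt_or(x: float) -> str:
    """Odds ratio / CI bound at display precision: 2 decimals."""
    return f"{round_half_away(x, 2):.2f}"


def fmt_ratio(x: float) -> str:
    """AI ratio at display precision: 4 decimals."""
    return f"{round_half_away(x, 4):.4f}"
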