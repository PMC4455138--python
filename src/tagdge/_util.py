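"""Small shared helpers (rounding, percentages, reverse complement)."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

from tagdge.errors import UndefinedStatisticError

_RC_TABLE = str.maketrans("ACGTacgt", "TGCAtgca")


def round_half_up(value: float, decimals: int) -> float:
    """Round ``value`` to ``decimals`` places with ties going away from zero.

    Report tables use conventional half-up rounding, not banker's rounding.
    """
    quantum = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(value))).quantize(quantum, rounding=ROUND_HALF_UP))


def percent(numerator: float, denominator: float, decimals: int = 2) -> float:
    """``100 * numerator / denominator`` rounded half-up to ``decimals``."""
    if denominator == 0:
        raise UndefinedStatisticError(
            "percentage undefined: denominator is zero"
        )
    return round_half_up(100.0 * numerator / denominator, decimals)


def reverse_complement(seq: str) -> str:
    return seq.translate(_RC_TABLE)[::-1]
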