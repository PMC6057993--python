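"""Small shared helpers: rounding and coordinate conventions."""

from __future__ import annotations

import math
from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero on the positive side (0.5 -> 1).

    Python's built-in ``round`` is banker's rounding; printed tables in this
    field conventionally use half-up, so percentages like 18.9008 -> 19 and
    frequencies like 0.00641 -> 0.0064 are reproduced exactly.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def percentage(numerator: int, denominator: int) -> int:
    """100 * numerator / denominator, half-up rounded to the nearest integer."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if numerator < 0:
        raise ValueError("numerator must be non-negative")
    return int(round_half_up(100.0 * numerator / denominator, 0))


def vcf_pos_to_bed(pos: int) -> int:
    """1-based VCF position -> 0-based point coordinate (BED convention)."""
    if pos < 1:
        raise ValueError(f"VCF positions are 1-based, got {pos}")
    return pos - 1


def bed_contains(start: int, end: int, pos: int) -> bool:
    """Does the half-open 0-based interval [start, end) contain 1-based pos?"""
    return start <= vcf_pos_to_bed(pos) < end


def check_probability(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0) or math.isnan(value):
        raise ValueError(f"{name} must be a probability in [0, 1], got {value}")
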