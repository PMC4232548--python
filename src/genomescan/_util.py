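"""Small shared helpers: complements, rounding, formatting."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def complement(base: str) -> str:
    return base.translate(_COMP)


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero (table convention), not banker's rounding."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def sig3(x: float) -> float:
    """Round to three significant figures (used for summary ratios)."""
    return float(f"{x:.3g}")
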