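"""Assembly and annotation summary arithmetic.

N50, percentages, ratios and mean lengths with explicit rounding semantics:
every derived number is computed with exact rational arithmetic and rounded
half-up exactly once, at the printed precision. This matters when summary
tables are regenerated and compared digit-for-digit against earlier reports.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal, localcontext
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

__all__ = [
    "n50",
    "percent",
    "mean_length",
    "gc_percent",
    "summarize_assembly",
    "round_half_up",
]

_UNIT_BP = {"bp": 1, "kb": 10**3, "Mb": 10**6, "Gb": 10**9}


def round_half_up(value: float | Fraction | int, decimals: int = 2) -> float:
    """Round with ties away from zero (half-up), not banker's rounding."""
    frac = Fraction(value)
    with localcontext() as ctx:
        ctx.prec = 60
        dec = Decimal(frac.numerator) / Decimal(frac.denominator)
        q = Decimal(1).scaleb(-decimals)
        return float(dec.quantize(q, rounding=ROUND_HALF_UP))


def n50(lengths: Iterable[int]) -> int:
    """Length at which the descending cumulative sum first reaches half the total."""
    sizes = sorted((int(x) for x in lengths), reverse=True)
    if not sizes:
        raise ValueError("n50 of an empty length set is undefined")
    if any(s <= 0 for s in sizes):
        raise ValueError("lengths must be positive")
    half = Fraction(sum(sizes), 2)
    running = 0
    for s in sizes:
        running += s
        if running >= half:
            return s
    raise AssertionError("unreachable")  # pragma: no cover


def percent(numerator: float, denominator: float, decimals: int = 2) -> float:
    """100 * numerator / denominator, half-up rounded to ``decimals``."""
    if denominator == 0:
        raise ZeroDivisionError("percent with zero denominator")
    return round_half_up(Fraction(numerator) * 100 / Fraction(denominator), decimals)


def mean_length(total_bp: float, count: int, unit: str = "bp", decimals: int = 2) -> float:
    """Mean entity length, unit-converted (kb = 1e3, Mb = 1e6), half-up rounded."""
    if count == 0:
        raise ZeroDivisionError("mean length of zero entities")
    if unit not in _UNIT_BP:
        raise ValueError(f"unknown unit {unit!r}; expected one of {sorted(_UNIT_BP)}")
    value = Fraction(total_bp) / (Fraction(count) * _UNIT_BP[unit])
    return round_half_up(value, decimals)


def gc_percent(seq: str, decimals: int = 2) -> float:
    upper = seq.upper()
    acgt = sum(upper.count(b) for b in "ACGT")
    if acgt == 0:
        raise ValueError("sequence contains no unambiguous bases")
    return percent(upper.count("G") + upper.count("C"), acgt, decimals)


def summarize_assembly(
    contig_lengths: Sequence[int],
    scaffold_lengths: Sequence[int] | None = None,
    sequences: Mapping[str, str] | None = None,
) -> dict:
    """Per-entity-class count / total / N50 / longest (+ GC% when sequences given).

    Every stored metric is re-derivable from the inputs; nothing is cached
    across calls.
    """
    table: dict[str, dict] = {}

    def _block(lengths: Sequence[int]) -> dict:
        sizes = [int(x) for x in lengths]
        return {
            "count": len(sizes),
            "total_bp": sum(sizes),
            "n50_bp": n50(sizes),
            "longest_bp": max(sizes),
        }

    table["contigs"] = _block(contig_lengths)
    if scaffold_lengths is not None:
        table["scaffolds"] = _block(scaffold_lengths)
    if sequences is not None:
        joined = "".join(sequences.values())
        table["gc_percent"] = gc_percent(joined)
    return table
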