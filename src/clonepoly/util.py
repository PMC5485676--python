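"""Small shared helpers: banker's rounding and pair iteration."""

from __future__ import annotations

import decimal
from itertools import combinations
from typing import Iterable, Iterator, TypeVar

T = TypeVar("T")


def round_half_even(x: float, ndigits: int) -> float:
    """Round to `ndigits` decimals with IEEE half-even tie-breaking.

    Reported percentages use 2 decimals and nucleotide diversity 4; going
    through Decimal avoids binary-float artefacts near ties.
    """
    q = decimal.Decimal(10) ** -ndigits
    return float(decimal.Decimal(repr(x)).quantize(q, rounding=decimal.ROUND_HALF_EVEN))


def fmt_pct(x: float | None) -> str:
    """Format a percentage to 2 decimals; missing values render empty."""
    return "" if x is None else f"{round_half_even(x, 2):.2f}"


def fmt_pi(x: float | None) -> str:
    """Format nucleotide diversity to 4 decimals; missing values render empty."""
    return "" if x is None else f"{round_half_even(x, 4):.4f}"


def unordered_pairs(items: Iterable[T]) -> Iterator[tuple[T, T]]:
    return combinations(items, 2)
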