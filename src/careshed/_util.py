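"""Small shared helpers: rounding, interval handling."""

from __future__ import annotations

import math
from decimal import Decimal, ROUND_HALF_UP

Interval = tuple[float, float]  # half-open (lo, hi]; hi may be math.inf


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero at `ndigits` decimals.

    Published accessibility tables print whole persons and two-decimal
    percentages; banker's rounding (Python's built-in) would disagree on
    exact .5 ties, so counts and percentages use half-up throughout.
    """
    if not math.isfinite(x):
        return x
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def interval_label(interval: Interval) -> str:
    """Human-readable label for a half-open driving-time interval."""
    lo, hi = interval
    if math.isinf(hi):
        return f"over {lo:g}"
    return f"{lo:g}-{hi:g}"


def interval_contains(interval: Interval, t: float) -> bool:
    lo, hi = interval
    if lo == 0:
        return 0 <= t <= hi
    return lo < t <= hi


def parse_interval_label(label: str) -> Interval:
    label = label.strip()
    if label.startswith("over"):
        return (float(label.split()[1]), math.inf)
    lo, hi = label.split("-")
    return (float(lo), float(hi))
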