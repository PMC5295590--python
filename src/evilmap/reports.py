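"""Tabular accounting helpers shared by the reporting stages.

Percentages follow the conventions of the summary tables this pipeline
emits: one-decimal percentages round half up, whole-number percentages
round half up to the nearest integer.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import pandas as pd

from .filters import STAGE_NAMES, FilterReport


def round_half_up(x: float, ndigits: int = 0) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def percent(numerator: float, denominator: float, ndigits: int = 1) -> float:
    """Percentage with round-half-up at ``ndigits`` decimals."""
    if denominator == 0:
        raise ZeroDivisionError("percentage of an empty total")
    return round_half_up(100.0 * numerator / denominator, ndigits)


def reduction_percent(before: float, after: float) -> float:
    """Whole-number percentage of items removed between two stages."""
    return percent(before - after, before, ndigits=0)


def cascade_totals(reports: Sequence[FilterReport]) -> dict[str, int]:
    """Column sums of per-line filter reports (the multi-line summary row)."""
    totals: dict[str, int] = {}
    for stage in STAGE_NAMES:
        totals[stage] = sum(r.count(stage) for r in reports)
    return totals


def cascade_table(reports: Sequence[FilterReport]) -> pd.DataFrame:
    """Per-line survivor counts per stage, plus a Total row."""
    rows = [
        {"line": r.line_id, **{name: n for name, n in r.stages}} for r in reports
    ]
    totals = cascade_totals(reports)
    rows.append({"line": "Total", **totals})
    return pd.DataFrame(rows)
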