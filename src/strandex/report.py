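"""Rounding conventions and report-table arithmetic.

Percentages throughout the pipeline's report tables are rounded half-up to one
decimal (the convention of the published tables); mean lengths are integers
rounded half-up.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping

import pandas as pd

__all__ = ["round_half_up", "percentage", "single_timepoint_fraction", "de_membership_table"]


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero at the given decimal place."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def percentage(count: int, total: int, ndigits: int = 1) -> float:
    """count/total as a percentage, rounded half-up to ``ndigits`` decimals."""
    if total == 0:
        return 0.0
    return round_half_up(100.0 * count / total, ndigits)


def single_timepoint_fraction(de_sets: Mapping[str, Iterable[str]]) -> pd.DataFrame:
    """Count transcripts differentially expressed at exactly 1, 2 or 3 time points.

    ``de_sets`` maps each post-conditioning time point to its DE transcript
    ids.  Percentages are of the union of all DE transcripts, rounded half-up
    to one decimal.
    """
    sets = {tp: set(ids) for tp, ids in de_sets.items()}
    universe = set().union(*sets.values()) if sets else set()
    multiplicity = {
        t: sum(t in s for s in sets.values()) for t in universe
    }
    total = len(universe)
    rows = []
    for k in (1, 2, 3):
        members = sorted(t for t, m in multiplicity.items() if m == k)
        rows.append(
            {
                "n_timepoints": k,
                "count": len(members),
                "percent": percentage(len(members), total),
            }
        )
    return pd.DataFrame(rows, columns=["n_timepoints", "count", "percent"])


def de_membership_table(
    up_sets: Mapping[str, Iterable[str]], down_sets: Mapping[str, Iterable[str]]
) -> pd.DataFrame:
    """Per-direction membership counts across time-point combinations.

    For each direction and each non-empty combination of time points, counts
    the transcripts significant in that direction at exactly that combination
    (the logic behind the published up/down time-point diagram).
    """
    rows = []
    for direction, sets in (("up", up_sets), ("down", down_sets)):
        sets = {tp: set(ids) for tp, ids in sets.items()}
        tps = sorted(sets)
        universe = set().union(*sets.values()) if sets else set()
        for t in sorted(universe):
            combo = tuple(tp for tp in tps if t in sets[tp])
            rows.append({"direction": direction, "combo": "+".join(combo), "transcript_id": t})
    if not rows:
        return pd.DataFrame(columns=["direction", "combo", "count"])
    df = pd.DataFrame(rows)
    out = (
        df.groupby(["direction", "combo"], sort=True)
        .size()
        .reset_index(name="count")
    )
    return out
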