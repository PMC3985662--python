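"""Differential protection between two states.

Peptide-by-peptide: per-time percent-exchange differences (Δ%D) and the
fold change in the time both states need to reach the same exchange level,
with explicit censoring when a level is never reached inside the time grid.
Residue-by-residue: consensus difference categories over the covering
peptides, with uncovered positions marked distinctly from "no difference".

Peptides are matched by exact (chain, start, end, sequence); fold-time
ratios are binned into the categories <10, 10-1000 and >=1000 (bounds bin
by their bound value).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ratemap import TimeToLevel, UptakeCurve, time_to_level
from .synthetic import PeptidePool

__all__ = [
    "FoldTime",
    "StateComparison",
    "delta_percent",
    "fold_time",
    "bin_fold_time",
    "consensus_difference",
    "compare_states",
]

logger = logging.getLogger(__name__)

CATEGORIES = ("<10", "10-1000", ">=1000")
NO_DATA = "no data"
INDETERMINATE = "indeterminate"


def _match_key(curve: UptakeCurve) -> tuple:
    return (curve.chain, curve.start, curve.end, curve.sequence)


def delta_percent(curve_a: UptakeCurve, curve_b: UptakeCurve) -> pd.DataFrame:
    """Per-time %D(B) - %D(A) for one peptide; times present in only one
    curve are skipped."""
    if _match_key(curve_a) != _match_key(curve_b):
        raise ValueError("curves are not the same peptide")
    ta = {float(t): p for t, p in zip(curve_a.times, curve_a.percent)}
    tb = {float(t): p for t, p in zip(curve_b.times, curve_b.percent)}
    times = sorted(set(ta) & set(tb))
    return pd.DataFrame(
        {
            "time_s": times,
            "delta_percent": [tb[t] - ta[t] for t in times],
        }
    )


@dataclass(frozen=True)
class FoldTime:
    """time_to_level(B) / time_to_level(A), possibly censored.

    ``censor``: "exact"; "lower" (true ratio >= value); "upper" (true ratio
    <= value); "indeterminate" (both curves censored the same way).
    """

    value: float
    censor: str = "exact"

    def __str__(self) -> str:
        mark = {"exact": "", "lower": ">=", "upper": "<=", "indeterminate": "?"}[
            self.censor
        ]
        return f"{mark}{self.value:g}"


def fold_time(curve_a: UptakeCurve, curve_b: UptakeCurve, level: float = 50.0) -> FoldTime:
    """Fold increase in the time state B needs to reach ``level`` %D
    relative to state A.  Censored times propagate into bounds:
    bound/bound in opposite directions stays a bound, same direction is
    indeterminate."""
    ta = time_to_level(curve_a, level)
    tb = time_to_level(curve_b, level)
    ratio = tb.time_s / ta.time_s
    ca, cb = ta.censor, tb.censor
    if ca == "exact" and cb == "exact":
        return FoldTime(ratio, "exact")
    if cb == "lower" and ca in ("exact", "upper"):
        return FoldTime(ratio, "lower")  # B slower than measurable: >= ratio
    if cb == "upper" and ca in ("exact", "lower"):
        return FoldTime(ratio, "upper")
    if cb == "exact" and ca == "lower":
        return FoldTime(ratio, "upper")
    if cb == "exact" and ca == "upper":
        return FoldTime(ratio, "lower")
    return FoldTime(ratio, "indeterminate")


def bin_fold_time(ft: FoldTime, bins: tuple[float, float] = (10.0, 1000.0)) -> str:
    """Category of a fold-time ratio or bound: <10, 10-1000, >=1000.

    Lower bounds bin by their bound value; upper bounds bin only when they
    fit entirely below the first threshold, otherwise indeterminate.
    """
    lo, hi = bins
    if ft.censor == "indeterminate":
        return INDETERMINATE
    if ft.censor == "upper":
        return CATEGORIES[0] if ft.value <= lo else INDETERMINATE
    v = ft.value
    if v < lo:
        return CATEGORIES[0]
    if v < hi:
        return CATEGORIES[1]
    return CATEGORIES[2]


def consensus_difference(
    peptide_categories: dict[str, str],
    pool: PeptidePool,
) -> dict[tuple[str, int], str]:
    """Majority consensus category per residue over covering peptides.

    Only peptides in which the residue is measurable (peptide-relative
    position >= 3, non-proline) vote; indeterminate votes are discarded.
    Ties resolve toward the smaller |Δ| category.  Uncovered (or vote-less)
    positions are marked "no data".
    """
    order = {c: i for i, c in enumerate(CATEGORIES)}
    votes: dict[tuple[str, int], list[str]] = {}
    covered: set[tuple[str, int]] = set()
    for p in pool:
        cat = peptide_categories.get(p.peptide_id)
        for rel in range(3, p.end - p.start + 2):
            if p.sequence[rel - 1] == "P":
                continue
            key = (p.chain, p.start + rel - 1)
            covered.add(key)
            if cat is not None and cat in order:
                votes.setdefault(key, []).append(cat)
    out: dict[tuple[str, int], str] = {}
    for key in covered:
        vs = votes.get(key, [])
        if not vs:
            out[key] = NO_DATA
            continue
        counts: dict[str, int] = {}
        for v in vs:
            counts[v] = counts.get(v, 0) + 1
        top = max(counts.values())
        winners = [c for c, n in counts.items() if n == top]
        out[key] = min(winners, key=lambda c: order[c])  # tie -> smaller |delta|
    return out


@dataclass
class StateComparison:
    """Full two-state comparison (A = reference, B = comparison)."""

    state_a: str
    state_b: str
    level: float
    peptide_table: pd.DataFrame
    residue_categories: dict[tuple[str, int], str]
    bins: tuple[float, float] = (10.0, 1000.0)

    def residue_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"chain": c, "residue_index": i, "category": cat}
                for (c, i), cat in sorted(self.residue_categories.items())
            ]
        )


def compare_states(
    curves_a: list[UptakeCurve],
    curves_b: list[UptakeCurve],
    pool: PeptidePool,
    level: float = 50.0,
    bins: tuple[float, float] = (10.0, 1000.0),
) -> StateComparison:
    """Match peptides between two states and compute Δ%D, fold times and the
    per-residue consensus difference map."""
    a_by_key = {_match_key(c): c for c in curves_a}
    b_by_key = {_match_key(c): c for c in curves_b}
    rows = []
    categories: dict[str, str] = {}
    for key in sorted(set(a_by_key) | set(b_by_key)):
        if key not in a_by_key or key not in b_by_key:
            logger.info("peptide %s present in only one state; excluded", key)
            continue
        ca, cb = a_by_key[key], b_by_key[key]
        deltas = delta_percent(ca, cb)
        ft = fold_time(ca, cb, level)
        cat = bin_fold_time(ft, bins)
        categories[ca.peptide_id] = cat
        row = {
            "peptide_id": ca.peptide_id,
            "chain": ca.chain,
            "start": ca.start,
            "end": ca.end,
            "sequence": ca.sequence,
            "fold_time": ft.value,
            "fold_time_censor": ft.censor,
            "category": cat,
        }
        for t, d in zip(deltas["time_s"], deltas["delta_percent"]):
            row[f"delta_pct_{t:g}s"] = d
        rows.append(row)
    residue_categories = consensus_difference(categories, pool)
    state_a = curves_a[0].state_id if curves_a else "A"
    state_b = curves_b[0].state_id if curves_b else "B"
    return StateComparison(
        state_a=state_a,
        state_b=state_b,
        level=level,
        peptide_table=pd.DataFrame(rows),
        residue_categories=residue_categories,
        bins=bins,
    )
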