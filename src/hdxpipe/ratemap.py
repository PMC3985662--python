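"""Per-peptide uptake curves and residue-level consensus rate-class maps.

Overlapping peptides constrain each residue's exchange speed: the map
assigns every covered measurable residue one of the discrete rate classes
(:mod:`hdxpipe.rateclasses`) by minimizing the squared difference between
observed per-peptide deuteron counts and the counts predicted from the
class rates, summed over peptides and time points.  Connected components of
residues (linked by shared peptides) are solved exhaustively when small,
otherwise by seeded coordinate descent with random restarts.  Known helical
segments may seed (not freeze) residues at the slowest class.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import isotonic_regression

from .chemistry import ExchangeConditions
from .rateclasses import RATE_CLASSES, RateClass
from .synthetic import Peptide, PeptidePool

__all__ = [
    "UptakeCurve",
    "TimeToLevel",
    "RateClassMap",
    "build_curves",
    "time_to_level",
    "consensus_residue_map",
    "map_residuals",
]

logger = logging.getLogger(__name__)


@dataclass
class UptakeCurve:
    """Charge-merged uptake of one peptide over the time grid."""

    peptide_id: str
    chain: str
    start: int
    end: int
    sequence: str
    times: np.ndarray  # seconds, strictly increasing
    percent: np.ndarray
    deuterons: np.ndarray
    modality: np.ndarray | None = None  # per-time "unimodal"/"bimodal"
    state_id: str = ""
    gaps: bool = False

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.percent = np.asarray(self.percent, dtype=float)
        self.deuterons = np.asarray(self.deuterons, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def isotonic_percent(self) -> np.ndarray:
        """Non-decreasing fit of the percent curve (end points preserved by
        the pool-adjacent-violators construction when already monotone)."""
        return isotonic_regression(self.percent).x


def build_curves(
    uptake_table: pd.DataFrame, expected_times: tuple[float, ...] | None = None
) -> list[UptakeCurve]:
    """One curve per (state, peptide) from a charge-merged uptake table."""
    if uptake_table.empty:
        return []
    curves = []
    for (state, pid), grp in uptake_table.groupby(["state_id", "peptide_id"]):
        grp = grp.sort_values("time_s")
        first = grp.iloc[0]
        gaps = False
        if expected_times is not None:
            gaps = set(np.asarray(expected_times, dtype=float)) - set(
                grp["time_s"].astype(float)
            ) != set()
            if gaps:
                logger.warning("peptide %s: missing time points", pid)
        curves.append(
            UptakeCurve(
                peptide_id=pid,
                chain=first["chain"],
                start=int(first["start"]),
                end=int(first["end"]),
                sequence=first["sequence"],
                times=grp["time_s"].to_numpy(dtype=float),
                percent=grp["percent_exchange"].to_numpy(dtype=float),
                deuterons=grp["deuterons"].to_numpy(dtype=float),
                modality=grp["modality"].to_numpy() if "modality" in grp else None,
                state_id=state,
                gaps=gaps,
            )
        )
    return curves


@dataclass(frozen=True)
class TimeToLevel:
    """Time to reach an exchange level; possibly a censored bound.

    ``censor`` is ``"exact"``, ``"lower"`` (level not reached by the last
    time: true value > ``time_s``) or ``"upper"`` (level already exceeded at
    the first time: true value < ``time_s``).
    """

    time_s: float
    censor: str = "exact"

    def __str__(self) -> str:
        mark = {"exact": "", "lower": ">", "upper": "<"}[self.censor]
        return f"{mark}{self.time_s:g}s"


def time_to_level(curve: UptakeCurve, level_percent: float) -> TimeToLevel:
    """Log-linear interpolation of the time at which a curve crosses a
    level; censored bounds at the grid edges; non-monotone curves are
    interpolated on their isotonic fit."""
    if not (0.0 < level_percent < 100.0):
        raise ValueError("level must be in (0, 100)")
    pct = curve.percent
    if np.any(np.diff(pct) < 0):
        pct = curve.isotonic_percent()
    if pct[0] >= level_percent:
        return TimeToLevel(curve.times[0], "upper")
    if pct[-1] < level_percent:
        return TimeToLevel(curve.times[-1], "lower")
    idx = int(np.searchsorted(pct >= level_percent, True))
    t0, t1 = curve.times[idx - 1], curve.times[idx]
    p0, p1 = pct[idx - 1], pct[idx]
    if p1 == p0:
        return TimeToLevel(t1, "exact")
    frac = (level_percent - p0) / (p1 - p0)
    logt = math.log10(t0) + frac * (math.log10(t1) - math.log10(t0))
    return TimeToLevel(10.0 ** logt, "exact")


# ---------------------------------------------------------------------------
# consensus rate-class maps


@dataclass
class RateClassMap:
    """Per-residue consensus exchange-rate class with ambiguity flags."""

    entries: dict[tuple[str, int], dict] = field(default_factory=dict)
    total_residual: float = 0.0

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"chain": c, "residue_index": i, **v}
            for (c, i), v in sorted(self.entries.items())
        ]
        return pd.DataFrame(rows)

    def numeric(self) -> dict[tuple[str, int], float]:
        """Class ordinal (1..6) per residue, for structure export."""
        order = {cls.label: j + 1 for j, cls in enumerate(RATE_CLASSES)}
        return {k: float(order[v["class_label"]]) for k, v in self.entries.items()}


def _peptide_sites(p: Peptide) -> list[int]:
    """Global positions of measurable sites: peptide-relative >= 3, not P."""
    return [
        p.start + rel - 1
        for rel in range(3, p.end - p.start + 2)
        if p.sequence[rel - 1] != "P"
    ]


def _class_uptake_matrix(
    times: np.ndarray, cond: ExchangeConditions, classes: tuple[RateClass, ...]
) -> np.ndarray:
    """u[class, time] = plateau-scaled single-site uptake in deuterons."""
    k = np.array([c.rep_rate for c in classes])
    return cond.d2o_fraction * (1.0 - np.exp(-np.outer(k, times)))


def consensus_residue_map(
    curves: list[UptakeCurve],
    pool: PeptidePool,
    cond: ExchangeConditions,
    classes: tuple[RateClass, ...] = RATE_CLASSES,
    seeds: list[tuple[str, int, int]] | None = None,
    exhaustive_max: int = 6,
    n_restarts: int = 10,
    ambiguity_tol: float = 1e-6,
    rng_seed: int = 0,
) -> RateClassMap:
    """Assign each covered measurable residue a consensus rate class.

    Minimizes sum over peptides and times of squared (observed deuterons -
    sum over sites of class uptake).  ``seeds`` are (chain, start, end)
    helix segments whose residues start at the slowest class.  Residues
    whose optimum is not unique within ``ambiguity_tol`` (relative residual)
    are flagged ambiguous and reported at the slower class.
    """
    by_id = {p.peptide_id: p for p in pool}
    usable = []
    for curve in curves:
        p = by_id.get(curve.peptide_id)
        if p is None:
            continue
        sites = _peptide_sites(p)
        if not sites:
            logger.warning("peptide %s has no measurable amides; ignored", p.peptide_id)
            continue
        usable.append((curve, p, sites))
    if not usable:
        return RateClassMap()

    # residue registry and peptide incidence
    residues = sorted({(p.chain, s) for _, p, sites in usable for s in sites})
    ridx = {r: j for j, r in enumerate(residues)}
    pep_sites = []  # per usable peptide: residue indices, observed deuterons, u matrix
    support = np.zeros(len(residues), dtype=int)
    for curve, p, sites in usable:
        ids = np.array([ridx[(p.chain, s)] for s in sites])
        support[ids] += 1
        u = _class_uptake_matrix(curve.times, cond, classes)
        pep_sites.append((ids, curve.deuterons.copy(), u))

    n_res, n_cls = len(residues), len(classes)

    # initial assignment: seeded residues at the slowest class, others at
    # their marginal per-site best
    slowest = n_cls - 1
    assign = np.zeros(n_res, dtype=int)
    marginal = np.zeros((n_res, n_cls))
    counts = np.zeros(n_res)
    for ids, obs, u in pep_sites:
        per_site = obs / len(ids)  # crude equal split for initialization
        err = (u - per_site[None, :]) ** 2  # (cls, time)
        marginal[ids] += err.sum(axis=1)[None, :]
        counts[ids] += 1
    assign = np.argmin(marginal, axis=1)
    seeded = np.zeros(n_res, dtype=bool)
    for chain, s0, s1 in seeds or []:
        for pos in range(s0, s1 + 1):
            j = ridx.get((chain, pos))
            if j is not None:
                seeded[j] = True
                assign[j] = slowest

    # connected components via shared peptides
    parent = list(range(n_res))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    for ids, _, _ in pep_sites:
        for j in ids[1:]:
            union(int(ids[0]), int(j))
    comps: dict[int, list[int]] = {}
    for j in range(n_res):
        comps.setdefault(find(j), []).append(j)

    def total_residual(a: np.ndarray) -> float:
        tot = 0.0
        for ids, obs, u in pep_sites:
            pred = u[a[ids]].sum(axis=0)
            tot += float(((obs - pred) ** 2).sum())
        return tot

    # longest covering peptide per residue -> greedy sweep order
    longest = np.zeros(n_res, dtype=int)
    for ids, _, _ in pep_sites:
        longest[ids] = np.maximum(longest[ids], len(ids))

    rng = np.random.default_rng(rng_seed)
    peps_of_res: list[list[int]] = [[] for _ in range(n_res)]
    for pi, (ids, _, _) in enumerate(pep_sites):
        for j in ids:
            peps_of_res[int(j)].append(pi)

    def local_residual(a: np.ndarray, j: int) -> float:
        tot = 0.0
        for pi in peps_of_res[j]:
            ids, obs, u = pep_sites[pi]
            pred = u[a[ids]].sum(axis=0)
            tot += float(((obs - pred) ** 2).sum())
        return tot

    # coordinate descent: full passes until no residue changes class
    def sweep(a: np.ndarray, order: np.ndarray) -> np.ndarray:
        a = a.copy()
        for _ in range(100):
            changed = False
            for j in order:
                cur = a[j]
                best_c, best_r = cur, local_residual(a, j)
                for c in range(n_cls):
                    if c == cur:
                        continue
                    a[j] = c
                    r = local_residual(a, j)
                    if r < best_r - 1e-15:
                        best_r, best_c = r, c
                a[j] = best_c
                changed = changed or best_c != cur
            if not changed:
                break
        return a

    for comp in comps.values():
        comp = sorted(comp)
        if len(comp) <= exhaustive_max:
            comp_arr = np.array(comp)
            best_a, best_r = None, math.inf
            for combo in itertools.product(range(n_cls), repeat=len(comp)):
                trial = assign.copy()
                trial[comp_arr] = combo
                r = _component_residual(trial, comp, peps_of_res, pep_sites)
                # product order is lexicographically increasing, so taking
                # ties (<= tol) keeps the slower assignment — the
                # conservative protection claim
                if r < best_r - 1e-15 or (best_a is not None and r <= best_r + 1e-15):
                    best_r, best_a = min(r, best_r), trial
            assign[comp_arr] = best_a[comp_arr]
        else:
            order = np.array(sorted(comp, key=lambda j: -longest[j]))
            best_a = sweep(assign, order)
            best_r = _component_residual(best_a, comp, peps_of_res, pep_sites)
            # restarts are free draws: seeding shapes only the first start
            for _ in range(max(0, n_restarts - 1)):
                start = assign.copy()
                start[comp] = rng.integers(0, n_cls, size=len(comp))
                cand = sweep(start, order)
                r = _component_residual(cand, comp, peps_of_res, pep_sites)
                if r < best_r - 1e-15:
                    best_a, best_r = cand, r
            assign[comp] = best_a[comp]

    # ambiguity: residues whose best alternative class is within tolerance
    total = total_residual(assign)
    scale = max(total, 1.0)
    result = RateClassMap(total_residual=total)
    for j, (chain, pos) in enumerate(residues):
        cur = int(assign[j])
        base = local_residual(assign, j)
        ambiguous = False
        chosen = cur
        trial = assign.copy()
        for c in range(n_cls):
            if c == cur:
                continue
            trial[j] = c
            r = local_residual(trial, j)
            if abs(r - base) <= ambiguity_tol * scale:
                ambiguous = True
                chosen = max(chosen, c)  # report the slower class
            trial[j] = cur
        result.entries[(chain, pos)] = {
            "class_label": classes[chosen].label,
            "ambiguous": ambiguous,
            "support": int(support[j]),
        }
    return result


def _component_residual(a, comp, peps_of_res, pep_sites) -> float:
    peps = sorted({pi for j in comp for pi in peps_of_res[j]})
    tot = 0.0
    for pi in peps:
        ids, obs, u = pep_sites[pi]
        pred = u[a[ids]].sum(axis=0)
        tot += float(((obs - pred) ** 2).sum())
    return tot


def map_residuals(
    rate_map: RateClassMap,
    curves: list[UptakeCurve],
    pool: PeptidePool,
    cond: ExchangeConditions,
    classes: tuple[RateClass, ...] = RATE_CLASSES,
    tolerance: float = 1.0,
) -> pd.DataFrame:
    """Predicted-vs-observed deuterons per peptide/time; peptides whose
    worst residual exceeds ``tolerance`` deuterons are flagged."""
    if not rate_map.entries:
        raise ValueError("empty rate-class map")
    by_label = {c.label: c for c in classes}
    by_id = {p.peptide_id: p for p in pool}
    rows = []
    for curve in curves:
        p = by_id.get(curve.peptide_id)
        if p is None:
            continue
        sites = _peptide_sites(p)
        rates = []
        for s in sites:
            entry = rate_map.entries.get((p.chain, s))
            if entry is not None:
                rates.append(by_label[entry["class_label"]].rep_rate)
        if not rates:
            continue
        k = np.array(rates)
        pred = cond.d2o_fraction * (1.0 - np.exp(-np.outer(k, curve.times))).sum(axis=0)
        resid = curve.deuterons - pred
        worst = float(np.abs(resid).max())
        for t, o, pr in zip(curve.times, curve.deuterons, pred):
            rows.append(
                {
                    "peptide_id": p.peptide_id,
                    "state_id": curve.state_id,
                    "time_s": t,
                    "observed": o,
                    "predicted": pr,
                    "residual": o - pr,
                    "flagged": worst > tolerance,
                }
            )
    return pd.DataFrame(rows)
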