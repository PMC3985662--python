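"""Synthetic H/DX-MS datasets with known ground truth.

Generates multi-chain protein states with per-residue protection factors
and optional EX1 (concerted-unfolding) segments, overlapping peptic-style
peptide pools, and full time-course isotopic envelopes (undeuterated,
labeling series, fully-deuterated reference) with per-peptide back-exchange
and multiplicative intensity noise.

Presets emulate the architecture of histone-chaperone H/DX studies:

``tetramer``
    a histone-fold H3/H4 pair with an unfolded N-terminal tail and alphaN
    helix (fast exchange), a moderately protected core, and an EX1 segment
    spanning the alpha2-L2-alpha3 region of H3.
``trimer``
    the same chains plus a chaperone chain, globally far slower (the bound,
    rigidified complex), with a locally accelerated L2 loop and no EX1.
``monomer_unfolded``
    the free chaperone: near-zero protection everywhere except one stable
    "tower" segment.

The exchange model is single-site first-order kinetics toward the D2O
plateau (EX2); EX1 segments are two-state: a closed population exchanging
at the protected rates and an open population carrying full plateau
deuteration over the segment, mixed with weights exp(-k_open t) and
1 - exp(-k_open t) (exchange assumed faster than reclosing).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .chemistry import ExchangeConditions, SiteKinetics, intrinsic_rates
from .rateclasses import CLASS_BY_LABEL, class_rate
from .spectra import (
    DELTA_MASS_D,
    IsotopicEnvelope,
    deuterated_sticks,
    natural_envelope,
    poisson_binomial,
    to_mz,
)

__all__ = [
    "Ex1Region",
    "GroundTruthState",
    "Peptide",
    "PeptidePool",
    "SimulatedDataset",
    "PRESETS",
    "generate_state",
    "generate_digest",
    "simulate_envelope",
    "simulate_dataset",
    "H3_SEQ",
    "H4_SEQ",
    "CHAPERONE_SEQ",
]

# Human histone H3.3 and H4 (mature, 135 and 102 residues).
H3_SEQ = (
    "ARTKQTARKSTGGKAPRKQLATKAARKSAPSTGGVKKPHRYRPGTVALRE"
    "IRRYQKSTELLIRKLPFQRLVREIAQDFKTDLRFQSAAIGALQEASEAYL"
    "VGLFEDTNLCAIHAKRVTIMPKDIQLARRIRGERA"
)
H4_SEQ = (
    "SGRGKGGKGLGKGGAKRHRKVLRDNIQGITKPAIRRLARRGGVKRISGLI"
    "YEETRGVLKVFLENVIRDAVTYTEHAKRKTVTAMDVVYALKRQGRTLYGF"
    "GG"
)


def _synthetic_chain(length: int, seed: int) -> str:
    """Deterministic synthetic protein-like sequence (globular composition,
    prolines kept sparse). Used for the chaperone chain, which has no
    embedded reference sequence."""
    aa = np.array(list("ACDEFGHIKLMNQRSTVWYP"))
    w = np.array([8, 2, 6, 7, 4, 7, 2, 6, 7, 10, 2, 4, 4, 6, 7, 6, 7, 1, 3, 1.0])
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(aa, size=length, p=w / w.sum()))


#: synthetic stand-in for a 235-residue chaperone histone-binding domain
CHAPERONE_SEQ = _synthetic_chain(235, seed=4137)


@dataclass(frozen=True)
class Ex1Region:
    """A segment that unfolds concertedly with first-order opening rate."""

    chain: str
    start: int
    end: int
    k_open: float  # s^-1

    def __post_init__(self) -> None:
        if self.k_open <= 0:
            raise ValueError("opening rate must be positive")
        if self.start > self.end:
            raise ValueError("start must be <= end")


@dataclass
class GroundTruthState:
    """Per-residue exchange kinetics of one conformational state."""

    state_id: str
    chains: dict[str, str]
    log10_pf: dict[str, np.ndarray]
    ex1_regions: list[Ex1Region] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        for chain, seq in self.chains.items():
            pf = np.asarray(self.log10_pf[chain], dtype=float)
            if len(pf) != len(seq):
                raise ValueError(f"chain {chain}: protection array length mismatch")
            if np.any(pf < 0):
                raise ValueError("log10 protection factors must be >= 0")
            self.log10_pf[chain] = pf
        for reg in self.ex1_regions:
            if reg.chain not in self.chains:
                raise ValueError(f"EX1 region references unknown chain {reg.chain}")
            if not (1 <= reg.start <= reg.end <= len(self.chains[reg.chain])):
                raise ValueError("EX1 region outside chain")

    def site_kinetics(self, chain: str, cond: ExchangeConditions) -> list[SiteKinetics]:
        """Chain-level kinetics with this state's protection applied."""
        sites = intrinsic_rates(self.chains[chain], cond)
        out = []
        for s, lp in zip(sites, self.log10_pf[chain]):
            meas = s.residue != "P" and s.residue_index > 1
            k = SiteKinetics(
                s.residue_index,
                s.residue,
                s.k_int,
                lp if meas else 0.0,
                measurable=meas,
            )
            out.append(k)
        return out


@dataclass(frozen=True)
class Peptide:
    peptide_id: str
    chain: str
    start: int  # 1-based inclusive
    end: int
    sequence: str
    charge_states: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("start must be <= end")
        if any(z < 1 for z in self.charge_states):
            raise ValueError("charges must be positive")


@dataclass
class PeptidePool:
    peptides: list[Peptide]

    def __post_init__(self) -> None:
        self.peptides = sorted(self.peptides, key=lambda p: (p.chain, p.start, p.end))

    def __iter__(self):
        return iter(self.peptides)

    def __len__(self) -> int:
        return len(self.peptides)

    def validate_against(self, chains: dict[str, str]) -> None:
        for p in self.peptides:
            if p.chain not in chains:
                raise ValueError(f"peptide {p.peptide_id}: unknown chain {p.chain}")
            if chains[p.chain][p.start - 1 : p.end] != p.sequence:
                raise ValueError(f"peptide {p.peptide_id}: sequence != chain slice")

    def coverage(self, chains: dict[str, str]) -> dict[str, np.ndarray]:
        cov = {c: np.zeros(len(s), dtype=int) for c, s in chains.items()}
        for p in self.peptides:
            cov[p.chain][p.start - 1 : p.end] += 1
        return cov

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "peptide_id": p.peptide_id,
                    "chain": p.chain,
                    "start": p.start,
                    "end": p.end,
                    "sequence": p.sequence,
                    "charge_states": ";".join(map(str, p.charge_states)),
                }
                for p in self.peptides
            ]
        )

    @classmethod
    def from_frame(cls, df) -> "PeptidePool":
        peps = [
            Peptide(
                str(r.peptide_id),
                str(r.chain),
                int(r.start),
                int(r.end),
                str(r.sequence),
                tuple(int(z) for z in str(r.charge_states).split(";")),
            )
            for r in df.itertuples()
        ]
        return cls(peps)


# ---------------------------------------------------------------------------
# ground-truth states

PRESETS: dict[str, dict] = {
    # unbound histone-fold pair: tails and alphaN fast, core moderately
    # protected, EX1 unfolding across the alpha2-L2-alpha3 analog
    "tetramer": {
        "chains": {"H3": H3_SEQ, "H4": H4_SEQ},
        "default_class": "C4",
        "segments": [
            {"chain": "H3", "start": 1, "end": 44, "rate_class": "C1"},
            {"chain": "H3", "start": 45, "end": 57, "rate_class": "C1"},  # alphaN analog
            {"chain": "H3", "start": 58, "end": 85, "rate_class": "C4"},
            {"chain": "H3", "start": 86, "end": 102, "rate_class": "C5"},
            {"chain": "H3", "start": 103, "end": 126, "rate_class": "C5"},
            {"chain": "H3", "start": 127, "end": 135, "rate_class": "C2"},
            {"chain": "H4", "start": 1, "end": 25, "rate_class": "C1"},
            {"chain": "H4", "start": 26, "end": 95, "rate_class": "C4"},
            {"chain": "H4", "start": 96, "end": 102, "rate_class": "C2"},
        ],
        "ex1_regions": [{"chain": "H3", "start": 103, "end": 126, "k_open": 1e-4}],
    },
    # chaperone-bound pair: global rigidification, locally accelerated L2
    "trimer": {
        "chains": {"H3": H3_SEQ, "H4": H4_SEQ, "D": CHAPERONE_SEQ},
        "default_class": "C6",
        "segments": [
            {"chain": "H3", "start": 1, "end": 37, "rate_class": "C1"},
            {"chain": "H3", "start": 38, "end": 44, "rate_class": "C3"},
            {"chain": "H3", "start": 45, "end": 57, "rate_class": "C6"},  # alphaN folded
            {"chain": "H3", "start": 58, "end": 109, "rate_class": "C6"},
            {"chain": "H3", "start": 110, "end": 116, "rate_class": "C2"},  # L2 accelerated
            {"chain": "H3", "start": 117, "end": 135, "rate_class": "C6"},
            {"chain": "H4", "start": 1, "end": 25, "rate_class": "C1"},
            {"chain": "H4", "start": 26, "end": 102, "rate_class": "C6"},
            {"chain": "D", "start": 1, "end": 30, "rate_class": "C3"},
            {"chain": "D", "start": 31, "end": 215, "rate_class": "C6"},
            {"chain": "D", "start": 216, "end": 235, "rate_class": "C3"},
        ],
        "ex1_regions": [],
    },
    # free chaperone: essentially unfolded except the stable tower segment
    "monomer_unfolded": {
        "chains": {"D": CHAPERONE_SEQ},
        "default_class": "C1",
        "segments": [
            {"chain": "D", "start": 60, "end": 100, "rate_class": "C5"},  # tower analog
        ],
        "ex1_regions": [],
    },
}


def generate_state(
    template: dict | str,
    seed: int = 0,
    cond: ExchangeConditions | None = None,
    state_id: str | None = None,
) -> GroundTruthState:
    """Build a :class:`GroundTruthState` from a template (or preset name).

    Template segments give either a ``rate_class`` label or an explicit
    ``log10_pf``; per-residue protection factors are derived so the site's
    observed rate equals the class's representative rate (floored at
    protection factor 1).  Deterministic given ``seed``.
    """
    if isinstance(template, str):
        name = template
        template = PRESETS[template]
        state_id = state_id or name
    cond = cond or ExchangeConditions()
    chains = dict(template["chains"])
    default_class = template.get("default_class", "C1")

    assigned: dict[str, list] = {c: [None] * len(s) for c, s in chains.items()}
    for seg in template.get("segments", []):
        c, s0, s1 = seg["chain"], seg["start"], seg["end"]
        if c not in chains or not (1 <= s0 <= s1 <= len(chains[c])):
            raise ValueError(f"segment outside chain: {seg}")
        spec = seg.get("rate_class") or ("log10_pf", seg["log10_pf"])
        for i in range(s0 - 1, s1):
            if assigned[c][i] is not None and assigned[c][i] != spec:
                raise ValueError(
                    f"contradictory segment specs for chain {c} residue {i + 1}"
                )
            assigned[c][i] = spec

    log10_pf: dict[str, np.ndarray] = {}
    for c, seq in chains.items():
        sites = intrinsic_rates(seq, cond)
        pf = np.zeros(len(seq))
        for i, site in enumerate(sites):
            spec = assigned[c][i] if assigned[c][i] is not None else default_class
            if seq[i] == "P" or i == 0 or not math.isfinite(site.k_int):
                continue
            if isinstance(spec, tuple):  # explicit log10_pf
                pf[i] = max(0.0, float(spec[1]))
            else:
                pf[i] = max(0.0, math.log10(site.k_int / class_rate(spec)))
        log10_pf[c] = pf

    ex1 = [
        Ex1Region(r["chain"], r["start"], r["end"], r["k_open"])
        for r in template.get("ex1_regions", [])
    ]
    return GroundTruthState(
        state_id=state_id or "state", chains=chains, log10_pf=log10_pf,
        ex1_regions=ex1, seed=seed,
    )


def generate_digest(
    chains: dict[str, str],
    mean_len: float = 10.0,
    len_sd: float = 3.0,
    target_redundancy: float = 3.0,
    seed: int = 0,
) -> PeptidePool:
    """Random overlapping peptide pool emulating a peptic digest.

    Every residue is covered by at least one peptide whenever
    ``target_redundancy >= 1``.  Deterministic given ``seed``.
    """
    import logging

    if mean_len < 4:
        raise ValueError("mean_len must be >= 4")
    rng = np.random.default_rng(seed)
    peptides: list[tuple[str, int, int]] = []
    for chain in sorted(chains):
        L = len(chains[chain])
        if L < mean_len:
            logging.getLogger(__name__).warning(
                "chain %s shorter than mean peptide length; emitting one full-length peptide",
                chain,
            )
            peptides.append((chain, 1, L))
            continue
        n_pep = max(1, math.ceil(target_redundancy * L / mean_len))
        for _ in range(n_pep):
            ln = int(round(rng.normal(mean_len, len_sd)))
            ln = max(4, min(ln, L))
            start = int(rng.integers(1, L - ln + 2))
            peptides.append((chain, start, start + ln - 1))
        if target_redundancy >= 1:
            cov = np.zeros(L, dtype=int)
            for c, s, e in peptides:
                if c == chain:
                    cov[s - 1 : e] += 1
            for pos in np.nonzero(cov == 0)[0]:
                s = max(1, min(int(pos) + 1 - int(mean_len) // 2, L - int(mean_len) + 1))
                e = min(L, s + int(mean_len) - 1)
                peptides.append((chain, s, e))
                cov[s - 1 : e] += 1

    peptides = sorted(set(peptides))
    out = []
    for i, (chain, s, e) in enumerate(peptides):
        seq = chains[chain][s - 1 : e]
        z = max(1, int(round(len(seq) / 7)))
        charges = (z,) if rng.random() < 0.5 else tuple(sorted({z, z + 1}))
        out.append(Peptide(f"p{i:04d}", chain, s, e, seq, charges))
    return PeptidePool(out)


# ---------------------------------------------------------------------------
# envelope simulation

def _site_probs(
    peptide: Peptide,
    kinetics: list[SiteKinetics],
    t: float,
    cond: ExchangeConditions,
    backexchange: float,
) -> tuple[np.ndarray, np.ndarray]:
    """(global positions, deuteration probabilities) of the peptide's
    measurable sites: peptide-relative position >= 3, non-proline."""
    pos, probs = [], []
    for rel in range(3, peptide.end - peptide.start + 2):
        gpos = peptide.start + rel - 1
        site = kinetics[gpos - 1]
        if site.residue == "P" or not site.measurable:
            continue
        f = cond.d2o_fraction * -math.expm1(-site.k_obs * t)
        pos.append(gpos)
        probs.append(f * (1.0 - backexchange))
    return np.array(pos, dtype=int), np.array(probs, dtype=float)


def simulate_envelope(
    peptide: Peptide,
    charge: int,
    state: GroundTruthState,
    t: object,
    cond: ExchangeConditions,
    backexchange_fraction: float = 0.0,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    intensity_floor: float = 0.0,
    _kinetics_cache: dict | None = None,
) -> IsotopicEnvelope:
    """Stick spectrum of one peptide x charge x time.

    ``t`` is seconds, or the sentinels ``"undeut"`` / ``"FD"``.  EX1 segments
    overlapping the peptide yield a two-component mixture (closed/open
    populations); otherwise deuteration is independent per-site Bernoulli.
    """
    if not (0.0 <= backexchange_fraction < 1.0):
        raise ValueError("backexchange_fraction must be in [0, 1)")
    if peptide.chain not in state.chains:
        raise ValueError(f"peptide chain {peptide.chain} not in state {state.state_id}")
    if state.chains[peptide.chain][peptide.start - 1 : peptide.end] != peptide.sequence:
        raise ValueError(f"peptide {peptide.peptide_id} does not match state chain")

    cache = _kinetics_cache if _kinetics_cache is not None else {}
    key = (state.state_id, peptide.chain)
    if key not in cache:
        cache[key] = state.site_kinetics(peptide.chain, cond)
    kinetics = cache[key]

    nat_m, nat_p = natural_envelope(peptide.sequence)
    b = backexchange_fraction

    if t == "undeut":
        masses, inten = nat_m, nat_p.copy()
    else:
        if t == "FD":
            pos, probs = _site_probs(peptide, kinetics, math.inf, cond, b)
            probs[:] = cond.d2o_fraction * (1.0 - b)
            components = [(1.0, probs)]
        else:
            tf = float(t)
            if tf < 0:
                raise ValueError("time must be non-negative")
            pos, probs = _site_probs(peptide, kinetics, tf, cond, b)
            components = [(1.0, probs)]
            for reg in state.ex1_regions:
                if reg.chain != peptide.chain or reg.end < peptide.start or reg.start > peptide.end:
                    continue
                w_open = -math.expm1(-reg.k_open * tf)
                in_seg = (pos >= reg.start) & (pos <= reg.end)
                if not in_seg.any() or w_open <= 0:
                    continue
                open_probs = probs.copy()
                open_probs[in_seg] = cond.d2o_fraction * (1.0 - b)
                components = [(1.0 - w_open, probs), (w_open, open_probs)]
        sticks = []
        for w, p in components:
            dm, di = deuterated_sticks(nat_m, nat_p, poisson_binomial(p))
            sticks.append((dm, w * di))
        masses = np.concatenate([s[0] for s in sticks])
        inten = np.concatenate([s[1] for s in sticks])
        order = np.argsort(masses, kind="stable")
        masses, inten = masses[order], inten[order]
        if len(masses) > 1:
            grp = np.concatenate([[0], np.cumsum(np.diff(masses) > 1e-9)])
            ni = np.zeros(grp[-1] + 1)
            nm = np.zeros(grp[-1] + 1)
            np.add.at(ni, grp, inten)
            np.add.at(nm, grp, inten * masses)
            keep = ni > 0
            masses = (nm / np.maximum(ni, 1e-300))[keep]
            inten = ni[keep]

    if noise_sd > 0:
        if rng is None:
            raise ValueError("rng required when noise_sd > 0")
        inten = inten * rng.lognormal(mean=0.0, sigma=noise_sd, size=inten.shape)
    if intensity_floor > 0:
        keep = inten >= intensity_floor * inten.max()
        masses, inten = masses[keep], inten[keep]
    inten = inten / inten.max()

    return IsotopicEnvelope(
        peptide_id=peptide.peptide_id,
        chain=peptide.chain,
        start=peptide.start,
        end=peptide.end,
        sequence=peptide.sequence,
        charge=charge,
        time_s=t,
        mz=to_mz(masses, charge),
        intensity=inten,
        state_id=state.state_id,
    )


@dataclass
class SimulatedDataset:
    states: list[GroundTruthState]
    pool: PeptidePool
    conditions: ExchangeConditions
    time_grid: tuple[float, ...]
    envelopes: list[IsotopicEnvelope]
    true_backexchange: dict[tuple[str, str], float]  # (state_id, peptide_id) -> b
    seed: int
    manifest: dict = field(default_factory=dict)

    def to_frame(self):
        from .tables import envelopes_to_frame

        return envelopes_to_frame(self.envelopes)


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float
) -> float:
    if sd == 0:
        return float(min(max(mean, lo), hi))
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(min(max(mean, lo), hi))


def simulate_dataset(
    states: GroundTruthState | list[GroundTruthState],
    pool: PeptidePool,
    cond: ExchangeConditions | None = None,
    time_grid: tuple[float, ...] = (1e1, 1e2, 1e3, 1e4, 1e5),
    backexchange_mean: float = 0.18,
    backexchange_sd: float = 0.05,
    backexchange_bounds: tuple[float, float] = (0.0, 0.5),
    noise_sd: float = 0.02,
    intensity_floor: float = 1e-3,
    seed: int = 0,
    dataset_id: str = "sim",
) -> SimulatedDataset:
    """Full time-course envelope dataset for one or more states.

    Per-peptide back-exchange is drawn once per (state, peptide) from a
    truncated normal and applied identically at every time point (and to the
    FD reference), matching the single-number FD normalization downstream.
    """
    if isinstance(states, GroundTruthState):
        states = [states]
    cond = cond or ExchangeConditions()
    for st in states:
        shared = PeptidePool([p for p in pool if p.chain in st.chains])
        shared.validate_against(st.chains)
    rng = np.random.default_rng(seed)

    true_b: dict[tuple[str, str], float] = {}
    for st in states:
        for p in pool:
            if p.chain not in st.chains:
                continue
            true_b[(st.state_id, p.peptide_id)] = _truncated_normal(
                rng, backexchange_mean, backexchange_sd, *backexchange_bounds
            )

    cache: dict = {}
    envelopes: list[IsotopicEnvelope] = []
    labels: list[object] = ["undeut", *time_grid, "FD"]
    for st in states:
        for p in pool:
            if p.chain not in st.chains:
                continue
            b = true_b[(st.state_id, p.peptide_id)]
            for z in p.charge_states:
                for t in labels:
                    env = simulate_envelope(
                        p, z, st, t, cond,
                        backexchange_fraction=b,
                        noise_sd=0.0 if t == "undeut" else noise_sd,
                        rng=rng,
                        intensity_floor=intensity_floor,
                        _kinetics_cache=cache,
                    )
                    env.dataset_id = dataset_id
                    envelopes.append(env)

    manifest = {
        "dataset_id": dataset_id,
        "seed": seed,
        "states": [st.state_id for st in states],
        "time_grid": list(time_grid),
        "conditions": {
            "pD": cond.pD,
            "temperature_K": cond.temperature_K,
            "d2o_fraction": cond.d2o_fraction,
        },
        "backexchange": {
            "mean": backexchange_mean,
            "sd": backexchange_sd,
            "bounds": list(backexchange_bounds),
        },
        "noise_sd": noise_sd,
        "intensity_floor": intensity_floor,
        "n_peptides": len(pool),
    }
    return SimulatedDataset(
        states=states,
        pool=pool,
        conditions=cond,
        time_grid=tuple(time_grid),
        envelopes=envelopes,
        true_backexchange=true_b,
        seed=seed,
        manifest=manifest,
    )
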