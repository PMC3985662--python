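"""Intrinsic backbone-amide exchange rates and single-site exchange kinetics.

Amide hydrogens exchange with solvent deuterium through acid-, base- and
water-catalyzed pathways.  In an unstructured chain the rate of each amide
(the *intrinsic* rate ``k_int``) is set by the side chains flanking it, the
solution pD and the temperature.  Structure slows exchange by a *protection
factor* ``P`` so that the observed rate is ``k_obs = k_int / P``.

The parameterization follows the standard poly-DL-alanine reference
calibration: base rates for the three catalytic terms at 293.15 K, additive
log10 nearest-neighbor side-chain factors (packaged in
``data/exchange_factors.csv``), N-/C-terminal corrections, and Arrhenius
temperature scaling with activation energies of 14, 17 and 19 kcal/mol for
the acid, base and water terms respectively.  Acid/base factors for Asp, Glu
and His are blended across their (heavy-water) pKa by
Henderson-Hasselbalch weighting.
"""

from __future__ import annotations

import csv
import enum
import math
import statistics
from dataclasses import dataclass, field
from importlib import resources

__all__ = [
    "Direction",
    "ExchangeConditions",
    "SiteKinetics",
    "intrinsic_rates",
    "intrinsic_rate_terms",
    "site_uptake_fraction",
    "quench_factor",
    "d2o_after_mixing",
]

# poly-DL-alanine reference rates, log10, per minute (acid/base per M per
# minute), 293.15 K, H->D exchange in D2O
LOG_KA_REF = 1.62
LOG_KB_REF = 10.05
LOG_KW_REF = -1.50
T_REF_K = 293.15
PKD_D2O = 15.05

# activation energies, kcal/mol
EA_ACID = 14.0
EA_BASE = 17.0
EA_WATER = 19.0
R_KCAL = 1.9872041e-3  # kcal/(mol K)

# side-chain pKa values in D2O used for titratable-factor blending
PKA_D2O = {"D": 4.48, "E": 4.93, "H": 7.42}

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")


class Direction(enum.Enum):
    H_TO_D = "H_to_D"
    D_TO_H = "D_to_H"


@dataclass(frozen=True)
class ExchangeConditions:
    """Solution conditions of an exchange reaction.

    ``pD`` is the pH-meter-style reading; an optional glass-electrode
    correction (+0.4) is applied upstream in the run configuration, never
    here.  ``d2o_fraction`` is the mole fraction of D2O and sets the
    exchange plateau.
    """

    pD: float = 7.0
    temperature_K: float = 273.15
    d2o_fraction: float = 0.75
    direction: Direction = Direction.H_TO_D

    def __post_init__(self) -> None:
        if not (0.0 <= self.d2o_fraction <= 1.0):
            raise ValueError(f"d2o_fraction must be in [0, 1], got {self.d2o_fraction}")
        if self.temperature_K <= 0:
            raise ValueError("temperature must be positive (kelvin)")
        if not (0.0 <= self.pD <= 14.0):
            raise ValueError(f"pD must be in [0, 14], got {self.pD}")


@dataclass
class SiteKinetics:
    """Exchange kinetics of one backbone amide.

    ``protection_factor`` is stored as log10; ``k_obs = k_int / P``.
    Positions 1-2 of a chain and prolines carry no measurable amide signal.
    """

    residue_index: int  # 1-based
    residue: str
    k_int: float  # s^-1; nan when not measurable
    log10_protection_factor: float = 0.0
    measurable: bool = True

    def __post_init__(self) -> None:
        if self.log10_protection_factor < 0:
            raise ValueError("protection factor must be >= 1 (log10 >= 0)")

    @property
    def protection_factor(self) -> float:
        return 10.0 ** self.log10_protection_factor

    @property
    def k_obs(self) -> float:
        if not self.measurable:
            return 0.0
        return self.k_int / self.protection_factor


def _load_factor_table() -> dict[str, tuple[float, float, float, float]]:
    table: dict[str, tuple[float, float, float, float]] = {}
    src = resources.files("hdxpipe.data").joinpath("exchange_factors.csv")
    with src.open() as fh:
        for row in csv.DictReader(fh):
            table[row["residue"]] = (
                float(row["acid_lambda"]),
                float(row["acid_rho"]),
                float(row["base_lambda"]),
                float(row["base_rho"]),
            )
    return table


_FACTORS = _load_factor_table()


def _blend(f_prot: float, f_deprot: float, pD: float, pKa: float) -> float:
    """log10 of the population-weighted linear factor of a titratable group."""
    h = 10.0 ** (-pD)
    ka = 10.0 ** (-pKa)
    return math.log10((10.0 ** f_prot * h + 10.0 ** f_deprot * ka) / (h + ka))


def _residue_factors(res: str, pD: float) -> tuple[float, float, float, float]:
    if res in ("D", "E"):
        prot = _FACTORS[f"{res}_prot"]
        deprot = _FACTORS[f"{res}_deprot"]
        pka = PKA_D2O[res]
        return tuple(_blend(p, d, pD, pka) for p, d in zip(prot, deprot))  # type: ignore[return-value]
    if res == "H":
        prot = _FACTORS["H_prot"]
        deprot = _FACTORS["H_neut"]
        return tuple(_blend(p, d, pD, PKA_D2O["H"]) for p, d in zip(prot, deprot))  # type: ignore[return-value]
    return _FACTORS[res]


def _arrhenius(ea_kcal: float, temperature_K: float) -> float:
    return math.exp(-ea_kcal / R_KCAL * (1.0 / temperature_K - 1.0 / T_REF_K))


def intrinsic_rate_terms(
    sequence: str, index: int, cond: ExchangeConditions
) -> tuple[float, float, float]:
    """Acid-, base- and water-catalyzed contributions (s^-1) to ``k_int``
    of the amide of ``sequence[index-1]`` (1-based ``index``).

    The amide of residue i is modulated by the side chain of residue i
    (lambda columns) and of residue i-1 (rho columns); the N-terminus adds a
    rho-type correction on residue 2 and the C-terminal residue a
    lambda-type correction on itself.
    """
    i = index - 1
    res = sequence[i]
    left = sequence[i - 1]
    la, _, lb, _ = _residue_factors(res, cond.pD)
    _, ra, _, rb = _residue_factors(left, cond.pD)
    log_fa = la + ra
    log_fb = lb + rb
    if index == 2:
        log_fa += _FACTORS["NT"][1]
        log_fb += _FACTORS["NT"][3]
    if index == len(sequence):
        log_fa += _FACTORS["CT"][0]
        log_fb += _FACTORS["CT"][2]

    # per-minute -> per-second, Arrhenius scaling per catalytic term
    acid = (
        10.0 ** (LOG_KA_REF + log_fa - cond.pD) / 60.0 * _arrhenius(EA_ACID, cond.temperature_K)
    )
    base = (
        10.0 ** (LOG_KB_REF + log_fb + cond.pD - PKD_D2O)
        / 60.0
        * _arrhenius(EA_BASE, cond.temperature_K)
    )
    water = 10.0 ** (LOG_KW_REF + log_fb) / 60.0 * _arrhenius(EA_WATER, cond.temperature_K)
    return acid, base, water


def _validate_sequence(sequence: str) -> None:
    if len(sequence) < 3:
        raise ValueError("sequence must have length >= 3")
    for pos, aa in enumerate(sequence, start=1):
        if aa not in STANDARD_AA:
            raise ValueError(f"unknown residue code {aa!r} at position {pos}")


def intrinsic_rates(sequence: str, cond: ExchangeConditions) -> list[SiteKinetics]:
    """Per-residue intrinsic exchange rates of an unstructured chain.

    Returns one :class:`SiteKinetics` per residue with protection factor 1.
    Residues 1-2 and prolines are flagged non-measurable (residue 1 has no
    peptide amide; residue 2 back-exchanges during workup; prolines lack an
    amide proton).
    """
    _validate_sequence(sequence)
    out: list[SiteKinetics] = []
    for idx, res in enumerate(sequence, start=1):
        if res == "P" or idx == 1:
            out.append(SiteKinetics(idx, res, float("nan"), 0.0, measurable=False))
            continue
        k = sum(intrinsic_rate_terms(sequence, idx, cond))
        out.append(SiteKinetics(idx, res, k, 0.0, measurable=(idx > 2)))
    return out


def site_uptake_fraction(k: SiteKinetics, t: float, cond: ExchangeConditions) -> float:
    """Deuterated fraction of one site after ``t`` seconds of labeling.

    First-order approach to the D2O-fraction plateau:
    ``f(t) = d2o_fraction * (1 - exp(-k_obs t))``; 0 for non-measurable
    sites.
    """
    if t < 0:
        raise ValueError("time must be non-negative")
    if not k.measurable:
        return 0.0
    return cond.d2o_fraction * -math.expm1(-k.k_obs * t)


def quench_factor(
    native: ExchangeConditions, quench: ExchangeConditions, sequence: str
) -> float:
    """Median fold-slowdown of intrinsic exchange on moving from native to
    quench conditions (low pD, typically ~2.3-2.5, on ice)."""
    nat = intrinsic_rates(sequence, native)
    qch = intrinsic_rates(sequence, quench)
    ratios = [n.k_int / q.k_int for n, q in zip(nat, qch) if n.measurable]
    if not ratios:
        raise ValueError("sequence has no measurable amides")
    return statistics.median(ratios)


def d2o_after_mixing(
    sample_ul: float, buffer_ul: float, buffer_d2o_fraction: float = 1.0
) -> float:
    """Final D2O fraction when an aqueous sample is diluted into
    deuterated labeling buffer (e.g. 5 ul sample + 15 ul D2O buffer -> 0.75)."""
    if sample_ul < 0 or buffer_ul <= 0:
        raise ValueError("volumes must be positive")
    return buffer_ul * buffer_d2o_fraction / (sample_ul + buffer_ul)
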