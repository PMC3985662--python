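"""Isotopic stick spectra: containers and exact envelope arithmetic.

An :class:`IsotopicEnvelope` is a stick spectrum (one peak per
isotopologue) for one peptide x charge x state x time.  Natural isotope
envelopes are computed from the peptide's exact elemental composition
(pyteomics composition and NIST isotope tables) by aggregated convolution
on a nominal-mass grid that tracks the exact mean mass of every bin, so
centroids are exact.  Deuteration is a Poisson-binomial over the measurable
sites and shifts mass by the deuterium-protium difference per incorporated
deuteron.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from pyteomics import mass as pmass

PROTON_MASS = 1.00727646688
#: deuterium minus protium mass, Da
DELTA_MASS_D = pmass.nist_mass["H"][2][0] - pmass.nist_mass["H"][1][0]

_PRUNE = 1e-10  # drop isotopologue bins below this total probability


@dataclass
class IsotopicEnvelope:
    """One stick spectrum with its identity keys.

    ``time_s`` is either a float (seconds) or one of the sentinels
    ``"undeut"`` / ``"FD"``.
    """

    peptide_id: str
    chain: str
    start: int
    end: int
    sequence: str
    charge: int
    time_s: object
    mz: np.ndarray
    intensity: np.ndarray
    state_id: str = ""
    dataset_id: str = ""

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if np.any(self.intensity < 0) or not np.any(self.intensity > 0):
            raise ValueError("intensities must be >= 0 with at least one > 0")
        if np.any(np.diff(self.mz) <= 0):
            raise ValueError("mz values must be strictly increasing")

    def normalized(self) -> "IsotopicEnvelope":
        return replace(self, intensity=self.intensity / self.intensity.max())


def peptide_composition(sequence: str) -> pmass.Composition:
    return pmass.Composition(sequence=sequence)


def monoisotopic_mass(sequence: str) -> float:
    return pmass.calculate_mass(sequence=sequence)


def _element_isotopes(element: str) -> tuple[np.ndarray, np.ndarray]:
    """(neutron offsets, abundances) and exact masses of an element's
    natural isotopes; returns (masses per offset, probabilities per offset)."""
    iso = pmass.nist_mass[element]
    base = min(k for k in iso if k != 0)
    offsets = sorted(k - base for k in iso if k != 0 and iso[k][1] > 0)
    masses = np.zeros(offsets[-1] + 1)
    probs = np.zeros(offsets[-1] + 1)
    for k, (m, ab) in iso.items():
        if k == 0 or ab <= 0:
            continue
        probs[k - base] = ab
        masses[k - base] = m
    return masses, probs


def _convolve_tracked(
    p1: np.ndarray, m1: np.ndarray, p2: np.ndarray, m2: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Convolve two (probability, probability-weighted-mass) distributions."""
    p = np.convolve(p1, p2)
    mw = np.convolve(m1, p2) + np.convolve(p1, m2)
    return p, mw


def _atom_power(
    p: np.ndarray, mw: np.ndarray, n: int
) -> tuple[np.ndarray, np.ndarray]:
    """n-fold self-convolution by binary exponentiation."""
    rp, rmw = np.array([1.0]), np.array([0.0])
    bp, bmw = p, mw
    while n:
        if n & 1:
            rp, rmw = _convolve_tracked(rp, rmw, bp, bmw)
        n >>= 1
        if n:
            bp, bmw = _convolve_tracked(bp, bmw, bp, bmw)
    keep = rp > _PRUNE
    last = np.nonzero(keep)[0].max() + 1
    return rp[:last], rmw[:last]


def natural_envelope(sequence: str) -> tuple[np.ndarray, np.ndarray]:
    """Aggregated natural isotope distribution of the neutral peptide.

    Returns (masses, probabilities): one entry per nominal isotopologue bin,
    mass = exact probability-weighted mean mass of the bin, probabilities
    summing to ~1.
    """
    comp = peptide_composition(sequence)
    p, mw = np.array([1.0]), np.array([0.0])
    for element, count in comp.items():
        im, ip = _element_isotopes(element)
        # offset masses relative to the lightest isotope; add the base mass
        # exactly via the mass-weight channel
        base_mass = im[0]
        rel_mw = (im - base_mass) * ip
        ap, amw = _atom_power(ip, rel_mw, count)
        amw = amw + ap * base_mass * count
        p, mw = _convolve_tracked(p, mw, ap, amw)
        keep = p > _PRUNE
        last = np.nonzero(keep)[0].max() + 1
        p, mw = p[:last], mw[:last]
    with np.errstate(invalid="ignore", divide="ignore"):
        masses = np.where(p > 0, mw / np.maximum(p, 1e-300), 0.0)
    sel = p > _PRUNE
    return masses[sel], p[sel] / p[sel].sum()


def poisson_binomial(ps: np.ndarray) -> np.ndarray:
    """Distribution of the number of successes of independent Bernoulli
    trials with probabilities ``ps``."""
    dist = np.array([1.0])
    for p in np.asarray(ps, dtype=float):
        dist = np.convolve(dist, [1.0 - p, p])
    return dist


def deuterated_sticks(
    nat_masses: np.ndarray,
    nat_probs: np.ndarray,
    d_probs: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Cross natural isotopologues with a deuteron-count distribution.

    Peak masses are ``m_nat + d * DELTA_MASS_D`` so the centroid shift over
    the natural envelope is exactly ``E[d] * DELTA_MASS_D``.
    """
    masses = (nat_masses[:, None] + np.arange(len(d_probs))[None, :] * DELTA_MASS_D).ravel()
    inten = (nat_probs[:, None] * d_probs[None, :]).ravel()
    order = np.argsort(masses, kind="stable")
    masses, inten = masses[order], inten[order]
    # merge numerically coincident sticks
    if len(masses) > 1:
        grp = np.concatenate([[0], np.cumsum(np.diff(masses) > 1e-9)])
        nm = np.zeros(grp[-1] + 1)
        ni = np.zeros(grp[-1] + 1)
        np.add.at(ni, grp, inten)
        np.add.at(nm, grp, inten * masses)
        with np.errstate(invalid="ignore"):
            nm = np.where(ni > 0, nm / np.maximum(ni, 1e-300), 0.0)
        keep = ni > 0
        masses, inten = nm[keep], ni[keep]
    return masses, inten


def to_mz(masses: np.ndarray, charge: int) -> np.ndarray:
    """(M + z * m_proton) / z convention."""
    return (np.asarray(masses, dtype=float) + charge * PROTON_MASS) / charge
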