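"""From isotopic envelopes to corrected deuterium uptake.

Centroids, mass shifts against the undeuterated reference, normalization to
the fully-deuterated (FD) reference ("percent exchange"), deuteron counts,
dataset back-exchange estimation, bimodal (EX1) detection by one- vs
two-component mixture fitting, and charge-state merging.

Conventions
-----------
* percent exchange = 100 x shift(t) / shift(FD); by construction the FD
  point is 100% and back-exchange cancels.
* "number of deuterons" = percent/100 x measurable_amides x d2o_fraction:
  the D2O plateau is left in the reported numbers (the measurable maximum
  is ``measurable_amides x d2o_fraction``), unless ``plateau_corrected``
  is set.
* Negative mass shifts (noise) are retained in tables, never clamped here.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import lmfit

from .chemistry import ExchangeConditions
from .spectra import DELTA_MASS_D, IsotopicEnvelope, PROTON_MASS

__all__ = [
    "EnvelopeFit",
    "UptakePoint",
    "centroid",
    "measurable_amides",
    "mass_shift",
    "percent_exchange",
    "deuterons_corrected",
    "estimate_backexchange",
    "detect_bimodal",
    "mixture_average_shift",
    "merge_charge_states",
    "analyze_envelopes",
]

logger = logging.getLogger(__name__)

#: average stick spacing (Da) used to bin envelopes on an integer grid;
#: between the 13C spacing (1.00336) and the H->D shift (1.00628)
NOMINAL_SPACING = 1.0045


def centroid(env: IsotopicEnvelope) -> float:
    """Intensity-weighted mean m/z of an envelope."""
    total = env.intensity.sum()
    if total <= 0:
        raise ValueError("all-zero intensities")
    return float(np.dot(env.mz, env.intensity) / total)


def measurable_amides(sequence: str) -> int:
    """Backbone amides with observable exchange: length minus the first two
    residues minus prolines at positions >= 3."""
    if len(sequence) < 3:
        raise ValueError("sequence must have length >= 3")
    return len(sequence) - 2 - sequence[2:].count("P")


def _check_same_species(a: IsotopicEnvelope, b: IsotopicEnvelope) -> None:
    if (a.peptide_id, a.charge) != (b.peptide_id, b.charge):
        raise ValueError(
            f"envelope key mismatch: {(a.peptide_id, a.charge)} vs {(b.peptide_id, b.charge)}"
        )


def mass_shift(env_t: IsotopicEnvelope, env_undeut: IsotopicEnvelope, charge: int | None = None) -> float:
    """Deuteration-induced mass shift in Da: (centroid difference) x charge."""
    _check_same_species(env_t, env_undeut)
    z = charge if charge is not None else env_t.charge
    return (centroid(env_t) - centroid(env_undeut)) * z


def percent_exchange(shift_t: float, shift_fd: float, epsilon: float = 1e-9) -> float:
    """Exchange level normalized to the FD reference, in percent."""
    if shift_fd <= epsilon:
        raise ValueError("FD mass shift is not positive; peptide unusable")
    return 100.0 * shift_t / shift_fd


def deuterons_corrected(
    percent: float,
    sequence: str,
    cond: ExchangeConditions,
    plateau_corrected: bool = False,
) -> float:
    """Back-exchange-corrected deuteron count for a peptide.

    Default convention leaves the D2O plateau in the number, so the maximum
    measurable is ``measurable_amides x d2o_fraction``; with
    ``plateau_corrected`` the count is rescaled to the full amide count.
    """
    n = measurable_amides(sequence)
    scale = 1.0 if plateau_corrected else cond.d2o_fraction
    return percent / 100.0 * n * scale


def estimate_backexchange(
    shift_fd: float, sequence: str, cond: ExchangeConditions
) -> float:
    """Per-peptide back-exchange fraction from the FD reference shift:
    ``1 - shift_FD / (N x f_D2O x dm_D)``.  Negative estimates (noise) are
    clipped to 0 with a warning."""
    n = measurable_amides(sequence)
    theo = n * cond.d2o_fraction * DELTA_MASS_D
    est = 1.0 - shift_fd / theo
    if est < 0:
        logger.warning("negative back-exchange estimate %.4f clipped to 0", est)
        return 0.0
    return float(est)


def dataset_backexchange(
    envelopes: list[IsotopicEnvelope], cond: ExchangeConditions
) -> pd.DataFrame:
    """Per-peptide back-exchange estimates from the FD references of an
    envelope list; the dataset summary is the unweighted mean over peptides
    (one row per state x peptide x charge, averaged over charge)."""
    groups: dict[tuple, dict] = {}
    for env in envelopes:
        if str(env.time_s) in ("undeut", "FD"):
            groups.setdefault((env.state_id, env.peptide_id, env.charge), {})[
                str(env.time_s)
            ] = env
    rows = []
    for (state, pid, z), envs in sorted(groups.items()):
        if "undeut" not in envs or "FD" not in envs:
            continue
        shift_fd = mass_shift(envs["FD"], envs["undeut"])
        rows.append(
            {
                "state_id": state,
                "peptide_id": pid,
                "charge": z,
                "backexchange": estimate_backexchange(
                    shift_fd, envs["FD"].sequence, cond
                ),
            }
        )
    df = pd.DataFrame(rows)
    if not df.empty:
        df = (
            df.groupby(["state_id", "peptide_id"], as_index=False)["backexchange"]
            .mean()
        )
    return df


# ---------------------------------------------------------------------------
# bimodal detection


@dataclass
class EnvelopeFit:
    """Result of unimodal-vs-bimodal envelope model selection.

    ``components`` holds ``(weight, centroid_mz, width_mz)``; weights sum
    to 1.  ``aic_delta`` is AIC(unimodal) - AIC(bimodal): positive values
    favor the two-component model.
    """

    modality: str  # "unimodal" | "bimodal"
    components: list[tuple[float, float, float]]
    residual_norm: float
    aic_delta: float
    converged: bool = True

    def __post_init__(self) -> None:
        w = sum(c[0] for c in self.components)
        if abs(w - 1.0) > 1e-6:
            raise ValueError("component weights must sum to 1")
        if self.modality == "bimodal" and len(self.components) != 2:
            raise ValueError("bimodal fit must have two components")


def _bin_envelope(env: IsotopicEnvelope, mz0: float, charge: int, n_bins: int) -> np.ndarray:
    """Sum stick intensities onto an integer isotopologue grid anchored at
    ``mz0`` (the undeuterated base peak)."""
    idx = np.rint((env.mz - mz0) * charge / NOMINAL_SPACING).astype(int)
    out = np.zeros(n_bins)
    ok = (idx >= 0) & (idx < n_bins)
    np.add.at(out, idx[ok], env.intensity[ok])
    return out


def _binomial_pmf(n: int, p: float) -> np.ndarray:
    k = np.arange(n + 1)
    from scipy.stats import binom

    return binom.pmf(k, n, p)


def _mixture_model(
    nat: np.ndarray, n_sites: int, n_bins: int, params: list[tuple[float, float]]
) -> np.ndarray:
    """Natural envelope convolved with binomial uptake components."""
    out = np.zeros(n_bins)
    for w, p in params:
        conv = np.convolve(nat, _binomial_pmf(n_sites, p))[:n_bins]
        out[: len(conv)] += w * conv
    s = out.sum()
    return out / s if s > 0 else out


def detect_bimodal(
    env_t: IsotopicEnvelope,
    env_undeut: IsotopicEnvelope,
    sequence: str,
    cond: ExchangeConditions,
    aic_delta_threshold: float = 10.0,
    min_separation_da: float = 1.5,
    min_weight: float = 0.05,
) -> EnvelopeFit:
    """Classify an envelope as unimodal (EX2) or bimodal (EX1).

    Both models convolve the observed undeuterated envelope with binomial
    uptake over the measurable amides (one free mean, or two means plus a
    weight; widths tied through the shared binomial spread).  The
    two-component model is selected only when the AIC improves by more than
    ``aic_delta_threshold`` AND the component centroid separation is at
    least ``min_separation_da`` AND the minor weight is at least
    ``min_weight`` — ties break toward unimodal.
    """
    _check_same_species(env_t, env_undeut)
    z = env_t.charge
    n_sites = measurable_amides(sequence)
    n_nat = int(np.rint((env_undeut.mz[-1] - env_undeut.mz[0]) * z / NOMINAL_SPACING)) + 1
    n_bins = n_nat + n_sites + 3

    nat = _bin_envelope(env_undeut, env_undeut.mz[0], z, n_nat)
    nat = nat / nat.sum()
    obs = _bin_envelope(env_t, env_undeut.mz[0], z, n_bins)
    obs_sum = obs.sum()
    if obs_sum <= 0:
        raise ValueError("empty deuterated envelope")
    obs = obs / obs_sum

    nat_centroid_idx = float(np.dot(np.arange(n_nat), nat))
    obs_centroid_idx = float(np.dot(np.arange(n_bins), obs))
    p_init = min(max((obs_centroid_idx - nat_centroid_idx) / max(n_sites, 1), 0.01), 0.99)

    def resid_uni(params):
        model = _mixture_model(nat, n_sites, n_bins, [(1.0, params["p"].value)])
        return model - obs

    uni = lmfit.Parameters()
    uni.add("p", value=p_init, min=0.0, max=1.0)
    fit_uni = lmfit.minimize(resid_uni, uni, method="leastsq")

    def resid_bi(params):
        w = params["w"].value
        model = _mixture_model(
            nat, n_sites, n_bins,
            [(1.0 - w, params["p1"].value), (w, params["p2"].value)],
        )
        return model - obs

    bi = lmfit.Parameters()
    bi.add("p1", value=max(p_init - 0.25, 0.01), min=0.0, max=1.0)
    bi.add("p2", value=min(p_init + 0.25, 0.99), min=0.0, max=1.0)
    bi.add("w", value=0.5, min=0.0, max=1.0)
    fit_bi = lmfit.minimize(resid_bi, bi, method="leastsq")

    def component(weight: float, p: float) -> tuple[float, float, float]:
        cen = centroid(env_undeut) + n_sites * p * DELTA_MASS_D / z
        width = math.sqrt(max(n_sites * p * (1.0 - p), 0.0)) * DELTA_MASS_D / z
        return (weight, cen, width)

    uni_fit = EnvelopeFit(
        modality="unimodal",
        components=[component(1.0, fit_uni.params["p"].value)],
        residual_norm=float(np.linalg.norm(fit_uni.residual)),
        aic_delta=0.0,
        converged=bool(fit_uni.success),
    )
    if not (fit_uni.success and fit_bi.success):
        uni_fit.converged = False
        return uni_fit

    aic_delta = float(fit_uni.aic - fit_bi.aic)
    p1, p2 = fit_bi.params["p1"].value, fit_bi.params["p2"].value
    w2 = fit_bi.params["w"].value
    if p1 > p2:  # canonical order: lighter component first
        p1, p2, w2 = p2, p1, 1.0 - w2
    separation = (p2 - p1) * n_sites * DELTA_MASS_D
    minor = min(w2, 1.0 - w2)

    if (
        aic_delta > aic_delta_threshold
        and separation >= min_separation_da
        and minor >= min_weight
    ):
        return EnvelopeFit(
            modality="bimodal",
            components=[component(1.0 - w2, p1), component(w2, p2)],
            residual_norm=float(np.linalg.norm(fit_bi.residual)),
            aic_delta=aic_delta,
        )
    uni_fit.aic_delta = aic_delta
    return uni_fit


def mixture_average_shift(
    fit: EnvelopeFit, env_undeut: IsotopicEnvelope, charge: int
) -> float:
    """Weight-averaged component centroid minus the undeuterated centroid,
    in Da — the "average centroid over the relative intensities" of the open
    and closed populations; identical to :func:`mass_shift` for unimodal
    fits on the same envelope."""
    avg = sum(w * c for w, c, _ in fit.components)
    return (avg - centroid(env_undeut)) * charge


# ---------------------------------------------------------------------------
# uptake points and charge merging


@dataclass
class UptakePoint:
    peptide_id: str
    chain: str
    start: int
    end: int
    sequence: str
    time_s: object
    mass_shift_da: float
    percent: float
    deuterons: float
    modality: str = "unimodal"
    charge: int | None = None  # None after charge merging
    total_intensity: float = 1.0
    qc_flags: list[str] = field(default_factory=list)


def merge_charge_states(points: list[UptakePoint], tolerance: float = 10.0) -> UptakePoint:
    """Total-intensity-weighted mean over charge states of one peptide/time.

    Dispersion beyond ``tolerance`` percentage points is flagged, not
    dropped.
    """
    if not points:
        raise ValueError("no points to merge")
    keys = {(p.peptide_id, str(p.time_s)) for p in points}
    if len(keys) > 1:
        raise ValueError(f"cannot merge across peptides/times: {sorted(keys)}")
    w = np.array([p.total_intensity for p in points], dtype=float)
    w = w / w.sum()
    pct = np.array([p.percent for p in points])
    merged_pct = float(np.dot(w, pct))
    spread = float(pct.max() - pct.min())
    flags = sorted({f for p in points for f in p.qc_flags})
    if spread > tolerance:
        flags.append("charge_disagreement")
    p0 = points[0]
    scale = merged_pct / p0.percent if p0.percent != 0 else 0.0
    return UptakePoint(
        peptide_id=p0.peptide_id,
        chain=p0.chain,
        start=p0.start,
        end=p0.end,
        sequence=p0.sequence,
        time_s=p0.time_s,
        mass_shift_da=float(np.dot(w, [p.mass_shift_da for p in points])),
        percent=merged_pct,
        deuterons=float(np.dot(w, [p.deuterons for p in points])),
        modality="bimodal" if any(p.modality == "bimodal" for p in points) else "unimodal",
        charge=None,
        total_intensity=float(sum(p.total_intensity for p in points)),
        qc_flags=flags,
    )


def analyze_envelopes(
    envelopes: list[IsotopicEnvelope],
    cond: ExchangeConditions,
    detect_ex1: bool = True,
    plateau_corrected: bool = False,
    aic_delta_threshold: float = 10.0,
    min_separation_da: float = 1.5,
    min_weight: float = 0.05,
    charge_merge_tolerance: float = 10.0,
) -> pd.DataFrame:
    """Envelope list -> charge-merged uptake table.

    Groups by (state, peptide, charge); requires an ``undeut`` and an ``FD``
    envelope per group; emits one row per (state, peptide, time) after
    charge merging, with columns percent_exchange, deuterons, modality and
    qc_flags.
    """
    groups: dict[tuple, dict] = {}
    for env in envelopes:
        key = (env.state_id, env.peptide_id, env.charge)
        groups.setdefault(key, {})[str(env.time_s)] = env

    per_time: dict[tuple, list[UptakePoint]] = {}
    for (state, pid, z), envs in sorted(groups.items()):
        if "undeut" not in envs or "FD" not in envs:
            logger.warning("peptide %s charge %d: missing undeut/FD reference", pid, z)
            continue
        und, fd = envs["undeut"], envs["FD"]
        shift_fd = mass_shift(fd, und)
        try:
            percent_exchange(0.0, shift_fd)
        except ValueError:
            logger.warning("peptide %s: unusable FD shift %.3g", pid, shift_fd)
            continue
        for label, env in envs.items():
            if label in ("undeut", "FD"):
                continue
            modality = "unimodal"
            if detect_ex1:
                fit = detect_bimodal(
                    env, und, env.sequence, cond,
                    aic_delta_threshold=aic_delta_threshold,
                    min_separation_da=min_separation_da,
                    min_weight=min_weight,
                )
                modality = fit.modality
                shift = mixture_average_shift(fit, und, z)
            else:
                shift = mass_shift(env, und)
            pct = percent_exchange(shift, shift_fd)
            point = UptakePoint(
                peptide_id=pid,
                chain=env.chain,
                start=env.start,
                end=env.end,
                sequence=env.sequence,
                time_s=float(label),
                mass_shift_da=shift,
                percent=pct,
                deuterons=deuterons_corrected(pct, env.sequence, cond, plateau_corrected),
                modality=modality,
                charge=z,
                total_intensity=float(env.intensity.sum()),
            )
            per_time.setdefault((state, pid, float(label)), []).append(point)

    rows = []
    for (state, pid, t), pts in sorted(per_time.items()):
        m = merge_charge_states(pts, tolerance=charge_merge_tolerance)
        rows.append(
            {
                "state_id": state,
                "peptide_id": pid,
                "chain": m.chain,
                "start": m.start,
                "end": m.end,
                "sequence": m.sequence,
                "time_s": t,
                "percent_exchange": m.percent,
                "deuterons": m.deuterons,
                "mass_shift_da": m.mass_shift_da,
                "modality": m.modality,
                "n_charge_states": len(pts),
                "qc_flags": ";".join(m.qc_flags),
            }
        )
    return pd.DataFrame(rows)
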