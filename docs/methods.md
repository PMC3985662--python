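# Methods

## Exchange chemistry

Backbone amide exchange is modeled as the sum of acid-, base- and
water-catalyzed pathways referenced to poly-DL-alanine:

```
k_int(i) = k_A · 10^(−pD) · F_A(i)  +  k_B · 10^(pD − pK_D) · F_B(i)  +  k_W · F_B(i)
```

with `log10 k_A = 1.62`, `log10 k_B = 10.05`, `log10 k_W = −1.50`
(per M per minute / per minute, 293.15 K, H→D exchange in D₂O) and
`pK_D = 15.05`. The neighbor factors `F_A`, `F_B` multiply the log-additive
side-chain contributions of residue *i* (its own amide) and residue *i−1*
(left neighbor), from the packaged table
`hdxpipe/data/exchange_factors.csv`; the N-terminus adds a correction to
residue 2's amide and the C-terminal residue to its own. Asp, Glu and His
factors are blended between their protonated and deprotonated rows by
Henderson–Hasselbalch weighting at D₂O pKa values 4.48 / 4.93 / 7.42.
Temperature enters through per-term Arrhenius factors with activation
energies 14 (acid), 17 (base) and 19 (water) kcal·mol⁻¹; `pK_D` is held at
its 20 °C value, i.e. the ionization enthalpy is folded into the base-term
activation energy. Between 25 °C and 0 °C the base term — dominant at
pD 7 — falls 13.8-fold, which is why on-ice labeling stretches the usable
time course.

`pD` is used as given; a `pD_correction` config key (default 0, set 0.4 for
the electrode-corrected convention) is applied when conditions are built
from a run config, never inside the chemistry.

One consequence worth knowing: at a pD ≈ 2.3 quench on ice, the median
intrinsic rate drops by a factor of a few hundred relative to pD 7 (the
acid pathway, with its lower activation energy, already dominates at
pD 2.3). The slowdown exceeds 10³ only nearer the rate minimum (pD ≈ 3.3)
or at warmer temperature; the package reports the computed ratio rather
than a canonical constant.

Site kinetics are strictly first-order toward the D₂O-fraction plateau:
`f_i(t) = f_D2O · (1 − e^{−k_obs,i t})`, `k_obs = k_int / P` with protection
factor `P ≥ 1` (stored as log10). Positions 1–2 of a peptide and prolines
contribute no measurable signal; position 2 of a *chain* still has an amide
and is simulated when it sits at position ≥ 3 of some peptide.

## Synthetic data

The generator emulates the experimental design the analysis was built for:
75% D₂O (5 µl sample + 15 µl deuterated buffer), pD 7, exchange on ice,
five time points at 10¹…10⁵ s, undeuterated and fully-deuterated (FD)
references, overlapping peptic-style peptides with multiple charge states,
and per-peptide back-exchange drawn once per peptide from a truncated
normal (mean 0.18, sd 0.05, bounds [0, 0.5]) and applied identically at all
time points including the FD reference — matching the single-number FD
normalization used downstream.

Envelopes are stick spectra: the natural isotope distribution is computed
from the peptide's exact elemental composition (pyteomics composition and
NIST isotope tables) by aggregated convolution on a nominal-mass grid that
carries each bin's exact mean mass, then crossed with the Poisson-binomial
distribution of deuteron counts at `Δm_D = 1.00628` Da per deuteron. This
makes the centroid identity `shift = Σ p_i · Δm_D` exact (the tests assert
it to 10⁻⁶ Da), so the whole uptake chain can be validated in closed form.
Averagine is never used — sequences are known. EX1 segments produce a
two-component mixture with closed/open weights `e^{−k_open t}` /
`1 − e^{−k_open t}`; the open component carries full plateau deuteration
over the segment (exchange assumed faster than reclosing — the EX1 limit;
refolding rates are not modeled). Noise is multiplicative log-normal
(σ = 2% of peak height) with a 0.1% relative floor cutoff; everything is
reproducible from the recorded seed and manifest.

Presets (`tetramer`, `trimer`, `monomer_unfolded`) mimic the biology the
package was written around: an unbound histone pair with fast tails, a
moderately protected core and a concertedly unfolding α2–L2–α3-like segment
(k_open = 10⁻⁴ s⁻¹, giving bimodality that appears at 10³ s and peaks at
10⁴ s); a chaperone-bound complex that is globally far slower with a
locally accelerated loop; and a free chaperone that is essentially unfolded
outside one stable "tower" segment. Histone chains carry the human H3.3 and
H4 sequences; the chaperone chain is a deterministic synthetic 235-residue
sequence (the real domain sequence is not embedded).

What the generator does *not* emulate: chromatography, profile peak
shapes (except in the optional mzML export), peptide misidentification,
overlapping-envelope interference, intensity-dependent (shot) noise, and
site-correlated back-exchange. Passing tests therefore demonstrate
correctness of the inference chain under the stated noise model, not
robustness to every artifact of real LC-MS data.

Rate classes: class Cj (j = 1…5) means "exchanges by 10^j s" and carries a
representative rate `−ln(0.05)/10^j` (95% exchanged at its deadline); C6
("not exchanged by 10⁵ s") continues the decade pattern at `−ln(0.05)/10⁷`,
i.e. ~3% uptake at the last time point. When a template assigns a class,
each site's protection factor is `max(1, k_int / k_class)`. Because class
C1's representative rate (0.30 s⁻¹) exceeds many intrinsic rates at 0 °C,
C1 sites saturate at `P = 1` and exchange at their intrinsic rates — "C1"
ground truth is therefore approximate for slow-k_int sites, and exactness
checks use C2–C6.

## Envelope analysis

Centroids are intensity-weighted mean m/z. Mass shift is
`(centroid(t) − centroid(undeut)) · z` in Da; negative shifts from noise
are retained in tables (clamping, if any, is presentation-level). Percent
exchange is `100 · shift(t) / shift(FD)`, making the FD point exactly 100%
and canceling back-exchange. Deuteron counts use the convention
`%/100 · N_measurable · f_D2O` — the plateau stays in the number, so the
"maximum measurable" line is `N · 0.75`; a `plateau_corrected` switch
rescales to the full amide count for the other convention. Back-exchange
per peptide is the FD inversion `1 − shift_FD / (N · f_D2O · Δm_D)`; the
dataset summary is the unweighted mean over peptides.

EX1 detection fits two nested models to the (undeuterated-envelope ⊗
binomial-uptake) family on a unit-spaced isotopologue grid: one free mean
uptake, versus two means plus a mixture weight (component widths tied
through the shared binomial spread — same peptide, two uptake levels). The
two-component model is accepted only when all three hold: AIC improvement
> 10, component centroid separation ≥ 1.5 Da, minor weight ≥ 0.05; ties and
optimizer failures fall back to unimodal (the conservative call, consistent
with cautious "EX1-like" language for marginal cases). All three thresholds
are config keys; the defaults were set by the detection contract in the
test suite (< 5% false positives at default noise, ≥ 95% power at ≥ 3 Da
separation and minor weight ≥ 0.3). For bimodal spectra the reported shift
is the weight-averaged component centroid — the "average centroid over the
relative intensities" of the open and closed populations — which coincides
with the plain centroid of the mixture.

Charge states are merged by total-intensity-weighted mean of percent
exchange; dispersion beyond 10 percentage points sets a QC flag but never
drops data.

## Rate-class maps

The consensus map minimizes
`Σ_peptides Σ_times (D_obs − Σ_sites f_class(site)(t))²` where
`f_class(t) = f_D2O(1 − e^{−k_class t})` in the same plateau-in units as the
observed deuteron counts. Residues are grouped into connected components by
shared peptides. Components of ≤ 6 residues are solved exhaustively (6⁶ ≈
4.7·10⁴ assignments; the cutoff is configurable — it is kept at 6 because
the enumeration cost grows as 6^n while coordinate descent with restarts
already recovers the optimum reliably at n > 6). Larger components use
coordinate descent (sweep residues in order of their longest covering
peptide, descending) from a marginal-fit initialization, with 10 random
restarts from a recorded seed; known helical segments can seed residues at
the slowest class — seeds shape only the first start and are never frozen,
so restarts remain free. Ties at the optimum are resolved toward the slower
class (the conservative protection claim) and flagged ambiguous when an
alternative class changes the local residual by less than a relative 10⁻⁶.

Identifiability: residues covered by *identical* sets of peptides are
mutually exchangeable in this objective — peptide-level data cannot order
them. The map returns one optimum; recovery tests assert a perfect fit, the
exact class multiset over every peptide's sites, and ≥ 90% positionwise
agreement, which is what the data define.

Time-to-level interpolates the percent curve log-linearly in time; levels
outside the observed range return explicit censored bounds (`>t_max`,
`<t_min`), and non-monotone curves (noise) are interpolated on their
isotonic fit and flagged.

## Differential comparison

Peptides match across states by exact (chain, start, end, sequence).
Fold time is `t_B(level) / t_A(level)` with censoring algebra: a bound in
one curve propagates to a `≥`/`≤` bound on the ratio; bounds on both sides
in the same direction are indeterminate. The default comparison level is
50% of the FD-normalized scale — the published comparisons fix no level, so
it is a config/CLI choice; categories use the 10 and 1000 thresholds.
Lower bounds bin by their bound value (a `≥ 10⁴` bound lands in `≥1000`).
Per-residue consensus takes the majority over covering peptides (only
positions measurable within each peptide vote), ties resolve toward the
smaller-|Δ| category with a flag, and positions without coverage are marked
"no data", distinct from "no difference".

## Structure mapping

SASA is Shrake–Rupley on heavy atoms: golden-spiral sphere sampling
(default 960 points, probe 1.4 Å) with element radii C 1.70, N 1.55,
O 1.52, S 1.80 Å from a packaged table; hydrogens and (by default) waters
and heteroatoms are stripped. Buried area between two chain groups is
per-residue `SASA(own group alone) − SASA(complex)`, floored at numerical
zero; the interface total sums both sides (per-interface BSA convention —
the acceptance check against published one-sided totals tries both
conventions). Apolar fraction is the carbon+sulfur share of buried area.
Per-residue scalars are exported through the B-factor column (clipped to
[0, 99.99], sentinel −1.00 for unmapped residues), with an explicit
chain-map CSV (dataset chain → PDB chain + numbering offset) — mappings are
never guessed. Comparisons against other SASA implementations agree to ~2%
at 960–1920 sphere points; published interface totals from different
algorithms are compared at ±15%.

## Sizes and numerical choices

Test and acceptance workloads are deliberately compact: recovery and
comparison tests use a 40–50-residue chain at digest redundancy 3
(~15–21 peptides), the detection-contract test uses 200 unimodal and 40
bimodal envelopes, and the acceptance script simulates a 235-residue chain
(~70 peptides, references only) — the statistical contracts they verify are
size-independent. Optimizer tolerances: coordinate-descent improvement
10⁻¹⁵ (exact arithmetic ties), ambiguity tolerance 10⁻⁶ relative, mixture
fits by Levenberg–Marquardt from a moment-based initialization with a
0.25-split two-component start. Degenerate inputs are rejected with named
positions (unknown residues, mismatched envelope keys, empty envelopes,
all-zero intensities, non-positive FD shifts).

## Known limitations

* Back-exchange is a single per-peptide number; no site-resolved or
  time-dependent deuterium loss.
* No continuous per-residue rate estimation — discrete classes only, by
  design, mirroring the time-grid resolution of the experiment.
* EX1 modeling assumes exchange-before-reclosing; intermediate EXX regimes
  are not simulated and would be classified by the bimodality test alone.
* The mzML path is a convenience for centroided data laid out one spectrum
  per time label; it does no retention-time alignment or feature finding.
* Interface areas depend on radii and sampling; they reproduce published
  totals only within the cross-implementation tolerance (±15%).
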