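# hdxpipe

Peptide-level analysis of hydrogen/deuterium-exchange mass spectrometry
(H/DX-MS), built around the inference chain used to study how a histone
chaperone rigidifies its histone cargo: isotopic envelopes → centroids →
back-exchange-corrected uptake → EX1/EX2 classification → residue-level
rate-class maps → differential protection between states → structure
mapping and interface characterization.

## Who this is for

H/DX-MS measures backbone dynamics: amide protons exchange with solvent
deuterons quickly in unfolded regions and slowly where they are
hydrogen-bonded in stable structure. `hdxpipe` is for analysts who have (or
want to simulate) peptide-level envelope data over a log-spaced time course
and need corrected uptake curves, residue-resolution exchange-speed maps,
and rigorous two-state comparisons with explicit censoring — plus the
structural bookkeeping (B-factor export, buried-surface-area analysis) to
relate those maps to crystal structures.

## The model

* **Intrinsic rates.** For an unstructured chain, each amide's exchange
  rate is `k_int = k_A·[D+]·F_A + k_B·[OD−]·F_B + k_W·F_B`, with
  poly-DL-alanine reference constants, nearest-neighbor side-chain factors
  `F_A`, `F_B` (packaged table), and Arrhenius scaling (14/17/19 kcal·mol⁻¹
  for acid/base/water). Structure slows a site by its protection factor
  `P ≥ 1`: `k_obs = k_int / P`.
* **EX2 envelopes.** Site deuteration is independent first-order approach
  to the D₂O plateau: `p_i(t) = f_D2O·(1 − e^{−k_obs,i t})·(1 − b)` with
  per-peptide back-exchange `b`. The stick spectrum is the natural isotope
  distribution (exact elemental composition) convolved with the
  Poisson-binomial of the `p_i`, peaks at `(M + n·Δm_D + z·m_H⁺)/z`.
* **EX1 segments.** A segment that unfolds concertedly with opening rate
  `k_open` yields a two-component mixture: closed population (weight
  `e^{−k_open t}`) exchanging at protected rates, open population carrying
  full plateau deuteration — a bimodal envelope.
* **Uptake.** Percent exchange = 100 × shift(t)/shift(FD), normalizing to a
  fully-deuterated reference so back-exchange cancels; deuteron counts keep
  the 75% plateau in the reported number (the "maximum measurable" is
  `N_amides × f_D2O`), matching common practice.
* **Rate classes.** Residues are assigned discrete classes C1…C6
  ("exchanges by 10¹ s" … "not exchanged by 10⁵ s") by minimizing the
  squared difference between observed per-peptide deuterons and the counts
  predicted from class rates, over all overlapping peptides and times.
* **Differential protection.** Matched peptides give Δ%D per time and the
  fold change in time-to-level, censored (`≥`, `≤`, indeterminate) when a
  level is never reached inside the grid, binned into <10, 10–1000, ≥1000.
* **Structure mapping.** Per-residue scalars are written into PDB B-factor
  columns; interface burial is Shrake–Rupley SASA(group alone) −
  SASA(complex), with apolar fraction from carbon/sulfur contributions.

## Worked example

```python
from hdxpipe import (
    ExchangeConditions, generate_state, generate_digest, simulate_dataset,
    analyze_envelopes, dataset_backexchange, build_curves,
    consensus_residue_map, compare_states,
)

cond = ExchangeConditions(pD=7.0, temperature_K=273.15, d2o_fraction=0.75)

free_state = generate_state("tetramer", seed=1, cond=cond)   # unbound histone pair
bound_state = generate_state("trimer", seed=1, cond=cond)    # chaperone-bound
pool = generate_digest({"H3": free_state.chains["H3"]}, target_redundancy=3, seed=2)

curves = {}
for state in (free_state, bound_state):
    ds = simulate_dataset(state, pool, cond, seed=3)
    uptake = analyze_envelopes(ds.envelopes, cond)
    curves[state.state_id] = build_curves(uptake)
    bx = dataset_backexchange(ds.envelopes, cond)
    print(f"{state.state_id}: mean back-exchange "
          f"{bx['backexchange'].mean():.3f} over {len(bx)} peptides")

rmap = consensus_residue_map(curves["tetramer"], pool, cond, rng_seed=0)
cmp = compare_states(curves["tetramer"], curves["trimer"], pool, level=50.0)
print(cmp.peptide_table["category"].value_counts().to_dict())
```

prints

```
tetramer: mean back-exchange 0.180 over 47 peptides
trimer: mean back-exchange 0.180 over 47 peptides
{'10-1000': 21, '<10': 10, '>=1000': 9, 'indeterminate': 7}
```

The back-exchange estimator recovers the generator's 18% mean from the FD
references alone. The fold-time categories say that for 21 of the matched
peptides the bound state needs 10–1000× longer to reach half exchange, and
for 9 at least 1000× — the global rigidification signature — while the
locally destabilized loop and the fast tails fall in `<10`. In the free
state the same run detects bimodal (EX1) envelopes at intermediate times in
the concertedly unfolding segment (22 peptide-time points flagged).

The same pipeline is scriptable from the shell:

```bash
hdxpipe simulate --preset tetramer --seed 1 --out sim/
hdxpipe analyze  --envelopes sim/envelopes.csv --out uptake.csv
hdxpipe ratemap  --uptake uptake.csv --pool sim/pool.csv --out map.csv
hdxpipe diff     --uptake-a uptake_A.csv --uptake-b uptake_B.csv \
                 --pool sim/pool.csv --out cmp
hdxpipe structure --pdb complex.pdb --map map.csv --out annotated
hdxpipe report   --uptake uptake.csv --out report
```

## Layout

| module | role |
| --- | --- |
| `hdxpipe.chemistry` | intrinsic rates, site kinetics, quench factors |
| `hdxpipe.spectra` | stick spectra, natural-isotope and deuteration convolution |
| `hdxpipe.synthetic` | ground-truth states, digests, envelope simulation |
| `hdxpipe.envelopes` | centroids, FD normalization, back-exchange, EX1 detection, charge merging |
| `hdxpipe.ratemap` | uptake curves, time-to-level, consensus rate-class maps |
| `hdxpipe.differential` | Δ%D, censored fold times, residue difference categories |
| `hdxpipe.structure` | PDB I/O, B-factor annotation, SASA and buried interfaces |
| `hdxpipe.config` / `tables` / `mzml` / `cli` | configuration, CSV schemas, optional mzML, command line |

See `docs/methods.md` for the full methods note: assumptions, parameter
defaults, numerical choices, and what the synthetic data do and do not
emulate.
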