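# agnckit

Time-resolved fluorescence and crystal-contact analysis for DNA-stabilized
silver nanoclusters (DNA:AgNCs) — few-atom Ag emitters wrapped in short
single-stranded DNA, of interest as bright, large-Stokes-shift near-infrared
fluorescent probes. The package implements the full characterization chain
used for such emitters, for spectroscopists and structural analysts alike:

* **TCSPC lifetime fitting** — `ReconvolutionModel` fits a photon-counting
  histogram with the model
  `N(t) = (IRF ⊗ Σᵢ aᵢ e^(−t/τᵢ)) + s·IRF + b`, shift-aligning the
  instrument response and weighting residuals by Poisson statistics
  (`w = 1/max(obs, 1)`); `TailFitModel` fits the bare multi-exponential
  after the IRF has decayed. Both return a results object with lifetimes
  (ascending), amplitudes, reduced χ², standard errors and the
  intensity-weighted average lifetime `⟨τ⟩ = Σaᵢτᵢ²/Σaᵢτᵢ`.
* **Time-resolved emission spectra (TRES)** — per-wavelength decays
  (e.g. 650–825 nm in 5 nm steps) are sliced in time, converted to
  wavenumbers with the Jacobian factor `I_ν = I_λ·10⁷/ν²` (area-conserving),
  and spline-interpolated on a grid equivalent to 0.001 nm steps to locate
  emission maxima; `⟨τ_w⟩` averages `⟨τ(λ)⟩` weighted by the steady-state
  intensity.
* **Anisotropy & Perrin analysis** — `AnisotropyModel` jointly reconvolution-
  fits a VV/VH polarized decay pair with shared intensity decay and
  `r(t) = r₀e^(−t/θ)`; the Perrin relation `θ = ηV_hydro/k_BT`
  (spherical rotor) converts θ measured across temperatures into a
  hydrodynamic volume, with a packaged water-viscosity correlation.
* **Steady-state utilities** — Stokes shift `10⁷/λ_abs − 10⁷/λ_em` (cm⁻¹),
  interpolated emission maxima, relative quantum yield against a reference
  dye.
* **Crystal-structure contacts** — from PDB/mmCIF files (gemmi):
  argentophilic Ag–Ag interactions below the van der Waals sum (3.44 Å),
  nucleotide→Ag coordination bonds (one per aromatic N to the nearest Ag,
  up to two per carbonyl/phosphate O; 2.2–2.8 Å expected), occupancy
  partitioning of Ag sites, distance histograms, and sugar-pucker
  classification from the pseudorotation phase.
* **Synthetic data** — every input above can be generated with known ground
  truth (Poisson-noised convolved decays, relaxing emission bands,
  polarized pairs, planted contact geometries), so the whole chain is
  testable without instrument data.

## Worked example

Fit a simulated 10⁶-count decay of the ~3.4 ns near-infrared emitter and
recover a hydrodynamic volume from three-temperature anisotropy:

```python
import agnckit as ak
from agnckit.anisotropy import (AnisotropyModel, perrin_series,
                                perrin_theta, water_viscosity)

cfg = ak.DecaySimConfig(components=((1.0, 3.42),), total_counts=1e6, seed=1)
decay = ak.simulate_decay(cfg)
irf = ak.simulate_irf(cfg, noiseless=True)
print(ak.ReconvolutionModel(decay, irf, n_exp=1).fit().summary())

entries = []
for j, T in enumerate((278.15, 298.15, 313.15)):
    acfg = ak.AnisotropySimConfig(
        decay=ak.DecaySimConfig(total_counts=1e6, seed=j),
        r0=0.38, theta=perrin_theta(9.72, T, water_viscosity(T)))
    vv, vh = ak.simulate_anisotropy(acfg)
    airf = ak.simulate_irf(acfg.decay, noiseless=True)
    entries.append((AnisotropyModel(vv, vh, airf, n_exp=1).fit(), T))
print(perrin_series(entries).summary())
```

which prints

```
reconvolution fit, 1 exponential(s)
  converged: True
  a1 = 1.0000   tau1 = 3.421 +/- 0.00755 ns
  scatter = 6.666e-28   background = 4.253e-20 cts/ch   IRF shift = -1.1 ps
  <tau> = 3.421 ns   reduced chi2 = 0.9247
Perrin hydrodynamic-volume series (spherical rotor)
  T =  278.15 K  eta = 1.4897 mPa s  theta =  3.762 ns  V =  9.697 nm^3
  T =  298.15 K  eta = 0.8921 mPa s  theta =  2.102 ns  V =  9.700 nm^3
  T =  313.15 K  eta = 0.6557 mPa s  theta =  1.476 ns  V =  9.733 nm^3
  pooled V_hydro = 9.710 nm^3, spread = 0.020 nm^3
```

The fitted lifetime (3.421 ns, χ²_R ≈ 0.92) recovers the planted 3.42 ns to
0.03%, and the pooled hydrodynamic volume recovers the planted 9.72 nm³ to
0.1% — the cluster behaves as a ~9.7 nm³ sphere tumbling in water.
`ak.stokes_shift(523, 756)` gives the emitter's 5893 cm⁻¹ Stokes shift.

A thin CLI mirrors the two I/O-heavy workflows:

```sh
agnckit simulate decay --seed 3 -o decay.tsv     # + decay.truth.json sidecar
agnckit contacts structure.cif --ag-ag-cutoff 3.44
```

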