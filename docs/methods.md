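# Methods

## Decay model and reconvolution fitting

A TCSPC histogram records photon arrival times in uniform channels (default
4096 × 16 ps ≈ 65 ns, roughly twenty lifetimes of the ~3.4 ns emitter, so
tail fits see a clean baseline). The measured curve is the true decay
convolved with the instrument response function (IRF):

    N(t) = N_tot · normalize[(1 − s)·(IRF ⊗ Σᵢ aᵢ e^(−t/τᵢ)) + s·IRF] + b

with scattered-light fraction `s`, background `b` counts/channel, and
amplitudes normalized to unit sum. The IRF is either an analytic Gaussian
parameterized by its FWHM (150 ps default, typical of a ps-pulsed
diode-laser system) or a measured trace; a temporal shift of the IRF is
fitted as a free parameter because detector color shift is unavoidable in
real data. Convolution is discrete and causal (FFT-based, clipped at zero).

Fitting minimizes Neyman-weighted residuals, `w_c = 1/max(obs_c, 1)`, with
bounded trust-region least squares (`scipy.optimize.least_squares`,
`x_scale="jac"` — the parameters span ~6 orders of magnitude between
amplitudes in counts and shifts in ns, and unscaled steps stall the
optimizer far from the minimum). For two or more exponentials the lifetime
starting values are multi-started around a crude log-linear tail estimate
and the best χ² wins; reported lifetimes are always sorted ascending, which
resolves the permutation ambiguity. Standard errors come from the Jacobian
at the optimum scaled by the reduced χ².

**Fit window.** The default window runs from 10% of the rising edge to the
last channel holding at least `max(1, 0.02 × peak)` counts. The tail floor
matters: Neyman weights are unbiased only in the Gaussian limit
(`E[(X−μ)²/max(X,1)]` is 0.59 at μ = 1, 1.63 at μ = 5, 1.04 at μ = 50 for
Poisson X), so extending the window into the single-count tail biases the
reduced χ² to ~0.7 and the lifetime by ~0.6% at 10⁶ counts, while the 2%
floor yields median χ²_R ≈ 1.00 and ~0.1% lifetime error. The window is
user-overridable for dim data.

**Degenerate fits** are flagged, never silently returned: a fit whose
decaying signal falls below three standard deviations of the windowed shot
noise, or whose lifetime runs into its bounds, carries `degenerate=True`
(e.g. a flat-background input).

**Global fitting.** `GlobalDecayModel` links lifetimes (and the IRF shift)
across a set of histograms while leaving per-histogram amplitudes and
backgrounds free — the usual treatment of a wavelength-stepped decay set.
It is solved by variable projection: only the shared nonlinear parameters
are searched; the linear amplitudes/backgrounds are re-solved per evaluation
by non-negative weighted least squares. This reduces a ~100-parameter joint
problem to 2–4 nonlinear dimensions and runs in ~0.1 s for 36 wavelengths.

## TRES reconstruction

Time-resolved emission spectra are built from per-wavelength decays either
by evaluating the fitted (deconvolved) multi-exponential at each slice time
(default, suppresses shot noise and removes the IRF delay, matching the
fit-then-reconstruct workflow) or by reading raw counts at the nearest
channel. Slice spectra are detector-corrected (identity curve unless a
measured correction is supplied), optionally peak-normalized, then moved to
wavenumber space via `ν = 10⁷/λ` and the Jacobian factor `I_ν = I_λ·10⁷/ν²`,
which conserves integrated band intensity (verified to 10⁻⁴ relative and
better).

Emission maxima come from an exact cubic interpolating spline evaluated on
a dense grid with wavenumber steps equivalent to 0.001 nm — the
interpolant passes through every data point by construction, satisfying the
10⁻¹⁰ pass-through contract with zero residual; fewer than four points fall
back to exact polynomial interpolation with a logged note. Exact ties
report the leftmost maximum and set an ambiguity flag. Maxima are reported
in cm⁻¹ with nm conversion.

Decay-time summaries: `⟨τ(λ)⟩` is the intensity-weighted average lifetime
per wavelength (a flat series is the no-slow-relaxation signature), and
`⟨τ_w⟩ = Σ_λ I_ss(λ)⟨τ(λ)⟩ / Σ_λ I_ss(λ)` condenses it into one number per
temperature, weighting by the steady-state spectrum interpolated at the
decay wavelengths. Unconverged fits are excluded with a logged warning.

## Anisotropy and the Perrin volume

From vertically and horizontally polarized decays,
`r(t) = (I_VV − G·I_VH)/(I_VV + 2G·I_VH)` with the G-factor supplied by the
user (default 1.0); channels below an intensity floor are masked. For
parameter estimation the noisy r(t) curve is **not** fitted directly;
instead both polarized channels are fitted simultaneously by reconvolution
with a shared intensity decay (up to three exponentials) and
mono-exponential depolarization `r(t) = r₀e^(−t/θ)`:

    I_VV ∝ I(t)(1 + 2r(t))/3,   I_VH ∝ I(t)(1 − r(t))/(3G)

This is statistically better behaved than ratio fitting because the Poisson
model applies to the raw channels. The intensity parameters are seeded from
a fit of the magic-angle sum `I_VV + 2G·I_VH`. θ unresolved by the time
window (frozen rotor) or unidentifiable (r₀ ≈ 0) is flagged explicitly.

The Perrin relation `V_hydro = θ·k_B·T/η` (spherical-rotor assumption,
recorded in the output) converts θ to a hydrodynamic volume in nm³.
`perrin_series` pools per-temperature volumes into mean ± spread. Water
viscosity uses the Vogel correlation
`η/mPa·s = exp(−3.7188 + 578.919/(T/K − 137.546))` — 0.892 mPa·s at 25 °C,
within 1% of tabulated values around ambient temperature, degrading to ~2%
near 5 °C; a measured viscosity can be passed instead.

## Structure contacts

Structures load from PDB or mmCIF through gemmi; the default altloc policy
keeps the highest-occupancy alternative location (ties to the earlier
letter). No symmetry expansion is applied by default — inter-asymmetric-unit
analyses can opt into deposited symmetry operators with
`symmetry_mates=True`.

Rules, applied in deposited Cartesian Å:

* **Ag–Ag**: unordered pairs strictly below 3.44 Å, the sum of two silver
  van der Waals radii. Detection uses a k-d tree but is exactly equivalent
  to all-pairs enumeration (tested against brute-force oracles).
* **Coordination bonds**: donor chemistry is data-driven
  (`data/donors.json`): aromatic ring nitrogens (purine N1/N3/N7, pyrimidine
  N3), carbonyl oxygens (O2/O4/O6) and non-bridging phosphate oxygens
  (OP1/OP2). Per aromatic N, at most one bond to the nearest Ag within the
  3.0 Å search radius; per oxygen donor, up to two bonds to the two nearest
  Ag. Exactly equal distances break by lower atom serial, keeping outputs
  deterministic. The 2.2–2.8 Å range is treated as the *observed/validation*
  window for genuine coordination bonds, not as the detection cutoff — the
  3.0 Å search radius covers it with margin (the choice is recorded in the
  CLI summary output). Bridging ester oxygens (O3′/O5′) are excluded by
  default and available via a flag.
* **Occupancy partition**: Ag sites split at a 0.99 threshold into full and
  low-occupancy (mobile) sites, counted per subunit.
* **Sugar pucker**: pseudorotation phase P from the five endocyclic
  torsions, `tan P = [(ν₄+ν₁)−(ν₃+ν₀)] / [2ν₂(sin 36° + sin 72°)]`;
  C3′-endo for P ∈ [0°, 36°), C2′-endo for P ∈ [144°, 180°), otherwise
  "other"; boundaries go to the lower-index class; missing ring atoms give
  "incomplete".

## Synthetic data: what it emulates, and what it does not

The generators reproduce the statistical structure of the measurements:
multi-exponential kinetics convolved with a finite Gaussian IRF, per-channel
Poisson counting noise, monochromator-stepped decay sets whose Gaussian
(in energy) emission band relaxes as `ν(t) = ν_∞ + Δν·e^(−t/τ_relax)`
(defined per unit wavenumber and converted by the inverse Jacobian, so the
downstream wavenumber transform recovers the band exactly), polarized pairs
with single-exponential depolarization, and metal/donor coordinate clouds
whose distances are rejection-sampled to stay ≥ 0.1 Å away from every
decision boundary, making the planted contact truth robust. Defaults follow
the measured system: τ = 3.42 ns, IRF FWHM 150 ps, 650–825 nm scan in 5 nm
steps, band maximum near 756 nm, r₀ = 0.38, V_hydro = 9.72 nm³,
10⁶ total counts for recovery studies.

Not emulated: detector afterpulsing and dead time, pile-up, wavelength-
dependent IRF shape, real detector-efficiency curves, solvent heterogeneity
(single-species decays only), and crystallographic disorder beyond the
occupancy field. Passing tests therefore demonstrate correctness of the
estimators under ideal counting statistics, not robustness to instrument
artifacts.

The sugar-ring generator (`furanose_ring`) builds a puckered pentagon with
out-of-plane displacements `z_j ∝ cos(φ + 4πj/5)` and root-finds φ so the
ring's pseudorotation phase equals the request. The resulting torsions do
not follow the idealized cosine law exactly (the displacement construction
and the torsion formalism differ at second order), but the defining phase
formula is exact on them, which is what the classifier consumes.

## Problem sizes and numerical choices

Recovery studies use 10⁶-count histograms and 20–50 seeds (tests) or 30
seeds (acceptance script); TRES studies use 36 wavelengths × 2048 channels.
Optimizer tolerances are 10⁻¹² (single fits) and 10⁻¹⁰ (variable-projection
global fits); the noiseless model-in-model recovery is exact to ~10⁻¹²
relative. Lifetime bounds are [10⁻⁴, 10⁴] ns. FFT convolution outputs are
clipped at zero to suppress ringing at the 10⁻¹⁶ level.

## Known limitations

* The Neyman-weighted χ² is only calibrated when the fit window respects
  the Gaussian-limit floor (see above); very dim decays (≲10⁴ counts) keep
  a residual percent-level lifetime bias.
* Fitted-mode TRES slices inherit the multi-exponential approximation: when
  a band relaxes on a timescale comparable to the decay, a shared-lifetime
  bi-exponential reproduces the band trajectory only to within a few
  percent of the bandwidth; raw-mode slices are exact but noisy.
* The Perrin analysis assumes a spherical rotor and a single rotational
  correlation time; anisotropic or flexible species violate both.
* The viscosity correlation is for pure water; buffers with cosolvents need
  a measured value.
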