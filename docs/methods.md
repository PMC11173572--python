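# Methods

This note documents the models, conventions and numerical choices behind
`hydrashell`, and what the synthetic-data generator does and does not
emulate.

## Units and conventions

Internal units are Å, fs, Debye, cm⁻¹, kJ/mol, Kelvin and degrees (for
dihedral/collective variables). Conversion factors live in
`hydrashell.units`: 1 e·Å = 4.80320425 D, 1 Hartree = 2625.4996 kJ/mol,
R = 8.3145·10⁻³ kJ/(mol·K). File dialects declare their units in `#`
headers, and all unit conversions are involutive. Coordinates on disk are
wrapped into [0, L); analyses that need whole molecules rebuild them by
minimum-image chaining from a reference atom.

## Molecular dipoles from Wannier centers

Nuclei carry their valence charge (H +1, C +4, N +5, O +6 — the
pseudopotential convention, since core electrons are pseudized) and each
Wannier center −2e. A molecule is neutral under this convention, which makes
its classical dipole origin-independent; non-neutral input is rejected
rather than silently producing an origin-dependent number. Centers are
attributed to the molecule of their nearest atom under the minimum image;
an exact distance tie (within 10⁻⁹ Å) goes to the lower molecule index.
The per-molecule center count must equal half the molecular valence-electron
count (water 4, the CH₄N₂O₂ solute 15) — any other count raises an error
naming the frame and molecule, because it would corrupt every downstream
dipole. Since centers stay bonded to their molecules on vibrational time
scales, the assignment computed on the first frame is reused by default;
per-frame reassignment is available.

## IR spectra

Spectra are Fourier transforms of dipole time-correlation functions,
computed on the **derivative route**: the TCF of finite-difference dipole
derivatives (central differences; one-sided at the series ends) is
transformed, which suppresses the static dipole offset and already contains
the ω² factor of the absorption coefficient — the quantum prefactor
therefore adds no further ω² term. Choices:

* **TCF estimator** — unbiased (divide by the number of time origins per
  lag), vector dot product, FFT-accelerated; ensemble averaging over
  multiple trajectories is a plain mean of TCFs. Cross TCFs are symmetrized,
  (⟨a(0)b(t)⟩+⟨b(0)a(t)⟩)/2, so cross spectra are real by construction.
* **Windowing** — Hann on the lag domain (leakage control for ~10–20 ps
  segments at ~1 cm⁻¹ nominal resolution), zero-padding to the power of two
  that brings the FFT spacing below the requested resolution (default
  1 cm⁻¹), then interpolation onto the uniform output grid.
* **Quantum prefactor** — the harmonic correction
  Q(ν̃) = x/(1−e^{−x}), x = hcν̃/k_BT, is the default; `classical`/`none`
  are config options and the choice is stamped in the output metadata. The
  prefactor convention in the literature is not unique, so it must be
  explicit for cross-implementation comparability.
* **Smoothing** — convolution with a unit-area Gaussian, width parameter =
  its standard deviation, default 20 cm⁻¹, reflective boundary handling
  (which makes the discrete operator doubly stochastic, hence
  intensity-conserving).
* **Kramers–Kronig** — the imaginary refractive index is taken as
  k = α/(4πν̃n_D) (weak-absorption linearization), n(ν̃) is reconstructed by
  the singly subtracted KK relation anchored at the optical index of water
  n_D = 1.3325, using Maclaurin's alternating-point quadrature for the
  principal value (validated to <1% against the closed-form
  Lorentz-oscillator index), and the absorption is rescaled by n_D/n(ν̃). A
  band that has not decayed at either grid end sets a warning flag instead
  of failing.
* **Band positions** — maximum of the smoothed band (parabolically refined),
  because the red-shift correlation uses a single point reference; a
  centroid mode is provided. Red shift Δν̃ = 3660 − ν̃ against the free-OH
  reference of water in CCl₄, and per-bond hydrogen-bond enthalpy
  −ΔH = 1.3·Δν̃^{1/2} kJ/mol.

## Spatial decompositions

The molecular dipole density ρ_μ(t,r) smears each molecular dipole with an
isotropic Gaussian of width σ at its center of mass (periodic images summed
per axis). σ is not dictated by the underlying theory; the default 1.0 Å
resolves first-shell structure (~2.8 Å spacing) while keeping the cell
integral of the density equal to ΣμΡ within 0.5% on a 0.5 Å grid.

For the radially resolved spectrum the density is reduced to spherical
shells around the solute's instantaneous center of mass. Instead of binning
3-D grid points, the shell value uses the **exact angular average** of the
same Gaussian,
⟨G⟩(r; d) = (2πσ²)^{−3/2}·e^{−(r²+d²)/2σ²}·σ²·sinh(rd/σ²)/(rd),
evaluated in its overflow-free two-exponential form. This is the analytic
limit of grid binning with no discretization noise and preserves the sum
rule ∫4πr²⟨G⟩dr = 1 exactly, so the radial integral of α×(ω,r) reproduces
the directly computed solute–total cross spectrum (tested). The solute is
re-centered every frame; output is signed — negative cross-correlation
(anti-phase solvent response) is physically meaningful.

For the distance-dependent spectrum, solvent molecules are folded into a
solute-centered sphere with logistic weights of width D (default 0.25 Å —
sharp enough to define shells, smooth enough that the carved dipole stays
continuous between frames; the value is a declared default, not an
inference) and the carved dipole is normalized to a single molecule by
N = (1+ΣP²)^{−1/2}. Solute–solvent distances are center-of-mass distances
under the minimum image. The affected-shell cutoff R_c* is the inflection
point of the intensity-vs-R_c modulation at a probe band (default
320 cm⁻¹): a cubic-spline interpolant's maximum-magnitude derivative,
rejected with a diagnostic when no plateau exists at both ends of the
cutoff range. Both the soft water count ⟨ΣP⟩ and the hard count
(distance < R_c) are reported, since either convention is defensible.

## Structure analysis

RDFs are minimum-image pair histograms normalized by shell volume and
partner density ((N−1)/V for self-pairing), bin width 0.02 Å and
r_max = L/2 by default. The coordination number integrates g(r) to its
first minimum, detected on a 3-bin moving average; a first shell that
decays to <1% of its peak without a subsequent rise is treated as bounded
there (isolated-shell case). Dihedrals use the standard plane-normal/atan2
convention with minimum-image bond vectors, signed, in [−180°, 180°);
collinear frames are flagged, not fatal. The geometric H-bond criterion
(donor–acceptor < 3.5 Å and donor–H···acceptor angle > 140°) is a standard
convention, configurable, adopted because snapshot H-bond statements need
*some* criterion.

## Well-tempered metadynamics

The CV is periodic on [−180°, 180°); every Gaussian (hills and bias) is
summed over its ±360° images. Defaults mirror a common AIMD protocol:
W₀ = 0.001 Hartree = 2.6255 kJ/mol, deposition every 25 fs, biasing
temperature 1500 K. A hill *width* quoted in energy units is dimensionally
meaningless for an angular CV, so the width is a CV-space config value
(default 20°) and is never derived from an energy number. The engine keeps
the accumulated bias and its analytic force on a 1° grid (updated
incrementally per deposition, interpolated per step) and drives the same
overdamped Langevin integrator used by the synthetic sampler; the
well-tempered height uses the per-mole form W = W₀e^{−V/(R·T_bias)}, clamped
against exponent overflow.

Reconstruction averages −V_bias over the final third of the deposition
history to damp hill-granularity ripple. Two conventions are provided and
stamped in metadata: `plain` (direct inversion) and `well_tempered_scaled`
(multiplied by (T+ΔT)/ΔT, ΔT = T_bias), which corrects the asymptotic
attenuation of well-tempered filling and is the default; the two differ by
exactly that factor at every grid point. ΔF is the difference of basin
minima (windows may wrap), barriers are the path maximum between the two
minima minus the origin minimum, K = e^{ΔF/RT} with the direction
documented by the caller, and barriers are also reported in multiples of
R·T.

On a toy double well with a 10 kJ/mol basin gap the engine recovers ΔF
within 1.5 kJ/mol per seed with ~6000 hills (150 ps of 1 fs dynamics) — the
problem size used throughout the tests.

## The synthetic-data generator

The generator emulates the *inputs* of the analysis chain, not the physics
of liquid water:

* **Geometry** — rigid water (OH 0.96 Å, HOH 104.5°) and a rigid planar
  hydroxyurea-like solute (9 atoms, CH₄N₂O₂, 15 centers); initial placement
  by rejection sampling with a 2.4 Å center–center exclusion (deterministic
  retry cap 10⁴, failure is an explicit error) or an `ideal` uniform option
  used for ideal-gas reference statistics.
* **Dynamics** — bounded low-frequency center-of-mass oscillations
  (default amplitude 0.1 Å at 298.15 K) and rigid-body libration (default
  5°); there are no intermolecular forces and hence no realistic structure
  or diffusion.
* **Dipoles** — each molecule's dipole magnitude follows
  base + Σ_k A_k cos(2πcν̃_k t + φ) exactly: the pseudo-Wannier centers sit
  at bonds/lone pairs plus a common per-frame offset solved so the classical
  charge sum reproduces the configured magnitude to machine precision.
  Default modes (3400 cm⁻¹, 0.2 D) and (1650 cm⁻¹, 0.1 D) stand in for the
  OH stretch and HOH bend; the water base dipole defaults to the gas-phase
  1.85 D as a neutral reference value and the solute to 7.68 D, typical of a
  strongly polar hydrated solute. Mode phases are random per molecule
  (incoherent solvent) unless coherent phases are requested. The dipole
  sampling stride defaults to 2 fs.
* **CV sampling** — overdamped Euler–Maruyama Langevin on analytic periodic
  Gaussian-sum potentials (diffusion constant 10 deg²/fs, default step
  1 fs), whose stationary law is the Boltzmann distribution; this validates
  the metadynamics machinery against numerically exact Boltzmann weights.

Consequently, a passing test suite demonstrates the *correctness of the
analysis operators* (normalizations, sum rules, sign conventions, limits,
free-energy recovery) — it does not demonstrate that any particular liquid's
spectrum or hydration structure is predicted, which requires first-principles
trajectories upstream. Trajectories are stationary by construction, so no
burn-in/equilibration detection is provided.

## Degenerate inputs and tie-breaks

Non-neutral molecules, ragged/truncated files, non-monotone hill times,
aliasing vibrational modes, r_max beyond L/2, windows without grid points
and sub-resolution smoothing widths all raise errors rather than degrade
silently. Constant dipole series skip the normal fit with a flag; collinear
dihedrals yield flagged NaNs; center-assignment distance ties break to the
lower molecule index.

## Known limitations

* One cubic cell, NVT/NVE-style fixed volume; no triclinic or variable
  cells, no binary trajectory formats.
* The radial decomposition assumes the solute is a single tagged molecule;
  no multi-solute generalization.
* The quantum-correction prefactor family is limited to
  harmonic/classical/none.
* Metadynamics is strictly 1-D with fixed-width hills; no reweighting
  estimators beyond bias inversion.
* The Kramers–Kronig correction linearizes k in the absorption; strongly
  absorbing bands would need a self-consistent (iterative) treatment.
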