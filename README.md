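# hydrashell

Solvation-shell resolved infrared spectroscopy and conformational
free-energy analysis for aqueous solutes, from molecular-dynamics
trajectories that carry maximally localized Wannier-function (MLWF) centers.

Small solutes such as *N*-hydroxyurea — a first-line chemotherapeutic whose
hydration controls both its transport and its binding at the radical site of
ribonucleotide reductase — perturb the hydrogen-bond network of water in
ways that are directly visible in the infrared spectrum. This package
implements the post-simulation analysis chain used to quantify that
perturbation:

* **Molecular dipoles from Wannier centers.** In a closed-shell system each
  MLWF center carries −2e and each pseudized nucleus its valence charge
  (H +1, C +4, N +5, O +6), so the total dipole decomposes exactly into
  molecular dipoles, `M(t) = Σᵢ μᵢ(t)`, with each `μᵢ = Σₙ qₙrₙ − 2e Σ_w r_w`
  after making the molecule whole across the periodic boundary.
* **IR spectra from dipole time-correlation functions.**
  `α(ω) = F(ω) ∫dt e^{−iωt} ⟨M(0)·M(t)⟩`, evaluated through finite-difference
  dipole derivatives, with a configurable quantum-correction prefactor,
  1 cm⁻¹ resolution, 20 cm⁻¹ Gaussian smoothing, and numerical
  Kramers–Kronig removal of the refractive index anchored at n_D = 1.3325.
* **Two spatial decompositions.** Radially resolved cross spectra
  `α×(ω,r) = F(ω)·4πr² ∫dt e^{−iωt}⟨μ_s(0)·ρ_μ(t,r)⟩` built from a
  Gaussian-smoothed molecular dipole density, and distance-dependent spectra
  of a smoothly carved sphere dipole
  `μ_s^R = N_s^R [μ_s + Σᵢ P_{s,i} μᵢ]` with logistic edge weights
  `P = [1+exp((R_{s,i}−R_c)/D)]⁻¹`, plus selection of the spectrally
  affected-shell cutoff at the inflection of the intensity modulation and
  the (possibly fractional) count of affected waters `⟨Σᵢ P_{s,i}⟩`.
* **Structure.** Minimum-image RDFs with running coordination integrals
  `n(r) = 4πρ∫g r² dr`, signed dihedral time series, intramolecular distance
  distributions and a geometric hydrogen-bond criterion.
* **Well-tempered metadynamics** on a periodic 1-D collective variable:
  Gaussian bias deposition with height attenuation
  `W = W₀ e^{−V/k_B T_bias}`, free-energy reconstruction
  `F(s) = −V_bias(s, t→∞)` (plain or (T+ΔT)/ΔT-rescaled), basin ΔF,
  barriers in k_BT and equilibrium constants `K = e^{ΔF/RT}`.
* **Red-shift thermochemistry.** Per-bond hydrogen-bond enthalpy from the
  OH-stretch red shift against the 3660 cm⁻¹ free-OH reference,
  `−ΔH = 1.3·Δν̃^{1/2}` (kJ/mol).

Because ab-initio trajectories are expensive and rarely redistributed, a
first-class synthetic-data module generates all pipeline inputs at desk
scale: rigid-water (and hydroxyurea-like solute) boxes with pseudo-Wannier
centers whose classical dipoles follow prescribed vibrational modes exactly,
analytic harmonic dipole series, and overdamped Langevin sampling on known
periodic potentials for validating the metadynamics engine against
Boltzmann statistics.

## Worked example

```python
from hydrashell import RunConfig, run_pipeline

cfg = RunConfig(outdir="demo_run", seed=7, n_water=16, cell_edge=11.0,
                n_steps=4096, vibrational_modes=[[3400.0, 0.2], [1650.0, 0.1]],
                run_metadynamics=True)
summary = run_pipeline(cfg)
```

writes the trajectory, dipole table, smoothed IR spectrum, O–O RDF,
free-energy profile and a thermochemistry summary into `demo_run/`, and
returns:

```json
{
 "hbond_enthalpy_kjmol": 20.96,
 "mtd_K": 53.15,
 "mtd_barrier_kT": 4.57,
 "mtd_barrier_kjmol": 11.33,
 "mtd_delta_F_kjmol": 9.85,
 "oh_band_cm-1": 3399.99,
 "oh_red_shift_cm-1": 260.01,
 "water_dipole_mean_D": 1.850,
 "water_dipole_std_D": 0.158
}
```

Reading the numbers: the generator's 3400 cm⁻¹ OH-stretch mode is recovered
by the TCF spectrum to 0.01 cm⁻¹ (`oh_band_cm-1`), which sits 260 cm⁻¹ below
the 3660 cm⁻¹ free-OH reference and corresponds to a per-bond hydrogen-bond
enthalpy of ≈ 21 kJ/mol. The per-water dipole distribution is centred on the
configured 1.85 D. The metadynamics stage, run on the built-in asymmetric
double well (basin free-energy gap ≈ 10 kJ/mol), recovers
`mtd_delta_F_kjmol` = 9.85 kJ/mol — within the hill granularity — giving an
equilibrium constant of 53 and a 4.6 k_BT barrier out of the shallower
basin.

The same stages are available from the shell:

```bash
hydrashell gen box box.xyz --n-water 16 --n-steps 2048 --cell-edge 11 --seed 7
hydrashell spectrum box.xyz spectrum.tsv
hydrashell rdf box.xyz rdf.tsv --element-a O --element-b O
hydrashell mtd run HILLS --n-steps 60000 && hydrashell mtd fes HILLS fes.tsv
```

## Layout

| module | contents |
| --- | --- |
| `hydrashell.synthetic` | box/dipole/CV generators, box-composition arithmetic |
| `hydrashell.io` | XYZ trajectories (+ Wannier sidecars), HILLS files, spectrum tables |
| `hydrashell.dipoles` | center assignment, molecular dipoles, dipole distributions |
| `hydrashell.spectra` | TCFs, FFT spectra, smoothing, Kramers–Kronig, red-shift enthalpy |
| `hydrashell.spatial` | dipole density, radially resolved & distance-dependent spectra |
| `hydrashell.structure` | RDFs, coordination numbers, dihedrals, H-bond criterion |
| `hydrashell.metadynamics` | WT-MTD engine, FES reconstruction, ΔF/K/barriers |
| `hydrashell.pipeline` / `hydrashell.cli` | orchestration and the `hydrashell` CLI |

See `docs/methods.md` for the scientific conventions, parameter defaults and
known limitations.
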