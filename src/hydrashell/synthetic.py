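"""Synthetic trajectory, dipole and collective-variable generators.

This module produces every input the analysis pipeline consumes, at desk
scale: toy solvated-solute boxes carrying pseudo-Wannier centers, analytic
harmonic dipole series, and overdamped Langevin trajectories on known periodic
1-D potentials.  The generators are deterministic given (spec, seed).

Molecules are rigid bodies: water is fixed at OH 0.96 Å / HOH 104.5° and the
hydroxyurea-like solute at an idealized planar geometry.  Vibrational
structure is emulated entirely through the dipole: each molecule's dipole
magnitude oscillates as ``base + Σ_k A_k·cos(2π c ν̃_k t + φ)``, realized by a
rigid common offset of that molecule's Wannier centers, so the classical
charge sum reproduces the configured dipole exactly at every frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import Frame, Molecule, Topology, Trajectory, DipoleSeries, minimum_image, wrap_positions
from .units import (
    C_CM_PER_FS,
    CENTER_CHARGE,
    EA_TO_DEBYE,
    M_WATER,
    N_AVOGADRO,
    R_KJMOL,
    VALENCE_CHARGE,
    nyquist_wavenumber,
)

_MASS = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999}

# --------------------------------------------------------------------------
# rigid templates


def _water_template() -> tuple[list[str], np.ndarray, np.ndarray, np.ndarray]:
    """Water atoms + 4 pseudo-Wannier centers, COM at origin, dipole axis +z."""
    theta = np.deg2rad(104.5 / 2.0)
    o = np.array([0.0, 0.0, 0.0])
    h1 = 0.96 * np.array([np.sin(theta), 0.0, np.cos(theta)])
    h2 = 0.96 * np.array([-np.sin(theta), 0.0, np.cos(theta)])
    atoms = np.array([o, h1, h2])
    # two bond centers + two lone pairs behind the oxygen
    lp = np.deg2rad(54.75)
    centers = np.array(
        [
            0.5 * (o + h1),
            0.5 * (o + h2),
            o + 0.3 * np.array([0.0, np.sin(lp), -np.cos(lp)]),
            o + 0.3 * np.array([0.0, -np.sin(lp), -np.cos(lp)]),
        ]
    )
    elements = ["O", "H", "H"]
    masses = np.array([_MASS[e] for e in elements])
    com = (atoms * masses[:, None]).sum(0) / masses.sum()
    return elements, atoms - com, centers - com, np.array([0.0, 0.0, 1.0])


def _solute_template() -> tuple[list[str], np.ndarray, np.ndarray, np.ndarray]:
    """Hydroxyurea-like solute: 9 atoms (CH4N2O2) + 15 centers, COM at origin.

    Atom order follows the conventional numbering: N1 (hydroxamic N, bears H7
    and O8-H9), C2 (carbonyl C), N3 (amine N, bears H5/H6), O4 (carbonyl O),
    H5, H6, H7, O8 (hydroxyl O), H9 (hydroxyl H).  Valence charges sum to 30,
    balanced by 15 centers of −2e.
    """
    pos = {
        "N1": np.array([1.290, -0.640, 0.0]),
        "C2": np.array([0.000, 0.000, 0.0]),
        "N3": np.array([-1.220, -0.680, 0.0]),
        "O4": np.array([0.000, 1.230, 0.0]),
        "H5": np.array([-2.090, -0.180, 0.0]),
        "H6": np.array([-1.250, -1.690, 0.0]),
        "H7": np.array([2.130, -0.080, 0.0]),
        "O8": np.array([1.380, -2.020, 0.0]),
        "H9": np.array([2.280, -2.350, 0.0]),
    }
    order = ["N1", "C2", "N3", "O4", "H5", "H6", "H7", "O8", "H9"]
    atoms = np.array([pos[k] for k in order])
    elements = [k[0] for k in order]

    def bond(a: str, b: str, f: float = 0.5) -> np.ndarray:
        return pos[a] + f * (pos[b] - pos[a])

    centers = np.array(
        [
            bond("C2", "N1", 0.6),           # C–N bonds: centers pulled to N
            bond("C2", "N3", 0.6),
            bond("C2", "O4", 0.55),          # C=O double bond → two centers
            bond("C2", "O4", 0.65),
            bond("N1", "O8", 0.5),
            bond("N1", "H7", 0.4),
            bond("N3", "H5", 0.4),
            bond("N3", "H6", 0.4),
            bond("O8", "H9", 0.4),
            pos["O4"] + np.array([0.25, 0.17, 0.0]),    # O4 lone pairs
            pos["O4"] + np.array([-0.25, 0.17, 0.0]),
            pos["O8"] + np.array([-0.10, -0.15, 0.25]),  # O8 lone pairs
            pos["O8"] + np.array([-0.10, -0.15, -0.25]),
            pos["N1"] + np.array([0.0, 0.0, 0.30]),      # N lone pairs
            pos["N3"] + np.array([0.0, 0.0, 0.30]),
        ]
    )
    masses = np.array([_MASS[e] for e in elements])
    com = (atoms * masses[:, None]).sum(0) / masses.sum()
    # dipole axis: roughly from the NHOH side towards the carbonyl oxygen
    axis = np.array([-0.3, 1.0, 0.0])
    axis /= np.linalg.norm(axis)
    return elements, atoms - com, centers - com, axis


def _template_dipole(elements: list[str], atoms: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """Classical dipole of a template in e·Å (origin-free: templates are neutral)."""
    q = np.array([VALENCE_CHARGE[e] for e in elements], dtype=float)
    return (q[:, None] * atoms).sum(0) + CENTER_CHARGE * centers.sum(0)


# --------------------------------------------------------------------------
# specs


@dataclass
class SyntheticBoxSpec:
    """Conditions for a synthetic solute+water box.

    ``vibrational_modes`` is a list of (wavenumber cm⁻¹, dipole amplitude D)
    pairs superimposed on ``base_dipole`` for every water; the solute carries
    the same modes on top of ``solute_dipole``.  All wavenumbers must lie
    below the Nyquist limit of the sampling interval ``dt``.
    """

    n_water: int
    n_solute: int = 0
    cell_edge: float = 12.0          # Å
    temperature: float = 298.15      # K
    dt: float = 2.0                  # fs — mirrors the 2 fs dipole saving stride
    n_steps: int = 100
    seed: int = 0
    vibrational_modes: list[tuple[float, float]] = field(
        default_factory=lambda: [(3400.0, 0.20), (1650.0, 0.10)]
    )
    base_dipole: float = 1.85        # D, per water
    solute_dipole: float = 7.68      # D
    placement: str = "rejection"     # "rejection" (2.4 Å O–O exclusion) | "ideal"
    com_amplitude: float = 0.10      # Å, bounded thermal COM oscillation at 298.15 K
    libration_amplitude: float = 5.0  # °, rigid-body libration
    coherent_phases: bool = False    # zero mode phases on every molecule

    def validate(self) -> None:
        if self.cell_edge <= 0:
            raise ValueError("cell_edge must be positive")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.n_solute not in (0, 1):
            raise ValueError("n_solute must be 0 or 1")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        nyq = nyquist_wavenumber(self.dt)
        for nu, _ in self.vibrational_modes:
            if nu >= nyq:
                raise ValueError(f"mode at {nu} cm⁻¹ is at/above the Nyquist limit {nyq:.1f}")
        if self.placement not in ("rejection", "ideal"):
            raise ValueError("placement must be 'rejection' or 'ideal'")


class PlacementError(RuntimeError):
    """Raised when rejection sampling cannot place a molecule without overlap."""


# --------------------------------------------------------------------------
# box generation


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix via a random unit quaternion."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def _rodrigues(axis: np.ndarray, angles: np.ndarray, vecs: np.ndarray) -> np.ndarray:
    """Rotate ``vecs`` (k, 3) about ``axis`` by per-time ``angles`` (nt,) → (nt, k, 3)."""
    k = axis / np.linalg.norm(axis)
    c = np.cos(angles)[:, None, None]
    s = np.sin(angles)[:, None, None]
    v = vecs[None, :, :]
    kxv = np.cross(np.broadcast_to(k, v.shape), v)
    kdv = (v @ k)[:, :, None]
    return v * c + kxv * s + k * kdv * (1.0 - c)


def _place_coms(spec: SyntheticBoxSpec, rng: np.random.Generator) -> np.ndarray:
    """Initial molecular center positions (solute first when present)."""
    n_mol = spec.n_solute + spec.n_water
    coms = np.empty((n_mol, 3))
    placed = 0
    if spec.n_solute:
        coms[0] = spec.cell_edge / 2.0
        placed = 1
    min_d, cap = 2.4, 10_000
    for _ in range(spec.n_water):
        if spec.placement == "ideal":
            coms[placed] = rng.uniform(0.0, spec.cell_edge, 3)
            placed += 1
            continue
        for attempt in range(cap):
            trial = rng.uniform(0.0, spec.cell_edge, 3)
            if placed == 0:
                break
            d = np.linalg.norm(minimum_image(coms[:placed] - trial, spec.cell_edge), axis=1)
            if np.all(d >= min_d):
                break
        else:
            raise PlacementError(
                f"could not place molecule {placed} after {cap} attempts "
                f"(box too dense for the {min_d} Å exclusion radius)"
            )
        coms[placed] = trial
        placed += 1
    return coms


def generate_water_box(spec: SyntheticBoxSpec) -> tuple[Trajectory, Topology]:
    """Generate a periodic box of rigid waters (plus at most one solute).

    Every water contributes 3 atoms + 4 pseudo-Wannier centers, the solute 9
    atoms + 15 centers; each molecule is charge-neutral under the valence
    convention.  Molecular centers of mass undergo small bounded oscillations,
    molecules librate rigidly, and each molecule's classical dipole follows
    its configured magnitude exactly (centers carry a common tuning offset).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    times = np.arange(spec.n_steps) * spec.dt
    nt = spec.n_steps
    L = spec.cell_edge

    w_el, w_atoms, w_centers, w_axis = _water_template()
    s_el, s_atoms, s_centers, s_axis = _solute_template()

    coms0 = _place_coms(spec, rng)
    n_mol = coms0.shape[0]

    species = (["solute"] if spec.n_solute else []) + ["water"] * spec.n_water
    templates = {
        "water": (w_el, w_atoms, w_centers, w_axis, spec.base_dipole),
        "solute": (s_el, s_atoms, s_centers, s_axis, spec.solute_dipole),
    }

    # thermal COM oscillation: two incommensurate low frequencies, bounded amp
    amp = spec.com_amplitude * np.sqrt(spec.temperature / 298.15)
    f1, f2 = 2.0 * np.pi * C_CM_PER_FS * 60.0, 2.0 * np.pi * C_CM_PER_FS * 173.0

    all_elements: list[str] = []
    mol_atom_idx: list[list[int]] = []
    atom_blocks: list[np.ndarray] = []    # per molecule: (nt, k, 3)
    center_blocks: list[np.ndarray] = []

    next_atom = 0
    for m in range(n_mol):
        el, t_atoms, t_centers, t_axis, base = templates[species[m]]
        nu_c = CENTER_CHARGE * len(t_centers)  # dμ/dΔ for a common center shift (e)

        R0 = _random_rotation(rng)
        lib_axis = rng.normal(size=3)
        lib_phase = rng.uniform(0, 2 * np.pi)
        lib_freq = 2.0 * np.pi * C_CM_PER_FS * rng.uniform(300.0, 600.0)
        angles = np.deg2rad(spec.libration_amplitude) * np.sin(lib_freq * times + lib_phase)

        u1, u2 = rng.normal(size=3), rng.normal(size=3)
        u1 /= np.linalg.norm(u1)
        u2 /= np.linalg.norm(u2)
        p1, p2 = rng.uniform(0, 2 * np.pi, 2)
        com_t = coms0[m] + amp * (
            np.sin(f1 * times + p1)[:, None] * u1 + np.sin(f2 * times + p2)[:, None] * u2
        )

        # dipole magnitude per frame
        mag = np.full(nt, base)
        for nu, a in spec.vibrational_modes:
            phase = 0.0 if spec.coherent_phases else rng.uniform(0, 2 * np.pi)
            mag = mag + a * np.cos(2.0 * np.pi * C_CM_PER_FS * nu * times + phase)

        atoms_r = _rodrigues(lib_axis, angles, t_atoms @ R0.T)       # (nt, k, 3)
        centers_r = _rodrigues(lib_axis, angles, t_centers @ R0.T)
        axis_r = _rodrigues(lib_axis, angles, (R0 @ t_axis)[None, :])[:, 0, :]

        mu_template = _template_dipole(el, t_atoms, t_centers)       # e·Å
        mu_cur = _rodrigues(lib_axis, angles, (R0 @ mu_template)[None, :])[:, 0, :]
        mu_target = (mag / EA_TO_DEBYE)[:, None] * axis_r
        delta = (mu_cur - mu_target) / (-nu_c)                       # common center shift

        atom_blocks.append(atoms_r + com_t[:, None, :])
        center_blocks.append(centers_r + delta[:, None, :] + com_t[:, None, :])
        all_elements.extend(el)
        mol_atom_idx.append(list(range(next_atom, next_atom + len(el))))
        next_atom += len(el)

    atoms_t = np.concatenate(atom_blocks, axis=1)      # (nt, n_atoms, 3)
    centers_t = np.concatenate(center_blocks, axis=1)  # (nt, n_centers, 3)

    frames = [
        Frame(
            time=times[k],
            cell_edge=L,
            elements=all_elements,
            positions=wrap_positions(atoms_t[k], L),
            centers=wrap_positions(centers_t[k], L),
        )
        for k in range(nt)
    ]
    topology = Topology(
        molecules=[Molecule(species=species[m], atom_indices=mol_atom_idx[m]) for m in range(n_mol)],
        elements=all_elements,
    )
    return Trajectory(frames, dt=spec.dt), topology


# --------------------------------------------------------------------------
# analytic dipole series


def generate_harmonic_dipole(
    wavenumber: float,
    amplitude: float,
    dt: float,
    n_steps: int,
    direction: np.ndarray | None = None,
    phase: float = 0.0,
) -> DipoleSeries:
    """Single-molecule dipole μ(t) = A·cos(2π c ν̃ t + φ)·ê on a uniform grid."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    nyq = nyquist_wavenumber(dt)
    if wavenumber >= nyq:
        raise ValueError(f"wavenumber {wavenumber} cm⁻¹ aliases: Nyquist limit is {nyq:.1f}")
    e = np.array([1.0, 0.0, 0.0]) if direction is None else np.asarray(direction, float)
    e = e / np.linalg.norm(e)
    t = np.arange(n_steps) * dt
    mu = amplitude * np.cos(2.0 * np.pi * C_CM_PER_FS * wavenumber * t + phase)
    return DipoleSeries(times=t, dipoles=mu[:, None, None] * e[None, None, :], tags=["mol"])


# --------------------------------------------------------------------------
# toy potentials and Langevin sampling


@dataclass
class ToyPotential:
    """Periodic 1-D potential on s ∈ [−180°, 180°): a sum of Gaussians.

    ``terms`` is a list of (height kJ/mol, location °, width °); negative
    heights carve wells.  Periodic continuity holds because each Gaussian is
    summed over its ±360° images.
    """

    terms: list[tuple[float, float, float]] = field(default_factory=list)
    temperature: float = 298.15

    def value(self, s: np.ndarray | float) -> np.ndarray | float:
        s = np.asarray(s, dtype=float)
        out = np.zeros_like(s)
        for h, loc, w in self.terms:
            d0 = minimum_image(s - loc, 360.0)
            for shift in (-360.0, 0.0, 360.0):
                d = d0 + shift
                out = out + h * np.exp(-(d * d) / (2.0 * w * w))
        return out

    def force(self, s: np.ndarray | float) -> np.ndarray | float:
        """−dU/ds in kJ/mol per degree."""
        s = np.asarray(s, dtype=float)
        out = np.zeros_like(s)
        for h, loc, w in self.terms:
            d0 = minimum_image(s - loc, 360.0)
            for shift in (-360.0, 0.0, 360.0):
                d = d0 + shift
                out = out + h * d / (w * w) * np.exp(-(d * d) / (2.0 * w * w))
        return out


def langevin_on_potential(
    potential: ToyPotential,
    dt: float,
    n_steps: int,
    seed: int,
    s0: float | np.ndarray | None = None,
    diffusion: float = 10.0,
    n_walkers: int = 1,
    bias_force=None,
) -> np.ndarray:
    """Overdamped Langevin sampling of the periodic CV, in degrees.

    Euler–Maruyama update ``s += βD·F(s)·dt + √(2D·dt)·ξ`` with D in deg²/fs;
    the stationary distribution is the Boltzmann weight exp(−U/RT).  Returns
    (n_steps+1,) for one walker or (n_steps+1, n_walkers) otherwise.  An
    optional ``bias_force(s)`` callable is added to the systematic force (used
    by the metadynamics engine).
    """
    if dt <= 0 or n_steps < 1:
        raise ValueError("dt must be positive and n_steps >= 1")
    rng = np.random.default_rng(seed)
    beta = 1.0 / (R_KJMOL * potential.temperature)
    if s0 is None:
        s = rng.uniform(-180.0, 180.0, size=n_walkers)
    else:
        s = np.broadcast_to(np.asarray(s0, dtype=float), (n_walkers,)).copy()
    sigma = np.sqrt(2.0 * diffusion * dt)
    out = np.empty((n_steps + 1, n_walkers))
    out[0] = s
    for k in range(n_steps):
        f = potential.force(s)
        if bias_force is not None:
            f = f + bias_force(s)
        s = s + beta * diffusion * f * dt + sigma * rng.standard_normal(n_walkers)
        s = minimum_image(s, 360.0)
        out[k + 1] = s
    return out[:, 0] if n_walkers == 1 else out


# --------------------------------------------------------------------------
# box composition arithmetic


def molality_of_box(n_solute: int, n_water: int) -> float:
    """Solute molality (mol/kg) of a box of ``n_water`` waters."""
    if n_water <= 0:
        raise ValueError("n_water must be positive")
    return n_solute / (n_water * M_WATER * 1e-3)


def cell_edge_from_density(n_water: int, density: float) -> float:
    """Cubic cell edge (Å) holding ``n_water`` waters at ``density`` kg/m³."""
    if density <= 0:
        raise ValueError("density must be positive")
    mass_kg = n_water * M_WATER * 1e-3 / N_AVOGADRO
    return (mass_kg / density) ** (1.0 / 3.0) * 1e10
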