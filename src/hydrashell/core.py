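"""Core data containers shared across the analysis modules.

All containers are plain dataclasses wrapping numpy arrays; they carry their
units implicitly (Å, fs, Debye, cm⁻¹, kJ/mol, degrees — see :mod:`.units`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .units import VALENCE_CHARGE


def minimum_image(delta: np.ndarray, cell_edge: float) -> np.ndarray:
    """Wrap displacement vectors into [-L/2, L/2) per Cartesian component."""
    d = np.asarray(delta, dtype=float)
    return d - cell_edge * np.round(d / cell_edge)


def wrap_positions(pos: np.ndarray, cell_edge: float) -> np.ndarray:
    """Wrap coordinates into [0, L)."""
    return np.mod(pos, cell_edge)


@dataclass
class Frame:
    """One stored trajectory frame: atoms plus Wannier centers in a cubic cell."""

    time: float                      # fs
    cell_edge: float                 # Å
    elements: list[str]
    positions: np.ndarray            # (n_atoms, 3) Å
    centers: np.ndarray              # (n_centers, 3) Å
    wrapped: bool = True

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        self.centers = (
            np.asarray(self.centers, dtype=float).reshape(-1, 3)
            if np.size(self.centers)
            else np.empty((0, 3))
        )
        if self.cell_edge <= 0:
            raise ValueError("cell_edge must be positive")
        if not (np.all(np.isfinite(self.positions)) and np.all(np.isfinite(self.centers))):
            raise ValueError("non-finite coordinates in frame")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    @property
    def n_centers(self) -> int:
        return self.centers.shape[0]


@dataclass
class Trajectory:
    """Time-ordered frames with constant atom/center counts."""

    frames: list[Frame]
    dt: float | None = None          # fs between stored frames

    def __post_init__(self) -> None:
        if self.frames:
            na = self.frames[0].n_atoms
            nc = self.frames[0].n_centers
            for k, f in enumerate(self.frames):
                if f.n_atoms != na or f.n_centers != nc:
                    raise ValueError(f"inconsistent atom/center count at frame {k}")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])

    @property
    def cell_edge(self) -> float:
        return self.frames[0].cell_edge

    @property
    def elements(self) -> list[str]:
        return self.frames[0].elements

    def positions_array(self) -> np.ndarray:
        """(n_frames, n_atoms, 3) stacked atom positions."""
        return np.stack([f.positions for f in self.frames])

    def centers_array(self) -> np.ndarray:
        """(n_frames, n_centers, 3) stacked Wannier-center positions."""
        return np.stack([f.centers for f in self.frames])


@dataclass
class Molecule:
    species: str                     # "water" | "solute" | "other"
    atom_indices: list[int]


@dataclass
class Topology:
    """Molecule membership and valence-charge bookkeeping for one system."""

    molecules: list[Molecule]
    elements: list[str]

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for m in self.molecules:
            for i in m.atom_indices:
                if i in seen:
                    raise ValueError(f"atom {i} assigned to more than one molecule")
                seen.add(i)
        if seen != set(range(len(self.elements))):
            raise ValueError("every atom must belong to exactly one molecule")

    @property
    def n_molecules(self) -> int:
        return len(self.molecules)

    def molecule_of_atom(self) -> np.ndarray:
        out = np.empty(len(self.elements), dtype=int)
        for j, m in enumerate(self.molecules):
            out[m.atom_indices] = j
        return out

    def valence_charge(self, mol_index: int) -> float:
        return float(
            sum(VALENCE_CHARGE[self.elements[i]] for i in self.molecules[mol_index].atom_indices)
        )

    def expected_center_count(self, mol_index: int) -> int:
        """Centers needed for neutrality: valence electrons / 2 (closed shell)."""
        q = self.valence_charge(mol_index)
        if q % 2:
            raise ValueError(f"molecule {mol_index} has odd valence charge {q}")
        return int(q // 2)

    def species_tags(self) -> list[str]:
        return [m.species for m in self.molecules]


@dataclass
class DipoleSeries:
    """Per-molecule dipole vectors on a uniform time grid (Debye)."""

    times: np.ndarray                # (n_t,) fs
    dipoles: np.ndarray              # (n_t, n_mol, 3) D
    tags: list[str] = field(default_factory=list)
    coms: np.ndarray | None = None   # (n_t, n_mol, 3) Å — molecular centers of mass
    cell_edge: float | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.dipoles = np.asarray(self.dipoles, dtype=float)
        if self.dipoles.ndim == 2:
            self.dipoles = self.dipoles[:, None, :]
        if not self.tags:
            self.tags = ["mol"] * self.dipoles.shape[1]
        if len(self.times) >= 2:
            dts = np.diff(self.times)
            if not np.allclose(dts, dts[0], rtol=1e-8, atol=1e-10):
                raise ValueError("DipoleSeries requires a uniform time grid")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def n_molecules(self) -> int:
        return self.dipoles.shape[1]

    def total(self) -> np.ndarray:
        """Total dipole M(t) = Σ_i μ_i(t), shape (n_t, 3)."""
        return self.dipoles.sum(axis=1)


@dataclass
class TCF:
    """Time-correlation function on a uniform lag grid."""

    lags: np.ndarray                 # fs
    values: np.ndarray
    normalized: bool = False
    metadata: dict = field(default_factory=dict)

    @property
    def dt(self) -> float:
        return float(self.lags[1] - self.lags[0])


@dataclass
class Spectrum:
    """Absorption (or cross-absorption) on a uniform wavenumber grid."""

    wavenumbers: np.ndarray          # cm⁻¹, strictly increasing, uniform
    values: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        w = np.asarray(self.wavenumbers, dtype=float)
        if w.size >= 2:
            dw = np.diff(w)
            if np.any(dw <= 0) or not np.allclose(dw, dw[0], rtol=1e-8):
                raise ValueError("wavenumber grid must be uniform and increasing")
        self.wavenumbers = w
        self.values = np.asarray(self.values, dtype=float)

    @property
    def resolution(self) -> float:
        return float(self.wavenumbers[1] - self.wavenumbers[0])


@dataclass
class RadialSpectrum:
    """2-D cross-absorption indexed by wavenumber × radius (signed)."""

    wavenumbers: np.ndarray          # (n_w,) cm⁻¹
    radii: np.ndarray                # (n_r,) Å — shell centers
    values: np.ndarray               # (n_w, n_r)
    metadata: dict = field(default_factory=dict)


@dataclass
class RDFResult:
    """Pair distribution g(r) with running coordination integral."""

    r: np.ndarray                    # Å, bin centers
    g: np.ndarray
    density: float                   # partner number density, Å⁻³
    coordination: np.ndarray         # n(r), running integral
    metadata: dict = field(default_factory=dict)


@dataclass
class HillRecord:
    """One deposited metadynamics Gaussian."""

    time: float                      # fs
    center: float                    # ° (CV value)
    width: float                     # ° (Gaussian σ)
    height: float                    # kJ/mol

    def __post_init__(self) -> None:
        if self.height <= 0:
            raise ValueError("hill height must be positive")
        if self.width <= 0:
            raise ValueError("hill width must be positive")


@dataclass
class FreeEnergyProfile:
    """Free energy on a periodic CV grid, min-shifted to zero."""

    grid: np.ndarray                 # ° in [-180, 180)
    values: np.ndarray               # kJ/mol
    metadata: dict = field(default_factory=dict)

    def shifted(self) -> "FreeEnergyProfile":
        return FreeEnergyProfile(self.grid, self.values - self.values.min(), dict(self.metadata))
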