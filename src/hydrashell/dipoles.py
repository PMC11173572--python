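"""Molecular dipoles from Wannier centers.

The total dipole of a closed-shell system decomposes exactly into molecular
dipoles: each molecule's dipole is the classical sum over its positive nuclei
(valence charges, pseudopotential convention) and its Wannier centers, each
carrying −2e.  Because every molecule is neutral the molecular dipole is
origin independent, provided the molecule is first made whole across the
periodic boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import DipoleSeries, Frame, Topology, Trajectory, minimum_image
from .units import CENTER_CHARGE, EA_TO_DEBYE, VALENCE_CHARGE

_MASS = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999}

#: distance tolerance for nearest-atom ties (Å); ties go to the lower molecule index
TIE_TOL = 1e-9


class AssignmentError(ValueError):
    pass


def assign_centers(
    frame: Frame, topology: Topology, frame_index: int | None = None, validate: bool = True
) -> list[np.ndarray]:
    """Assign each Wannier center to the molecule of its nearest atom.

    Distances use the minimum-image convention; a center equidistant (within
    ``TIE_TOL``) from atoms of several molecules goes to the lowest molecule
    index.  With ``validate`` the per-molecule center count must equal half
    the molecular valence-electron count (4 for water, 15 for the solute).
    """
    mol_of_atom = topology.molecule_of_atom()
    delta = minimum_image(
        frame.centers[:, None, :] - frame.positions[None, :, :], frame.cell_edge
    )
    d = np.linalg.norm(delta, axis=2)                      # (n_centers, n_atoms)
    dmin = d.min(axis=1, keepdims=True)
    candidates = d <= dmin + TIE_TOL
    mol_idx = np.where(candidates, mol_of_atom[None, :], np.iinfo(int).max).min(axis=1)

    out = [np.flatnonzero(mol_idx == j) for j in range(topology.n_molecules)]
    if validate:
        tag = f" (frame {frame_index})" if frame_index is not None else ""
        for j, idx in enumerate(out):
            expected = topology.expected_center_count(j)
            if len(idx) != expected:
                raise AssignmentError(
                    f"molecule {j} ({topology.molecules[j].species}) received "
                    f"{len(idx)} centers, expected {expected}{tag}"
                )
    return out


def molecular_dipole(
    elements: list[str],
    positions: np.ndarray,
    centers: np.ndarray,
    cell_edge: float | None = None,
    charges: np.ndarray | None = None,
) -> np.ndarray:
    """Classical dipole μ = Σ qₙrₙ − 2e Σ r_w of one molecule, in Debye.

    The molecule is made whole by minimum-image chaining from its first atom
    before the sum.  Raises if the valence charge does not balance the
    centers (the dipole would be origin dependent).
    """
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    centers = np.asarray(centers, dtype=float).reshape(-1, 3)
    q = (
        np.asarray(charges, dtype=float)
        if charges is not None
        else np.array([VALENCE_CHARGE[e] for e in elements], dtype=float)
    )
    net = q.sum() + CENTER_CHARGE * len(centers)
    if abs(net) > 1e-9:
        raise ValueError(f"molecule is not neutral (net charge {net:+g} e)")
    ref = positions[0]
    if cell_edge is not None:
        rel_a = minimum_image(positions - ref, cell_edge)
        rel_c = minimum_image(centers - ref, cell_edge)
    else:
        rel_a, rel_c = positions - ref, centers - ref
    mu = (q[:, None] * rel_a).sum(0) + CENTER_CHARGE * rel_c.sum(0)
    return mu * EA_TO_DEBYE


def compute_molecular_dipoles(
    traj: Trajectory,
    topology: Topology,
    assignment: str | list[np.ndarray] = "first-frame",
) -> DipoleSeries:
    """Per-molecule dipole vectors and centers of mass for a whole trajectory.

    ``assignment`` is ``"first-frame"`` (nearest-atom assignment computed once
    and reused — valid while centers stay bonded to their molecule),
    ``"per-frame"`` (recomputed each frame), or an explicit per-molecule list
    of center indices.
    """
    n_mol = topology.n_molecules
    L = traj.cell_edge
    pos = traj.positions_array()
    cen = traj.centers_array()
    nt = traj.n_frames

    if isinstance(assignment, str):
        if assignment == "first-frame":
            assignments = [assign_centers(traj.frames[0], topology, 0)] * nt
        elif assignment == "per-frame":
            assignments = [assign_centers(f, topology, k) for k, f in enumerate(traj.frames)]
        else:
            raise ValueError("assignment must be 'first-frame', 'per-frame' or a list")
    else:
        assignments = [assignment] * nt

    dipoles = np.empty((nt, n_mol, 3))
    coms = np.empty((nt, n_mol, 3))
    per_frame = assignment == "per-frame"

    for j in range(n_mol):
        a_idx = np.asarray(topology.molecules[j].atom_indices)
        el = [topology.elements[i] for i in a_idx]
        q = np.array([VALENCE_CHARGE[e] for e in el], dtype=float)
        m = np.array([_MASS[e] for e in el])
        p = pos[:, a_idx, :]                              # (nt, k, 3)
        ref = p[:, :1, :]
        rel_a = minimum_image(p - ref, L)
        if per_frame:
            rel_c = np.stack(
                [minimum_image(cen[k, assignments[k][j], :] - ref[k], L) for k in range(nt)]
            )
        else:
            c_idx = assignments[0][j]
            if q.sum() + CENTER_CHARGE * len(c_idx) != 0:
                raise AssignmentError(
                    f"molecule {j} not neutral with {len(c_idx)} assigned centers"
                )
            rel_c = minimum_image(cen[:, c_idx, :] - ref, L)
        mu = (q[None, :, None] * rel_a).sum(1) + CENTER_CHARGE * rel_c.sum(1)
        dipoles[:, j, :] = mu * EA_TO_DEBYE
        coms[:, j, :] = np.mod(
            ref[:, 0, :] + (m[None, :, None] * rel_a).sum(1) / m.sum(), L
        )

    return DipoleSeries(
        times=traj.times,
        dipoles=dipoles,
        tags=topology.species_tags(),
        coms=coms,
        cell_edge=L,
    )


@dataclass
class DipoleDistribution:
    """Normalized |μ| histogram with a maximum-likelihood normal fit."""

    bin_edges: np.ndarray            # D
    density: np.ndarray              # integrates to 1
    mean: float | None               # fitted normal mean, D
    std: float | None                # fitted normal σ, D
    fitted: bool
    n_samples: int


def dipole_distribution(
    series: DipoleSeries, tag: str | None = None, bins: int = 50
) -> DipoleDistribution:
    """Distribution of dipole magnitudes for molecules matching ``tag``.

    A degenerate (constant-magnitude) series yields the single-bin histogram
    with the fit skipped and flagged.
    """
    if tag is None:
        sel = np.arange(series.n_molecules)
    else:
        sel = np.flatnonzero(np.array(series.tags) == tag)
        if sel.size == 0:
            raise ValueError(f"no molecules tagged {tag!r}")
    mags = np.linalg.norm(series.dipoles[:, sel, :], axis=2).ravel()
    if mags.size < 100:
        raise ValueError(f"need >= 100 samples for a distribution, got {mags.size}")
    if np.ptp(mags) < 1e-12:
        edges = np.array([mags[0] - 0.5, mags[0] + 0.5])
        return DipoleDistribution(edges, np.array([1.0]), None, None, False, mags.size)
    density, edges = np.histogram(mags, bins=bins, density=True)
    mean, std = stats.norm.fit(mags)
    return DipoleDistribution(edges, density, float(mean), float(std), True, mags.size)
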