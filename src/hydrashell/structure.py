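"""Radial distribution functions, coordination numbers, dihedrals and
intramolecular distance distributions.

RDFs use minimum-image pair histograms normalized by the spherical-shell
volume and the partner number density; the running coordination integral
n(r) = 4πρ∫g(r)r²dr counts partners within a radius, and the first-shell
coordination number integrates g(r) to its first minimum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import RDFResult, Topology, Trajectory, minimum_image


def rdf(
    traj: Trajectory,
    selection_a: np.ndarray,
    selection_b: np.ndarray,
    bin_width: float = 0.02,
    r_max: float | None = None,
) -> RDFResult:
    """Pair distribution g(r) between two atom selections.

    Selections are atom-index arrays; identical selections are self-paired
    without double counting (i≠j ordered pairs, partner density (N−1)/V).
    ``r_max`` defaults to L/2 and may not exceed it (minimum image).
    """
    L = traj.cell_edge
    if r_max is None:
        r_max = L / 2.0
    if r_max > L / 2.0 + 1e-9:
        raise ValueError(f"r_max {r_max} exceeds half the cell edge {L / 2.0}")
    a = np.asarray(selection_a, dtype=int)
    b = np.asarray(selection_b, dtype=int)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty selection")
    same = a.size == b.size and np.array_equal(np.sort(a), np.sort(b))

    edges = np.arange(0.0, r_max + bin_width, bin_width)
    counts = np.zeros(edges.size - 1)
    pos = traj.positions_array()
    for k in range(traj.n_frames):
        delta = minimum_image(pos[k, b][None, :, :] - pos[k, a][:, None, :], L)
        d = np.linalg.norm(delta, axis=2)
        if same:
            d = d[~np.eye(a.size, dtype=bool)]
        else:
            overlap = np.isin(a, b)
            if overlap.any():
                mask = a[:, None] == b[None, :]
                d = d[~mask]
        counts += np.histogram(d.ravel(), bins=edges)[0]

    n_partners = (b.size - 1) if same else b.size
    rho = n_partners / L**3
    shell_vol = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    norm = traj.n_frames * a.size * rho * shell_vol
    g = counts / norm
    coordination = np.cumsum(counts) / (traj.n_frames * a.size)
    r = 0.5 * (edges[1:] + edges[:-1])
    return RDFResult(r=r, g=g, density=rho, coordination=coordination,
                     metadata={"bin_width_A": bin_width, "r_max_A": r_max,
                               "n_frames": traj.n_frames})


def coordination_number(result: RDFResult, bound: str | float = "first-minimum") -> tuple[float, float]:
    """Coordination number n(r_bound) and the bound used.

    ``bound='first-minimum'`` places r_bound at the first local minimum of a
    3-bin moving-average smoothed g(r) after its first maximum; a numeric
    ``bound`` is used directly.  Raises when g(r) has no detectable first
    peak followed by a minimum.
    """
    if isinstance(bound, (int, float)):
        rb = float(bound)
        return float(np.interp(rb, result.r, result.coordination)), rb
    g = np.convolve(result.g, np.ones(3) / 3.0, mode="same")
    peak = None
    for i in range(1, g.size - 1):
        if g[i] > g[i - 1] and g[i] >= g[i + 1] and g[i] > 0.5 * g.max():
            peak = i
            break
    if peak is None:
        raise ValueError("g(r) has no detectable first maximum")
    for i in range(peak + 1, g.size - 1):
        # a true local minimum, or g effectively decayed to zero (isolated
        # first shell with no second peak)
        if g[i] <= g[i - 1] and (g[i] < g[i + 1] or g[i] < 0.01 * g[peak]):
            rb = result.r[i]
            return float(np.interp(rb, result.r, result.coordination)), float(rb)
    raise ValueError("g(r) has no first minimum after its first maximum")


@dataclass
class DihedralSeries:
    """Signed dihedral angle per frame, degrees in [−180, 180)."""

    times: np.ndarray
    angles: np.ndarray               # ° (NaN where degenerate)
    atoms: tuple[int, int, int, int]
    degenerate_frames: np.ndarray    # indices flagged collinear


def dihedral_series(traj: Trajectory, atoms: tuple[int, int, int, int]) -> DihedralSeries:
    """Signed dihedral of an atom quadruple along the trajectory.

    Standard plane-normal convention: the angle between the (1,2,3) and
    (2,3,4) planes, signed by the handedness about the central bond; bond
    vectors use the minimum image.  Collinear geometries are flagged and
    yield NaN.
    """
    if len(set(atoms)) != 4:
        raise ValueError("dihedral requires four distinct atoms")
    L = traj.cell_edge
    pos = traj.positions_array()
    p = pos[:, list(atoms), :]
    b1 = minimum_image(p[:, 1] - p[:, 0], L)
    b2 = minimum_image(p[:, 2] - p[:, 1], L)
    b3 = minimum_image(p[:, 3] - p[:, 2], L)
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = np.linalg.norm(b2, axis=1)
    degenerate = (np.linalg.norm(n1, axis=1) < 1e-10) | (np.linalg.norm(n2, axis=1) < 1e-10)
    x = np.einsum("ij,ij->i", n1, n2)
    y = np.einsum("ij,ij->i", np.cross(n1, n2), b2 / np.where(b2n, b2n, 1.0)[:, None])
    ang = np.degrees(np.arctan2(y, x))
    ang = minimum_image(ang, 360.0)
    ang[degenerate] = np.nan
    return DihedralSeries(times=traj.times, angles=ang, atoms=tuple(atoms),
                          degenerate_frames=np.flatnonzero(degenerate))


def intramolecular_distance_distribution(
    traj: Trajectory,
    topology: Topology,
    atom_pair: tuple[int, int],
    bin_width: float = 0.05,
    r_max: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Normalized histogram of an intramolecular atom–atom distance.

    Returns ``(bin_centers, density)`` with the density integrating to 1.
    Raises when the two atoms belong to different molecules.
    """
    i, j = atom_pair
    mol = topology.molecule_of_atom()
    if mol[i] != mol[j]:
        raise ValueError(f"atoms {i} and {j} belong to different molecules")
    L = traj.cell_edge
    pos = traj.positions_array()
    d = np.linalg.norm(minimum_image(pos[:, j] - pos[:, i], L), axis=1)
    if r_max is None:
        r_max = max(d.max() * 1.2, d.max() + bin_width)
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    density, edges = np.histogram(d, bins=edges, density=True)
    return 0.5 * (edges[1:] + edges[:-1]), density


def hydrogen_bond_fraction(
    traj: Trajectory,
    donor: int,
    hydrogen: int,
    acceptors: np.ndarray,
    distance_cutoff: float = 3.5,
    angle_cutoff: float = 140.0,
) -> float:
    """Fraction of frames with a geometric H-bond from donor–H to any acceptor.

    Criterion (a common convention, configurable): donor–acceptor heavy-atom
    distance < ``distance_cutoff`` Å and donor–H···acceptor angle >
    ``angle_cutoff`` degrees.
    """
    L = traj.cell_edge
    pos = traj.positions_array()
    acc = np.asarray(acceptors, dtype=int)
    da = minimum_image(pos[:, acc, :] - pos[:, donor : donor + 1, :], L)
    d_da = np.linalg.norm(da, axis=2)
    dh = minimum_image(pos[:, hydrogen] - pos[:, donor], L)
    ha = minimum_image(pos[:, acc, :] - pos[:, hydrogen : hydrogen + 1, :], L)
    # donor–H···acceptor angle at H (180° = linear H-bond)
    hd = -dh
    cosang = np.einsum("tac,tc->ta", ha, hd) / (
        np.linalg.norm(ha, axis=2) * np.linalg.norm(hd, axis=1)[:, None]
    )
    ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    bonded = np.any((d_da < distance_cutoff) & (ang > angle_cutoff), axis=1)
    return float(bonded.mean())
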