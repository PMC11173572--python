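"""Readers and writers for trajectories, hills files and spectrum tables.

On-disk dialects:

* Trajectories: (extended) XYZ.  The comment line carries ``cell=<Å>
  time=<fs> frame=<k>``; pseudo-element ``X`` records are Wannier centers and
  may be inline (after the atoms) or in a sidecar XYZ with identical frame
  count.
* Metadynamics hills: PLUMED-HILLS-like whitespace table ``time center sigma
  height`` with ``#! FIELDS`` / ``#! UNITS`` headers.
* Spectra, profiles, RDFs: delimited text with ``#`` unit headers.

All readers reject silently truncated files rather than returning partial
data, and all unit conversions are involutive.
"""

from __future__ import annotations

import os

import numpy as np

from .core import Frame, HillRecord, RadialSpectrum, Spectrum, Trajectory
from .units import HARTREE_TO_KJMOL


class ParseError(ValueError):
    pass


# --------------------------------------------------------------------------
# XYZ trajectories

_CENTER_LABEL = "X"


def write_xyz_trajectory(path: str, traj: Trajectory, centers: str = "inline") -> None:
    """Write a trajectory as XYZ; Wannier centers inline as ``X`` records or
    to ``<path>.centers.xyz`` when ``centers='sidecar'``."""
    if centers not in ("inline", "sidecar", "none"):
        raise ValueError("centers must be 'inline', 'sidecar' or 'none'")
    sidecar = None
    if centers == "sidecar":
        sidecar = open(_sidecar_path(path), "w")
    with open(path, "w") as fh:
        for k, fr in enumerate(traj.frames):
            comment = f"cell={fr.cell_edge:.10g} time={fr.time:.10g} frame={k}"
            n = fr.n_atoms + (fr.n_centers if centers == "inline" else 0)
            fh.write(f"{n}\n{comment}\n")
            for el, p in zip(fr.elements, fr.positions):
                fh.write(f"{el} {p[0]:.10f} {p[1]:.10f} {p[2]:.10f}\n")
            if centers == "inline":
                for p in fr.centers:
                    fh.write(f"{_CENTER_LABEL} {p[0]:.10f} {p[1]:.10f} {p[2]:.10f}\n")
            elif centers == "sidecar":
                sidecar.write(f"{fr.n_centers}\n{comment}\n")
                for p in fr.centers:
                    sidecar.write(f"{_CENTER_LABEL} {p[0]:.10f} {p[1]:.10f} {p[2]:.10f}\n")
    if sidecar is not None:
        sidecar.close()


def _sidecar_path(path: str) -> str:
    root, ext = os.path.splitext(path)
    return f"{root}.centers{ext or '.xyz'}"


def _parse_comment(comment: str) -> dict:
    out = {}
    for token in comment.split():
        if "=" in token:
            key, _, val = token.partition("=")
            try:
                out[key] = float(val)
            except ValueError:
                pass
    return out


def _read_raw_xyz(path: str) -> list[tuple[list[str], np.ndarray, dict]]:
    frames = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i, k = 0, 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError as exc:
            raise ParseError(f"frame {k}: bad atom-count line {lines[i]!r}") from exc
        if i + 1 + n >= len(lines) + 1 and n > 0 and i + 2 + n > len(lines):
            raise ParseError(f"frame {k}: truncated (declared {n} records)")
        meta = _parse_comment(lines[i + 1]) if i + 1 < len(lines) else {}
        if i + 2 + n > len(lines):
            raise ParseError(f"frame {k}: truncated (declared {n} records)")
        els, pos = [], np.empty((n, 3))
        for j in range(n):
            parts = lines[i + 2 + j].split()
            if len(parts) < 4:
                raise ParseError(f"frame {k}: ragged record {lines[i + 2 + j]!r}")
            els.append(parts[0])
            try:
                pos[j] = [float(parts[1]), float(parts[2]), float(parts[3])]
            except ValueError as exc:
                raise ParseError(f"frame {k}: non-numeric coordinate in {lines[i + 2 + j]!r}") from exc
        frames.append((els, pos, meta))
        i += 2 + n
        k += 1
    return frames


def read_xyz_trajectory(
    path: str,
    cell_edge: float | None = None,
    dt: float | None = None,
    sidecar: str | None = None,
) -> Trajectory:
    """Read an (extended-)XYZ trajectory; ``X`` records become Wannier centers.

    Frame times come from the comment line when present, else ``t0 + k·dt``.
    A sidecar centers file, when given, must match the frame count exactly.
    """
    raw = _read_raw_xyz(path)
    if not raw:
        raise ParseError(f"{path}: no frames")
    side = _read_raw_xyz(sidecar) if sidecar else None
    if side is not None and len(side) != len(raw):
        raise ParseError(
            f"sidecar frame count {len(side)} does not match trajectory {len(raw)}"
        )
    ref_order: list[str] | None = None
    frames = []
    for k, (els, pos, meta) in enumerate(raw):
        is_center = np.array([e == _CENTER_LABEL for e in els])
        atoms = pos[~is_center]
        atom_els = [e for e in els if e != _CENTER_LABEL]
        centers = pos[is_center]
        if side is not None:
            centers = np.vstack([centers, side[k][1]]) if centers.size else side[k][1]
        if ref_order is None:
            ref_order = atom_els
        elif atom_els != ref_order:
            raise ParseError(f"frame {k}: inconsistent atom ordering")
        L = meta.get("cell", cell_edge)
        if L is None:
            raise ParseError(f"frame {k}: no cell edge in file and none supplied")
        t = meta.get("time")
        if t is None:
            if dt is None:
                raise ParseError(f"frame {k}: no time in file and no dt supplied")
            t = k * dt
        frames.append(Frame(time=t, cell_edge=float(L), elements=atom_els,
                            positions=atoms, centers=centers))
    times = np.array([f.time for f in frames])
    inferred_dt = float(times[1] - times[0]) if len(times) > 1 else dt
    return Trajectory(frames, dt=inferred_dt)


# --------------------------------------------------------------------------
# hills files

_TIME_UNITS = {"fs": 1.0, "ps": 1000.0}
_ANGLE_UNITS = {"deg": 1.0, "rad": 180.0 / np.pi}
_ENERGY_UNITS = {"kjmol": 1.0, "kj/mol": 1.0, "hartree": HARTREE_TO_KJMOL}


def write_hills(path: str, hills: list[HillRecord]) -> None:
    with open(path, "w") as fh:
        fh.write("#! FIELDS time center sigma height\n")
        fh.write("#! UNITS time=fs center=deg sigma=deg height=kjmol\n")
        for h in hills:
            fh.write(f"{h.time:.10g} {h.center:.10g} {h.width:.10g} {h.height:.10g}\n")


def read_hills(path: str) -> list[HillRecord]:
    """Read a HILLS-dialect file into internal units (fs, °, °, kJ/mol)."""
    units = {"time": "fs", "center": "deg", "sigma": "deg", "height": "kjmol"}
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "UNITS" in line:
                    for token in line.split():
                        if "=" in token:
                            key, _, val = token.partition("=")
                            if key in units:
                                units[key] = val.lower()
                continue
            parts = line.split()
            if len(parts) < 4:
                raise ParseError(f"hills record too short: {line!r}")
            try:
                rows.append([float(x) for x in parts[:4]])
            except ValueError as exc:
                raise ParseError(f"non-numeric hills record: {line!r}") from exc
    for key, table in (("time", _TIME_UNITS), ("center", _ANGLE_UNITS),
                       ("sigma", _ANGLE_UNITS), ("height", _ENERGY_UNITS)):
        if units[key] not in table:
            raise ParseError(f"unknown unit tag {units[key]!r} for {key}")
    ft = _TIME_UNITS[units["time"]]
    fc = _ANGLE_UNITS[units["center"]]
    fs_ = _ANGLE_UNITS[units["sigma"]]
    fe = _ENERGY_UNITS[units["height"]]
    hills = [HillRecord(time=r[0] * ft, center=r[1] * fc, width=r[2] * fs_, height=r[3] * fe)
             for r in rows]
    times = [h.time for h in hills]
    if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
        raise ParseError("hill deposition times are not strictly increasing")
    return hills


# --------------------------------------------------------------------------
# spectrum / table IO


def write_spectrum(path: str, spectrum: Spectrum | RadialSpectrum) -> None:
    """Write a spectrum as delimited text with a unit header.

    1-D spectra: two columns (wavenumber cm⁻¹, value); 2-D radial spectra:
    three columns (wavenumber, radius Å, value), wavenumber-major order.
    """
    with open(path, "w") as fh:
        for key, val in sorted(spectrum.metadata.items()):
            fh.write(f"# {key} = {val}\n")
        if isinstance(spectrum, RadialSpectrum):
            fh.write("# columns: wavenumber_cm-1 radius_A value\n")
            for i, w in enumerate(spectrum.wavenumbers):
                for j, r in enumerate(spectrum.radii):
                    fh.write(f"{w:.10g} {r:.10g} {spectrum.values[i, j]:.12e}\n")
        else:
            fh.write("# columns: wavenumber_cm-1 value\n")
            for w, v in zip(spectrum.wavenumbers, spectrum.values):
                fh.write(f"{w:.10g} {v:.12e}\n")


def read_spectrum(path: str) -> Spectrum | RadialSpectrum:
    meta: dict = {}
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("# ")
                if "=" in body:
                    key, _, val = body.partition("=")
                    meta[key.strip()] = val.strip()
                continue
            rows.append([float(x) for x in line.split()])
    if not rows:
        return Spectrum(wavenumbers=np.empty(0), values=np.empty(0), metadata=meta)
    arr = np.asarray(rows)
    if arr.shape[1] == 2:
        return Spectrum(wavenumbers=arr[:, 0], values=arr[:, 1], metadata=meta)
    wavenumbers = np.unique(arr[:, 0])
    radii = np.unique(arr[:, 1])
    values = arr[:, 2].reshape(len(wavenumbers), len(radii))
    return RadialSpectrum(wavenumbers=wavenumbers, radii=radii, values=values, metadata=meta)


def write_table(path: str, columns: dict[str, np.ndarray], metadata: dict | None = None) -> None:
    """Generic delimited-text table with ``#`` header (RDFs, FES profiles...)."""
    names = list(columns)
    data = np.column_stack([np.asarray(columns[n], dtype=float) for n in names])
    with open(path, "w") as fh:
        for key, val in sorted((metadata or {}).items()):
            fh.write(f"# {key} = {val}\n")
        fh.write("# columns: " + " ".join(names) + "\n")
        for row in data:
            fh.write(" ".join(f"{x:.12e}" for x in row) + "\n")
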