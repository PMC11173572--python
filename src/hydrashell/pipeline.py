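"""End-to-end orchestration: generate → dipoles → spectra → structure →
metadynamics → thermochemistry, from one structured config.

Every defaulted parameter is materialized into the emitted provenance record,
all randomness flows from one root seed via named substreams, and re-running
with the same (config, seed) reproduces the numeric tables byte for byte.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import yaml

from . import __version__
from .dipoles import compute_molecular_dipoles, dipole_distribution
from .io import write_spectrum, write_table, write_xyz_trajectory
from .metadynamics import (
    WTMTDConfig,
    barrier,
    barrier_in_kt,
    equilibrium_constant,
    free_energy_difference,
    reconstruct_fes,
    run_wtmtd,
)
from .spectra import FREE_OH_REFERENCE, band_position, hbond_enthalpy, ir_spectrum, red_shift
from .structure import rdf
from .synthetic import SyntheticBoxSpec, ToyPotential, generate_water_box


@dataclass
class RunConfig:
    """Structured pipeline configuration with explicit units."""

    outdir: str = "hydrashell_run"
    seed: int = 0
    # synthetic box
    n_water: int = 16
    n_solute: int = 0
    cell_edge: float = 12.0          # Å
    n_steps: int = 2000
    dt: float = 2.0                  # fs
    vibrational_modes: list = field(default_factory=lambda: [[3400.0, 0.20], [1650.0, 0.10]])
    base_dipole: float = 1.85        # D
    # analysis toggles
    run_spectra: bool = True
    run_structure: bool = True
    run_metadynamics: bool = False
    # spectral settings
    smoothing: float = 20.0          # cm⁻¹
    resolution: float = 1.0          # cm⁻¹
    prefactor: str = "harmonic"
    oh_band_window: list = field(default_factory=lambda: [3000.0, 3700.0])
    # structure settings
    rdf_bin_width: float = 0.05      # Å
    # metadynamics settings
    mtd_steps: int = 60000
    mtd_dt: float = 1.0              # fs
    mtd_potential: list = field(default_factory=lambda: [[-20.0, -90.0, 30.0], [-10.0, 90.0, 30.0]])
    wtmtd: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


class StageError(RuntimeError):
    pass


def _stage(name: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except Exception as exc:
        raise StageError(f"pipeline stage {name!r} failed: {exc}") from exc


def run_pipeline(config: RunConfig) -> dict:
    """Run the configured stages and write the report bundle to ``outdir``.

    Returns a summary dict (also written as ``thermo.json`` /
    ``provenance.json``).  Deterministic given (config, seed).
    """
    os.makedirs(config.outdir, exist_ok=True)
    streams = np.random.SeedSequence(config.seed).spawn(2)
    box_seed = int(streams[0].generate_state(1)[0] % (2**31))
    mtd_seed = int(streams[1].generate_state(1)[0] % (2**31))

    summary: dict = {}
    provenance = {"package": "hydrashell", "version": __version__,
                  "seed": config.seed, "substream_seeds": {"box": box_seed, "mtd": mtd_seed},
                  "config": asdict(config)}

    needs_box = config.run_spectra or config.run_structure
    if needs_box:
        spec = SyntheticBoxSpec(
            n_water=config.n_water, n_solute=config.n_solute,
            cell_edge=config.cell_edge, n_steps=config.n_steps, dt=config.dt,
            vibrational_modes=[tuple(m) for m in config.vibrational_modes],
            base_dipole=config.base_dipole, seed=box_seed,
        )
        traj, topo = _stage("generate", generate_water_box, spec)
        _stage("write-trajectory", write_xyz_trajectory,
               os.path.join(config.outdir, "trajectory.xyz"), traj)
        series = _stage("dipoles", compute_molecular_dipoles, traj, topo)
        total = series.total()
        write_table(
            os.path.join(config.outdir, "dipoles.tsv"),
            {"time_fs": series.times, "Mx_D": total[:, 0], "My_D": total[:, 1],
             "Mz_D": total[:, 2]},
        )
        dist = dipole_distribution(series, tag="water")
        summary["water_dipole_mean_D"] = dist.mean
        summary["water_dipole_std_D"] = dist.std

    if config.run_spectra:
        spec_ir = _stage(
            "spectrum", ir_spectrum, series,
            prefactor=config.prefactor, resolution=config.resolution,
            smoothing=config.smoothing,
        )
        write_spectrum(os.path.join(config.outdir, "spectrum.tsv"), spec_ir)
        lo, hi = config.oh_band_window
        band = _stage("band", band_position, spec_ir, (lo, hi))
        shift = red_shift(band, FREE_OH_REFERENCE)
        summary["oh_band_cm-1"] = band
        summary["oh_red_shift_cm-1"] = shift
        if shift >= 0:
            summary["hbond_enthalpy_kjmol"] = hbond_enthalpy(shift)

    if config.run_structure:
        o_idx = np.array([i for m in topo.molecules if m.species == "water"
                          for i in m.atom_indices[:1]])
        if o_idx.size >= 2:
            r = _stage("rdf", rdf, traj, o_idx, o_idx, config.rdf_bin_width)
            write_table(
                os.path.join(config.outdir, "rdf_OO.tsv"),
                {"r_A": r.r, "g": r.g, "n": r.coordination},
                metadata=r.metadata,
            )

    if config.run_metadynamics:
        pot = ToyPotential(terms=[tuple(t) for t in config.mtd_potential])
        cfg = WTMTDConfig(**config.wtmtd)
        hills, _ = _stage("wtmtd", run_wtmtd, pot, cfg, config.mtd_steps,
                          config.mtd_dt, mtd_seed)
        fes = _stage("fes", reconstruct_fes, hills, cfg)
        write_table(os.path.join(config.outdir, "fes.tsv"),
                    {"cv_deg": fes.grid, "F_kjmol": fes.values},
                    metadata={k: v for k, v in fes.metadata.items()})
        basin_a, basin_b = (config.mtd_potential[0][1] - 60, config.mtd_potential[0][1] + 60), (
            config.mtd_potential[1][1] - 60, config.mtd_potential[1][1] + 60)
        df = free_energy_difference(fes, basin_b, basin_a)
        summary["mtd_delta_F_kjmol"] = df
        summary["mtd_K"] = equilibrium_constant(df, cfg.temperature)
        summary["mtd_barrier_kjmol"] = barrier(fes, basin_b, basin_a)
        summary["mtd_barrier_kT"] = barrier_in_kt(summary["mtd_barrier_kjmol"], cfg.temperature)

    with open(os.path.join(config.outdir, "thermo.json"), "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    with open(os.path.join(config.outdir, "provenance.json"), "w") as fh:
        json.dump(provenance, fh, indent=1, sort_keys=True, default=str)
    return summary
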