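"""Config I/O (YAML), measurement CSVs, and PSF/XYZ trajectory export.

Trajectories use a fixed-capacity particle table: every point slot of the
state (plus every mesh node) is an atom, so the atom count is constant
across frames and standard molecular viewers can load the files despite
segment birth and death.  Inactive slots are parked at a sentinel position
outside the domain.  On-disk units are micrometres and seconds.
"""

from __future__ import annotations

import csv
import dataclasses
from pathlib import Path

import numpy as np
import yaml

from .engine import Scenario
from .errors import ConfigError
from .measurement import MeasurementRecord
from .params import ParameterSet, RegionSet, build_reference_config
from .state import SystemState

SENTINEL_UM = (-1.0, -1.0, -1.0)
SPECIES_CODES = {0: "ACT", 1: "ACP", 2: "ARP", 3: "MOT", 4: "SUB", -1: "OFF"}


# ---------------------------------------------------------------------------
# configuration files
# ---------------------------------------------------------------------------

def save_config(path, params: ParameterSet,
                regions: RegionSet | None = None,
                scenario: Scenario | None = None) -> None:
    """Write a structured YAML config: [parameters], [regions], [scenario],
    [output], [seed], plus a provenance map for documentation."""
    regions = regions or RegionSet()
    doc = {
        "parameters": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in params.items()},
        "provenance": {k: params.provenance(k) for k, _ in params.items()},
        "regions": dataclasses.asdict(regions),
        "scenario": {
            "duration": scenario.duration if scenario else 20.0,
            "flow_every": scenario.flow_every if scenario else 2.0,
            "density_every": scenario.density_every if scenario else 1.0,
            "label": scenario.label if scenario else "scenario",
        },
        "output": {"frame_every": (scenario.frame_every if scenario
                                   else None)},
        "seed": scenario.seed if scenario else 0,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_config(path) -> tuple[ParameterSet, RegionSet, Scenario]:
    """Lossless counterpart of :func:`save_config`; unknown keys are
    rejected with the offending name."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    known = {"parameters", "provenance", "regions", "scenario", "output",
             "seed"}
    unknown = set(doc) - known
    if unknown:
        raise ConfigError(f"unknown config section(s): {sorted(unknown)}")
    pvals = dict(doc.get("parameters") or {})
    params = build_reference_config(**pvals)
    rdoc = dict(doc.get("regions") or {})
    try:
        regions = RegionSet(**{k: (tuple(v) if isinstance(v, list) else v)
                               for k, v in rdoc.items()})
    except TypeError as exc:
        raise ConfigError(f"bad regions section: {exc}") from exc
    sdoc = dict(doc.get("scenario") or {})
    odoc = dict(doc.get("output") or {})
    scenario = Scenario(
        duration=float(sdoc.get("duration", 20.0)),
        flow_every=float(sdoc.get("flow_every", 2.0)),
        density_every=float(sdoc.get("density_every", 1.0)),
        label=str(sdoc.get("label", "scenario")),
        frame_every=odoc.get("frame_every"),
        seed=int(doc.get("seed", 0)),
        base=params, regions=regions)
    return params, regions, scenario


# ---------------------------------------------------------------------------
# trajectory export
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class TrajectoryBundle:
    """Fixed-capacity particle table + coordinate frames (um)."""

    species: np.ndarray          # (n_atoms,) int codes into SPECIES_CODES
    bonds: list                  # (i, j) pairs at bundle creation
    frames: list                 # list of (time, coords (n_atoms, 3))

    @property
    def n_atoms(self) -> int:
        return self.species.shape[0]


def species_codes(state: SystemState) -> np.ndarray:
    """Per-point species code (actin/acp/arp/motor); -1 for empty slots."""
    codes = np.full(state.x.shape[0], -1, dtype=np.int64)
    codes[state.filid >= 0] = 0
    for arr, code in ((state.acp_pts, 1), (state.arp_pts, 2),
                      (state.mot_pts, 3)):
        pts = arr[arr >= 0]
        codes[pts] = code
    codes[state.active == 0] = -1
    return codes


def bundle_from_frames(state: SystemState, frames: list) -> TrajectoryBundle:
    """Build a trajectory bundle from engine frames (+ mesh nodes)."""
    codes = species_codes(state)
    n_mesh = state.mx.shape[0]
    species = np.concatenate([codes, np.full(n_mesh, 4, dtype=np.int64)])
    bonds = []
    for p in np.flatnonzero(state.filid >= 0):
        q = int(state.nxt[p])
        if q >= 0:
            bonds.append((int(p), q))
    out_frames = []
    for fr in frames:
        coords = np.vstack([fr["x_um"], state.mx / 1e-6])
        off = fr["active"] == 0
        coords[:off.size][off] = SENTINEL_UM
        out_frames.append((fr["time"], coords))
    if not out_frames:
        coords = np.vstack([state.x_um.copy(), state.mx / 1e-6])
        coords[:state.x.shape[0]][state.active == 0] = SENTINEL_UM
        out_frames.append((state.clock, coords))
    return TrajectoryBundle(species, bonds, out_frames)


def write_trajectory(bundle: TrajectoryBundle, path) -> tuple[Path, Path]:
    """Emit ``<path>.psf`` (topology) and ``<path>.xyz`` (frames, um)."""
    path = Path(path)
    psf = path.with_suffix(".psf")
    xyz = path.with_suffix(".xyz")
    n = bundle.n_atoms
    with open(psf, "w") as fh:
        fh.write("PSF\n\n       1 !NTITLE\n REMARKS lamelliflow trajectory\n\n")
        fh.write(f"{n:8d} !NATOM\n")
        for i in range(n):
            name = SPECIES_CODES.get(int(bundle.species[i]), "OFF")
            fh.write(f"{i + 1:8d} SYS  {1:<4d} SEG  {name:<4s} {name:<4s} "
                     f"{0.0:10.6f} {1.0:13.4f} {0:11d}\n")
        fh.write(f"\n{len(bundle.bonds):8d} !NBOND: bonds\n")
        row = []
        for i, j in bundle.bonds:
            row += [i + 1, j + 1]
            if len(row) == 8:
                fh.write("".join(f"{v:8d}" for v in row) + "\n")
                row = []
        if row:
            fh.write("".join(f"{v:8d}" for v in row) + "\n")
    with open(xyz, "w") as fh:
        for t, coords in bundle.frames:
            fh.write(f"{n}\n")
            fh.write(f"t= {t:.6f} s (coordinates in um)\n")
            for i in range(n):
                name = SPECIES_CODES.get(int(bundle.species[i]), "OFF")
                cx, cy, cz = coords[i]
                fh.write(f"{name} {cx:.6f} {cy:.6f} {cz:.6f}\n")
    return psf, xyz


def read_xyz_frames(path) -> list[tuple[float, np.ndarray]]:
    """Parse a multi-frame XYZ file written by :func:`write_trajectory`."""
    frames = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        n = int(lines[i])
        t = float(lines[i + 1].split()[1])
        coords = np.array([[float(v) for v in ln.split()[1:4]]
                           for ln in lines[i + 2:i + 2 + n]])
        frames.append((t, coords))
        i += 2 + n
    return frames


def write_force_dump(state: SystemState, path) -> None:
    """Diagnostic CSV: per-endpoint positions (um) and deterministic forces
    (pN), plus the total potential energy in the header comment."""
    from .mechanics import total_energy
    F, _ = state.compute_forces(walls=True)
    E = total_energy(state, walls=True)
    with open(path, "w", newline="") as fh:
        fh.write(f"# total_potential_energy_J,{E:.9e}\n")
        w = csv.writer(fh)
        w.writerow(["point", "x_um", "y_um", "z_um",
                    "Fx_pN", "Fy_pN", "Fz_pN", "anchored"])
        for p in np.flatnonzero(state.active == 1):
            x, y, z = state.x[p] / 1e-6
            fx, fy, fz = F[p] / 1e-12
            w.writerow([int(p), f"{x:.6f}", f"{y:.6f}", f"{z:.6f}",
                        f"{fx:.6g}", f"{fy:.6g}", f"{fz:.6g}",
                        int(state.anchored[p])])


# ---------------------------------------------------------------------------
# measurement tables
# ---------------------------------------------------------------------------

def write_measurements(record: MeasurementRecord, outdir) -> None:
    """flow_speed.csv, density_kymograph.csv, cv.csv, substrate_force.csv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "flow_speed.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["time_s", "flow_nm_s"])
        w.writerows(zip(record.flow_times, record.flow_nm_s))
    with open(outdir / "cv.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["time_s", "cv"])
        w.writerows(zip(record.density_times, record.cv))
    with open(outdir / "substrate_force.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["time_s", "force_pN", "n_links"])
        w.writerows(zip(record.force_times, record.force_pN, record.n_links))
    with open(outdir / "density_kymograph.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["time_s"] + [f"bin{i}" for i in range(40)])
        for t, prof in zip(record.density_times, record.density_profiles):
            w.writerow([t] + list(np.asarray(prof)))
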