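"""File IO: GRO-style snapshots (via MDAnalysis) and trajectory files.

Trajectories are stored as NumPy archives (.npz) carrying positions,
velocities, boxes, times, the integrator config hash and the seed; a
columnar text export is available for interoperability.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .engine import Frame, Trajectory
from .topology import BeadTopology

__all__ = ["write_gro", "read_gro", "save_trajectory", "load_trajectory",
           "write_trajectory_text"]


def write_gro(topology: BeadTopology, frame: Frame, path,
              title: str = "amphimem snapshot") -> None:
    import MDAnalysis as mda
    n = topology.n_beads
    u = mda.Universe.empty(n, n_residues=topology.n_molecules,
                           atom_resindex=[b.molecule for b in topology.beads],
                           trajectory=True)
    u.add_TopologyAttr("names", [b.name for b in topology.beads])
    u.add_TopologyAttr("resnames",
                       [lab[:4].upper() or "MOL" for lab in topology.molecule_labels])
    u.add_TopologyAttr("resids", list(range(1, topology.n_molecules + 1)))
    u.atoms.positions = frame.positions * 10.0  # nm -> Angstrom
    u.dimensions = [frame.box[0] * 10, frame.box[1] * 10, frame.box[2] * 10,
                    90.0, 90.0, 90.0]
    u.atoms.write(str(path))


def read_gro(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a GRO file; returns (positions nm, box nm)."""
    import MDAnalysis as mda
    u = mda.Universe(str(path))
    return (u.atoms.positions / 10.0).astype(float), \
        (u.dimensions[:3] / 10.0).astype(float)


def save_trajectory(traj: Trajectory, path) -> None:
    np.savez_compressed(
        Path(path),
        positions=np.stack([f.positions for f in traj.frames]),
        velocities=np.stack([f.velocities for f in traj.frames]),
        boxes=np.stack([f.box for f in traj.frames]),
        times=traj.times,
        config_hash=np.array(traj.provenance.get("config_hash", ""), dtype="U32"),
        seed=np.array(traj.provenance.get("seed", 0)),
        log_columns=np.array(list(traj.log.columns), dtype="U32"),
        log_values=traj.log.to_numpy(float),
    )


def load_trajectory(path) -> Trajectory:
    import pandas as pd
    with np.load(Path(path)) as z:
        frames = [Frame(p, v, b, t) for p, v, b, t in
                  zip(z["positions"], z["velocities"], z["boxes"], z["times"])]
        log = pd.DataFrame(z["log_values"], columns=list(z["log_columns"]))
        prov = {"config_hash": str(z["config_hash"]), "seed": int(z["seed"])}
    return Trajectory(frames, log, prov)


def write_trajectory_text(traj: Trajectory, path) -> None:
    """Columnar text export: one block per frame, documented in-line."""
    with open(path, "w") as fh:
        fh.write("# amphimem trajectory (text export)\n")
        fh.write(f"# config_hash {traj.provenance.get('config_hash', '')}\n")
        fh.write(f"# seed {traj.provenance.get('seed', 0)}\n")
        fh.write("# columns: bead_index x y z vx vy vz (nm, nm/ps)\n")
        for f in traj.frames:
            fh.write(f"@frame time={f.time:.6g} "
                     f"box={f.box[0]:.6g},{f.box[1]:.6g},{f.box[2]:.6g}\n")
            for i, (p, v) in enumerate(zip(f.positions, f.velocities)):
                fh.write(f"{i} {p[0]:.6f} {p[1]:.6f} {p[2]:.6f} "
                         f"{v[0]:.6f} {v[1]:.6f} {v[2]:.6f}\n")
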