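"""Deterministic constructors for simulated systems.

Builds a lamellar DPPC bilayer (two leaflets on a lattice at a chosen area
per lipid), solvates it with CG water (one bead = four real waters),
replaces waters with Na+/Cl- to reach a salt concentration, and places a
single amphiphile at a height above the bilayer.  The published system is
512 DPPC with ~20,000 CG waters and 120 mM NaCl; the test fixture is a
128-lipid scaled replica.  All builders are pure functions of (spec, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .engine import Frame, System
from .library import build_molecule_topology, generate_conformer
from .topology import BeadTopology

__all__ = ["SystemSpec", "GeometryError", "PackingError", "build_bilayer",
           "solvate", "add_ions", "place_am", "build_system", "PRESETS"]

#: one CG water bead represents four real waters (molarity arithmetic)
WATERS_PER_BEAD = 4
#: molar concentration of pure water, mol/L
WATER_MOLARITY = 55.5


class GeometryError(ValueError):
    pass


class PackingError(ValueError):
    pass


@dataclass(frozen=True)
class SystemSpec:
    n_lipids: int = 128
    area_per_lipid: float = 0.64        # nm^2
    n_waters: int | str = "fill"        # CG water beads, or "fill"
    salt_conc: float = 120.0            # mM
    am_species: str | None = None
    am_height: float = 7.0              # nm above bilayer midplane
    box_z: float | None = None          # nm; default sized from contents
    thickness: float = 4.0              # initial phosphate-plane separation, nm
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lipids % 2:
            raise ValueError("n_lipids must be even (two leaflets)")
        if self.salt_conc < 0:
            raise ValueError("salt_conc must be >= 0")


PRESETS = {
    # the published system: 512 DPPC, ~20,000 CG waters, 120 mM NaCl
    "paper-full": SystemSpec(n_lipids=512, n_waters=20000, salt_conc=120.0),
    # desk-scale replica used as the test fixture
    "fixture-small": SystemSpec(n_lipids=128, n_waters=1500, salt_conc=120.0),
}


def _bilayer_z_offsets(thickness: float) -> dict[str, float]:
    """Per-role |z| offsets from the midplane for one leaflet.

    The phosphate plane sits at thickness/2; tails interdigitate toward the
    midplane with slightly compressed spacing so the stack fits the target
    thickness.
    """
    zp = thickness / 2.0
    dz = (zp - 0.2) / 5.0   # five stacking levels below PO4: GL + 4 tail beads
    return {"NC3": zp + 0.3, "PO4": zp, "GL": zp - dz,
            "tail": dz}  # handled specially below


def build_bilayer(spec: SystemSpec) -> tuple[BeadTopology, Frame]:
    """Two leaflets of n_lipids/2 DPPC each on a square lattice.

    Head groups point outward (+z / -z), tails inward; phosphate planes are
    constructed ``spec.thickness`` apart.  Deterministic per seed (the seed
    only jitters in-plane placements).
    """
    n_leaf = spec.n_lipids // 2
    n_side = math.ceil(math.sqrt(n_leaf))
    a = math.sqrt(spec.area_per_lipid)
    box_xy = n_side * a
    z_extra = 2.0 * (spec.am_height + 2.0) if spec.am_species else 5.0
    box_z = spec.box_z if spec.box_z is not None else spec.thickness + z_extra
    if box_z < spec.thickness + 2.0:
        raise GeometryError(f"box z {box_z} nm too small for a "
                            f"{spec.thickness} nm bilayer")
    box = np.array([box_xy, box_xy, box_z])
    rng = np.random.default_rng(spec.seed)

    mono = build_molecule_topology("DPPC")
    roles = [b.role for b in mono.beads]
    off = _bilayer_z_offsets(spec.thickness)
    zp = spec.thickness / 2.0
    dz = (zp - 0.2) / 5.0
    # stacking order along |z| (outward -> midplane)
    zlevels = {"NC3": zp + 0.35, "PO4": zp, "GL": zp - dz}
    tail_levels = [zp - 2 * dz, zp - 3 * dz, zp - 4 * dz, zp - 5 * dz]

    top = BeadTopology()
    positions = []
    mid = box_z / 2.0
    count = 0
    for leaflet, sign in ((0, 1.0), (1, -1.0)):
        for cell in range(n_leaf):
            ix, iy = divmod(cell, n_side)
            x0 = (ix + 0.5) * a + 0.03 * a * rng.standard_normal()
            y0 = (iy + 0.5) * a + 0.03 * a * rng.standard_normal()
            tail_ix = {"A": 0, "B": 0}
            for bead, role in zip(mono.beads, roles):
                if role in zlevels:
                    z = zlevels[role]
                else:
                    chain = bead.name[-1]
                    z = tail_levels[tail_ix[chain]]
                    tail_ix[chain] += 1
                dxy = {"NC3": (0.0, 0.0), "PO4": (0.0, 0.0),
                       "GL": (0.16 if bead.name == "GL2" else -0.16, 0.0)}
                ox, oy = dxy.get(role, (0.18 if bead.name.endswith("B") else -0.18, 0.0))
                positions.append((x0 + ox, y0 + oy, mid + sign * z))
            top = top.merge(mono)
            count += 1
    pos = np.array(positions)
    pos[:, :2] %= box[:2]
    frame = Frame(pos, np.zeros_like(pos), box)
    top.metadata.update({"kind": "bilayer", "n_lipids": spec.n_lipids,
                         "midplane_z": mid, "thickness0": spec.thickness,
                         "spec_seed": spec.seed})
    return top, frame


def solvate(topology: BeadTopology, frame: Frame, n_waters: int | str,
            min_dist: float = 0.4, seed: int = 0) -> tuple[BeadTopology, Frame]:
    """Place CG water beads outside the lipid (or solute) exclusion slab.

    Waters go on a jittered cubic grid (spacing 0.48 nm, near liquid CG
    water density) in the free volume; placements closer than ``min_dist``
    nm to an existing bead or to each other are rejected.
    ``n_waters='fill'`` occupies every available site.  Raises
    :class:`PackingError` if an explicit request cannot be met.
    """
    if n_waters == 0:
        return topology, frame
    box = frame.box
    rng = np.random.default_rng(seed)
    spacing = 0.48
    nx = max(int(box[0] / spacing), 1)
    ny = max(int(box[1] / spacing), 1)
    nz = max(int(box[2] / spacing), 1)
    gx, gy, gz = box[0] / nx, box[1] / ny, box[2] / nz
    grid = np.array([[(i + 0.5) * gx, (j + 0.5) * gy, (k + 0.5) * gz]
                     for i in range(nx) for j in range(ny) for k in range(nz)])
    grid += 0.05 * spacing * rng.standard_normal(grid.shape)
    grid %= box
    # keep grid points outside the lipid slab and away from existing beads
    if topology.metadata.get("kind") == "bilayer":
        mid = topology.metadata.get("midplane_z", box[2] / 2.0)
        half = topology.metadata.get("thickness0", 4.0) / 2.0 + 0.45
        grid = grid[np.abs(grid[:, 2] - mid) > half]
    if topology.n_beads:
        from scipy.spatial import cKDTree
        # KD-tree with periodic box handles the pair exclusion efficiently
        tree = cKDTree(frame.positions % box, boxsize=box)
        close = tree.query_ball_point(grid, r=min_dist)
        keep = np.array([len(c) == 0 for c in close])
        grid = grid[keep]
    if n_waters == "fill":
        n_waters = len(grid)
    elif len(grid) < n_waters:
        raise PackingError(f"requested {n_waters} waters; only {len(grid)} "
                           "grid sites available")
    order = rng.permutation(len(grid))
    chosen = grid[order[:n_waters]]
    water = build_molecule_topology("water")
    new_top = topology
    for _ in range(n_waters):
        new_top = new_top.merge(water)
    pos = np.vstack([frame.positions, chosen])
    vel = np.zeros_like(pos)
    out = BeadTopology(new_top.beads, new_top.bonds, new_top.angles,
                       new_top.ring_dihedrals, new_top.molecule_labels,
                       dict(topology.metadata))
    return out, Frame(pos, vel, box.copy(), frame.time)


def add_ions(topology: BeadTopology, frame: Frame, conc_mM: float,
             seed: int = 0) -> tuple[BeadTopology, Frame]:
    """Replace waters by Na+/Cl- to reach ``conc_mM``, neutralizing first.

    Ion pair count derives from the CG water count (4 real waters per bead):
    n_pairs = conc * n_waters * 4 / 55.5 M.  Counterions neutralizing the
    solute's net charge are added before the salt pairs.
    """
    water_mols = topology.molecules_with_label("water")
    net = round(topology.net_charge())
    n_counter = abs(net)
    n_pairs = int(round(conc_mM * 1e-3 * len(water_mols) * WATERS_PER_BEAD
                        / WATER_MOLARITY))
    n_na = n_pairs + (n_counter if net < 0 else 0)
    n_cl = n_pairs + (n_counter if net > 0 else 0)
    if n_na + n_cl == 0:
        return topology, frame
    if n_na + n_cl > len(water_mols):
        raise PackingError(f"need {n_na + n_cl} waters to ionize, "
                           f"have {len(water_mols)}")
    rng = np.random.default_rng(seed)
    picked = rng.choice(len(water_mols), size=n_na + n_cl, replace=False)
    picked_mols = [water_mols[i] for i in picked]
    # ion beads replace the water beads in place: swap bead identity
    na_top = build_molecule_topology("Na").beads[0]
    cl_top = build_molecule_topology("Cl").beads[0]
    beads = list(topology.beads)
    labels = list(topology.molecule_labels)
    for n, mol in enumerate(picked_mols):
        idx = topology.indices(molecule=mol)[0]
        proto = na_top if n < n_na else cl_top
        b = beads[idx]
        beads[idx] = type(b)(name=proto.name, bead_type=proto.bead_type,
                             charge=proto.charge, mass=proto.mass,
                             diameter=proto.diameter, molecule=b.molecule,
                             role="ION")
        labels[mol] = "Na" if n < n_na else "Cl"
    out = BeadTopology(beads, topology.bonds, topology.angles,
                       topology.ring_dihedrals, labels, dict(topology.metadata))
    assert round(out.net_charge()) == 0
    return out, frame


def place_am(topology: BeadTopology, frame: Frame, species: str,
             height: float = 7.0, peg_len: int | None = None,
             reference: str = "midplane", force: bool = False,
             seed: int = 0) -> tuple[BeadTopology, Frame]:
    """Insert one amphiphile with its backbone COM ``height`` nm above the
    bilayer midplane (or above the outer phosphate plane with
    ``reference='phosphate'``); overlapping waters are removed."""
    mid = topology.metadata.get("midplane_z", frame.box[2] / 2.0)
    z_ref = mid
    if reference == "phosphate":
        z_ref = mid + topology.metadata.get("thickness0", 4.0) / 2.0
    z_target = z_ref + height
    if not force and height < topology.metadata.get("thickness0", 4.0) / 2.0:
        raise GeometryError(f"height {height} nm places the amphiphile inside "
                            "the bilayer (pass force=True to override)")
    if not 0.0 <= z_target <= frame.box[2]:
        raise GeometryError(f"target z {z_target:.2f} nm outside box "
                            f"(0, {frame.box[2]:.2f})")
    am = build_molecule_topology(species, peg_len)
    conf = generate_conformer(am, seed=am.metadata.get("geometry_seed", 0))
    bb = am.indices(role="backbone")
    anchor = bb if len(bb) else np.arange(am.n_beads)
    m = am.masses()
    com = np.average(conf[anchor], axis=0, weights=m[anchor])
    conf = conf - com + np.array([frame.box[0] / 2.0, frame.box[1] / 2.0, z_target])
    # reflect (not clip) any overshoot at the box top/bottom so bead
    # spacings survive
    zmax, zmin = frame.box[2] - 0.1, 0.1
    over = conf[:, 2] > zmax
    conf[over, 2] = 2 * zmax - conf[over, 2]
    under = conf[:, 2] < zmin
    conf[under, 2] = 2 * zmin - conf[under, 2]
    conf[:, 2] = np.clip(conf[:, 2], zmin, zmax)

    # displace clashing waters
    from scipy.spatial import cKDTree
    tree = cKDTree(conf % frame.box, boxsize=frame.box)
    clash = set()
    for i, b in enumerate(topology.beads):
        if topology.molecule_labels[b.molecule] == "water":
            if tree.query_ball_point(frame.positions[i] % frame.box, r=0.4):
                clash.add(b.molecule)
    keep_mask = np.array([b.molecule not in clash for b in topology.beads])
    stripped = topology.remove_molecules(clash)
    pos = frame.positions[keep_mask]
    merged = stripped.merge(am)
    merged.metadata.update(topology.metadata)
    merged.metadata["am_molecule"] = merged.n_molecules - 1
    new_pos = np.vstack([pos, conf])
    return merged, Frame(new_pos, np.zeros_like(new_pos), frame.box.copy(),
                         frame.time)


def build_system(spec: SystemSpec) -> tuple[BeadTopology, Frame]:
    """Full deterministic construction: bilayer -> solvent -> ions -> AM."""
    top, frame = build_bilayer(spec)
    if spec.am_species is not None:
        top, frame = place_am(top, frame, spec.am_species, spec.am_height,
                              seed=spec.seed)
    top, frame = solvate(top, frame, spec.n_waters, seed=spec.seed + 1)
    top, frame = add_ions(top, frame, spec.salt_conc, seed=spec.seed + 2)
    return top, frame
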