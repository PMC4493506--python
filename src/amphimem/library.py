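"""Coarse-grained topology library: amphiphilic macromolecules, PEG, DPPC,
water and ions.

The amphiphilic macromolecules (AMs) are carbohydrate-derived: a sugar-acid
backbone acylated with aliphatic arms (parameterized as lipid tails), a
polar or charged terminal head group, and a poly(ethylene glycol) tail of
45 beads (one bead per ethylene-oxide monomer).  The eleven AM species plus
the PEG control form the 12-structure set.  Bead-level connectivity beyond
the published class legend is a best-effort reconstruction, documented per
species below; stereoisomer pairs share an identical topology and differ
only in their stereo tag and equilibrium-geometry seed, which drives the
conformer generator (exposed vs. caged charge presentation).
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field

import numpy as np

from .forcefield import AngleParam, BondParam, MASS_RING, MASS_STD
from .topology import Bead, BeadTopology

__all__ = ["AM_SPECIES", "SPECIES", "build_molecule_topology", "generate_conformer",
           "load_structure_library"]

# bonded defaults: standard CG bond and the linear-chain angle
BOND = BondParam(0.47, 1250.0)
ANGLE_LINEAR = AngleParam(180.0, 25.0)
ANGLE_GLYCEROL = AngleParam(120.0, 25.0)
# PEG bonded parameters (shipped values; one bead per ethylene-oxide unit)
PEG_BOND = BondParam(0.33, 7000.0)
PEG_ANGLE = AngleParam(130.0, 50.0)
PEG_MASS = 44.0
RING_BOND = BondParam(0.30, 5000.0)
RING_IMPROPER_K = 500.0  # kJ/mol/rad^2, keeps 4-bead rings planar
DEFAULT_PEG_LEN = 45


@dataclass(frozen=True)
class AMSpec:
    """Recipe for one AM species."""

    backbone_n: int
    n_arms: int
    arm_len: int
    heads: tuple[tuple[str, float], ...]   # (bead_type, charge) per head bead
    stereo: str
    charge_exposed: bool
    ring: str | None = None                # ring bead type (4 small beads) or None
    note: str = ""


# The eleven AMs.  Naming: leading digit = number of head charges
# (0c neutral, 1c one carboxylate, 1n amine, 2c diacid); M/S and L-/M- mark
# stereoisomer pairs; T = truncated (tartaric) backbone; G = heterocyclic
# arm variant; P = shortened arms; AR = aromatic variant; BM = bulky
# isophthalate diacid head.
AM_SPECIES: dict[str, AMSpec] = {
    "1cM": AMSpec(3, 4, 3, (("Qa", -1.0),), "M", True,
                  note="mucic-acid backbone, exposed carboxylate"),
    "1cS": AMSpec(3, 4, 3, (("Qa", -1.0),), "S", False,
                  note="stereoisomer of 1cM, caged charge"),
    "0cM": AMSpec(3, 4, 3, (("P1", 0.0),), "M", True,
                  note="neutral analog of 1cM"),
    "1nM": AMSpec(3, 4, 3, (("Qd", 1.0),), "M", True,
                  note="amine head (protonated at physiological pH)"),
    "L-1cT": AMSpec(2, 2, 3, (("Qa", -1.0),), "L", True,
                    note="truncated tartaric backbone"),
    "M-1cT": AMSpec(2, 2, 3, (("Qa", -1.0),), "M", False,
                    note="stereoisomer of L-1cT, caged charge"),
    "0cG": AMSpec(3, 2, 3, (("P1", 0.0),), "R", True, ring="SN0",
                  note="neutral, heterocyclic ring in place of two arms"),
    "0cG-L": AMSpec(3, 2, 3, (("P1", 0.0),), "L", False, ring="SN0",
                    note="stereoisomer of 0cG"),
    "2cBM": AMSpec(3, 4, 3, (("Qa", -1.0), ("Qa", -1.0)), "M", True, ring="SC4",
                   note="isophthalate diacid head on an aromatic ring"),
    "1cP": AMSpec(3, 4, 2, (("Qa", -1.0),), "M", True,
                  note="shortened aliphatic arms (external test structure)"),
    "1cAR": AMSpec(3, 4, 3, (("Qa", -1.0),), "M", True, ring="SC4",
                   note="aromatic ring variant (external test structure)"),
}

SPECIES = list(AM_SPECIES) + ["PEG", "DPPC", "water", "Na", "Cl"]


def _am_topology(label: str, spec: AMSpec, peg_len: int) -> BeadTopology:
    beads: list[Bead] = []
    bonds: list = []
    angles: list = []
    dihs: list = []

    def add(name, btype, charge=0.0, role="", mass=None, diameter=0.47):
        mass = mass if mass is not None else (MASS_RING if diameter == 0.43 else MASS_STD)
        beads.append(Bead(name=name, bead_type=btype, charge=charge, mass=mass,
                          diameter=diameter, molecule=0, role=role))
        return len(beads) - 1

    bb = [add(f"BB{i+1}", "N0", role="backbone") for i in range(spec.backbone_n)]
    for a, b in zip(bb, bb[1:]):
        bonds.append((a, b, BOND))

    head_ids = []
    ring_ids = []
    if spec.ring is not None:
        attach = bb[0] if label == "2cBM" else bb[min(1, len(bb) - 1)]
        ring_ids = [add(f"R{i+1}", spec.ring, role="ring", diameter=0.43)
                    for i in range(4)]
        for i in range(4):
            bonds.append((ring_ids[i], ring_ids[(i + 1) % 4], RING_BOND))
        bonds.append((ring_ids[0], ring_ids[2],
                      BondParam(RING_BOND.r0 * math.sqrt(2.0), RING_BOND.k)))
        dihs.append((*ring_ids, 0.0, RING_IMPROPER_K))
        bonds.append((ring_ids[0], attach, BOND))
    if label == "2cBM":
        # the two carboxylates sit on the ring, meta to each other
        for h, rpos in zip(spec.heads, (1, 3)):
            hid = add(f"HD{len(head_ids)+1}", h[0], charge=h[1], role="head")
            bonds.append((hid, ring_ids[rpos], BOND))
            head_ids.append(hid)
    else:
        for h in spec.heads:
            hid = add(f"HD{len(head_ids)+1}", h[0], charge=h[1], role="head")
            bonds.append((hid, bb[0], BOND))
            head_ids.append(hid)

    # aliphatic arms, distributed round-robin over backbone beads
    for arm in range(spec.n_arms):
        attach = bb[arm % len(bb)]
        prev = attach
        chain = []
        for seg in range(spec.arm_len):
            cid = add(f"A{arm+1}C{seg+1}", "C1", role="arm")
            bonds.append((prev, cid, BOND))
            chain.append(cid)
            prev = cid
        trip = [attach] + chain
        for i in range(len(trip) - 2):
            angles.append((trip[i], trip[i + 1], trip[i + 2], ANGLE_LINEAR))

    # PEG tail off the last backbone bead
    prev = bb[-1]
    peg = []
    for i in range(peg_len):
        pid = add(f"PEG{i+1}", "N0", role="peg", mass=PEG_MASS)
        bonds.append((prev, pid, PEG_BOND if i > 0 else BOND))
        peg.append(pid)
        prev = pid
    for i in range(len(peg) - 2):
        angles.append((peg[i], peg[i + 1], peg[i + 2], PEG_ANGLE))

    top = BeadTopology(beads, bonds, angles, dihs, [label],
                       metadata={"species": label, "stereo": spec.stereo,
                                 "charge_exposed": spec.charge_exposed,
                                 "geometry_seed": zlib.crc32(
                                     f"{label}:{spec.stereo}".encode()) % (2 ** 16),
                                 "head_roles": ["head"], "note": spec.note})
    return top


def _peg_topology(peg_len: int) -> BeadTopology:
    beads = [Bead(name=f"PEG{i+1}", bead_type="N0", mass=PEG_MASS, molecule=0,
                  role="peg") for i in range(peg_len)]
    bonds = [(i, i + 1, PEG_BOND) for i in range(peg_len - 1)]
    angles = [(i, i + 1, i + 2, PEG_ANGLE) for i in range(peg_len - 2)]
    return BeadTopology(beads, bonds, angles, [], ["PEG"],
                        metadata={"species": "PEG", "stereo": "-",
                                  "charge_exposed": False, "geometry_seed": 0})


def _dppc_topology() -> BeadTopology:
    names = ["NC3", "PO4", "GL1", "GL2",
             "C1A", "C2A", "C3A", "C4A", "C1B", "C2B", "C3B", "C4B"]
    types = ["Q0", "Qa", "Na", "Na"] + ["C1"] * 8
    charges = [1.0, -1.0] + [0.0] * 10
    roles = ["NC3", "PO4", "GL", "GL"] + ["tail"] * 8
    beads = [Bead(name=n, bead_type=t, charge=q, molecule=0, role=r)
             for n, t, q, r in zip(names, types, charges, roles)]
    i = {n: k for k, n in enumerate(names)}
    bonds = [(i["NC3"], i["PO4"], BOND), (i["PO4"], i["GL1"], BOND),
             (i["GL1"], i["GL2"], BOND), (i["GL1"], i["C1A"], BOND),
             (i["C1A"], i["C2A"], BOND), (i["C2A"], i["C3A"], BOND),
             (i["C3A"], i["C4A"], BOND), (i["GL2"], i["C1B"], BOND),
             (i["C1B"], i["C2B"], BOND), (i["C2B"], i["C3B"], BOND),
             (i["C3B"], i["C4B"], BOND)]
    angles = [(i["PO4"], i["GL1"], i["GL2"], ANGLE_GLYCEROL),
              (i["PO4"], i["GL1"], i["C1A"], ANGLE_LINEAR),
              (i["GL1"], i["C1A"], i["C2A"], ANGLE_LINEAR),
              (i["C1A"], i["C2A"], i["C3A"], ANGLE_LINEAR),
              (i["C2A"], i["C3A"], i["C4A"], ANGLE_LINEAR),
              (i["GL2"], i["C1B"], i["C2B"], ANGLE_LINEAR),
              (i["C1B"], i["C2B"], i["C3B"], ANGLE_LINEAR),
              (i["C2B"], i["C3B"], i["C4B"], ANGLE_LINEAR)]
    return BeadTopology(beads, bonds, angles, [], ["DPPC"])


def build_molecule_topology(species: str, peg_len: int | None = None) -> BeadTopology:
    """Build the validated single-molecule topology for a library species.

    ``peg_len`` (default 45 -- the truncated tail used to keep the systems
    tractable) applies to AM species and the PEG control.
    """
    if species in AM_SPECIES:
        return _am_topology(species, AM_SPECIES[species],
                            DEFAULT_PEG_LEN if peg_len is None else peg_len)
    if species == "PEG":
        return _peg_topology(DEFAULT_PEG_LEN if peg_len is None else peg_len)
    if species == "DPPC":
        return _dppc_topology()
    if species == "water":
        return BeadTopology([Bead(name="W", bead_type="P4", molecule=0, role="W")],
                            [], [], [], ["water"])
    if species == "Na":
        return BeadTopology([Bead(name="NA", bead_type="Qd", charge=1.0,
                                  molecule=0, role="ION")], [], [], [], ["Na"])
    if species == "Cl":
        return BeadTopology([Bead(name="CL", bead_type="Qa", charge=-1.0,
                                  molecule=0, role="ION")], [], [], [], ["Cl"])
    raise KeyError(f"unknown species {species!r}; known: {SPECIES}")


def generate_conformer(top: BeadTopology, seed: int | None = None) -> np.ndarray:
    """Deterministic low-energy-style conformer for a single AM/PEG molecule.

    Geometry encodes the stereochemistry-driven charge presentation: for
    charge-exposed species the aliphatic arms splay away from the head
    (charge solvent-accessible); for caged stereoisomers the arms fold
    around the head group.  Positions in nm, molecule roughly centered on
    its backbone.
    """
    meta = top.metadata
    if seed is None:
        seed = int(meta.get("geometry_seed", 0))
    rng = np.random.default_rng(seed)
    pos = np.zeros((top.n_beads, 3))
    bb = top.indices(role="backbone")
    heads = top.indices(role="head")
    ring = top.indices(role="ring")
    exposed = bool(meta.get("charge_exposed", True))

    for n, i in enumerate(bb):
        pos[i] = (0.47 * n, 0.0, 0.0)
    head_dir = np.array([-1.0, 0.0, 0.0])
    for n, i in enumerate(heads):
        pos[i] = (pos[bb[0]] if len(bb) else 0.0) + head_dir * 0.47 * (n + 1)
    if len(ring):
        anchor = pos[bb[0]] if len(bb) else np.zeros(3)
        r0 = RING_BOND.r0 / math.sqrt(2.0)
        # between the lateral arm directions, clear of arms and head
        ring_center = anchor + 0.75 * np.array([0.0, math.cos(math.pi / 4),
                                                math.sin(math.pi / 4)])
        for n, i in enumerate(ring):
            ang = math.pi / 2 * n
            pos[i] = ring_center + r0 * np.array([math.cos(ang), math.sin(ang), 0.0])

    # arms: chains grouped by name prefix A<k>
    arm_groups: dict[str, list[int]] = {}
    for i in top.indices(role="arm"):
        key = top.beads[i].name.split("C")[0]
        arm_groups.setdefault(key, []).append(int(i))
    head_pos = pos[heads[0]] if len(heads) else np.zeros(3)
    for k, (key, chain) in enumerate(sorted(arm_groups.items())):
        phi = 2.0 * math.pi * k / max(len(arm_groups), 1)
        lateral = np.array([0.0, math.cos(phi), math.sin(phi)])
        if exposed:
            # splay outward, tilted away from the head (+x hemisphere)
            direction = lateral + np.array([0.7, 0.0, 0.0])
        else:
            # fold back over the head group, caging the charge
            direction = 0.55 * lateral + np.array([-1.0, 0.0, 0.0])
        direction /= np.linalg.norm(direction)
        # attachment bead: first bonded partner of the chain root
        root = chain[0]
        attach = next(a if b == root else b for a, b, _ in top.bonds
                      if root in (a, b) and (a != root or b != root) and
                      (top.beads[a].role != "arm" or top.beads[b].role != "arm"))
        base = pos[attach]
        for n, i in enumerate(chain):
            pos[i] = base + direction * 0.47 * (n + 1)

    peg = top.indices(role="peg")
    if len(peg):
        start = pos[bb[-1]] if len(bb) else np.zeros(3)
        prev = start
        # gentle upward drift: a compact coil pointing away from the
        # membrane side, so the molecule stays smaller than small boxes
        drift = np.array([0.0, 0.0, 0.25])
        body = [pos[k] for k in range(top.n_beads)
                if top.beads[k].role != "peg"]
        placed: list[np.ndarray] = list(body)
        for i in peg:
            # biased self-avoiding walk: retry steps clashing (< 0.31 nm)
            # with any already-placed non-adjacent bead of the molecule;
            # keep the best candidate seen if none clears
            best, best_clearance = None, -1.0
            for _ in range(60):
                step = drift + 0.8 * rng.standard_normal(3)
                step /= np.linalg.norm(step)
                cand = prev + PEG_BOND.r0 * step
                others = placed[:-1] if len(placed) > len(body) else placed
                clearance = np.inf if not others else float(np.min(
                    np.linalg.norm(np.asarray(others) - cand, axis=1)))
                if clearance > best_clearance:
                    best, best_clearance = cand, clearance
                if clearance > 0.31:
                    break
            prev = best
            pos[i] = prev
            placed.append(best)
    return pos


def load_structure_library(peg_len: int | None = None) -> dict[str, BeadTopology]:
    """The 12-structure macromolecule set (11 AMs + the PEG control)."""
    return {s: build_molecule_topology(s, peg_len) for s in list(AM_SPECIES) + ["PEG"]}
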