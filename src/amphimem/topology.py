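"""Bead topologies: containers, validation and the structured-text format.

A :class:`BeadTopology` holds beads with molecule membership and role tags,
harmonic bonds and cosine-harmonic angles, and improper "ring" dihedrals
that keep small-bead ring structures planar.

The on-disk format is a plain-text file with ``[beads]``, ``[bonds]``,
``[angles]`` and ``[dihedrals]`` sections; the reader/writer round-trips
losslessly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .forcefield import AngleParam, BeadSpec, BondParam

__all__ = ["Bead", "BeadTopology", "validate_topology"]


@dataclass
class Bead(BeadSpec):
    """A BeadSpec placed inside a system: molecule membership plus a role tag
    (e.g. head / backbone / arm / peg / NC3 / PO4 / GL / tail / W / ion)."""

    molecule: int = 0
    role: str = ""


@dataclass
class BeadTopology:
    beads: list[Bead] = field(default_factory=list)
    bonds: list[tuple[int, int, BondParam]] = field(default_factory=list)
    angles: list[tuple[int, int, int, AngleParam]] = field(default_factory=list)
    # improper dihedrals (i, j, k, l, xi0_deg, k_kJ): ring planarity restraints
    ring_dihedrals: list[tuple[int, int, int, int, float, float]] = field(default_factory=list)
    molecule_labels: list[str] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    # -- basic queries ----------------------------------------------------
    @property
    def n_beads(self) -> int:
        return len(self.beads)

    @property
    def n_molecules(self) -> int:
        return len(self.molecule_labels)

    def masses(self) -> np.ndarray:
        return np.array([b.mass for b in self.beads])

    def charges(self) -> np.ndarray:
        return np.array([b.charge for b in self.beads])

    def bead_types(self) -> list[str]:
        return [b.bead_type for b in self.beads]

    def net_charge(self) -> float:
        return float(self.charges().sum())

    def indices(self, *, role: str | None = None, molecule: int | None = None,
                label: str | None = None) -> np.ndarray:
        """Bead indices filtered by role tag, molecule index and/or molecule label."""
        out = []
        for i, b in enumerate(self.beads):
            if role is not None and b.role != role:
                continue
            if molecule is not None and b.molecule != molecule:
                continue
            if label is not None and self.molecule_labels[b.molecule] != label:
                continue
            out.append(i)
        return np.array(out, dtype=np.int64)

    def molecules_with_label(self, label: str) -> list[int]:
        return [m for m, lab in enumerate(self.molecule_labels) if lab == label]

    # -- composition ------------------------------------------------------
    def merge(self, other: "BeadTopology") -> "BeadTopology":
        """Concatenate two topologies (bead and molecule indices re-offset)."""
        off = self.n_beads
        moff = self.n_molecules
        beads = list(self.beads) + [replace(b, molecule=b.molecule + moff) for b in other.beads]
        bonds = list(self.bonds) + [(i + off, j + off, p) for i, j, p in other.bonds]
        angles = list(self.angles) + [(i + off, j + off, k + off, p)
                                      for i, j, k, p in other.angles]
        dihs = list(self.ring_dihedrals) + [(i + off, j + off, k + off, l + off, x0, kk)
                                            for i, j, k, l, x0, kk in other.ring_dihedrals]
        return BeadTopology(beads, bonds, angles, dihs,
                            self.molecule_labels + other.molecule_labels,
                            {**self.metadata, **other.metadata})

    def remove_molecules(self, molecule_ids: set[int]) -> "BeadTopology":
        """Drop whole molecules (used when solvent is displaced or ionized).

        Only valid for molecules that carry no bonded terms crossing into
        other molecules (always true here).
        """
        keep = [i for i, b in enumerate(self.beads) if b.molecule not in molecule_ids]
        old2new = {old: new for new, old in enumerate(keep)}
        mkeep = [m for m in range(self.n_molecules) if m not in molecule_ids]
        mol2new = {old: new for new, old in enumerate(mkeep)}
        beads = [replace(self.beads[i], molecule=mol2new[self.beads[i].molecule]) for i in keep]
        def remap(idx):
            return tuple(old2new[i] for i in idx)
        bonds = [( *remap((i, j)), p) for i, j, p in self.bonds
                 if i in old2new and j in old2new]
        angles = [( *remap((i, j, k)), p) for i, j, k, p in self.angles
                  if all(x in old2new for x in (i, j, k))]
        dihs = [( *remap((i, j, k, l)), x0, kk) for i, j, k, l, x0, kk in self.ring_dihedrals
                if all(x in old2new for x in (i, j, k, l))]
        labels = [self.molecule_labels[m] for m in mkeep]
        return BeadTopology(beads, bonds, angles, dihs, labels, dict(self.metadata))

    # -- text format -------------------------------------------------------
    def to_text(self) -> str:
        lines = ["[beads]",
                 "; index name type charge mass diameter molecule role"]
        for i, b in enumerate(self.beads):
            lines.append(f"{i} {b.name} {b.bead_type} {b.charge:.17g} {b.mass:.17g} "
                         f"{b.diameter:.17g} {b.molecule} {b.role or '-'}")
        lines += ["", "[bonds]", "; i j r0 k"]
        for i, j, p in self.bonds:
            lines.append(f"{i} {j} {p.r0:.17g} {p.k:.17g}")
        lines += ["", "[angles]", "; i j k theta0 k"]
        for i, j, k, p in self.angles:
            lines.append(f"{i} {j} {k} {p.theta0:.17g} {p.k:.17g}")
        lines += ["", "[dihedrals]", "; i j k l xi0 k (improper)"]
        for i, j, k, l, x0, kk in self.ring_dihedrals:
            lines.append(f"{i} {j} {k} {l} {x0:.17g} {kk:.17g}")
        lines += ["", "[molecules]", "; index label"]
        for m, lab in enumerate(self.molecule_labels):
            lines.append(f"{m} {lab}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "BeadTopology":
        section = None
        beads, bonds, angles, dihs = [], [], [], []
        labels: dict[int, str] = {}
        for raw in text.splitlines():
            line = raw.split(";", 1)[0].strip()
            if not line:
                continue
            if line.startswith("["):
                section = line.strip("[]").lower()
                continue
            tok = line.split()
            if section == "beads":
                beads.append(Bead(name=tok[1], bead_type=tok[2], charge=float(tok[3]),
                                  mass=float(tok[4]), diameter=float(tok[5]),
                                  molecule=int(tok[6]),
                                  role="" if tok[7] == "-" else tok[7]))
            elif section == "bonds":
                bonds.append((int(tok[0]), int(tok[1]),
                              BondParam(float(tok[2]), float(tok[3]))))
            elif section == "angles":
                angles.append((int(tok[0]), int(tok[1]), int(tok[2]),
                               AngleParam(float(tok[3]), float(tok[4]))))
            elif section == "dihedrals":
                dihs.append((int(tok[0]), int(tok[1]), int(tok[2]), int(tok[3]),
                             float(tok[4]), float(tok[5])))
            elif section == "molecules":
                labels[int(tok[0])] = tok[1]
            else:
                raise ValueError(f"unknown topology section {section!r}")
        mol_labels = [labels[m] for m in sorted(labels)]
        return cls(beads, bonds, angles, dihs, mol_labels)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_text())

    @classmethod
    def load(cls, path) -> "BeadTopology":
        with open(path) as fh:
            return cls.from_text(fh.read())


def validate_topology(t: BeadTopology) -> list[str]:
    """Report structural violations (empty list means valid).

    Checks: bond/angle/dihedral indices in range and unique, Q-beads with
    zero charge (and vice versa), ring dihedrals only among 0.43 nm beads,
    and rings of >= 4 small beads lacking a planarity restraint.
    """
    n = t.n_beads
    report: list[str] = []
    for i, b in enumerate(t.beads):
        if b.bead_class == "Q" and b.charge == 0.0:
            report.append(f"bead {i} ({b.name}): Q class with zero charge")
        if b.bead_class != "Q" and b.charge != 0.0:
            report.append(f"bead {i} ({b.name}): charge on non-Q bead")
        if not 0 <= b.molecule < t.n_molecules:
            report.append(f"bead {i}: molecule index {b.molecule} out of range")
    seen_bonds = set()
    for i, j, _ in t.bonds:
        if not (0 <= i < n and 0 <= j < n) or i == j:
            report.append(f"bond ({i},{j}): dangling or degenerate index")
            continue
        key = (min(i, j), max(i, j))
        if key in seen_bonds:
            report.append(f"bond ({i},{j}): duplicate")
        seen_bonds.add(key)
    seen_ang = set()
    for i, j, k, _ in t.angles:
        if not all(0 <= x < n for x in (i, j, k)) or len({i, j, k}) < 3:
            report.append(f"angle ({i},{j},{k}): dangling or degenerate index")
            continue
        key = (min(i, k), j, max(i, k))
        if key in seen_ang:
            report.append(f"angle ({i},{j},{k}): duplicate")
        seen_ang.add(key)
    restrained = set()
    for i, j, k, l, _, _ in t.ring_dihedrals:
        idx = (i, j, k, l)
        if not all(0 <= x < n for x in idx) or len(set(idx)) < 4:
            report.append(f"dihedral {idx}: dangling or degenerate index")
            continue
        small = all(t.beads[x].diameter == 0.43 for x in idx)
        if not small:
            report.append(f"dihedral {idx}: ring restraint on non-ring (0.47 nm) beads")
        restrained.update(idx)
    # ring detection: connected components of small beads with a cycle
    small_beads = {i for i, b in enumerate(t.beads) if b.is_ring}
    adj: dict[int, set[int]] = {i: set() for i in small_beads}
    ring_bond_count = 0
    for i, j, _ in t.bonds:
        if i in small_beads and j in small_beads:
            adj[i].add(j)
            adj[j].add(i)
            ring_bond_count += 1
    visited: set[int] = set()
    for start in small_beads:
        if start in visited:
            continue
        comp, stack = set(), [start]
        edges = 0
        while stack:
            v = stack.pop()
            if v in comp:
                continue
            comp.add(v)
            edges += len(adj[v])
            stack.extend(adj[v] - comp)
        visited |= comp
        has_cycle = edges // 2 >= len(comp) and len(comp) >= 3
        if has_cycle and len(comp) >= 4 and not comp & restrained:
            report.append(f"ring {sorted(comp)}: no planarity (dihedral) restraint")
    return report
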