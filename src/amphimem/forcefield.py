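"""MARTINI-style coarse-grained force-field primitives.

Bead taxonomy: four classes -- polar (P), nonpolar (N), apolar (C) and
charged (Q) -- with sub-types encoding polarity level (1..5) or hydrogen
bonding capability (d/a/da/0).  Standard beads have an effective diameter of
0.47 nm; small ring beads 0.43 nm.  Nonbonded interactions are a
Lennard-Jones 12-6 potential smoothly shifted to zero between 0.9 and 1.2 nm
and a screened Coulomb potential shifted to zero between 0 and 1.2 nm;
bonds and angles are harmonic (angles in the cosine-harmonic convention).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .constants import F_ELEC

__all__ = [
    "BeadSpec",
    "BondParam",
    "AngleParam",
    "LJPair",
    "NonbondedConfig",
    "InteractionTable",
    "lj_energy_force",
    "coulomb_energy_force",
    "bond_energy_force",
    "angle_energy_force",
    "shift_coefficients",
]

#: standard / small (ring) bead diameters in nm
DIAMETER_STD = 0.47
DIAMETER_RING = 0.43

#: default bead masses in amu (72 = 4 waters; ring beads are lighter)
MASS_STD = 72.0
MASS_RING = 45.0

_TYPE_RE = re.compile(r"^S?(Q(da|d|a|0)|P[1-5]|N(da|d|a|0)|C[1-5])$")


def _validate_type(name: str) -> None:
    if not _TYPE_RE.match(name):
        raise ValueError(f"unknown bead type {name!r}")


@dataclass
class BeadSpec:
    """One coarse-grained interaction site.

    ``bead_type`` is the full sub-typed name (e.g. ``Qa``, ``P4``, ``C1``,
    ring beads prefixed ``S``); ``bead_class`` is the leading class letter.
    """

    name: str
    bead_type: str
    charge: float = 0.0
    mass: float = MASS_STD
    diameter: float = DIAMETER_STD

    def __post_init__(self) -> None:
        _validate_type(self.bead_type)
        if self.diameter not in (DIAMETER_STD, DIAMETER_RING):
            raise ValueError(f"bead diameter must be 0.47 or 0.43 nm, got {self.diameter}")
        if (self.bead_class == "Q") != (self.charge != 0.0):
            raise ValueError(
                f"bead {self.name}: class Q iff charge nonzero "
                f"(type={self.bead_type}, charge={self.charge})"
            )

    @property
    def bead_class(self) -> str:
        return self.bead_type.lstrip("S")[0]

    @property
    def is_ring(self) -> bool:
        return self.bead_type.startswith("S")


@dataclass(frozen=True)
class BondParam:
    """Harmonic bond: U = 1/2 k (r - r0)^2."""

    r0: float = 0.47       # nm
    k: float = 1250.0      # kJ mol^-1 nm^-2

    def __post_init__(self) -> None:
        if self.r0 <= 0 or self.k < 0:
            raise ValueError(f"invalid bond parameters r0={self.r0}, k={self.k}")


@dataclass(frozen=True)
class AngleParam:
    """Cosine-harmonic angle: U = 1/2 k (cos(theta) - cos(theta0))^2."""

    theta0: float = 180.0  # degrees
    k: float = 25.0        # kJ mol^-1

    def __post_init__(self) -> None:
        if not 0.0 < self.theta0 <= 180.0:
            raise ValueError(f"theta0 must lie in (0, 180], got {self.theta0}")

    @property
    def cos0(self) -> float:
        return math.cos(math.radians(self.theta0))


@dataclass(frozen=True)
class LJPair:
    epsilon: float  # kJ mol^-1
    sigma: float    # nm

    def __post_init__(self) -> None:
        if self.epsilon <= 0 or self.sigma <= 0:
            raise ValueError("epsilon and sigma must be positive")


@dataclass(frozen=True)
class NonbondedConfig:
    lj_shift_start: float = 0.9
    cutoff: float = 1.2
    coulomb_shift_start: float = 0.0
    eps_r: float = 15.0    # screened-Coulomb relative permittivity

    def __post_init__(self) -> None:
        if not 0.0 <= self.lj_shift_start < self.cutoff:
            raise ValueError("need 0 <= lj_shift_start < cutoff")
        if not 0.0 <= self.coulomb_shift_start < self.cutoff:
            raise ValueError("need 0 <= coulomb_shift_start < cutoff")


def shift_coefficients(p: int, r1: float, rc: float) -> tuple[float, float, float]:
    """Polynomial coefficients (A, B, C) of the shift applied to a 1/r^p term.

    Between r1 and rc the force gains A(r-r1)^2 + B(r-r1)^3 so that force and
    its derivative vanish continuously at the cutoff; C shifts the potential
    so U(rc) = 0.
    """
    d = rc - r1
    A = -p * ((p + 4) * rc - (p + 1) * r1) / (rc ** (p + 2) * d ** 2)
    B = p * ((p + 3) * rc - (p + 1) * r1) / (rc ** (p + 2) * d ** 3)
    C = 1.0 / rc ** p - (A / 3.0) * d ** 3 - (B / 4.0) * d ** 4
    return A, B, C


def _shifted_phi(r: np.ndarray, p: int, r1: float, rc: float):
    """Shifted 1/r^p potential and its (radial) force 1/r^p -> (phi, f)."""
    A, B, C = shift_coefficients(p, r1, rc)
    r = np.asarray(r, dtype=float)
    d = np.clip(r - r1, 0.0, None)
    phi = 1.0 / r ** p - (A / 3.0) * d ** 3 - (B / 4.0) * d ** 4 - C
    f = p / r ** (p + 1) + A * d ** 2 + B * d ** 3
    beyond = r >= rc
    phi = np.where(beyond, 0.0, phi)
    f = np.where(beyond, 0.0, f)
    return phi, f


def lj_energy_force(r, pair: LJPair, cfg: NonbondedConfig = NonbondedConfig(),
                    shifted: bool = True):
    """Shifted 12-6 Lennard-Jones energy (kJ/mol) and radial force (kJ/mol/nm).

    Positive force means repulsion.  With ``shifted=False`` the raw truncated
    12-6 form is returned (useful for hand checks).
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("interbead distance must be positive")
    c12 = 4.0 * pair.epsilon * pair.sigma ** 12
    c6 = 4.0 * pair.epsilon * pair.sigma ** 6
    if not shifted:
        sr6 = (pair.sigma / r) ** 6
        e = 4.0 * pair.epsilon * (sr6 ** 2 - sr6)
        f = 24.0 * pair.epsilon * (2.0 * sr6 ** 2 - sr6) / r
        return e, f
    p12, f12 = _shifted_phi(r, 12, cfg.lj_shift_start, cfg.cutoff)
    p6, f6 = _shifted_phi(r, 6, cfg.lj_shift_start, cfg.cutoff)
    return c12 * p12 - c6 * p6, c12 * f12 - c6 * f6


def coulomb_energy_force(r, qi: float, qj: float,
                         cfg: NonbondedConfig = NonbondedConfig()):
    """Shifted screened-Coulomb energy and radial force.

    U = f_elec qi qj / (eps_r r), smoothly shifted to zero between
    ``coulomb_shift_start`` (default 0) and the cutoff.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("interbead distance must be positive")
    c = F_ELEC * qi * qj / cfg.eps_r
    if c == 0.0:
        z = np.zeros_like(r)
        return z, z
    phi, f = _shifted_phi(r, 1, cfg.coulomb_shift_start, cfg.cutoff)
    return c * phi, c * f


def bond_energy_force(r, p: BondParam):
    """Harmonic bond energy and radial force (positive = repulsive)."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("bond length must be positive")
    dr = r - p.r0
    return 0.5 * p.k * dr ** 2, -p.k * dr


def angle_energy_force(theta, p: AngleParam):
    """Cosine-harmonic angle energy and generalized force -dU/dtheta.

    ``theta`` in degrees, energy kJ/mol, returned force in kJ/mol/rad.
    The cosine form is regular at theta = 180 deg, which is what keeps
    linear aliphatic chains stable.
    """
    theta = np.asarray(theta, dtype=float)
    if np.any(theta <= 0) or np.any(theta > 180.0):
        raise ValueError("theta must lie in (0, 180] degrees")
    th = np.radians(theta)
    c = np.cos(th)
    e = 0.5 * p.k * (c - p.cos0) ** 2
    force = p.k * (c - p.cos0) * np.sin(th)   # -dU/dtheta
    return e, force


class InteractionTable:
    """Symmetric bead-type -> (epsilon, sigma) Lennard-Jones table.

    Loaded from a CSV with columns type_a, type_b, epsilon, sigma covering
    the upper triangle of the base (non-ring) type matrix.  Ring (S-prefixed)
    types reuse the base-type entry; pairs of two ring beads use
    sigma = 0.43 nm with epsilon scaled by 0.75, the convention that keeps
    small-bead packing consistent.
    """

    RING_SIGMA = DIAMETER_RING
    RING_EPS_SCALE = 0.75

    def __init__(self, frame: pd.DataFrame):
        self._pairs: dict[tuple[str, str], LJPair] = {}
        for row in frame.itertuples(index=False):
            key = tuple(sorted((row.type_a, row.type_b)))
            pair = LJPair(float(row.epsilon), float(row.sigma))
            if key in self._pairs and self._pairs[key] != pair:
                raise ValueError(f"conflicting entries for pair {key}")
            self._pairs[key] = pair
        self._types = sorted({t for k in self._pairs for t in k})
        for a in self._types:
            for b in self._types:
                if tuple(sorted((a, b))) not in self._pairs:
                    raise ValueError(f"interaction table missing pair ({a}, {b})")

    @classmethod
    def default(cls) -> "InteractionTable":
        with resources.files("amphimem.data").joinpath("interaction_table.csv").open() as fh:
            return cls(pd.read_csv(fh))

    @classmethod
    def from_csv(cls, path) -> "InteractionTable":
        return cls(pd.read_csv(path))

    @property
    def base_types(self) -> list[str]:
        return list(self._types)

    def lookup(self, type_a: str, type_b: str) -> LJPair:
        ring = type_a.startswith("S") and type_b.startswith("S")
        base = self._pairs[tuple(sorted((type_a.lstrip("S"), type_b.lstrip("S"))))]
        if ring:
            return LJPair(base.epsilon * self.RING_EPS_SCALE, self.RING_SIGMA)
        return base

    def matrices(self, bead_types: list[str]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (type_index, eps_matrix, sig_matrix) for the given beads."""
        uniq = sorted(set(bead_types))
        index = {t: i for i, t in enumerate(uniq)}
        tidx = np.array([index[t] for t in bead_types], dtype=np.int64)
        n = len(uniq)
        eps = np.empty((n, n))
        sig = np.empty((n, n))
        for a, ia in index.items():
            for b, ib in index.items():
                p = self.lookup(a, b)
                eps[ia, ib] = p.epsilon
                sig[ia, ib] = p.sigma
        if not np.allclose(eps, eps.T) or not np.allclose(sig, sig.T):
            raise AssertionError("interaction table must be symmetric")
        return tidx, eps, sig
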