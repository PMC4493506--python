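"""Coarse-grained molecular dynamics engine.

Velocity-Verlet dynamics in NVE, NVT or NPT with Berendsen weak coupling
(thermostat at 310 K, tau_T = 1.0 ps; barostat at 1.0 bar, tau_P = 2.0 ps,
compressibility 3e-5 1/bar), an all-pairs Verlet neighbor list with a 1.4 nm
cutoff refreshed every 10 steps, and a 10 fs time step -- the standard
coarse-grained protocol for lipid-bilayer systems.  Pressure coupling is
isotropic by default with a semi-isotropic option for planar bilayers.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from . import _kernels
from .constants import KB, F_ELEC, PRESSURE_BAR
from .forcefield import InteractionTable, NonbondedConfig, shift_coefficients
from .topology import BeadTopology

__all__ = ["Frame", "IntegratorConfig", "Trajectory", "System", "COMZRestraint",
           "compute_forces", "berendsen_lambda", "kinetic_temperature",
           "maxwell_velocities", "run_md", "run_replicates", "minimize_energy",
           "IntegrationError", "SingularityError"]


class IntegrationError(RuntimeError):
    pass


class SingularityError(RuntimeError):
    pass


@dataclass
class Frame:
    """Simulation state: positions/velocities (nm, nm/ps), orthorhombic box (nm), time (ps)."""

    positions: np.ndarray
    velocities: np.ndarray
    box: np.ndarray
    time: float = 0.0

    def __post_init__(self) -> None:
        self.positions = np.ascontiguousarray(self.positions, dtype=np.float64)
        self.velocities = np.ascontiguousarray(self.velocities, dtype=np.float64)
        self.box = np.asarray(self.box, dtype=np.float64)
        if self.positions.shape != self.velocities.shape:
            raise ValueError("positions and velocities must have matching shape")

    def wrapped(self) -> "Frame":
        pos = self.positions - self.box * np.floor(self.positions / self.box)
        return Frame(pos, self.velocities.copy(), self.box.copy(), self.time)

    def copy(self) -> "Frame":
        return Frame(self.positions.copy(), self.velocities.copy(),
                     self.box.copy(), self.time)


@dataclass(frozen=True)
class IntegratorConfig:
    dt: float = 0.01               # ps (10 fs)
    T0: float = 310.0              # K
    tau_T: float = 1.0             # ps
    P0: float = 1.0                # bar
    tau_P: float = 2.0             # ps
    compressibility: float = 3e-5  # 1/bar
    nb_update_interval: int = 10   # steps
    nb_list_cutoff: float = 1.4    # nm
    ensemble: str = "NVT"
    semi_isotropic: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.tau_T <= 0 or self.tau_P <= 0:
            raise ValueError("dt, tau_T and tau_P must be positive")
        if self.ensemble.upper() not in ("NVE", "NVT", "NPT"):
            raise ValueError(f"unknown ensemble {self.ensemble!r}")

    def config_hash(self) -> str:
        return hashlib.sha256(repr(sorted(self.__dict__.items())).encode()).hexdigest()[:16]


@dataclass
class Trajectory:
    frames: list[Frame]
    log: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])

    def __post_init__(self) -> None:
        t = self.times
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("trajectory times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)


@dataclass
class COMZRestraint:
    """Harmonic restraint on the z-distance between two bead groups' COMs.

    The reaction coordinate is the z-component distance between the
    restrained group's COM and the reference group's COM (absolute-valued
    across the midplane by default).  ``target`` may be a constant (nm) or
    a callable target(t_ps) for steered pulling.
    """

    group: np.ndarray
    k: float
    target: float | Callable[[float], float]
    reference: np.ndarray | None = None
    absolute: bool = True

    def target_at(self, t: float) -> float:
        return self.target(t) if callable(self.target) else float(self.target)

    def coordinate(self, frame: Frame, masses: np.ndarray) -> float:
        zg = _group_com_z(frame, masses, self.group)
        zr = _group_com_z(frame, masses, self.reference) if self.reference is not None else 0.0
        dz = zg - zr
        box_z = frame.box[2]
        dz -= box_z * np.rint(dz / box_z)
        return abs(dz) if self.absolute else dz

    def apply(self, frame: Frame, masses: np.ndarray, forces: np.ndarray) -> float:
        zg = _group_com_z(frame, masses, self.group)
        zr = _group_com_z(frame, masses, self.reference) if self.reference is not None else 0.0
        dz = zg - zr
        box_z = frame.box[2]
        dz -= box_z * np.rint(dz / box_z)
        xi = abs(dz) if self.absolute else dz
        dev = xi - self.target_at(frame.time)
        energy = 0.5 * self.k * dev * dev
        fz = -self.k * dev * (math.copysign(1.0, dz) if self.absolute else 1.0)
        mg = masses[self.group]
        forces[self.group, 2] += fz * mg / mg.sum()
        if self.reference is not None:
            mr = masses[self.reference]
            forces[self.reference, 2] -= fz * mr / mr.sum()
        return energy


def _group_com_z(frame: Frame, masses: np.ndarray, idx: np.ndarray) -> float:
    """Mass-weighted COM z of a bead group, unwrapped by minimum image
    relative to the group's first bead (groups are assumed compact)."""
    z = frame.positions[idx, 2]
    box_z = frame.box[2]
    z = z[0] + ((z - z[0]) - box_z * np.rint((z - z[0]) / box_z))
    m = masses[idx]
    return float(np.average(z, weights=m))


class System:
    """A topology bound to force-field tables and a simulation frame."""

    def __init__(self, topology: BeadTopology, frame: Frame,
                 table: InteractionTable | None = None,
                 nonbonded: NonbondedConfig = NonbondedConfig()):
        if frame.positions.shape[0] != topology.n_beads:
            raise ValueError("frame/topology size mismatch")
        self.topology = topology
        self.frame = frame
        self.table = table if table is not None else InteractionTable.default()
        self.nonbonded = nonbonded
        self._build_arrays()

    def _build_arrays(self) -> None:
        top = self.topology
        self.masses = top.masses()
        self.charges = top.charges()
        self.tidx, self.eps_t, self.sig_t = self.table.matrices(top.bead_types())
        nb = [(i, j, p) for i, j, p in top.bonds]
        self.bond_i = np.array([b[0] for b in nb], dtype=np.int64)
        self.bond_j = np.array([b[1] for b in nb], dtype=np.int64)
        self.bond_r0 = np.array([b[2].r0 for b in nb])
        self.bond_k = np.array([b[2].k for b in nb])
        ang = top.angles
        self.ang_i = np.array([a[0] for a in ang], dtype=np.int64)
        self.ang_j = np.array([a[1] for a in ang], dtype=np.int64)
        self.ang_k = np.array([a[2] for a in ang], dtype=np.int64)
        self.ang_cos0 = np.array([a[3].cos0 for a in ang])
        self.ang_kp = np.array([a[3].k for a in ang])
        dih = top.ring_dihedrals
        self.dih = tuple(np.array([d[c] for d in dih], dtype=np.int64) for c in range(4))
        self.dih_xi0 = np.radians(np.array([d[4] for d in dih]))
        self.dih_k = np.array([d[5] for d in dih])
        # exclusions: directly bonded (1-2) pairs
        neigh: list[list[int]] = [[] for _ in range(top.n_beads)]
        for i, j, _ in top.bonds:
            neigh[i].append(j)
            neigh[j].append(i)
        width = max((len(v) for v in neigh), default=0)
        self.excl = np.full((top.n_beads, max(width, 1)), -1, dtype=np.int64)
        for i, v in enumerate(neigh):
            self.excl[i, :len(v)] = sorted(v)
        # shift coefficients for the 12-, 6- and 1-power terms
        nbc = self.nonbonded
        self._sc12 = shift_coefficients(12, nbc.lj_shift_start, nbc.cutoff)
        self._sc6 = shift_coefficients(6, nbc.lj_shift_start, nbc.cutoff)
        self._sc1 = shift_coefficients(1, nbc.coulomb_shift_start, nbc.cutoff)

    @property
    def n_beads(self) -> int:
        return self.topology.n_beads

    def neighbor_list(self, frame: Frame | None = None,
                      list_cutoff: float = 1.4) -> tuple[np.ndarray, np.ndarray]:
        fr = frame if frame is not None else self.frame
        return _kernels.neighbor_pairs(fr.positions, fr.box, list_cutoff, self.excl)


def compute_forces(frame: Frame, system: System,
                   pairs: tuple[np.ndarray, np.ndarray] | None = None,
                   restraints: Sequence[COMZRestraint] = ()):
    """Forces (kJ/mol/nm), energy breakdown (kJ/mol) and virial diagonal.

    ``pairs`` is a current neighbor list; if omitted one is built from this
    frame.  Raises :class:`SingularityError` if any interacting pair is
    closer than 1e-6 nm.
    """
    if pairs is None:
        pairs = system.neighbor_list(frame)
    n = system.n_beads
    forces = np.zeros((n, 3))
    virial = np.zeros(3)
    nbc = system.nonbonded
    a12, b12, c12 = system._sc12
    a6, b6, c6 = system._sc6
    a1, b1, c1 = system._sc1
    e_lj, e_coul, min_r2 = _kernels.nonbonded_forces(
        frame.positions, frame.box, pairs[0], pairs[1],
        system.tidx, system.eps_t, system.sig_t, system.charges,
        nbc.cutoff, a12, b12, c12, a6, b6, c6, nbc.lj_shift_start,
        F_ELEC / nbc.eps_r, a1, b1, c1, nbc.coulomb_shift_start,
        forces, virial)
    if min_r2 < 1e-12:
        raise SingularityError(f"overlapping beads: min pair distance "
                               f"{math.sqrt(max(min_r2, 0.0)):.2e} nm")
    e_bond = _kernels.bond_forces(frame.positions, frame.box, system.bond_i,
                                  system.bond_j, system.bond_r0, system.bond_k,
                                  forces, virial) if len(system.bond_i) else 0.0
    e_ang = _kernels.angle_forces(frame.positions, frame.box, system.ang_i,
                                  system.ang_j, system.ang_k, system.ang_cos0,
                                  system.ang_kp, forces, virial) if len(system.ang_i) else 0.0
    e_dih = _kernels.improper_forces(frame.positions, frame.box, *system.dih,
                                     system.dih_xi0, system.dih_k,
                                     forces, virial) if len(system.dih[0]) else 0.0
    e_res = 0.0
    for r in restraints:
        e_res += r.apply(frame, system.masses, forces)
    breakdown = {"bond": e_bond, "angle": e_ang, "improper": e_dih,
                 "lj": e_lj, "coulomb": e_coul, "restraint": e_res,
                 "bonded": e_bond + e_ang + e_dih,
                 "potential": e_bond + e_ang + e_dih + e_lj + e_coul + e_res}
    return forces, breakdown, virial


def berendsen_lambda(T_inst: float, cfg: IntegratorConfig) -> float:
    """Berendsen velocity-scaling factor lambda = sqrt(1 + dt/tau (T0/T - 1)).

    lambda == 1 exactly at the target temperature.  A zero instantaneous
    temperature (no thermal motion to scale) returns 1 (scaling skipped).
    """
    if T_inst < 0:
        raise ValueError("instantaneous temperature must be >= 0")
    if T_inst == 0.0:
        return 1.0
    lam2 = 1.0 + (cfg.dt / cfg.tau_T) * (cfg.T0 / T_inst - 1.0)
    return math.sqrt(max(lam2, 0.0))


def kinetic_temperature(frame: Frame, topology: BeadTopology) -> float:
    """Instantaneous kinetic temperature, Ndof = 3N - 3 (COM motion removed)."""
    m = topology.masses()
    ke = 0.5 * float(np.sum(m[:, None] * frame.velocities ** 2))
    ndof = 3 * topology.n_beads - 3
    if ndof <= 0:
        return 0.0
    return 2.0 * ke / (ndof * KB)


def maxwell_velocities(topology: BeadTopology, T: float, seed: int) -> np.ndarray:
    """Maxwell-Boltzmann velocities at T, COM drift removed, rescaled to T exactly."""
    rng = np.random.default_rng(seed)
    m = topology.masses()
    v = rng.standard_normal((topology.n_beads, 3)) * np.sqrt(KB * T / m)[:, None]
    v -= np.average(v, axis=0, weights=m)
    fr = Frame(np.zeros_like(v), v, np.ones(3))
    t_now = kinetic_temperature(fr, topology)
    if t_now > 0:
        v *= math.sqrt(T / t_now)
    return v


def _remove_com_motion(frame: Frame, masses: np.ndarray) -> None:
    frame.velocities -= np.average(frame.velocities, axis=0, weights=masses)


def _pressure_diag(frame: Frame, masses: np.ndarray, virial: np.ndarray) -> np.ndarray:
    vol = float(np.prod(frame.box))
    twice_ke = np.sum(masses[:, None] * frame.velocities ** 2, axis=0)
    return (twice_ke + virial) / vol * PRESSURE_BAR


def run_md(system: System, cfg: IntegratorConfig, n_steps: int, stride: int = 100,
           restraints: Sequence[COMZRestraint] = (),
           log_interval: int | None = None) -> Trajectory:
    """Integrate and return a Trajectory with frames every ``stride`` steps.

    Deterministic given (system, cfg, restraints): all stochasticity lives
    in the initial velocities.  The initial frame is always stored.
    """
    top = system.topology
    masses = system.masses
    ensemble = cfg.ensemble.upper()
    frame = system.frame.copy().wrapped()
    log_interval = stride if log_interval is None else log_interval
    pairs = system.neighbor_list(frame, cfg.nb_list_cutoff)
    forces, breakdown, virial = compute_forces(frame, system, pairs, restraints)
    frames = [frame.copy()]
    records = []

    def record(step):
        T = kinetic_temperature(frame, top)
        pdiag = _pressure_diag(frame, masses, virial)
        ke = 0.5 * float(np.sum(masses[:, None] * frame.velocities ** 2))
        records.append({"step": step, "time": frame.time, "temperature": T,
                        "pressure": float(pdiag.mean()),
                        "pressure_xx": pdiag[0], "pressure_yy": pdiag[1],
                        "pressure_zz": pdiag[2], "kinetic": ke,
                        **{k: breakdown[k] for k in
                           ("bond", "angle", "improper", "lj", "coulomb",
                            "restraint", "potential")},
                        "total": ke + breakdown["potential"],
                        "box_x": frame.box[0], "box_z": frame.box[2]})

    record(0)
    inv_m = (1.0 / masses)[:, None]
    for step in range(1, n_steps + 1):
        frame.velocities += 0.5 * cfg.dt * forces * inv_m
        frame.positions += cfg.dt * frame.velocities
        frame.time += cfg.dt
        refresh = step % cfg.nb_update_interval == 0
        if refresh:
            frame = frame.wrapped()
            if ensemble in ("NVE", "NVT"):
                _remove_com_motion(frame, masses)
            pairs = system.neighbor_list(frame, cfg.nb_list_cutoff)
            if not np.all(np.isfinite(frame.positions)):
                raise IntegrationError(f"non-finite coordinates at step {step}")
        forces, breakdown, virial = compute_forces(frame, system, pairs, restraints)
        frame.velocities += 0.5 * cfg.dt * forces * inv_m
        if ensemble == "NVT" or ensemble == "NPT":
            lam = berendsen_lambda(kinetic_temperature(frame, top), cfg)
            frame.velocities *= min(max(lam, 0.8), 1.25)
        if ensemble == "NPT":
            pdiag = _pressure_diag(frame, masses, virial)
            kappa = cfg.compressibility
            if cfg.semi_isotropic:
                p_lat = 0.5 * (pdiag[0] + pdiag[1])
                mu_xy = (1.0 - cfg.dt / cfg.tau_P * kappa * (cfg.P0 - p_lat)) ** (1 / 3)
                mu_z = (1.0 - cfg.dt / cfg.tau_P * kappa * (cfg.P0 - pdiag[2])) ** (1 / 3)
                mu = np.array([mu_xy, mu_xy, mu_z])
            else:
                p = float(pdiag.mean())
                mu = np.full(3, (1.0 - cfg.dt / cfg.tau_P * kappa * (cfg.P0 - p)) ** (1 / 3))
            mu = np.clip(mu, 0.98, 1.02)
            frame.box *= mu
            frame.positions *= mu
        if step % log_interval == 0 or step == n_steps:
            record(step)
        if step % stride == 0:
            frames.append(frame.copy())
    if n_steps % stride != 0 and frames[-1].time < frame.time:
        frames.append(frame.copy())
    system.frame = frame
    return Trajectory(frames, pd.DataFrame(records),
                      provenance={"config_hash": cfg.config_hash(), "seed": cfg.seed,
                                  "n_steps": n_steps, "stride": stride})


def run_replicates(system: System, cfg: IntegratorConfig, n_steps: int,
                   stride: int, seeds: Sequence[int],
                   restraints: Sequence[COMZRestraint] = ()) -> list[Trajectory]:
    """Independent replicate runs from the same start with per-seed velocities
    (the study design used 10 replicates per macromolecule)."""
    out = []
    for s in seeds:
        sys_i = System(system.topology, system.frame.copy(), system.table,
                       system.nonbonded)
        sys_i.frame.velocities = maxwell_velocities(system.topology, cfg.T0, s)
        out.append(run_md(sys_i, replace(cfg, seed=int(s)), n_steps, stride,
                          restraints))
    return out


def minimize_energy(system: System, max_steps: int = 200, max_disp: float = 0.02,
                    f_tol: float = 10.0) -> float:
    """Steepest-descent relaxation with displacement capping; returns final
    potential energy.  Used to remove construction clashes before dynamics."""
    frame = system.frame
    e_prev = None
    for _ in range(max_steps):
        forces, breakdown, _ = compute_forces(frame, system)
        fmax = float(np.abs(forces).max()) if len(forces) else 0.0
        if fmax < f_tol:
            break
        step = min(max_disp / max(fmax, 1e-12), 1e-3)
        frame.positions += step * forces
        frame = frame.wrapped()
        e_prev = breakdown["potential"]
    system.frame = frame
    forces, breakdown, _ = compute_forces(frame, system)
    return breakdown["potential"]
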