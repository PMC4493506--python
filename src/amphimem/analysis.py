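"""Binding statistics from trajectories: insertion events, PEG orientation
and height, bilayer geometry.

An insertion event is a frame where the amphiphile head-group COM sits
closer than 2 nm (half the ~4 nm DPPC bilayer thickness) to the bilayer
COM along z.  PEG orientation is the angle between the first-to-terminal
PEG bead vector and the membrane normal (z); PEG heights are measured from
the mean phosphate plane of the outer leaflet.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .engine import Frame, Trajectory
from .topology import BeadTopology

__all__ = ["InsertionSeries", "OrientationSeries", "bilayer_com_z",
           "detect_insertions", "peg_orientation", "bilayer_thickness",
           "binding_summary", "INSERTION_THRESHOLD"]

#: default insertion criterion, nm (half the ~4 nm bilayer thickness)
INSERTION_THRESHOLD = 2.0


@dataclass
class InsertionSeries:
    times: np.ndarray          # ps
    distance: np.ndarray       # nm, head-group COM to bilayer COM (z)
    threshold: float = INSERTION_THRESHOLD
    label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.distance = np.asarray(self.distance, float)

    @property
    def inserted(self) -> np.ndarray:
        return self.distance < self.threshold

    @property
    def inserted_fraction(self) -> float:
        return float(self.inserted.mean()) if len(self.times) else 0.0

    @property
    def first_insertion_time(self) -> float | None:
        """Time of the first insertion event, None if censored (no event)."""
        hits = np.flatnonzero(self.inserted)
        return float(self.times[hits[0]]) if len(hits) else None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_ps": self.times, "distance_nm": self.distance,
                             "inserted": self.inserted})


@dataclass
class OrientationSeries:
    times: np.ndarray
    angle: np.ndarray          # degrees vs +z, in [0, 180]; NaN if undefined
    tail_height: np.ndarray    # nm of terminal PEG bead above phosphate plane
    mean_peg_height: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_ps": self.times, "angle_deg": self.angle,
                             "tail_height_nm": self.tail_height,
                             "mean_peg_height_nm": self.mean_peg_height})


def _lipid_indices(topology: BeadTopology) -> np.ndarray:
    idx = np.array([i for i, b in enumerate(topology.beads)
                    if topology.molecule_labels[b.molecule] == "DPPC"],
                   dtype=np.int64)
    if not len(idx):
        raise ValueError("no lipids in topology")
    return idx


def _unwrapped_z(frame: Frame, idx: np.ndarray, ref_z: float | None = None) -> np.ndarray:
    """z of selected beads, minimum-imaged about ref_z (default: first bead)."""
    z = frame.positions[idx, 2]
    box_z = frame.box[2]
    r = z[0] if ref_z is None else ref_z
    return r + ((z - r) - box_z * np.rint((z - r) / box_z))


def bilayer_com_z(frame: Frame, topology: BeadTopology) -> float:
    """Mass-weighted COM z of all lipid beads.

    Uses the circular-mean construction so the result is exact under
    periodic boundaries even when the bilayer spans more than half the
    box (a single minimum-image reference bead would fail there)."""
    idx = _lipid_indices(topology)
    box_z = frame.box[2]
    theta = 2.0 * np.pi * frame.positions[idx, 2] / box_z
    m = topology.masses()[idx]
    c = np.average(np.cos(theta), weights=m)
    s = np.average(np.sin(theta), weights=m)
    return float((np.arctan2(s, c) % (2.0 * np.pi)) * box_z / (2.0 * np.pi))


def _head_indices(topology: BeadTopology) -> np.ndarray:
    head = topology.indices(role="head")
    if not len(head):
        head = topology.indices(role="backbone")
    if not len(head):
        raise ValueError("no amphiphile head group in topology")
    return head


def detect_insertions(traj: Trajectory, topology: BeadTopology,
                      threshold: float = INSERTION_THRESHOLD,
                      label: str = "") -> InsertionSeries:
    """Per-frame |z| distance of the head-group COM from the bilayer COM and
    the boolean insertion flag (distance < threshold).  Idempotent and
    threshold-monotone by construction."""
    head = _head_indices(topology)
    m = topology.masses()
    dist = np.empty(len(traj.frames))
    for n, fr in enumerate(traj.frames):
        zb = bilayer_com_z(fr, topology)
        zh = np.average(_unwrapped_z(fr, head, ref_z=None), weights=m[head])
        dz = zh - zb
        dz -= fr.box[2] * np.rint(dz / fr.box[2])
        dist[n] = abs(dz)
    return InsertionSeries(traj.times, dist, threshold, label)


def _phosphate_plane(frame: Frame, topology: BeadTopology,
                     leaflet: str = "outer") -> float:
    po4 = topology.indices(role="PO4")
    if not len(po4):
        raise ValueError("no phosphate beads tagged in topology")
    mid = bilayer_com_z(frame, topology)
    z = _unwrapped_z(frame, po4, ref_z=mid)
    upper = z[z >= mid]
    lower = z[z < mid]
    if not len(upper) or not len(lower):
        raise ValueError("leaflet assignment failed: all phosphates on one side")
    return float(upper.mean() if leaflet == "outer" else lower.mean())


def peg_orientation(traj: Trajectory, topology: BeadTopology) -> OrientationSeries:
    """PEG end-to-end angle to the z-axis, terminal-bead and mean PEG heights
    above the outer phosphate plane.  A zero-length end-to-end vector makes
    that frame's angle NaN (reported missing)."""
    peg = topology.indices(role="peg")
    if not len(peg):
        raise ValueError("no PEG beads in topology")
    first, last = peg[0], peg[-1]
    n = len(traj.frames)
    angle = np.full(n, np.nan)
    tail_h = np.empty(n)
    mean_h = np.empty(n)
    for k, fr in enumerate(traj.frames):
        box = fr.box
        vec = fr.positions[last] - fr.positions[first]
        vec -= box * np.rint(vec / box)
        norm = np.linalg.norm(vec)
        if norm > 1e-9:
            angle[k] = np.degrees(np.arccos(np.clip(vec[2] / norm, -1.0, 1.0)))
        plane = _phosphate_plane(fr, topology, "outer")
        zpeg = _unwrapped_z(fr, peg, ref_z=plane)
        tail_h[k] = zpeg[-1] - plane
        mean_h[k] = zpeg.mean() - plane
    return OrientationSeries(traj.times, angle, tail_h, mean_h)


def bilayer_thickness(traj: Trajectory, topology: BeadTopology) -> float:
    """Mean inter-leaflet phosphate-plane separation averaged over frames (nm)."""
    vals = []
    for fr in traj.frames:
        up = _phosphate_plane(fr, topology, "outer")
        lo = _phosphate_plane(fr, topology, "inner")
        vals.append(up - lo)
    return float(np.mean(vals))


def binding_summary(replicates: list[InsertionSeries]) -> pd.DataFrame:
    """Per-label summary over replicate insertion series.

    Reports replicate count, mean inserted fraction, median first-insertion
    time among replicates with events, and the number of censored
    replicates (no event by trajectory end)."""
    if not replicates:
        raise ValueError("need at least one replicate")
    rows: dict[str, list[InsertionSeries]] = {}
    for s in replicates:
        rows.setdefault(s.label or "AM", []).append(s)
    out = []
    for label, series in rows.items():
        firsts = [s.first_insertion_time for s in series]
        events = [t for t in firsts if t is not None]
        out.append({
            "label": label,
            "n_replicates": len(series),
            "inserted_fraction": float(np.mean([s.inserted_fraction for s in series])),
            "median_first_insertion_ps": float(np.median(events)) if events else np.nan,
            "n_censored": sum(t is None for t in firsts),
        })
    return pd.DataFrame(out)
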