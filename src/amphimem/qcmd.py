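"""QCM-D data model and analysis.

Quartz-crystal microbalance with dissipation traces record per-overtone
frequency shifts Df_n (Hz) and dissipation shifts DD_n (in units of 1e-6)
for harmonics n in {3, 5, 7, 9, 11} of a 5 MHz fundamental.  Rigid films
obey the Sauerbrey relation Dm = -C Df/n with C = 17.7 ng cm^-2 Hz^-1;
soft films are modelled as a Voigt element (spring and dashpot in
parallel) under a semi-infinite Newtonian liquid, in the small-load
(Voinova) approximation.  Binding kinetics are quantified by linear
regression of Sauerbrey mass versus time and by the plateau mass at the
end of the binding phase.

Dissipation values are expressed in units of 1e-6 throughout this module's
interfaces, matching instrument output.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = ["OVERTONES", "SauerbreyParams", "VoigtFilm", "BulkLiquid",
           "BindingKinetics", "QCMDTrace", "PHASES", "sauerbrey_mass",
           "voigt_predict", "voigt_fit", "deposition_rate", "plateau_mass",
           "segment_trace", "VoigtFitError"]

OVERTONES = (3, 5, 7, 9, 11)
PHASES = ("baseline", "SLB", "rinse", "AM", "final_rinse")
#: fundamental frequency, Hz (5 MHz sensor)
F0_DEFAULT = 5e6


class VoigtFitError(RuntimeError):
    pass


@dataclass(frozen=True)
class SauerbreyParams:
    C: float = 17.7  # ng cm^-2 Hz^-1

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("quartz constant C must be positive")


@dataclass(frozen=True)
class VoigtFilm:
    """Viscoelastic film: shear modulus (Pa), viscosity (Pa s),
    density (kg m^-3), thickness (m)."""

    shear_modulus: float
    viscosity: float
    density: float
    thickness: float

    def __post_init__(self) -> None:
        if min(self.shear_modulus, self.viscosity, self.density) <= 0 \
                or self.thickness < 0:
            raise ValueError("Voigt film parameters must be positive")

    @property
    def areal_mass_ng_cm2(self) -> float:
        return self.density * self.thickness / 1e-8  # kg/m^2 -> ng/cm^2


@dataclass(frozen=True)
class BulkLiquid:
    density: float = 1000.0    # kg m^-3
    viscosity: float = 8.9e-4  # Pa s (water-like buffer)


@dataclass
class BindingKinetics:
    rate: float            # ng cm^-2 min^-1
    rate_se: float
    window: tuple[float, float]  # min
    plateau_mass: float | None
    r_squared: float


def _quartz_areal_mass(C_ng: float, f0: float) -> float:
    """rho_q h_q (kg m^-2) consistent with the Sauerbrey constant."""
    return C_ng * 1e-8 * f0  # ng cm^-2 Hz^-1 -> kg m^-2 Hz^-1, times f0


def sauerbrey_mass(delta_f, n: int = 3,
                   params: SauerbreyParams = SauerbreyParams()) -> np.ndarray | float:
    """Sauerbrey mass Dm = -C Df/n in ng/cm^2 (linear in Df)."""
    if n == 0:
        raise ValueError("overtone order must be nonzero")
    return -params.C * np.asarray(delta_f, float) / n


def voigt_predict(film: VoigtFilm, liquid: BulkLiquid = BulkLiquid(),
                  f0: float = F0_DEFAULT, n: int = 3,
                  params: SauerbreyParams = SauerbreyParams()) -> tuple[float, float]:
    """Small-load Voigt-film response at overtone n, baseline-subtracted.

    Returns (Df in Hz, DD in 1e-6 units) of the film relative to the bare
    sensor in the same liquid.  In the rigid limit (large shear modulus)
    Df/n is overtone-independent and -C Df/n recovers the areal mass
    rho*h; dissipation vanishes.
    """
    if film.thickness == 0.0:
        return 0.0, 0.0
    w = 2.0 * math.pi * n * f0
    rho_h_q = _quartz_areal_mass(params.C, f0)
    xi2 = liquid.viscosity * liquid.density * w / 2.0  # (eta_l/delta_l)^2
    denom = film.shear_modulus ** 2 + (w * film.viscosity) ** 2
    df = -(1.0 / (2.0 * math.pi * rho_h_q)) * (
        film.thickness * film.density * w
        - 2.0 * film.thickness * xi2 * film.viscosity * w ** 2 / denom)
    dd = (1.0 / (math.pi * n * f0 * rho_h_q)) * (
        2.0 * film.thickness * xi2 * film.shear_modulus * w / denom)
    return df, dd * 1e6


def voigt_fit(delta_f: dict[int, float], delta_d: dict[int, float],
              init: VoigtFilm, liquid: BulkLiquid = BulkLiquid(),
              f0: float = F0_DEFAULT,
              bounds: tuple[VoigtFilm, VoigtFilm] | None = None,
              density: float | None = None, n_restarts: int = 0,
              seed: int = 0) -> tuple[VoigtFilm, pd.DataFrame]:
    """Least-squares Voigt-film fit over all overtones' Df and DD jointly.

    ``delta_f``/``delta_d`` map overtone order -> measured shift (Hz, 1e-6).
    The film density is fixed (``density``, default the init's) since rho
    and h only enter the small-load response through near-degenerate
    combinations.  Returns the fitted film and per-overtone residuals.
    Multi-start (``n_restarts``) draws seeded log-uniform initial points
    between the bounds.
    """
    overtones = sorted(set(delta_f) & set(delta_d))
    if len(overtones) < 2:
        raise VoigtFitError("need at least two overtones to constrain the fit")
    rho = density if density is not None else init.density
    if bounds is None:
        lo = VoigtFilm(1e2, 1e-6, rho, 1e-10)
        hi = VoigtFilm(1e9, 1e-1, rho, 1e-6)
    else:
        lo, hi = bounds
    f_obs = np.array([delta_f[n] for n in overtones])
    d_obs = np.array([delta_d[n] for n in overtones])
    # weights put Df/n (a few Hz) and DD (a few 1e-6) on comparable scales
    wf = 1.0 / max(np.abs(f_obs / np.array(overtones)).max(), 1e-3)
    wd = 1.0 / max(np.abs(d_obs).max(), 1e-2)

    def unpack(x):
        return VoigtFilm(math.exp(x[0]), math.exp(x[1]), rho, math.exp(x[2]))

    def residuals(x):
        film = unpack(x)
        out = []
        for n, fo, do in zip(overtones, f_obs, d_obs):
            fp, dp = voigt_predict(film, liquid, f0, n)
            out.append((fp - fo) / n * wf)
            out.append((dp - do) * wd)
        return np.array(out)

    x0 = np.log([init.shear_modulus, init.viscosity, init.thickness])
    xlo = np.log([lo.shear_modulus, lo.viscosity, lo.thickness])
    xhi = np.log([hi.shear_modulus, hi.viscosity, hi.thickness])
    starts = [np.clip(x0, xlo, xhi)]
    rng = np.random.default_rng(seed)
    for _ in range(n_restarts):
        starts.append(xlo + rng.random(3) * (xhi - xlo))
    best = None
    for s in starts:
        try:
            res = optimize.least_squares(residuals, s, bounds=(xlo, xhi),
                                         xtol=1e-14, ftol=1e-14, gtol=1e-14)
        except ValueError:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None or not best.success and best.cost > 1e-6:
        raise VoigtFitError(f"Voigt fit failed (residual norm "
                            f"{math.sqrt(2 * best.cost) if best else float('nan'):.3e})")
    film = unpack(best.x)
    at_bound = np.any(np.isclose(best.x, xlo, atol=1e-6) |
                      np.isclose(best.x, xhi, atol=1e-6))
    if at_bound:
        warnings.warn("Voigt fit parameter at bound", RuntimeWarning,
                      stacklevel=2)
    rows = []
    for n, fo, do in zip(overtones, f_obs, d_obs):
        fp, dp = voigt_predict(film, liquid, f0, n)
        rows.append({"overtone": n, "delta_f_obs": fo, "delta_f_fit": fp,
                     "delta_d_obs": do, "delta_d_fit": dp})
    return film, pd.DataFrame(rows)


@dataclass
class QCMDTrace:
    """Multi-overtone QCM-D time series with phase annotations.

    ``data`` columns: time_min, f3..f11 (Hz), d3..d11 (1e-6), phase (str,
    may be empty before segmentation).  Missing overtone columns are
    tolerated.
    """

    data: pd.DataFrame
    f0: float = F0_DEFAULT
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = self.data["time_min"].to_numpy()
        if len(t) and np.any(np.diff(t) <= 0):
            raise ValueError("trace times must be strictly increasing")
        if "phase" not in self.data.columns:
            self.data = self.data.assign(phase="")
        bad = [n for n in self.overtones if n not in OVERTONES]
        if bad:
            raise ValueError(f"unsupported overtones {bad}; allowed {OVERTONES}")

    @property
    def overtones(self) -> list[int]:
        return sorted(int(c[1:]) for c in self.data.columns
                      if c.startswith("f") and c[1:].isdigit())

    @property
    def times(self) -> np.ndarray:
        return self.data["time_min"].to_numpy()

    def phase_slice(self, phase: str) -> pd.DataFrame:
        sel = self.data[self.data["phase"] == phase]
        if sel.empty:
            raise ValueError(f"phase {phase!r} not annotated in trace")
        return sel

    def mass_series(self, n: int = 3,
                    params: SauerbreyParams = SauerbreyParams()) -> pd.DataFrame:
        """Sauerbrey mass (ng/cm^2) vs time from overtone ``n``."""
        return pd.DataFrame({"time_min": self.times,
                             "mass": sauerbrey_mass(self.data[f"f{n}"], n, params),
                             "phase": self.data["phase"]})

    def write_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path, f0: float = F0_DEFAULT) -> "QCMDTrace":
        return cls(pd.read_csv(path, keep_default_na=False,
                               na_values=[""]).fillna({"phase": ""}), f0=f0)


def segment_trace(trace: QCMDTrace, protocol: dict[str, tuple[float, float]]
                  | None = None, detect: bool = False,
                  slope_threshold: float | None = None) -> QCMDTrace:
    """Annotate the five protocol phases.

    With an explicit ``protocol`` (phase -> (t0, t1) minutes, half-open
    intervals) phases are assigned exactly as given and must appear in
    protocol order.  With ``detect=True`` boundaries are located from the
    third-overtone frequency: active segments (|smoothed slope| above
    threshold) alternate with flat holds; the first active segment is the
    lipid-bilayer (SLB) formation -- validated by its
    minimum-then-recovery Df signature -- and the second is amphiphile
    binding.
    """
    if trace.data.empty:
        raise ValueError("empty trace")
    t = trace.times
    phase = np.array([""] * len(t), dtype=object)
    if protocol is not None:
        order = [p for p in protocol]
        if order != [p for p in PHASES if p in protocol]:
            raise ValueError(f"protocol phases out of order: {order}")
        last_end = -np.inf
        for p, (t0, t1) in protocol.items():
            if t0 < last_end:
                raise ValueError("protocol intervals overlap")
            phase[(t >= t0) & (t < t1)] = p
            last_end = t1
    elif detect:
        # rolling-regression slope of f3; phase starts are activity onsets
        # (SLB formation, post-SLB rinse, binding, final rinse)
        f3 = trace.data["f3"].to_numpy(float)
        dt = float(np.median(np.diff(t)))
        n_win = max(int(round(0.5 / dt)), 3)
        half = n_win // 2
        x = (np.arange(n_win) - (n_win - 1) / 2) * dt
        sxx = float(np.sum(x * x))
        slope = np.zeros(len(t))
        for i in range(len(t)):
            lo_i, hi_i = max(0, i - half), min(len(t), i - half + n_win)
            seg = f3[lo_i:hi_i]
            xs = (t[lo_i:hi_i] - t[lo_i:hi_i].mean())
            slope[i] = float(np.sum(xs * (seg - seg.mean())) /
                             max(np.sum(xs * xs), 1e-12))
        if slope_threshold is None:
            # robust noise scale of the slope from its own distribution
            mad = 1.4826 * np.median(np.abs(slope - np.median(slope)))
            thr = max(6.0 * mad, 1.0)
        else:
            thr = slope_threshold
        # hysteresis: activate above thr, deactivate below thr/3, so runs
        # hovering near threshold do not fragment
        active = np.zeros(len(t), dtype=bool)
        on = False
        for i, s in enumerate(np.abs(slope)):
            if not on and s > thr:
                on = True
            elif on and s < thr / 3.0:
                on = False
            active[i] = on
        # merge activity runs separated by gaps shorter than 1 min
        gap = max(int(round(1.0 / dt)), 1)
        idx = np.flatnonzero(np.diff(np.concatenate(
            ([0], active.view(np.int8), [0]))))
        runs = [[idx[i], idx[i + 1]] for i in range(0, len(idx), 2)]
        merged: list[list[int]] = []
        for run in runs:
            if merged and run[0] - merged[-1][1] < gap:
                merged[-1][1] = run[1]
            else:
                merged.append(run)
        if len(merged) < 4:
            raise ValueError(f"could not detect the four activity onsets "
                             f"(found {len(merged)})")
        onsets = [r[0] for r in merged[:4]]
        phase[:onsets[0]] = "baseline"
        phase[onsets[0]:onsets[1]] = "SLB"
        phase[onsets[1]:onsets[2]] = "rinse"
        phase[onsets[2]:onsets[3]] = "AM"
        phase[onsets[3]:] = "final_rinse"
        # SLB signature: frequency minimum (liposome load) then recovery
        slb = f3[onsets[0]:onsets[1]]
        if len(slb) > 3 and not slb.min() < min(slb[0], slb[-1]) - 1e-9:
            warnings.warn("SLB phase lacks the minimum-then-recovery "
                          "frequency signature", RuntimeWarning, stacklevel=2)
    else:
        raise ValueError("provide a protocol or set detect=True")
    out = trace.data.copy()
    out["phase"] = phase
    return QCMDTrace(out, trace.f0, dict(trace.meta))


def deposition_rate(trace: QCMDTrace, phase: str = "AM",
                    window: tuple[float, float] | None = None, n: int = 3,
                    equilibration_skip: float = 0.5,
                    params: SauerbreyParams = SauerbreyParams()) -> BindingKinetics:
    """Mass-deposition rate: OLS slope of Sauerbrey mass vs time.

    The regression window defaults to the first 5 minutes of the binding
    phase after a 30 s equilibration skip.  Returns slope, its standard
    error and the fit r^2.
    """
    seg = trace.phase_slice(phase)
    t0 = seg["time_min"].iloc[0]
    if window is None:
        window = (t0 + equilibration_skip, t0 + equilibration_skip + 5.0)
    sel = seg[(seg["time_min"] >= window[0]) & (seg["time_min"] <= window[1])]
    if len(sel) < 3:
        raise ValueError(f"regression window {window} has fewer than 3 points")
    mass = sauerbrey_mass(sel[f"f{n}"].to_numpy(), n, params)
    res = stats.linregress(sel["time_min"].to_numpy(), mass)
    return BindingKinetics(rate=float(res.slope), rate_se=float(res.stderr),
                           window=window, plateau_mass=None,
                           r_squared=float(res.rvalue ** 2))


def plateau_mass(trace: QCMDTrace, phase: str = "AM", n: int = 3,
                 final_fraction: float = 0.1,
                 params: SauerbreyParams = SauerbreyParams()) -> float:
    """Plateau mass: mean Sauerbrey mass over the final 10% of the phase.

    Emits a warning if the tail still drifts (|slope| over the averaging
    window exceeds 5% of the plateau per minute: plateau not reached)."""
    seg = trace.phase_slice(phase)
    k = max(int(round(len(seg) * final_fraction)), 1)
    tail = seg.iloc[-k:]
    mass = sauerbrey_mass(tail[f"f{n}"].to_numpy(), n, params)
    value = float(mass.mean())
    if len(tail) >= 3:
        slope = stats.linregress(tail["time_min"].to_numpy(), mass).slope
        if abs(slope) > 0.05 * max(abs(value), 1.0):
            warnings.warn(f"plateau slope test failed "
                          f"({slope:.2f} ng/cm^2/min): plateau may not be "
                          "reached", RuntimeWarning, stacklevel=2)
    return value
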