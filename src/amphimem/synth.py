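"""Seeded synthetic-data generators with machine-readable ground truth.

Every generator is bit-reproducible per (parameters, seed) and attaches --
or writes alongside its output -- a ground-truth record, so pipeline
recovery tests read truth from the sidecar rather than hard-coding it.

Generators:
  * QCM-D traces: baseline -> SLB formation (with the liposome
    overshoot/rupture signature) -> rinse -> exponential-approach
    amphiphile binding -> final rinse; Gaussian per-overtone noise at the
    instrument sensitivities (~1.8 ng/cm^2 mass, 0.1e-6 dissipation).
  * Umbrella-window samples: exact Boltzmann draws (inverse CDF on a fine
    grid) under a known analytic free-energy landscape plus harmonic bias.
  * QSAR datasets: correlated descriptor matrices with a planted linear
    response, split 10 train / 2 test.
  * Bilayer fixtures: desk-scale lamellar systems from the builders.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .build import SystemSpec, build_system
from .constants import KB, T_BODY
from .pmf import UmbrellaSpec, WindowSample
from .qcmd import (OVERTONES, BulkLiquid, F0_DEFAULT, QCMDTrace,
                   SauerbreyParams, VoigtFilm, voigt_predict)

__all__ = ["gen_qcmd_trace", "gen_umbrella_samples", "gen_qsar_dataset",
           "gen_bilayer_fixture", "write_with_truth", "QCMDTruth"]

#: instrument sensitivities: mass (ng/cm^2) and dissipation (1e-6)
MASS_NOISE_SD = 1.8
DISS_NOISE_SD = 0.1

DEFAULT_PHASES = {"baseline": 5.0, "SLB": 15.0, "rinse": 5.0,
                  "AM": 60.0, "final_rinse": 5.0}


@dataclass
class QCMDTruth:
    plateau_mass: float
    rate_constant: float
    slb_mass: float
    initial_rate: float           # plateau_mass * rate_constant
    phase_bounds: dict
    mode: str
    seed: int


def gen_qcmd_trace(plateau_mass: float = 750.0, rate_constant: float = 0.1,
                   slb_mass: float = 450.0,
                   noise_sd: float | None = None,
                   phase_durations: dict[str, float] | None = None,
                   f0: float = F0_DEFAULT, dt: float = 0.05,
                   mode: str = "rigid", film_template: VoigtFilm | None = None,
                   biexponential: tuple[float, float] | None = None,
                   seed: int = 0) -> tuple[QCMDTrace, QCMDTruth]:
    """Synthetic five-overtone QCM-D trace with known kinetics.

    The mass program is 0 during baseline, a smoothed step plus
    overshoot/recovery during SLB formation, and
    m(t) = M (1 - exp(-k t)) during the binding phase (optionally
    bi-exponential with ``biexponential=(fraction_slow, k_slow)``).  In
    ``rigid`` mode frequency shifts invert the Sauerbrey relation and
    dissipation stays at noise level; in ``viscoelastic`` mode the response
    comes from the Voigt film model with thickness tracking the mass
    program.  Noise is Gaussian and independent per overtone; the
    frequency noise per overtone is the instrument mass sensitivity
    mapped through Sauerbrey.
    """
    if noise_sd is not None and noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    durations = dict(DEFAULT_PHASES if phase_durations is None else phase_durations)
    if any(v <= 0 for v in durations.values()):
        raise ValueError("phase durations must be positive")
    rng = np.random.default_rng(seed)
    params = SauerbreyParams()
    bounds = {}
    t0 = 0.0
    for p, dur in durations.items():
        bounds[p] = (t0, t0 + dur)
        t0 += dur
    t = np.arange(0.0, t0, dt) + dt  # strictly increasing, no t=0 duplicate
    mass = np.zeros_like(t)
    slb0, slb1 = bounds["SLB"]
    am0, am1 = bounds["AM"]
    in_slb = (t >= slb0) & (t < slb1)
    ts = t[in_slb] - slb0
    k_slb = 1.0
    ramp = slb_mass * (1.0 - np.exp(-k_slb * ts))
    hump = 0.35 * slb_mass * np.exp(-0.5 * ((ts - 2.0) / 1.0) ** 2)
    mass[in_slb] = ramp + hump
    mass[t >= slb1] = slb_mass
    in_am = (t >= am0) & (t < am1)
    ta = t[in_am] - am0
    if biexponential is not None:
        frac_slow, k_slow = biexponential
        binding = plateau_mass * ((1 - frac_slow) * (1 - np.exp(-rate_constant * ta))
                                  + frac_slow * (1 - np.exp(-k_slow * ta)))
    else:
        binding = plateau_mass * (1.0 - np.exp(-rate_constant * ta))
    mass[in_am] = slb_mass + binding
    mass[t >= am1] = slb_mass + (binding[-1] if len(binding) else 0.0)

    # buffer-exchange transients at the rinse onsets: a brief mass dip that
    # fully recovers (loosely bound material re-equilibrating under flow);
    # zero net mass change, but a detectable activity burst
    def transient(t0, amplitude):
        tr = t - t0
        pulse = np.where(tr >= 0,
                         np.exp(-np.clip(tr, 0, None) / 0.5)
                         - np.exp(-np.clip(tr, 0, None) / 0.1), 0.0)
        return -amplitude * pulse

    mass = mass + transient(bounds["rinse"][0], 0.25 * slb_mass)
    mass = mass + transient(bounds["final_rinse"][0], 0.20 * plateau_mass)

    cols = {"time_min": t}
    mass_sd = MASS_NOISE_SD if noise_sd is None else noise_sd
    if mode == "rigid":
        for n in OVERTONES:
            f_clean = -mass / params.C * n          # invert Sauerbrey
            f_noise = (mass_sd / params.C) * n
            cols[f"f{n}"] = f_clean + f_noise * rng.standard_normal(len(t))
            d_sd = DISS_NOISE_SD if noise_sd is None else noise_sd * DISS_NOISE_SD / MASS_NOISE_SD
            cols[f"d{n}"] = d_sd * rng.standard_normal(len(t))
    elif mode == "viscoelastic":
        film = film_template or VoigtFilm(5e4, 2e-3, 1100.0, 1e-9)
        for n in OVERTONES:
            fs, ds = [], []
            for m in mass:
                h = m * 1e-8 / film.density  # ng/cm^2 -> kg/m^2, over kg/m^3
                fm = VoigtFilm(film.shear_modulus, film.viscosity,
                               film.density, max(h, 0.0))
                df, dd = voigt_predict(fm, BulkLiquid(), f0, n)
                fs.append(df)
                ds.append(dd)
            f_noise = (mass_sd / params.C) * n
            d_sd = DISS_NOISE_SD if noise_sd is None else noise_sd * DISS_NOISE_SD / MASS_NOISE_SD
            cols[f"f{n}"] = np.array(fs) + f_noise * rng.standard_normal(len(t))
            cols[f"d{n}"] = np.array(ds) + d_sd * rng.standard_normal(len(t))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    phase = np.array([""] * len(t), dtype=object)
    for p, (a, b) in bounds.items():
        phase[(t >= a) & (t < b)] = p
    data = pd.DataFrame({**cols, "phase": phase})
    truth = QCMDTruth(plateau_mass=plateau_mass, rate_constant=rate_constant,
                      slb_mass=slb_mass,
                      initial_rate=plateau_mass * rate_constant,
                      phase_bounds=bounds, mode=mode, seed=seed)
    trace = QCMDTrace(data, f0=f0, meta={"truth": asdict(truth)})
    return trace, truth


def gen_umbrella_samples(analytic_pmf, spec: UmbrellaSpec, n_samples: int = 2000,
                         temperature: float = T_BODY, seed: int = 0,
                         z_range: tuple[float, float] | None = None,
                         centers: np.ndarray | None = None,
                         grid_points: int = 4000) -> list[WindowSample]:
    """Exact Boltzmann samples per umbrella window under a known landscape.

    Draws from the density prop. to exp(-[U(z) + k/2 (z - zc)^2]/kT) by
    inverse-CDF sampling on a fine grid; U is the analytic free-energy
    callable (kJ/mol as a function of z in nm)."""
    rng = np.random.default_rng(seed)
    kT = KB * temperature
    if centers is None:
        centers = spec.window_centers()
    out = []
    for zc in centers:
        half = max(6.0 * np.sqrt(kT / spec.k_restraint), 0.5)
        lo, hi = (zc - half, zc + half) if z_range is None else z_range
        z = np.linspace(lo, hi, grid_points)
        u = np.asarray(analytic_pmf(z), float) + 0.5 * spec.k_restraint * (z - zc) ** 2
        if not np.all(np.isfinite(u)):
            raise ValueError("analytic landscape not finite over the window")
        w = np.exp(-(u - u.min()) / kT)
        norm = np.trapezoid(w, z)
        if norm <= 0 or not np.isfinite(norm):
            raise ValueError("unnormalizable biased density")
        cdf = np.concatenate(([0.0], np.cumsum((w[1:] + w[:-1]) / 2 * np.diff(z))))
        cdf /= cdf[-1]
        samples = np.interp(rng.random(n_samples), cdf, z)
        out.append(WindowSample(center=float(zc), samples=samples,
                                k_restraint=spec.k_restraint,
                                temperature=temperature))
    return out


def gen_qsar_dataset(n_structures: int = 12, n_descriptors: int = 20,
                     informative_set: list[int] | None = None,
                     coefficients: np.ndarray | None = None,
                     noise_sd: float | None = None, snr: float = 10.0,
                     n_test: int = 2, latent_rank: int = 4,
                     seed: int = 0):
    """Correlated descriptor matrix with a planted linear response.

    The informative descriptors are manifest variables of one driving
    latent trait (loading 0.85, with loading signs matching their
    coefficients) -- the typical QSAR situation where several descriptors
    report the same underlying property that drives the activity; the
    remaining columns carry their own low-rank latent structure plus
    independent noise.  The response is y = X beta + eps, autoscaled X.
    When ``noise_sd`` is None it is set from ``snr``:
    var(X beta)/var(eps) = snr.  Default design mirrors the study: 12
    structures split 10 train / 2 test.

    Returns (table, response, truth) where truth records the split, the
    informative columns and their coefficients, and the realized noise sd.
    """
    if n_structures < 3:
        raise ValueError("need at least 3 structures")
    rng = np.random.default_rng(seed)
    informative = list(informative_set) if informative_set is not None else [0, 1, 2, 3]
    if any(j >= n_descriptors for j in informative):
        raise ValueError("informative_set outside descriptor columns")
    if coefficients is None:
        base = [3.0, -3.0, 2.0, -2.0]
        coefficients = np.array([base[i % 4] * (1 + i // 4)
                                 for i in range(len(informative))])
    coefficients = np.asarray(coefficients, float)
    load = 0.85
    trait = rng.standard_normal(n_structures)
    X = np.empty((n_structures, n_descriptors))
    nuisance = [j for j in range(n_descriptors) if j not in informative]
    for j, b in zip(informative, coefficients):
        X[:, j] = np.sign(b) * load * trait \
            + np.sqrt(1 - load ** 2) * rng.standard_normal(n_structures)
    if nuisance:
        rank = min(latent_rank, len(nuisance))
        L = rng.standard_normal((n_structures, rank))
        G = rng.standard_normal((rank, len(nuisance))) * 0.8
        X[:, nuisance] = L @ G + rng.standard_normal((n_structures, len(nuisance)))
    X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    beta = np.zeros(n_descriptors)
    beta[informative] = coefficients
    signal = X @ beta
    if noise_sd is None:
        noise_sd = float(np.std(signal) / np.sqrt(snr))
    y = signal + noise_sd * rng.standard_normal(n_structures)
    cols = [f"desc_{i:02d}" for i in range(n_descriptors)]
    idx = [f"AM_{chr(65 + i)}" for i in range(n_structures)]
    table = pd.DataFrame(X, columns=cols, index=idx)
    response = pd.Series(y, index=idx, name="response")
    test_rows = idx[-n_test:] if n_test else []
    truth = {"informative_columns": [cols[j] for j in informative],
             "coefficients": {cols[j]: float(b)
                              for j, b in zip(informative, coefficients)},
             "noise_sd": float(noise_sd), "snr": float(snr),
             "train_rows": idx[:n_structures - n_test],
             "test_rows": test_rows, "seed": seed}
    return table, response, truth


def gen_bilayer_fixture(n_lipids: int = 128, with_am: str | None = None,
                        n_waters: int | str = "fill", salt_conc: float = 120.0,
                        seed: int = 0):
    """Desk-scale bilayer fixture (delegates to the system builders)."""
    spec = SystemSpec(n_lipids=n_lipids, n_waters=n_waters,
                      salt_conc=salt_conc, am_species=with_am, seed=seed)
    top, frame = build_system(spec)
    top.metadata["fixture"] = True
    truth = {"n_lipids": n_lipids, "with_am": with_am, "n_waters": n_waters,
             "salt_conc": salt_conc, "seed": seed,
             "thickness0": top.metadata.get("thickness0"),
             "midplane_z": top.metadata.get("midplane_z")}
    return top, frame, truth


def write_with_truth(obj, truth: dict, out_prefix) -> Path:
    """Write an artifact plus its ``<prefix>.truth.json`` sidecar."""
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(obj, QCMDTrace):
        obj.write_csv(out_prefix.with_suffix(".csv"))
    elif isinstance(obj, pd.DataFrame):
        obj.to_csv(out_prefix.with_suffix(".csv"))
    elif isinstance(obj, pd.Series):
        obj.to_frame().to_csv(out_prefix.with_suffix(".csv"))
    elif hasattr(obj, "save"):
        obj.save(out_prefix.with_suffix(".top"))
    else:
        raise TypeError(f"cannot serialize {type(obj)}")
    sidecar = out_prefix.with_suffix(".truth.json")
    with open(sidecar, "w") as fh:
        json.dump(truth, fh, indent=1, default=str)
    return sidecar
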