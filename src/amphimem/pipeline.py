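"""Workflow orchestration: configuration, manifests, and the end-to-end
fixture pipeline (simulation arm: build -> simulate -> analyze/PMF;
experiment arm: QCM-D traces -> response table -> QSAR).

A run is described by a single configuration mapping; every output file is
listed in a manifest carrying the configuration hash, and all randomness
flows from one master seed via named substreams.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("amphimem")

__all__ = ["DEFAULT_CONFIG", "config_hash", "derive_seed", "run_workflow",
           "report", "DependencyError"]


class DependencyError(RuntimeError):
    pass


DEFAULT_CONFIG = {
    "workflow": "full",
    "seed": 0,
    "out_dir": "amphimem_run",
    "simulate": {"n_lipids": 64, "n_waters": 300, "salt_conc": 0.0,
                 "steps": 500, "stride": 100, "ensemble": "NVT"},
    "pmf": {"n_windows": 12, "k_restraint": 200.0, "span": (1.0, 4.0),
            "n_samples": 800, "bin_width": 0.05},
    "qcmd": {"plateau_mass": 750.0, "rate_constant": 0.1, "slb_mass": 450.0},
    "qsar": {"n_structures": 12, "n_descriptors": 20, "n_components": 4},
}


def config_hash(config: dict) -> str:
    canon = yaml.safe_dump(config, sort_keys=True, default_flow_style=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def derive_seed(master: int, stream: str) -> int:
    """Named substream seed below 2^31, stable across runs."""
    h = hashlib.sha256(f"{master}:{stream}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        out[k] = _merge(base[k], v) if isinstance(v, dict) and \
            isinstance(base.get(k), dict) else v
    return out


def run_workflow(config: dict | None = None) -> dict:
    """Execute the configured stages; returns the output manifest.

    Stages consume only files recorded in the manifest; any failure stops
    the chain with a stage-level diagnostic.  Re-running with an identical
    configuration reproduces identical output hashes.
    """
    cfg = _merge(DEFAULT_CONFIG, config or {})
    out_dir = Path(cfg["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    chash = config_hash(cfg)
    seed = int(cfg["seed"])
    workflow = cfg["workflow"]
    stages = (["simulate", "analyze", "pmf", "qcmd", "qsar"]
              if workflow == "full" else [workflow])
    manifest: dict = {"config_hash": chash, "seed": seed, "workflow": workflow,
                      "outputs": {}}
    with open(out_dir / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh)

    def add(stage: str, name: str, path: Path, **extra):
        digest = hashlib.sha256(path.read_bytes()).hexdigest()[:16]
        manifest["outputs"].setdefault(stage, {})[name] = \
            {"path": str(path), "sha": digest, **extra}

    state: dict = {}
    for stage in stages:
        logger.info("stage %s", stage)
        try:
            if stage == "simulate":
                _stage_simulate(cfg, seed, out_dir, state, add)
            elif stage == "analyze":
                if "trajectory" not in state:
                    raise DependencyError("analyze requires the simulate stage "
                                          "(missing trajectory artifact)")
                _stage_analyze(cfg, out_dir, state, add)
            elif stage == "pmf":
                _stage_pmf(cfg, seed, out_dir, state, add)
            elif stage == "qcmd":
                _stage_qcmd(cfg, seed, out_dir, state, add)
            elif stage == "qsar":
                _stage_qsar(cfg, seed, out_dir, state, add)
            else:
                raise DependencyError(f"unknown workflow stage {stage!r}")
        except DependencyError:
            raise
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


def _stage_simulate(cfg, seed, out_dir, state, add):
    from .build import SystemSpec, build_system
    from .engine import IntegratorConfig, System, maxwell_velocities, \
        minimize_energy, run_md
    from .io import save_trajectory
    s = cfg["simulate"]
    spec = SystemSpec(n_lipids=s["n_lipids"], n_waters=s["n_waters"],
                      salt_conc=s["salt_conc"],
                      am_species=s.get("am_species"),
                      seed=derive_seed(seed, "build"))
    top, frame = build_system(spec)
    system = System(top, frame)
    minimize_energy(system, max_steps=50)
    system.frame.velocities = maxwell_velocities(
        top, 310.0, derive_seed(seed, "velocities"))
    icfg = IntegratorConfig(ensemble=s["ensemble"],
                            seed=derive_seed(seed, "md"))
    traj = run_md(system, icfg, s["steps"], s["stride"])
    tpath = out_dir / "trajectory.npz"
    save_trajectory(traj, tpath)
    top.save(out_dir / "system.top")
    traj.log.to_csv(out_dir / "energies.csv", index=False)
    add("simulate", "trajectory", tpath, n_frames=len(traj))
    add("simulate", "topology", out_dir / "system.top")
    add("simulate", "energies", out_dir / "energies.csv")
    state["trajectory"] = traj
    state["topology"] = top


def _stage_analyze(cfg, out_dir, state, add):
    from .analysis import bilayer_thickness, detect_insertions
    traj, top = state["trajectory"], state["topology"]
    thick = bilayer_thickness(traj, top)
    rows = {"bilayer_thickness_nm": thick}
    if len(top.indices(role="head")):
        ins = detect_insertions(traj, top)
        ins.to_frame().to_csv(out_dir / "insertion.csv", index=False)
        add("analyze", "insertion", out_dir / "insertion.csv")
        rows["inserted_fraction"] = ins.inserted_fraction
    path = out_dir / "analysis_summary.csv"
    pd.DataFrame([rows]).to_csv(path, index=False)
    add("analyze", "summary", path, **{k: float(v) for k, v in rows.items()})
    state["analysis"] = rows


def _stage_pmf(cfg, seed, out_dir, state, add):
    from .pmf import UmbrellaSpec, normalize_pmf, wham
    from .synth import gen_umbrella_samples
    p = cfg["pmf"]
    lo, hi = p["span"]
    centers = np.linspace(hi, lo, p["n_windows"])
    z_min = (lo + hi) / 2.0

    def landscape(z):
        return 10.0 * (np.asarray(z) - z_min) ** 2

    spec = UmbrellaSpec(k_restraint=p["k_restraint"])
    windows = gen_umbrella_samples(landscape, spec, n_samples=p["n_samples"],
                                   seed=derive_seed(seed, "umbrella"),
                                   centers=centers)
    profile = wham(windows, bin_width=p["bin_width"])
    profile = normalize_pmf(profile, reference_z=float(profile.z[-2]))
    path = out_dir / "pmf.csv"
    profile.save_csv(path)
    add("pmf", "profile", path, minimum_z=profile.minimum()[0])
    state["pmf"] = profile


def _stage_qcmd(cfg, seed, out_dir, state, add):
    from .qcmd import deposition_rate, plateau_mass
    from .synth import gen_qcmd_trace, write_with_truth
    q = cfg["qcmd"]
    trace, truth = gen_qcmd_trace(plateau_mass=q["plateau_mass"],
                                  rate_constant=q["rate_constant"],
                                  slb_mass=q["slb_mass"],
                                  seed=derive_seed(seed, "qcmd"))
    write_with_truth(trace, truth.__dict__, out_dir / "qcmd_trace")
    kin = deposition_rate(trace)
    plateau = plateau_mass(trace) - truth.slb_mass
    path = out_dir / "qcmd_summary.csv"
    pd.DataFrame([{"plateau_mass_ng_cm2": plateau,
                   "rate_ng_cm2_min": kin.rate, "rate_se": kin.rate_se,
                   "r_squared": kin.r_squared}]).to_csv(path, index=False)
    add("qcmd", "trace", out_dir / "qcmd_trace.csv")
    add("qcmd", "summary", path, plateau=float(plateau), rate=float(kin.rate))
    state["qcmd"] = {"plateau": plateau, "rate": kin.rate}


def _stage_qsar(cfg, seed, out_dir, state, add):
    from .qsar import loo_q2, pls_fit, pls_predict
    from .synth import gen_qsar_dataset
    q = cfg["qsar"]
    table, y, truth = gen_qsar_dataset(n_structures=q["n_structures"],
                                       n_descriptors=q["n_descriptors"],
                                       seed=derive_seed(seed, "qsar"))
    train, test = truth["train_rows"], truth["test_rows"]
    model = pls_fit(table.loc[train], y.loc[train], q["n_components"])
    q2 = loo_q2(table.loc[train], y.loc[train], q["n_components"])
    pred = pls_predict(model, table.loc[test]) if test else None
    path = out_dir / "qsar_metrics.csv"
    pd.DataFrame([{"r_squared": model.r_squared, "q_squared": q2,
                   "n_components": model.n_components}]).to_csv(path, index=False)
    add("qsar", "metrics", path, r2=float(model.r_squared), q2=float(q2))
    if pred is not None:
        ppath = out_dir / "qsar_predictions.csv"
        pred.assign(observed=y.loc[test]).to_csv(ppath)
        add("qsar", "predictions", ppath)
    state["qsar"] = {"r2": model.r_squared, "q2": q2}


def report(manifest: dict) -> str:
    """Human-readable summary of a completed manifest (read-only)."""
    lines = [f"amphimem run report (config {manifest.get('config_hash', '?')}, "
             f"seed {manifest.get('seed', '?')})"]
    outputs = manifest.get("outputs", {})
    if not outputs:
        lines.append("(empty manifest)")
    for stage, items in outputs.items():
        lines.append(f"\n[{stage}]")
        for name, info in items.items():
            extras = {k: v for k, v in info.items() if k not in ("path", "sha")}
            suffix = "".join(f"  {k}={v:.4g}" if isinstance(v, float)
                             else f"  {k}={v}" for k, v in extras.items())
            lines.append(f"  {name}: {info['path']}{suffix}")
    return "\n".join(lines) + "\n"


def verify_manifest(manifest: dict) -> bool:
    """Check that every listed output still hashes to its recorded value."""
    for items in manifest.get("outputs", {}).values():
        for info in items.values():
            p = Path(info["path"])
            if not p.exists():
                return False
            if hashlib.sha256(p.read_bytes()).hexdigest()[:16] != info["sha"]:
                return False
    return True
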