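"""Descriptor-based QSAR: open descriptor set, PLS regression with
leave-one-out validation, PCA, and loading decomposition.

Descriptors are computed from the coarse-grained bead topologies (2D:
composition, connectivity, Crippen-style logP analog, polar/hydrophobic
surface-area estimates from bead classes) plus, when a conformer is
supplied, shape descriptors (radius of gyration, charge-exposure
fraction) that distinguish stereoisomer pairs whose 2D graphs are
identical.  The regression is partial least squares (NIPALS) on
autoscaled data with the component count capped at four; internal
validation is leave-one-out q^2 = 1 - PRESS/TSS.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.cross_decomposition import PLSRegression
from sklearn.decomposition import PCA as _SkPCA

from .topology import BeadTopology

__all__ = ["compute_descriptors", "descriptor_table", "filter_descriptors",
           "PLSModel", "pls_fit", "loo_q2", "pls_predict", "PCAModel", "pca",
           "loading_report", "DESCRIPTOR_ANALOGS"]

#: mapping from proprietary descriptor names in the field's reports to the
#: open analogs computed here
DESCRIPTOR_ANALOGS = {
    "slogP": "logp_analog",
    "ASA_H": "hydrophobic_area",
    "ASA_P": "polar_area",
    "Weight": "molecular_weight",
}

# Crippen-style per-bead-class lipophilicity increments (logP analog)
_LOGP_INCREMENT = {"C": 0.55, "N": 0.0, "P": -0.45, "Q": -1.2}


def _bead_area(diameter: float) -> float:
    return np.pi * diameter ** 2  # nm^2, exposed-sphere estimate


def compute_descriptors(topology: BeadTopology,
                        conformer: np.ndarray | None = None) -> pd.Series:
    """Descriptor vector for one structure.

    2D (graph/composition) descriptors are deterministic functions of the
    topology; conformational descriptors (radius of gyration,
    charge-exposure fraction, span) require ``conformer`` coordinates with
    one row per bead.
    """
    n = topology.n_beads
    if conformer is not None and len(conformer) != n:
        raise ValueError(f"conformer has {len(conformer)} rows for {n} beads")
    classes = [b.bead_class for b in topology.beads]
    charges = topology.charges()
    masses = topology.masses()
    counts = {c: classes.count(c) for c in "PNCQ"}
    d: dict[str, float] = {
        "n_beads": float(n),
        "molecular_weight": float(masses.sum()),
        "net_charge": float(charges.sum()),
        "abs_charge": float(np.abs(charges).sum()),
        "n_anionic": float((charges < 0).sum()),
        "n_cationic": float((charges > 0).sum()),
        "n_polar": float(counts["P"]),
        "n_nonpolar": float(counts["N"]),
        "n_apolar": float(counts["C"]),
        "n_charged": float(counts["Q"]),
        "frac_apolar": counts["C"] / n,
        "frac_polar": (counts["P"] + counts["Q"]) / n,
        "n_ring_beads": float(sum(b.is_ring for b in topology.beads)),
        "n_bonds": float(len(topology.bonds)),
        "n_angles": float(len(topology.angles)),
        "logp_analog": float(sum(_LOGP_INCREMENT[c] for c in classes)),
        "hydrophobic_area": float(sum(_bead_area(b.diameter)
                                      for b in topology.beads
                                      if b.bead_class == "C")),
        "polar_area": float(sum(_bead_area(b.diameter)
                                for b in topology.beads
                                if b.bead_class in ("P", "Q"))),
        "n_peg": float(len(topology.indices(role="peg"))),
        "n_arm_beads": float(len(topology.indices(role="arm"))),
        "n_head_beads": float(len(topology.indices(role="head"))),
    }
    g = nx.Graph()
    g.add_nodes_from(range(n))
    g.add_edges_from((i, j) for i, j, _ in topology.bonds)
    deg = dict(g.degree())
    d["n_branch_points"] = float(sum(v > 2 for v in deg.values()))
    d["randic_index"] = float(sum(1.0 / np.sqrt(deg[i] * deg[j])
                                  for i, j in g.edges))
    if nx.is_connected(g) and n > 1:
        d["wiener_index"] = float(nx.wiener_index(g))
        ecc = nx.eccentricity(g)
        d["graph_diameter"] = float(max(ecc.values()))
    else:
        d["wiener_index"] = np.nan
        d["graph_diameter"] = np.nan
    if conformer is not None:
        com = np.average(conformer, axis=0, weights=masses)
        rg2 = np.average(np.sum((conformer - com) ** 2, axis=1), weights=masses)
        d["radius_of_gyration"] = float(np.sqrt(rg2))
        d["span"] = float(pdist(conformer).max()) if n > 1 else 0.0
        charged = np.flatnonzero(charges != 0)
        if len(charged):
            dists = squareform(pdist(conformer))
            exposure = []
            for i in charged:
                near = np.sum((dists[i] < 0.8) & (np.arange(n) != i))
                exposure.append(1.0 - near / max(n - 1, 1))
            d["charge_exposure"] = float(np.mean(exposure))
            d["charge_com_dist"] = float(np.mean(
                np.linalg.norm(conformer[charged] - com, axis=1)))
        else:
            d["charge_exposure"] = 0.0
            d["charge_com_dist"] = 0.0
    return pd.Series(d)


def descriptor_table(structures: dict[str, BeadTopology],
                     conformers: dict[str, np.ndarray] | None = None) -> pd.DataFrame:
    """Rows = structures, columns = descriptors; NaN columns dropped."""
    rows = {name: compute_descriptors(top,
                                      None if conformers is None
                                      else conformers.get(name))
            for name, top in structures.items()}
    table = pd.DataFrame(rows).T
    return table.dropna(axis=1)


def filter_descriptors(table: pd.DataFrame, variance_floor: float = 1e-8,
                       correlation_ceiling: float = 0.98) -> pd.DataFrame:
    """Information-content filtering: drop near-constant columns and, for
    each pair correlated above the ceiling, the later column in name order.
    Idempotent on tables already satisfying the thresholds."""
    if len(table) < 2:
        raise ValueError("need at least two rows to filter")
    keep = table.columns[table.var(ddof=1) >= variance_floor]
    t = table[sorted(keep)]
    if t.shape[1] == 0:
        raise ValueError("all descriptor columns dropped by variance filter")
    corr = t.corr().abs()
    drop: set[str] = set()
    cols = list(t.columns)
    for a_i, a in enumerate(cols):
        if a in drop:
            continue
        for b in cols[a_i + 1:]:
            if b not in drop and corr.loc[a, b] > correlation_ceiling:
                drop.add(b)
    out = t[[c for c in cols if c not in drop]]
    if out.shape[1] == 0:
        raise ValueError("all descriptor columns dropped")
    return out


@dataclass
class PLSModel:
    """Fitted PLS regression with autoscaling baked in."""

    columns: list[str]
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    y_scale: float
    coef_scaled: np.ndarray          # on autoscaled X, scaled y
    weights: np.ndarray              # p x a
    x_loadings: np.ndarray           # p x a
    y_loadings: np.ndarray           # a
    x_scores: np.ndarray             # n x a
    n_components: int
    r_squared: float
    q_squared: float | None = None
    x_min: np.ndarray | None = None  # training ranges (applicability domain)
    x_max: np.ndarray | None = None

    @property
    def coefficients(self) -> pd.Series:
        """Regression coefficients on the original descriptor scale."""
        b = self.coef_scaled * self.y_scale / self.x_scale
        return pd.Series(b, index=self.columns)


def _as_xy(X, y):
    if isinstance(X, pd.DataFrame):
        cols = list(X.columns)
        Xv = X.to_numpy(float)
    else:
        Xv = np.asarray(X, float)
        cols = [f"x{i}" for i in range(Xv.shape[1])]
    yv = np.asarray(y, float).ravel()
    return Xv, yv, cols


def pls_fit(X, y, n_components: int = 4) -> PLSModel:
    """NIPALS partial-least-squares regression on autoscaled data.

    ``n_components`` defaults to four latent variables and is reduced to
    min(n_rows - 1, n_columns) when the data cannot support it.  Reports
    the training r^2.
    """
    Xv, yv, cols = _as_xy(X, y)
    n, p = Xv.shape
    if len(yv) != n:
        raise ValueError("X and y length mismatch")
    if n < 2 or np.var(yv) == 0:
        raise ValueError("response must have nonzero variance over >= 2 rows")
    a = int(min(n_components, n - 1, p))
    x_mean = Xv.mean(axis=0)
    x_scale = Xv.std(axis=0, ddof=1)
    x_scale[x_scale == 0] = 1.0
    y_mean = float(yv.mean())
    y_scale = float(yv.std(ddof=1))
    Xs = (Xv - x_mean) / x_scale
    ys = (yv - y_mean) / y_scale
    pls = PLSRegression(n_components=a, scale=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pls.fit(Xs, ys)
    yhat = pls.predict(Xs).ravel() * y_scale + y_mean
    ss_res = float(np.sum((yv - yhat) ** 2))
    ss_tot = float(np.sum((yv - yv.mean()) ** 2))
    return PLSModel(columns=cols, x_mean=x_mean, x_scale=x_scale,
                    y_mean=y_mean, y_scale=y_scale,
                    coef_scaled=pls.coef_.ravel(),
                    weights=pls.x_weights_, x_loadings=pls.x_loadings_,
                    y_loadings=pls.y_loadings_.ravel(),
                    x_scores=pls.x_scores_, n_components=a,
                    r_squared=1.0 - ss_res / ss_tot,
                    x_min=Xv.min(axis=0), x_max=Xv.max(axis=0))


def pls_predict(model: PLSModel, X_new) -> pd.DataFrame:
    """Apply a fitted PLS model; flags rows outside the training descriptor
    ranges (outside the applicability domain)."""
    if isinstance(X_new, pd.DataFrame):
        missing = [c for c in model.columns if c not in X_new.columns]
        if missing:
            raise ValueError(f"missing descriptor columns: {missing}")
        Xv = X_new[model.columns].to_numpy(float)
        index = X_new.index
    else:
        Xv = np.asarray(X_new, float)
        if Xv.shape[1] != len(model.columns):
            raise ValueError(f"expected {len(model.columns)} columns, "
                             f"got {Xv.shape[1]}")
        index = pd.RangeIndex(len(Xv))
    Xs = (Xv - model.x_mean) / model.x_scale
    pred = Xs @ model.coef_scaled * model.y_scale + model.y_mean
    in_domain = np.ones(len(Xv), dtype=bool)
    if model.x_min is not None:
        tol = 1e-9 + 1e-9 * np.abs(model.x_max - model.x_min)
        in_domain = np.all((Xv >= model.x_min - tol) &
                           (Xv <= model.x_max + tol), axis=1)
    return pd.DataFrame({"prediction": pred, "in_domain": in_domain},
                        index=index)


def loo_q2(X, y, n_components: int = 4) -> float:
    """Leave-one-out cross-validated q^2 = 1 - PRESS/TSS.

    Each row is predicted by a model trained without it; descriptor
    columns losing all variance in a fold are dropped fold-wise."""
    Xv, yv, cols = _as_xy(X, y)
    n = len(yv)
    if n < 3:
        raise ValueError("need at least 3 rows for leave-one-out validation")
    press = 0.0
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        Xt = Xv[mask]
        var = Xt.std(axis=0, ddof=1)
        keep = var > 0
        m = pls_fit(Xt[:, keep], yv[mask], n_components)
        pred = pls_predict(m, Xv[i:i + 1, keep])["prediction"].iloc[0]
        press += (yv[i] - pred) ** 2
    tss = float(np.sum((yv - yv.mean()) ** 2))
    return 1.0 - press / tss


def select_components(X, y, max_components: int = 4) -> int:
    """Component count maximizing LOO q^2, capped at 4; ties -> fewer."""
    best_a, best_q = 1, -np.inf
    for a in range(1, max_components + 1):
        q = loo_q2(X, y, a)
        if q > best_q + 1e-12:
            best_a, best_q = a, q
    return best_a


@dataclass
class PCAModel:
    columns: list[str]
    scores: np.ndarray
    loadings: np.ndarray            # p x a, orthonormal columns
    explained_variance: np.ndarray
    explained_variance_ratio: np.ndarray
    mean: np.ndarray
    scale: np.ndarray


def pca(X, n_components: int | None = None) -> PCAModel:
    """Centered/autoscaled principal-component analysis."""
    Xv, _, cols = _as_xy(X, np.zeros(len(X)))
    n, p = Xv.shape
    if n < 2:
        raise ValueError("need at least two rows")
    a = min(n_components or min(n - 1, p), n - 1, p)
    if n_components is not None and a < n_components:
        warnings.warn(f"reduced to {a} components (rank limit)",
                      RuntimeWarning, stacklevel=2)
    mean = Xv.mean(axis=0)
    scale = Xv.std(axis=0, ddof=1)
    scale[scale == 0] = 1.0
    Xs = (Xv - mean) / scale
    sk = _SkPCA(n_components=a)
    scores = sk.fit_transform(Xs)
    return PCAModel(columns=cols, scores=scores, loadings=sk.components_.T,
                    explained_variance=sk.explained_variance_,
                    explained_variance_ratio=sk.explained_variance_ratio_,
                    mean=mean, scale=scale)


def loading_report(model: PLSModel | PCAModel, component: int = 0,
                   top: int | None = None) -> pd.DataFrame:
    """Descriptors ranked by absolute loading/coefficient contribution.

    For a PLS model the ranking uses the scaled regression coefficients
    (sign preserved); for a PCA model the loadings of the requested
    component.  Rank order is invariant to column permutation."""
    if isinstance(model, PLSModel):
        vals = pd.Series(model.coef_scaled, index=model.columns)
        kind = "pls_coefficient"
    else:
        vals = pd.Series(model.loadings[:, component], index=model.columns)
        kind = f"pca_loading_{component + 1}"
    out = pd.DataFrame({"descriptor": vals.index, kind: vals.to_numpy(),
                        "abs_contribution": np.abs(vals.to_numpy())})
    out = out.sort_values(["abs_contribution", "descriptor"],
                          ascending=[False, True]).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out if top is None else out.head(top)
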