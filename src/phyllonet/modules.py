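"""Module detection, eigengenes, saponin PCA, candidate screening, ML check.

Modules come from fast-greedy (Clauset–Newman–Moore) modularity
maximization.  Each module with >= 5 members gets an eigengene: the first
principal component of the standardized member relative abundances, sign
oriented so it tracks the members' mean profile.  Saponin variation is
summarized by covariance-PCA PC1 (contents are absolute quantifications,
so no variance scaling).  Candidate modules and environmental factors are
screened by Spearman correlation with saponin PC1 at FDR < 0.05, and the
added predictive value of candidate eigengenes is checked with paired
five-fold KNN and random-forest regressions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold
from sklearn.neighbors import KNeighborsRegressor

from .network import Network, bh_adjust

__all__ = [
    "ModulePartition",
    "SaponinSummary",
    "detect_modules",
    "module_eigengene",
    "compute_eigengenes",
    "saponin_pca",
    "collinearity_filter",
    "screen_candidates",
    "ml_compare",
]

MIN_EIGENGENE_SIZE = 5


@dataclass
class ModulePartition:
    """Node -> module assignment with optional per-module eigengenes."""

    node_to_module: dict[str, int]
    eigengenes: pd.DataFrame | None = None  # samples x "M<k>"
    variance_explained: dict[int, float] = field(default_factory=dict)

    def communities(self) -> list[set]:
        out: dict[int, set] = {}
        for v, m in self.node_to_module.items():
            out.setdefault(m, set()).add(v)
        return [out[m] for m in sorted(out)]

    def members(self, module: int) -> list[str]:
        return sorted(v for v, m in self.node_to_module.items() if m == module)

    @property
    def sizes(self) -> dict[int, int]:
        sizes: dict[int, int] = {}
        for m in self.node_to_module.values():
            sizes[m] = sizes.get(m, 0) + 1
        return sizes


@dataclass
class SaponinSummary:
    pc1: pd.Series  # per-sample PC1 scores
    variance_fraction: float
    total: pd.Series  # per-sample total content (mg/g)
    all_fractions: np.ndarray


def detect_modules(net: Network | nx.Graph, seed: int | None = None) -> ModulePartition:
    """Fast-greedy (CNM) modularity maximization on the unweighted graph.

    Modules are renumbered 0.. by decreasing size (ties by smallest member
    id) so module labels are deterministic.  ``seed`` is accepted for
    interface symmetry; the algorithm itself is deterministic.
    """
    g = net.graph if isinstance(net, Network) else net
    if g.number_of_nodes() == 0:
        raise ValueError("network is empty")
    if g.number_of_edges() == 0:
        comms = [{v} for v in g.nodes]
    else:
        comms = [set(c) for c in nx.community.greedy_modularity_communities(g)]
    comms.sort(key=lambda c: (-len(c), min(str(v) for v in c)))
    node_to_module = {v: m for m, c in enumerate(comms) for v in c}
    return ModulePartition(node_to_module=node_to_module)


def module_eigengene(
    abund: pd.DataFrame, members: list[str]
) -> tuple[pd.Series, float]:
    """PC1 of the standardized member relative-abundance submatrix.

    The sign is oriented so the eigengene correlates non-negatively with
    the members' mean standardized profile (WGCNA-style convention).
    Returns ``(eigengene, variance_explained)``.
    """
    members = [m for m in members if m in abund.columns]
    if len(members) < MIN_EIGENGENE_SIZE:
        raise ValueError(f"need >= {MIN_EIGENGENE_SIZE} members present")
    rel = abund.div(abund.sum(axis=1), axis=0)
    sub = rel[members].to_numpy(dtype=float)
    sd = sub.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} constant member profiles", stacklevel=2
        )
        sub = sub[:, keep]
        sd = sd[keep]
    z = (sub - sub.mean(axis=0)) / sd
    u, s, _ = np.linalg.svd(z, full_matrices=False)
    scores = u[:, 0] * s[0]
    mean_profile = z.mean(axis=1)
    if np.dot(scores, mean_profile) < 0:
        scores = -scores
    var_explained = float(s[0] ** 2 / (s**2).sum())
    return pd.Series(scores, index=abund.index), var_explained


def compute_eigengenes(
    abund: pd.DataFrame,
    partition: ModulePartition,
    min_size: int = MIN_EIGENGENE_SIZE,
) -> pd.DataFrame:
    """Eigengenes for every module with >= min_size members; fills partition."""
    cols = {}
    for m, size in sorted(partition.sizes.items()):
        if size < min_size:
            continue
        eg, ve = module_eigengene(abund, partition.members(m))
        cols[f"M{m}"] = eg
        partition.variance_explained[m] = ve
    eigengenes = pd.DataFrame(cols, index=abund.index)
    partition.eigengenes = eigengenes
    return eigengenes


def saponin_pca(sap: pd.DataFrame) -> SaponinSummary:
    """Covariance PCA (centered, unscaled) of the saponin content table.

    Contents are absolute quantifications on a shared mg/g scale, so
    columns are deliberately not variance-scaled; PC1 then weights the
    saponins by their actual content variability.
    """
    if len(sap) < 3:
        raise ValueError("need at least 3 samples")
    x = sap.to_numpy(dtype=float)
    xc = x - x.mean(axis=0)
    u, s, _ = np.linalg.svd(xc, full_matrices=False)
    scores = u[:, 0] * s[0]
    fractions = s**2 / (s**2).sum()
    return SaponinSummary(
        pc1=pd.Series(scores, index=sap.index, name="PC1"),
        variance_fraction=float(fractions[0]),
        total=sap.sum(axis=1).rename("total_saponin"),
        all_fractions=fractions,
    )


def collinearity_filter(env: pd.DataFrame, rho2_cut: float = 0.6) -> pd.DataFrame:
    """Greedy removal of collinear variables (Spearman rho^2 > cut).

    While any pair exceeds the cut, drop the variable of the worst pair
    with the larger mean |rho| to all remaining variables.
    """
    cols = list(env.columns)
    while len(cols) > 1:
        r = stats.spearmanr(env[cols].to_numpy())[0]
        r = np.atleast_2d(r)
        r2 = r**2
        np.fill_diagonal(r2, 0.0)
        i, j = np.unravel_index(np.argmax(r2), r2.shape)
        if r2[i, j] <= rho2_cut:
            break
        mean_abs = (np.abs(r).sum(axis=0) - 1) / (len(cols) - 1)
        drop = cols[i] if mean_abs[i] >= mean_abs[j] else cols[j]
        cols.remove(drop)
    return env[cols]


def screen_candidates(
    eigengenes: pd.DataFrame,
    env: pd.DataFrame,
    sap: SaponinSummary,
    fdr: float = 0.05,
) -> dict:
    """Spearman screen of eigengenes and env factors against saponin PC1.

    BH correction is applied within each family (modules, environment)
    separately; candidates are entries with q < fdr.
    """
    out: dict = {}
    for name, table in (("modules", eigengenes), ("environment", env)):
        if table is None or table.shape[1] == 0:
            out[name] = pd.DataFrame(columns=["rho", "p", "q", "candidate"])
            continue
        rows = []
        for c in table.columns:
            r, p = stats.spearmanr(table[c], sap.pc1)
            rows.append({"variable": c, "rho": r, "p": p})
        df = pd.DataFrame(rows).set_index("variable")
        df["q"] = bh_adjust(df["p"].to_numpy())
        df["candidate"] = df["q"] < fdr
        out[name] = df
    out["candidate_modules"] = list(out["modules"].index[out["modules"]["candidate"]])
    out["candidate_env"] = list(
        out["environment"].index[out["environment"]["candidate"]]
    )
    return out


def _spearman_safe(a, b) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    return float(stats.spearmanr(a, b)[0])


def ml_compare(
    feature_sets: dict[str, pd.DataFrame],
    response: pd.Series,
    k_folds: int = 5,
    seed: int = 0,
    knn_k: int = 7,
    rf_trees: int = 500,
) -> pd.DataFrame:
    """Paired five-fold comparison of feature sets with KNN and RF learners.

    The same fold assignment is shared by every feature set and learner so
    scores are directly comparable.  MSE and Spearman rho are computed on
    the pooled out-of-fold predictions.
    """
    if len(response) < k_folds:
        raise ValueError("need at least k_folds samples")
    kf = KFold(n_splits=k_folds, shuffle=True, random_state=seed)
    splits = list(kf.split(np.arange(len(response))))
    y = response.to_numpy(dtype=float)

    rows = []
    for model_name, feats in feature_sets.items():
        if feats is None or feats.shape[1] == 0:
            warnings.warn(f"feature set {model_name!r} empty: skipped", stacklevel=2)
            continue
        x = feats.to_numpy(dtype=float)
        for learner_name in ("KNN", "RF"):
            pred = np.empty_like(y)
            for train, test in splits:
                if learner_name == "KNN":
                    est = KNeighborsRegressor(n_neighbors=min(knn_k, len(train)))
                else:
                    est = RandomForestRegressor(
                        n_estimators=rf_trees, random_state=seed, n_jobs=1
                    )
                est.fit(x[train], y[train])
                pred[test] = est.predict(x[test])
            rows.append(
                {
                    "model": model_name,
                    "learner": learner_name,
                    "mse": float(np.mean((y - pred) ** 2)),
                    "spearman_rho": _spearman_safe(y, pred),
                }
            )
    return pd.DataFrame(rows)
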