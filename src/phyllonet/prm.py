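"""Positive regulation modules (PRMs) and their validation.

A candidate module becomes a PRM when at least half of its members
correlate significantly (Spearman, BH-FDR < 0.05) and positively with the
total saponin content.  PRMs are then compared against the remaining
network nodes in degree (Wilcoxon rank-sum), functional-guild composition,
and community-assembly stochasticity (NST), and their direct effect on
total saponin is tested with a path SEM.  Members of SEM-validated PRMs
that correlate significantly and positively with total saponin are the
positive regulation taxa (PRT).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .modules import ModulePartition
from .network import Network, bh_adjust
from .sem import fit_path_model  # noqa: F401  (re-exported pipeline surface)

__all__ = [
    "PRMResult",
    "NSTResult",
    "identify_prm",
    "degree_compare",
    "guild_composition",
    "nst",
    "identify_prt",
    "fit_path_model",
]

PLANT_ASSOCIATED = {"plant pathogen", "endophyte", "epiphyte"}
CONFIDENT = {"Probable", "Highly Probable"}


@dataclass
class PRMResult:
    module: int
    n_members: int
    n_sig_positive: int
    is_prm: bool
    member_stats: pd.DataFrame = field(repr=False)  # rho, p, q per member

    @property
    def members(self) -> list[str]:
        return list(self.member_stats.index)


@dataclass
class NSTResult:
    group: str
    nst: float
    null_model: str
    n_randomizations: int
    seed: int


def identify_prm(
    partition: ModulePartition,
    abund: pd.DataFrame,
    total_saponin: pd.Series,
    candidate_modules: list[int] | None = None,
    fdr: float = 0.05,
) -> list[PRMResult]:
    """Flag candidate modules where >= half the members are significantly
    positively correlated with total saponin content.

    Member correlations use relative abundances; BH correction is applied
    across all members tested (all candidate modules together).  The
    "half" rule is boundary-inclusive: exactly 50% qualifies.
    """
    if candidate_modules is None:
        candidate_modules = sorted(partition.sizes)
    rel = abund.div(abund.sum(axis=1), axis=0)
    y = total_saponin.loc[abund.index].to_numpy(dtype=float)

    frames = []
    for m in candidate_modules:
        for member in partition.members(m):
            if member not in rel.columns:
                continue
            r, p = stats.spearmanr(rel[member].to_numpy(), y)
            frames.append({"module": m, "member": member, "rho": r, "p": p})
    stats_df = pd.DataFrame(frames)
    if stats_df.empty:
        return []
    stats_df["q"] = bh_adjust(stats_df["p"].to_numpy())

    results = []
    for m in candidate_modules:
        sub = stats_df[stats_df["module"] == m].set_index("member")
        n_members = len(sub)
        if n_members == 0:
            continue
        n_pos = int(((sub["q"] < fdr) & (sub["rho"] > 0)).sum())
        results.append(
            PRMResult(
                module=m,
                n_members=n_members,
                n_sig_positive=n_pos,
                is_prm=bool(n_pos >= n_members / 2),
                member_stats=sub[["rho", "p", "q"]],
            )
        )
    return results


def degree_compare(prm_nodes, other_nodes, net: Network) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test on node degrees (PRM vs others).

    Exact when samples are small and tie-free, otherwise the mid-rank
    normal approximation with continuity correction (R's wilcox.test
    behaviour).  Returns ``(U statistic, p)``.
    """
    prm_nodes, other_nodes = list(prm_nodes), list(other_nodes)
    if not prm_nodes or not other_nodes:
        raise ValueError("both groups must be non-empty")
    g = net.graph
    a = np.array([g.degree(v) for v in prm_nodes], dtype=float)
    b = np.array([g.degree(v) for v in other_nodes], dtype=float)
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


def guild_composition(nodes, guilds: pd.DataFrame) -> dict:
    """Guild fractions for a node set, keeping only confident predictions.

    Nodes without a table entry or with low-confidence ("Possible")
    predictions are tallied as unassigned.  Plant pathogen, endophyte, and
    epiphyte jointly form the plant-associated aggregate.
    """
    nodes = list(nodes)
    counts: dict[str, int] = {}
    for v in nodes:
        if v in guilds.index:
            guild = guilds.at[v, "guild"]
            conf = guilds.at[v, "confidence"]
            if guild != "unassigned" and conf not in CONFIDENT:
                guild = "unassigned"
        else:
            guild = "unassigned"
        counts[guild] = counts.get(guild, 0) + 1
    n = len(nodes)
    fractions = {g: c / n for g, c in counts.items()} if n else {}
    plant = sum(fractions.get(g, 0.0) for g in PLANT_ASSOCIATED)
    return {"fractions": fractions, "plant_associated": plant, "n": n}


def _ruzicka_condensed(x: np.ndarray) -> np.ndarray:
    """Pairwise Ruzicka (abundance Jaccard) dissimilarity, condensed form.

    1 - sum(min)/sum(max) = 2 * BC / (1 + BC); computed from city-block
    distances and row sums for speed.
    """
    row = x.sum(axis=1)
    l1 = pdist(x, metric="cityblock")
    n = x.shape[0]
    iu = np.triu_indices(n, k=1)
    tot = row[iu[0]] + row[iu[1]]
    smin = (tot - l1) / 2.0
    smax = (tot + l1) / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(smax > 0, 1.0 - smin / smax, 0.0)
    return d


def nst(
    subcommunity: pd.DataFrame,
    null_model: str = "occupancy-proportional",
    n_rand: int = 1000,
    seed: int = 0,
) -> NSTResult:
    """Stochasticity ratio of community assembly for a taxon subset.

    Observed pairwise Ruzicka dissimilarities are compared with their
    expectation under a null that preserves each sample's richness and
    draws taxa proportionally to their occupancy frequency, re-assigning
    the sample's observed abundance values at random.  Per pair, the
    stochasticity ratio is E/C when the pair is more similar than expected
    (C > E) and (1-E)/(1-C) when less similar, so fully random assembly
    scores 1 and strong selection scores near 0.  The mean over pairs is
    clamped to [0, 1].
    """
    x = subcommunity.to_numpy(dtype=float)
    n, p = x.shape
    if n < 4 or p < 2:
        raise ValueError("need at least 4 samples and 2 taxa")
    rng = np.random.default_rng(seed)

    d_obs = _ruzicka_condensed(x)
    occupancy = (x > 0).sum(axis=0).astype(float)
    if occupancy.sum() == 0:
        raise ValueError("subcommunity is entirely empty")
    prob = occupancy / occupancy.sum()
    richness = (x > 0).sum(axis=1)

    d_null = np.zeros_like(d_obs)
    taxa_idx = np.arange(p)
    for _ in range(n_rand):
        xr = np.zeros_like(x)
        for s in range(n):
            r = richness[s]
            if r == 0:
                continue
            chosen = rng.choice(taxa_idx, size=r, replace=False, p=prob)
            vals = x[s, x[s] > 0]
            xr[s, chosen] = rng.permutation(vals)
        d_null += _ruzicka_condensed(xr)
    e_d = d_null / n_rand

    c_obs = 1.0 - d_obs
    e_c = 1.0 - e_d
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio_sim = np.where(c_obs > 0, e_c / np.where(c_obs > 0, c_obs, 1), 1.0)
        ratio_dis = np.where(d_obs > 0, e_d / np.where(d_obs > 0, d_obs, 1), 1.0)
    st = np.where(c_obs > e_c, ratio_sim, ratio_dis)
    value = float(np.clip(np.mean(np.clip(st, 0.0, 1.0)), 0.0, 1.0))
    return NSTResult(
        group="",
        nst=value,
        null_model=null_model,
        n_randomizations=n_rand,
        seed=seed,
    )


def identify_prt(prm: PRMResult, fdr: float = 0.05) -> list[str]:
    """Members of a validated PRM significantly positively tied to saponin."""
    s = prm.member_stats
    mask = (s["q"] < fdr) & (s["rho"] > 0)
    return list(s.index[mask])
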