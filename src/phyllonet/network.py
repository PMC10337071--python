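"""Co-occurrence network construction.

Pipeline: filter rare ASVs by overall relative abundance, compute the
pairwise Spearman correlation matrix with BH-FDR q-values, zero
non-significant correlations, scan candidate |rho| cutoffs for the point
where the nearest-neighbour spacing distribution (NNSD) of the unfolded
eigenvalues switches from Gaussian-orthogonal-ensemble (Wigner) to Poisson
statistics, and build the signed network at that threshold.  The
GOE-to-Poisson transition marks the cutoff below which correlations behave
like random-matrix noise, giving a non-arbitrary threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import interpolate, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CorrelationMatrix",
    "ThresholdScan",
    "Network",
    "abundance_filter",
    "spearman_matrix",
    "bh_adjust",
    "rmt_scan",
    "select_transition",
    "build_network",
    "nnsd_fit",
]


@dataclass
class CorrelationMatrix:
    """Symmetric Spearman rho / p / BH-q matrices over ASVs."""

    rho: np.ndarray
    pval: np.ndarray
    qval: np.ndarray
    asv_ids: list[str]

    def masked(self, fdr: float = 0.05) -> np.ndarray:
        """rho with entries at q > fdr zeroed (diagonal kept at 1)."""
        out = np.where(self.qval <= fdr, self.rho, 0.0)
        np.fill_diagonal(out, 1.0)
        return out


@dataclass
class ThresholdScan:
    thresholds: np.ndarray
    n_kept_eigenvalues: np.ndarray
    poisson_fit_stat: np.ndarray
    goe_fit_stat: np.ndarray
    poisson_pvalue: np.ndarray
    usable: np.ndarray
    transition_point: float | None = None


@dataclass
class Network:
    """Undirected signed co-occurrence graph plus the threshold that built it."""

    graph: nx.Graph
    threshold_used: float
    label: str | None = None

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def positive_fraction(self) -> float:
        m = self.graph.number_of_edges()
        if m == 0:
            return float("nan")
        pos = sum(1 for *_, d in self.graph.edges(data=True) if d["sign"] == "+")
        return pos / m

    def edge_table(self) -> pd.DataFrame:
        rows = [
            {"source": u, "target": v, "rho": d["rho"], "sign": d["sign"]}
            for u, v, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["source", "target", "rho", "sign"])


def abundance_filter(abund: pd.DataFrame, min_rel_abund: float = 1e-4) -> pd.DataFrame:
    """Drop ASVs whose overall relative abundance is at or below the cutoff.

    Overall relative abundance = ASV total count / grand total, the
    standard 0.01% rare-taxon filter applied before correlation to avoid
    spurious associations.
    """
    if (abund.sum(axis=1) <= 0).any():
        raise ValueError("abundance table has non-positive row sums")
    rel = abund.sum(axis=0) / abund.to_numpy().sum()
    keep = rel > min_rel_abund
    if not keep.any():
        raise ValueError("abundance filter removed every ASV")
    return abund.loc[:, keep]


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def spearman_matrix(abund: pd.DataFrame) -> CorrelationMatrix:
    """Pairwise Spearman correlations with two-sided p and BH q-values.

    q-values are computed over the strict upper triangle only and mirrored.
    Zero-variance ASVs get rho = 0, q = 1 (with a warning) instead of NaN.
    """
    n, p = abund.shape
    if n < 4 or p < 2:
        raise ValueError("need at least 4 samples and 2 ASVs")
    x = abund.to_numpy(dtype=float)
    const = x.std(axis=0) == 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho, pv = stats.spearmanr(x)
    rho = np.atleast_2d(np.asarray(rho, dtype=float))
    pv = np.atleast_2d(np.asarray(pv, dtype=float))
    if rho.shape != (p, p):
        # scipy degenerates to a scalar when a column is constant; fall back
        # to Pearson on mid-ranks with the same t-based two-sided p-value
        ranks = np.apply_along_axis(stats.rankdata, 0, x)
        with np.errstate(invalid="ignore", divide="ignore"):
            rho = np.corrcoef(ranks, rowvar=False)
            t = rho * np.sqrt((n - 2) / np.clip(1 - rho**2, 1e-300, None))
            pv = 2 * stats.t.sf(np.abs(t), n - 2)
    if const.any():
        warnings.warn(
            f"{int(const.sum())} zero-variance ASVs: correlations set to 0",
            stacklevel=2,
        )
        rho[const, :] = 0.0
        rho[:, const] = 0.0
        pv[const, :] = 1.0
        pv[:, const] = 1.0
    np.fill_diagonal(rho, 1.0)
    np.fill_diagonal(pv, 0.0)
    rho = np.nan_to_num(rho, nan=0.0)
    pv = np.where(np.isnan(pv), 1.0, pv)

    iu = np.triu_indices(p, k=1)
    q = np.ones_like(pv)
    q[iu] = bh_adjust(pv[iu])
    q = np.minimum(q, q.T)
    np.fill_diagonal(q, 0.0)
    q = np.maximum(q, pv)  # adjusted never below raw
    return CorrelationMatrix(rho=rho, pval=pv, qval=q, asv_ids=list(abund.columns))


# ---------------------------------------------------------------------------
# RMT threshold scan


def _unfold(eigs: np.ndarray, spline_df: int = 10) -> np.ndarray:
    """Map eigenvalues to unit mean spacing via a smooth cumulative density.

    Fits a cubic least-squares spline (interior knots at quantiles;
    spline_df coefficients) to the empirical cumulative spectral function
    and evaluates it at each eigenvalue.
    """
    lam = np.sort(eigs)
    n = lam.size
    ecdf = np.arange(1, n + 1, dtype=float)
    # strictly increasing abscissae required by the spline
    lam_u, idx = np.unique(lam, return_index=True)
    ecdf_u = ecdf[idx]
    n_interior = max(spline_df - 4, 1)
    qs = np.linspace(0, 1, n_interior + 2)[1:-1]
    knots = np.quantile(lam_u, qs)
    knots = np.unique(knots[(knots > lam_u[0]) & (knots < lam_u[-1])])
    try:
        spl = interpolate.LSQUnivariateSpline(lam_u, ecdf_u, knots, k=3)
        unfolded = spl(lam)
    except Exception:
        unfolded = np.interp(lam, lam_u, ecdf_u)
    return np.sort(unfolded)


def nnsd_fit(
    eigs: np.ndarray, spline_df: int = 10, n_bins: int = 40
) -> tuple[float, float, float, int]:
    """Chi-square fit of the NNSD against Poisson and GOE (Wigner surmise).

    Returns ``(poisson_stat, goe_stat, poisson_pvalue, n_spacings)`` where
    the statistics are per-bin-normalized chi-squares of the observed
    spacing histogram against exp(-s) and (pi s / 2) exp(-pi s^2 / 4).
    """
    # drop (near-)degenerate eigenvalues: zeroed rows pile up identical
    # eigenvalues whose zero spacings are artefacts of the masking
    lam = np.sort(np.asarray(eigs, dtype=float))
    keep = np.concatenate(([True], np.diff(lam) > 1e-8))
    lam = lam[keep]
    if lam.size < 11:
        return np.nan, np.nan, np.nan, max(lam.size - 1, 0)
    unfolded = _unfold(lam, spline_df=spline_df)
    s = np.diff(unfolded)
    s = s[s >= 0]
    if s.size < 10:
        return np.nan, np.nan, np.nan, s.size
    s = s / s.mean()

    # with few spacings a 40-bin chi-square has near-empty bins and is pure
    # noise; shrink the binning so expected counts stay O(1) or larger
    n_bins = int(min(n_bins, max(8, s.size // 4)))
    smax = 3.0
    edges = np.linspace(0.0, smax, n_bins + 1)
    obs, _ = np.histogram(np.clip(s, 0, smax - 1e-12), bins=edges)
    n = s.size

    def cdf_poisson(t):
        return 1.0 - np.exp(-t)

    def cdf_goe(t):
        return 1.0 - np.exp(-np.pi * t**2 / 4.0)

    stats_out = []
    for cdf in (cdf_poisson, cdf_goe):
        expected = n * np.diff(cdf(edges))
        # tail mass folded into the last bin so totals match
        expected[-1] += n * (1.0 - cdf(edges[-1]))
        use = expected > 0.5
        chi2 = float(np.sum((obs[use] - expected[use]) ** 2 / expected[use]))
        stats_out.append((chi2, int(use.sum())))
    (chi_p, k_p), (chi_g, _) = stats_out
    dof = max(k_p - 2, 1)
    p_poisson = float(stats.chi2.sf(chi_p, dof))
    return chi_p, chi_g, p_poisson, s.size


def rmt_scan(
    corr: CorrelationMatrix,
    t_min: float = 0.3,
    t_max: float = 0.99,
    step: float = 0.01,
    fdr: float = 0.05,
    spline_df: int = 10,
    n_bins: int = 40,
) -> ThresholdScan:
    """Scan |rho| cutoffs for the GOE-to-Poisson NNSD transition.

    At each candidate threshold the FDR-masked correlation matrix is
    hard-thresholded, eigendecomposed, its spectrum unfolded, and the NNSD
    compared against both reference distributions.  Thresholds leaving
    fewer than 10 spacings are marked unusable.
    """
    m = corr.masked(fdr=fdr)
    thresholds = np.round(np.arange(t_min, t_max + step / 2, step), 10)
    n_t = thresholds.size
    n_eig = np.zeros(n_t, dtype=int)
    chi_p = np.full(n_t, np.nan)
    chi_g = np.full(n_t, np.nan)
    p_p = np.full(n_t, np.nan)
    usable = np.zeros(n_t, dtype=bool)
    for i, t in enumerate(thresholds):
        a = np.where(np.abs(m) >= t, m, 0.0)
        np.fill_diagonal(a, 1.0)
        # restrict to nodes retaining at least one off-diagonal entry
        off = (np.abs(a) > 0).sum(axis=0) - 1
        sel = off > 0
        if sel.sum() < 12:
            continue
        eigs = np.linalg.eigvalsh(a[np.ix_(sel, sel)])
        cp, cg, pp, ns = nnsd_fit(eigs, spline_df=spline_df, n_bins=n_bins)
        n_eig[i] = ns + 1
        if np.isnan(cp):
            continue
        chi_p[i], chi_g[i], p_p[i] = cp, cg, pp
        usable[i] = True
    return ThresholdScan(
        thresholds=thresholds,
        n_kept_eigenvalues=n_eig,
        poisson_fit_stat=chi_p,
        goe_fit_stat=chi_g,
        poisson_pvalue=p_p,
        usable=usable,
    )


def select_transition(scan: ThresholdScan, alpha: float = 0.05) -> float:
    """Smallest usable threshold where the NNSD is Poisson rather than GOE.

    Poisson must both beat the GOE chi-square and not be rejected at
    ``alpha``.  Deterministic given the scan.
    """
    if not scan.usable.any():
        raise ValueError("no usable thresholds in scan; widen the grid")
    ok = (
        scan.usable
        & (scan.poisson_fit_stat < scan.goe_fit_stat)
        & (scan.poisson_pvalue > alpha)
    )
    if not ok.any():
        raise ValueError(
            "no threshold reaches Poisson statistics; widen the grid or "
            "relax the FDR mask"
        )
    t = float(scan.thresholds[np.argmax(ok)])
    scan.transition_point = t
    return t


def build_network(
    corr: CorrelationMatrix,
    threshold: float,
    fdr: float = 0.05,
    label: str | None = None,
) -> Network:
    """Keep edges with q <= fdr and |rho| >= threshold; drop isolated nodes."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    rho, q = corr.rho, corr.qval
    g = nx.Graph()
    p = len(corr.asv_ids)
    iu, ju = np.triu_indices(p, k=1)
    keep = (q[iu, ju] <= fdr) & (np.abs(rho[iu, ju]) >= threshold)
    for i, j in zip(iu[keep], ju[keep]):
        r = float(rho[i, j])
        g.add_edge(
            corr.asv_ids[i], corr.asv_ids[j], rho=r, sign="+" if r > 0 else "-",
            weight=abs(r),
        )
    if g.number_of_edges() == 0:
        warnings.warn("network has no edges at this threshold", stacklevel=2)
    return Network(graph=g, threshold_used=float(threshold), label=label)
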