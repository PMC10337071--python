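"""Module detection, eigengenes, saponin PCA, screening, ML comparison."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from phyllonet import modules as md
from phyllonet import network as nw


# ---------------------------------------------------------------------------
# fast-greedy module detection


def _brute_force_best_q(g):
    """Exhaustive maximal modularity over all partitions (tiny graphs only)."""
    nodes = list(g.nodes)
    best = -1.0
    for labels in itertools.product(range(len(nodes)), repeat=len(nodes)):
        groups = {}
        for v, lab in zip(nodes, labels):
            groups.setdefault(lab, set()).add(v)
        q = nx.community.modularity(g, list(groups.values()))
        best = max(best, q)
    return best


def test_two_cliques_recovered_exactly():
    g = nx.disjoint_union(nx.complete_graph(4), nx.complete_graph(4))
    g.add_edge(0, 4)
    part = md.detect_modules(g)
    comms = {frozenset(c) for c in part.communities()}
    assert comms == {frozenset({0, 1, 2, 3}), frozenset({4, 5, 6, 7})}


def test_fast_greedy_not_above_brute_force_optimum():
    rng = np.random.default_rng(0)
    for seed in range(3):
        g = nx.gnp_random_graph(7, 0.45, seed=seed)
        if g.number_of_edges() < 3:
            continue
        part = md.detect_modules(g)
        q = nx.community.modularity(g, part.communities())
        assert q <= _brute_force_best_q(g) + 1e-12


def test_disconnected_components_never_share_module(small_graphs):
    g = small_graphs["two_edges"]
    part = md.detect_modules(g)
    assert part.node_to_module[0] == part.node_to_module[1]
    assert part.node_to_module[0] != part.node_to_module[2]


def test_detection_deterministic():
    g = nx.gnp_random_graph(30, 0.2, seed=5)
    p1 = md.detect_modules(g).node_to_module
    p2 = md.detect_modules(g).node_to_module
    assert p1 == p2


# ---------------------------------------------------------------------------
# eigengenes


def _counts(cols, index=None):
    df = pd.DataFrame(cols, index=index)
    return df


def test_rank_one_module_eigengene():
    """All members sharing one profile: eigengene = that profile standardized."""
    rng = np.random.default_rng(1)
    x = rng.uniform(10, 100, 12)
    abund = _counts({f"m{i}": np.round(x * (i + 1)).astype(int) for i in range(5)})
    abund["filler"] = 1000  # keeps row sums from being fully collinear
    eg, ve = md.module_eigengene(abund, [f"m{i}" for i in range(5)])
    z = (eg - eg.mean()) / eg.std(ddof=1)
    rel = abund.div(abund.sum(axis=1), axis=0)["m0"]
    zx = (rel - rel.mean()) / rel.std(ddof=1)
    # integer rounding of counts leaves the matrix only approximately rank-1
    assert np.abs(np.corrcoef(z, zx)[0, 1]) > 0.999
    assert ve == pytest.approx(1.0, abs=1e-3)
    assert stats.pearsonr(eg, rel)[0] > 0  # sign orientation


def test_eigengene_invariant_to_member_order():
    rng = np.random.default_rng(2)
    abund = _counts(
        {f"a{i}": rng.integers(10, 1000, 15) for i in range(8)}
    )
    members = [f"a{i}" for i in range(6)]
    eg1, _ = md.module_eigengene(abund, members)
    eg2, _ = md.module_eigengene(abund, members[::-1])
    assert np.allclose(eg1, eg2, atol=1e-9)


def test_eigengene_tracks_planted_factor(lownoise_draw):
    cfg, abund, _, _, truth = lownoise_draw
    members = [a for a, m in truth.module_of_asv.items() if m == 0]
    eg, ve = md.module_eigengene(abund, members)
    rho = abs(stats.spearmanr(eg, truth.module_factors["M0"])[0])
    assert rho > 0.95


def test_eigengene_matches_svd_oracle(default_draw):
    _, abund, *_ = default_draw
    members = list(abund.columns[:7])
    eg, ve = md.module_eigengene(abund, members)
    rel = abund.div(abund.sum(axis=1), axis=0)[members].to_numpy()
    z = (rel - rel.mean(0)) / rel.std(0, ddof=1)
    cov = np.cov(z, rowvar=False)
    w, v = np.linalg.eigh(cov)
    scores = z @ v[:, -1]
    assert min(np.abs(eg - scores).max(), np.abs(eg + scores).max()) < 1e-8
    assert ve == pytest.approx(w[-1] / w.sum(), abs=1e-8)


def test_eigengene_needs_five_members(default_draw):
    _, abund, *_ = default_draw
    with pytest.raises(ValueError, match=">= 5"):
        md.module_eigengene(abund, list(abund.columns[:3]))


# ---------------------------------------------------------------------------
# saponin PCA


def test_rank_one_saponin_table():
    rng = np.random.default_rng(3)
    f = rng.uniform(1, 5, 10)
    sap = pd.DataFrame({f"s{k}": f * (k + 1) for k in range(4)})
    res = md.saponin_pca(sap)
    assert res.variance_fraction == pytest.approx(1.0)
    assert np.allclose(res.total, sap.sum(axis=1))


def test_pc1_variance_matches_eigen_oracle():
    rng = np.random.default_rng(4)
    sap = pd.DataFrame(rng.uniform(0, 10, (5, 8)))
    res = md.saponin_pca(sap)
    cov = np.cov(sap.to_numpy(), rowvar=False, ddof=1)
    w = np.linalg.eigvalsh(cov)
    assert res.variance_fraction == pytest.approx(w[-1] / w.sum(), abs=1e-10)


def test_covariance_pca_is_scale_sensitive():
    """Doubling one column's scale changes unscaled-PCA loadings."""
    rng = np.random.default_rng(5)
    sap = pd.DataFrame(rng.uniform(1, 4, (20, 3)), columns=list("abc"))
    r1 = md.saponin_pca(sap)
    sap2 = sap.copy()
    sap2["c"] = sap2["c"] * 10
    r2 = md.saponin_pca(sap2)
    c1 = abs(np.corrcoef(r1.pc1, sap["c"])[0, 1])
    c2 = abs(np.corrcoef(r2.pc1, sap2["c"])[0, 1])
    assert c2 > c1  # the inflated column dominates PC1 under covariance PCA


# ---------------------------------------------------------------------------
# collinearity filter


def test_identical_variables_deduplicated():
    rng = np.random.default_rng(6)
    x = rng.standard_normal(30)
    env = pd.DataFrame({"a": x, "b": x, "c": rng.standard_normal(30)})
    out = md.collinearity_filter(env)
    assert out.shape[1] == 2
    assert "c" in out.columns


def test_independent_variables_untouched(default_draw):
    _, _, env, _, _ = default_draw
    out = md.collinearity_filter(env)
    assert list(out.columns) == list(env.columns)


def test_filter_postcondition_rho2_below_cut():
    rng = np.random.default_rng(7)
    base = rng.standard_normal(40)
    env = pd.DataFrame({
        "a": base,
        "b": base + 0.1 * rng.standard_normal(40),
        "c": base + 0.2 * rng.standard_normal(40),
        "d": rng.standard_normal(40),
    })
    out = md.collinearity_filter(env, rho2_cut=0.6)
    if out.shape[1] > 1:
        r = np.atleast_2d(stats.spearmanr(out.to_numpy())[0])
        np.fill_diagonal(r, 0.0)
        assert (r**2 <= 0.6 + 1e-12).all()


# ---------------------------------------------------------------------------
# candidate screening


def test_screen_perfect_eigengene_is_candidate():
    rng = np.random.default_rng(8)
    sap = pd.DataFrame(rng.uniform(1, 5, (40, 3)))
    summary = md.saponin_pca(sap)
    eg = pd.DataFrame({"M0": summary.pc1, "M1": rng.standard_normal(40)})
    env = pd.DataFrame({"pH": rng.standard_normal(40)})
    out = md.screen_candidates(eg, env, summary)
    assert "M0" in out["candidate_modules"]
    assert out["modules"].at["M0", "rho"] == pytest.approx(1.0)


def test_screen_noise_eigengene_not_candidate():
    rng = np.random.default_rng(9)
    sap = pd.DataFrame(rng.uniform(1, 5, (200, 3)))
    summary = md.saponin_pca(sap)
    eg = pd.DataFrame({"M0": rng.standard_normal(200)})
    out = md.screen_candidates(eg, pd.DataFrame(index=sap.index), summary)
    assert out["candidate_modules"] == []


def test_candidate_set_monotone_in_fdr(recovery_draw, lownoise_draw):
    rng = np.random.default_rng(10)
    sap = pd.DataFrame(rng.uniform(1, 5, (60, 4)))
    summary = md.saponin_pca(sap)
    eg = pd.DataFrame(
        {f"M{k}": summary.pc1 * (1 - 0.2 * k) + rng.standard_normal(60) * k
         for k in range(5)}
    )
    env = pd.DataFrame(index=sap.index)
    strict = set(md.screen_candidates(eg, env, summary, fdr=0.01)["candidate_modules"])
    loose = set(md.screen_candidates(eg, env, summary, fdr=0.05)["candidate_modules"])
    assert strict <= loose


# ---------------------------------------------------------------------------
# ML comparison


def test_response_as_feature_knn1_near_zero_mse():
    rng = np.random.default_rng(11)
    y = pd.Series(rng.uniform(0, 10, 100))
    feats = {"cheat": pd.DataFrame({"y": y})}
    out = md.ml_compare(feats, y, seed=0, knn_k=1)
    knn = out[(out["learner"] == "KNN")].iloc[0]
    assert knn["mse"] < 0.5
    assert (out["spearman_rho"].abs() <= 1.0).all()


def test_empty_feature_set_skipped_with_warning():
    y = pd.Series(np.arange(10.0))
    with pytest.warns(UserWarning, match="empty"):
        out = md.ml_compare({"none": pd.DataFrame(index=y.index)}, y, seed=0)
    assert out.empty


def test_folds_shared_across_models():
    """Identical feature sets under different names give identical scores."""
    rng = np.random.default_rng(12)
    x = pd.DataFrame(rng.standard_normal((50, 3)))
    y = pd.Series(x.sum(axis=1) + 0.1 * rng.standard_normal(50))
    out = md.ml_compare({"A": x, "B": x.copy()}, y, seed=3)
    a = out[out["model"] == "A"].set_index("learner")
    b = out[out["model"] == "B"].set_index("learner")
    assert np.allclose(a["mse"], b["mse"])
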