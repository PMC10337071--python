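"""Correlation matrices, BH adjustment, RMT threshold scan, network building."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from phyllonet import network as nw


def _toy_table(cols, index=None):
    return pd.DataFrame(cols, index=index)


# ---------------------------------------------------------------------------
# abundance filter


def test_abundance_filter_hand_example():
    # one sample: relative abundances 0.5 / 0.4999 / 0.0001
    abund = _toy_table({"a": [5000], "b": [4999], "c": [1]})
    kept = nw.abundance_filter(abund, 1e-4)
    assert list(kept.columns) == ["a", "b"]


def test_abundance_filter_zero_cutoff_keeps_all(default_draw):
    _, abund, *_ = default_draw
    pd.testing.assert_frame_equal(nw.abundance_filter(abund, 0.0), abund)


def test_abundance_filter_monotone(default_draw):
    _, abund, *_ = default_draw
    small = set(nw.abundance_filter(abund, 1e-3).columns)
    large = set(nw.abundance_filter(abund, 1e-4).columns)
    assert small <= large


def test_abundance_filter_all_removed():
    with pytest.raises(ValueError, match="every ASV"):
        nw.abundance_filter(_toy_table({"a": [1], "b": [1]}), 0.9)


# ---------------------------------------------------------------------------
# Spearman matrix


def test_spearman_monotone_and_reversed():
    x = np.arange(1.0, 11.0)
    df = _toy_table({"x": x, "x2": x**2, "neg": -x})
    c = nw.spearman_matrix(df)
    i, j, k = (c.asv_ids.index(v) for v in ("x", "x2", "neg"))
    assert c.rho[i, j] == pytest.approx(1.0)
    assert c.rho[i, k] == pytest.approx(-1.0)
    assert np.allclose(c.rho, c.rho.T)
    assert np.all(np.diag(c.rho) == 1.0)
    assert np.all(c.qval >= c.pval)


def test_spearman_matches_rank_pearson_oracle_with_ties():
    """Mid-rank Spearman == Pearson on average ranks, to 1e-12."""
    rng = np.random.default_rng(0)
    x = rng.integers(0, 5, size=(30, 4)).astype(float)  # heavy ties
    df = pd.DataFrame(x, columns=list("abcd"))
    c = nw.spearman_matrix(df)
    ranks = np.apply_along_axis(stats.rankdata, 0, x)
    oracle = np.corrcoef(ranks, rowvar=False)
    assert np.allclose(c.rho, oracle, atol=1e-12)


def test_spearman_zero_variance_column():
    df = _toy_table({"a": [1.0, 2, 3, 4, 5], "b": [2.0, 2, 2, 2, 2],
                     "c": [5.0, 4, 3, 2, 1]})
    with pytest.warns(UserWarning, match="zero-variance"):
        c = nw.spearman_matrix(df)
    i = c.asv_ids.index("b")
    assert np.all(c.rho[i, [0, 2]] == 0.0)
    assert np.all(c.qval[i, [0, 2]] == 1.0)


# ---------------------------------------------------------------------------
# BH adjustment


def test_bh_stepup_hand_example():
    assert nw.bh_adjust([0.01, 0.02, 0.04]) == pytest.approx([0.03, 0.03, 0.04])


def test_bh_equal_and_single():
    assert nw.bh_adjust([0.2, 0.2, 0.2]) == pytest.approx([0.2, 0.2, 0.2])
    assert nw.bh_adjust([0.7]) == pytest.approx([0.7])


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        nw.bh_adjust([0.5, 1.5])


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=40))
def test_bh_properties(pvals):
    q = nw.bh_adjust(pvals)
    assert np.all(q <= 1.0) and np.all(q >= np.asarray(pvals))
    # order statistics of q are monotone in order statistics of p
    order = np.argsort(pvals)
    assert np.all(np.diff(np.asarray(q)[order]) >= -1e-12)


def test_bh_matches_stepup_formula_oracle():
    rng = np.random.default_rng(1)
    p = rng.uniform(size=25)
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):  # step-up from the largest p
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        adj[idx] = running
    assert nw.bh_adjust(p) == pytest.approx(adj)


# ---------------------------------------------------------------------------
# RMT scan


def test_nnsd_diagonal_random_matrix_is_poisson():
    rng = np.random.default_rng(42)
    eigs = np.linalg.eigvalsh(np.diag(rng.uniform(0, 1, 300)))
    chi_p, chi_g, p_p, _ = nw.nnsd_fit(eigs)
    assert chi_p < chi_g
    assert p_p > 0.05


def test_nnsd_goe_matrix_is_wigner():
    rng = np.random.default_rng(42)
    a = rng.standard_normal((300, 300))
    eigs = np.linalg.eigvalsh((a + a.T) / np.sqrt(2))
    chi_p, chi_g, _, _ = nw.nnsd_fit(eigs)
    assert chi_g < chi_p


def test_scan_grid_respects_bounds():
    rng = np.random.default_rng(0)
    x = pd.DataFrame(rng.integers(0, 100, (30, 20)).astype(float))
    x.columns = [f"a{i}" for i in range(20)]
    c = nw.spearman_matrix(x)
    scan = nw.rmt_scan(c, t_min=0.4, t_max=0.6, step=0.05)
    assert scan.thresholds[0] == pytest.approx(0.4)
    assert scan.thresholds[-1] == pytest.approx(0.6)
    assert np.allclose(np.diff(scan.thresholds), 0.05)


@pytest.fixture(scope="module")
def two_block_corr():
    """Several planted correlation blocks over independent factors."""
    rng = np.random.default_rng(10)
    n = 300
    cols = {}
    for b in range(5):
        f = rng.standard_normal(n)
        for i in range(16):
            cols[f"{chr(65 + b)}{i}"] = 0.95 * f + 0.3 * rng.standard_normal(n)
    return nw.spearman_matrix(pd.DataFrame(cols))


def test_transition_separates_planted_blocks(two_block_corr):
    c = two_block_corr
    p = len(c.asv_ids)
    same = np.array([[a[0] == b[0] for b in c.asv_ids] for a in c.asv_ids])
    iu = np.triu_indices(p, k=1)
    within = np.abs(c.rho[iu])[same[iu]]
    between = np.abs(c.rho[iu])[~same[iu]]
    scan = nw.rmt_scan(c)
    t = nw.select_transition(scan)
    assert between.max() < t <= within.min()


def test_transition_deterministic(two_block_corr):
    s1 = nw.rmt_scan(two_block_corr)
    s2 = nw.rmt_scan(two_block_corr)
    assert nw.select_transition(s1) == nw.select_transition(s2)


def test_transition_returns_t_min_when_poisson_wins_everywhere():
    scan = nw.ThresholdScan(
        thresholds=np.array([0.3, 0.4, 0.5]),
        n_kept_eigenvalues=np.array([50, 50, 50]),
        poisson_fit_stat=np.array([1.0, 1.0, 1.0]),
        goe_fit_stat=np.array([9.0, 9.0, 9.0]),
        poisson_pvalue=np.array([0.9, 0.9, 0.9]),
        usable=np.array([True, True, True]),
    )
    assert nw.select_transition(scan) == pytest.approx(0.3)


def test_transition_error_when_nothing_qualifies():
    scan = nw.ThresholdScan(
        thresholds=np.array([0.3]),
        n_kept_eigenvalues=np.array([50]),
        poisson_fit_stat=np.array([9.0]),
        goe_fit_stat=np.array([1.0]),
        poisson_pvalue=np.array([0.0]),
        usable=np.array([True]),
    )
    with pytest.raises(ValueError, match="grid"):
        nw.select_transition(scan)


# ---------------------------------------------------------------------------
# network building


def _corr_from_entries(ids, entries, q=0.01):
    p = len(ids)
    rho = np.eye(p)
    qv = np.zeros((p, p))
    for (i, j), r in entries.items():
        rho[i, j] = rho[j, i] = r
        qv[i, j] = qv[j, i] = q
    return nw.CorrelationMatrix(rho=rho, pval=qv, qval=qv, asv_ids=list(ids))


def test_build_network_thresholding_and_sign():
    c = _corr_from_entries("abc", {(0, 1): 0.9, (0, 2): 0.1, (1, 2): 0.05})
    net = nw.build_network(c, 0.8)
    assert net.n_edges == 1
    assert net.graph["a"]["b"]["sign"] == "+"
    assert set(net.nodes) == {"a", "b"}  # isolated node dropped

    c2 = _corr_from_entries("ab", {(0, 1): -0.95})
    assert nw.build_network(c2, 0.8).graph["a"]["b"]["sign"] == "-"


def test_build_network_raising_threshold_never_adds_edges(default_draw):
    _, abund, *_ = default_draw
    c = nw.spearman_matrix(nw.abundance_filter(abund))
    e_low = set(map(frozenset, nw.build_network(c, 0.55).graph.edges))
    e_high = set(map(frozenset, nw.build_network(c, 0.7).graph.edges))
    assert e_high <= e_low


def test_build_network_fdr_mask_applies():
    c = _corr_from_entries("ab", {(0, 1): 0.9}, q=0.2)
    with pytest.warns(UserWarning, match="no edges"):
        net = nw.build_network(c, 0.5)
    assert net.n_edges == 0


def test_edge_set_invariant_to_column_permutation(default_draw):
    _, abund, *_ = default_draw
    c1 = nw.spearman_matrix(abund)
    rng = np.random.default_rng(0)
    perm = abund.iloc[:, rng.permutation(abund.shape[1])]
    c2 = nw.spearman_matrix(perm)
    e1 = set(map(frozenset, nw.build_network(c1, 0.6).graph.edges))
    e2 = set(map(frozenset, nw.build_network(c2, 0.6).graph.edges))
    assert e1 == e2


def test_positive_loading_run_gives_all_positive_edges(lownoise_draw):
    """All planted couplings have positive loadings, so edges are all '+'."""
    _, abund, *_ = lownoise_draw
    c = nw.spearman_matrix(nw.abundance_filter(abund))
    net = nw.build_network(c, nw.select_transition(nw.rmt_scan(c)))
    assert net.positive_fraction() == pytest.approx(1.0)


def test_within_module_edge_fraction_high_on_lownoise_draw(lownoise_draw):
    _, abund, _, _, truth = lownoise_draw
    c = nw.spearman_matrix(nw.abundance_filter(abund))
    net = nw.build_network(c, nw.select_transition(nw.rmt_scan(c)))
    mod = truth.module_of_asv
    within = sum(
        1 for u, v in net.graph.edges
        if mod.get(u) is not None and mod.get(u) == mod.get(v)
    )
    assert within / net.n_edges >= 0.8
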