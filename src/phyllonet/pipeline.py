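"""End-to-end orchestration of the phyllosphere network analysis.

Stages: simulate -> network construction -> topology/robustness -> link
attribution -> modules & ML -> PRM/NST/SEM -> enrichment & taxonomy tree.
Every stage reads its inputs from files written by earlier stages and
writes its own outputs, so the pipeline is replayable stage by stage.
Per-stage random seeds are derived from the master seed via CRC32 of the
stage name, so reruns with the same config are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import enrichment as enr
from . import lted, modules, network, prm, simulate, topology

log = logging.getLogger("phyllonet")

COMPARTMENTS = ["LE", "LP"]  # leaf endosphere / leaf surface (phylloplane)


def stage_seed(master: int, name: str) -> int:
    """Deterministic per-stage seed: CRC32-fold the stage name into the master."""
    return int(
        np.random.SeedSequence([master, zlib.crc32(name.encode())]).generate_state(1)[0]
        % 2**31
    )


@dataclass
class RunConfig:
    """Settings of one pipeline run; defaults follow the study's analysis."""

    seed: int = 0
    simulation: dict = field(default_factory=dict)
    fdr: float = 0.05
    min_rel_abund: float = 1e-4
    rmt_t_min: float = 0.3
    rmt_t_max: float = 0.99
    rmt_step: float = 0.01
    ensemble_reps: int = 100
    removal_fractions: tuple = (0.2, 0.3, 0.4)
    mantel_r_cut: float = 0.6
    mantel_permutations: int = 999
    ml_k_folds: int = 5
    ml_knn_k: int = 7
    ml_rf_trees: int = 500
    nst_randomizations: int = 1000

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _write_tsv(df: pd.DataFrame, path: Path, index_label: str | None = None) -> None:
    df.to_csv(path, sep="\t", index_label=index_label)


def _read_tsv(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


# ---------------------------------------------------------------------------
# stages


def stage_simulate(config: RunConfig, outdir: Path) -> None:
    """Simulate both compartments over shared plants, env, and coordinates."""
    outdir.mkdir(parents=True, exist_ok=True)
    base_kwargs = dict(config.simulation)
    cfg0 = simulate.GeneratorConfig(
        **{**base_kwargs, "seed": stage_seed(config.seed, "simulate-shared")}
    )
    rng = np.random.default_rng(cfg0.seed)
    env = pd.DataFrame(
        rng.standard_normal((cfg0.n_samples, cfg0.n_env_factors)),
        index=simulate._sample_ids(cfg0.n_samples),
        columns=simulate.ENV_NAMES[: cfg0.n_env_factors],
    )
    coords = pd.DataFrame(
        rng.uniform(0, 1, size=(cfg0.n_samples, 2)),
        index=env.index,
        columns=["x", "y"],
    )
    _write_tsv(env, outdir / "env.tsv", "sample")
    _write_tsv(coords, outdir / "coords.tsv", "sample")

    factor_frames, prm_cols, truth_json = [], [], {}
    n_asvs_total = 0
    for comp in COMPARTMENTS:
        cfg = simulate.GeneratorConfig(
            **{**base_kwargs, "seed": stage_seed(config.seed, f"simulate-{comp}")}
        )
        abund, _, _, truth = simulate.generate_community(
            cfg, env=env, coords=coords, asv_prefix=f"{comp}_"
        )
        _write_tsv(abund, outdir / f"abundance_{comp}.tsv", "sample")
        factor_frames.append(truth.module_factors.add_prefix(f"{comp}_"))
        prm_cols += [f"{comp}_M{m}" for m in sorted(truth.planted_prms)]
        truth_json[comp] = truth.to_jsonable()
        n_asvs_total = max(n_asvs_total, cfg.n_asvs)
        if comp == COMPARTMENTS[0]:
            sap_cfg, sap_truth = cfg, truth

    factors = pd.concat(factor_frames, axis=1)
    sap = simulate.generate_saponins(
        _read_tsv(outdir / f"abundance_{COMPARTMENTS[0]}.tsv"),
        sap_truth,
        sap_cfg,
        env=env,
        factors=factors,
        prm_columns=prm_cols,
    )
    _write_tsv(sap, outdir / "saponins.tsv", "sample")
    factors.to_csv(outdir / "latent_factors.tsv", sep="\t", index_label="sample")

    all_asvs = []
    for comp in COMPARTMENTS:
        all_asvs += list(_read_tsv(outdir / f"abundance_{comp}.tsv").columns)
    tax, guilds = simulate.generate_taxonomy_guilds(
        len(all_asvs), seed=stage_seed(config.seed, "taxonomy")
    )
    tax.index = all_asvs
    guilds.index = all_asvs
    _write_tsv(tax, outdir / "taxonomy.tsv", "asv")
    _write_tsv(guilds, outdir / "guilds.tsv", "asv")
    (outdir / "truth.json").write_text(json.dumps(truth_json, indent=1))
    log.info("simulated %d compartments", len(COMPARTMENTS))


def stage_network(config: RunConfig, outdir: Path) -> None:
    for comp in COMPARTMENTS:
        abund = _read_tsv(outdir / f"abundance_{comp}.tsv")
        filtered = network.abundance_filter(abund, config.min_rel_abund)
        corr = network.spearman_matrix(filtered)
        scan = network.rmt_scan(
            corr,
            t_min=config.rmt_t_min,
            t_max=config.rmt_t_max,
            step=config.rmt_step,
            fdr=config.fdr,
        )
        try:
            t = network.select_transition(scan)
        except ValueError:
            t = config.rmt_t_min
            log.warning("%s: no RMT transition found; using t_min=%.2f", comp, t)
        net = network.build_network(corr, t, fdr=config.fdr, label=comp)
        _write_tsv(net.edge_table(), outdir / f"edges_{comp}.tsv")
        nx.write_graphml(net.graph, outdir / f"network_{comp}.graphml")
        pd.DataFrame(
            {
                "threshold": scan.thresholds,
                "n_eigen": scan.n_kept_eigenvalues,
                "poisson_stat": scan.poisson_fit_stat,
                "goe_stat": scan.goe_fit_stat,
                "poisson_p": scan.poisson_pvalue,
                "usable": scan.usable,
            }
        ).to_csv(outdir / f"rmt_scan_{comp}.tsv", sep="\t", index=False)
        (outdir / f"threshold_{comp}.txt").write_text(f"{t}\n")
        log.info("%s: threshold %.2f, %d nodes, %d edges",
                 comp, t, len(net.nodes), net.n_edges)


def _load_network(outdir: Path, comp: str) -> network.Network:
    g = nx.read_graphml(outdir / f"network_{comp}.graphml")
    t = float((outdir / f"threshold_{comp}.txt").read_text())
    return network.Network(graph=g, threshold_used=t, label=comp)


def stage_topology(config: RunConfig, outdir: Path) -> None:
    seed = stage_seed(config.seed, "topology")
    summaries, ensembles = [], []
    for comp in COMPARTMENTS:
        net = _load_network(outdir, comp)
        part = modules.detect_modules(net)
        summ = topology.complexity_indices(net, part)
        summaries.append({"compartment": comp, **asdict(summ)})

        n, m = summ.n_nodes, summ.n_edges
        metrics = {
            "global_efficiency": (topology.global_efficiency, summ.global_efficiency),
            "avgL": (topology.avg_path_length, summ.avgL),
            "natural_connectivity": (
                topology.natural_connectivity, summ.natural_connectivity),
            "degree_centralization": (
                topology.degree_centralization, summ.degree_centralization),
            "clustering_coefficient": (
                lambda g: nx.average_clustering(g), summ.clustering_coefficient),
            "modularity": (
                lambda g: nx.community.modularity(
                    g, nx.community.greedy_modularity_communities(g)),
                summ.modularity),
        }
        for name, (fn, obs) in metrics.items():
            es = topology.er_ensemble(
                n, m, fn, obs, n_rep=config.ensemble_reps,
                seed=stage_seed(config.seed, f"er-{comp}-{name}"), name=name)
            ensembles.append({"compartment": comp, **asdict(es)})

        curve = topology.robustness_removal(
            net, config.removal_fractions, n_rep=config.ensemble_reps, seed=seed)
        curve.insert(0, "compartment", comp)
        curve.to_csv(outdir / f"removal_curve_{comp}.tsv", sep="\t", index=False)

        roles = topology.zi_pi(net, part)
        roles.to_csv(outdir / f"node_roles_{comp}.tsv", sep="\t", index_label="node")

        fit = topology.tail_powerlaw(net)
        (outdir / f"tail_fit_{comp}.json").write_text(json.dumps(asdict(fit)))

    pd.DataFrame(summaries).to_csv(
        outdir / "topology_summary.tsv", sep="\t", index=False)
    pd.DataFrame(ensembles).to_csv(
        outdir / "ensemble_stats.tsv", sep="\t", index=False)


def stage_lted(config: RunConfig, outdir: Path) -> None:
    env = _read_tsv(outdir / "env.tsv")
    coords = _read_tsv(outdir / "coords.tsv")
    summaries = []
    for comp in COMPARTMENTS:
        net = _load_network(outdir, comp)
        abund = _read_tsv(outdir / f"abundance_{comp}.tsv")
        att = lted.attribute_links(
            net, abund, env, coords,
            mantel_r_cut=config.mantel_r_cut,
            n_perm=config.mantel_permutations,
            seed=stage_seed(config.seed, f"lted-{comp}"),
            fdr=config.fdr,
        )
        att.edges.to_csv(outdir / f"link_attribution_{comp}.tsv", sep="\t", index=False)
        att.node_mantel.to_csv(
            outdir / f"node_mantel_{comp}.tsv", sep="\t", index_label="node")
        summaries.append({"compartment": comp, **att.proportions})
    pd.DataFrame(summaries).to_csv(
        outdir / "attribution_summary.tsv", sep="\t", index=False)


def stage_modules(config: RunConfig, outdir: Path) -> None:
    sap = modules.saponin_pca(_read_tsv(outdir / "saponins.tsv"))
    sap_df = pd.DataFrame({"PC1": sap.pc1, "total_saponin": sap.total})
    _write_tsv(sap_df, outdir / "saponin_summary.tsv", "sample")
    (outdir / "saponin_pca.json").write_text(
        json.dumps({"pc1_variance_fraction": sap.variance_fraction,
                    "all_fractions": sap.all_fractions.tolist()}))

    env = collin = modules.collinearity_filter(_read_tsv(outdir / "env.tsv"))
    eg_frames = {}
    for comp in COMPARTMENTS:
        net = _load_network(outdir, comp)
        abund = _read_tsv(outdir / f"abundance_{comp}.tsv")
        part = modules.detect_modules(net)
        pd.Series(part.node_to_module).rename("module").to_csv(
            outdir / f"modules_{comp}.tsv", sep="\t", index_label="node")
        eg = modules.compute_eigengenes(abund, part)
        eg_frames[comp] = eg.add_prefix(f"{comp}_")
        _write_tsv(eg, outdir / f"eigengenes_{comp}.tsv", "sample")

    eigengenes = pd.concat(eg_frames.values(), axis=1)
    screen = modules.screen_candidates(eigengenes, collin, sap, fdr=config.fdr)
    screen["modules"].to_csv(outdir / "candidates_modules.tsv", sep="\t")
    screen["environment"].to_csv(outdir / "candidates_env.tsv", sep="\t")

    cand_env = screen["candidate_env"] or list(collin.columns)
    cand_mod = screen["candidate_modules"]
    feats = {"Env": collin[cand_env]}
    for comp in COMPARTMENTS:
        cols = [c for c in cand_mod if c.startswith(f"{comp}_")]
        feats[f"Env{comp}"] = pd.concat([collin[cand_env], eigengenes[cols]], axis=1)
    feats["EnvALL"] = pd.concat(
        [collin[cand_env], eigengenes[cand_mod]], axis=1)
    scores = modules.ml_compare(
        feats, sap.pc1, k_folds=config.ml_k_folds,
        seed=stage_seed(config.seed, "ml"),
        knn_k=config.ml_knn_k, rf_trees=config.ml_rf_trees)
    scores.to_csv(outdir / "ml_scores.tsv", sep="\t", index=False)


def stage_prm(config: RunConfig, outdir: Path) -> None:
    sap_df = _read_tsv(outdir / "saponin_summary.tsv")
    total = sap_df["total_saponin"]
    env = modules.collinearity_filter(_read_tsv(outdir / "env.tsv"))
    cand_env = list(
        pd.read_csv(outdir / "candidates_env.tsv", sep="\t", index_col=0)
        .query("candidate").index
    )
    cand_mod = list(
        pd.read_csv(outdir / "candidates_modules.tsv", sep="\t", index_col=0)
        .query("candidate").index
    )

    prm_rows, nst_rows, prt_all = [], [], {}
    sem_data = {}
    for comp in COMPARTMENTS:
        net = _load_network(outdir, comp)
        abund = _read_tsv(outdir / f"abundance_{comp}.tsv")
        part = modules.detect_modules(net)
        eg = _read_tsv(outdir / f"eigengenes_{comp}.tsv")
        comp_cands = [
            int(c.split("_M")[1]) for c in cand_mod if c.startswith(f"{comp}_")
        ]
        results = prm.identify_prm(
            part, abund, total, candidate_modules=comp_cands, fdr=config.fdr)
        prm_nodes: set = set()
        for r in results:
            prm_rows.append({
                "compartment": comp, "module": r.module,
                "n_members": r.n_members, "n_sig_positive": r.n_sig_positive,
                "is_prm": r.is_prm,
            })
            if r.is_prm:
                prm_nodes |= set(r.members)
                prt = prm.identify_prt(r, fdr=config.fdr)
                prt_all.setdefault(comp, set()).update(prt)
                col = f"M{r.module}"
                if col in eg.columns:
                    sem_data[f"{comp}_{col}"] = eg[col]
        other = [v for v in net.nodes if v not in prm_nodes]
        if len(prm_nodes) >= 2 and len(other) >= 2:
            w, p = prm.degree_compare(prm_nodes, other, net)
            (outdir / f"degree_compare_{comp}.json").write_text(
                json.dumps({"W": w, "p": p}))
        guilds = _read_tsv(outdir / "guilds.tsv")
        comp_guilds = {
            "PRM": prm.guild_composition(prm_nodes, guilds),
            "other": prm.guild_composition(other, guilds),
        }
        (outdir / f"guild_composition_{comp}.json").write_text(
            json.dumps(comp_guilds))
        seed = stage_seed(config.seed, f"nst-{comp}")
        for group, nodes in (("PRM", sorted(prm_nodes)), ("other", sorted(other))):
            if len(nodes) >= 2:
                res = prm.nst(abund[nodes], n_rand=config.nst_randomizations,
                              seed=seed)
                nst_rows.append({
                    "compartment": comp, "group": group, "nst": res.nst,
                    "null_model": res.null_model,
                    "n_randomizations": res.n_randomizations,
                })
        pd.Series(sorted(prt_all.get(comp, set()))).rename("prt").to_csv(
            outdir / f"prt_{comp}.tsv", sep="\t", index=False)

    pd.DataFrame(prm_rows).to_csv(outdir / "prm_results.tsv", sep="\t", index=False)
    pd.DataFrame(nst_rows).to_csv(outdir / "nst_results.tsv", sep="\t", index=False)

    # path SEM: Env -> Modules, Env -> Saponins, Modules -> Saponins
    if sem_data:
        data = pd.DataFrame(sem_data)
        env_used = cand_env or list(env.columns[:1])
        for c in env_used:
            data[c] = env[c]
        data["total_saponin"] = total
        mods = [c for c in sem_data]
        formulas = [f"total_saponin ~ {' + '.join(env_used + mods)}"]
        for mcol in mods:
            formulas.append(f"{mcol} ~ {' + '.join(env_used)}")
        fit = prm.fit_path_model(data, formulas)
        (outdir / "sem_fit.json").write_text(json.dumps(fit.to_dict(), indent=1))
        log.info("SEM chi2=%.3f df=%d CFI=%.3f RMSEA=%.3f",
                 fit.chi2, fit.df, fit.cfi, fit.rmsea)


def stage_enrichment(config: RunConfig, outdir: Path) -> None:
    tax = _read_tsv(outdir / "taxonomy.tsv")
    rows = []
    prt_by_comp = {}
    for comp in COMPARTMENTS:
        net = _load_network(outdir, comp)
        prt_file = outdir / f"prt_{comp}.tsv"
        prt_nodes = set()
        if prt_file.exists():
            s = pd.read_csv(prt_file, sep="\t")
            if "prt" in s.columns:
                prt_nodes = set(s["prt"].dropna())
        prt_by_comp[comp] = prt_nodes
        for res in enr.order_enrichment(prt_nodes, set(net.nodes), tax):
            rows.append({"compartment": comp, **asdict(res)})
    pd.DataFrame(rows).to_csv(outdir / "enrichment.tsv", sep="\t", index=False)

    tree = enr.taxonomy_tree(tax)
    (outdir / "tree.nwk").write_text(
        tree.as_string(schema="newick", suppress_rooting=True))
    presence = enr.prt_presence(prt_by_comp, tax)
    presence.to_csv(outdir / "presence_matrix.tsv", sep="\t", index_label="genus")


STAGES = [
    ("simulate", stage_simulate),
    ("network", stage_network),
    ("topology", stage_topology),
    ("lted", stage_lted),
    ("modules", stage_modules),
    ("prm", stage_prm),
    ("enrichment", stage_enrichment),
]


def run_all(config: RunConfig, outdir) -> Path:
    """Run every stage and write a manifest with output hashes."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, fn in STAGES:
        log.info("stage: %s", name)
        try:
            fn(config, outdir)
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
    manifest = {
        "seed": config.seed,
        "config": {**asdict(config), "removal_fractions": list(config.removal_fractions)},
        "outputs": {},
    }
    for f in sorted(outdir.iterdir()):
        if f.is_file() and f.name != "run_manifest.json":
            manifest["outputs"][f.name] = hashlib.sha256(f.read_bytes()).hexdigest()
    (outdir / "run_manifest.json").write_text(json.dumps(manifest, indent=1))
    return outdir
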