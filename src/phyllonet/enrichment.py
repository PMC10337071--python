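"""Order-level enrichment of positive regulation taxa and taxonomy trees.

Enrichment asks whether an order contributes more of the PRT than its
share of the network would predict: a one-sided hypergeometric upper tail
(identical to one-sided Fisher's exact on the 2x2 table), BH-corrected
across orders.  The taxonomy tree is a rank-layered tree (kingdom down to
genus, ASVs as tips) used to summarize PRT conservatism across host
species.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy import stats

from .network import bh_adjust

__all__ = [
    "EnrichmentResult",
    "order_enrichment",
    "taxonomy_tree",
    "prt_presence",
]

RANKS = ["kingdom", "phylum", "class", "order", "family", "genus"]


@dataclass
class EnrichmentResult:
    order: str
    n_prt_in_order: int
    n_order_in_mens: int
    n_prt_total: int
    n_mens_total: int
    p: float
    fdr: float
    enriched: bool
    skipped: bool = False


def order_enrichment(
    prt,
    mens_nodes,
    taxonomy: pd.DataFrame,
    fdr_cut: float = 0.05,
    min_order_size: int = 2,
) -> list[EnrichmentResult]:
    """One-sided hypergeometric enrichment of PRT per fungal order.

    Population = network ASVs with a known order; successes = the order's
    members; draws = PRT.  Orders with fewer than ``min_order_size``
    network members are reported but skipped (no test).
    """
    prt = set(prt)
    mens_nodes = set(mens_nodes)
    if not prt <= mens_nodes:
        raise ValueError("PRT must be a subset of network nodes")
    known = [v for v in mens_nodes if v in taxonomy.index]
    order_of = taxonomy.loc[known, "order"]
    n_total = len(known)
    prt_known = [v for v in prt if v in taxonomy.index]
    n_prt = len(prt_known)

    results = []
    pvals, tested = [], []
    for order, members in order_of.groupby(order_of).groups.items():
        k_order = len(members)
        k_hit = len(set(members) & prt)
        if k_order < min_order_size:
            results.append(
                EnrichmentResult(order, k_hit, k_order, n_prt, n_total,
                                 p=np.nan, fdr=np.nan, enriched=False, skipped=True)
            )
            continue
        # P(X >= k_hit) for X ~ Hypergeom(N=n_total, K=k_order, n=n_prt)
        p = float(stats.hypergeom.sf(k_hit - 1, n_total, k_order, n_prt)) if n_prt else 1.0
        res = EnrichmentResult(order, k_hit, k_order, n_prt, n_total,
                               p=p, fdr=np.nan, enriched=False)
        results.append(res)
        pvals.append(p)
        tested.append(res)
    if pvals:
        for res, q in zip(tested, bh_adjust(pvals)):
            res.fdr = float(q)
            res.enriched = bool(q < fdr_cut)
    return results


def taxonomy_tree(taxonomy: pd.DataFrame) -> dendropy.Tree:
    """Rank-layered tree from lineages; tips are ASV ids.

    Raises on rank conflicts (the same name nested under two different
    parents), which would make the layering ambiguous.
    """
    for child, parent in zip(RANKS[1:], RANKS[:-1]):
        conflicts = taxonomy.groupby(child)[parent].nunique()
        bad = conflicts[conflicts > 1]
        if len(bad):
            raise ValueError(
                f"rank conflict: {child} {bad.index[0]!r} appears under "
                f"multiple {parent} values"
            )
    tree = dendropy.Tree()
    nodes: dict[tuple, dendropy.Node] = {}

    def get_node(path: tuple, label: str) -> dendropy.Node:
        if path in nodes:
            return nodes[path]
        parent = tree.seed_node if len(path) == 1 else get_node(path[:-1], path[-2])
        node = parent.new_child()
        node.label = label
        nodes[path] = node
        return node

    for asv, row in taxonomy.iterrows():
        path = tuple(row[r] for r in RANKS)
        genus_node = get_node(path, path[-1])
        tip = genus_node.new_child()
        tip.taxon = tree.taxon_namespace.new_taxon(label=str(asv))
    return tree


def prt_presence(
    prt_by_species: dict[str, set], taxonomy: pd.DataFrame
) -> pd.DataFrame:
    """Genus x species presence matrix of PRT, with a 'conserved' flag.

    A genus is conserved when PRT of that genus occur in every species.
    """
    species = sorted(prt_by_species)
    genera: dict[str, dict[str, bool]] = {}
    for sp in species:
        for node in prt_by_species[sp]:
            if node not in taxonomy.index:
                continue
            genus = taxonomy.at[node, "genus"]
            genera.setdefault(genus, {s: False for s in species})[sp] = True
    mat = pd.DataFrame.from_dict(genera, orient="index").reindex(columns=species)
    mat = mat.fillna(False).astype(bool).sort_index()
    mat["conserved"] = mat[species].all(axis=1)
    return mat
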