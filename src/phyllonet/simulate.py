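"""Synthetic phyllosphere-community generator.

Emulates the statistical structure the network analysis assumes: blocks of
co-varying ASVs (latent module factors), ASV pairs coupled through shared
environmental drivers, dispersal-limited ASVs tracking a shared spatial
gradient, multinomial sequencing followed by rarefaction
to a fixed depth, and leaf-saponin contents driven by the factors of
"positive regulation" modules.  The planted structure is returned as a
:class:`GroundTruth` so downstream recovery tests have an oracle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "generate_community",
    "generate_saponins",
    "generate_taxonomy_guilds",
    "DEFAULT_SAPONINS",
    "DEFAULT_ORDERS",
]

#: The eight saponins quantified in Panax leaves (ginsenosides and
#: notoginsenoside R1), in mg/g dry weight.
DEFAULT_SAPONINS = ["Rb1", "Rb2", "Rc", "Rd", "Re", "Rg1", "F1", "R1"]

#: A pool of common phyllosphere fungal orders used for synthetic lineages.
DEFAULT_ORDERS = [
    "Pleosporales",
    "Capnodiales",
    "Hypocreales",
    "Helotiales",
    "Xylariales",
    "Dothideales",
    "Eurotiales",
    "Tremellales",
]

GUILDS = ["plant pathogen", "endophyte", "epiphyte", "saprotroph", "unassigned"]


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic community.

    Defaults mirror the study scale: 27 samples per species x compartment,
    reads rarefied to 12,412 per sample, modules large enough (>= 5 members)
    to receive eigengenes, and a single planted positive-regulation module
    with effect size 0.8 on the saponin profile.
    """

    n_samples: int = 27
    n_asvs: int = 80
    n_modules: int = 4
    module_sizes: list[int] = field(default_factory=lambda: [24, 10, 6, 5])
    within_module_rho: float = 0.8
    n_env_factors: int = 5
    env_driven_pairs: list[tuple[int, int, int]] | None = None
    n_dispersal_asvs: int = 8
    distance_decay_rate: float = 3.0
    n_saponins: int = 8
    prm_indices: list[int] = field(default_factory=lambda: [0])
    prm_effect_size: float = 0.8
    env_saponin_effect: float = 0.2
    noise_sd: float = 0.3
    rarefaction_depth: int = 12412
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.module_sizes) != self.n_modules:
            raise ValueError("module_sizes must have n_modules entries")
        if sum(self.module_sizes) > self.n_asvs:
            raise ValueError("sum(module_sizes) exceeds n_asvs")
        if not 0 < self.within_module_rho < 1:
            raise ValueError("within_module_rho must lie in (0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.rarefaction_depth <= 0:
            raise ValueError("rarefaction_depth must be positive")
        if self.distance_decay_rate < 0:
            raise ValueError("distance_decay_rate must be non-negative")
        if any(m < 0 or m >= self.n_modules for m in self.prm_indices):
            raise ValueError("prm_indices must reference existing modules")
        n_structured = sum(self.module_sizes)
        if self.env_driven_pairs is None:
            # plant three env-coupled pairs on the first background ASVs
            free = self.n_asvs - n_structured - self.n_dispersal_asvs
            n_pairs = min(3, self.n_env_factors, free // 2)
            b = n_structured
            self.env_driven_pairs = [
                (b + 2 * k, b + 2 * k + 1, k) for k in range(n_pairs)
            ]
        for i, j, k in self.env_driven_pairs:
            if not (0 <= i < self.n_asvs and 0 <= j < self.n_asvs):
                raise ValueError("env_driven_pairs reference ASVs out of range")
            if not 0 <= k < self.n_env_factors:
                raise ValueError("env_driven_pairs reference an unknown factor")


@dataclass
class GroundTruth:
    """Planted structure of one generator draw (the recovery-test oracle)."""

    module_of_asv: dict[str, int | None]
    planted_prms: set[int]
    planted_env_links: set[tuple[str, str]]
    planted_dispersal_links: set[tuple[str, str]]
    path_coefficients: dict[tuple[str, str], float]
    module_factors: pd.DataFrame  # samples x modules latent factors
    spatial_gradient: tuple[float, float] | None = None

    def to_jsonable(self) -> dict:
        return {
            "module_of_asv": {k: v for k, v in self.module_of_asv.items()},
            "planted_prms": sorted(self.planted_prms),
            "planted_env_links": sorted(map(list, self.planted_env_links)),
            "planted_dispersal_links": sorted(map(list, self.planted_dispersal_links)),
            "path_coefficients": {f"{a}->{b}": c for (a, b), c in self.path_coefficients.items()},
            "spatial_gradient": self.spatial_gradient,
        }


ENV_NAMES = ["pH", "OC", "AK", "NIN", "MC", "Ca", "AMN", "AP", "TN", "TP"]


def _asv_ids(n: int) -> list[str]:
    return [f"ASV_{i + 1:04d}" for i in range(n)]


def _sample_ids(n: int) -> list[str]:
    return [f"S{i + 1:03d}" for i in range(n)]


def generate_community(
    config: GeneratorConfig,
    env: pd.DataFrame | None = None,
    coords: pd.DataFrame | None = None,
    asv_prefix: str = "",
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Draw one synthetic community.

    Returns ``(abundance, env, coords, truth)`` where ``abundance`` is a
    samples x ASVs rarefied count table (every row sums to
    ``config.rarefaction_depth``), ``env`` holds per-sample edaphic
    variables, ``coords`` holds spatial positions on the unit square, and
    ``truth`` records the planted structure.

    Latent log-abundances follow a Gaussian factor model: module members
    load sqrt(rho) on their module factor plus ``noise_sd`` Gaussian noise;
    env-driven pairs load on a shared environmental factor; dispersal ASVs
    follow a shared linear spatial gradient of log-abundance with slope
    ``distance_decay_rate`` (random direction), so their pairwise
    Bray-Curtis dissimilarity grows with geographic distance.  Counts are
    drawn multinomially at twice the rarefaction depth, then subsampled
    without replacement to exactly the depth.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n, p = cfg.n_samples, cfg.n_asvs
    asvs = [asv_prefix + a for a in _asv_ids(p)]
    samples = _sample_ids(n)

    # env and coords may be supplied (e.g. shared between the leaf-surface
    # and endosphere compartments of the same plants); the per-draw random
    # stream consumes the same number of variates either way
    env_drawn = rng.standard_normal((n, cfg.n_env_factors))
    coords_drawn = rng.uniform(0.0, 1.0, size=(n, 2))
    env = env_drawn if env is None else env.to_numpy(dtype=float)
    coords = coords_drawn if coords is None else coords.to_numpy(dtype=float)
    factors = rng.standard_normal((n, cfg.n_modules))

    # latent log-abundance
    x = np.zeros((n, p))
    module_of: dict[str, int | None] = {a: None for a in asvs}
    load = np.sqrt(cfg.within_module_rho)

    # per-member loading jitter: strong loaders become intra-module hubs,
    # weak loaders peripheral nodes, giving the degree heterogeneity
    # (centralization, heavy-ish degree tail) real networks show
    idx = 0
    for m, size in enumerate(cfg.module_sizes):
        for _ in range(size):
            u = rng.uniform(0.35, 1.0)
            x[:, idx] = u * load * factors[:, m] + cfg.noise_sd * rng.standard_normal(n)
            module_of[asvs[idx]] = m
            idx += 1
    structured_end = idx

    env_links: set[tuple[str, str]] = set()
    for i, j, k in cfg.env_driven_pairs:
        for node in (i, j):
            x[:, node] = load * env[:, k] + cfg.noise_sd * rng.standard_normal(n)
        env_links.add(tuple(sorted((asvs[i], asvs[j]))))

    env_members = {i for pair in cfg.env_driven_pairs for i in pair[:2]}
    gradient = None
    disp_links: set[tuple[str, str]] = set()
    if cfg.n_dispersal_asvs > 0:
        # dispersal-limited ASVs follow a shared linear spatial gradient of
        # log-abundance with slope distance_decay_rate: pairwise Bray-Curtis
        # then grows with geographic distance (distance decay), which is the
        # signal the per-node Mantel test must detect
        theta = rng.uniform(0.0, 2 * np.pi)
        w = cfg.distance_decay_rate * np.array([np.cos(theta), np.sin(theta)])
        gradient = (float(w[0]), float(w[1]))
        g = coords @ w
        g = g - g.mean()
        disp_idx = [
            i for i in range(structured_end, p) if i not in env_members
        ][: cfg.n_dispersal_asvs]
        # low noise: the planted class emulates ASVs that meet the
        # definitional Mantel cut (r >= 0.6) for dispersal limitation
        for i in disp_idx:
            x[:, i] = g + 0.25 * cfg.noise_sd * rng.standard_normal(n)
        for a in range(len(disp_idx)):
            for b in range(a + 1, len(disp_idx)):
                disp_links.add(tuple(sorted((asvs[disp_idx[a]], asvs[disp_idx[b]]))))
    else:
        disp_idx = []

    taken = set(range(structured_end)) | env_members | set(disp_idx)
    for i in range(p):
        if i not in taken:
            x[:, i] = 0.5 * rng.standard_normal(n)

    # Structured ASVs (modules, env pairs, dispersal) get a small share of
    # the total read mass so their coherent swings barely move the
    # rarefaction denominator; otherwise compositional closure induces
    # spurious correlations between unrelated taxa.
    role = np.zeros(p, dtype=int)  # 0 background, 1 structured, 2 dispersal
    role[list(taken)] = 1
    role[disp_idx] = 2
    base_bg = rng.normal(0.5, 0.5, size=p)
    base_st = rng.normal(-2.0, 0.3, size=p)
    base_dp = rng.normal(-1.0, 0.2, size=p)
    base = np.choose(role, [base_bg, base_st, base_dp])

    # multinomial sequencing, then rarefy without replacement
    logit = base[None, :] + x
    prob = np.exp(logit - logit.max(axis=1, keepdims=True))
    prob /= prob.sum(axis=1, keepdims=True)
    depth = cfg.rarefaction_depth
    counts = np.empty((n, p), dtype=np.int64)
    for s in range(n):
        raw = rng.multinomial(2 * depth, prob[s])
        counts[s] = rng.multivariate_hypergeometric(raw, depth)

    abund = pd.DataFrame(counts, index=samples, columns=asvs)
    env_df = pd.DataFrame(env, index=samples, columns=ENV_NAMES[: cfg.n_env_factors])
    coords_df = pd.DataFrame(coords, index=samples, columns=["x", "y"])

    path = {("env", "saponins"): cfg.env_saponin_effect}
    for m in cfg.prm_indices:
        path[(f"M{m}", "saponins")] = cfg.prm_effect_size

    truth = GroundTruth(
        module_of_asv=module_of,
        planted_prms=set(cfg.prm_indices),
        planted_env_links=env_links,
        planted_dispersal_links=disp_links,
        path_coefficients=path,
        module_factors=pd.DataFrame(
            factors, index=samples, columns=[f"M{m}" for m in range(cfg.n_modules)]
        ),
        spatial_gradient=gradient,
    )
    return abund, env_df, coords_df, truth


def generate_saponins(
    abund: pd.DataFrame,
    truth: GroundTruth,
    config: GeneratorConfig,
    env: pd.DataFrame | None = None,
    factors: pd.DataFrame | None = None,
    prm_columns: list[str] | None = None,
) -> pd.DataFrame:
    """Draw per-sample saponin contents (mg/g) from the planted path model.

    Each saponin is a positive, strictly monotone function of the summed
    planted-PRM factors: base * exp(effect * sum(factors) + env term +
    noise).  The total content (row sum used downstream) therefore rises
    with the PRM factors, which is the signal the screening and SEM stages
    must recover.
    """
    cfg = config
    if cfg.prm_effect_size == 0 and cfg.prm_indices:
        warnings.warn("prm_effect_size is 0: planted PRM signal absent", stacklevel=2)
    rng = np.random.default_rng([cfg.seed, 7])
    n = len(abund)
    names = DEFAULT_SAPONINS[: cfg.n_saponins]
    if cfg.n_saponins > len(DEFAULT_SAPONINS):
        names = names + [f"Sap{k}" for k in range(len(DEFAULT_SAPONINS), cfg.n_saponins)]

    if factors is None:
        factors = truth.module_factors
    if prm_columns is None:
        prm_columns = [f"M{m}" for m in sorted(truth.planted_prms)]
    signal = np.zeros(n)
    for col in prm_columns:
        signal = signal + factors[col].to_numpy()
    env_term = np.zeros(n)
    if env is not None and env.shape[1] > 0:
        env_term = cfg.env_saponin_effect * env.iloc[:, 0].to_numpy()

    base = rng.uniform(1.0, 5.0, size=cfg.n_saponins)
    out = np.empty((n, cfg.n_saponins))
    for k in range(cfg.n_saponins):
        noise = cfg.noise_sd * rng.standard_normal(n)
        out[:, k] = base[k] * np.exp(
            cfg.prm_effect_size * signal + env_term + noise
        )
    return pd.DataFrame(out, index=abund.index, columns=names)


def generate_taxonomy_guilds(
    n_asvs: int,
    orders: list[str] | None = None,
    guild_probs: dict[str, float] | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assign 7-rank lineages and functional guilds to ASVs.

    Lineages are drawn from a synthetic rank hierarchy built over the
    supplied order pool (two families per order, two genera per family),
    so prefix consistency (same genus => same family => same order) holds
    by construction.  Guild labels follow ``guild_probs``; each assignment
    carries a confidence tag, and only "Probable"/"Highly Probable" tags
    survive the downstream guild tally.
    """
    if orders is None:
        orders = DEFAULT_ORDERS
    if not orders:
        raise ValueError("order pool must be non-empty")
    if guild_probs is None:
        guild_probs = {
            "plant pathogen": 0.2,
            "endophyte": 0.25,
            "epiphyte": 0.15,
            "saprotroph": 0.25,
            "unassigned": 0.15,
        }
    total = sum(guild_probs.values())
    if not np.isclose(total, 1.0):
        raise ValueError("guild_probs must sum to 1")

    rng = np.random.default_rng(seed)
    phyla = ["Ascomycota", "Basidiomycota"]
    classes = {"Ascomycota": "Dothideomycetes", "Basidiomycota": "Tremellomycetes"}
    hierarchy = {}
    for oi, order in enumerate(orders):
        phylum = phyla[oi % 2]
        fams = [f"{order[:-3]}aceae{f + 1}" for f in range(2)]
        hierarchy[order] = {
            "phylum": phylum,
            "class": classes[phylum],
            "families": {fam: [f"{fam}_gen{g + 1}" for g in range(2)] for fam in fams},
        }

    asvs = _asv_ids(n_asvs)
    rows = []
    for a in asvs:
        order = orders[rng.integers(len(orders))]
        h = hierarchy[order]
        fam = list(h["families"])[rng.integers(2)]
        genus = h["families"][fam][rng.integers(2)]
        rows.append(
            {
                "kingdom": "Fungi",
                "phylum": h["phylum"],
                "class": h["class"],
                "order": order,
                "family": fam,
                "genus": genus,
                "species": f"{genus}_sp",
            }
        )
    taxonomy = pd.DataFrame(rows, index=asvs)

    guild_names = list(guild_probs)
    probs = np.array([guild_probs[g] for g in guild_names])
    choice = rng.choice(len(guild_names), size=n_asvs, p=probs)
    confidence = rng.choice(
        ["Highly Probable", "Probable", "Possible"], size=n_asvs, p=[0.4, 0.4, 0.2]
    )
    guilds = pd.DataFrame(
        {
            "guild": [guild_names[c] for c in choice],
            "confidence": confidence,
        },
        index=asvs,
    )
    guilds.loc[guilds["guild"] == "unassigned", "confidence"] = "-"
    return taxonomy, guilds
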