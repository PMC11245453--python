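"""Synthetic study generator with controllable community-assembly regimes.

Emulates a 4-fertilizer-regime x 4-season x 3-replicate rhizosphere design
(48 samples per marker).  A regional species pool with a log-normal species
abundance distribution lives on a simulated Yule phylogeny; per-taxon niche
optima evolve by Brownian motion along the tree so that habitat preference
carries phylogenetic signal (without which phylogenetic turnover metrics
cannot detect selection).  Local communities are then assembled under one of
four scenarios:

``neutral``
    Migration-drift balance around the regional pool.  Local relative
    abundances are drawn from Dirichlet(N*m*pool) -- the stationary
    distribution of a Hubbell-style local community of size N receiving
    immigrants at rate m -- and reads are a multinomial draw on top.  The
    migration parameter therefore has exactly the meaning of m in the Sloan
    neutral community model.
``dispersal_limited``
    Each (regime, season) cell assembles from its own log-normally perturbed
    copy of the pool, so between-cell turnover exceeds within-cell turnover.
``selection``
    Sampling weights are multiplied by a Gaussian habitat filter
    exp(-strength * (trait - env)^2); a shared env across cells yields
    homogeneous selection, distinct env values yield variable selection.
``mixed``
    Cells cycle through the three scenarios above; the per-sample truth
    labels record which one applied.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import dendropy

from .io import (
    REGIMES,
    SEASONS,
    RANKS,
    OtuTable,
    write_otu_table,
    write_metadata,
    write_taxonomy,
    write_tree,
)

__all__ = [
    "SimulationConfig",
    "SimulatedStudy",
    "simulate_tree",
    "simulate_metacommunity",
    "simulate_local_communities",
    "emit_study",
    "distinct_env_by_regime",
    "scenario_preset",
    "DEFAULT_SELECTION_ENV",
]

SCENARIOS = ("neutral", "dispersal_limited", "selection", "mixed")


@dataclass
class SimulationConfig:
    """Study-design and assembly parameters for one synthetic marker.

    Defaults mirror a bacteria-like marker: 500 taxa, 10,000 reads per
    sample, moderate migration.  Use ``n_taxa=150`` for a fungi-like preset.
    """

    n_taxa: int = 500
    n_samples_per_cell: int = 3
    regimes: tuple = REGIMES
    seasons: tuple = SEASONS
    sad_lognormal_mu: float = 0.0
    sad_lognormal_sigma: float = 1.5
    scenario: str = "neutral"
    migration_m: float = 0.5
    selection_strength: float = 10.0
    dispersal_noise_sigma: float = 1.5
    env_by_cell: dict | None = None
    community_size: int = 10_000
    ultrametric: bool = True
    trait_eb_decay: float = 6.0
    kingdom: str = "Bacteria"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 3:
            raise ValueError("n_taxa must be >= 3")
        if self.n_samples_per_cell < 1:
            raise ValueError("n_samples_per_cell must be positive")
        if not (0 < self.migration_m <= 1):
            raise ValueError("migration_m must be in (0, 1]")
        if self.selection_strength < 0:
            raise ValueError("selection_strength must be non-negative")
        if self.community_size < 1:
            raise ValueError("community_size must be positive")
        if self.scenario not in SCENARIOS:
            raise ValueError(
                f"unknown scenario {self.scenario!r}; expected one of {SCENARIOS}"
            )


@dataclass
class SimulatedStudy:
    table: OtuTable
    metadata: pd.DataFrame
    tree: dendropy.Tree
    taxonomy: pd.DataFrame
    truth: dict
    pool: pd.Series = field(repr=False, default=None)
    trait: pd.Series = field(repr=False, default=None)


#: Shared niche optimum used by the selection scenario when no env map is
#: given.  Placed well off the trait mean: an extreme environment selects
#: the clades that drifted toward it, whereas an optimum at the root value
#: (trait 0) is matched by convergent tips from every clade and yields far
#: weaker phylogenetic clustering.
DEFAULT_SELECTION_ENV = 2.0


def distinct_env_by_regime(regimes=REGIMES, seasons=SEASONS, spread: float = 4.0) -> dict:
    """Environment map giving each regime its own niche optimum (variable
    selection across regimes), constant across seasons."""
    optima = np.linspace(-spread / 2, spread / 2, len(regimes))
    return {(r, s): float(optima[i]) for i, r in enumerate(regimes) for s in seasons}


def scenario_preset(scenario: str, seed: int = 0, marker: str = "bacteria", **overrides) -> SimulationConfig:
    """Canonical study conditions per assembly scenario.

    ``neutral``, ``dispersal_limited`` and ``mixed`` use the dense-community
    defaults (10,000 reads/sample, migration 0.5).  ``selection`` emulates a
    strong-habitat-filtering regime: small local communities (500
    individuals), low immigration (m = 0.1) and a flatter species abundance
    distribution, the conditions under which environmental filtering leaves
    a detectable phylogenetic-turnover signature -- in large, high-dispersal
    communities nearly all taxa are shared between samples and the
    filtering signal is masked.  ``marker``: "bacteria" (500 taxa) or
    "fungi" (150 taxa).
    """
    if marker not in ("bacteria", "fungi"):
        raise ValueError("marker must be 'bacteria' or 'fungi'")
    kw: dict = {"n_taxa": 500 if marker == "bacteria" else 150,
                "kingdom": "Bacteria" if marker == "bacteria" else "Fungi",
                "scenario": scenario, "seed": seed}
    if scenario == "selection":
        kw.update(
            community_size=500,
            migration_m=0.1,
            sad_lognormal_sigma=1.0,
            selection_strength=5.0,
        )
    kw.update(overrides)
    return SimulationConfig(**kw)


# ---------------------------------------------------------------------------
# tree simulation
# ---------------------------------------------------------------------------

def simulate_tree(
    n_taxa: int,
    seed: int,
    ultrametric: bool = True,
    birth_rate: float = 1.0,
    rate_noise_sigma: float = 0.4,
) -> dendropy.Tree:
    """Simulate a rooted Yule (pure-birth) tree with ``n_taxa`` tips.

    With ``ultrametric=True`` all root-to-tip path lengths are equal by
    construction; otherwise every branch length is jittered by independent
    log-normal rate noise.  Fully deterministic given ``seed``.
    """
    if n_taxa < 3:
        raise ValueError("n_taxa must be >= 3")
    rng = np.random.default_rng(seed)

    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    root = tree.seed_node
    start = {id(root): 0.0}
    active = [root]
    t = 0.0
    while len(active) < n_taxa:
        k = len(active)
        t += rng.exponential(1.0 / (birth_rate * k))
        node = active.pop(int(rng.integers(k)))
        node.edge.length = t - start[id(node)]
        for _ in range(2):
            child = node.new_child()
            start[id(child)] = t
            active.append(child)
    t_end = t + rng.exponential(1.0 / (birth_rate * n_taxa))
    for leaf in active:
        leaf.edge.length = t_end - start[id(leaf)]

    if not ultrametric:
        for edge in tree.preorder_edge_iter():
            if edge.length is not None:
                edge.length *= float(rng.lognormal(0.0, rate_noise_sigma))

    width = len(str(n_taxa))
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon = tns.new_taxon(f"OTU{i:0{width}d}")
    tree.seed_node.edge.length = None
    return tree


# ---------------------------------------------------------------------------
# metacommunity: pool + trait
# ---------------------------------------------------------------------------

def simulate_metacommunity(
    tree: dendropy.Tree, config: SimulationConfig
) -> tuple[pd.Series, pd.Series]:
    """Regional pool relative abundances and Brownian niche-optimum traits.

    The pool is a log-normal draw per taxon normalized to sum 1
    (``sad_lognormal_sigma=0`` degenerates to a perfectly even pool).  The
    niche trait diffuses from the root with per-branch Gaussian increments
    of variance branch_length * rate, where the rate decays exponentially
    with node height (an early-burst clock, ``trait_eb_decay`` e-folds over
    the tree depth).  Concentrating variance on deep branches makes habitat
    preference a clade-level property -- tips within a clade share similar
    optima and convergence between distant clades is rare -- mirroring the
    deep phylogenetic conservation of microbial habitat association that
    phylogenetic turnover metrics rely on.  ``trait_eb_decay=0`` recovers
    homogeneous-rate Brownian motion.  The trait is standardized to mean 0,
    sd 1 across tips.
    """
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(labels) < config.n_taxa:
        raise ValueError("tree has fewer tips than config.n_taxa")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))

    raw = rng.lognormal(config.sad_lognormal_mu, config.sad_lognormal_sigma, len(labels))
    pool = pd.Series(raw / raw.sum(), index=labels)

    depth = {}
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        depth[id(node)] = (
            0.0 if parent is None else depth[id(parent)] + (node.edge.length or 0.0)
        )
    total_depth = max(depth[id(lf)] for lf in tree.leaf_node_iter()) or 1.0

    value = {}
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        if parent is None:
            value[id(node)] = 0.0
            continue
        bl = node.edge.length or 0.0
        mid = depth[id(parent)] + bl / 2.0
        rate = np.exp(-config.trait_eb_decay * mid / total_depth)
        value[id(node)] = value[id(parent)] + rng.normal(0.0, np.sqrt(bl * rate))
    trait = pd.Series({lf.taxon.label: value[id(lf)] for lf in tree.leaf_node_iter()})
    sd = trait.std(ddof=0)
    if sd > 0:
        trait = (trait - trait.mean()) / sd
    return pool, trait.loc[labels]


# ---------------------------------------------------------------------------
# local community assembly
# ---------------------------------------------------------------------------

def _cell_scenarios(config: SimulationConfig) -> dict:
    cells = [(r, s) for r in config.regimes for s in config.seasons]
    if config.scenario != "mixed":
        return {cell: config.scenario for cell in cells}
    cycle = ("neutral", "dispersal_limited", "selection")
    return {cell: cycle[i % 3] for i, cell in enumerate(cells)}


def _draw_sample(rng, weights: np.ndarray, config: SimulationConfig) -> np.ndarray:
    """One local community: Dirichlet migration-drift stationary draw around
    ``weights`` followed by a multinomial read draw."""
    alpha = config.community_size * config.migration_m * weights
    alpha = np.clip(alpha, 1e-12, None)
    rel = rng.dirichlet(alpha)
    return rng.multinomial(config.community_size, rel)


def simulate_local_communities(
    pool: pd.Series, trait: pd.Series, config: SimulationConfig
) -> tuple[OtuTable, pd.DataFrame, dict]:
    """Assemble the full sample-by-sample study under ``config.scenario``.

    Returns the OTU table, the sample metadata, and per-sample truth labels.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    taxa = list(pool.index)
    pool_v = pool.to_numpy()
    trait_v = trait.loc[taxa].to_numpy()
    scen_by_cell = _cell_scenarios(config)

    env_map = config.env_by_cell
    if env_map is None:
        env_map = {cell: DEFAULT_SELECTION_ENV for cell in scen_by_cell}

    columns, meta_rows, truth = {}, [], {}
    for regime in config.regimes:
        for season in config.seasons:
            cell = (regime, season)
            scen = scen_by_cell[cell]
            weights = pool_v
            if scen == "dispersal_limited":
                noise = rng.lognormal(0.0, config.dispersal_noise_sigma, len(taxa))
                weights = pool_v * noise
                weights = weights / weights.sum()
            elif scen == "selection":
                env = float(env_map.get(cell, 0.0))
                kernel = np.exp(-config.selection_strength * (trait_v - env) ** 2)
                weights = pool_v * kernel
                if weights.sum() == 0:
                    raise ValueError("selection kernel removed all taxa; lower selection_strength")
                weights = weights / weights.sum()
            for rep in range(1, config.n_samples_per_cell + 1):
                sid = f"{regime}_{season}_{rep}"
                columns[sid] = _draw_sample(rng, weights, config)
                meta_rows.append(
                    {"sample_id": sid, "regime": regime, "season": season, "replicate": rep}
                )
                truth[sid] = {
                    "scenario": scen,
                    "migration_m": config.migration_m,
                    "selection_strength": config.selection_strength if scen == "selection" else 0.0,
                    "env": float(env_map.get(cell, 0.0)) if scen == "selection" else None,
                }

    table = OtuTable(pd.DataFrame(columns, index=taxa))
    metadata = pd.DataFrame(meta_rows)
    return table, metadata, truth


# ---------------------------------------------------------------------------
# taxonomy from tree clades
# ---------------------------------------------------------------------------

def _clade_groups(tree: dendropy.Tree, n_groups: int) -> dict:
    """Partition tips into up to ``n_groups`` monophyletic groups by
    repeatedly splitting the largest clade."""
    nodes = [tree.seed_node]
    while len(nodes) < n_groups:
        nodes.sort(key=lambda nd: -len(nd.leaf_nodes()))
        biggest = nodes[0]
        kids = biggest.child_nodes()
        if not kids:
            break
        nodes = nodes[1:] + kids
    assignment = {}
    for gi, node in enumerate(nodes, start=1):
        for leaf in node.leaf_iter():
            assignment[leaf.taxon.label] = gi
    return assignment


def simulate_taxonomy(tree: dendropy.Tree, config: SimulationConfig) -> pd.DataFrame:
    """Clade-consistent lineages: phyla and classes are monophyletic blocks,
    genus is taxon-specific, order/family left unassigned."""
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    n = len(labels)
    n_phyla = max(2, min(12, n // 10))
    n_classes = max(3, min(36, n // 4))
    phylum = _clade_groups(tree, n_phyla)
    klass = _clade_groups(tree, n_classes)
    rows = {}
    for t in labels:
        rows[t] = {
            "kingdom": config.kingdom,
            "phylum": f"Phylum{phylum[t]:02d}",
            "class": f"Class{klass[t]:02d}",
            "order": "",
            "family": "",
            "genus": f"Genus_{t}",
        }
    tax = pd.DataFrame.from_dict(rows, orient="index")
    tax.index.name = "taxon_id"
    return tax[list(RANKS)]


# ---------------------------------------------------------------------------
# full study
# ---------------------------------------------------------------------------

def emit_study(config: SimulationConfig, outdir: str | Path | None = None) -> SimulatedStudy:
    """Generate a complete study and optionally write it to ``outdir``.

    Files written: table.tsv, table.biom, tree.nwk, taxonomy.tsv,
    metadata.tsv, truth.json.  Byte-identical output for identical configs.
    """
    tree = simulate_tree(
        config.n_taxa,
        seed=int(np.random.SeedSequence([config.seed, 0]).generate_state(1)[0] % (2**31)),
        ultrametric=config.ultrametric,
    )
    pool, trait = simulate_metacommunity(tree, config)
    table, metadata, truth = simulate_local_communities(pool, trait, config)
    taxonomy = simulate_taxonomy(tree, config)
    study = SimulatedStudy(
        table=table,
        metadata=metadata,
        tree=tree,
        taxonomy=taxonomy,
        truth=truth,
        pool=pool,
        trait=trait,
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_otu_table(table, outdir / "table.tsv", format="tsv")
        write_otu_table(table, outdir / "table.biom", format="biom")
        write_tree(tree, outdir / "tree.nwk")
        write_taxonomy(taxonomy, outdir / "taxonomy.tsv")
        write_metadata(metadata, outdir / "metadata.tsv")
        payload = {
            "config": {
                k: (v if not isinstance(v, dict) else {f"{r}|{s}": e for (r, s), e in v.items()})
                for k, v in dataclasses.asdict(config).items()
            },
            "samples": truth,
        }
        (outdir / "truth.json").write_text(json.dumps(payload, indent=1, sort_keys=True))
    return study
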