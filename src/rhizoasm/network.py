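"""Signed co-occurrence networks with topological characterization.

Builds Spearman-correlation networks between taxa under two thresholding
dialects (a fixed |rho| cutoff, as in molecular ecological network analysis
with its random-matrix-theory-chosen thresholds, or a joint rho/p rule),
detects modules, scores every node's within-module degree z (Zi) and
participation coefficient (Pi) for keystone classification, and compares the
empirical topology against degree-preserving rewired random baselines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import networkx as nx
from scipy import stats

from .io import OtuTable

__all__ = [
    "spearman_matrix",
    "CooccurrenceNetwork",
    "threshold_network",
    "rmt_scan",
    "NetworkTopology",
    "topology_metrics",
    "module_detect",
    "zi_pi",
    "RandomBaseline",
    "random_baseline",
    "rewired_replicates",
    "export_edge_table",
    "export_node_table",
    "write_gexf",
    "write_graphml",
]

#: Zi / Pi quadrant thresholds for node roles; nodes with Zi >= 2.5 or
#: Pi >= 0.62 are keystone candidates.
ZI_THRESHOLD = 2.5
PI_THRESHOLD = 0.62


# ---------------------------------------------------------------------------
# correlation
# ---------------------------------------------------------------------------

def spearman_matrix(
    table: OtuTable, prevalence_min: float = 0.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All-pairs Spearman rho and p between taxa.

    Taxa are first filtered to prevalence (fraction of samples with a
    non-zero count) >= ``prevalence_min``.  Ties receive average ranks; p is
    the usual t approximation with n - 2 degrees of freedom.  Constant
    (zero-variance) taxa have no defined correlation and are excluded with a
    warning.
    """
    n_samples = len(table.sample_ids)
    if n_samples < 4:
        raise ValueError("need at least 4 samples for correlation networks")
    data = table.data
    prevalence = (data > 0).mean(axis=1)
    data = data.loc[prevalence >= prevalence_min]
    constant = data.nunique(axis=1) <= 1
    if constant.any():
        warnings.warn(
            f"excluding {int(constant.sum())} constant taxa with undefined correlation"
        )
        data = data.loc[~constant]
    taxa = list(data.index)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho, p = stats.spearmanr(data.to_numpy(), axis=1)
    if np.ndim(rho) == 0:  # spearmanr collapses the 2-taxon case to scalars
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
        p = np.array([[0.0, float(p)], [float(p), 0.0]])
    np.fill_diagonal(rho, 1.0)
    np.fill_diagonal(p, 0.0)
    return (
        pd.DataFrame(rho, index=taxa, columns=taxa),
        pd.DataFrame(p, index=taxa, columns=taxa),
    )


# ---------------------------------------------------------------------------
# thresholding
# ---------------------------------------------------------------------------

@dataclass
class CooccurrenceNetwork:
    """Signed undirected taxon graph plus its build parameters.

    ``graph`` edges carry ``rho`` and ``sign`` attributes; isolated nodes are
    dropped at construction.
    """

    graph: nx.Graph = field(repr=False)
    dialect: str = "fixed_cutoff"
    cutoff: float = 0.6
    p_max: float | None = None
    modules: dict | None = None  # node -> module id

    @property
    def nodes(self) -> list:
        return list(self.graph.nodes)

    @property
    def edges(self) -> list:
        return [
            (a, b, d["rho"], d["sign"]) for a, b, d in self.graph.edges(data=True)
        ]


def threshold_network(
    corr: pd.DataFrame,
    pvals: pd.DataFrame | None = None,
    dialect: str = "fixed_cutoff",
    cutoff: float = 0.6,
    p_max: float = 0.01,
) -> CooccurrenceNetwork:
    """Build the signed network from a correlation matrix.

    fixed_cutoff: edge iff |rho| >= cutoff.
    rho_p:        edge iff |rho| > cutoff and p < p_max.
    """
    if not (0 < cutoff < 1):
        raise ValueError("cutoff must be in (0, 1)")
    if dialect not in ("fixed_cutoff", "rho_p"):
        raise ValueError(f"unknown dialect {dialect!r}")
    if dialect == "rho_p" and pvals is None:
        raise ValueError("rho_p dialect requires a p-value matrix")

    taxa = list(corr.index)
    r = corr.to_numpy()
    g = nx.Graph()
    iu, ju = np.triu_indices(len(taxa), k=1)
    if dialect == "fixed_cutoff":
        keep = np.abs(r[iu, ju]) >= cutoff
    else:
        pm = pvals.to_numpy()
        keep = (np.abs(r[iu, ju]) > cutoff) & (pm[iu, ju] < p_max)
    for i, j in zip(iu[keep], ju[keep]):
        rho = float(r[i, j])
        g.add_edge(taxa[i], taxa[j], rho=rho, sign="+" if rho >= 0 else "-")
    if g.number_of_edges() == 0:
        warnings.warn("no edges survive the threshold; returning an empty network")
    return CooccurrenceNetwork(graph=g, dialect=dialect, cutoff=cutoff,
                               p_max=p_max if dialect == "rho_p" else None)


# ---------------------------------------------------------------------------
# RMT threshold scan
# ---------------------------------------------------------------------------

def _unfolded_spacings(eigvals: np.ndarray, poly_degree: int = 5) -> np.ndarray:
    """Nearest-neighbor spacings of the spectrally unfolded eigenvalues.

    The cumulative spectral function is smoothed with a low-order polynomial
    fit; unfolded eigenvalues are its values at the sorted spectrum, which
    removes the system-specific mean density and leaves mean spacing 1.
    """
    ev = np.sort(np.unique(np.round(eigvals, 10)))
    if len(ev) < 10:
        raise ValueError("too few distinct eigenvalues for unfolding")
    cum = np.arange(1, len(ev) + 1, dtype=float)
    coeffs = np.polyfit(ev, cum, deg=min(poly_degree, len(ev) - 2))
    unfolded = np.polyval(coeffs, ev)
    spacings = np.diff(unfolded)
    spacings = spacings[spacings > 0]
    return spacings / spacings.mean()


def _nnsd_chi2(spacings: np.ndarray, form: str, n_bins: int = 10) -> tuple[float, float]:
    """Chi-square GOF of the spacing histogram against Poisson or GOE forms.

    Poisson: P(s) = exp(-s).  GOE (Wigner surmise): P(s) =
    (pi s / 2) exp(-pi s^2 / 4).  Returns (chi2, p).
    """
    edges = np.linspace(0, max(3.0, spacings.max()), n_bins + 1)
    obs, _ = np.histogram(spacings, bins=edges)
    if form == "poisson":
        cdf = 1.0 - np.exp(-edges)
    elif form == "goe":
        cdf = 1.0 - np.exp(-np.pi * edges**2 / 4.0)
    else:
        raise ValueError(form)
    expected = np.diff(cdf) * len(spacings)
    # merge sparse bins from the right to keep the chi-square valid
    while len(expected) > 2 and expected[-1] < 1:
        expected[-2] += expected[-1]
        obs[-2] += obs[-1]
        expected, obs = expected[:-1], obs[:-1]
    mask = expected > 0
    chi2 = float(np.sum((obs[mask] - expected[mask]) ** 2 / expected[mask]))
    dof = max(int(mask.sum()) - 1, 1)
    return chi2, float(stats.chi2.sf(chi2, dof))


def rmt_scan(corr: pd.DataFrame, cutoff_grid=None) -> pd.DataFrame:
    """Scan correlation cutoffs and test the nearest-neighbor spacing
    distribution (NNSD) of the thresholded matrix's spectrum.

    Random-matrix theory predicts GOE (Wigner) spacing statistics for noise
    and Poisson statistics once only system-specific (modular) structure
    remains; the recommended cutoff is the smallest grid value whose NNSD is
    consistent with Poisson (chi-square p > 0.05).  The returned frame has
    one row per cutoff with chi2/p against both forms and a ``recommended``
    flag on the chosen row (all False when no cutoff qualifies).
    """
    n = len(corr)
    if n < 20:
        raise ValueError("correlation matrix too small for stable spectra (< 20 taxa)")
    if cutoff_grid is None:
        cutoff_grid = np.round(np.arange(0.3, 0.96, 0.05), 2)
    cutoff_grid = np.asarray(cutoff_grid, dtype=float)
    if np.any((cutoff_grid <= 0) | (cutoff_grid >= 1)):
        raise ValueError("cutoff grid must lie within (0, 1)")

    r = corr.to_numpy().copy()
    rows = []
    for c in np.sort(cutoff_grid):
        m = np.where(np.abs(r) >= c, r, 0.0)
        np.fill_diagonal(m, 1.0)
        eig = np.linalg.eigvalsh(m)
        degenerate = False
        try:
            spac = _unfolded_spacings(eig)
            chi_p, p_pois = _nnsd_chi2(spac, "poisson")
            chi_g, p_goe = _nnsd_chi2(spac, "goe")
        except ValueError:
            # identity-like spectrum: the threshold removed all correlated
            # structure, which is trivially Poisson-consistent
            degenerate = True
            chi_p = chi_g = np.nan
            p_pois, p_goe = 1.0, 0.0
        rows.append(
            {"cutoff": float(c), "chi2_poisson": chi_p, "p_poisson": p_pois,
             "chi2_goe": chi_g, "p_goe": p_goe, "degenerate": degenerate}
        )
    out = pd.DataFrame(rows)
    out["recommended"] = False
    ok = out.index[out["p_poisson"] > 0.05]
    if len(ok):
        out.loc[ok[0], "recommended"] = True
    return out


# ---------------------------------------------------------------------------
# topology
# ---------------------------------------------------------------------------

@dataclass
class NetworkTopology:
    n_nodes: int
    n_links: int
    positive_links: int
    positive_pct: float
    negative_links: int
    negative_pct: float
    avgK: float
    avgCC: float
    GD: float
    HD: float
    modularity: float
    powerlaw_r2: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def _geodesics(g: nx.Graph) -> tuple[float, float]:
    """(GD, HD): mean shortest path over connected pairs, and harmonic mean
    geodesic with disconnected pairs contributing 0 to the reciprocal sum."""
    n = g.number_of_nodes()
    if n < 2:
        return 0.0, 0.0
    total = 0.0
    count = 0
    recip = 0.0
    for _, dists in nx.all_pairs_shortest_path_length(g):
        for d in dists.values():
            if d > 0:
                total += d
                count += 1
                recip += 1.0 / d
    n_pairs = n * (n - 1)
    gd = total / count if count else float("inf")
    hd = n_pairs / recip if recip > 0 else float("inf")
    return gd, hd


def _powerlaw_r2(g: nx.Graph) -> float:
    """R^2 of the least-squares line on log(frequency) vs log(degree);
    zero-frequency degrees are omitted by construction."""
    degrees = np.array([d for _, d in g.degree()])
    degrees = degrees[degrees > 0]
    if len(degrees) == 0:
        return float("nan")
    values, freqs = np.unique(degrees, return_counts=True)
    if len(values) < 3:
        return float("nan")
    x, y = np.log(values.astype(float)), np.log(freqs.astype(float))
    res = stats.linregress(x, y)
    return float(res.rvalue**2)


def module_detect(net: CooccurrenceNetwork, method: str = "greedy", seed: int | None = None) -> dict:
    """Detect modules on the unsigned skeleton.

    Greedy (Clauset-Newman-Moore) modularity maximization by default --
    deterministic -- with Louvain available behind a seed.  Module ids are
    assigned in decreasing module-size order (ties broken by the smallest
    contained node id), starting at 0.
    """
    g = net.graph
    if g.number_of_nodes() == 0:
        return {}
    if method == "greedy":
        communities = nx.community.greedy_modularity_communities(g)
    elif method == "louvain":
        communities = nx.community.louvain_communities(g, seed=seed)
    else:
        raise ValueError(f"unknown method {method!r}")
    communities = sorted(
        (sorted(c) for c in communities), key=lambda c: (-len(c), c[0])
    )
    modules = {}
    for mid, members in enumerate(communities):
        for node in members:
            modules[node] = mid
    net.modules = modules
    return modules


def topology_metrics(net: CooccurrenceNetwork) -> NetworkTopology:
    """Whole-network descriptors: size, signed link shares, mean degree,
    clustering, geodesics, modularity of the detected partition, and the
    degree-distribution power-law fit."""
    g = net.graph
    n = g.number_of_nodes()
    if n == 0:
        raise ValueError("empty network")
    links = g.number_of_edges()
    signs = [d["sign"] for _, _, d in g.edges(data=True)]
    pos = signs.count("+")
    neg = links - pos
    if net.modules is None:
        module_detect(net)
    comms: dict[int, set] = {}
    for node, mid in net.modules.items():
        comms.setdefault(mid, set()).add(node)
    modularity = nx.community.modularity(g, comms.values()) if links else 0.0
    gd, hd = _geodesics(g)
    return NetworkTopology(
        n_nodes=n,
        n_links=links,
        positive_links=pos,
        positive_pct=100.0 * pos / links if links else 0.0,
        negative_links=neg,
        negative_pct=100.0 * neg / links if links else 0.0,
        avgK=2.0 * links / n,
        avgCC=float(np.mean(list(nx.clustering(g).values()))),
        GD=gd,
        HD=hd,
        modularity=float(modularity),
        powerlaw_r2=_powerlaw_r2(g),
    )


# ---------------------------------------------------------------------------
# Zi-Pi keystones
# ---------------------------------------------------------------------------

def zi_pi(net: CooccurrenceNetwork, modules: dict | None = None) -> pd.DataFrame:
    """Within-module degree z-score (Zi) and participation coefficient (Pi)
    per node, with the four-quadrant role classification.

    Zi z-scores a node's within-module degree against its module's mean/sd
    (sd = 0 gives Zi = 0 by convention); Pi = 1 - sum_s (k_is / k_i)^2 over
    modules s.  Roles: peripheral (Zi < 2.5, Pi < 0.62), connector
    (Zi < 2.5, Pi >= 0.62), module hub (Zi >= 2.5, Pi < 0.62), network hub
    (Zi >= 2.5, Pi >= 0.62).  Keystone = module hub, network hub or
    connector (Zi >= 2.5 or Pi >= 0.62).
    """
    g = net.graph
    if modules is None:
        modules = net.modules if net.modules is not None else module_detect(net)
    missing = set(g.nodes) - set(modules)
    if missing:
        raise ValueError(f"module assignment missing for node(s): {sorted(missing)[:5]}")

    within_degree = {}
    for node in g.nodes:
        within_degree[node] = sum(
            1 for nb in g.neighbors(node) if modules[nb] == modules[node]
        )
    by_module: dict[int, list] = {}
    for node in g.nodes:
        by_module.setdefault(modules[node], []).append(within_degree[node])
    mod_mean = {m: float(np.mean(v)) for m, v in by_module.items()}
    mod_sd = {m: float(np.std(v)) for m, v in by_module.items()}

    rows = []
    for node in g.nodes:
        k = g.degree(node)
        if k == 0:
            continue
        m = modules[node]
        zi = 0.0 if mod_sd[m] == 0 else (within_degree[node] - mod_mean[m]) / mod_sd[m]
        per_module: dict[int, int] = {}
        for nb in g.neighbors(node):
            per_module[modules[nb]] = per_module.get(modules[nb], 0) + 1
        pi = 1.0 - sum((c / k) ** 2 for c in per_module.values())
        if zi >= ZI_THRESHOLD:
            role = "network_hub" if pi >= PI_THRESHOLD else "module_hub"
        else:
            role = "connector" if pi >= PI_THRESHOLD else "peripheral"
        rows.append(
            {"node": node, "module": m, "degree": k, "Zi": zi, "Pi": pi,
             "role": role, "keystone": zi >= ZI_THRESHOLD or pi >= PI_THRESHOLD}
        )
    return pd.DataFrame(rows).set_index("node")


# ---------------------------------------------------------------------------
# random baselines
# ---------------------------------------------------------------------------

@dataclass
class RandomBaseline:
    n_random: int
    avgCC_mean: float
    avgCC_sd: float
    GD_mean: float
    GD_sd: float
    modularity_mean: float
    modularity_sd: float
    method: str = "rewire"

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def rewired_replicates(graph: nx.Graph, n_random: int, seed: int | None = None,
                       swaps_per_link: int = 10):
    """Yield ``(replicate_graph, method)`` pairs.

    Each replicate applies ``swaps_per_link * n_links`` double-edge swaps,
    which preserve the degree multiset exactly.  If the graph admits no
    legal swap (e.g. a triangle), the replicate falls back to an
    Erdos-Renyi G(n, L) graph and is flagged with method "erdos_renyi".
    """
    links = graph.number_of_edges()
    rng = np.random.default_rng(seed)
    for _ in range(n_random):
        rand = graph.copy()
        method = "rewire"
        try:
            nx.double_edge_swap(
                rand,
                nswap=swaps_per_link * links,
                max_tries=100 * swaps_per_link * links,
                seed=int(rng.integers(2**31 - 1)),
            )
        except nx.NetworkXError:
            method = "erdos_renyi"
            rand = nx.gnm_random_graph(
                graph.number_of_nodes(), links, seed=int(rng.integers(2**31 - 1))
            )
        except nx.NetworkXAlgorithmError:
            # swap budget exhausted; the partially rewired graph still has
            # the exact degree sequence, keep it
            pass
        yield rand, method


def random_baseline(
    net: CooccurrenceNetwork, n_random: int = 100, seed: int | None = None,
    swaps_per_link: int = 10,
) -> RandomBaseline:
    """Topology of degree-preserving rewired replicates (mean +/- SD over
    ``n_random`` graphs; see :func:`rewired_replicates`)."""
    g = net.graph
    if g.number_of_edges() < 2:
        raise ValueError("need at least 2 edges for a random baseline")

    cc, gd, q = [], [], []
    method = "rewire"
    for rand, how in rewired_replicates(g, n_random, seed=seed,
                                        swaps_per_link=swaps_per_link):
        if how == "erdos_renyi":
            method = how
        comms = nx.community.greedy_modularity_communities(rand)
        cc.append(float(np.mean(list(nx.clustering(rand).values()))))
        gd.append(_geodesics(rand)[0])
        q.append(nx.community.modularity(rand, comms))
    return RandomBaseline(
        n_random=n_random,
        avgCC_mean=float(np.mean(cc)), avgCC_sd=float(np.std(cc)),
        GD_mean=float(np.mean(gd)), GD_sd=float(np.std(gd)),
        modularity_mean=float(np.mean(q)), modularity_sd=float(np.std(q)),
        method=method,
    )


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def export_edge_table(net: CooccurrenceNetwork, path) -> None:
    rows = [
        {"taxon_a": a, "taxon_b": b, "rho": d["rho"], "sign": d["sign"]}
        for a, b, d in net.graph.edges(data=True)
    ]
    pd.DataFrame(rows, columns=["taxon_a", "taxon_b", "rho", "sign"]).to_csv(
        path, sep="\t", index=False
    )


def export_node_table(node_stats: pd.DataFrame, path) -> None:
    node_stats.to_csv(path, sep="\t")


def write_gexf(net: CooccurrenceNetwork, path) -> None:
    g = net.graph.copy()
    if net.modules:
        nx.set_node_attributes(g, net.modules, "module")
    nx.write_gexf(g, path)


def write_graphml(net: CooccurrenceNetwork, path) -> None:
    g = net.graph.copy()
    if net.modules:
        nx.set_node_attributes(g, net.modules, "module")
    nx.write_graphml(g, path)
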