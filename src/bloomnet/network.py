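"""Signed Spearman co-occurrence networks and their comparison.

Edges are Spearman correlations passing |rho| > r_min (default 0.6) and
p < p_max (default 0.05), both strict, computed on abundance-filtered ASVs
(mean relative abundance > 0.01%, prevalence > 20% of samples).  Modules
come from Clauset-Newman-Moore greedy modularity maximisation on |rho|
weights; keystones are the highest-betweenness nodes.  Signs are carried as
edge annotations throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import scipy.stats

__all__ = [
    "CorrelationMatrix", "ModuleSet", "NetworkStats", "network_filter",
    "spearman_matrix", "build_network", "fast_greedy_modules",
    "network_stats", "keystone_rank", "extract_modules", "compare_regions",
    "write_graphml", "read_graphml", "average_degree", "node_metadata",
]


@dataclass
class CorrelationMatrix:
    rho: pd.DataFrame
    p: pd.DataFrame
    n: int


@dataclass
class ModuleSet:
    assignment: dict[str, int]
    modularity: float
    edge_signs: pd.DataFrame = field(default_factory=pd.DataFrame)

    def members(self, module_id: int) -> list[str]:
        return sorted(a for a, m in self.assignment.items() if m == module_id)

    @property
    def n_modules(self) -> int:
        return len(set(self.assignment.values()))


@dataclass
class NetworkStats:
    n_nodes: int
    n_prok_nodes: int
    n_euk_nodes: int
    n_edges: int
    proportion_positive: float
    average_degree: float
    average_path_length: float
    diameter: int
    clustering_coefficient: float
    mean_betweenness: float
    n_modules: int
    modularity: float
    betweenness_flag: str = ""


def average_degree(n_nodes: int, n_edges: int) -> float:
    """Mean degree 2E/N of an undirected graph."""
    if n_nodes <= 0:
        raise ValueError("need at least one node")
    return 2.0 * n_edges / n_nodes


def network_filter(rel_abund: pd.DataFrame, min_abund: float = 1e-4,
                   min_prev: float = 0.2) -> list[str]:
    """ASVs kept for network inference.

    Keep an ASV iff its overall mean relative abundance is strictly greater
    than ``min_abund`` (0.01%) AND it is present (count > 0) in strictly
    more than ``min_prev`` of samples.
    """
    mean_ok = rel_abund.mean(axis=0) > min_abund
    prev_ok = (rel_abund > 0).mean(axis=0) > min_prev
    kept = [a for a in rel_abund.columns if mean_ok[a] and prev_ok[a]]
    if not kept:
        raise ValueError(
            "no ASV passes the abundance/prevalence filter; relax min_abund "
            f"(={min_abund}) or min_prev (={min_prev})")
    return kept


def spearman_matrix(x: pd.DataFrame) -> CorrelationMatrix:
    """All-pairs Spearman rho (mid-rank) with two-sided t-approximation p.

    Constant columns yield NaN rho/p for their pairs and contribute no
    edges downstream.  |rho| = 1 maps to p = 0.
    """
    n = x.shape[0]
    if n < 5:
        raise ValueError(f"need at least 5 samples for correlations, got {n}")
    if x.shape[1] < 2:
        raise ValueError("need at least 2 features")
    import warnings
    with warnings.catch_warnings():
        # constant columns are legal inputs; their pairs yield NaN and no edge
        warnings.simplefilter("ignore", scipy.stats.ConstantInputWarning)
        rho, p = scipy.stats.spearmanr(x.to_numpy(dtype=float), axis=0)
    if np.ndim(rho) == 0:  # scipy collapses the 2-feature case to a scalar
        rho = np.array([[1.0, rho], [rho, 1.0]])
        p = np.array([[0.0, p], [p, 0.0]])
    np.fill_diagonal(rho, 1.0)
    np.fill_diagonal(p, 0.0)
    p[np.abs(rho) >= 1.0 - 1e-15] = 0.0
    cols = list(x.columns)
    return CorrelationMatrix(
        rho=pd.DataFrame(rho, index=cols, columns=cols),
        p=pd.DataFrame(p, index=cols, columns=cols), n=n)


def node_metadata(rel_abund: pd.DataFrame, tax: pd.DataFrame) -> pd.DataFrame:
    """Per-ASV node annotations: domain tag, lineage string, mean abundance."""
    asvs = list(rel_abund.columns)
    lineage = tax.loc[asvs].astype(str).agg(";".join, axis=1)
    domain = np.where(tax.loc[asvs, "domain"].str.lower() == "eukaryota",
                      "eukaryote", "prokaryote")
    return pd.DataFrame({"domain": domain, "lineage": lineage,
                         "mean_rel_abund": rel_abund.mean(axis=0)}, index=asvs)


def build_network(corr: CorrelationMatrix, node_meta: pd.DataFrame,
                  r_min: float = 0.6, p_max: float = 0.05,
                  bh_correct: bool = False) -> nx.Graph:
    """Threshold a correlation matrix into a signed co-occurrence graph.

    An edge requires |rho| > r_min AND p < p_max, both strict.  Isolated
    nodes are excluded, so reported node counts are connected nodes.  Set
    ``bh_correct`` to apply Benjamini-Hochberg to the pairwise p-values
    before thresholding (off by default: raw p < 0.05).
    """
    asvs = list(corr.rho.columns)
    rho = corr.rho.to_numpy()
    p = corr.p.to_numpy()
    iu = np.triu_indices(len(asvs), k=1)
    pvals = p[iu]
    if bh_correct:
        from statsmodels.stats.multitest import multipletests
        finite = np.isfinite(pvals)
        adj = np.full_like(pvals, np.nan)
        if finite.any():
            adj[finite] = multipletests(pvals[finite], method="fdr_bh")[1]
        pvals = adj
    g = nx.Graph()
    with np.errstate(invalid="ignore"):
        keep = (np.abs(rho[iu]) > r_min) & (pvals < p_max)
    keep &= np.isfinite(rho[iu]) & np.isfinite(pvals)
    for i, j, ok, pe in zip(iu[0], iu[1], keep, pvals):
        if not ok:
            continue
        r = float(rho[i, j])
        g.add_edge(asvs[i], asvs[j], rho=r, weight=abs(r),
                   sign="+" if r > 0 else "-", p=float(pe))
    for node in g.nodes:
        meta = node_meta.loc[node]
        g.nodes[node].update(domain=str(meta["domain"]),
                             lineage=str(meta["lineage"]),
                             mean_rel_abund=float(meta["mean_rel_abund"]))
    return g


def fast_greedy_modules(net: nx.Graph) -> ModuleSet:
    """Clauset-Newman-Moore greedy modularity modules on |rho| weights.

    Edge signs are annotations only; modularity is computed on the unsigned
    weights.  An edgeless network yields singleton modules with Q = 0.
    Module ids are assigned in decreasing module size, ties by smallest
    member id.
    """
    if net.number_of_nodes() == 0:
        return ModuleSet(assignment={}, modularity=0.0)
    if net.number_of_edges() == 0:
        assignment = {n: i for i, n in enumerate(sorted(net.nodes))}
        return ModuleSet(assignment=assignment, modularity=0.0)
    communities = nx.community.greedy_modularity_communities(net, weight="weight")
    communities = sorted((sorted(c) for c in communities),
                         key=lambda c: (-len(c), c[0]))
    q = nx.community.modularity(net, communities, weight="weight")
    assignment = {node: i for i, comm in enumerate(communities) for node in comm}
    sign_rows = []
    for i, comm in enumerate(communities):
        sub = net.subgraph(comm)
        pos = sum(1 for *_, d in sub.edges(data=True) if d["sign"] == "+")
        neg = sub.number_of_edges() - pos
        sign_rows.append(dict(module=i, n_nodes=len(comm),
                              n_pos_edges=pos, n_neg_edges=neg))
    return ModuleSet(assignment=assignment, modularity=float(q),
                     edge_signs=pd.DataFrame(sign_rows).set_index("module"))


def network_stats(net: nx.Graph, modules: ModuleSet) -> NetworkStats:
    """Topology summary of a co-occurrence network.

    Path length averages over connected ordered pairs only; the diameter is
    the maximum eccentricity across components; the clustering coefficient
    averages local clustering over nodes of degree >= 2; mean betweenness
    is over pair-normalised (Brandes) values.
    """
    n = net.number_of_nodes()
    e = net.number_of_edges()
    if n == 0:
        return NetworkStats(0, 0, 0, 0, 0.0, 0.0, 0.0, 0, 0.0, 0.0,
                            modules.n_modules, modules.modularity,
                            betweenness_flag="empty network")
    domains = nx.get_node_attributes(net, "domain")
    n_prok = sum(1 for v in domains.values() if v == "prokaryote")
    n_euk = sum(1 for v in domains.values() if v == "eukaryote")
    signs = [d["sign"] for *_, d in net.edges(data=True)]
    prop_pos = signs.count("+") / e if e else 0.0

    path_sum, pair_count, diam = 0.0, 0, 0
    for comp in nx.connected_components(net):
        sub = net.subgraph(comp)
        if len(comp) >= 2:
            for _, dists in nx.shortest_path_length(sub):
                path_sum += sum(dists.values())
                pair_count += len(dists) - 1
            diam = max(diam, nx.diameter(sub))
    apl = path_sum / pair_count if pair_count else 0.0

    clustering = nx.clustering(net)
    deg2 = [c for node, c in clustering.items() if net.degree(node) >= 2]
    cc = float(np.mean(deg2)) if deg2 else 0.0

    flag = ""
    if n < 3:
        mean_btw = 0.0
        flag = "betweenness undefined for N < 3"
    else:
        btw = nx.betweenness_centrality(net, normalized=True)
        mean_btw = float(np.mean(list(btw.values())))
    return NetworkStats(
        n_nodes=n, n_prok_nodes=n_prok, n_euk_nodes=n_euk, n_edges=e,
        proportion_positive=prop_pos, average_degree=average_degree(n, e),
        average_path_length=apl, diameter=diam, clustering_coefficient=cc,
        mean_betweenness=mean_btw, n_modules=modules.n_modules,
        modularity=modules.modularity, betweenness_flag=flag)


def keystone_rank(net: nx.Graph, top_k: int = 10) -> pd.DataFrame:
    """Top-betweenness nodes (raw Brandes values, undirected pair counting).

    Zero-betweenness nodes are never keystones; an all-zero network (e.g.
    disjoint cliques) yields an empty table.  Ties break by degree, then id.
    """
    if net.number_of_nodes() == 0:
        return pd.DataFrame(columns=["betweenness", "degree", "lineage"])
    btw = nx.betweenness_centrality(net, normalized=False)
    rows = [(node, b, net.degree(node),
             net.nodes[node].get("lineage", ""))
            for node, b in btw.items() if b > 0]
    rows.sort(key=lambda t: (-t[1], -t[2], t[0]))
    df = pd.DataFrame(rows[:top_k],
                      columns=["asv_id", "betweenness", "degree", "lineage"])
    return df.set_index("asv_id")


def _module_subreport(net: nx.Graph, members: list[str]) -> pd.DataFrame:
    rows = []
    for u, v, d in net.subgraph(members).edges(data=True):
        rows.append(dict(source=u, target=v, rho=d["rho"], sign=d["sign"]))
    return pd.DataFrame(rows, columns=["source", "target", "rho", "sign"])


def extract_modules(net: nx.Graph, modules: ModuleSet, focal_genus: str,
                    tax: pd.DataFrame) -> dict:
    """Focused module reports.

    Returns a dict with:

    ``largest_negative``
        members/edges of the largest module (by node count) containing at
        least one negative edge, or ``None``;
    ``largest_prok_negative``
        same restricted to all-prokaryote modules, or ``None``;
    ``focal_modules``
        one entry per module containing an ASV annotated to
        ``focal_genus``: members, the focal ASVs, and each focal ASV's
        neighbors with lineage and edge sign;
    ``focal_found``
        False when the genus is absent from the network.
    """
    sizes: dict[int, list[str]] = {}
    for node, m in modules.assignment.items():
        sizes.setdefault(m, []).append(node)

    def has_negative(members):
        return any(d["sign"] == "-" for *_, d in net.subgraph(members).edges(data=True))

    def all_prok(members):
        return all(net.nodes[n].get("domain") == "prokaryote" for n in members)

    neg_mods = [(m, mem) for m, mem in sizes.items() if has_negative(mem)]
    largest_neg = max(neg_mods, key=lambda t: (len(t[1]), -t[0]), default=None)
    prok_neg = [(m, mem) for m, mem in neg_mods if all_prok(mem)]
    largest_prok_neg = max(prok_neg, key=lambda t: (len(t[1]), -t[0]), default=None)

    genus_lower = focal_genus.strip().lower()
    focal_asvs = [n for n in net.nodes
                  if n in tax.index
                  and str(tax.loc[n, "genus"]).strip().lower() == genus_lower]
    focal_reports = []
    for m, members in sorted(sizes.items()):
        in_module = [a for a in focal_asvs if modules.assignment.get(a) == m]
        if not in_module:
            continue
        neighbors = []
        for a in in_module:
            for nb in net.neighbors(a):
                d = net.edges[a, nb]
                neighbors.append(dict(focal=a, neighbor=nb,
                                      lineage=net.nodes[nb].get("lineage", ""),
                                      rho=d["rho"], sign=d["sign"]))
        focal_reports.append(dict(
            module=m, members=sorted(members), focal_asvs=in_module,
            has_negative=has_negative(members),
            neighbors=pd.DataFrame(
                neighbors, columns=["focal", "neighbor", "lineage", "rho", "sign"])))

    def pack(entry):
        if entry is None:
            return None
        m, members = entry
        return dict(module=m, members=sorted(members),
                    edges=_module_subreport(net, members))

    return dict(largest_negative=pack(largest_neg),
                largest_prok_negative=pack(largest_prok_neg),
                focal_modules=focal_reports,
                focal_found=bool(focal_asvs))


_COMPARE_METRICS = [
    ("n_nodes", "higher_is_more_complex"),
    ("n_prok_nodes", "higher_is_more_complex"),
    ("n_euk_nodes", "higher_is_more_complex"),
    ("n_edges", "higher_is_more_complex"),
    ("proportion_positive", "neutral"),
    ("average_degree", "higher_is_more_complex"),
    ("average_path_length", "neutral"),
    ("diameter", "neutral"),
    ("clustering_coefficient", "higher_is_more_complex"),
    ("mean_betweenness", "neutral"),
    ("n_modules", "higher_is_more_complex"),
    ("modularity", "neutral"),
]


def compare_regions(stats_br: NetworkStats, stats_nr: NetworkStats) -> pd.DataFrame:
    """Side-by-side BR/NR topology comparison with directional flags.

    ``direction`` says which region is larger per metric; ``multi_module``
    marks modularity strictly greater than 0.4.
    """
    rows = []
    for metric, _ in _COMPARE_METRICS:
        b = getattr(stats_br, metric)
        r = getattr(stats_nr, metric)
        if b < r:
            direction = "BR_lower"
        elif b > r:
            direction = "BR_higher"
        else:
            direction = "equal"
        rows.append(dict(metric=metric, br=b, nr=r, direction=direction))
    df = pd.DataFrame(rows).set_index("metric")
    df["multi_module"] = ""
    df.loc["modularity", "multi_module"] = (
        f"BR:{stats_br.modularity > 0.4} NR:{stats_nr.modularity > 0.4}")
    return df


def write_graphml(net: nx.Graph, modules: ModuleSet, path) -> None:
    """GraphML export with module ids and raw betweenness on nodes.

    Attribute values are plain str/float/int so the file validates against
    the GraphML schema and loads in Gephi.
    """
    g = net.copy()
    btw = (nx.betweenness_centrality(g, normalized=False)
           if g.number_of_nodes() >= 3 else {n: 0.0 for n in g.nodes})
    for node in g.nodes:
        g.nodes[node]["module"] = int(modules.assignment.get(node, -1))
        g.nodes[node]["betweenness"] = float(btw[node])
    try:
        nx.write_graphml(g, path)
    except OSError as exc:
        raise OSError(f"failed writing GraphML to {path}: {exc}") from exc


def read_graphml(path) -> nx.Graph:
    if not Path(path).exists():
        raise FileNotFoundError(path)
    return nx.read_graphml(path)
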