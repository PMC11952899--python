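"""PPI community grammar of a predicted granule proteome.

Given a STRING-style edge list and a propensity table, this module
builds the predicted-proteome interaction graph and quantifies the
"community grammar": seven node-importance metrics with within-network
percentile ranks, probability-binned metric trends with adjacent-bin
one-way ANOVA, Louvain modularity clusters with a high-confidence
membership filter, cluster summaries, multi-list overlap counts, and an
optional seeded 2D embedding for plotting.

Edge weights (combined scores) are used for thresholding only; metrics
and clustering run on the unweighted simple graph unless requested.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

CENTRALITY_METRICS = (
    "degree",
    "betweenness",
    "eigenvector",
    "pagerank",
    "closeness",
    "clustering_coefficient",
    "degree_centrality",
)

PROBABILITY_BIN_EDGES = (0.5, 0.6, 0.7, 0.8, 0.9, 1.0)


def load_string_edges(path: str | Path, score_threshold: float = 400) -> nx.Graph:
    """Read a STRING-style edge list into an undirected simple graph.

    Expects whitespace- or tab-separated columns ``protein1``,
    ``protein2``, ``combined_score``; keeps edges with score >= the
    threshold (default 400, STRING "medium confidence"), dropping
    self-loops and collapsing parallel edges to their maximum score.
    """
    table = pd.read_csv(path, sep=r"\s+")
    missing = {"protein1", "protein2", "combined_score"} - set(table.columns)
    if missing:
        raise ValueError(f"edge list missing columns {sorted(missing)}")
    scores = pd.to_numeric(table["combined_score"], errors="coerce")
    if scores.isna().any():
        line = int(scores.index[scores.isna()][0]) + 2  # header + 1-based
        raise ValueError(f"non-numeric combined_score at line {line}")
    graph = nx.Graph(score_threshold=score_threshold)
    kept = table[scores >= score_threshold]
    for u, v, w in zip(kept["protein1"], kept["protein2"], scores[kept.index]):
        if u == v:
            continue
        if graph.has_edge(u, v):
            graph[u][v]["weight"] = max(graph[u][v]["weight"], float(w))
        else:
            graph.add_edge(u, v, weight=float(w))
    if graph.number_of_edges() == 0:
        warnings.warn("no edges pass the score threshold")
    return graph


def induce_predicted_subgraph(
    graph: nx.Graph, propensity: pd.DataFrame, min_p: float = 0.5
) -> nx.Graph:
    """Node-induced subgraph on accessions with propensity >= min_p.

    Isolated nodes are retained (a predicted protein with no surviving
    interaction still belongs to the community's node set).
    """
    if len(propensity) == 0:
        raise ValueError("empty propensity table")
    keep = set(propensity.index[propensity["p"] >= min_p])
    nodes = [n for n in graph.nodes if n in keep]
    if not nodes:
        raise ValueError(f"no graph nodes with p >= {min_p}")
    return graph.subgraph(nodes).copy()


def _percentile_rank(values: pd.Series) -> pd.Series:
    """Mid-rank fraction in (0, 1]; the unique maximum maps to 1.0."""
    return values.rank(method="average", pct=True)


def compute_centralities(graph: nx.Graph) -> pd.DataFrame:
    """Seven node-importance metrics plus their percentile ranks.

    Eigenvector centrality is computed per connected component by power
    iteration (singletons get 0); closeness uses the Wasserman-Faust
    component-size correction; PageRank uses damping 0.85 with uniform
    teleport. All metrics ignore edge weights.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    if graph.number_of_nodes() == 1:
        warnings.warn("single-node graph; centralities are degenerate")
    nodes = list(graph.nodes)
    n = len(nodes)
    eigen: dict = {}
    for comp in nx.connected_components(graph):
        if len(comp) == 1:
            eigen[next(iter(comp))] = 0.0
        else:
            sub = graph.subgraph(comp)
            eigen.update(
                nx.eigenvector_centrality(sub, max_iter=5000, tol=1e-8)
            )
    table = pd.DataFrame(
        {
            "degree": pd.Series(dict(graph.degree()), dtype=float),
            "betweenness": pd.Series(nx.betweenness_centrality(graph, normalized=True)),
            "eigenvector": pd.Series(eigen),
            "pagerank": pd.Series(nx.pagerank(graph, alpha=0.85, tol=1e-9, max_iter=1000)),
            "closeness": pd.Series(nx.closeness_centrality(graph, wf_improved=True)),
            "clustering_coefficient": pd.Series(nx.clustering(graph)),
            "degree_centrality": pd.Series(
                nx.degree_centrality(graph) if n > 1 else {nodes[0]: 0.0}
            ),
        }
    ).loc[nodes]
    for metric in CENTRALITY_METRICS:
        table[f"{metric}_pct"] = _percentile_rank(table[metric])
    return table


def bin_by_probability(
    centralities: pd.DataFrame,
    propensity: pd.DataFrame,
    metric_list: Sequence[str] = CENTRALITY_METRICS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Metric summaries over probability bins, with adjacent-bin ANOVA.

    Bins are [0.5,0.6), ..., [0.9,1.0]; every node must have p >= 0.5
    (the network is built from predicted granule proteins). Returns
    ``(summary, anova)``: per-bin mean/sd/n per metric, and a one-way
    ANOVA comparing each bin with its predecessor. Pairs where a bin has
    n < 2 are flagged and skipped; identical constant values give F = 0,
    p = 1.
    """
    p = propensity.loc[centralities.index, "p"]
    if (p < PROBABILITY_BIN_EDGES[0]).any():
        raise ValueError("all nodes must have propensity >= 0.5")
    edges = np.asarray(PROBABILITY_BIN_EDGES)
    idx = np.clip(np.digitize(p, edges, right=False) - 1, 0, len(edges) - 2)
    labels = [f"[{lo:.1f},{hi:.1f})" for lo, hi in zip(edges[:-1], edges[1:])]
    labels[-1] = labels[-1][:-1] + "]"
    summary_rows, anova_rows = [], []
    groups = {b: centralities.index[idx == b] for b in range(len(labels))}
    for metric in metric_list:
        if metric not in centralities.columns:
            raise KeyError(f"unknown metric {metric!r}")
        for b, label in enumerate(labels):
            vals = centralities.loc[groups[b], metric]
            summary_rows.append(
                {
                    "bin": label,
                    "metric": metric,
                    "mean": float(vals.mean()) if len(vals) else np.nan,
                    "sd": float(vals.std(ddof=1)) if len(vals) > 1 else np.nan,
                    "n": int(len(vals)),
                }
            )
            if b == 0:
                continue
            prev = centralities.loc[groups[b - 1], metric]
            row = {"bin": label, "previous_bin": labels[b - 1], "metric": metric}
            if len(vals) < 2 or len(prev) < 2:
                row.update(F=np.nan, p=np.nan, flagged="insufficient_n")
            elif prev.std() == 0 and vals.std() == 0 and prev.iloc[0] == vals.iloc[0]:
                row.update(F=0.0, p=1.0, flagged="constant")
            else:
                F, pval = stats.f_oneway(prev, vals)
                row.update(F=float(F), p=float(pval), flagged="")
            anova_rows.append(row)
    return pd.DataFrame(summary_rows), pd.DataFrame(anova_rows)


@dataclass
class CommunityPartition:
    """Louvain partition with clusters relabeled by descending size."""

    assignment: dict[str, int]
    modularity: float
    resolution: float
    seed: int

    @property
    def n_clusters(self) -> int:
        return len(set(self.assignment.values()))

    def members(self, cluster: int) -> list[str]:
        return [n for n, c in self.assignment.items() if c == cluster]

    def sizes(self) -> pd.Series:
        return pd.Series(self.assignment).value_counts().sort_index()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"accession": list(self.assignment), "cluster": list(self.assignment.values())}
        )


def louvain_partition(
    graph: nx.Graph, resolution: float = 1.0, seed: int = 0
) -> CommunityPartition:
    """Louvain modularity clustering, deterministic for a given seed.

    Clusters are relabeled 1, 2, ... by descending size (ties by the
    lexicographically smallest member) so cluster numbering is stable.
    An edgeless graph yields singleton clusters with a warning.
    """
    if graph.number_of_edges() == 0:
        warnings.warn("edgeless graph: every node is its own cluster")
        communities = [{n} for n in sorted(graph.nodes)]
        modularity = float("nan")
    else:
        communities = nx.community.louvain_communities(
            graph, weight=None, resolution=resolution, seed=seed
        )
        modularity = nx.community.modularity(
            graph, communities, weight=None, resolution=resolution
        )
    ordered = sorted(communities, key=lambda c: (-len(c), min(c)))
    assignment = {n: i + 1 for i, comm in enumerate(ordered) for n in sorted(comm)}
    return CommunityPartition(
        assignment=assignment,
        modularity=modularity,
        resolution=resolution,
        seed=seed,
    )


def summarize_clusters(
    partition: CommunityPartition,
    propensity: pd.DataFrame,
    centralities: pd.DataFrame,
    min_p: float = 0.7,
    top_k: int = 3,
) -> pd.DataFrame:
    """Per-cluster high-confidence membership summaries.

    For each cluster: total size, the high-confidence member list
    (p > min_p), its size, mean propensity and mean PageRank percentile
    over those members (NA when empty). The *top_k* clusters by
    high-confidence size carry ``selected=True``.
    """
    rows = []
    for cluster in sorted(set(partition.assignment.values())):
        members = partition.members(cluster)
        p = propensity.loc[[m for m in members if m in propensity.index], "p"]
        high = p[p > min_p]
        hc = list(high.index)
        pct = centralities.loc[[m for m in hc if m in centralities.index], "pagerank_pct"]
        rows.append(
            {
                "cluster": cluster,
                "size": len(members),
                "high_confidence_n": len(hc),
                "mean_p": float(high.mean()) if hc else np.nan,
                "mean_pagerank_pct": float(pct.mean()) if len(pct) else np.nan,
                "high_confidence_members": hc,
            }
        )
    summary = pd.DataFrame(rows).sort_values(
        ["high_confidence_n", "cluster"], ascending=[False, True], kind="mergesort"
    )
    summary["selected"] = False
    summary.iloc[: min(top_k, len(summary)), summary.columns.get_loc("selected")] = True
    return summary.reset_index(drop=True)


def overlap_analysis(lists: Mapping[str, Sequence[str]]) -> dict:
    """Venn-style overlap counts across 2-8 named accession lists.

    Lists are deduplicated first. Returns the union size, per-region
    counts keyed by membership pattern (e.g. ``"A&B"`` for items in
    exactly A and B), and the members shared by all lists.
    """
    if not 2 <= len(lists) <= 8:
        raise ValueError("need between 2 and 8 lists")
    sets = {}
    for name, items in lists.items():
        unique = set(items)
        if not unique:
            raise ValueError(f"list {name!r} is empty")
        sets[name] = unique
    names = list(sets)
    union = set.union(*sets.values())
    regions: dict[str, int] = {}
    for item in union:
        pattern = "&".join(n for n in names if item in sets[n])
        regions[pattern] = regions.get(pattern, 0) + 1
    shared = sorted(set.intersection(*sets.values()))
    return {
        "list_sizes": {n: len(s) for n, s in sets.items()},
        "union_size": len(union),
        "region_counts": regions,
        "all_shared_size": len(shared),
        "all_shared_members": shared,
    }


def embed_2d(graph: nx.Graph, seed: int = 0) -> pd.DataFrame:
    """Seeded t-SNE of the node adjacency rows, for 2D plotting only."""
    from sklearn.manifold import TSNE

    nodes = list(graph.nodes)
    n = len(nodes)
    if n < 3:
        raise ValueError("need at least 3 nodes to embed")
    adjacency = nx.to_numpy_array(graph, nodelist=nodes, weight=None)
    perplexity = min(30.0, max(2.0, (n - 1) / 3))
    coords = TSNE(
        n_components=2, perplexity=perplexity, init="pca", random_state=seed
    ).fit_transform(adjacency)
    return pd.DataFrame(coords, index=nodes, columns=["component_1", "component_2"])


def write_graphml(graph: nx.Graph, path: str | Path) -> None:
    out = nx.Graph()
    out.add_nodes_from(graph.nodes)
    out.add_edges_from((u, v, d) for u, v, d in graph.edges(data=True))
    nx.write_graphml(out, path)
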