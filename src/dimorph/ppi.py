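"""Interaction graphs from STRING-style edge lists: filtering, communities,
and centrality-based node ranking.

Edges are kept when the combined confidence score is at least the minimum
(default 0.7 on the 0-1 scale; 0-1000 inputs are rescaled) and, when channel
columns are present, edges supported only by the text-mining channel are
discarded.  Community detection is Louvain-style modularity maximization on
the score-weighted graph; centralities (degree, betweenness, closeness) are
computed on the unweighted graph.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

MIN_SCORE = 0.7
TEXTMINING_COLUMNS = ("textmining", "text_mining", "txt")


def read_string_edges(
    path: str | Path,
    min_score: float = MIN_SCORE,
    drop_textmining_only: bool = True,
) -> nx.Graph:
    """Load a TSV edge list into a filtered, score-weighted graph.

    Expects two node columns (first two), a ``combined_score`` column, and
    optional per-channel score columns.  Scores may be on the 0-1 or 0-1000
    scale; anything else is an error.
    """
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 3:
        raise ValueError(f"edge list {path} needs node1, node2 and combined_score columns")
    node_a, node_b = df.columns[:2]
    if "combined_score" not in df.columns:
        raise ValueError(f"edge list {path} lacks a combined_score column")
    scores = df["combined_score"].astype(float)
    if (scores < 0).any():
        raise ValueError("negative combined_score")
    if scores.max() > 1.0:
        if scores.max() > 1000:
            raise ValueError("combined_score outside both the 0-1 and 0-1000 scales")
        scores = scores / 1000.0
        channel_scale = 1000.0
    else:
        channel_scale = 1.0

    channel_cols = [
        c for c in df.columns[2:]
        if c != "combined_score" and pd.api.types.is_numeric_dtype(df[c])
    ]
    tm_cols = [c for c in channel_cols if c.lower() in TEXTMINING_COLUMNS]
    other_cols = [c for c in channel_cols if c not in tm_cols]

    g = nx.Graph()
    for i in range(len(df)):
        score = float(scores.iloc[i])
        if score < min_score:
            continue
        if drop_textmining_only and tm_cols and channel_cols:
            tm = max(float(df[c].iloc[i]) / channel_scale for c in tm_cols)
            rest = max(
                (float(df[c].iloc[i]) / channel_scale for c in other_cols), default=0.0
            )
            if tm > 0 and rest == 0:
                continue
        u, v = str(df[node_a].iloc[i]), str(df[node_b].iloc[i])
        if u == v:
            continue
        g.add_edge(u, v, weight=score)
    return g


def detect_communities(g: nx.Graph, resolution: float = 1.0, seed: int = 0) -> tuple[dict[str, int], float]:
    """Louvain community detection on edge weights; returns (partition, Q)."""
    if g.number_of_edges() == 0:
        raise ValueError("community detection requires at least one edge")
    comms = nx.community.louvain_communities(g, weight="weight", resolution=resolution, seed=seed)
    partition = {n: i for i, c in enumerate(sorted(comms, key=lambda c: (-len(c), sorted(c)))) for n in c}
    q = nx.community.modularity(g, comms, weight="weight", resolution=resolution)
    return partition, float(q)


def modularity(g: nx.Graph, partition: Mapping[str, int], weight: str | None = "weight") -> float:
    groups: dict[int, set] = {}
    for n, c in partition.items():
        groups.setdefault(c, set()).add(n)
    return float(nx.community.modularity(g, list(groups.values()), weight=weight))


def closeness(g: nx.Graph, node) -> float:
    """n_reachable / sum(distances) within the node's connected component."""
    lengths = nx.single_source_shortest_path_length(g, node)
    lengths.pop(node, None)
    if not lengths:
        return 0.0
    return len(lengths) / sum(lengths.values())


def centralities(g: nx.Graph) -> pd.DataFrame:
    """Degree, betweenness, closeness, per-metric descending ranks, and a
    combined rank (rank of the mean rank; ties share mean ranks)."""
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    nodes = sorted(g.nodes())
    deg = np.array([g.degree(n) for n in nodes], dtype=float)
    btw_map = nx.betweenness_centrality(g, normalized=False)
    btw = np.array([btw_map[n] for n in nodes])
    clo = np.array([closeness(g, n) for n in nodes])

    def desc_rank(x: np.ndarray) -> np.ndarray:
        return stats.rankdata(-x, method="average")

    r_deg, r_btw, r_clo = desc_rank(deg), desc_rank(btw), desc_rank(clo)
    mean_rank = (r_deg + r_btw + r_clo) / 3.0
    combined = stats.rankdata(mean_rank, method="average")
    return pd.DataFrame(
        {
            "degree": deg.astype(int),
            "betweenness": btw,
            "closeness": clo,
            "degree_rank": r_deg,
            "betweenness_rank": r_btw,
            "closeness_rank": r_clo,
            "mean_rank": mean_rank,
            "combined_rank": combined,
        },
        index=pd.Index(nodes, name="node"),
    )


def bias_overlay_and_overlap(
    g: nx.Graph,
    bias: Mapping[str, str],
    other_set: Iterable[str],
    partition: Mapping[str, int] | None = None,
) -> dict:
    """Annotate nodes with bias labels and report overlap/composition.

    Returns the overlap size with ``other_set``, per-community bias
    composition, and the community with the best (lowest) mean combined rank.
    """
    other = set(other_set)
    for n in g.nodes:
        g.nodes[n]["bias"] = bias.get(n, "nb")
        g.nodes[n]["shared"] = n in other
    report: dict = {"overlap": len(set(g.nodes) & other)}
    if partition is not None:
        comp: dict[int, dict[str, int]] = {}
        for n, c in partition.items():
            comp.setdefault(c, {"XX": 0, "XY": 0, "nb": 0})
            comp[c][bias.get(n, "nb")] = comp[c].get(bias.get(n, "nb"), 0) + 1
        report["community_bias"] = comp
        cent = centralities(g)
        best, best_rank = None, np.inf
        for c in set(partition.values()):
            members = [n for n, cc in partition.items() if cc == c]
            mean_rank = float(cent.loc[members, "combined_rank"].mean())
            if mean_rank < best_rank:
                best, best_rank = c, mean_rank
        report["top_community"] = best
        report["top_community_mean_rank"] = best_rank
    return report
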