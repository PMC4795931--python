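"""Network topology of the high-confidence direct-physical PPI graph:
largest connected component, degree, betweenness, hubs and bottlenecks.

Hubs are the top 10% of nodes by degree; bottlenecks the top 10% by
shortest-path betweenness; only the largest singly connected component is
analysed.  Betweenness is the undirected, unnormalized convention with
endpoints excluded and each unordered source–target pair counted once,
with fractional credit shared across equal-length shortest paths; any
consistent convention preserves ranks on a connected graph, and ranking is
all the hub/bottleneck classifier consumes.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from .types import GenesetnetError


def graph_from_pairs(pairs: Iterable[tuple[str, str]]) -> nx.Graph:
    """Simple undirected graph from unordered gene pairs (self-loops and
    duplicates dropped)."""
    g = nx.Graph()
    for a, b in pairs:
        if a != b:
            g.add_edge(a, b)
    return g


def largest_component(g: nx.Graph) -> nx.Graph:
    """Induced subgraph on the largest connected component.

    Size ties are broken by the smallest lexicographic node id contained in
    the component.
    """
    if g.number_of_nodes() == 0:
        raise GenesetnetError("empty graph has no components")
    comps = [sorted(c, key=str) for c in nx.connected_components(g)]
    best = sorted(comps, key=lambda c: (-len(c), str(c[0])))[0]
    return g.subgraph(best).copy()


def degree(g: nx.Graph) -> dict[str, int]:
    return dict(g.degree())


def betweenness(g: nx.Graph) -> dict[str, float]:
    """Unnormalized shortest-path betweenness (Brandes' algorithm)."""
    return nx.betweenness_centrality(g, normalized=False)


def top_fraction(values: Mapping[str, float], fraction: float) -> set[str]:
    """Nodes in the top ``fraction`` by value, tie-inclusive.

    k = ceil(fraction * N); the cutoff is the k-th ranked value and every
    node with value >= cutoff is included, so ties at the boundary may push
    the set above the nominal fraction.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if not values:
        return set()
    ranked = sorted(values.values(), reverse=True)
    k = math.ceil(fraction * len(ranked))
    cutoff = ranked[k - 1]
    return {n for n, v in values.items() if v >= cutoff}


def centrality_table(g: nx.Graph, fraction: float = 0.10) -> pd.DataFrame:
    """Per-node degree and betweenness with hub/bottleneck flags.

    Intended to be called on the largest component; returns a DataFrame with
    columns node, degree, betweenness, is_hub, is_bottleneck, sorted by
    descending degree then node id.
    """
    deg = degree(g)
    btw = betweenness(g)
    hubs = top_fraction(deg, fraction)
    bottlenecks = top_fraction(btw, fraction)
    df = pd.DataFrame(
        {
            "node": list(deg),
            "degree": [deg[n] for n in deg],
            "betweenness": [btw[n] for n in deg],
            "is_hub": [n in hubs for n in deg],
            "is_bottleneck": [n in bottlenecks for n in deg],
        }
    )
    return df.sort_values(["degree", "node"], ascending=[False, True], kind="mergesort").reset_index(
        drop=True
    )


def classify_hubs_bottlenecks(
    cent: pd.DataFrame, fraction: float = 0.10
) -> pd.DataFrame:
    """(Re)assign hub/bottleneck flags on an existing centrality table."""
    deg = dict(zip(cent["node"], cent["degree"]))
    btw = dict(zip(cent["node"], cent["betweenness"]))
    hubs = top_fraction(deg, fraction)
    bottlenecks = top_fraction(btw, fraction)
    out = cent.copy()
    out["is_hub"] = [n in hubs for n in out["node"]]
    out["is_bottleneck"] = [n in bottlenecks for n in out["node"]]
    return out
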