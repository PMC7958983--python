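"""Item-level co-occurrence network from pairwise item-profile correlations.

Two items are connected when the Pearson correlation of their response
columns exceeds a threshold (default 0.2, strict).  Zero-variance item
columns have undefined correlations; those entries are NaN and never form
edges.  Summaries cover connected components, degree, and cross-degree
(edges to items of a different assigned violence type).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .cohort import ItemCatalog, ResponseMatrix


def item_correlation_matrix(matrix: ResponseMatrix) -> pd.DataFrame:
    """Symmetric item x item Pearson correlation matrix.

    Zero-variance columns yield NaN rows/columns (with a warning); the
    diagonal is 1 for all non-degenerate items.
    """
    if matrix.n_survivors < 3:
        raise ValueError("item correlations require at least 3 survivors")
    df = matrix.to_frame()
    constant = df.columns[df.nunique(axis=0) == 1].tolist()
    if constant:
        warnings.warn(
            f"{len(constant)} zero-variance item(s) have undefined correlations: "
            f"{constant[:5]}{'...' if len(constant) > 5 else ''}",
            stacklevel=2,
        )
    corr = df.corr(method="pearson")
    # pandas leaves the diagonal of constant columns at 1; make degeneracy explicit
    for c in constant:
        corr.loc[c, :] = np.nan
        corr.loc[:, c] = np.nan
    return corr


def build_network(
    corr: pd.DataFrame,
    catalog: ItemCatalog | dict[str, str] | None = None,
    threshold: float = 0.2,
) -> nx.Graph:
    """Undirected item network with an edge where correlation > threshold.

    The comparison is strict and NaN correlations never create edges.
    Nodes carry a ``violence_type`` attribute when a catalog (or an
    item -> type mapping) is supplied; edges carry the correlation as
    ``weight``.
    """
    if isinstance(catalog, ItemCatalog):
        type_of = catalog.type_of()
    else:
        type_of = dict(catalog) if catalog else {}
    g = nx.Graph(threshold=threshold)
    items = list(corr.columns)
    for item in items:
        g.add_node(item, violence_type=type_of.get(item, "unknown"))
    vals = corr.to_numpy()
    for i in range(len(items)):
        for j in range(i + 1, len(items)):
            w = vals[i, j]
            if np.isfinite(w) and w > threshold:
                g.add_edge(items[i], items[j], weight=float(w))
    return g


@dataclass
class NetworkSummary:
    """Connected components, degrees and cross-degrees of an item network."""

    components: list[dict]       # size, members, type counts, sorted big-first
    degree: pd.Series
    cross_degree: pd.Series
    top_degree: list[tuple[str, int]]
    top_cross_degree: list[tuple[str, int]]


def network_summary(g: nx.Graph, k: int = 5) -> NetworkSummary:
    """Summarize a network: components, degree, cross-degree, top-k lists.

    Cross-degree counts a node's edges whose other endpoint carries a
    different ``violence_type``.  Top-k ties break by item ID.
    """
    comps = []
    for members in sorted(nx.connected_components(g), key=lambda s: (-len(s), sorted(s))):
        types = pd.Series(
            [g.nodes[m].get("violence_type", "unknown") for m in members]
        ).value_counts().to_dict()
        comps.append({"size": len(members), "members": sorted(members), "types": types})
    degree = pd.Series({n: d for n, d in g.degree()}, dtype=int).sort_index()
    cross = {}
    for n in g.nodes:
        t = g.nodes[n].get("violence_type")
        cross[n] = sum(
            1 for m in g.neighbors(n) if g.nodes[m].get("violence_type") != t
        )
    cross_degree = pd.Series(cross, dtype=int).sort_index()

    def top(series: pd.Series) -> list[tuple[str, int]]:
        order = sorted(series.items(), key=lambda kv: (-kv[1], kv[0]))
        return [(n, int(d)) for n, d in order[:k]]

    return NetworkSummary(
        components=comps,
        degree=degree,
        cross_degree=cross_degree,
        top_degree=top(degree),
        top_cross_degree=top(cross_degree),
    )


def write_edge_list(g: nx.Graph, path) -> None:
    """Export edges as CSV (item_a, item_b, correlation)."""
    rows = [(a, b, d["weight"]) for a, b, d in g.edges(data=True)]
    pd.DataFrame(rows, columns=["item_a", "item_b", "correlation"]).to_csv(path, index=False)


def write_graphml(g: nx.Graph, path) -> None:
    nx.write_graphml(g, path)
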