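"""Module network export and MNC hub-centrality mining.

A significant module is exported as a weighted undirected network whose edge
weights are TOM entries; hub OTUs are ranked by the maximal neighbourhood
component (MNC): the size of the largest connected component of the subgraph
induced by a node's neighbours (the node itself excluded). MNC is computed on
the thresholded, unweighted graph, matching how the popular network-viewer
plug-in treats imported edge lists.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from longicore.coexpression_network import ModulePartition


@dataclass
class WeightedNetwork:
    """Undirected module network: node annotations + TOM-weighted edges."""

    graph: nx.Graph
    module: str

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_table(self) -> pd.DataFrame:
        rows = [
            {"source": u, "target": v, "weight": d["weight"]}
            for u, v, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["source", "target", "weight"])

    def node_table(self) -> pd.DataFrame:
        rows = []
        for node, data in self.graph.nodes(data=True):
            rows.append(
                {
                    "id": node,
                    "genus": data.get("genus", ""),
                    "mnc": mnc(self, node),
                    "connectivity": data.get("connectivity", 0.0),
                }
            )
        return pd.DataFrame(rows, columns=["id", "genus", "mnc", "connectivity"])


def export_module_network(
    tom: pd.DataFrame,
    partition: ModulePartition,
    module: str,
    weight_threshold: float | None = None,
    top_edges_per_node: float = 3.0,
    genus_annotation: pd.Series | None = None,
) -> WeightedNetwork:
    """Build the weighted network of one module from its TOM block.

    With an explicit ``weight_threshold`` every member pair with TOM above it
    becomes an edge. By default the export is density-controlled instead:
    the strongest ``top_edges_per_node * module size`` edges are retained,
    which keeps exports comparable across module sizes.
    Nodes without a retained edge are dropped; node connectivity is the sum
    of retained incident weights.
    """
    members = partition.members(module)
    if not members:
        raise ValueError(f"unknown or empty module {module!r}")
    sub = tom.loc[members, members].to_numpy(dtype=float)
    m = len(members)
    iu = np.triu_indices(m, k=1)
    weights = sub[iu]

    if weight_threshold is not None:
        if not 0 <= weight_threshold < 1:
            raise ValueError("weight_threshold must be in [0, 1)")
        keep = weights > weight_threshold
    else:
        n_keep = min(len(weights), int(round(top_edges_per_node * m)))
        keep = np.zeros(len(weights), dtype=bool)
        if n_keep > 0:
            order = np.argsort(-weights, kind="stable")[:n_keep]
            keep[order] = True
        keep &= weights > 0

    g = nx.Graph()
    for a, b, w in zip(iu[0][keep], iu[1][keep], weights[keep]):
        g.add_edge(members[a], members[b], weight=float(w))
    for node in g.nodes:
        genus = ""
        if genus_annotation is not None and node in genus_annotation.index:
            genus = str(genus_annotation.loc[node])
        g.nodes[node]["genus"] = genus
        g.nodes[node]["connectivity"] = float(
            sum(d["weight"] for _, _, d in g.edges(node, data=True))
        )
    return WeightedNetwork(graph=g, module=module)


def mnc(network: WeightedNetwork, node: str) -> int:
    """Maximal neighbourhood component centrality of one node.

    Size of the largest connected component of the subgraph induced by the
    open neighbourhood of ``node``. Isolated nodes score 0; a node whose
    neighbours are pairwise non-adjacent scores 1.
    """
    g = network.graph
    if node not in g:
        raise ValueError(f"node {node!r} not in network")
    neigh = list(g.neighbors(node))
    if not neigh:
        return 0
    sub = g.subgraph(neigh)
    return max(len(c) for c in nx.connected_components(sub))


def top_hubs(network: WeightedNetwork, k: int = 10) -> pd.DataFrame:
    """Top-k hub nodes by (MNC desc, weighted connectivity desc, id asc)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if network.n_edges == 0:
        raise ValueError("network has no edges")
    table = network.node_table()
    if k > len(table):
        warnings.warn(f"k={k} exceeds node count {len(table)}; returning all")
        k = len(table)
    table = table.sort_values(
        ["mnc", "connectivity", "id"], ascending=[False, False, True],
        kind="stable",
    ).head(k)
    table["rank"] = np.arange(1, len(table) + 1)
    return table.reset_index(drop=True)


def hub_genera(hub_table: pd.DataFrame) -> list[str]:
    """Genus names of ranked hubs, first-appearance order, duplicates dropped."""
    seen, out = set(), []
    for g in hub_table["genus"]:
        if g and g not in seen:
            seen.add(g)
            out.append(g)
    return out


def write_network(network: WeightedNetwork, edge_path, node_path,
                  sif_path=None) -> None:
    """Edge/node TSVs in graph-viewer column order, plus optional SIF."""
    network.edge_table().to_csv(edge_path, sep="\t", index=False)
    network.node_table().to_csv(node_path, sep="\t", index=False)
    if sif_path is not None:
        with open(sif_path, "w") as fh:
            for u, v in network.graph.edges():
                fh.write(f"{u}\tco\t{v}\n")
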