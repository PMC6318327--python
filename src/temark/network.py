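"""Bipartite mark/modifier-TE relational network from thresholded enrichment."""

from __future__ import annotations

import warnings

import networkx as nx
import pandas as pd

from .enrichment import EnrichmentMatrix

__all__ = ["build_relational_network", "network_summary", "export_network", "read_network_tsv"]


def build_relational_network(
    mark_matrix: EnrichmentMatrix,
    cm_matrix: EnrichmentMatrix | None = None,
    threshold: float = 2.0,
    strict: bool = True,
    keep_isolates: bool = False,
) -> nx.Graph:
    """Draw an edge between a mark (or chromatin modifier) and a TE type when
    the mark's fold enrichment at that type passes ``threshold``.

    Marks and modifiers are distinct node types in one graph; nodes that
    end up without edges are dropped unless ``keep_isolates``.  When both
    matrices are given their TE-type column spaces are intersected (an
    empty intersection is an error).
    """
    layers = [("mark", mark_matrix)]
    if cm_matrix is not None:
        layers.append(("modifier", cm_matrix))
        common = [t for t in mark_matrix.te_types if t in set(cm_matrix.te_types)]
        if not common:
            raise ValueError("mark and modifier matrices share no TE types")
        if len(common) < len(mark_matrix.te_types) or len(common) < len(cm_matrix.te_types):
            warnings.warn(f"using intersection of TE spaces ({len(common)} types)")
    else:
        common = mark_matrix.te_types

    g = nx.Graph(threshold=threshold, strict=strict)
    for node_type, matrix in layers:
        fold = matrix.fold[common]
        lf = matrix.log2fold[common]
        for mark in fold.index:
            g.add_node(mark, node_type=node_type)
            for te in common:
                f = float(fold.loc[mark, te])
                if (f > threshold) if strict else (f >= threshold):
                    g.add_node(te, node_type="te_type")
                    g.add_edge(mark, te, log2fold=float(lf.loc[mark, te]))
    if keep_isolates:
        for te in common:
            if te not in g:
                g.add_node(te, node_type="te_type")
    else:
        g.remove_nodes_from(list(nx.isolates(g)))
    return g


def network_summary(g: nx.Graph, n_hubs: int = 10) -> dict:
    """Degree table, connected-component count and top-degree hubs
    (ties broken lexicographically)."""
    degrees = pd.DataFrame(
        [(n, g.nodes[n].get("node_type", ""), d) for n, d in g.degree()],
        columns=["node", "node_type", "degree"],
    ).sort_values(["degree", "node"], ascending=[False, True], kind="stable").reset_index(drop=True)
    hubs = degrees["node"].head(n_hubs).tolist()
    return {
        "degrees": degrees,
        "n_components": nx.number_connected_components(g),
        "n_edges": g.number_of_edges(),
        "hubs": hubs,
    }


def export_network(g: nx.Graph, path: str, format: str = "tsv_edgelist") -> None:
    """Write the network as GraphML or a TSV edge list
    (source, target, source_type, log2fold)."""
    if format == "graphml":
        nx.write_graphml(g, path)
    elif format == "tsv_edgelist":
        rows = [
            (u, v, g.nodes[u].get("node_type", ""), f"{d['log2fold']:.6g}")
            for u, v, d in sorted(g.edges(data=True))
        ]
        pd.DataFrame(rows, columns=["source", "target", "source_type", "log2fold"]).to_csv(
            path, sep="\t", index=False
        )
    else:
        raise ValueError(f"unknown network format: {format!r}")


def read_network_tsv(path: str) -> nx.Graph:
    """Read back a TSV edge list written by :func:`export_network`."""
    df = pd.read_csv(path, sep="\t", dtype={"source": str, "target": str})
    g = nx.Graph()
    for row in df.itertuples(index=False):
        g.add_node(row.source, node_type=row.source_type)
        g.add_node(row.target, node_type="te_type")
        g.add_edge(row.source, row.target, log2fold=float(row.log2fold))
    return g
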