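"""Cytoscape-compatible exports of the biochemical network.

GraphML round-trips all node/edge attributes; SIF export writes one line per
edge plus sidecar node/edge attribute TSVs. Rendering hints are materialized
as attributes: node ``size`` scales with the fold-change magnitude and
``color`` encodes direction (blue lower / red higher in ERneg, grey
unchanged).
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import numpy as np

_DIRECTION_COLOR = {"up": "red", "down": "blue", "unchanged": "grey"}


def _with_render_attrs(graph: nx.Graph) -> nx.Graph:
    g = graph.copy()
    for node, data in g.nodes(data=True):
        fc = float(data.get("fold_change", 1.0))
        # size proportional to |log2 fold change|, with a visible floor
        data["size"] = round(20.0 * (1.0 + abs(np.log2(max(fc, 1e-12)))), 3)
        data["color"] = _DIRECTION_COLOR.get(data.get("direction", "unchanged"),
                                             "grey")
    return g


def export_graph(graph: nx.Graph, path: str | Path, fmt: str = "graphml") -> None:
    """Write the graph as GraphML or as SIF plus attribute tables."""
    path = Path(path)
    g = _with_render_attrs(graph)
    if fmt == "graphml":
        nx.write_graphml(g, path)
    elif fmt == "sif":
        with open(path, "w") as fh:
            for u, v, data in sorted(g.edges(data=True)):
                fh.write(f"{u}\t{data['edge_class']}\t{v}\n")
        node_path = path.with_suffix(".nodes.tsv")
        with open(node_path, "w") as fh:
            fh.write("id\tkind\tfold_change\traw_p\tdirection\tsize\tcolor\n")
            for node, d in sorted(g.nodes(data=True)):
                fh.write(f"{node}\t{d['kind']}\t{d['fold_change']:.6g}\t"
                         f"{d['raw_p']:.6g}\t{d['direction']}\t{d['size']}\t"
                         f"{d['color']}\n")
        edge_path = path.with_suffix(".edges.tsv")
        with open(edge_path, "w") as fh:
            fh.write("source\ttarget\tedge_class\tweight\n")
            for u, v, d in sorted(g.edges(data=True)):
                w = f"{d['weight']:.6g}" if "weight" in d else ""
                fh.write(f"{u}\t{v}\t{d['edge_class']}\t{w}\n")
    else:
        raise ValueError(f"unknown format {fmt!r}; use 'graphml' or 'sif'")


def load_graphml(path: str | Path) -> nx.Graph:
    return nx.read_graphml(path)
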