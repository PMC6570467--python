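"""Integrated metabolite-protein-gene biochemical network.

Nodes are genes, proteins, metabolites and enzymes (EC numbers); edges come
in five classes: gene-enzyme and protein-enzyme (shared EC annotation),
compound-enzyme (a metabolite is substrate/product of the EC's reaction),
rpair (curated biochemical reactant pairs), and chemical-similarity
(Tanimoto similarity of structural fingerprints strictly above a threshold,
0.7 by default). Node attributes carry each entity's fold change, raw
p-value and direction for Cytoscape-style rendering (size by fold change,
color by direction).
"""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .bionet_export import export_graph, load_graphml  # noqa: F401 (re-export)
from .diffstat import DiffTable
from .synthio import CompoundRecord

logger = logging.getLogger(__name__)

EDGE_CLASSES = ("gene-enzyme", "protein-enzyme", "compound-enzyme",
                "rpair", "chemical-similarity")


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """Tanimoto similarity |a AND b| / |a OR b| of two equal-length bitsets.

    Two all-zero fingerprints score 0, not 1, so unannotated compounds do not
    form spurious similarity cliques.
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"fingerprint length mismatch: {a.size} vs {b.size}")
    union = int(np.sum(a | b))
    if union == 0:
        return 0.0
    return float(np.sum(a & b) / union)


def _node_attrs(feature: str, diff_lookup: dict[str, tuple[float, float, str]],
                kind: str) -> dict:
    if feature in diff_lookup:
        p, fc, direction = diff_lookup[feature]
    else:
        p, fc, direction = 1.0, 1.0, "unchanged"
        if kind != "enzyme":
            logger.warning("no differential record for %s %s; neutral "
                           "attributes assigned", kind, feature)
    return {"kind": kind, "raw_p": float(p), "fold_change": float(fc),
            "direction": direction}


def build_network(compounds: dict[str, CompoundRecord],
                  ec_ann: dict[str, set[str]],
                  protein_ec: dict[str, set[str]],
                  diff_tables: list[DiffTable],
                  threshold: float = 0.7) -> nx.Graph:
    """Assemble the typed undirected graph from annotations and statistics.

    Chemical-similarity edges require Tanimoto STRICTLY greater than
    ``threshold`` (a pair at exactly the threshold gets no edge). Node and
    edge insertion order is sorted, so construction is a pure function of
    its inputs.
    """
    lookup: dict[str, tuple[float, float, str]] = {}
    for dt in diff_tables:
        for row in dt.table.itertuples(index=False):
            lookup[row.feature] = (row.raw_p, row.fold_change, row.direction)

    g = nx.Graph()
    ecs_used = sorted(
        set().union(*ec_ann.values()) if ec_ann else set(),
        ) if ec_ann else []
    ecs_used = sorted(set(ecs_used)
                      | set().union(*(protein_ec.values() or [set()]))
                      | set().union(*(c.ec_links for c in compounds.values())
                                    or [set()]))
    for ec in ecs_used:
        g.add_node(ec, **_node_attrs(ec, lookup, "enzyme"))
    for gene in sorted(ec_ann):
        g.add_node(gene, **_node_attrs(gene, lookup, "gene"))
        for ec in sorted(ec_ann[gene]):
            g.add_edge(gene, ec, edge_class="gene-enzyme")
    for prot in sorted(protein_ec):
        g.add_node(prot, **_node_attrs(prot, lookup, "protein"))
        for ec in sorted(protein_ec[prot]):
            g.add_edge(prot, ec, edge_class="protein-enzyme")

    cids = sorted(compounds)
    for cid in cids:
        g.add_node(cid, **_node_attrs(cid, lookup, "metabolite"))
        for ec in sorted(compounds[cid].ec_links):
            g.add_edge(cid, ec, edge_class="compound-enzyme")
    for cid in cids:
        for partner in sorted(compounds[cid].reactant_pairs):
            if partner in compounds and partner != cid:
                g.add_edge(cid, partner, edge_class="rpair")
    for i, a in enumerate(cids):
        for b in cids[i + 1:]:
            if g.has_edge(a, b):
                continue  # rpair takes precedence for the pair
            sim = tanimoto(compounds[a].fingerprint, compounds[b].fingerprint)
            if sim > threshold:
                g.add_edge(a, b, edge_class="chemical-similarity",
                           weight=round(sim, 6))
    return g


def detect_communities(graph: nx.Graph, seed: int = 0) -> dict[str, int]:
    """Label every node with a community id via greedy modularity clustering.

    Run per connected component so components are never merged; labels are
    deterministic (components and their communities are processed in sorted
    order). The algorithm is pluggable in spirit: swap this function for any
    mapping node -> int.
    """
    labels: dict[str, int] = {}
    next_label = 0
    components = sorted(nx.connected_components(graph), key=lambda c: min(c))
    for comp in components:
        sub = graph.subgraph(comp)
        if sub.number_of_edges() == 0:
            comms = [set(sub.nodes)]
        else:
            comms = nx.community.greedy_modularity_communities(sub)
        for comm in sorted((sorted(c) for c in comms), key=lambda c: c[0]):
            for node in comm:
                labels[node] = next_label
            next_label += 1
    return labels


def read_rpairs_tsv(path: str | Path) -> set[tuple[str, str]]:
    df = pd.read_csv(path, sep="\t")
    pairs = set()
    for a, b in zip(df.iloc[:, 0], df.iloc[:, 1]):
        if a != b:
            pairs.add((min(a, b), max(a, b)))
    return pairs


def compounds_from_inputs(fingerprints: dict[str, np.ndarray],
                          rpairs: set[tuple[str, str]] | None = None,
                          ec_links: dict[str, set[str]] | None = None
                          ) -> dict[str, CompoundRecord]:
    """Assemble CompoundRecords from fingerprint/rpair/EC-link inputs."""
    rpairs = rpairs or set()
    ec_links = ec_links or {}
    lengths = {fp.size for fp in fingerprints.values()}
    if len(lengths) > 1:
        raise ValueError(f"inconsistent fingerprint lengths: {sorted(lengths)}")
    out = {cid: CompoundRecord(cid, fp, set(), set(ec_links.get(cid, set())))
           for cid, fp in fingerprints.items()}
    for a, b in rpairs:
        if a in out and b in out:
            out[a].reactant_pairs.add(b)
            out[b].reactant_pairs.add(a)
    return out
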