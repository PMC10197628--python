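"""Seed-centered cross-tissue correlation networks.

Nodes are (tissue, gene) pairs: the seed, its top within-tissue correlates
and its top peripheral (other-tissue) correlates by |bicor|. Edges are
computed between *all* node pairs, not just seed spokes, and kept when the
absolute coefficient falls inside a window (default 0.6 <= |r| <= 0.99; the
upper bound drops duplicate/identical transcripts whose r = 1). Edge sign is
recorded so positive and negative correlations can be styled apart.
"""

from __future__ import annotations

import itertools
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .archive import DataError, ExpressionTensor
from .bicor import DEFAULT_MIN_N, bicor_matrix
from .query import seed_gene_query

DEFAULT_MIN_BICOR = 0.6
DEFAULT_MAX_BICOR = 0.99


def build_network(
    tensor: ExpressionTensor,
    seed_tissue: str,
    seed_gene: str,
    n_within: int = 15,
    n_peripheral: int = 15,
    min_bicor: float = DEFAULT_MIN_BICOR,
    max_bicor: float = DEFAULT_MAX_BICOR,
    min_n: int = DEFAULT_MIN_N,
) -> nx.Graph:
    """Undirected correlation network around a seed gene-tissue pair.

    Node selection: the ``n_within`` seed-tissue genes and ``n_peripheral``
    other-tissue genes with the largest |bicor| to the seed. Every pair of
    selected nodes (seed included) is then correlated and an edge emitted
    when ``min_bicor <= |r| <= max_bicor``. Nodes are ``(tissue, gene)``
    tuples with a ``within`` attribute; edges carry ``r`` and ``sign``.
    """
    if n_within < 0 or n_peripheral < 0:
        raise ValueError("n_within and n_peripheral must be >= 0")
    if not 0 <= min_bicor <= max_bicor:
        raise ValueError("need 0 <= min_bicor <= max_bicor")
    table = seed_gene_query(tensor, seed_tissue, seed_gene, min_n=min_n).table
    table = table.reindex(
        table["bicor"].abs().sort_values(ascending=False, kind="mergesort").index
    )
    within = table[table["tissue"] == seed_tissue].head(n_within)
    peripheral = table[table["tissue"] != seed_tissue].head(n_peripheral)
    nodes = [(seed_tissue, seed_gene)] + [
        (t, g) for t, g in zip(within["tissue"], within["gene"])
    ] + [(t, g) for t, g in zip(peripheral["tissue"], peripheral["gene"])]

    graph = nx.Graph(
        seed_tissue=seed_tissue,
        seed_gene=seed_gene,
        min_bicor=min_bicor,
        max_bicor=max_bicor,
    )
    for tissue, gene in nodes:
        graph.add_node(
            (tissue, gene), tissue=tissue, gene=gene, within=(tissue == seed_tissue)
        )
    vectors = np.vstack(
        [
            tensor.matrix(t).loc[g].to_numpy(dtype=float)[None, :]
            for t, g in nodes
        ]
    )
    r, n = bicor_matrix(vectors, vectors, min_n=min_n)
    for i, j in itertools.combinations(range(len(nodes)), 2):
        rij = r[i, j]
        if np.isfinite(rij) and min_bicor <= abs(rij) <= max_bicor:
            graph.add_edge(
                nodes[i],
                nodes[j],
                r=float(rij),
                sign="positive" if rij >= 0 else "negative",
            )
    return graph


def edge_list(graph: nx.Graph) -> pd.DataFrame:
    """Edges as a frame with tissue:gene endpoints and signed r."""
    rows = [
        {
            "source": f"{a[0]}:{a[1]}",
            "target": f"{b[0]}:{b[1]}",
            "r": d["r"],
            "sign": d["sign"],
        }
        for a, b, d in graph.edges(data=True)
    ]
    return pd.DataFrame(rows, columns=["source", "target", "r", "sign"])


def write_edge_list(graph: nx.Graph, path: str | Path) -> None:
    edge_list(graph).to_csv(path, sep="\t", index=False)


def write_graphml(graph: nx.Graph, path: str | Path) -> None:
    """GraphML export; tuple node IDs are flattened to 'tissue:gene'."""
    flat = nx.relabel_nodes(graph, {n: f"{n[0]}:{n[1]}" for n in graph.nodes})
    nx.write_graphml(flat, path)
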