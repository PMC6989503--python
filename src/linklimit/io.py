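"""Readers and writers for plain edge lists and GraphML.

Edge-list dialect: whitespace/tab delimited, ``#``-prefixed comment lines,
arbitrary string labels, extra columns (e.g. weights) ignored with a warning.
Nodes are relabeled to contiguous integers ``0..n-1``; the original labels are
retained on the returned graph and round-tripped through GraphML as a node
attribute.
"""
from __future__ import annotations

import warnings
from pathlib import Path
from typing import Union

import networkx as nx

from .graph import UndirectedGraph

__all__ = ["read_edge_list", "write_edge_list", "read_graphml", "write_graphml"]


class EdgeListParseError(ValueError):
    pass


def read_edge_list(path: Union[str, Path], comment: str = "#") -> UndirectedGraph:
    """Parse a two-column whitespace-delimited edge list.

    Duplicate edges (in either orientation) are deduplicated silently;
    self-loops are dropped and reported in a single warning.
    """
    path = Path(path)
    labels: dict[str, int] = {}
    edges = set()
    self_loops = 0
    extra_cols = False
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith(comment):
                continue
            tokens = stripped.split()
            if len(tokens) < 2:
                raise EdgeListParseError(
                    f"{path}:{lineno}: expected at least 2 tokens, got {len(tokens)}"
                )
            if len(tokens) > 2:
                extra_cols = True
            a, b = tokens[0], tokens[1]
            if a == b:
                self_loops += 1
                continue
            for lab in (a, b):
                if lab not in labels:
                    labels[lab] = len(labels)
            u, v = labels[a], labels[b]
            edges.add((u, v) if u < v else (v, u))
    if self_loops:
        warnings.warn(f"{path}: dropped {self_loops} self-loop(s)")
    if extra_cols:
        warnings.warn(f"{path}: extra columns ignored (graph treated as unweighted)")
    if not labels:
        raise EdgeListParseError(f"{path}: no edges found")
    label_list = [None] * len(labels)
    for lab, i in labels.items():
        label_list[i] = lab
    return UndirectedGraph(len(labels), edges, labels=label_list)


def write_edge_list(g: UndirectedGraph, path: Union[str, Path]) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# n={g.n} e={g.num_edges}\n")
        for u, v in sorted(g.edges):
            if g.labels is not None:
                fh.write(f"{g.labels[u]} {g.labels[v]}\n")
            else:
                fh.write(f"{u} {v}\n")


def to_networkx(g: UndirectedGraph) -> nx.Graph:
    gx = nx.Graph()
    for i in range(g.n):
        label = g.labels[i] if g.labels is not None else str(i)
        gx.add_node(i, label=str(label))
    gx.add_edges_from(g.edges)
    return gx


def from_networkx(gx: nx.Graph) -> UndirectedGraph:
    nodes = list(gx.nodes())
    index = {node: i for i, node in enumerate(nodes)}
    labels = [str(gx.nodes[node].get("label", node)) for node in nodes]
    edges = set()
    for a, b in gx.edges():
        if a == b:
            continue
        u, v = index[a], index[b]
        edges.add((u, v) if u < v else (v, u))
    return UndirectedGraph(len(nodes), edges, labels=labels)


def read_graphml(path: Union[str, Path]) -> UndirectedGraph:
    return from_networkx(nx.read_graphml(Path(path)))


def write_graphml(g: UndirectedGraph, path: Union[str, Path]) -> None:
    nx.write_graphml(to_networkx(g), Path(path))
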