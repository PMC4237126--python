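"""Mutation-step distance matrices and haplotype networks.

Distances between haplotypes are Hamming distances over coded characters
(one step per substitution difference, one step per differing indel
character).  Two network constructions are provided:

* the epsilon-relaxed minimum spanning network (MSN): the union of all
  minimum spanning trees, plus every link whose weight is within
  ``epsilon`` of the threshold at which its endpoints' components merge;
* a median-joining network: the MSN is iteratively augmented with median
  vectors (consensus haplotypes of connected triplets, computed per
  character by strict majority on a binary character expansion), then
  median vectors that do not shorten the network are pruned.

All tie-breaking is lexicographic on node ids, so both constructions are
deterministic and invariant to haplotype input order.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .seqio import HaplotypeSet, coded_distance

log = logging.getLogger(__name__)

__all__ = [
    "MutationDistanceMatrix",
    "HaploNetwork",
    "NetworkError",
    "mutation_distance_matrix",
    "minimum_spanning_network",
    "median_joining_network",
    "write_graphml",
    "write_edgelist",
    "read_edgelist",
    "draw_network",
]


class NetworkError(ValueError):
    """Raised for invalid network inputs (e.g. duplicate haplotype vectors)."""


@dataclass(frozen=True)
class MutationDistanceMatrix:
    """Symmetric matrix of mutation-step counts between haplotypes."""

    ids: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = self.matrix
        if m.shape != (len(self.ids), len(self.ids)):
            raise NetworkError("matrix shape does not match ids")
        if not np.allclose(m, m.T):
            raise NetworkError("distance matrix is not symmetric")
        if np.diag(m).any():
            raise NetworkError("distance matrix diagonal must be zero")
        off = m[~np.eye(len(self.ids), dtype=bool)]
        if len(self.ids) > 1 and (off < 1).any():
            raise NetworkError(
                "zero distance between distinct haplotypes; collapse first"
            )

    def index(self) -> dict[str, int]:
        return {h: i for i, h in enumerate(self.ids)}

    def submatrix(self, ids: Sequence[str]) -> "MutationDistanceMatrix":
        idx = self.index()
        sel = [idx[h] for h in ids]
        return MutationDistanceMatrix(tuple(ids), self.matrix[np.ix_(sel, sel)])


@dataclass
class HaploNetwork:
    """A haplotype network: graph over haplotypes and inferred median vectors.

    Node attributes: ``count`` (observed carriers; 0 for median vectors) and
    ``is_median``.  Edge attribute ``steps`` holds the mutation count.
    """

    graph: nx.Graph
    epsilon: int = 0

    @property
    def total_length(self) -> int:
        return int(sum(d["steps"] for _, _, d in self.graph.edges(data=True)))

    @property
    def haplotype_ids(self) -> tuple[str, ...]:
        return tuple(
            n for n, d in sorted(self.graph.nodes(data=True)) if not d["is_median"]
        )

    @property
    def median_ids(self) -> tuple[str, ...]:
        return tuple(
            n for n, d in sorted(self.graph.nodes(data=True)) if d["is_median"]
        )


def mutation_distance_matrix(haps: HaplotypeSet) -> MutationDistanceMatrix:
    """Pairwise mutation steps (coded-character Hamming distance)."""
    ids = tuple(haps.ids)
    H = len(ids)
    m = np.zeros((H, H), dtype=int)
    for i in range(H):
        for j in range(i + 1, H):
            m[i, j] = m[j, i] = coded_distance(
                haps.vectors[ids[i]], haps.vectors[ids[j]]
            )
    return MutationDistanceMatrix(ids, m)


# ---------------------------------------------------------------------------
# minimum spanning network
# ---------------------------------------------------------------------------


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb


def _msn_edges(
    ids: Sequence[str], matrix: np.ndarray, epsilon: int
) -> list[tuple[str, str, int]]:
    """Edges of the epsilon-relaxed MSN.

    Edge (u, v) of weight w is kept iff u and v are in different connected
    components of the graph restricted to edges of weight < w - epsilon.
    At epsilon = 0 this is exactly the union of all minimum spanning trees.
    """
    n = len(ids)
    if n <= 1:
        return []
    pairs = sorted(
        (int(matrix[i, j]),) + tuple(sorted((ids[i], ids[j])))
        for i in range(n)
        for j in range(i + 1, n)
    )
    uf = _UnionFind(ids)
    ptr = 0
    kept = []
    for w, u, v in pairs:
        thr = w - epsilon
        while ptr < len(pairs) and pairs[ptr][0] < thr:
            uf.union(pairs[ptr][1], pairs[ptr][2])
            ptr += 1
        if uf.find(u) != uf.find(v):
            kept.append((u, v, w))
    return kept


def _build_network(
    ids: Sequence[str],
    edges: Sequence[tuple[str, str, int]],
    counts: Mapping[str, int],
    medians: set[str],
    epsilon: int,
) -> HaploNetwork:
    g = nx.Graph()
    for h in sorted(ids):
        g.add_node(h, count=int(counts.get(h, 0)), is_median=h in medians)
    for u, v, w in sorted(edges):
        g.add_edge(u, v, steps=int(w))
    return HaploNetwork(graph=g, epsilon=epsilon)


def minimum_spanning_network(
    D: MutationDistanceMatrix,
    epsilon: int = 0,
    counts: Mapping[str, int] | None = None,
) -> HaploNetwork:
    """Epsilon-relaxed minimum spanning network over observed haplotypes."""
    if epsilon < 0:
        raise NetworkError("epsilon must be >= 0")
    edges = _msn_edges(D.ids, D.matrix, epsilon)
    return _build_network(D.ids, edges, counts or {}, set(), epsilon)


# ---------------------------------------------------------------------------
# median joining
# ---------------------------------------------------------------------------


def _binary_expand(vectors: Mapping[str, tuple]) -> dict[str, np.ndarray]:
    """Expand coded vectors to binary characters.

    Characters with two observed states map to one 0/1 column; characters
    with more than two states (possible only with homoplasy on raw
    nucleotide states) are one-hot expanded, one binary column per state.
    Constant characters are dropped.  Missing values are not supported here:
    haplotypes are by construction complete.
    """
    ids = list(vectors)
    length = len(next(iter(vectors.values()))) if ids else 0
    cols: list[np.ndarray] = []
    for j in range(length):
        states = sorted({vectors[h][j] for h in ids}, key=str)
        if any(s is None for s in states):
            raise NetworkError("missing states in haplotype vectors")
        if len(states) == 1:
            continue
        if len(states) == 2:
            cols.append(
                np.array([vectors[h][j] == states[1] for h in ids], dtype=np.uint8)
            )
        else:
            for s in states:
                cols.append(
                    np.array([vectors[h][j] == s for h in ids], dtype=np.uint8)
                )
    if cols:
        mat = np.stack(cols, axis=1)
    else:
        mat = np.zeros((len(ids), 0), dtype=np.uint8)
    return {h: mat[i] for i, h in enumerate(ids)}


def _hamming_matrix(ids: Sequence[str], vecs: Mapping[str, np.ndarray]) -> np.ndarray:
    arr = np.stack([vecs[h] for h in ids]).astype(np.int16)
    return np.abs(arr[:, None, :] - arr[None, :, :]).sum(axis=2)


def median_joining_network(
    haps: HaplotypeSet, epsilon: int = 0, max_rounds: int = 30
) -> HaploNetwork:
    """Median-joining network over coded haplotypes.

    Iteratively builds the epsilon-relaxed MSN over the current node set and,
    for every triplet of nodes connected by at least two MSN links, adds the
    per-character majority consensus (median vector) if it is a new sequence.
    When no vector can be added, median vectors whose removal leaves a
    network no longer in total length are pruned.
    """
    base = _binary_expand({h: haps.vectors[h] for h in haps.ids})
    nodes: dict[str, np.ndarray] = dict(base)
    known = {tuple(v): h for h, v in nodes.items()}
    medians: set[str] = set()
    mv_count = 0

    if len(nodes) == 1:
        return _build_network(list(nodes), [], haps.counts, set(), epsilon)

    for _ in range(max_rounds):
        ids_sorted = sorted(nodes)
        M = _hamming_matrix(ids_sorted, nodes)
        edges = _msn_edges(ids_sorted, M, epsilon)
        adj = {frozenset((u, v)) for u, v, _ in edges}
        new_batch: list[np.ndarray] = []
        seen_batch: set[tuple] = set()
        for a, b, c in itertools.combinations(ids_sorted, 3):
            links = (
                (frozenset((a, b)) in adj)
                + (frozenset((a, c)) in adj)
                + (frozenset((b, c)) in adj)
            )
            if links < 2:
                continue
            trip = np.stack([nodes[a], nodes[b], nodes[c]])
            med = (trip.sum(axis=0) >= 2).astype(np.uint8)
            key = tuple(med)
            if key in known or key in seen_batch:
                continue
            seen_batch.add(key)
            new_batch.append(med)
        if not new_batch:
            break
        for med in new_batch:
            mv_count += 1
            name = f"mv{mv_count}"
            nodes[name] = med
            known[tuple(med)] = name
            medians.add(name)
    else:
        log.warning("median joining did not converge in %d rounds", max_rounds)

    def net_total(node_ids: Sequence[str]) -> int:
        M = _hamming_matrix(node_ids, nodes)
        return sum(w for _, _, w in _msn_edges(node_ids, M, epsilon))

    current = sorted(nodes)
    changed = True
    while changed:
        changed = False
        base_total = net_total(current)
        for m in sorted(medians & set(current)):
            cand = [x for x in current if x != m]
            if net_total(cand) <= base_total:
                current = cand
                changed = True
                break

    M = _hamming_matrix(current, nodes)
    edges = _msn_edges(current, M, epsilon)
    net = _build_network(current, edges, haps.counts, medians & set(current), epsilon)
    for m in net.median_ids:
        if net.graph.degree(m) < 2:  # pruned medians cannot dangle
            log.warning("median vector %s has degree < 2 after pruning", m)
    return net


# ---------------------------------------------------------------------------
# output
# ---------------------------------------------------------------------------


def write_graphml(net: HaploNetwork, path: str | Path) -> None:
    nx.write_graphml(net.graph, str(path))


def write_edgelist(net: HaploNetwork, path: str | Path) -> None:
    """Plain TSV edge list: source, target, steps (sorted, deterministic)."""
    rows = sorted(
        (u, v, d["steps"]) if u <= v else (v, u, d["steps"])
        for u, v, d in net.graph.edges(data=True)
    )
    pd.DataFrame(rows, columns=["source", "target", "steps"]).to_csv(
        path, sep="\t", index=False
    )


def read_edgelist(path: str | Path) -> nx.Graph:
    df = pd.read_csv(path, sep="\t")
    g = nx.Graph()
    for _, row in df.iterrows():
        g.add_edge(str(row["source"]), str(row["target"]), steps=int(row["steps"]))
    return g


def draw_network(net: HaploNetwork, ax=None, layout_seed: int = 0, scale: float = 60.0):
    """Plot hook: spring layout, node size proportional to haplotype frequency,
    median vectors drawn as small open squares."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    g = net.graph
    pos = nx.spring_layout(g, seed=layout_seed)
    haps = [n for n, d in g.nodes(data=True) if not d["is_median"]]
    meds = [n for n, d in g.nodes(data=True) if d["is_median"]]
    sizes = [scale * max(g.nodes[n]["count"], 1) for n in haps]
    nx.draw_networkx_edges(g, pos, ax=ax)
    nx.draw_networkx_nodes(g, pos, nodelist=haps, node_size=sizes, ax=ax)
    if meds:
        nx.draw_networkx_nodes(
            g, pos, nodelist=meds, node_shape="s", node_size=scale / 2,
            node_color="white", edgecolors="black", ax=ax,
        )
    nx.draw_networkx_labels(g, pos, font_size=7, ax=ax)
    labels = {(u, v): d["steps"] for u, v, d in g.edges(data=True) if d["steps"] > 1}
    if labels:
        nx.draw_networkx_edge_labels(g, pos, edge_labels=labels, font_size=6, ax=ax)
    ax.set_axis_off()
    return ax
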