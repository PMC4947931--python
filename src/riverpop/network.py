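"""Minimum-spanning and median-joining haplotype networks.

The minimum spanning network (MSN) is the union of all minimum spanning
trees on Hamming distances: an edge (u, v) belongs to the MSN exactly when
its weight equals the bottleneck (minimax-path) distance between u and v;
the ``epsilon`` parameter relaxes the criterion to weight <= bottleneck +
epsilon, adding near-minimal alternative links.

Median joining iterates: build the MSN over the current node set, generate
consensus (median) vectors for linked triples, greedily add the median that
most reduces total minimum-spanning cost, and prune inferred nodes of degree
< 3.  Processing order is fixed (frequency descending, then label) so the
construction is deterministic.
"""

from __future__ import annotations

import itertools
import json

import networkx as nx
import numpy as np
import pandas as pd

from .seqcore import HaplotypeTable

__all__ = [
    "minimum_spanning_network",
    "median_joining",
    "export_network",
    "read_network",
]


def _hamming(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def _distance_matrix(seqs: list[str]) -> np.ndarray:
    m = len(seqs)
    d = np.zeros((m, m), dtype=np.int64)
    for i, j in itertools.combinations(range(m), 2):
        d[i, j] = d[j, i] = _hamming(seqs[i], seqs[j])
    return d


def _bottleneck_distances(d: np.ndarray) -> np.ndarray:
    """Minimax path weights via an MST + path maxima (small m, direct DP)."""
    m = d.shape[0]
    # Prim MST
    in_tree = np.zeros(m, dtype=bool)
    in_tree[0] = True
    best = d[0].astype(float).copy()
    best_edge = np.zeros(m, dtype=np.int64)
    mst_adj: dict[int, list[tuple[int, int]]] = {i: [] for i in range(m)}
    for _ in range(m - 1):
        cand = np.where(in_tree, np.inf, best)
        v = int(np.argmin(cand))
        u = int(best_edge[v])
        w = int(d[u, v])
        mst_adj[u].append((v, w))
        mst_adj[v].append((u, w))
        in_tree[v] = True
        closer = d[v] < best
        best = np.where(closer, d[v], best)
        best_edge = np.where(closer, v, best_edge)
    # max edge on MST path between every pair (BFS from each node)
    bn = np.zeros((m, m), dtype=np.int64)
    for s in range(m):
        stack = [(s, 0)]
        seen = {s}
        while stack:
            node, mx = stack.pop()
            for nb, w in mst_adj[node]:
                if nb in seen:
                    continue
                seen.add(nb)
                bn[s, nb] = max(mx, w)
                stack.append((nb, max(mx, w)))
    return bn


def _msn_edges(seqs: list[str], epsilon: int = 0) -> list[tuple[int, int, int]]:
    if len(seqs) < 2:
        return []
    d = _distance_matrix(seqs)
    bn = _bottleneck_distances(d)
    edges = []
    for i, j in itertools.combinations(range(len(seqs)), 2):
        if d[i, j] <= bn[i, j] + epsilon:
            edges.append((i, j, int(d[i, j])))
    return edges


def _mst_cost(seqs: list[str]) -> int:
    d = _distance_matrix(seqs)
    m = d.shape[0]
    in_tree = np.zeros(m, dtype=bool)
    in_tree[0] = True
    best = d[0].astype(float).copy()
    total = 0
    for _ in range(m - 1):
        cand = np.where(in_tree, np.inf, best)
        v = int(np.argmin(cand))
        total += int(cand[v])
        in_tree[v] = True
        best = np.minimum(best, d[v])
    return total


def _build_graph(
    ht: HaplotypeTable,
    node_seqs: list[str],
    node_names: list[str],
    epsilon: int,
) -> nx.Graph:
    observed = {seq: label for seq, label in zip(ht.sequences, ht.labels())}
    g = nx.Graph(epsilon=epsilon)
    for name, seq in zip(node_names, node_seqs):
        if seq in observed:
            row = ht.counts.loc[observed[seq]]
            g.add_node(
                name,
                sequence=seq,
                median=False,
                size=int(row.sum()),
                counts=json.dumps({p: int(c) for p, c in row.items() if c > 0}),
            )
        else:
            g.add_node(name, sequence=seq, median=True, size=0, counts="{}")
    for i, j, w in _msn_edges(node_seqs, epsilon):
        g.add_edge(node_names[i], node_names[j], weight=int(w))
    return g


def minimum_spanning_network(ht: HaplotypeTable, epsilon: int = 0) -> nx.Graph:
    """MSN over observed haplotypes (union of all MSTs, epsilon-relaxed)."""
    if ht.h < 2:
        raise ValueError("network needs >= 2 haplotypes")
    seqs = list(ht.sequences)
    return _build_graph(ht, seqs, ht.labels(), epsilon)


def _median_vector(a: str, b: str, c: str) -> str:
    """Per-site majority consensus; three-way ties resolved to the
    lexicographically smallest state (deterministic simplification)."""
    out = []
    for x, y, z in zip(a, b, c):
        if x == y or x == z:
            out.append(x)
        elif y == z:
            out.append(y)
        else:
            out.append(min(x, y, z))
    return "".join(out)


def median_joining(
    ht: HaplotypeTable, epsilon: int = 0, max_iter: int = 100
) -> nx.Graph:
    """Median-joining network: MSN augmented with inferred median vectors.

    Medians are generated from triples of nodes linked in the current MSN
    and added greedily while they strictly reduce the minimum-spanning cost;
    inferred nodes of degree < 3 are pruned.  Raises if the iteration cap is
    hit without convergence.
    """
    if ht.h < 2:
        raise ValueError("network needs >= 2 haplotypes")
    observed = list(ht.sequences)
    freq = {s: int(c) for s, c in zip(observed, ht.total_counts())}
    nodes = sorted(observed, key=lambda s: (-freq[s], s))
    for it in range(max_iter):
        changed = False
        # greedy median augmentation
        while True:
            edges = _msn_edges(nodes, epsilon)
            adj: dict[int, set[int]] = {i: set() for i in range(len(nodes))}
            for i, j, _ in edges:
                adj[i].add(j)
                adj[j].add(i)
            base_cost = _mst_cost(nodes)
            candidates: list[str] = []
            seen: set[str] = set(nodes)
            for i in range(len(nodes)):
                # triples sharing a hub: i-j and i-k both MSN-linked
                for j, k in itertools.combinations(sorted(adj[i]), 2):
                    med = _median_vector(nodes[i], nodes[j], nodes[k])
                    if med not in seen:
                        seen.add(med)
                        candidates.append(med)
            best: tuple[int, str] | None = None
            for med in sorted(candidates):
                cost = _mst_cost(nodes + [med])
                if cost < base_cost and (best is None or cost < best[0]):
                    best = (cost, med)
            if best is None:
                break
            nodes.append(best[1])
            changed = True
        # prune inferred nodes with degree < 3
        while True:
            edges = _msn_edges(nodes, epsilon)
            degree = {i: 0 for i in range(len(nodes))}
            for i, j, _ in edges:
                degree[i] += 1
                degree[j] += 1
            drop = [
                i
                for i in range(len(nodes))
                if nodes[i] not in freq and degree[i] < 3
            ]
            if not drop:
                break
            nodes = [s for i, s in enumerate(nodes) if i not in set(drop)]
            changed = True
        if not changed:
            break
    else:
        raise RuntimeError(
            f"median joining did not converge in {max_iter} iterations "
            f"({len(nodes)} nodes)"
        )
    label_of = dict(zip(ht.sequences, ht.labels()))
    names = []
    n_median = 0
    for s in nodes:
        if s in label_of:
            names.append(label_of[s])
        else:
            n_median += 1
            names.append(f"mv{n_median}")
    return _build_graph(ht, nodes, names, epsilon)


def export_network(net: nx.Graph, path, fmt: str = "graphml") -> None:
    """Write a network as GraphML, GML or a CSV edge list."""
    path = str(path)
    if fmt == "graphml":
        nx.write_graphml(net, path)
    elif fmt == "gml":
        nx.write_gml(net, path)
    elif fmt == "edgelist":
        rows = [
            {"source": u, "target": v, "weight": d["weight"]}
            for u, v, d in net.edges(data=True)
        ]
        pd.DataFrame(rows).to_csv(path, index=False)
    else:
        raise ValueError(f"unknown network format: {fmt!r}")


def read_network(path, fmt: str = "graphml") -> nx.Graph:
    path = str(path)
    if fmt == "graphml":
        g = nx.read_graphml(path)
    elif fmt == "gml":
        g = nx.read_gml(path)
    else:
        raise ValueError(f"unknown network format: {fmt!r}")
    # normalize attribute types lost in serialisation
    out = nx.Graph(epsilon=int(g.graph.get("epsilon", 0)))
    for node, d in g.nodes(data=True):
        out.add_node(
            node,
            sequence=d["sequence"],
            median=bool(d["median"]) if not isinstance(d["median"], str) else d["median"] == "True",
            size=int(d["size"]),
            counts=d["counts"],
        )
    for u, v, d in g.edges(data=True):
        out.add_edge(u, v, weight=int(d["weight"]))
    return out
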