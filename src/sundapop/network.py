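"""Median-joining haplotype networks.

The construction follows Bandelt, Forster & Röhl's median-joining scheme:

1. connect the current node set (sampled haplotypes plus any inferred median
   vectors) by a *minimum spanning network* (MSN) — the union of all minimum
   spanning trees, relaxed by a tolerance ``epsilon``: a link (u, v) is kept
   when its cost d(u, v) does not exceed the minimax ("bottleneck") path cost
   between u and v by more than epsilon;
2. for every triplet of nodes with at least two of its three pairs linked in
   the MSN (equivalently, sharing a common linked neighbour), propose the
   per-site majority consensus (quasi-median) as an unsampled intermediate;
3. accept the proposal that most reduces the minimum-spanning-tree cost over
   the node set (ties broken lexicographically by sequence) and iterate;
4. when no proposal reduces cost, prune obsolete median vectors (those whose
   removal leaves the spanning cost unchanged) and emit the final MSN.

Distances are Hamming counts over sites where both sequences carry an
unambiguous base; median vectors have zero observed frequency.  The network
cost can therefore never exceed that of a minimum spanning tree on the
sampled haplotypes alone.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse.csgraph import minimum_spanning_tree as _scipy_mst

from .popgen.alignment import HaplotypeTable

__all__ = [
    "median_joining",
    "minimum_spanning_network",
    "hamming",
    "total_cost",
    "write_graphml",
    "edge_list",
]

_ACGT = np.frombuffer(b"ACGT", np.uint8)


def _to_bytes(seqs: list[str]) -> np.ndarray:
    return np.frombuffer("".join(seqs).encode(), np.uint8).reshape(len(seqs), -1)


def hamming(a: str, b: str) -> int:
    """Mutational distance: mismatches over sites where both are in ACGT."""
    x = np.frombuffer(a.encode(), np.uint8)
    y = np.frombuffer(b.encode(), np.uint8)
    ok = np.isin(x, _ACGT) & np.isin(y, _ACGT)
    return int(((x != y) & ok).sum())


def _dist_to_all(mat: np.ndarray, row: np.ndarray) -> np.ndarray:
    ok = np.isin(mat, _ACGT) & np.isin(row, _ACGT)[None, :]
    return ((mat != row[None, :]) & ok).sum(axis=1)


def _distance_matrix(mat: np.ndarray) -> np.ndarray:
    m = mat.shape[0]
    d = np.zeros((m, m), int)
    for i in range(m):
        d[i] = _dist_to_all(mat, mat[i])
    return d


def _mst_edges(d: np.ndarray) -> list[tuple[int, int, int]]:
    # +1 offset so zero-cost links survive the sparse representation
    t = _scipy_mst(d + 1).tocoo()
    return [(int(i), int(j), int(v - 1)) for i, j, v in zip(t.row, t.col, t.data)]


def _mst_cost_from_d(d: np.ndarray) -> int:
    return sum(c for _, _, c in _mst_edges(d))


def _bottleneck_costs(d: np.ndarray) -> np.ndarray:
    """Minimax path cost between all node pairs (max edge on an MST path)."""
    m = d.shape[0]
    edges = _mst_edges(d)
    adj: dict[int, list[tuple[int, int]]] = {i: [] for i in range(m)}
    for i, j, c in edges:
        adj[i].append((j, c))
        adj[j].append((i, c))
    bn = np.zeros((m, m), int)
    for root in range(m):
        stack = [(root, 0)]
        seen = {root}
        while stack:
            node, mx = stack.pop()
            bn[root, node] = mx
            for nb, c in adj[node]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append((nb, max(mx, c)))
    return bn


def _msn_edges(d: np.ndarray, epsilon: int) -> list[tuple[int, int, int]]:
    bn = _bottleneck_costs(d)
    m = d.shape[0]
    return [
        (i, j, int(d[i, j]))
        for i in range(m)
        for j in range(i + 1, m)
        if d[i, j] <= bn[i, j] + epsilon
    ]


def minimum_spanning_network(
    seqs: list[str], epsilon: int = 0
) -> list[tuple[int, int, int]]:
    """Edges (i, j, cost) of the epsilon-relaxed minimum spanning network."""
    return _msn_edges(_distance_matrix(_to_bytes(seqs)), epsilon)


def _quasi_median(u: np.ndarray, v: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Per-site majority consensus; three-way ties resolved to the smallest
    byte value (lexicographic, deterministic)."""
    out = np.minimum(np.minimum(u, v), w)
    out = np.where(u == v, u, out)
    out = np.where(u == w, u, out)
    out = np.where(v == w, v, out)
    return out


def median_joining(
    table: HaplotypeTable | list[str],
    epsilon: int = 0,
    max_rounds: int = 500,
) -> nx.Graph:
    """Median-joining network of a haplotype table.

    Returns a :class:`networkx.Graph` whose nodes carry ``sequence``,
    ``is_median`` and (for sampled haplotypes) ``frequency`` / per-site
    ``counts`` attributes; edges carry a ``mutations`` cost.  A single
    haplotype yields a trivial one-node network.
    """
    if isinstance(table, HaplotypeTable):
        sampled = list(table.haplotypes)
        counts = table.counts
    else:
        sampled = list(table)
        counts = None

    g = nx.Graph()
    if len(sampled) == 1:
        g.add_node("H1", sequence=sampled[0], is_median=False, frequency=1)
        return g

    mat = _to_bytes(sampled)
    d = _distance_matrix(mat)
    for _ in range(max_rounds):
        links = _msn_edges(d, epsilon)
        adj: dict[int, set[int]] = {i: set() for i in range(mat.shape[0])}
        for i, j, _c in links:
            adj[i].add(j)
            adj[j].add(i)
        base_cost = _mst_cost_from_d(d)
        seen: set[bytes] = {row.tobytes() for row in mat}
        candidates: dict[bytes, np.ndarray] = {}
        for x, nbrs in adj.items():
            ns = sorted(nbrs)
            for a_i in range(len(ns)):
                for b_i in range(a_i + 1, len(ns)):
                    med = _quasi_median(mat[x], mat[ns[a_i]], mat[ns[b_i]])
                    key = med.tobytes()
                    if key not in seen and key not in candidates:
                        candidates[key] = med
        best_row = None
        best_cost = base_cost
        m = mat.shape[0]
        for key in sorted(candidates):
            med = candidates[key]
            dv = _dist_to_all(mat, med)
            d_ext = np.zeros((m + 1, m + 1), int)
            d_ext[:m, :m] = d
            d_ext[m, :m] = dv
            d_ext[:m, m] = dv
            cost = _mst_cost_from_d(d_ext)
            if cost < best_cost:  # ties keep the lexicographically first
                best_cost = cost
                best_row = med
        if best_row is None:
            break
        dv = _dist_to_all(mat, best_row)
        mat = np.vstack([mat, best_row])
        d = np.block([[d, dv[:, None]], [dv[None, :], np.zeros((1, 1), int)]])

    # prune obsolete medians: removal leaves the spanning cost unchanged
    n_sampled = len(sampled)
    keep = list(range(mat.shape[0]))
    changed = True
    while changed:
        changed = False
        cost_now = _mst_cost_from_d(d[np.ix_(keep, keep)])
        for node in keep:
            if node < n_sampled:
                continue
            trial = [k for k in keep if k != node]
            if _mst_cost_from_d(d[np.ix_(trial, trial)]) <= cost_now:
                keep = trial
                changed = True
                break

    d_final = d[np.ix_(keep, keep)]
    links = _msn_edges(d_final, epsilon)
    names = {}
    n_med = 0
    for pos, node in enumerate(keep):
        seq = mat[node].tobytes().decode()
        if node < n_sampled:
            name = f"H{node + 1}"
            attrs = {"sequence": seq, "is_median": False}
            if counts is not None:
                row = counts.iloc[node]
                attrs["frequency"] = int(row.sum())
                attrs["counts"] = row.to_dict()
            else:
                attrs["frequency"] = 1
            g.add_node(name, **attrs)
        else:
            n_med += 1
            name = f"mv{n_med}"
            g.add_node(name, sequence=seq, is_median=True, frequency=0)
        names[pos] = name
    for i, j, c in links:
        g.add_edge(names[i], names[j], mutations=c)
    return g


def total_cost(g: nx.Graph) -> int:
    """Summed mutation weight over all network edges."""
    return int(sum(w for _, _, w in g.edges(data="mutations")))


def spanning_cost(g: nx.Graph) -> int:
    """Cost of a minimum spanning tree of the network (connects all nodes)."""
    return int(
        sum(
            w
            for _, _, w in nx.minimum_spanning_tree(
                g, weight="mutations"
            ).edges(data="mutations")
        )
    )


def write_graphml(g: nx.Graph, path) -> None:
    """GraphML export (per-site count dicts flattened to strings)."""
    out = g.copy()
    for _, data in out.nodes(data=True):
        if "counts" in data:
            data["counts"] = ";".join(f"{k}:{v}" for k, v in data["counts"].items())
    nx.write_graphml(out, path)


def edge_list(g: nx.Graph) -> pd.DataFrame:
    rows = [
        {"node_a": a, "node_b": b, "mutations": int(w)}
        for a, b, w in g.edges(data="mutations")
    ]
    return pd.DataFrame(rows, columns=["node_a", "node_b", "mutations"])
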