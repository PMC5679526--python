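"""Network-motif detection in the mediated-loop graph.

Connected induced k-node subgraphs are enumerated exactly (ESU) or
estimated by weighted random descent of the enumeration tree; each
subgraph class is keyed by a canonical integer id (the minimum, over all
node permutations, of the row-major bit encoding of the adjacency
matrix). Significance is judged against a degree-preserving null
ensemble built by repeated two-edge switches: a motif is significant
when z >= 2, p <= 0.05 and its observed count is at least 5.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

Z_MIN = 2.0
P_MAX = 0.05
COUNT_MIN = 5


# ---------------------------------------------------------------------------
# canonical ids


def _encode(adj: np.ndarray) -> int:
    """Row-major integer encoding (first row = most significant bits)."""
    bits = adj.astype(int).ravel()
    out = 0
    for b in bits:
        out = (out << 1) | int(b)
    return out


_PERM_CACHE: dict[int, np.ndarray] = {}
_CANON_CACHE: dict[tuple[int, int], int] = {}


def _permutations(k: int) -> np.ndarray:
    if k not in _PERM_CACHE:
        _PERM_CACHE[k] = np.array(list(itertools.permutations(range(k))), dtype=np.intp)
    return _PERM_CACHE[k]


def canonical_id(adjacency: np.ndarray) -> int:
    """Canonical integer id of a directed simple graph's adjacency matrix.

    Minimum over all k! node permutations of the row-major bit encoding;
    a complete isomorphism invariant (two graphs get the same id iff they
    are isomorphic, since equal ids mean both permute to the same
    matrix).
    """
    adj = np.asarray(adjacency)
    if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
        raise ValueError("adjacency must be square")
    if np.diag(adj).any():
        raise ValueError("nonzero diagonal: self-loops are not allowed")
    k = adj.shape[0]
    raw = _encode(adj)
    key = (k, raw)
    cached = _CANON_CACHE.get(key)
    if cached is not None:
        return cached
    if k * k <= 62:
        perms = _permutations(k)
        permuted = adj[perms[:, :, None], perms[:, None, :]].reshape(len(perms), -1)
        powers = 1 << np.arange(k * k - 1, -1, -1, dtype=np.int64)
        best = int((permuted.astype(np.int64) @ powers).min())
    else:
        best = min(
            _encode(adj[np.ix_(p, p)]) for p in itertools.permutations(range(k))
        )
    _CANON_CACHE[key] = best
    return best


def decode_motif_id(motif_id: int, k: int) -> np.ndarray:
    """Inverse of the row-major encoding: id -> k x k binary adjacency."""
    if motif_id < 0 or motif_id >= 1 << (k * k):
        raise ValueError(f"motif id {motif_id} out of range for k={k}")
    bits = [(motif_id >> (k * k - 1 - i)) & 1 for i in range(k * k)]
    adj = np.array(bits, dtype=int).reshape(k, k)
    if np.diag(adj).any():
        raise ValueError(f"{motif_id} is not a simple-graph id (diagonal bit set)")
    return adj


# ---------------------------------------------------------------------------
# exact enumeration (ESU)


def _undirected_adjacency(g: nx.DiGraph) -> dict:
    und = {v: set() for v in g.nodes}
    for u, v in g.edges:
        und[u].add(v)
        und[v].add(u)
    return und


def _induced_adj(g: nx.DiGraph, nodes: list) -> np.ndarray:
    k = len(nodes)
    adj = np.zeros((k, k), dtype=int)
    for i, u in enumerate(nodes):
        for j, v in enumerate(nodes):
            if i != j and g.has_edge(u, v):
                adj[i, j] = 1
    return adj


def enumerate_subgraphs(g: nx.DiGraph, k: int) -> dict[int, int]:
    """Count every connected induced k-node subgraph, keyed by canonical id.

    Exact subgraph enumeration (ESU): each connected (ignoring edge
    direction) k-subset is visited exactly once. Returns an empty dict
    when the graph has fewer than k nodes.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    nodes = list(g.nodes)
    if k > len(nodes):
        return {}
    index = {v: i for i, v in enumerate(nodes)}
    und = _undirected_adjacency(g)
    counts: dict[int, int] = {}

    def extend(sub: list, extension: set, v_idx: int) -> None:
        if len(sub) == k:
            cid = canonical_id(_induced_adj(g, sub))
            counts[cid] = counts.get(cid, 0) + 1
            return
        ext = set(extension)
        neighborhood = set().union(*(und[w] for w in sub))
        while ext:
            w = ext.pop()
            new_ext = ext | {
                u
                for u in und[w]
                if index[u] > v_idx and u not in sub and u not in neighborhood
            }
            extend(sub + [w], new_ext, v_idx)

    for v in nodes:
        vi = index[v]
        ext = {u for u in und[v] if index[u] > vi}
        extend([v], ext, vi)
    return counts


def concentrations(counts: dict[int, int]) -> dict[int, float]:
    total = sum(counts.values())
    return {cid: c / total for cid, c in counts.items()} if total else {}


# ---------------------------------------------------------------------------
# sampled enumeration


def sample_subgraphs(
    g: nx.DiGraph, k: int, n_samples: int, seed: int = 0
) -> dict[int, float]:
    """Estimate subgraph-class concentrations by sampling the ESU tree.

    Each sample performs a random descent of the exact enumeration tree,
    choosing uniformly among the children at every level and weighting
    the reached leaf by the product of branching factors — an unbiased
    estimator of each class's count. Returned concentrations are
    normalised to sum to 1.
    """
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    if k < 3:
        raise ValueError("k must be >= 3")
    nodes = list(g.nodes)
    if k > len(nodes):
        return {}
    index = {v: i for i, v in enumerate(nodes)}
    und = _undirected_adjacency(g)
    rng = np.random.default_rng(seed)
    weights: dict[int, float] = {}

    for _ in range(n_samples):
        # root level: pick a starting vertex uniformly
        v = nodes[rng.integers(len(nodes))]
        weight = float(len(nodes))
        sub = [v]
        ext = sorted(u for u in und[v] if index[u] > index[v])
        dead = False
        while len(sub) < k:
            # children of this ESU node: one per extension vertex, where
            # child i removes the first i extension vertices before descending
            if not ext:
                dead = True
                break
            choice = int(rng.integers(len(ext)))
            weight *= len(ext)
            w = ext[choice]
            remaining = ext[choice + 1 :]
            neighborhood = set().union(*(und[s] for s in sub))
            new = [
                u
                for u in und[w]
                if index[u] > index[sub[0]] and u not in sub and u not in neighborhood
            ]
            sub.append(w)
            ext = sorted(set(remaining) | set(new))
        if dead:
            continue
        cid = canonical_id(_induced_adj(g, sub))
        weights[cid] = weights.get(cid, 0.0) + weight

    total = sum(weights.values())
    if total == 0:
        return {}
    return {cid: w / total for cid, w in sorted(weights.items())}


# ---------------------------------------------------------------------------
# null model


def randomize_graph(
    g: nx.DiGraph, switches_per_edge: int = 3, seed: int = 0
) -> nx.DiGraph:
    """Degree-preserving randomisation by two-edge switches.

    Repeatedly proposes (u->v, x->y) -> (u->y, x->v), rejecting proposals
    that would create self-loops or parallel edges. In- and out-degrees
    of every node (and node attributes) are preserved exactly.
    """
    out = g.copy()
    edges = list(out.edges)
    n_edges = len(edges)
    if n_edges < 2:
        return out
    rng = np.random.default_rng(seed)
    n_attempts = switches_per_edge * n_edges
    for _ in range(n_attempts):
        i, j = rng.integers(0, n_edges, size=2)
        if i == j:
            continue
        (u, v), (x, y) = edges[i], edges[j]
        if u == y or x == v:
            continue
        if out.has_edge(u, y) or out.has_edge(x, v):
            continue
        out.remove_edge(u, v)
        out.remove_edge(x, y)
        out.add_edge(u, y)
        out.add_edge(x, v)
        edges[i], edges[j] = (u, y), (x, v)
    return out


# ---------------------------------------------------------------------------
# significance


@dataclass
class MotifRecord:
    """One canonical subgraph class with its null-ensemble statistics."""

    motif_id: int
    k: int
    count: int
    concentration: float
    null_mean: float
    null_sd: float
    z: float
    p: float
    significant: bool


def motif_significance(
    g: nx.DiGraph,
    k: int,
    n_random: int = 1000,
    seed: int = 0,
    switches_per_edge: int = 3,
) -> list[MotifRecord]:
    """Score every observed k-node motif against a degree-preserving null.

    Real counts come from exact enumeration; the null ensemble is
    ``n_random`` edge-switch randomisations of the graph. z =
    (count - null_mean)/null_sd (undefined sd -> not significant); p is
    the add-one upper-tail estimate (1 + #{null >= observed})/(1 +
    n_random). Significance requires z >= 2, p <= 0.05 and count >= 5.
    """
    real = enumerate_subgraphs(g, k)
    conc = concentrations(real)
    rng = np.random.default_rng(seed)
    null_counts: dict[int, list[int]] = {cid: [] for cid in real}
    for _ in range(n_random):
        rg = randomize_graph(g, switches_per_edge, seed=int(rng.integers(2**31)))
        rc = enumerate_subgraphs(rg, k)
        for cid in null_counts:
            null_counts[cid].append(rc.get(cid, 0))

    records = []
    for cid in sorted(real):
        count = real[cid]
        nulls = np.asarray(null_counts[cid], dtype=float)
        mean, sd = float(nulls.mean()), float(nulls.std(ddof=1)) if len(nulls) > 1 else 0.0
        p = float((1 + np.sum(nulls >= count)) / (1 + n_random))
        if sd > 0:
            z = (count - mean) / sd
        else:
            z = float("nan")
            logger.info("motif %d: null sd = 0, z undefined", cid)
        significant = bool(
            np.isfinite(z) and z >= Z_MIN and p <= P_MAX and count >= COUNT_MIN
        )
        records.append(
            MotifRecord(
                motif_id=cid,
                k=k,
                count=count,
                concentration=conc[cid],
                null_mean=mean,
                null_sd=sd,
                z=float(z),
                p=p,
                significant=significant,
            )
        )
    return records


def motif_frame(records: list[MotifRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "motif_id": r.motif_id,
                "k": r.k,
                "count": r.count,
                "concentration": r.concentration,
                "null_mean": r.null_mean,
                "null_sd": r.null_sd,
                "z": r.z,
                "p": r.p,
                "significant": r.significant,
            }
            for r in records
        ]
    )


# ---------------------------------------------------------------------------
# motif composition


def _is_weakly_connected(adj: np.ndarray) -> bool:
    k = adj.shape[0]
    und = adj | adj.T
    seen = {0}
    stack = [0]
    while stack:
        u = stack.pop()
        for v in range(k):
            if und[u, v] and v not in seen:
                seen.add(v)
                stack.append(v)
    return len(seen) == k


def compose_motifs(m1: int, m2: int, k: int = 4) -> list[np.ndarray]:
    """All 6-node merges of two 4-node motifs overlapping on two nodes.

    Every ordered pair of nodes of the first motif is identified with
    every ordered pair of the second; a merge is kept only when the edge
    pattern between the two shared nodes agrees in both motifs and the
    merged (2k-2)-node graph is weakly connected. Results are
    de-duplicated up to isomorphism and returned in canonical form.
    """
    a1 = decode_motif_id(m1, k)
    a2 = decode_motif_id(m2, k)
    if canonical_id(a1) != m1 or canonical_id(a2) != m2:
        raise ValueError("motif ids must be canonical")
    n_out = 2 * k - 2
    seen: dict[int, np.ndarray] = {}
    pairs = [(i, j) for i in range(k) for j in range(k) if i != j]
    for (i, j) in pairs:
        for (p, q) in pairs:
            if (a2[p, q], a2[q, p]) != (a1[i, j], a1[j, i]):
                continue
            merged = np.zeros((n_out, n_out), dtype=int)
            merged[:k, :k] = a1
            # map motif-2 nodes: p->i, q->j, others -> k, k+1, ...
            mapping = {}
            nxt = k
            for node in range(k):
                if node == p:
                    mapping[node] = i
                elif node == q:
                    mapping[node] = j
                else:
                    mapping[node] = nxt
                    nxt += 1
            for u in range(k):
                for v in range(k):
                    if a2[u, v]:
                        merged[mapping[u], mapping[v]] = 1
            if not _is_weakly_connected(merged):
                continue
            cid = canonical_id(merged)
            if cid not in seen:
                seen[cid] = decode_motif_id(cid, n_out)
    return [seen[cid] for cid in sorted(seen)]


def render_adjacency(adj: np.ndarray) -> str:
    """ASCII rendering of a binary adjacency matrix for logs."""
    return "\n".join(" ".join(str(int(v)) for v in row) for row in adj)
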