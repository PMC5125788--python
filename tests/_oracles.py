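"""Independent oracles used by the test suite.

Everything here is deliberately naive — exhaustive enumeration and brute
force — and shares no code with the package implementation it checks.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

import numpy as np


# ---------------------------------------------------------------------------
# tree topologies: enumeration, bipartitions, least-squares fit

def _bipartitions_of_edges(edges, tips):
    """All non-trivial bipartitions of an edge-list tree (frozensets
    canonicalised to the side without the smallest tip)."""
    anchor = min(tips)
    adj = {}
    for u, v in edges:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
    out = set()
    for cut in edges:
        side = _component(adj, cut[0], cut) & tips
        if 1 < len(side) < len(tips) - 1:
            out.add(side if anchor not in side else tips - side)
    return out


def _component(adj, start, removed_edge):
    seen = {start}
    stack = [start]
    banned = {frozenset(removed_edge)}
    while stack:
        u = stack.pop()
        for v in adj[u]:
            if frozenset((u, v)) in banned or v in seen:
                continue
            seen.add(v)
            stack.append(v)
    return frozenset(x for x in seen if isinstance(x, str))


@lru_cache(maxsize=None)
def enumerate_topologies(labels: tuple):
    """Every unrooted binary topology on ``labels``, as edge-list tuples.

    Built by sequential insertion: each new tip subdivides every existing
    edge. 3 tips -> 1 topology, 4 -> 3, 5 -> 15, 6 -> 105.
    """
    labels = list(labels)
    assert len(labels) >= 3
    first = tuple((lab, 0) for lab in labels[:3])  # ints are internal nodes
    trees = [first]
    next_internal = 1
    for lab in labels[3:]:
        grown = []
        for edges in trees:
            for k, (u, v) in enumerate(edges):
                new = next_internal
                rest = edges[:k] + edges[k + 1:]
                grown.append(rest + ((u, new), (new, v), (lab, new)))
        trees = grown
        next_internal += 1
    return tuple(trees)


def topology_bipartitions(edges, labels):
    return _bipartitions_of_edges(edges, frozenset(labels))


def _path_edges(adj, a, b):
    """Edge indices on the tip-to-tip path (DFS on a tree)."""
    stack = [(a, None, [])]
    while stack:
        node, prev, path = stack.pop()
        if node == b:
            return path
        for idx, v in adj[node]:
            if v != prev:
                stack.append((v, node, path + [idx]))
    raise AssertionError("disconnected tree")


def least_squares_topology(matrix: np.ndarray, labels):
    """Best-fitting topology by exhaustive least squares.

    Fits branch lengths of every topology to the distance matrix with
    ordinary least squares over the path-incidence design matrix, and
    returns the bipartition set of the minimum-residual topology.
    """
    labels = list(labels)
    pairs = list(itertools.combinations(range(len(labels)), 2))
    d = np.array([matrix[i, j] for i, j in pairs])
    best = (np.inf, None)
    for edges in enumerate_topologies(tuple(labels)):
        adj = {}
        for idx, (u, v) in enumerate(edges):
            adj.setdefault(u, []).append((idx, v))
            adj.setdefault(v, []).append((idx, u))
        A = np.zeros((len(pairs), len(edges)))
        for row, (i, j) in enumerate(pairs):
            for idx in _path_edges(adj, labels[i], labels[j]):
                A[row, idx] = 1.0
        x, *_ = np.linalg.lstsq(A, d, rcond=None)
        resid = float(((A @ x - d) ** 2).sum())
        if resid < best[0]:
            best = (resid, topology_bipartitions(edges, labels))
    return best[1]


def random_additive_matrix(rng: np.random.Generator, n_taxa: int):
    """A random additive matrix plus its generating bipartitions.

    Random topology by sequential attachment, branch lengths uniform on
    [0.01, 0.2]; distances are path sums (exactly additive).
    """
    labels = [f"T{i}" for i in range(n_taxa)]
    topologies = enumerate_topologies(tuple(labels))
    edges = topologies[rng.integers(len(topologies))]
    lengths = rng.uniform(0.01, 0.2, size=len(edges))
    adj = {}
    for idx, (u, v) in enumerate(edges):
        adj.setdefault(u, []).append((idx, v))
        adj.setdefault(v, []).append((idx, u))
    mat = np.zeros((n_taxa, n_taxa))
    for i, j in itertools.combinations(range(n_taxa), 2):
        path = _path_edges(adj, labels[i], labels[j])
        mat[i, j] = mat[j, i] = lengths[path].sum()
    return mat, labels, topology_bipartitions(edges, labels)


# ---------------------------------------------------------------------------
# stop codons: brute-force frame scan

MITO_STOPS = {"TAA", "TAG", "AGA", "AGG"}


def brute_force_stop_counts(seq: str) -> dict[int, int]:
    """Stops per frame, scanning trigrams directly; the final in-frame
    codon (complete or partial) is skipped."""
    seq = seq.upper()
    out = {}
    for f in (0, 1, 2):
        starts = [s for s in range(f, len(seq) - 2, 3)]
        if starts and starts[-1] + 3 == len(seq):
            starts = starts[:-1]
        out[f] = sum(seq[s:s + 3] in MITO_STOPS for s in starts)
    return out


# ---------------------------------------------------------------------------
# alignment: exhaustive global alignment on short strings

def brute_force_alignment(a: str, b: str, match=1.0, mismatch=-1.0,
                          gap_open=-5.0, gap_extend=-2.0):
    """Maximum score over all global alignments with free end gaps.

    Enumerates alignments recursively (feasible for short strings). A
    length-k *internal* gap run costs ``gap_open + (k - 1) * gap_extend``;
    terminal gap runs are free. Returns (best score, number of columns of
    one best alignment).
    """
    best = {"score": -np.inf, "cols": None}

    def rec(i, j, score, cols, gap_state):
        # gap_state: None, 'a' (gap in a), or 'b'; runs priced on entry
        if i == len(a) and j == len(b):
            if score > best["score"]:
                best["score"], best["cols"] = score, cols
            return
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else mismatch
            rec(i + 1, j + 1, score + s, cols + 1, None)
        if j < len(b):  # gap in a
            free = i == 0 or i == len(a)  # terminal run
            cost = 0.0 if free else (gap_extend if gap_state == "a" else gap_open)
            rec(i, j + 1, score + cost, cols + 1, "a")
        if i < len(a):  # gap in b
            free = j == 0 or j == len(b)
            cost = 0.0 if free else (gap_extend if gap_state == "b" else gap_open)
            rec(i + 1, j, score + cost, cols + 1, "b")

    rec(0, 0, 0.0, 0, None)
    return best["score"], best["cols"]
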