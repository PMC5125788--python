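"""Neighbour-joining trees, bootstrap supports and monophyly queries.

The Saitou-Nei neighbour-joining algorithm is implemented directly (with
the standard Q-criterion) so that its conventions are explicit and
reproducible:

* deterministic tie-breaking — when several pairs minimise Q, the pair
  whose cluster labels (each cluster labelled by its lexicographically
  smallest tip) sort lowest is joined;
* negative branch-length handling after Kuhner & Felsenstein — a negative
  limb is clamped to zero and the deficit moved to its sibling so the
  joined pair's distance is preserved;
* the result is unrooted, represented as a scikit-bio ``TreeNode`` with a
  trifurcating root.

Bootstrap supports are column-resampling supports: alignment columns are
resampled with replacement, the p-distance matrix (same pairwise-deletion
rule as the original) and NJ tree are recomputed per replicate, and each
internal edge of the original tree is annotated with the percentage of
replicate trees containing the same bipartition.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
from skbio import DistanceMatrix
from skbio.tree import TreeNode

from .records import BarcodeRecord
from .distances import _encode, p_distance_matrix_from_alignment


class TreeError(ValueError):
    pass


# ---------------------------------------------------------------------------
# neighbour joining

def neighbor_joining(matrix: DistanceMatrix) -> TreeNode:
    """Unrooted NJ tree from a distance matrix.

    Requires at least three taxa and fully defined distances. Branch
    lengths are clamped to be non-negative (see module docstring).
    """
    ids = list(matrix.ids)
    n = len(ids)
    if n < 3:
        raise TreeError(f"neighbour joining needs >= 3 taxa, got {n}")
    D = matrix.data.astype(float).copy()
    if np.isnan(D).any():
        raise TreeError("distance matrix contains undefined entries")

    nodes = [TreeNode(name=i) for i in ids]
    labels = list(ids)  # cluster label = smallest tip name in the cluster

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        cand = np.argwhere(Q <= qmin + 1e-12)
        pairs = sorted(
            (tuple(sorted((labels[i], labels[j]))), (i, j))
            for i, j in cand if i < j
        )
        i, j = pairs[0][1]

        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = D[i, j] - li
        li, lj = _clamp_pair(li, lj)
        parent = TreeNode()
        a, b = nodes[i], nodes[j]
        a.length, b.length = li, lj
        parent.extend([a, b])

        d_new = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        D2 = np.empty((len(keep) + 1, len(keep) + 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = D2[:-1, -1] = d_new[keep]
        D2[-1, -1] = 0.0
        D = D2
        new_label = min(labels[i], labels[j])
        nodes = [nodes[k] for k in keep] + [parent]
        labels = [labels[k] for k in keep] + [new_label]

    # final trifurcation
    (a, b, c) = nodes
    la = max(0.0, 0.5 * (D[0, 1] + D[0, 2] - D[1, 2]))
    lb = max(0.0, 0.5 * (D[0, 1] + D[1, 2] - D[0, 2]))
    lc = max(0.0, 0.5 * (D[0, 2] + D[1, 2] - D[0, 1]))
    a.length, b.length, c.length = la, lb, lc
    root = TreeNode()
    root.extend([a, b, c])
    return root


def _clamp_pair(li: float, lj: float) -> tuple[float, float]:
    if li < 0:
        lj = max(0.0, lj + li)
        li = 0.0
    if lj < 0:
        li = max(0.0, li + lj)
        lj = 0.0
    return li, lj


# ---------------------------------------------------------------------------
# bipartitions and monophyly

def _tip_names(tree: TreeNode) -> frozenset:
    return frozenset(t.name for t in tree.tips())


def _canonical(side: frozenset, all_tips: frozenset, anchor) -> frozenset:
    return side if anchor not in side else all_tips - side


def bipartitions(tree: TreeNode) -> dict[frozenset, TreeNode]:
    """Internal-edge bipartitions, canonicalised to the side not holding
    the lexicographically smallest tip. Maps bipartition -> child node."""
    all_tips = _tip_names(tree)
    anchor = min(all_tips)
    out: dict[frozenset, TreeNode] = {}
    for node in tree.non_tips():
        if node is tree:
            continue
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(all_tips) - 1:
            out[_canonical(side, all_tips, anchor)] = node
    return out


def is_monophyletic(tree: TreeNode, tips: Iterable[str]) -> bool:
    """True when some edge separates exactly ``tips`` from the rest.

    On a rooted tree (bifurcating root) this is clade membership; on an
    unrooted tree either side of an edge counts.
    """
    target = frozenset(tips)
    all_tips = _tip_names(tree)
    unknown = target - all_tips
    if unknown:
        raise TreeError(f"tips not in tree: {sorted(unknown)!r}")
    if not target:
        raise TreeError("empty tip set")
    if target == all_tips or len(target) == 1:
        return True
    rooted = len(tree.children) == 2
    for node in tree.traverse(include_self=False):
        side = frozenset(t.name for t in node.tips()) if not _is_tip(node) \
            else frozenset([node.name])
        if side == target:
            return True
        if not rooted and all_tips - side == target:
            return True
    return False


def _is_tip(node: TreeNode) -> bool:
    return len(node.children) == 0


# ---------------------------------------------------------------------------
# bootstrap

def bootstrap_support(
    records: Sequence[BarcodeRecord],
    n_reps: int = 1000,
    seed: int = 0,
) -> TreeNode:
    """NJ tree with column-resampling bootstrap supports.

    ``records`` must form one alignment (equal lengths). The returned
    tree is the NJ tree of the full alignment; every internal edge
    carries ``node.support`` (percent of replicates containing its
    bipartition, also set as the node name for Newick output).
    """
    if n_reps < 1:
        raise TreeError("n_reps must be >= 1")
    if len(records) < 3:
        raise TreeError("bootstrap needs >= 3 sequences")
    ids = [r.id for r in records]
    encoded = _encode([r.sequence for r in records])
    rng = np.random.default_rng(seed)
    n_cols = encoded.shape[1]

    tree = neighbor_joining(p_distance_matrix_from_alignment(encoded, ids))
    edges = bipartitions(tree)
    counts = {bp: 0 for bp in edges}
    for _ in range(n_reps):
        cols = rng.integers(0, n_cols, size=n_cols)
        rep_dm = p_distance_matrix_from_alignment(encoded[:, cols], ids)
        rep_tree = neighbor_joining(rep_dm)
        for bp in bipartitions(rep_tree):
            if bp in counts:
                counts[bp] += 1
    for bp, node in edges.items():
        support = 100.0 * counts[bp] / n_reps
        node.support = support
        node.name = str(int(round(support)))
    return tree


def annotate_supports(tree: TreeNode, supports: dict[frozenset, float]) -> None:
    """Attach supports (bipartition -> percent) to a tree's internal edges."""
    all_tips = _tip_names(tree)
    anchor = min(all_tips)
    for node in tree.non_tips():
        if node is tree:
            continue
        side = frozenset(t.name for t in node.tips())
        if not (1 < len(side) < len(all_tips) - 1):
            continue
        bp = _canonical(side, all_tips, anchor)
        if bp in supports:
            node.support = supports[bp]
            node.name = str(int(round(supports[bp])))


def collect_supports(tree: TreeNode) -> dict[frozenset, float]:
    out = {}
    for bp, node in bipartitions(tree).items():
        support = getattr(node, "support", None)
        if support is None and node.name is not None:
            try:
                support = float(node.name)
            except ValueError:
                support = None
        if support is not None:
            out[bp] = float(support)
    return out


# ---------------------------------------------------------------------------
# rooting

def root_on_outgroup(tree: TreeNode, outgroup_tip: str) -> TreeNode:
    """Root the tree at the midpoint of the outgroup's pendant edge.

    Bipartition supports are preserved: they are collected before rooting
    and re-attached by bipartition matching afterwards, so each support
    stays on the edge it was computed for.
    """
    try:
        tip = tree.find(outgroup_tip)
    except Exception as exc:
        raise TreeError(f"outgroup tip {outgroup_tip!r} not in tree") from exc
    if not _is_tip(tip):
        raise TreeError(f"outgroup {outgroup_tip!r} is not a tip")
    supports = collect_supports(tree)
    rooted = tree.root_at(tip, above=True, reset=True)  # midpoint of edge
    for node in rooted.non_tips(include_self=True):
        node.name = None
        if hasattr(node, "support"):
            node.support = None
    annotate_supports(rooted, supports)
    return rooted


# ---------------------------------------------------------------------------
# Newick I/O

def write_newick(tree: TreeNode, path=None) -> str:
    """Serialize with branch lengths to six decimals and integer supports
    as internal-node labels. Returns the Newick string; optionally writes
    it to ``path``."""
    def fmt(node: TreeNode) -> str:
        if _is_tip(node):
            body = node.name or ""
        else:
            inner = ",".join(fmt(c) for c in node.children)
            body = f"({inner}){node.name or ''}"
        if node.length is not None:
            body += f":{node.length:.6f}"
        return body

    text = fmt(tree) + ";\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def read_newick(source) -> TreeNode:
    """Read a Newick tree (path or string); internal labels that parse as
    numbers become ``node.support``."""
    if isinstance(source, str) and "(" in source:
        tree = TreeNode.read([source])
    else:
        tree = TreeNode.read(str(source))
    for node in tree.non_tips(include_self=True):
        if node.name is not None:
            try:
                node.support = float(node.name)
            except ValueError:
                pass
    return tree
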