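"""Distance-based tree inference and labeled-topology combinatorics.

Implements the agglomerative neighbor-joining family used to build the
total-evidence and per-gene trees:

* :func:`neighbor_joining` -- classical NJ (Saitou & Nei): at each step join
  the pair minimizing ``Q(i,j) = (r-2) d(i,j) - sum_k d(i,k) - sum_k d(j,k)``.
* :func:`bionj` -- the variance-weighted variant: same pair selection, but the
  reduction mixes the two joined rows with a weight ``lambda`` chosen to
  minimize the variance of the new distances, tracked in a companion variance
  matrix initialized to the distances themselves.

Both are consistent: on exactly tree-additive matrices they recover the
generating topology.  Ties in the Q criterion are broken by the smallest
``(row, column)`` index pair under the current ordering, and negative branch
lengths are clamped to zero after the fact (the clamped total is logged), so
results are deterministic across runs and platforms.

Also here: uniform random labeled topologies (the "OUT" null-control tree),
the double-factorial counts of binary labeled topologies, and an exhaustive
enumerator used as an independent check of those counts at small sizes.
"""

from __future__ import annotations

import logging
from typing import Iterable

import numpy as np

from .treeio import DistanceMatrix, PhyloTree

__all__ = [
    "neighbor_joining",
    "bionj",
    "random_topology",
    "count_topologies",
    "enumerate_topologies",
]

logger = logging.getLogger(__name__)

#: Variance matrices share the DistanceMatrix container (same labels/shape).
VarianceMatrix = DistanceMatrix


def _check_input(D: DistanceMatrix) -> None:
    if D.n < 3:
        raise ValueError(f"need at least 3 taxa, got {D.n}")
    if not np.all(np.isfinite(D.values)):
        raise ValueError("distance matrix contains non-finite entries")


def _argmin_q(Q: np.ndarray) -> tuple[int, int]:
    """First (row-major) minimum over the strict upper triangle."""
    r = Q.shape[0]
    mask = np.triu(np.ones_like(Q, dtype=bool), k=1)
    Qm = np.where(mask, Q, np.inf)
    flat = int(np.argmin(Qm))
    return divmod(flat, r)


def _nj_core(D: DistanceMatrix, use_bionj: bool) -> PhyloTree:
    _check_input(D)
    labels = list(D.labels)
    d = D.values.astype(float).copy()
    v = d.copy() if use_bionj else None

    adj: dict[int, dict[int, float | None]] = {i: {} for i in range(len(labels))}
    tips = {i: lbl for i, lbl in enumerate(labels)}
    nodes = list(range(len(labels)))  # tree-node id of each active row
    next_id = len(labels)

    while len(nodes) > 3:
        r = len(nodes)
        S = d.sum(axis=1)
        Q = (r - 2) * d - S[:, None] - S[None, :]
        i, j = _argmin_q(Q)

        dij = d[i, j]
        bi = 0.5 * dij + (S[i] - S[j]) / (2 * (r - 2))
        bj = dij - bi

        if use_bionj:
            vij = v[i, j]
            if vij <= 0:
                lam = 0.5
            else:
                # sum over active k != i,j of (v[j,k] - v[i,k]); the i/j terms
                # cancel in the row-sum difference (symmetric, zero diagonal)
                lam = 0.5 + (v[j].sum() - v[i].sum()) / (2 * (r - 2) * vij)
                lam = min(1.0, max(0.0, lam))
        else:
            lam = 0.5

        du = lam * d[i] + (1 - lam) * d[j] - lam * bi - (1 - lam) * bj
        if use_bionj:
            vu = lam * v[i] + (1 - lam) * v[j] - lam * (1 - lam) * vij

        u = next_id
        next_id += 1
        adj[u] = {}
        for row, b in ((i, bi), (j, bj)):
            node = nodes[row]
            adj[u][node] = b
            adj[node][u] = b

        keep = [k for k in range(r) if k not in (i, j)]
        d = d[np.ix_(keep, keep)]
        du = du[keep]
        d = np.vstack([d, du[None, :]])
        d = np.hstack([d, np.append(du, 0.0)[:, None]])
        if use_bionj:
            v = v[np.ix_(keep, keep)]
            vu = vu[keep]
            v = np.vstack([v, vu[None, :]])
            v = np.hstack([v, np.append(vu, 0.0)[:, None]])
        nodes = [nodes[k] for k in keep] + [u]

    # final three-way join: branch lengths are determined analytically
    a, b, c = nodes
    dab, dac, dbc = d[0, 1], d[0, 2], d[1, 2]
    center = next_id
    adj[center] = {}
    for node, ln in (
        (a, 0.5 * (dab + dac - dbc)),
        (b, 0.5 * (dab + dbc - dac)),
        (c, 0.5 * (dac + dbc - dab)),
    ):
        adj[center][node] = ln
        adj[node][center] = ln

    # clamp negative branch lengths to zero, logging the total deficit
    deficit = 0.0
    for u, nbrs in adj.items():
        for w, ln in nbrs.items():
            if ln is not None and ln < 0:
                deficit += -ln
                nbrs[w] = 0.0
    if deficit > 0:
        logger.info(
            "%s: clamped negative branch lengths (total deficit %.6g)",
            "bionj" if use_bionj else "neighbor_joining",
            deficit / 2,  # each edge counted from both endpoints
        )
    return PhyloTree(adj, tips, root=center, rooted=False)


def neighbor_joining(D: DistanceMatrix) -> PhyloTree:
    """Classical neighbor-joining tree from a distance matrix."""
    return _nj_core(D, use_bionj=False)


def bionj(D: DistanceMatrix) -> PhyloTree:
    """Variance-weighted neighbor-joining (BIONJ) tree from a distance matrix.

    The variance matrix is initialized to the distance matrix; each
    agglomeration uses the weight

    ``lambda = 1/2 + sum_k (v(j,k) - v(i,k)) / (2 (r-2) v(i,j))``

    clamped to ``[0, 1]`` (``lambda = 1/2`` when ``v(i,j) = 0`` or only three
    taxa remain), with reduction formulas

    ``d(u,k) = lam d(i,k) + (1-lam) d(j,k) - lam b_i - (1-lam) b_j``
    ``v(u,k) = lam v(i,k) + (1-lam) v(j,k) - lam (1-lam) v(i,j)``.
    """
    return _nj_core(D, use_bionj=True)


# --------------------------------------------------------------------------
# Random topologies and topology counting
# --------------------------------------------------------------------------


def random_topology(labels: Iterable[str], seed, branch_length=1.0) -> PhyloTree:
    """Uniform random binary unrooted labeled topology.

    Tips are inserted in a random order, each onto a uniformly chosen existing
    edge, which yields the uniform distribution over all ``(2m-5)!!`` labeled
    topologies.  ``branch_length`` is either a constant or a callable
    ``f(rng) -> float`` sampled independently per edge.  ``seed`` may be an
    int, a :class:`numpy.random.SeedSequence`, or a Generator.
    """
    labels = sorted(set(labels))
    if len(labels) < 3:
        raise ValueError(f"need at least 3 labels, got {len(labels)}")
    rng = np.random.default_rng(seed)
    draw = branch_length if callable(branch_length) else (lambda _rng: branch_length)

    order = [labels[k] for k in rng.permutation(len(labels))]
    adj: dict[int, dict[int, float | None]] = {}
    tips: dict[int, str] = {}
    next_id = [0]

    def new_node(label=None):
        nid = next_id[0]
        next_id[0] += 1
        adj[nid] = {}
        if label is not None:
            tips[nid] = label
        return nid

    def connect(u, w):
        ln = float(draw(rng))
        adj[u][w] = ln
        adj[w][u] = ln

    center = new_node()
    edges: list[tuple[int, int]] = []
    for lbl in order[:3]:
        t = new_node(lbl)
        connect(center, t)
        edges.append((center, t))
    for lbl in order[3:]:
        u, w = edges[int(rng.integers(len(edges)))]
        mid = new_node()
        ln_uw = adj[u].pop(w)
        adj[w].pop(u)
        # split the old edge at a new node, keeping deterministic length draws
        adj[u][mid] = ln_uw
        adj[mid][u] = ln_uw
        connect(mid, w)
        t = new_node(lbl)
        connect(mid, t)
        edges.remove((u, w))
        edges.extend([(u, mid), (mid, w), (mid, t)])
    return PhyloTree(adj, tips, root=center, rooted=False)


def count_topologies(m: int, rooted: bool = False) -> int:
    """Number of distinct binary labeled tree topologies on ``m`` tips.

    ``(2m-5)!!`` unrooted or ``(2m-3)!!`` rooted, in exact integer
    arithmetic.  For four tips: 3 unrooted, 15 rooted; for six: 105 and 945.
    """
    if m < 3:
        raise ValueError(f"need m >= 3, got {m}")
    out = 1
    stop = 2 * m - 3 if rooted else 2 * m - 5
    for k in range(3, stop + 1, 2):
        out *= k
    return out


def _unrooted_keys(labels: list[str]) -> set:
    """All unrooted binary topologies on ``labels`` by exhaustive tip
    insertion, deduplicated by canonical bipartition-set keys."""

    def splits_key(edge_list):
        adjacency: dict = {}
        for u, w in edge_list:
            adjacency.setdefault(u, set()).add(w)
            adjacency.setdefault(w, set()).add(u)
        all_tips = frozenset(l for l in labels)
        key = set()
        for u, w in edge_list:
            # tip set on w's side of the edge
            seen = {u, w}
            work = [w]
            side = set()
            while work:
                x = work.pop()
                if isinstance(x, str):
                    side.add(x)
                for y in adjacency[x]:
                    if y not in seen:
                        seen.add(y)
                        work.append(y)
            side = frozenset(side)
            key.add(frozenset((side, all_tips - side)))
        return frozenset(key)

    # internal nodes are ints, tips are their label strings
    results: set = set()
    first = [(0, labels[0]), (0, labels[1]), (0, labels[2])]
    stack = [(first, 3, 1)]
    while stack:
        edges, k, nid = stack.pop()
        if k == len(labels):
            results.add(splits_key(edges))
            continue
        lbl = labels[k]
        for e in range(len(edges)):
            u, w = edges[e]
            new_edges = edges[:e] + edges[e + 1 :] + [(u, nid), (nid, w), (nid, lbl)]
            stack.append((new_edges, k + 1, nid + 1))
    return results


def _rooted_keys(labels: list[str]) -> set:
    """All rooted binary topologies by exhaustive insertion (including above
    the root), deduplicated by canonical clade-set keys."""

    def inserted(tree, leaf):
        yield (tree, leaf)
        if isinstance(tree, tuple):
            l, r = tree
            for nl in inserted(l, leaf):
                yield (nl, r)
            for nr in inserted(r, leaf):
                yield (l, nr)

    def clades(tree, acc):
        if isinstance(tree, tuple):
            left = clades(tree[0], acc)
            right = clades(tree[1], acc)
            here = left | right
        else:
            here = frozenset((tree,))
        acc.add(here)
        return here

    trees = [labels[0]]
    for lbl in labels[1:]:
        trees = [t for old in trees for t in inserted(old, lbl)]
    results = set()
    for t in trees:
        acc: set = set()
        clades(t, acc)
        results.add(frozenset(acc))
    return results


def enumerate_topologies(labels: Iterable[str], rooted: bool = False) -> set:
    """Exhaustively enumerate distinct binary labeled topologies on ``labels``.

    Returns the set of canonical topology keys (bipartition sets for unrooted
    trees, clade sets for rooted ones); its size is the topology count.  Only
    practical for small label sets (say m <= 8); serves as a brute-force
    cross-check of :func:`count_topologies`.
    """
    labels = sorted(set(labels))
    if len(labels) < 3:
        raise ValueError(f"need at least 3 labels, got {len(labels)}")
    return _rooted_keys(labels) if rooted else _unrooted_keys(labels)
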