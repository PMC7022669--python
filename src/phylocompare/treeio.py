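"""Phylogenetic trees: Newick I/O, bipartitions, pruning, patristic distances.

The central object is :class:`PhyloTree`, an undirected labeled tree stored as
an adjacency map with optional non-negative branch lengths.  Topology
comparisons in this package operate on *unrooted* trees; a bifurcating Newick
root is remembered (``rooted=True``) but ignored wherever bipartitions are
compared, so that the maximum Robinson-Foulds distance between binary trees on
``m`` tips is ``2m - 6``.

Conventions
-----------
* Tip labels are unique, non-empty strings and must match the sample names of
  any companion variant table exactly.
* Internal-node labels in Newick input are parsed and discarded: they carry no
  topological information.
* Degree-two internal nodes are suppressed on construction (their two incident
  branch lengths are summed); a bifurcating root of a rooted tree is kept.
* Polytomies are legal everywhere; they simply contribute fewer bipartitions.
"""

from __future__ import annotations

import dataclasses
import re
from typing import Callable, Iterable, Iterator, Mapping

import numpy as np

__all__ = [
    "NewickError",
    "Bipartition",
    "PhyloTree",
    "DistanceMatrix",
    "parse_newick",
    "write_newick",
    "read_trees",
]


class NewickError(ValueError):
    """Malformed Newick input; ``position`` is the 0-based offending index."""

    def __init__(self, message: str, position: int | None = None):
        if position is not None:
            message = f"{message} (at character {position})"
        super().__init__(message)
        self.position = position


@dataclasses.dataclass(frozen=True)
class Bipartition:
    """A two-way split of a tip-label set induced by one tree edge.

    Canonical orientation: ``side_a`` is the side containing the
    lexicographically smallest label of the full tip set, which makes equal
    splits compare equal regardless of how they were produced.
    """

    side_a: frozenset
    side_b: frozenset

    @classmethod
    def of(cls, side: Iterable[str], all_tips: Iterable[str]) -> "Bipartition":
        side = frozenset(side)
        all_tips = frozenset(all_tips)
        other = all_tips - side
        if not side or not other or not side <= all_tips:
            raise ValueError("bipartition sides must be a proper non-empty split of the tip set")
        if min(all_tips) in side:
            return cls(side, other)
        return cls(other, side)

    @property
    def tips(self) -> frozenset:
        return self.side_a | self.side_b

    @property
    def is_trivial(self) -> bool:
        return min(len(self.side_a), len(self.side_b)) <= 1

    def __str__(self) -> str:  # pragma: no cover - debugging aid
        return ",".join(sorted(self.side_a)) + "|" + ",".join(sorted(self.side_b))


# --------------------------------------------------------------------------
# Newick parsing
# --------------------------------------------------------------------------

_UNQUOTED_STOP = set("():,;[]'\t\n\r ")
_NEEDS_QUOTE = re.compile(r"[():,;\[\]'\s]")


def _skip_ws(text: str, i: int) -> int:
    n = len(text)
    while i < n and text[i].isspace():
        i += 1
    return i


def _parse_label(text: str, i: int) -> tuple[str, int]:
    n = len(text)
    if i < n and text[i] == "'":
        j = i + 1
        out = []
        while True:
            if j >= n:
                raise NewickError("unterminated quoted label", i)
            c = text[j]
            if c == "'":
                if j + 1 < n and text[j + 1] == "'":
                    out.append("'")
                    j += 2
                    continue
                return "".join(out), j + 1
            out.append(c)
            j += 1
    j = i
    while j < n and text[j] not in _UNQUOTED_STOP:
        j += 1
    return text[i:j], j


_FLOAT_RE = re.compile(r"[+-]?(\d+\.?\d*|\.\d+)([eE][+-]?\d+)?")


def _parse_length(text: str, i: int) -> tuple[float | None, int]:
    i = _skip_ws(text, i)
    if i >= len(text) or text[i] != ":":
        return None, i
    i = _skip_ws(text, i + 1)
    m = _FLOAT_RE.match(text, i)
    if not m:
        raise NewickError("invalid branch length", i)
    return float(m.group(0)), m.end()


def parse_newick(text: str) -> "PhyloTree":
    """Parse one Newick string (terminated by ``;``) into a :class:`PhyloTree`.

    Branch lengths are optional, quoted labels (``'...'`` with ``''`` escapes)
    are supported, internal-node labels are discarded.  Raises
    :class:`NewickError` naming the character position for malformed input
    (unbalanced parentheses, duplicate or empty tip labels, bad lengths).
    """
    # node = (children | None, label, length, pos)
    i = _skip_ws(text, 0)
    if i >= len(text):
        raise NewickError("empty input", 0)
    stack: list[list] = []
    root = None
    while root is None:
        i = _skip_ws(text, i)
        if i < len(text) and text[i] == "(":
            stack.append([])
            i = _skip_ws(text, i + 1)
            continue
        pos = i
        label, i = _parse_label(text, i)
        if not label:
            raise NewickError("empty tip label", pos)
        length, i = _parse_length(text, i)
        node = (None, label, length, pos)
        while True:
            i = _skip_ws(text, i)
            if stack:
                if i >= len(text):
                    raise NewickError("unbalanced parentheses", i)
                c = text[i]
                if c == ",":
                    stack[-1].append(node)
                    i += 1
                    break  # parse next subtree
                if c == ")":
                    stack[-1].append(node)
                    children = stack.pop()
                    pos = i
                    i = _skip_ws(text, i + 1)
                    _ilabel, i = _parse_label(text, i)  # internal label: discarded
                    length, i = _parse_length(text, i)
                    node = (children, None, length, pos)
                    continue
                raise NewickError(f"unexpected character {c!r}", i)
            if i >= len(text) or text[i] != ";":
                raise NewickError("expected ';'", min(i, len(text)))
            i += 1
            root = node
            break
    tail = _skip_ws(text, i)
    if tail < len(text):
        raise NewickError("trailing characters after ';'", tail)

    # flatten the nested node tuples into an adjacency map
    adj: dict[int, dict[int, float | None]] = {}
    tip_labels: dict[int, str] = {}
    seen: dict[str, int] = {}
    counter = [0]

    def new_node() -> int:
        counter[0] += 1
        return counter[0] - 1

    root_id = new_node()
    adj[root_id] = {}
    work = [(root, root_id)]
    while work:
        (children, label, _length, pos), nid = work.pop()
        if children is None:
            if label in seen:
                raise NewickError(f"duplicate tip label {label!r}", pos)
            seen[label] = nid
            tip_labels[nid] = label
            continue
        for child in reversed(children):
            cid = new_node()
            adj[cid] = {}
            adj[nid][cid] = child[2]
            adj[cid][nid] = child[2]
            work.append((child, cid))
    rooted = root[0] is not None and len(root[0]) == 2
    return PhyloTree(adj, tip_labels, root=root_id, rooted=rooted)


def _format_length(x: float) -> str:
    s = format(x, ".12g")
    return s


def _quote_label(label: str) -> str:
    if _NEEDS_QUOTE.search(label):
        return "'" + label.replace("'", "''") + "'"
    return label


# --------------------------------------------------------------------------
# The tree
# --------------------------------------------------------------------------


class PhyloTree:
    """Labeled (optionally branch-length-annotated) phylogenetic tree.

    Parameters
    ----------
    adjacency
        ``{node: {neighbor: length_or_None}}``; must describe a connected
        acyclic graph.  Node keys may be arbitrary hashables; they are
        relabeled to consecutive integers internally.
    tip_labels
        ``{node: label}`` for the leaves.  Labels must be unique, non-empty
        strings.
    root
        Traversal anchor; for ``rooted=True`` trees a bifurcating root is
        preserved, otherwise degree-two nodes (including the root) are
        suppressed.
    """

    __slots__ = ("_adj", "_tips", "_root", "rooted")

    def __init__(
        self,
        adjacency: Mapping,
        tip_labels: Mapping,
        root=None,
        rooted: bool = False,
        normalize: bool = True,
    ):
        # relabel nodes to consecutive ints in first-appearance order
        ids: dict = {}
        for u in adjacency:
            ids.setdefault(u, len(ids))
        adj: dict[int, dict[int, float | None]] = {ids[u]: {} for u in adjacency}
        for u, nbrs in adjacency.items():
            for v, ln in nbrs.items():
                if v not in ids:
                    raise ValueError(f"edge endpoint {v!r} missing from adjacency")
                if ln is not None:
                    ln = float(ln)
                    if not np.isfinite(ln) or ln < 0:
                        raise ValueError(f"branch length must be finite and >= 0, got {ln}")
                adj[ids[u]][ids[v]] = ln
        tips: dict[int, str] = {}
        for u, label in tip_labels.items():
            if not isinstance(label, str) or not label:
                raise ValueError(f"tip labels must be non-empty strings, got {label!r}")
            tips[ids[u]] = label
        if len(set(tips.values())) != len(tips):
            dupes = sorted({l for l in tips.values() if list(tips.values()).count(l) > 1})
            raise ValueError(f"duplicate tip labels: {dupes}")
        # symmetry
        for u, nbrs in adj.items():
            for v, ln in nbrs.items():
                if u not in adj[v]:
                    adj[v][u] = ln
        # connectivity / acyclicity
        n_edges = sum(len(nbrs) for nbrs in adj.values()) // 2
        if adj:
            start = next(iter(adj))
            seen = {start}
            work = [start]
            while work:
                u = work.pop()
                for v in adj[u]:
                    if v not in seen:
                        seen.add(v)
                        work.append(v)
            if len(seen) != len(adj) or n_edges != len(adj) - 1:
                raise ValueError("adjacency is not a connected acyclic tree")
        self._adj = adj
        self._tips = tips
        self._root = ids.get(root, next(iter(adj)) if adj else None)
        self.rooted = bool(rooted)
        if normalize:
            self._normalize()

    # -- construction helpers ------------------------------------------------

    def _normalize(self) -> None:
        """Drop unlabeled leaves and suppress degree-2 internal nodes.

        A bifurcating root of a rooted tree is retained; for unrooted trees a
        degree-2 root is merged away like any other degree-2 node.
        """
        adj, tips = self._adj, self._tips
        changed = True
        while changed:
            changed = False
            for u in list(adj):
                if u in tips:
                    continue
                deg = len(adj[u])
                if deg <= 1 and len(adj) > 1:
                    # unlabeled leaf (can arise from pruning): remove
                    for v in list(adj[u]):
                        del adj[v][u]
                    del adj[u]
                    changed = True
                elif deg == 2 and not (self.rooted and u == self._root):
                    (a, la), (b, lb) = adj[u].items()
                    if la is None and lb is None:
                        ln = None
                    else:
                        ln = (la or 0.0) + (lb or 0.0)
                    del adj[a][u]
                    del adj[b][u]
                    adj[a][b] = ln
                    adj[b][a] = ln
                    del adj[u]
                    changed = True
        if self._root not in adj:
            # prefer an internal node as traversal anchor
            internal = [u for u in adj if u not in tips]
            self._root = internal[0] if internal else next(iter(adj))

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        return parse_newick(text)

    def copy(self) -> "PhyloTree":
        return PhyloTree(
            {u: dict(nbrs) for u, nbrs in self._adj.items()},
            dict(self._tips),
            root=self._root,
            rooted=self.rooted,
            normalize=False,
        )

    # -- basic queries -------------------------------------------------------

    @property
    def tips(self) -> frozenset:
        """The set of tip labels."""
        return frozenset(self._tips.values())

    @property
    def tip_list(self) -> list[str]:
        """Tip labels in sorted order."""
        return sorted(self._tips.values())

    @property
    def n_tips(self) -> int:
        return len(self._tips)

    def edges(self) -> Iterator[tuple[int, int, float | None]]:
        """Iterate over edges as ``(u, v, length)`` with ``u < v``."""
        for u, nbrs in self._adj.items():
            for v, ln in nbrs.items():
                if u < v:
                    yield u, v, ln

    @property
    def has_branch_lengths(self) -> bool:
        return all(ln is not None for _u, _v, ln in self.edges())

    def total_branch_length(self) -> float:
        return sum(ln for _u, _v, ln in self.edges() if ln is not None)

    def _rooted_view(self) -> tuple[list[int], dict[int, int | None], dict[int, list[int]]]:
        """Postorder node list, parent map, children map from the anchor."""
        root = self._root
        parent: dict[int, int | None] = {root: None}
        children: dict[int, list[int]] = {}
        order: list[int] = []
        stack = [root]
        while stack:
            u = stack.pop()
            order.append(u)
            kids = [v for v in self._adj[u] if v != parent[u]]
            children[u] = kids
            for v in kids:
                parent[v] = u
                stack.append(v)
        order.reverse()  # children now precede parents
        return order, parent, children

    # -- Newick output -------------------------------------------------------

    def to_newick(self, include_lengths: bool | None = None) -> str:
        """Serialize to Newick.  Lengths are emitted iff any edge has one
        (override with ``include_lengths``)."""
        if include_lengths is None:
            include_lengths = any(ln is not None for _u, _v, ln in self.edges())
        if len(self._adj) == 1:
            only = next(iter(self._adj))
            return _quote_label(self._tips[only]) + ";"
        order, parent, children = self._rooted_view()
        rep: dict[int, str] = {}
        for u in order:
            if u in self._tips:
                s = _quote_label(self._tips[u])
            else:
                s = "(" + ",".join(rep[c] for c in children[u]) + ")"
            p = parent[u]
            if include_lengths and p is not None:
                ln = self._adj[u][p]
                if ln is not None:
                    s += ":" + _format_length(ln)
            rep[u] = s
        return rep[self._root] + ";"

    # -- topology ------------------------------------------------------------

    def unrooted(self) -> "PhyloTree":
        """Copy of this tree with the root forgotten (degree-2 root merged)."""
        return PhyloTree(
            {u: dict(nbrs) for u, nbrs in self._adj.items()},
            dict(self._tips),
            root=self._root,
            rooted=False,
        )

    def bipartitions(self) -> frozenset:
        """Non-trivial bipartitions of the tip set, one per internal edge.

        The tree is treated as unrooted (a bifurcating root contributes a
        single split).  Trees with fewer than four tips have no non-trivial
        splits and yield the empty set.
        """
        all_tips = self.tips
        if len(all_tips) < 4:
            return frozenset()
        order, parent, _children = self._rooted_view()
        below: dict[int, frozenset] = {}
        out = set()
        for u in order:
            if u in self._tips:
                below[u] = frozenset((self._tips[u],))
            else:
                below[u] = frozenset().union(*(below[c] for c in self._adj[u] if c != parent[u]))
            if parent[u] is not None:
                side = below[u]
                if 1 < len(side) < len(all_tips) - 1:
                    out.add(Bipartition.of(side, all_tips))
        return frozenset(out)

    def restrict(self, keep: Iterable[str]) -> "PhyloTree":
        """Induced subtree on the tip subset ``keep``.

        Pruned tips' edges are deleted and the resulting degree-2 nodes are
        suppressed with their branch lengths summed.  The result is unrooted.
        """
        keep = frozenset(keep)
        unknown = keep - self.tips
        if unknown:
            raise ValueError(f"unknown tip labels: {sorted(unknown)}")
        if len(keep) < 3:
            raise ValueError(f"need at least 3 tips to restrict, got {len(keep)}")
        order, parent, children = self._rooted_view()

        def addlen(a, b):
            if a is None and b is None:
                return None
            return (a or 0.0) + (b or 0.0)

        # red[u] = (node_spec, extra_length_toward_parent) or None
        # node_spec = ("tip", label) | ("int", [(child_spec, edge_len), ...])
        red: dict[int, tuple | None] = {}
        for u in order:
            if u in self._tips:
                red[u] = (("tip", self._tips[u]), None) if self._tips[u] in keep else None
                continue
            kept = []
            for c in children[u]:
                r = red[c]
                if r is None:
                    continue
                spec, extra = r
                kept.append((spec, addlen(self._adj[c][u], extra)))
            if not kept:
                red[u] = None
            elif len(kept) == 1:
                red[u] = (kept[0][0], kept[0][1])
            else:
                red[u] = (("int", kept), None)

        spec, _extra = red[self._root]
        adj: dict[int, dict[int, float | None]] = {}
        tips: dict[int, str] = {}
        counter = [0]

        def new_id():
            counter[0] += 1
            return counter[0] - 1

        rid = new_id()
        adj[rid] = {}
        work = [(spec, rid)]
        while work:
            node, nid = work.pop()
            if node[0] == "tip":
                tips[nid] = node[1]
                continue
            for cspec, clen in node[1]:
                cid = new_id()
                adj[cid] = {}
                adj[nid][cid] = clen
                adj[cid][nid] = clen
                work.append((cspec, cid))
        return PhyloTree(adj, tips, root=rid, rooted=False)

    # -- distances -----------------------------------------------------------

    def patristic_matrix(self) -> "DistanceMatrix":
        """Pairwise tip-to-tip path-length (patristic) distance matrix."""
        for u, v, ln in self.edges():
            if ln is None:
                near = self._tips.get(u) or self._tips.get(v) or "?"
                raise ValueError(
                    f"missing branch length on edge ({u},{v}) near tip {near!r}"
                )
        labels = self.tip_list
        tip_nodes = {lbl: n for n, lbl in self._tips.items()}
        m = len(labels)
        out = np.zeros((m, m))
        for i, lbl in enumerate(labels):
            start = tip_nodes[lbl]
            dist = {start: 0.0}
            work = [start]
            while work:
                u = work.pop()
                for v, ln in self._adj[u].items():
                    if v not in dist:
                        dist[v] = dist[u] + ln
                        work.append(v)
            for j, lbl2 in enumerate(labels):
                out[i, j] = dist[tip_nodes[lbl2]]
        return DistanceMatrix(tuple(labels), out)

    def __repr__(self) -> str:  # pragma: no cover
        return f"<PhyloTree {self.n_tips} tips, rooted={self.rooted}>"


def write_newick(tree: PhyloTree, include_lengths: bool | None = None) -> str:
    """Serialize ``tree`` to a Newick string (see :meth:`PhyloTree.to_newick`)."""
    return tree.to_newick(include_lengths=include_lengths)


def read_trees(path) -> list[PhyloTree]:
    """Read one or more Newick trees from a file (one per line or per ``;``)."""
    text = open(path, encoding="utf-8").read()
    trees = []
    for chunk in text.split(";"):
        if chunk.strip():
            trees.append(parse_newick(chunk + ";"))
    return trees


# --------------------------------------------------------------------------
# Distance matrices
# --------------------------------------------------------------------------


@dataclasses.dataclass
class DistanceMatrix:
    """Symmetric labeled matrix of pairwise distances with zero diagonal."""

    labels: tuple
    values: np.ndarray

    def __post_init__(self):
        self.labels = tuple(self.labels)
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("distance matrix labels must be unique")
        v = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if v.shape != (n, n):
            raise ValueError(f"values must be {n}x{n}, got {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError("distance matrix entries must be finite")
        if not np.allclose(v, v.T, atol=1e-8):
            raise ValueError("distance matrix must be symmetric")
        v = 0.5 * (v + v.T)
        if np.any(np.abs(np.diag(v)) > 1e-10):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(v < -1e-9):
            raise ValueError("distance matrix entries must be >= 0")
        np.fill_diagonal(v, 0.0)
        self.values = np.clip(v, 0.0, None)

    @property
    def n(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def __getitem__(self, pair) -> float:
        a, b = pair
        return float(self.values[self.index(a), self.index(b)])

    def reorder(self, labels: Iterable[str]) -> "DistanceMatrix":
        labels = list(labels)
        if set(labels) != set(self.labels) or len(labels) != self.n:
            raise ValueError("reorder requires a permutation of the existing labels")
        idx = [self.index(l) for l in labels]
        return DistanceMatrix(tuple(labels), self.values[np.ix_(idx, idx)])

    def submatrix(self, labels: Iterable[str]) -> "DistanceMatrix":
        labels = list(labels)
        missing = set(labels) - set(self.labels)
        if missing:
            raise ValueError(f"unknown labels: {sorted(missing)}")
        idx = [self.index(l) for l in labels]
        return DistanceMatrix(tuple(labels), self.values[np.ix_(idx, idx)])

    def to_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.values, index=list(self.labels), columns=list(self.labels)).to_csv(
            path, sep="\t"
        )

    @classmethod
    def from_tsv(cls, path) -> "DistanceMatrix":
        import pandas as pd

        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(tuple(str(c) for c in df.columns), df.to_numpy(dtype=float))
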