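"""Tree-topology comparison statistics and tree-space embeddings.

Core statistics
---------------
* :func:`rf_distance` -- Robinson-Foulds distance: the size of the symmetric
  difference between the two trees' non-trivial bipartition sets (trees are
  compared unrooted).  For binary trees on ``m`` tips its maximum is
  ``2m - 6``.
* :func:`pc_similarity` -- percentage of clades in common,
  ``PC = 100 (1 - RF / (2m - 6))``: 100 for identical unrooted topologies, 0
  when no non-trivial split is shared and both trees are fully resolved.  For
  ``m = 4`` the only possible values are 0 and 100, which is why
  representative-strain comparisons over four strains are all-or-nothing.
* :func:`cadm_w` -- congruence among distance matrices: Kendall's coefficient
  of concordance ``W`` over the rank-transformed upper triangles of several
  distance matrices (1 = complete agreement, 0 = complete disagreement), with
  the standard tie correction and an optional permutation test.

Embeddings place trees (by their pairwise RF distances) or strains (by their
patristic distances) in the plane with classical metric MDS, optionally
refined by deterministic SMACOF stress majorization.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from fractions import Fraction
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .treeio import DistanceMatrix, PhyloTree

__all__ = [
    "rf_distance",
    "pc_similarity",
    "similarity_matrix",
    "SimilarityMatrix",
    "cadm_w",
    "CadmResult",
    "tree_space_embed",
    "strain_space_embed",
    "Embedding2D",
    "clade_pc_table",
    "CladeTable",
    "subset_pc",
    "read_clade_map",
]

logger = logging.getLogger(__name__)


def _check_same_tips(t1: PhyloTree, t2: PhyloTree) -> frozenset:
    if t1.tips != t2.tips:
        only1 = sorted(t1.tips - t2.tips)
        only2 = sorted(t2.tips - t1.tips)
        raise ValueError(
            "trees must share one tip set; "
            f"only in first: {only1}, only in second: {only2}"
        )
    return t1.tips


def rf_distance(t1: PhyloTree, t2: PhyloTree) -> int:
    """Robinson-Foulds distance between two trees on the same tip set.

    Both trees are treated as unrooted; the distance is the number of
    non-trivial bipartitions present in exactly one of the two trees.  Zero
    iff the unrooted topologies are identical.
    """
    _check_same_tips(t1, t2)
    return len(t1.bipartitions() ^ t2.bipartitions())


def pc_similarity(t1: PhyloTree, t2: PhyloTree) -> float:
    """Percentage of clades in common, ``100 (1 - RF/(2m-6))``.

    Requires a shared tip set of at least four labels (the normalizer
    ``2m - 6`` is the maximum RF distance between binary unrooted trees).
    Computed in exact rational arithmetic before conversion to float.
    """
    tips = _check_same_tips(t1, t2)
    m = len(tips)
    if m < 4:
        raise ValueError(f"PC needs at least 4 shared tips (got {m}): denominator 2m-6 <= 0")
    rf = rf_distance(t1, t2)
    denom = 2 * m - 6
    return float(Fraction(100 * (denom - rf), denom))


@dataclasses.dataclass
class SimilarityMatrix:
    """Symmetric matrix of pairwise PC percentages (diagonal exactly 100)."""

    tree_ids: tuple
    values: np.ndarray

    def __post_init__(self):
        self.tree_ids = tuple(self.tree_ids)
        v = np.asarray(self.values, dtype=float)
        n = len(self.tree_ids)
        if v.shape != (n, n):
            raise ValueError(f"values must be {n}x{n}")
        if not np.allclose(v, v.T):
            raise ValueError("similarity matrix must be symmetric")
        if not np.all(np.diag(v) == 100.0):
            raise ValueError("similarity matrix diagonal must be exactly 100")
        if v.min() < 0 or v.max() > 100:
            raise ValueError("PC values must lie in [0, 100]")
        self.values = v

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.tree_ids), columns=list(self.tree_ids))

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path)

    def __getitem__(self, pair) -> float:
        a, b = pair
        return float(self.values[self.tree_ids.index(a), self.tree_ids.index(b)])


def similarity_matrix(trees: Mapping[str, PhyloTree]) -> SimilarityMatrix:
    """All-pairs PC similarity among named trees sharing one tip set."""
    ids = list(trees)
    n = len(ids)
    out = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = pc_similarity(trees[ids[i]], trees[ids[j]])
    return SimilarityMatrix(tuple(ids), out)


# --------------------------------------------------------------------------
# CADM
# --------------------------------------------------------------------------


@dataclasses.dataclass
class CadmResult:
    """Kendall's W over distance matrices, with optional permutation p-value."""

    w: float
    p_value: float | None = None


def _kendall_w(ranks: np.ndarray) -> float:
    """Kendall's coefficient of concordance with tie correction.

    ``ranks`` is a ``p x N`` array of within-row average ranks.
    """
    p, N = ranks.shape
    R = ranks.sum(axis=0)
    S = float(((R - R.mean()) ** 2).sum())
    T = 0.0
    for row in ranks:
        _vals, counts = np.unique(row, return_counts=True)
        T += float((counts**3 - counts).sum())
    denom = p**2 * (N**3 - N) - p * T
    if denom <= 0:
        # every matrix fully tied: any ranking is trivially concordant
        return 1.0
    return 12.0 * S / denom


def cadm_w(
    matrices: Iterable[DistanceMatrix],
    permutations: int = 0,
    seed=None,
) -> CadmResult:
    """Congruence among distance matrices (Kendall's W on ranked triangles).

    Each matrix's strict upper triangle (aligned to a common label order) is
    rank-transformed with average ranks for ties; W is computed over the
    ``p x n(n-1)/2`` rank table.  W = 1 means the matrices order all pairs of
    labels identically; W = 0 complete disagreement.

    If ``permutations > 0``, a permutation test is run in which the labels of
    every matrix except the first are independently permuted; the p-value is
    ``(1 + #{W* >= W}) / (1 + permutations)``.
    """
    matrices = list(matrices)
    if len(matrices) < 2:
        raise ValueError(f"need at least 2 matrices, got {len(matrices)}")
    labels = list(matrices[0].labels)
    if len(labels) < 4:
        raise ValueError("need at least 4 labels")
    for m in matrices[1:]:
        if set(m.labels) != set(labels):
            raise ValueError(
                "matrices must share one label set; difference: "
                f"{sorted(set(m.labels) ^ set(labels))}"
            )
    aligned = [m.reorder(labels).values for m in matrices]
    iu = np.triu_indices(len(labels), k=1)
    ranks = np.vstack([rankdata(a[iu]) for a in aligned])
    w = _kendall_w(ranks)
    p_value = None
    if permutations > 0:
        rng = np.random.default_rng(seed)
        n = len(labels)
        hits = 0
        first = ranks[0]
        for _ in range(permutations):
            rows = [first]
            for a in aligned[1:]:
                perm = rng.permutation(n)
                rows.append(rankdata(a[np.ix_(perm, perm)][iu]))
            if _kendall_w(np.vstack(rows)) >= w - 1e-12:
                hits += 1
        p_value = (1 + hits) / (1 + permutations)
    return CadmResult(w=w, p_value=p_value)


# --------------------------------------------------------------------------
# MDS embeddings
# --------------------------------------------------------------------------


@dataclasses.dataclass
class Embedding2D:
    """Planar MDS configuration plus its Kruskal stress-1."""

    ids: tuple
    coords: np.ndarray  # (n, 2)
    stress: float

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"id": list(self.ids), "x": self.coords[:, 0], "y": self.coords[:, 1]}
        )

    def to_csv(self, path, stress_path=None) -> None:
        self.to_dataframe().to_csv(path, index=False)
        if stress_path is not None:
            with open(stress_path, "w") as fh:
                json.dump({"stress": self.stress}, fh, indent=1)

    def distances(self) -> np.ndarray:
        diff = self.coords[:, None, :] - self.coords[None, :, :]
        return np.sqrt((diff**2).sum(axis=2))


def _classical_mds(D: np.ndarray) -> np.ndarray:
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    B = 0.5 * (B + B.T)
    w, V = np.linalg.eigh(B)
    order = np.argsort(w)[::-1][:2]
    coords = V[:, order] * np.sqrt(np.clip(w[order], 0.0, None))
    if coords.shape[1] < 2:  # pragma: no cover - n >= 3 always gives 2 columns
        coords = np.pad(coords, ((0, 0), (0, 2 - coords.shape[1])))
    # deterministic sign convention: largest-magnitude coordinate positive
    for k in range(2):
        col = coords[:, k]
        if np.any(col != 0) and col[int(np.argmax(np.abs(col)))] < 0:
            coords[:, k] = -col
    return coords


def _smacof(D: np.ndarray, init: np.ndarray, iters: int = 300, tol: float = 1e-10) -> np.ndarray:
    """Deterministic SMACOF stress majorization from a fixed start."""
    n = D.shape[0]
    X = init.copy()
    prev = np.inf
    for _ in range(iters):
        diff = X[:, None, :] - X[None, :, :]
        dist = np.sqrt((diff**2).sum(axis=2))
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(dist > 0, D / dist, 0.0)
        B = -ratio
        np.fill_diagonal(B, 0.0)
        np.fill_diagonal(B, -B.sum(axis=1))
        X = (B @ X) / n
        stress = ((dist - D)[np.triu_indices(n, 1)] ** 2).sum()
        if prev - stress < tol:
            break
        prev = stress
    return X


def _stress1(D: np.ndarray, coords: np.ndarray) -> float:
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=2))
    iu = np.triu_indices(D.shape[0], 1)
    denom = float((D[iu] ** 2).sum())
    if denom == 0:
        return 0.0
    return float(np.sqrt(((dist[iu] - D[iu]) ** 2).sum() / denom))


def _embed(D: DistanceMatrix, method: str) -> Embedding2D:
    coords = _classical_mds(D.values)
    if method == "smacof":
        coords = _smacof(D.values, coords)
    elif method != "classical":
        raise ValueError(f"unknown MDS method {method!r}")
    return Embedding2D(tuple(D.labels), coords, _stress1(D.values, coords))


def tree_space_embed(
    trees: Mapping[str, PhyloTree], method: str = "classical", seed=None
) -> Embedding2D:
    """Embed named trees in the plane by MDS on their pairwise RF distances.

    Classical (Torgerson double-centering) MDS by default; ``method="smacof"``
    refines it by stress majorization started from the classical solution, so
    both flavors are deterministic given the input order (``seed`` is accepted
    for interface symmetry but unused by these deterministic solvers).
    """
    ids = list(trees)
    if len(ids) < 3:
        raise ValueError(f"need at least 3 trees, got {len(ids)}")
    n = len(ids)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = rf_distance(trees[ids[i]], trees[ids[j]])
    return _embed(DistanceMatrix(tuple(ids), D), method)


def strain_space_embed(tree: PhyloTree, method: str = "classical", seed=None) -> Embedding2D:
    """Embed a tree's strains in the plane by MDS on patristic distances."""
    return _embed(tree.patristic_matrix(), method)


# --------------------------------------------------------------------------
# Clade-pruned and strain-subset comparisons
# --------------------------------------------------------------------------


def read_clade_map(path) -> dict[str, set]:
    """Read a two-column TSV (strain, clade) into ``{clade: set_of_strains}``."""
    df = pd.read_csv(path, sep="\t", header=None, names=["strain", "clade"], dtype=str)
    out: dict[str, set] = {}
    for strain, clade in zip(df["strain"], df["clade"]):
        out.setdefault(clade, set()).add(strain)
    return out


@dataclasses.dataclass
class CladeTable:
    """PC of each clade-restricted tree against the clade in a reference tree.

    Rows are clades, columns tree ids; cells for clades with fewer than four
    tips are undefined (NaN) because the PC normalizer vanishes.
    """

    table: pd.DataFrame
    clade_sizes: dict

    def to_csv(self, path) -> None:
        out = self.table.copy()
        out.insert(0, "n_tips", [self.clade_sizes[c] for c in out.index])
        out.to_csv(path)


def clade_pc_table(
    gene_trees: Mapping[str, PhyloTree],
    te_tree: PhyloTree,
    ref_tree: PhyloTree,
    out_tree: PhyloTree,
    clade_map: Mapping[str, Iterable[str]],
) -> CladeTable:
    """Compare every clade's topology in each tree against the reference.

    For each clade with at least four tips, every tree (per-gene, total
    evidence, and the random control) is restricted to the clade's tips and
    scored by PC against the identically restricted reference tree.
    """
    trees: dict[str, PhyloTree] = dict(gene_trees)
    trees["TE"] = te_tree
    trees["OUT"] = out_tree
    shared = ref_tree.tips
    sizes = {}
    rows = {}
    for clade in clade_map:
        tips = frozenset(clade_map[clade])
        unknown = tips - shared
        if unknown:
            raise ValueError(f"clade {clade!r} contains unknown tips: {sorted(unknown)}")
        sizes[clade] = len(tips)
        if len(tips) < 4:
            rows[clade] = {tid: np.nan for tid in trees}
            logger.info("clade %s has %d tips (<4): PC undefined", clade, len(tips))
            continue
        ref_sub = ref_tree.restrict(tips)
        row = {}
        for tid, tree in trees.items():
            row[tid] = pc_similarity(tree.restrict(tips), ref_sub)
        rows[clade] = row
    table = pd.DataFrame.from_dict(rows, orient="index")[list(trees)]
    return CladeTable(table=table, clade_sizes=sizes)


def subset_pc(
    trees: Mapping[str, PhyloTree], ref_tree: PhyloTree, subset: Iterable[str]
) -> dict[str, float]:
    """PC of each subset-restricted tree against the restricted reference.

    ``subset`` must contain at least four strains present in every tree.  For
    exactly four strains the outcome is binary (0 or 100), since four tips
    admit only three unrooted binary topologies with a single internal split.
    """
    subset = frozenset(subset)
    unknown = subset - ref_tree.tips
    if unknown:
        raise ValueError(f"unknown strains in subset: {sorted(unknown)}")
    if len(subset) < 4:
        raise ValueError(f"subset must contain at least 4 strains, got {len(subset)}")
    ref_sub = ref_tree.restrict(subset)
    return {tid: pc_similarity(t.restrict(subset), ref_sub) for tid, t in trees.items()}
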