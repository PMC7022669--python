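"""Synthetic clade-structured benchmarks with known ground truth.

Emulates, at configurable scale, the shape of a clade-structured yeast
population panel: a binary species tree whose tips fall into K monophyletic
clades separated by deep backbone branches, per-gene trees derived from the
species tree by a controlled number of random nearest-neighbor-interchange
(NNI) moves (each move displaces exactly one bipartition, so the expected
topological discordance grows with the move count), Jukes-Cantor sequence
evolution along each gene tree, and emission of the resulting polymorphic
sites as a standard VCF plus gene-region table.

Everything is driven by a single master seed through spawned NumPy seed
streams, so a benchmark is bit-reproducible and every pipeline stage can be
tested end-to-end against the stored truth without any external data.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .inference import random_topology
from .treeio import PhyloTree
from .variants import Alignment, GeneRegion

__all__ = [
    "JCParams",
    "BenchmarkParams",
    "SyntheticTruth",
    "Benchmark",
    "simulate_species_tree",
    "simulate_gene_tree",
    "simulate_alignment",
    "write_vcf",
    "make_benchmark",
]

logger = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))


@dataclasses.dataclass(frozen=True)
class JCParams:
    """Jukes-Cantor simulation parameters: substitution rate per site per unit
    branch length, and sites per gene."""

    mu: float
    L: int

    def __post_init__(self):
        if self.mu <= 0:
            raise ValueError("mu must be > 0")
        if self.L < 1:
            raise ValueError("L must be >= 1")


def _uniform_depth(depth: float):
    """Branch-length sampler: jittered uniformly within +/-50% of ``depth``."""

    def draw(rng):
        return depth * rng.uniform(0.5, 1.5)

    return draw


def simulate_species_tree(
    K: int,
    clade_sizes: Sequence[int],
    between_depth: float,
    within_depth: float,
    seed,
) -> tuple[PhyloTree, dict[str, str]]:
    """Random binary species tree with K monophyletic clades.

    A random backbone topology on K clade ancestors carries branch lengths
    around ``between_depth``; each ancestor subtends a random binary subtree
    over that clade's strains with branch lengths around ``within_depth``.
    Strains are named ``C{k}_{i:02d}`` and the returned clade map sends each
    strain to its clade name ``C{k}``.
    """
    if K < 2:
        raise ValueError("need K >= 2 clades")
    clade_sizes = list(clade_sizes)
    if len(clade_sizes) != K:
        raise ValueError(f"need {K} clade sizes, got {len(clade_sizes)}")
    if any(s < 2 for s in clade_sizes):
        raise ValueError("every clade needs at least 2 strains")
    if between_depth <= 0 or within_depth <= 0:
        raise ValueError("depths must be > 0")
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    backbone_seed, *clade_seeds = ss.spawn(K + 1)
    clade_names = [f"C{k + 1}" for k in range(K)]

    between = _uniform_depth(between_depth)
    within = _uniform_depth(within_depth)

    if K == 2:
        # degenerate backbone: a single edge between the two clade ancestors
        backbone_adj = {0: {1: between(np.random.default_rng(backbone_seed))}, 1: {}}
        anchor_of = {clade_names[0]: 0, clade_names[1]: 1}
        adj: dict = {u: dict(nbrs) for u, nbrs in backbone_adj.items()}
        for u, nbrs in list(adj.items()):
            for v, ln in nbrs.items():
                adj.setdefault(v, {})[u] = ln
    else:
        backbone = random_topology(clade_names, seed=backbone_seed, branch_length=between)
        adj = {u: dict(nbrs) for u, nbrs in backbone._adj.items()}
        anchor_of = {lbl: node for node, lbl in backbone._tips.items()}

    tips: dict[int, str] = {}
    clade_map: dict[str, str] = {}
    next_id = [max(adj) + 1]

    def new_node():
        nid = next_id[0]
        next_id[0] += 1
        adj[nid] = {}
        return nid

    for cname, size, cseed in zip(clade_names, clade_sizes, clade_seeds):
        rng = np.random.default_rng(cseed)
        strains = [f"{cname}_{i + 1:02d}" for i in range(size)]
        for s in strains:
            clade_map[s] = cname
        anchor = anchor_of[cname]  # backbone tip node becomes the clade root
        if size == 2:
            for s in strains:
                t = new_node()
                tips[t] = s
                ln = within(rng)
                adj[anchor][t] = ln
                adj[t][anchor] = ln
            continue
        sub = random_topology(strains, seed=rng, branch_length=within)
        # graft the unrooted clade tree by subdividing one of its edges at
        # the anchor, keeping the clade binary and monophyletic
        offset = next_id[0]
        for u, nbrs in sub._adj.items():
            adj[offset + u] = {offset + v: ln for v, ln in nbrs.items()}
        for u, lbl in sub._tips.items():
            tips[offset + u] = lbl
        next_id[0] = offset + max(sub._adj) + 1
        edges = sorted((u, v) for u, nbrs in sub._adj.items() for v in nbrs if u < v)
        eu, ev = edges[int(rng.integers(len(edges)))]
        u, v = offset + eu, offset + ev
        half = adj[u].pop(v) / 2.0
        adj[v].pop(u)
        adj[anchor][u] = half
        adj[u][anchor] = half
        adj[anchor][v] = half
        adj[v][anchor] = half
    tree = PhyloTree(adj, tips, root=anchor_of[clade_names[0]], rooted=False)
    return tree, clade_map


def simulate_gene_tree(
    species_tree: PhyloTree,
    n_nni: int,
    seed,
    length_jitter_sd: float = 0.1,
) -> PhyloTree:
    """Derive a gene tree by random NNI moves plus branch-length jitter.

    ``n_nni = 0`` returns a topologically identical copy.  Each move picks a
    random internal edge and swaps one subtree from either side across it,
    changing exactly one bipartition; successive moves can cancel, so the RF
    distance to the species tree grows with ``n_nni`` in expectation rather
    than deterministically.  Branch lengths are multiplied by i.i.d.
    log-normal noise with the given log-scale standard deviation.
    """
    if n_nni < 0:
        raise ValueError("n_nni must be >= 0")
    rng = np.random.default_rng(seed)
    tree = species_tree.unrooted()
    adj = {u: dict(nbrs) for u, nbrs in tree._adj.items()}
    tip_nodes = set(tree._tips)

    for _ in range(n_nni):
        internal_edges = sorted(
            (u, v)
            for u, nbrs in adj.items()
            for v in nbrs
            if u < v and u not in tip_nodes and v not in tip_nodes
        )
        if not internal_edges:
            break
        u, v = internal_edges[int(rng.integers(len(internal_edges)))]
        a_choices = sorted(x for x in adj[u] if x != v)
        b_choices = sorted(x for x in adj[v] if x != u)
        a = a_choices[int(rng.integers(len(a_choices)))]
        b = b_choices[int(rng.integers(len(b_choices)))]
        # swap subtree a (attached at u) with subtree b (attached at v)
        la = adj[u].pop(a)
        adj[a].pop(u)
        lb = adj[v].pop(b)
        adj[b].pop(v)
        adj[u][b] = lb
        adj[b][u] = lb
        adj[v][a] = la
        adj[a][v] = la

    if length_jitter_sd > 0:
        logger.debug("jittering branch lengths (log-normal sd=%g)", length_jitter_sd)
        for u in sorted(adj):
            for v in sorted(adj[u]):
                if u < v and adj[u][v] is not None:
                    factor = float(rng.lognormal(0.0, length_jitter_sd))
                    adj[u][v] = adj[u][v] * factor
                    adj[v][u] = adj[u][v]
    return PhyloTree(adj, dict(tree._tips), root=tree._root, rooted=False)


def simulate_alignment(
    tree: PhyloTree,
    jc: JCParams,
    seed,
    gene: str = "gene",
    chrom: str | None = None,
) -> Alignment:
    """Evolve sequences along a tree under the Jukes-Cantor model.

    The root sequence is uniform over {A, C, G, T}; along a branch of length
    ``t`` each site substitutes independently with probability
    ``(3/4)(1 - exp(-4 mu t / 3))``, to a uniformly chosen different base.
    """
    if not tree.has_branch_lengths:
        raise ValueError("simulate_alignment requires branch lengths on every edge")
    rng = np.random.default_rng(seed)
    chrom = chrom if chrom is not None else gene
    root = tree._root
    seqs: dict[int, np.ndarray] = {root: rng.integers(0, 4, size=jc.L, dtype=np.int8)}
    parent = {root: None}
    stack = [root]
    order = []
    while stack:
        u = stack.pop()
        order.append(u)
        for v in tree._adj[u]:
            if v != parent[u]:
                parent[v] = u
                stack.append(v)
    for u in order:
        if parent[u] is None:
            continue
        t = tree._adj[u][parent[u]]
        p_sub = 0.75 * (1.0 - np.exp(-4.0 * jc.mu * t / 3.0))
        seq = seqs[parent[u]].copy()
        hit = rng.random(jc.L) < p_sub
        n_hit = int(hit.sum())
        if n_hit:
            seq[hit] = (seq[hit] + rng.integers(1, 4, size=n_hit, dtype=np.int8)) % 4
        seqs[u] = seq
    labels = tree.tip_list
    node_of = {lbl: n for n, lbl in tree._tips.items()}
    sites = _BASES[np.stack([seqs[node_of[lbl]] for lbl in labels])]
    meta = pd.DataFrame({"gene": gene, "chrom": chrom, "pos": np.arange(1, jc.L + 1)})
    return Alignment(tuple(labels), sites, meta)


def write_vcf(
    alignments: Mapping[str, Alignment],
    gene_regions: Sequence[GeneRegion],
    vcf_path,
    fasta_path=None,
    reference_choice: str = "major",
) -> None:
    """Emit polymorphic alignment columns as a VCF 4.2 plus reference FASTA.

    Each polymorphic column of each gene becomes one SNP record at position
    ``region.start + column_index``; invariant columns are omitted.  The
    reference allele is the major allele (ties broken alphabetically) or the
    first strain's base (``reference_choice="first"``); remaining observed
    bases become ALT alleles ordered by descending count then alphabetically.
    Genotypes are homozygous diploid (``0/0``, ``1/1``, ...), with ``N`` as
    ``./.``.  Reading the VCF back through the variants module recovers the
    polymorphic columns exactly.
    """
    if reference_choice not in ("major", "first"):
        raise ValueError(f"unknown reference_choice {reference_choice!r}")
    regions = {r.name: r for r in gene_regions}
    missing = set(alignments) - set(regions)
    if missing:
        raise ValueError(f"no region for genes: {sorted(missing)}")
    names = list(alignments)
    labels = alignments[names[0]].labels
    for g in names[1:]:
        if alignments[g].labels != labels:
            raise ValueError(f"alignment {g!r} has a different strain ordering/set")

    rows = []
    ref_bases: dict[str, dict[int, str]] = {}
    for g in names:
        aln, region = alignments[g], regions[g]
        if aln.n_sites > region.length:
            raise ValueError(
                f"gene {g!r}: {aln.n_sites} columns exceed region capacity {region.length}"
            )
        for j in range(aln.n_sites):
            col = aln.sites[:, j]
            observed = col[col != "N"]
            bases, counts = np.unique(observed, return_counts=True)
            if len(bases) < 2:
                continue
            if reference_choice == "major":
                best = counts.max()
                ref = min(bases[counts == best])
            else:
                ref = col[0] if col[0] != "N" else min(bases)
            alts = sorted(
                (b for b in bases if b != ref),
                key=lambda b: (-counts[list(bases).index(b)], b),
            )
            allele_index = {ref: 0, **{b: k + 1 for k, b in enumerate(alts)}}
            pos = region.start + j
            gts = []
            for ch in col:
                if ch == "N":
                    gts.append("./.")
                else:
                    k = allele_index[ch]
                    gts.append(f"{k}/{k}")
            rows.append(
                (region.chrom, pos, ref, ",".join(alts), gts)
            )
            ref_bases.setdefault(region.chrom, {})[pos] = ref

    contig_len = {}
    for r in gene_regions:
        contig_len[r.chrom] = max(contig_len.get(r.chrom, 0), r.end)

    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=phylocompare-synthetic\n")
        for chrom in contig_len:
            fh.write(f"##contig=<ID={chrom},length={contig_len[chrom]}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(labels) + "\n")
        for chrom, pos, ref, alt, gts in rows:
            fh.write(
                f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n"
            )

    if fasta_path is not None:
        with open(fasta_path, "w") as fh:
            for chrom, length in contig_len.items():
                seq = np.full(length, "A", dtype="U1")
                for pos, base in ref_bases.get(chrom, {}).items():
                    seq[pos - 1] = base
                fh.write(f">{chrom}\n")
                s = "".join(seq)
                for k in range(0, len(s), 60):
                    fh.write(s[k : k + 60] + "\n")


@dataclasses.dataclass
class BenchmarkParams:
    """Study conditions for a synthetic benchmark.

    Defaults describe a population of five clades of twenty strains each,
    deep between-clade divergence relative to within-clade diversity, ten
    genes of 5000 sites evolving at mu = 0.03 substitutions per site per unit
    branch length, and fully concordant gene trees (``discordance = 0`` NNI
    moves per gene).
    """

    n_clades: int = 5
    clade_sizes: tuple = (20, 20, 20, 20, 20)
    between_depth: float = 1.0
    within_depth: float = 0.1
    n_genes: int = 10
    L: int = 5000
    mu: float = 0.03
    discordance: int = 0
    seed: int = 0


@dataclasses.dataclass
class SyntheticTruth:
    """Ground truth behind a benchmark: species tree, clade map, gene trees."""

    species_tree: PhyloTree
    clade_map: dict
    gene_trees: dict
    params: BenchmarkParams

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "species_tree.nwk").write_text(self.species_tree.to_newick() + "\n")
        for g, t in self.gene_trees.items():
            (out / f"true_{g}.nwk").write_text(t.to_newick() + "\n")
        with open(out / "clade_map.tsv", "w") as fh:
            for strain in sorted(self.clade_map):
                fh.write(f"{strain}\t{self.clade_map[strain]}\n")
        with open(out / "params.json", "w") as fh:
            json.dump(dataclasses.asdict(self.params), fh, indent=1)


@dataclasses.dataclass
class Benchmark:
    """A generated benchmark: file paths plus in-memory truth and alignments."""

    vcf_path: Path
    regions_path: Path
    fasta_path: Path
    truth: SyntheticTruth
    alignments: dict


def make_benchmark(params: BenchmarkParams, out_dir) -> Benchmark:
    """Generate a full benchmark: species tree -> gene trees -> alignments ->
    VCF + regions + truth bundle, all reproducible from ``params.seed``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(params.seed)
    species_seed, genes_seed = ss.spawn(2)
    species_tree, clade_map = simulate_species_tree(
        params.n_clades,
        params.clade_sizes,
        params.between_depth,
        params.within_depth,
        seed=species_seed,
    )
    jc = JCParams(mu=params.mu, L=params.L)
    gene_trees: dict[str, PhyloTree] = {}
    alignments: dict[str, Alignment] = {}
    regions = []
    gene_streams = genes_seed.spawn(params.n_genes)
    for g, gstream in enumerate(gene_streams):
        name = f"gene{g + 1:02d}"
        chrom = f"chr{g + 1}"
        tree_seed, aln_seed = gstream.spawn(2)
        gtree = simulate_gene_tree(species_tree, params.discordance, seed=tree_seed)
        gene_trees[name] = gtree
        alignments[name] = simulate_alignment(gtree, jc, seed=aln_seed, gene=name, chrom=chrom)
        regions.append(GeneRegion(name=name, chrom=chrom, start=1, end=params.L))

    vcf_path = out / "variants.vcf"
    fasta_path = out / "reference.fa"
    regions_path = out / "regions.tsv"
    write_vcf(alignments, regions, vcf_path, fasta_path)
    with open(regions_path, "w") as fh:
        for r in regions:
            fh.write(f"{r.name}\t{r.chrom}\t{r.start}\t{r.end}\n")
    truth = SyntheticTruth(
        species_tree=species_tree,
        clade_map=clade_map,
        gene_trees=gene_trees,
        params=params,
    )
    truth.write(out / "truth")
    return Benchmark(
        vcf_path=vcf_path,
        regions_path=regions_path,
        fasta_path=fasta_path,
        truth=truth,
        alignments=alignments,
    )
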