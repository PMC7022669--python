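"""End-to-end orchestration: variants -> trees -> topology comparisons.

:func:`run_pipeline` executes the three analysis stages from a single
:class:`RunConfig`: (i) data processing (VCF + gene regions to per-gene
polymorphic-site alignments and the concatenated total-evidence supermatrix),
(ii) distance-based phylogenetic inference (NJ or BIONJ per-gene trees, the
total-evidence tree, and a random null-control "OUT" topology), and (iii)
comparison analysis (PC similarity matrix, CADM concordance of the per-gene
distance matrices, tree-space and strain-space MDS embeddings, and -- when a
reference tree and clade map are supplied -- clade-pruned and strain-subset
comparison tables).

Strain-set mismatches between the VCF and a reference tree are a hard error
by default: RF-based statistics only compare trees over the same element set.
``intersect=True`` opts into restricting both sides to the shared strains,
with the dropped strains logged and recorded in the report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pysam
import yaml

from . import __version__
from .inference import bionj, neighbor_joining, random_topology
from .topocompare import (
    cadm_w,
    clade_pc_table,
    read_clade_map,
    similarity_matrix,
    strain_space_embed,
    subset_pc,
    tree_space_embed,
)
from .treeio import PhyloTree, read_trees
from .variants import (
    concatenate,
    jc_distance_matrix,
    p_distance_matrix,
    read_gene_regions,
    read_variants,
    variants_to_alignment,
)

__all__ = ["RunConfig", "ComparisonReport", "run_pipeline"]

logger = logging.getLogger(__name__)

_DISTANCE_MODELS = {"p": p_distance_matrix, "jc": jc_distance_matrix}
_TREE_METHODS = {"nj": neighbor_joining, "bionj": bionj}
_MDS_METHODS = ("classical", "smacof")
_CADM_INPUTS = ("sequence", "patristic")


@dataclasses.dataclass
class RunConfig:
    """Configuration of one pipeline run (see module docstring)."""

    vcf_path: str
    regions_path: str
    out_dir: str
    ref_tree_path: str | None = None
    clade_map_path: str | None = None
    representative_subset: tuple = ()
    control_subset: tuple = ()
    drop_monomorphic: bool = True
    distance_model: str = "p"
    tree_method: str = "bionj"
    mds_method: str = "classical"
    cadm_input: str = "sequence"
    cadm_permutations: int = 0
    intersect: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.distance_model not in _DISTANCE_MODELS:
            raise ValueError(f"distance_model must be one of {sorted(_DISTANCE_MODELS)}")
        if self.tree_method not in _TREE_METHODS:
            raise ValueError(f"tree_method must be one of {sorted(_TREE_METHODS)}")
        if self.mds_method not in _MDS_METHODS:
            raise ValueError(f"mds_method must be one of {_MDS_METHODS}")
        if self.cadm_input not in _CADM_INPUTS:
            raise ValueError(f"cadm_input must be one of {_CADM_INPUTS}")
        self.representative_subset = tuple(self.representative_subset)
        self.control_subset = tuple(self.control_subset)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)


@dataclasses.dataclass
class ComparisonReport:
    """All artifacts of one run, with their on-disk paths and provenance."""

    out_dir: Path
    strains: tuple
    gene_trees: dict
    te_tree: PhyloTree
    out_tree: PhyloTree
    ref_tree: PhyloTree | None
    similarity: "object"
    cadm: "object"
    tree_space: "object"
    strain_space: "object"
    clade_table: "object | None"
    subset_tables: dict
    files: dict
    provenance: dict


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            logger.info("stage %s: start", name)
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrapper

    return deco


def run_pipeline(config: RunConfig) -> ComparisonReport:
    """Run data processing, inference, and comparison; write all artifacts."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, str] = {}
    rng_seed = np.random.SeedSequence(config.seed)

    # ---- stage 1: data processing -----------------------------------------
    with pysam.VariantFile(str(config.vcf_path)) as vf:
        vcf_strains = list(vf.header.samples)
    ref_tree = None
    strains = sorted(vcf_strains)
    dropped: list[str] = []
    if config.ref_tree_path:
        ref_tree = read_trees(config.ref_tree_path)[0]
        if ref_tree.tips != frozenset(strains):
            diff_vcf = sorted(frozenset(strains) - ref_tree.tips)
            diff_ref = sorted(ref_tree.tips - frozenset(strains))
            if not config.intersect:
                raise PipelineError(
                    "stage 'data' failed: VCF strains and reference-tree tips differ "
                    f"(only in VCF: {diff_vcf}; only in tree: {diff_ref}). "
                    "Set intersect=true to compare on the shared strains."
                )
            shared = sorted(frozenset(strains) & ref_tree.tips)
            if len(shared) < 4:
                raise PipelineError("stage 'data' failed: fewer than 4 shared strains")
            dropped = diff_vcf + diff_ref
            logger.info("intersect mode: dropping %d strains: %s", len(dropped), dropped)
            strains = shared
            ref_tree = ref_tree.restrict(shared)

    regions = _read_regions(config)
    alignments = _build_alignments(config, regions, strains, out, files)
    te_aln = _concatenate(alignments, out, files)

    # ---- stage 2: inference ------------------------------------------------
    distance = _DISTANCE_MODELS[config.distance_model]
    method = _TREE_METHODS[config.tree_method]
    gene_trees, gene_dms = _infer_trees(alignments, distance, method, out, files)
    te_tree = _infer_te(te_aln, distance, method, out, files)
    out_tree = random_topology(strains, seed=rng_seed.spawn(1)[0])
    _write_tree(out_tree, out / "OUT.nwk", files, "out_tree")

    # ---- stage 3: comparison ----------------------------------------------
    all_trees = dict(gene_trees)
    all_trees["TE"] = te_tree
    if ref_tree is not None:
        all_trees["REF"] = ref_tree
    all_trees["OUT"] = out_tree
    sim, cadm, tspace, sspace = _compare(config, all_trees, gene_dms, te_tree, rng_seed, out, files)

    clade_table = None
    subset_tables: dict[str, dict] = {}
    if ref_tree is not None:
        comparable = {k: v for k, v in all_trees.items() if k not in ("REF",)}
        if config.clade_map_path:
            clade_map = read_clade_map(config.clade_map_path)
            clade_map = {
                c: {s for s in tips if s in set(strains)} for c, tips in clade_map.items()
            }
            clade_table = clade_pc_table(
                gene_trees, te_tree, ref_tree, out_tree, clade_map
            )
            path = out / "clade_pc_table.csv"
            clade_table.to_csv(path)
            files["clade_table"] = str(path)
        for name, subset in (
            ("representative", config.representative_subset),
            ("control", config.control_subset),
        ):
            if subset:
                table = subset_pc(comparable, ref_tree, subset)
                subset_tables[name] = table
                path = out / f"subset_pc_{name}.csv"
                with open(path, "w") as fh:
                    fh.write("tree,pc\n")
                    for tid in table:
                        fh.write(f"{tid},{table[tid]:.6g}\n")
                files[f"subset_{name}"] = str(path)

    provenance = {
        "package": "phylocompare",
        "version": __version__,
        "seed": config.seed,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "n_strains": len(strains),
        "dropped_strains": dropped,
        "genes": [r.name for r in regions],
        "cadm_w": cadm.w,
        "cadm_p": cadm.p_value,
    }
    with open(out / "report.json", "w") as fh:
        json.dump({"provenance": provenance, "files": files}, fh, indent=1, sort_keys=True)
    files["report"] = str(out / "report.json")

    return ComparisonReport(
        out_dir=out,
        strains=tuple(strains),
        gene_trees=gene_trees,
        te_tree=te_tree,
        out_tree=out_tree,
        ref_tree=ref_tree,
        similarity=sim,
        cadm=cadm,
        tree_space=tspace,
        strain_space=sspace,
        clade_table=clade_table,
        subset_tables=subset_tables,
        files=files,
        provenance=provenance,
    )


@_stage("regions")
def _read_regions(config):
    regions = read_gene_regions(config.regions_path)
    if not regions:
        raise ValueError("no gene regions")
    return regions


@_stage("alignments")
def _build_alignments(config, regions, strains, out, files):
    alignments = {}
    for region in regions:
        records = read_variants(config.vcf_path, region, strains)
        aln = variants_to_alignment(
            records, strains, drop_monomorphic=config.drop_monomorphic, gene=region.name
        )
        logger.info(
            "gene %s: %d SNP records, %d sites retained", region.name, len(records), aln.n_sites
        )
        path = out / f"{region.name}.fasta"
        aln.to_fasta(path)
        files[f"alignment_{region.name}"] = str(path)
        alignments[region.name] = aln
    return alignments


@_stage("concatenate")
def _concatenate(alignments, out, files):
    te_aln = concatenate(list(alignments.values()))
    path = out / "TE_supermatrix.fasta"
    te_aln.to_fasta(path)
    te_aln.write_site_meta(out / "TE_site_meta.tsv")
    files["te_supermatrix"] = str(path)
    files["te_site_meta"] = str(out / "TE_site_meta.tsv")
    return te_aln


def _write_tree(tree, path, files, key):
    Path(path).write_text(tree.to_newick() + "\n")
    files[key] = str(path)


@_stage("gene_trees")
def _infer_trees(alignments, distance, method, out, files):
    gene_trees, gene_dms = {}, {}
    for name, aln in alignments.items():
        dm = distance(aln)
        gene_dms[name] = dm
        tree = method(dm)
        gene_trees[name] = tree
        _write_tree(tree, out / f"{name}.nwk", files, f"tree_{name}")
    return gene_trees, gene_dms


@_stage("te_tree")
def _infer_te(te_aln, distance, method, out, files):
    te_tree = method(distance(te_aln))
    _write_tree(te_tree, out / "TE.nwk", files, "te_tree")
    return te_tree


@_stage("comparison")
def _compare(config, all_trees, gene_dms, te_tree, rng_seed, out, files):
    sim = similarity_matrix(all_trees)
    sim.to_csv(out / "similarity_matrix.csv")
    files["similarity"] = str(out / "similarity_matrix.csv")

    if config.cadm_input == "sequence":
        cadm_matrices = list(gene_dms.values())
    else:
        cadm_matrices = [all_trees[g].patristic_matrix() for g in gene_dms]
    cadm = cadm_w(
        cadm_matrices,
        permutations=config.cadm_permutations,
        seed=rng_seed.spawn(1)[0] if config.cadm_permutations else None,
    )
    with open(out / "cadm.json", "w") as fh:
        json.dump({"w": cadm.w, "p_value": cadm.p_value}, fh, indent=1)
    files["cadm"] = str(out / "cadm.json")

    tspace = tree_space_embed(all_trees, method=config.mds_method)
    tspace.to_csv(out / "tree_space.csv", out / "tree_space_stress.json")
    files["tree_space"] = str(out / "tree_space.csv")

    sspace = strain_space_embed(te_tree, method=config.mds_method)
    sspace.to_csv(out / "strain_space.csv", out / "strain_space_stress.json")
    files["strain_space"] = str(out / "strain_space.csv")
    return sim, cadm, tspace, sspace
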