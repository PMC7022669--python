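"""From a VCF variant table to per-gene alignments and sequence distances.

The pipeline's data-processing stage: read the SNP records overlapping each
gene region, collapse genotypes to one allele per strain, turn the records
into a strains x polymorphic-sites character alignment, concatenate the
per-gene alignments into a total-evidence supermatrix, and compute pairwise
sequence distances.

Conventions (the input panel is near-homozygous, so these are deliberately
simple and deterministic):

* Only single-nucleotide substitutions are used; indels and multi-nucleotide
  variants are excluded.
* Diploid genotypes are collapsed to their first allele; heterozygous calls
  are counted and logged.
* Missing genotypes become ``N`` and are pairwise-deleted in distances.
* Coordinates are 1-based inclusive, as in the VCF standard.
"""

from __future__ import annotations

import dataclasses
import logging
import os
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam

from .treeio import DistanceMatrix

__all__ = [
    "MISSING",
    "VariantRecord",
    "GeneRegion",
    "Alignment",
    "read_gene_regions",
    "read_variants",
    "variants_to_alignment",
    "concatenate",
    "p_distance_matrix",
    "jc_distance_matrix",
]

logger = logging.getLogger(__name__)

#: Sentinel for a missing genotype call.
MISSING = None

_BASES = frozenset("ACGT")


@dataclasses.dataclass(frozen=True)
class VariantRecord:
    """One bi- or multi-allelic SNP with per-strain allele indices.

    ``genotypes`` holds, per strain (in the caller-supplied order), the index
    of the called allele: 0 for the reference allele, ``k`` for
    ``alt_alleles[k-1]``, or :data:`MISSING`.
    """

    chrom: str
    pos: int  # 1-based
    ref_allele: str
    alt_alleles: tuple
    genotypes: tuple

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.ref_allele not in _BASES:
            raise ValueError(f"reference allele must be one of ACGT, got {self.ref_allele!r}")
        n_alleles = 1 + len(self.alt_alleles)
        for g in self.genotypes:
            if g is not MISSING and not (0 <= g < n_alleles):
                raise ValueError(f"allele index {g} out of range for {n_alleles} alleles")

    def allele_char(self, strain_index: int) -> str:
        g = self.genotypes[strain_index]
        if g is MISSING:
            return "N"
        return self.ref_allele if g == 0 else self.alt_alleles[g - 1]


@dataclasses.dataclass(frozen=True)
class GeneRegion:
    """A named 1-based inclusive genomic interval."""

    name: str
    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"region {self.name}: start {self.start} > end {self.end}")
        if self.start < 1:
            raise ValueError(f"region {self.name}: start must be >= 1")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def read_gene_regions(path) -> list[GeneRegion]:
    """Read gene regions from a 4-column TSV (name, chrom, start, end) or BED.

    BED files (detected by the ``.bed`` extension) use half-open 0-based
    coordinates and the column order chrom, start, end, name; they are
    converted to 1-based inclusive internally.
    """
    is_bed = str(path).lower().endswith(".bed")
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    regions = []
    for row in df.itertuples(index=False):
        if is_bed:
            chrom, start, end = row[0], int(row[1]) + 1, int(row[2])
            name = row[3] if len(row) > 3 else f"{chrom}:{start}-{end}"
        else:
            name, chrom, start, end = row[0], row[1], int(row[2]), int(row[3])
        regions.append(GeneRegion(name=name, chrom=chrom, start=start, end=end))
    names = [r.name for r in regions]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate region names: {dupes}")
    return regions


def _is_snp(ref: str, alts: tuple | None) -> bool:
    if ref is None or len(ref) != 1 or ref.upper() not in _BASES:
        return False
    if not alts:
        return False
    return all(a is not None and len(a) == 1 and a.upper() in _BASES for a in alts)


def read_variants(vcf_source, region: GeneRegion, strains: Sequence[str]) -> list[VariantRecord]:
    """Read the SNP records of one gene region for the requested strains.

    ``vcf_source`` is a path to a VCF (plain or bgzipped) or an open
    :class:`pysam.VariantFile`.  Records are returned in ascending position
    order; indels and multi-nucleotide variants are excluded.  Diploid
    genotypes are collapsed to their first allele (heterozygous calls are
    counted and logged); unreadable genotypes become :data:`MISSING`.
    """
    close = False
    if isinstance(vcf_source, (str, os.PathLike)):
        vcf = pysam.VariantFile(str(vcf_source))
        close = True
    else:
        vcf = vcf_source
    try:
        samples = list(vcf.header.samples)
        absent = [s for s in strains if s not in samples]
        if absent:
            raise ValueError(f"strains absent from VCF header: {absent}")
        records = []
        het = 0
        for rec in vcf.fetch() if vcf.index is not None else vcf:
            if rec.chrom != region.chrom or not (region.start <= rec.pos <= region.end):
                continue
            if not _is_snp(rec.ref, rec.alts):
                continue
            genotypes = []
            for s in strains:
                gt = rec.samples[s].get("GT")
                if not gt or gt[0] is None:
                    genotypes.append(MISSING)
                    continue
                if len(set(a for a in gt if a is not None)) > 1:
                    het += 1
                genotypes.append(int(gt[0]))
            records.append(
                VariantRecord(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref_allele=rec.ref.upper(),
                    alt_alleles=tuple(a.upper() for a in rec.alts),
                    genotypes=tuple(genotypes),
                )
            )
        if het:
            logger.info(
                "region %s: collapsed %d heterozygous calls to their first allele",
                region.name,
                het,
            )
        records.sort(key=lambda r: r.pos)
        return records
    finally:
        if close:
            vcf.close()


@dataclasses.dataclass
class Alignment:
    """Strains x sites character matrix over {A, C, G, T, N}.

    ``site_meta`` records, per column, the gene name, chromosome, and 1-based
    position the column came from; columns are ordered by (gene order, then
    position).
    """

    labels: tuple
    sites: np.ndarray  # (n_strains, n_sites) of single characters
    site_meta: pd.DataFrame

    def __post_init__(self):
        self.labels = tuple(self.labels)
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("alignment labels must be unique")
        self.sites = np.asarray(self.sites, dtype="U1")
        if self.sites.ndim != 2 or self.sites.shape[0] != len(self.labels):
            raise ValueError("sites must be (n_strains, n_sites)")
        if len(self.site_meta) != self.sites.shape[1]:
            raise ValueError("site_meta must have one row per column")

    @property
    def n_strains(self) -> int:
        return len(self.labels)

    @property
    def n_sites(self) -> int:
        return self.sites.shape[1]

    def row(self, label: str) -> str:
        return "".join(self.sites[self.labels.index(label)])

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for i, label in enumerate(self.labels):
                fh.write(f">{label}\n")
                seq = "".join(self.sites[i])
                for k in range(0, len(seq), 60):
                    fh.write(seq[k : k + 60] + "\n")

    @classmethod
    def from_fasta(cls, path, gene: str = "") -> "Alignment":
        from Bio import SeqIO

        labels, rows = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            labels.append(rec.id)
            rows.append(list(str(rec.seq).upper()))
        if not labels:
            raise ValueError(f"no sequences in {path}")
        sites = np.asarray(rows, dtype="U1")
        meta = pd.DataFrame(
            {"gene": gene, "chrom": "", "pos": np.arange(1, sites.shape[1] + 1)}
        )
        return cls(tuple(labels), sites, meta)

    def write_site_meta(self, path) -> None:
        out = self.site_meta.copy()
        out.insert(0, "column", np.arange(len(out)))
        out.to_csv(path, sep="\t", index=False)


def variants_to_alignment(
    records: Iterable[VariantRecord],
    strains: Sequence[str],
    drop_monomorphic: bool = True,
    gene: str = "",
) -> Alignment:
    """Build a character alignment from position-sorted SNP records.

    Each retained record becomes one column; a strain's cell is the allele
    character implied by its allele index, with missing calls as ``N``.  With
    ``drop_monomorphic`` (the default, matching a polymorphic-sites-only
    analysis), columns whose non-``N`` characters are all identical are
    removed.  An empty record list yields a zero-column alignment.
    """
    records = list(records)
    n = len(strains)
    cols, meta = [], []
    for rec in records:
        if len(rec.genotypes) != n:
            raise ValueError(
                f"record at {rec.chrom}:{rec.pos} has {len(rec.genotypes)} genotypes "
                f"for {n} strains"
            )
        col = np.array([rec.allele_char(i) for i in range(n)], dtype="U1")
        if drop_monomorphic:
            observed = set(col) - {"N"}
            if len(observed) < 2:
                continue
        cols.append(col)
        meta.append((gene, rec.chrom, rec.pos))
    sites = (
        np.stack(cols, axis=1) if cols else np.empty((n, 0), dtype="U1")
    )
    meta_df = pd.DataFrame(meta, columns=["gene", "chrom", "pos"])
    return Alignment(tuple(strains), sites, meta_df)


def concatenate(alignments: Sequence[Alignment]) -> Alignment:
    """Concatenate gene alignments into a total-evidence supermatrix.

    All inputs must share the same strain set; rows are matched by label (not
    by row position), and ``site_meta`` is preserved in input order.
    """
    alignments = list(alignments)
    if not alignments:
        raise ValueError("need at least one alignment")
    first = alignments[0]
    ref_set = set(first.labels)
    for aln in alignments[1:]:
        if set(aln.labels) != ref_set:
            raise ValueError(
                "alignments must share one strain set; difference: "
                f"{sorted(set(aln.labels) ^ ref_set)}"
            )
    blocks = []
    for aln in alignments:
        order = [aln.labels.index(l) for l in first.labels]
        blocks.append(aln.sites[order])
    sites = np.concatenate(blocks, axis=1)
    meta = pd.concat([a.site_meta for a in alignments], ignore_index=True)
    return Alignment(first.labels, sites, meta)


def p_distance_matrix(aln: Alignment) -> DistanceMatrix:
    """Pairwise p-distances with pairwise deletion of ``N`` sites.

    Entry (i, j) is the fraction of sites, among those where both strains have
    a called base, at which the two strains differ.  A pair with no comparable
    sites is an error.
    """
    if aln.n_strains < 2:
        raise ValueError("need at least 2 strains")
    if aln.n_sites < 1:
        raise ValueError("need at least 1 site")
    called = aln.sites != "N"
    n = aln.n_strains
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = called[i] & called[j]
            comparable = int(both.sum())
            if comparable == 0:
                raise ValueError(
                    f"no comparable sites for pair ({aln.labels[i]!r}, {aln.labels[j]!r})"
                )
            diffs = int((aln.sites[i][both] != aln.sites[j][both]).sum())
            out[i, j] = out[j, i] = diffs / comparable
    return DistanceMatrix(aln.labels, out)


def jc_distance_matrix(aln: Alignment) -> DistanceMatrix:
    """Jukes-Cantor-corrected distances, ``-3/4 ln(1 - 4p/3)``.

    Inverts the expected relationship between the raw mismatch fraction and
    substitutions per site under the one-parameter substitution model, so the
    result is additive in expectation.  Saturated pairs (p >= 3/4) are an
    error.
    """
    p = p_distance_matrix(aln)
    arg = 1.0 - 4.0 * p.values / 3.0
    if np.any(arg <= 0):
        i, j = np.argwhere(arg <= 0)[0]
        raise ValueError(
            f"pair ({p.labels[i]!r}, {p.labels[j]!r}) is saturated "
            "(p-distance >= 0.75); JC correction undefined"
        )
    d = -0.75 * np.log(arg)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(p.labels, d)
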