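# Methods

This note documents the models, statistics, and numerical choices behind
`phylocompare`, and what the synthetic benchmark does and does not establish.

## Topology statistics

All topology comparisons operate on **unrooted** trees; rooted inputs are
unrooted first (a bifurcating root is merged away). The unit of comparison is
the non-trivial bipartition: the two-way split of the tip set induced by an
internal edge, canonically oriented so that the side containing the
lexicographically smallest label comes first. Polytomies are legal
everywhere and simply contribute fewer bipartitions; after pruning, a
restricted tree may be unresolved, and the PC denominator deliberately stays
`2m − 6` so cells remain comparable across clades.

- `RF(T1, T2) = |B(T1) Δ B(T2)|`, the bipartition symmetric difference.
- `PC = 100 · (1 − RF/(2m − 6))`, computed in exact rational arithmetic
  before conversion to float, so `PC + 100·RF/(2m−6) = 100` holds exactly.
  `PC` is undefined for `m < 4` (the normalizer vanishes); clade-table cells
  for clades with fewer than four tips are reported as NaN rather than 0 or
  100.
- For `m = 4` there are only three unrooted binary topologies, each with one
  split, so PC is exactly 0 or 100. Four-strain "representative" comparisons
  are therefore binary, and a random topology matches by chance with
  probability 1/3. The topology counts `(2m−5)!!` (unrooted) and `(2m−3)!!`
  (rooted) quantify this small-m bias; an exhaustive insertion-order
  enumerator double-checks them for `m ≤ 7`.

## Distance-based inference

`neighbor_joining` implements the classical agglomeration: join the pair
minimizing `Q(i,j) = (r−2)·d(i,j) − Σk d(i,k) − Σk d(j,k)`; branch lengths
`b_i = d(i,j)/2 + (S_i − S_j)/(2(r−2))`; reduction
`d(u,k) = (d(i,k)+d(j,k)−d(i,j))/2`. `bionj` uses the same pair selection but
tracks a variance matrix `V` (initialized to `D`) and mixes the joined rows
with `λ = 1/2 + Σk(v(j,k)−v(i,k)) / (2(r−2)·v(i,j))`, clamped to `[0,1]`,
with `λ = 1/2` when `v(i,j) = 0` or three taxa remain:

```
d(u,k) = λ d(i,k) + (1−λ) d(j,k) − λ b_i − (1−λ) b_j
v(u,k) = λ v(i,k) + (1−λ) v(j,k) − λ(1−λ) v(i,j)
```

Numerical choices, all in the name of bit-reproducibility:

- Q-ties are broken by the smallest `(row, column)` pair under the current
  ordering (NumPy's first-minimum scan), so fully tied matrices produce a
  deterministic topology with zero-length internal branches.
- Negative branch lengths are clamped to zero after the full agglomeration
  (the raw values are used inside the reduction); the clamped deficit is
  logged.
- Both methods are consistent: the test suite verifies exact topology
  recovery from tree-additive matrices over hundreds of random trees.

### Distance model

The default sequence distance is the **p-distance** with pairwise deletion of
`N` sites. A Jukes–Cantor correction (`−3/4 ln(1 − 4p/3)`) is available
(`distance_model: jc`), but note that on polymorphic-sites-only alignments
the mismatch fraction is inflated by the discarded invariant sites and can
exceed 3/4 in small panels, where the correction is undefined (it raises a
clear error rather than guessing). Since dropping invariant sites scales all
pairwise p-distances by a common factor when missing data are rare, and NJ
topology is invariant to uniform scaling, the p-distance default loses
essentially nothing at the topology level.

## CADM

Kendall's coefficient of concordance over the `p` matrices' strict upper
triangles (`N = n(n−1)/2` entries each), rank-transformed per matrix with
average ranks for ties:

```
W = 12·S / (p²(N³−N) − p·ΣT),   S = Σi (Ri − R̄)²,   T = Σgroups (t³ − t)
```

If every matrix is fully tied the denominator vanishes and `W = 1` is
returned (any ranking is trivially concordant). The optional permutation test
independently permutes the labels of every matrix except the first and
reports `(1 + #{W* ≥ W})/(1 + nperm)`. By default the pipeline feeds CADM the
per-gene *sequence* distance matrices (what the gene trees are built from);
`cadm_input: patristic` switches to patristic distances from the inferred
gene trees. The implementation is verified against R's `ape::CADM.global` in
the test suite.

## Embeddings

Tree space: classical (Torgerson) MDS on the pairwise RF matrix —
double-centering, top-two eigenvectors scaled by the root eigenvalues, with a
deterministic sign convention (the largest-magnitude coordinate on each axis
is positive). `method="smacof"` refines the configuration by Guttman-majorization
iterations started from the classical solution; both flavors are exactly
reproducible given the same inputs, with no random initialization. Kruskal
stress-1 is reported. Strain space: the same machinery on the patristic
matrix of a single tree.

## Synthetic benchmark

The generator emulates a clade-structured population panel:

| parameter | default | meaning |
|---|---|---|
| `n_clades`, `clade_sizes` | 5 × 20 | monophyletic clades on a random binary backbone |
| `between_depth` | 1.0 | backbone branch lengths (× U(0.5, 1.5) jitter), substitutions-per-site units via μ |
| `within_depth` | 0.1 | within-clade branch lengths (same jitter) |
| `n_genes`, `L` | 10 × 5000 | genes and sites per gene |
| `mu` | 0.03 | substitution rate per site per unit branch length |
| `discordance` | 0 | NNI moves applied per gene tree |
| branch jitter | lognormal σ = 0.1 | per-gene branch-length noise |

With these defaults, cross-clade divergence is ≈ 0.2 substitutions per site
and roughly half the sites per gene are polymorphic across 100 strains —
deep-but-unsaturated structure comparable to a worldwide microbial panel.
Discordance is modeled by NNI moves rather than coalescent simulation
because each move displaces exactly one bipartition, giving direct, countable
control of the RF displacement that the comparison statistics are supposed
to detect; successive moves may cancel, so RF grows with the move count in
expectation, not deterministically. Sequences evolve under plain JC69 (no
rate heterogeneity, no indels, no recombination), the simplest model with a
closed-form p-distance expectation to test against. The VCF writer emits
each polymorphic column as a homozygous-diploid SNP record (reference allele
= major allele, ties broken alphabetically), so the variants module can be
round-trip-tested exactly.

What passing on this benchmark shows: the pipeline's statistics respond
correctly to known topological signal and noise. What it does not show:
robustness to recombination within genes, rate heterogeneity,
hybridization/introgression, heterozygosity, alignment error, or reference
bias — none of which the generator produces.

All randomness flows from one master seed through spawned NumPy seed
streams, so every artifact (VCF bytes included) is reproducible.

## Pipeline behavior

- Strain-set mismatches between the VCF and a reference tree are a hard
  error; `intersect: true` opts into comparing on the shared strains, with
  the dropped strains logged and recorded in the report — the same remedy a
  real analysis applies when one strain is absent from a reference panel.
- Gene order is the regions-file order; it affects only site metadata, not
  distances.
- Per-stage counts (records read, sites retained, heterozygous calls
  collapsed, clamped branch lengths) go to the standard `logging` stream.

## Problem sizes used in the checks

The acceptance-level tests run the full pipeline at 100 strains × 10 genes ×
5000 sites over five seeds (total-evidence recovery, representative-strain
subsets, OUT control), 500 random tree pairs for the RF oracle, 100 random
additive matrices for NJ/BIONJ consistency, 200 seeds for the discordance
response of PC, and 4-clade/16-strain panels for the CADM discordance
response — sizes chosen so the whole suite completes in a couple of minutes
while keeping every statistical margin wide.

## Known limitations

- Newick dialect: branch lengths and quoted labels are supported; internal
  node labels are parsed and discarded; NEXUS/PhyloXML are out of scope.
- The Newick parser keeps unquoted underscores literal (no space
  conversion), because tip labels must match VCF sample names exactly.
- `restrict` requires at least three kept tips; PC additionally needs four.
- CADM's permutation test permutes whole label sets; it does not implement
  the a-posteriori single-matrix tests.
- The MDS stress reported is stress-1 on raw dissimilarities (no monotone
  regression); the embedding is metric, not non-metric.
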