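# Methods

## Overview

`rps3kit` quantifies microbial community structure in assembled
metagenomes from a single-copy marker gene (ribosomal protein S3). The
unit of analysis is the *sequence cluster* — marker protein sequences at
≥99% identity — treated as a species-level organism proxy. Abundance is
the average read coverage of the marker-bearing scaffold region, which
assumes reads map approximately uniformly and that a scaffold's coverage
scales with its organism's abundance. Community comparisons then operate
on the cluster × site abundance matrix.

## Stages, parameters, and conventions

### Hit screening

Per-domain tabular hit files are screened with per-model bit-score minima
(user input; cutoff validation is an upstream curation task) and an
e-value ceiling of 1e-5. Score comparison is `>=` (cutoffs are minima);
the screening e-value test is inclusive (`<=`), while the best-hit
taxonomy step uses the strict `< 1e-5` convention. Taxonomy ranks
candidate hits by bit score by default (e-value available via
`rank_by="evalue"`); ties fall to the lower e-value, then to the earlier
row. Envelope coordinates define the gene span used later for flank
trimming.

### Alignment quality control

Columns with gap fraction strictly greater than 0.95 are removed; a
column exactly at 0.95 stays. Sequences with fewer than
`T = floor(0.5 · N)` non-gap positions are then dropped, where `N` is the
non-gap count of the longest **non-reference** sequence (with `N = 206`,
`T = 103`). Reference sequences — rows whose ids carry a configurable
prefix, default `REF|` — exist only to anchor the alignment: they are
exempt from removal, excluded from `N`, and dropped before clustering.
An alternative reading of the 50% rule ("half of the retained columns")
coincides with ours only when the longest sequence spans every retained
column; we use the longest-sequence reading because it reproduces the
206 → 103 arithmetic exactly. Gap characters are `-` and `.`;
residues are case-insensitive.

### Identity clustering

Greedy centroid clustering processes sequences in decreasing length order
(ties by input order). A sequence joins a centroid when identity ≥ 0.99,
query coverage ≥ 1.0 and target coverage ≥ 0.5; in the default exhaustive
mode (the analogue of unlimited accept/reject attempts in heuristic
clustering tools) all centroids are scored and the best identity wins,
ties to the earlier-created centroid. Identity is defined from an optimal
global alignment with free end gaps under unit scoring (match +1,
mismatch 0, gap −1 — the scoring only chooses the alignment):
matches / alignment columns excluding terminal-gap columns. Coverage of
each sequence is the fraction of its residues inside that core region, so
an exact substring has identity 1.0 and coverage = window/length. This
definition is deterministic and library-independent; heuristic tools'
internal definitions may differ by a fraction of a percent, which the
99% threshold tolerates in practice. The representative of a cluster is
its longest member (ties to earlier input).

### Coverage quantification

Scaffolds (only those > 1 kbp) are trimmed to windows of 2000 bp flanking
the gene; if the window would be shorter than 1000 bp the whole scaffold
is kept. Coordinates are 1-based inclusive throughout. Depth is counted
from primary, mapped SAM records only (no MAPQ filter), through
match/mismatch CIGAR operations; deletions and reference skips advance
the reference without contributing depth. Average coverage is total depth
/ region length; breadth is the fraction of positions with depth ≥ 1.

**Breadth-cutoff calibration.** Every cluster is genuinely present in at
least the sample its scaffold was assembled from, so scanning cutoffs
over the grid 0.1, 0.11, …, 1.0 (step 0.01 — the two-decimal grid implied
by published cutoffs such as 0.72), the chosen cutoff is the *maximal*
grid value at which every cluster retains at least one record with
breadth ≥ cutoff. Retention is monotone in the cutoff, so this is the
stringency just before the first cluster would be lost; any lower value
also retains all clusters, which is why a literal "lowest retaining
value" is not operational. Records below the cutoff have their coverage
zeroed (presumed cross-sample mapping noise) but are kept as true zeros.

Cluster abundance in a sample is the **sum** of its member scaffolds'
(cutoff-applied) coverage: when a taxon carries near-identical gene
copies on separate scaffolds, reads split between them and summation
conserves the total. Columns are then scaled by
`bp_largest_library / bp_sample` and replicate extractions averaged
(zeros included) into site-level values.

### Ecological statistics

* **Bray–Curtis** `d(i,j) = Σ|x_i − x_j| / Σ(x_i + x_j)`; an all-zero
  pair is defined as distance 0 with a warning.
* **UniFrac** on a rooted tree with cluster-labelled leaves. Unweighted:
  branch length unique to either community / branch length covered by
  either. Weighted raw: `Σ_b l_b·|p_A(b) − p_B(b)|` with `p` the
  descendant relative-abundance fraction; the normalized variant (the
  default) divides by `Σ_b l_b·(p_A + p_B)`, the value attained by fully
  disjoint communities. Abundances may be non-integer (coverage values).
  The root branch is excluded.
* **PCoA**: Gower double centering and symmetric eigendecomposition;
  coordinates are eigenvectors × √eigenvalue; negative eigenvalues (from
  non-Euclidean dissimilarities) are reported, never silently dropped;
  their axes get zero coordinates.
* **NMDS**: SMACOF with monotone regression minimizing Kruskal stress-1,
  best of a PCoA initialization plus seeded random restarts;
  deterministic given the seed; convergence flagged.
* **BIOENV**: variables standardized (ddof = 1), constant variables
  excluded with a warning; every non-empty subset up to the size cap is
  scored by correlating (Pearson default, Spearman available) the
  Euclidean distances of the standardized subset with the community
  dissimilarities over the lower triangle. Exhaustive enumeration is the
  default at this scale; a best-first forward-stepwise mode exists for
  many variables. Pearson vs Spearman is a config choice because both
  conventions are in circulation for this procedure; neither is forced.
* **Mantel**: correlation of lower triangles; p-value by label
  permutations of the second matrix, one-sided (greater), add-one
  convention `p = (1 + #{r_perm ≥ r_obs})/(1 + n_perm)` — never exactly
  zero; 999 permutations by default; seeded.
* **Covariate statistics**: Pearson r with two-sided parametric p, and
  OLS slope/intercept/r² of group abundance on a covariate (depth or
  distance). Constant inputs are rejected.

## The synthetic transect generator

The generator emulates the targeted field design: `n_sites` hillslope
positions with distance-to-river decreasing downslope, each cored at
several depths; every (position, depth) *site* has two replicate samples,
and the deepest site nearest the river has three. Taxon log-abundance is

    log a_t(s) = base_t + β_depth,t · z_depth(s) + β_dist,t · z_dist(s) + ε_ts

softmax-normalized per sample (`z` are max-normalized depth and
distance). Defaults: 20 taxa, baseline `base_t ~ N(0, 2²)` — a steep,
soil-like rank-abundance distribution spanning several orders of
magnitude, which also places the breadth calibration in its intended
regime (the weakest cluster detectable in only part of its range rather
than everywhere); 25% of taxa form a depth-trending group with
β_depth = +3 (the analogue of candidate-phyla enrichment at depth);
other coefficients `~ N(0, 1)`; per-observation noise σ = 0.3.

Markers derive from one random 217-aa ancestor by seeded point
substitution: between-taxon identity is forced ≤ 0.97 (verified pair by
pair), and ~30% of taxa get a second gene copy differing by exactly one
residue (≈99.5% identity) on a second scaffold, so clustering must merge
copies without merging taxa. Genes are reverse-translated with a fixed
codon per amino acid and embedded in uniform-random scaffolds
(2.5–4 kbp). Single-end 150 bp reads are placed uniformly with Poisson
counts targeting `mean_depth × n_taxa × a_ts × depth_factor_s / copies`
expected coverage (so the average taxon sits near `mean_depth`, default
20×); per-sample depth factors vary 0.7–1.3× to exercise library-size
normalization. Hit tables carry one qualifying hit per gene plus
configurable decoys that fail the score or e-value screen by
construction.

Geochemistry: the driving variables are a deterministic function of the
latent community structure — a metric-SMACOF Euclidean embedding of the
true-abundance Bray–Curtis matrix, rotated (distance-preservingly) so
each variable carries an equal share of variance; BIOENV's internal
standardization therefore keeps the between-sample geometry intact, and
at zero noise the generating subset is recovered with correlation
> 0.99. Gaussian noise is added as a fraction (default 10%) of each
variable's signal standard deviation; remaining variables are independent
noise. All randomness flows from one root seed through named substreams
(transect, genomes, reads, hits, geochem), so stages are independently
reproducible.

**What the generator does not emulate**: read errors and quality scores,
paired-end structure, assembly fragmentation and chimeras, ambiguous
mapping between near-identical references (reads are split
deterministically in expectation rather than by a mapper's tie-breaking),
alignment uncertainty (the bundled aligner is gapless, valid only for
substitution-derived markers), and real geochemical covariance. Passing
the recovery suites therefore demonstrates correctness of the pipeline's
computations and calibrations under the stated statistical model, not
robustness to assembly or mapping artifacts in field data.

## Problem sizes

The test and acceptance runs use desk-scale sizes chosen as the package's
default study conditions: 12 sites / 25 samples / 20 taxa / 20× depth
(~8,000 reads per sample), clustering constructions with ~18–50 ancestors
and ≤ 40–60 sequences for oracle comparisons, 8-leaf trees for UniFrac
oracles, ≤ 5 variables for exhaustive BIOENV checks, and 500 seeded
repeats for Mantel type-I calibration. Dataset-scale figures from deep
field sequencing (thousands of clusters from hundreds of Gbp) are not
reproducible from synthetic desk-scale data and are not targets of the
test suite.

## Numerical choices and degenerate inputs

Threshold comparisons on exact rational identities use a 1e-9 slack;
breadth-grid arithmetic is rounded to 10 decimals to avoid float-grid
drift. If the weakest cluster's best breadth falls below the grid
minimum, the calibration returns the grid minimum with a warning rather
than failing. Pairwise-identity with an empty core region returns 0.
Empty alignments, constant covariates, unmapped replicate samples,
unknown models, and label mismatches raise typed errors
(`InputError` / `ParseError` / `ConfigError`) naming the offender.
Outputs carry a config hash (excluding the output directory) and the
root seed in a header comment; reruns with the same configuration are
byte-identical.

## Known limitations

* The identity definition approximates, but is not bit-for-bit identical
  to, heuristic clustering tools; at the 99% threshold and desk scale the
  partition agrees with the exhaustive reference by construction tests.
* Exhaustive centroid search is quadratic; it is meant for marker-scale
  inputs (10³–10⁴ sequences), not whole-proteome clustering.
* BAM/CRAM are not read directly; SAM text suffices at this scale (the
  reader is a thin layer over pysam, so extension is straightforward).
* The breadth calibration assumes every cluster is present somewhere; a
  cluster absent from all samples (possible with externally supplied
  inputs) is a precondition violation and raises an error naming it.
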