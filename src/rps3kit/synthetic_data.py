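"""Synthetic hillslope-transect generator with known ground truth.

Emulates the sampling design the pipeline targets: several positions along
a hillslope (decreasing distance to the river downslope), each cored at
several depths; every (position, depth) combination is a *site* with two
replicate DNA extractions (one site gets three). Taxon log-abundance
follows a depth/distance gradient model,

    log a_t(s) = base_t + beta_depth_t * z_depth(s)
               + beta_dist_t * z_dist(s) + eps_ts,

softmax-normalized per sample, with a designated subset of taxa given a
strong positive depth response so depth-trending groups exist by
construction. Each taxon carries one marker gene embedded in a random
scaffold (some taxa get a second, nearly identical gene copy on a second
scaffold to exercise clustering); single-end reads are placed uniformly on
the scaffolds at depths proportional to abundance; hit tables, a taxonomy
table, a coalescent tree over taxa, and a geochemistry table (of which a
known subset of variables drives community dissimilarity) complete the
scenario.

All randomness flows from one root seed through named substreams
(transect, genomes, reads, hits, geochem) so stages are independently
reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
from sklearn.manifold import smacof

from . import ecology
from .align_qc import MultipleAlignment
from .errors import InputError
from .quant import TrimmedScaffold

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: One fixed codon per amino acid, so protein identity levels carry over
#: to the embedded nucleotide genes.
CODON_OF = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT",
    "M": "ATG", "N": "AAT", "P": "CCT", "Q": "CAA", "R": "CGT",
    "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT",
}

PHYLA = (
    "Acidobacteria", "Actinobacteria", "Chloroflexi", "Proteobacteria",
    "Verrucomicrobia", "Gemmatimonadetes", "Bacteroidetes", "Nitrospirae",
)

#: Geochemistry-flavoured variable names; the first ones become the
#: community-driving subset.
GEOCHEM_NAMES = (
    "moisture", "Na", "Se", "Zn", "Ca", "Fe", "K", "Mg",
    "Mn", "pH", "S", "Cu", "Ni", "P", "Al", "B",
)

_SUBSTREAMS = ("transect", "genomes", "reads", "hits", "geochem")


def _substream(seed: int, name: str) -> np.random.Generator:
    idx = _SUBSTREAMS.index(name)
    root = np.random.SeedSequence(seed)
    return np.random.default_rng(root.spawn(len(_SUBSTREAMS))[idx])


@dataclass
class TaxonInfo:
    taxon_id: str
    phylum: str
    beta_depth: float
    beta_dist: float


@dataclass
class SiteInfo:
    site_id: str
    depth_cm: float
    distance_to_river_m: float


@dataclass
class TransectTruth:
    """Ground truth for one synthetic scenario."""

    sites: list[SiteInfo]
    taxa: list[TaxonInfo]
    samples: list[str]
    replicate_map: dict[str, str]
    true_abundance: pd.DataFrame  # taxa x samples, columns sum to 1
    depth_trending: list[str]
    sample_depth_factor: dict[str, float]
    library_bp: dict[str, int]
    driving_env_subset: list[str]
    seed: int

    def site_of(self, sample: str) -> SiteInfo:
        sid = self.replicate_map[sample]
        return next(s for s in self.sites if s.site_id == sid)


def simulate_transect(
    n_sites: int = 4,
    depths_per_site: Sequence[float] = (10.0, 60.0, 120.0),
    n_taxa: int = 20,
    seed: int = 0,
    trending_fraction: float = 0.25,
    beta_depth_trend: float = 3.0,
    beta_sd: float = 1.0,
    base_sd: float = 2.0,
    noise_sd: float = 0.3,
    distance_range_m: tuple[float, float] = (20.0, 400.0),
    depth_factor_range: tuple[float, float] = (0.7, 1.3),
) -> TransectTruth:
    """Draw the transect layout, gradient model, and true abundances.

    ``n_sites`` hillslope positions (distance to the river decreasing
    downslope) x ``depths_per_site`` depths define the sites; every site
    has two replicate samples except the deepest site at the position
    closest to the river, which has three. Deterministic given ``seed``.
    """
    if n_taxa < 5:
        raise InputError("need at least 5 taxa")
    if n_sites < 2:
        raise InputError("need at least 2 hillslope positions")
    if not depths_per_site:
        raise InputError("need at least one depth")
    rng = _substream(seed, "transect")

    distances = np.linspace(distance_range_m[1], distance_range_m[0], n_sites)
    sites: list[SiteInfo] = []
    for p, dist in enumerate(distances):
        for depth in depths_per_site:
            sites.append(
                SiteInfo(f"P{p}D{int(depth)}", float(depth), float(dist))
            )
    extra_site = sites[-1].site_id  # deepest, closest to river: 3 replicates

    samples: list[str] = []
    replicate_map: dict[str, str] = {}
    for s in sites:
        n_rep = 3 if s.site_id == extra_site else 2
        for r in range(1, n_rep + 1):
            name = f"{s.site_id}R{r}"
            samples.append(name)
            replicate_map[name] = s.site_id

    n_trend = max(1, int(np.ceil(trending_fraction * n_taxa)))
    taxa: list[TaxonInfo] = []
    for t in range(n_taxa):
        tid = f"taxon{t:03d}"
        if t < n_trend:
            taxa.append(TaxonInfo(tid, "CandidatePhylum", beta_depth_trend, 0.0))
        else:
            taxa.append(
                TaxonInfo(
                    tid,
                    PHYLA[t % len(PHYLA)],
                    float(rng.normal(0, beta_sd)),
                    float(rng.normal(0, beta_sd)),
                )
            )

    max_depth = max(s.depth_cm for s in sites)
    max_dist = max(s.distance_to_river_m for s in sites)
    base = rng.normal(0, base_sd, size=n_taxa)
    log_a = np.empty((n_taxa, len(samples)))
    for j, sample in enumerate(samples):
        site = next(s for s in sites if s.site_id == replicate_map[sample])
        zd = site.depth_cm / max_depth
        zx = site.distance_to_river_m / max_dist
        for i, tx in enumerate(taxa):
            log_a[i, j] = (
                base[i]
                + tx.beta_depth * zd
                + tx.beta_dist * zx
                + rng.normal(0, noise_sd)
            )
    a = np.exp(log_a - log_a.max(axis=0, keepdims=True))
    a /= a.sum(axis=0, keepdims=True)
    abundance = pd.DataFrame(a, index=[t.taxon_id for t in taxa], columns=samples)

    factors = rng.uniform(*depth_factor_range, size=len(samples))
    return TransectTruth(
        sites=sites,
        taxa=taxa,
        samples=samples,
        replicate_map=replicate_map,
        true_abundance=abundance,
        depth_trending=[t.taxon_id for t in taxa[:n_trend]],
        sample_depth_factor={s: float(f) for s, f in zip(samples, factors)},
        library_bp={},
        driving_env_subset=[],
        seed=seed,
    )


# ---------------------------------------------------------------------------
# genomes, markers, tree


@dataclass
class GenomeSet:
    """Emitted scaffolds, gene coordinates, marker proteins, and tree."""

    scaffolds: dict[str, str]  # scaffold id -> nucleotide sequence
    genes: pd.DataFrame  # gene_id, scaffold_id, start, end, strand, taxon_id
    markers: dict[str, str]  # gene id -> protein sequence
    tree_newick: str
    taxon_of_gene: dict[str, str]
    model_id: str = "rpS3"


def _mutate_protein(
    rng: np.random.Generator, protein: str, n_subs: int
) -> str:
    """Substitute exactly ``n_subs`` distinct positions with different residues."""
    seq = list(protein)
    positions = rng.choice(len(seq), size=n_subs, replace=False)
    for p in positions:
        choices = [a for a in AMINO_ACIDS if a != seq[p]]
        seq[p] = choices[rng.integers(len(choices))]
    return "".join(seq)


def _hamming_identity(a: str, b: str) -> float:
    assert len(a) == len(b)
    matches = sum(1 for x, y in zip(a, b) if x == y)
    return matches / len(a)


def _random_coalescent_newick(
    rng: np.random.Generator, leaves: Sequence[str]
) -> str:
    """Random binary coalescent over the leaves with positive branch lengths."""
    nodes = [(name, 0.0) for name in leaves]  # (newick, age)
    time = 0.0
    while len(nodes) > 1:
        k = len(nodes)
        time += float(rng.exponential(2.0 / (k * (k - 1))))
        i, j = sorted(rng.choice(k, size=2, replace=False))
        (nwk_j, age_j) = nodes.pop(j)
        (nwk_i, age_i) = nodes.pop(i)
        merged = (
            f"({nwk_i}:{time - age_i:.6f},{nwk_j}:{time - age_j:.6f})"
        )
        nodes.append((merged, time))
    return nodes[0][0] + ";"


def emit_genomes_and_tree(
    truth: TransectTruth,
    scaffold_len_range: tuple[int, int] = (2500, 4000),
    marker_len_aa: int = 217,
    copies_fraction: float = 0.3,
    max_between_identity: float = 0.97,
    divergence: float = 0.08,
    seed: int | None = None,
) -> GenomeSet:
    """Scaffolds with embedded marker genes, gene table, markers, and tree.

    Marker proteins derive from a shared random ancestor by seeded point
    mutation: between-taxon identity is forced to ``<= max_between_identity``
    (verified pair by pair, offenders re-mutated) and within-taxon duplicate
    copies differ by exactly one residue (identity ~99.5%). Each gene sits
    on its own scaffold of random sequence.
    """
    lo, hi = scaffold_len_range
    gene_nt = 3 * marker_len_aa
    if lo < max(1001, gene_nt + 2):
        raise InputError(
            f"scaffold length range too small to host the {gene_nt} nt gene "
            "on a > 1 kbp scaffold"
        )
    if hi > 50000 or lo > hi:
        raise InputError("scaffold length range must lie within [1001, 50000]")
    rng = _substream(seed if seed is not None else truth.seed, "genomes")

    ancestor = "".join(
        AMINO_ACIDS[i] for i in rng.integers(len(AMINO_ACIDS), size=marker_len_aa)
    )
    n_subs = max(1, int(round(divergence * marker_len_aa)))
    taxon_ids = [t.taxon_id for t in truth.taxa]
    proteins: dict[str, str] = {}
    for tid in taxon_ids:
        proteins[tid] = _mutate_protein(rng, ancestor, n_subs)
    # enforce the between-taxon identity ceiling
    for _round in range(200):
        violation = None
        for i, a in enumerate(taxon_ids):
            for b in taxon_ids[i + 1 :]:
                if _hamming_identity(proteins[a], proteins[b]) > max_between_identity:
                    violation = b
                    break
            if violation:
                break
        if violation is None:
            break
        proteins[violation] = _mutate_protein(rng, ancestor, n_subs)
    else:
        raise InputError(
            "could not satisfy the between-taxon identity ceiling; "
            "increase divergence or marker length"
        )

    n_copy_taxa = int(round(copies_fraction * len(taxon_ids)))
    copy_taxa = set(taxon_ids[:n_copy_taxa])

    scaffolds: dict[str, str] = {}
    markers: dict[str, str] = {}
    taxon_of_gene: dict[str, str] = {}
    gene_rows = []
    nt = np.array(list("ACGT"))
    for tid in taxon_ids:
        n_copies = 2 if tid in copy_taxa else 1
        for c in range(1, n_copies + 1):
            gene_id = f"{tid}_g{c}"
            protein = (
                proteins[tid] if c == 1 else _mutate_protein(rng, proteins[tid], 1)
            )
            markers[gene_id] = protein
            gene_seq = "".join(CODON_OF[a] for a in protein)
            L = int(rng.integers(lo, hi + 1))
            start = int(rng.integers(1, L - gene_nt + 1))
            scaffold_id = f"scf_{tid}_{c}"
            background = "".join(nt[rng.integers(4, size=L)])
            seq = (
                background[: start - 1] + gene_seq + background[start - 1 + gene_nt :]
            )
            scaffolds[scaffold_id] = seq
            taxon_of_gene[gene_id] = tid
            gene_rows.append(
                {
                    "gene_id": gene_id,
                    "scaffold_id": scaffold_id,
                    "start": start,
                    "end": start + gene_nt - 1,
                    "strand": "+",
                    "taxon_id": tid,
                }
            )

    newick = _random_coalescent_newick(rng, taxon_ids)
    return GenomeSet(
        scaffolds=scaffolds,
        genes=pd.DataFrame(gene_rows),
        markers=markers,
        tree_newick=newick,
        taxon_of_gene=taxon_of_gene,
    )


def trimmed_regions(genomes: GenomeSet, truth: TransectTruth, quant_cfg=None) -> list[TrimmedScaffold]:
    """Flank-trim every emitted scaffold around its gene (origin = peak sample)."""
    from .marker_screen import MarkerHit
    from .quant import QuantConfig, trim_to_flanks

    quant_cfg = quant_cfg or QuantConfig()
    regions = []
    for row in genomes.genes.itertuples(index=False):
        origin = truth.true_abundance.loc[row.taxon_id].idxmax()
        hit = MarkerHit(
            scaffold_id=row.scaffold_id,
            gene_id=row.gene_id,
            model_id=genomes.model_id,
            bit_score=999.0,
            e_value=1e-60,
            gene_start=int(row.start),
            gene_end=int(row.end),
            strand=row.strand,
            sample_of_origin=str(origin),
        )
        region = trim_to_flanks(
            (row.scaffold_id, genomes.scaffolds[row.scaffold_id]), hit, quant_cfg
        )
        if region is not None:
            regions.append(region)
    return regions


# ---------------------------------------------------------------------------
# reads


def emit_reads_sam(
    truth: TransectTruth,
    regions: Sequence[TrimmedScaffold],
    taxon_of_region: Mapping[str, str],
    out_dir: str | Path,
    mean_depth: float = 20.0,
    read_len: int = 150,
    seed: int | None = None,
) -> dict[str, Path]:
    """Write one single-end SAM per sample; reads placed uniformly.

    The expected coverage of a region belonging to taxon ``t`` in sample
    ``s`` is ``mean_depth * n_taxa * a_ts * depth_factor_s / n_copies_t``
    (so the average taxon at the average depth factor sits near
    ``mean_depth``, and multi-copy taxa split their reads across copies);
    realized read counts are Poisson. Updates ``truth.library_bp`` with
    the realized per-sample bp totals.
    """
    if mean_depth <= 0:
        raise InputError("mean_depth must be positive")
    rng = _substream(seed if seed is not None else truth.seed, "reads")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    copies_per_taxon: dict[str, int] = {}
    for r in regions:
        t = taxon_of_region[r.id]
        copies_per_taxon[t] = copies_per_taxon.get(t, 0) + 1

    n_taxa = len(truth.taxa)
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": r.id, "LN": r.length} for r in regions],
    }
    ref_index = {r.id: i for i, r in enumerate(regions)}
    sam_paths: dict[str, Path] = {}
    for sample in truth.samples:
        path = out_dir / f"{sample}.sam"
        total_bp = 0
        with pysam.AlignmentFile(str(path), "w", header=header) as sam:
            for r in regions:
                t = taxon_of_region[r.id]
                a = float(truth.true_abundance.loc[t, sample])
                cov = (
                    mean_depth
                    * n_taxa
                    * a
                    * truth.sample_depth_factor[sample]
                    / copies_per_taxon[t]
                )
                n_reads = int(rng.poisson(cov * r.length / read_len))
                if r.length < read_len:
                    n_reads = 0
                starts = rng.integers(0, r.length - read_len + 1, size=n_reads)
                for k, s0 in enumerate(sorted(starts.tolist())):
                    rec = pysam.AlignedSegment()
                    rec.query_name = f"{sample}:{r.id}:{k}"
                    rec.flag = 0
                    rec.reference_id = ref_index[r.id]
                    rec.reference_start = int(s0)
                    rec.mapping_quality = 60
                    rec.cigarstring = f"{read_len}M"
                    sam.write(rec)
                    total_bp += read_len
        truth.library_bp[sample] = total_bp
        sam_paths[sample] = path
    return sam_paths


# ---------------------------------------------------------------------------
# hit tables and taxonomy


def emit_hit_tables(
    truth: TransectTruth,
    genomes: GenomeSet,
    out_dir: str | Path,
    score_cutoff: float = 100.0,
    decoy_fraction: float = 0.0,
    seed: int | None = None,
) -> dict[str, Path]:
    """Per-origin-sample hmmsearch-style per-domain tables plus taxonomy TSVs.

    True hits score comfortably above ``score_cutoff`` with e-values far
    below 1e-5; decoys (``decoy_fraction`` of the true count, rounded) fail
    the score cutoff or the e-value ceiling by construction.
    """
    rng = _substream(seed if seed is not None else truth.seed, "hits")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    by_sample: dict[str, list] = {}
    for row in genomes.genes.itertuples(index=False):
        origin = str(truth.true_abundance.loc[row.taxon_id].idxmax())
        by_sample.setdefault(origin, []).append(row)

    def domtbl_line(
        target: str, model: str, evalue: float, score: float,
        start: int, end: int, scaffold: str,
    ) -> str:
        tlen = end - start + 1
        return (
            f"{target} - {tlen} {model} - 217 {evalue:.2g} {score:.1f} 0.1 "
            f"1 1 {evalue:.2g} {evalue:.2g} {score:.1f} 0.1 "
            f"1 217 1 217 {start} {end} 0.98 scaffold={scaffold} strand=+"
        )

    paths: dict[str, Path] = {}
    for sample, rows in by_sample.items():
        path = out_dir / f"{sample}.domtbl"
        lines = ["# synthetic per-domain hit table"]
        for row in rows:
            score = score_cutoff + 50 + float(rng.uniform(0, 100))
            evalue = 10 ** float(rng.uniform(-80, -40))
            lines.append(
                domtbl_line(
                    row.gene_id, genomes.model_id, evalue, score,
                    int(row.start), int(row.end), row.scaffold_id,
                )
            )
        n_decoys = int(round(decoy_fraction * len(rows)))
        for d in range(n_decoys):
            if rng.uniform() < 0.5:  # fails the score cutoff
                score = float(rng.uniform(5, score_cutoff * 0.5))
                evalue = 10 ** float(rng.uniform(-20, -10))
            else:  # fails the e-value ceiling
                score = score_cutoff + 20
                evalue = 10 ** float(rng.uniform(-4, -1))
            lines.append(
                domtbl_line(
                    f"decoy_{sample}_{d}", genomes.model_id, evalue, score,
                    100, 300, f"scf_decoy_{sample}_{d}",
                )
            )
        path.write_text("\n".join(lines) + "\n")
        paths[sample] = path

    # best-hit taxonomy for every gene, plus the subject lineage map
    besthit = out_dir / "besthits.tsv"
    lineages = out_dir / "lineages.tsv"
    with besthit.open("w") as bh, lineages.open("w") as ln:
        bh.write("query\tsubject\tbitscore\tevalue\n")
        ln.write("subject\tlineage\n")
        seen = set()
        for row in genomes.genes.itertuples(index=False):
            taxon = row.taxon_id
            phylum = next(t.phylum for t in truth.taxa if t.taxon_id == taxon)
            subject = f"db|{taxon}"
            bh.write(f"{row.gene_id}\t{subject}\t{300 + rng.uniform(0, 50):.1f}\t1e-30\n")
            if subject not in seen:
                seen.add(subject)
                ln.write(f"{subject}\tBacteria;{phylum};{taxon}\n")
    paths["besthits"] = besthit
    paths["lineages"] = lineages
    return paths


# ---------------------------------------------------------------------------
# geochemistry


def _equalize_variances(Y: np.ndarray, tol: float = 1e-10, max_sweeps: int = 200) -> np.ndarray:
    """Rotate columns of Y so all column variances are equal.

    Pairwise Jacobi-style rotations preserve row-wise Euclidean distances
    while driving the covariance diagonal to a common value.
    """
    Y = Y - Y.mean(axis=0, keepdims=True)
    m = Y.shape[1]
    if m < 2:
        return Y
    for _ in range(max_sweeps):
        C = np.cov(Y, rowvar=False)
        diag = np.diag(C)
        if diag.max() - diag.min() <= tol * max(diag.max(), 1e-30):
            break
        i = int(np.argmax(diag))
        j = int(np.argmin(diag))
        a, b, c = C[i, i], C[j, j], C[i, j]
        theta = 0.5 * np.arctan2(b - a, 2 * c) if (c != 0 or a != b) else 0.0
        ct, st = np.cos(theta), np.sin(theta)
        yi, yj = Y[:, i].copy(), Y[:, j].copy()
        Y[:, i] = ct * yi + st * yj
        Y[:, j] = -st * yi + ct * yj
    return Y


def emit_geochem(
    truth: TransectTruth,
    n_variables: int = 8,
    driving_subset_size: int = 4,
    noise_sd: float = 0.1,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-sample geochemistry table with a known community-driving subset.

    The driving variables are a deterministic function of the latent
    community gradient: a least-squares (metric SMACOF, PCoA-initialized)
    Euclidean embedding of the Bray–Curtis dissimilarity among true
    abundances, rotated so each variable carries an equal share of the
    gradient variance (the rotation preserves between-sample Euclidean
    distances, so standardizing the variables keeps the between-sample
    geometry intact). Gaussian noise with
    standard deviation ``noise_sd`` x the signal's own standard deviation
    is added; the remaining variables are independent noise. Records the
    driving names in ``truth.driving_env_subset``.
    """
    if driving_subset_size > n_variables:
        raise InputError("driving_subset_size cannot exceed n_variables")
    if n_variables > len(GEOCHEM_NAMES):
        raise InputError(f"at most {len(GEOCHEM_NAMES)} variables supported")
    rng = _substream(seed if seed is not None else truth.seed, "geochem")

    bc = ecology.bray_curtis(truth.true_abundance)
    m = driving_subset_size
    D = np.asarray(bc.data, dtype=float)
    init = ecology.pcoa(bc, k=m).coordinates.values
    Y, _stress = smacof(
        D, metric=True, n_components=m, init=init, n_init=1,
        max_iter=500, eps=1e-10,
    )
    Y = _equalize_variances(Y)
    signal_sd = Y.std(axis=0, ddof=1)
    Y = Y + rng.normal(0, 1, size=Y.shape) * (noise_sd * signal_sd)

    names = list(GEOCHEM_NAMES[:n_variables])
    driving = names[:m]
    data = {}
    for k, name in enumerate(driving):
        data[name] = Y[:, k]
    for name in names[m:]:
        data[name] = rng.normal(0, 1, size=len(truth.samples))
    env = pd.DataFrame(data, index=truth.samples)
    # shuffle column order so position carries no information
    env = env[list(rng.permutation(names))]
    truth.driving_env_subset = driving
    return env


# ---------------------------------------------------------------------------
# gapless alignment of equal-ancestry markers, scenario assembly


def align_ungapped(markers: Mapping[str, str]) -> MultipleAlignment:
    """Stack same-ancestry marker proteins into a gapless alignment.

    Shorter sequences (if any) are padded with trailing gaps. This is the
    trivial aligner for synthetic markers that derive from one ancestor by
    substitution only; real data needs a genuine aligner upstream.
    """
    if not markers:
        raise InputError("no sequences to align")
    width = max(len(s) for s in markers.values())
    ids = list(markers)
    rows = [markers[i] + "-" * (width - len(markers[i])) for i in ids]
    return MultipleAlignment(ids, rows, [False] * len(ids))


@dataclass
class Scenario:
    """All file paths and the truth for one generated scenario."""

    out_dir: Path
    truth: TransectTruth
    genomes: GenomeSet
    regions: list[TrimmedScaffold]
    sam_paths: dict[str, Path]
    hit_paths: dict[str, Path]
    env: pd.DataFrame
    paths: dict[str, Path]


def generate_scenario(
    out_dir: str | Path,
    seed: int = 0,
    mean_depth: float = 20.0,
    decoy_fraction: float = 0.5,
    geochem_noise_sd: float = 0.1,
    score_cutoff: float = 100.0,
    **transect_kwargs,
) -> Scenario:
    """Generate and write a complete scenario under ``out_dir``.

    Writes scaffolds and trimmed scaffolds (FASTA), gene coordinates,
    marker proteins and their gapless alignment, per-sample SAMs, hit and
    taxonomy tables, the taxon tree (newick), sample metadata, geochemistry
    and the ground truth (JSON + TSV).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    truth = simulate_transect(seed=seed, **transect_kwargs)
    genomes = emit_genomes_and_tree(truth)
    regions = trimmed_regions(genomes, truth)
    taxon_of_region = {
        r.id: genomes.taxon_of_gene[r.gene_id] for r in regions
    }
    sam_paths = emit_reads_sam(
        truth, regions, taxon_of_region, out_dir / "sam", mean_depth=mean_depth
    )
    hit_paths = emit_hit_tables(
        truth, genomes, out_dir / "hits",
        score_cutoff=score_cutoff, decoy_fraction=decoy_fraction,
    )
    env = emit_geochem(truth, noise_sd=geochem_noise_sd)

    paths: dict[str, Path] = {}

    def fasta(path: Path, seqs: Mapping[str, str]) -> Path:
        with path.open("w") as fh:
            for sid, seq in seqs.items():
                fh.write(f">{sid}\n")
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")
        return path

    paths["scaffolds"] = fasta(out_dir / "scaffolds.fasta", genomes.scaffolds)
    paths["trimmed"] = fasta(
        out_dir / "trimmed_scaffolds.fasta", {r.id: r.sequence for r in regions}
    )
    paths["markers"] = fasta(out_dir / "markers.faa", genomes.markers)
    msa = align_ungapped(genomes.markers)
    msa.to_fasta(out_dir / "markers.aln.faa")
    paths["alignment"] = out_dir / "markers.aln.faa"
    genomes.genes.to_csv(out_dir / "genes.tsv", sep="\t", index=False)
    paths["genes"] = out_dir / "genes.tsv"
    (out_dir / "tree.nwk").write_text(genomes.tree_newick + "\n")
    paths["tree"] = out_dir / "tree.nwk"

    meta_rows = []
    for sample in truth.samples:
        site = truth.site_of(sample)
        meta_rows.append(
            {
                "sample_id": sample,
                "site_id": site.site_id,
                "depth_cm": site.depth_cm,
                "distance_m": site.distance_to_river_m,
                "library_bp": truth.library_bp[sample],
            }
        )
    pd.DataFrame(meta_rows).to_csv(out_dir / "metadata.tsv", sep="\t", index=False)
    paths["metadata"] = out_dir / "metadata.tsv"
    env.rename_axis("sample_id").to_csv(out_dir / "geochem.tsv", sep="\t")
    paths["geochem"] = out_dir / "geochem.tsv"
    truth.true_abundance.rename_axis("taxon_id").to_csv(
        out_dir / "true_abundance.tsv", sep="\t"
    )
    paths["true_abundance"] = out_dir / "true_abundance.tsv"

    truth_meta = {
        "seed": truth.seed,
        "depth_trending": truth.depth_trending,
        "driving_env_subset": truth.driving_env_subset,
        "replicate_map": truth.replicate_map,
        "library_bp": truth.library_bp,
        "score_cutoff": score_cutoff,
        "model_id": genomes.model_id,
    }
    (out_dir / "truth.json").write_text(json.dumps(truth_meta, indent=2))
    paths["truth"] = out_dir / "truth.json"

    return Scenario(
        out_dir=out_dir,
        truth=truth,
        genomes=genomes,
        regions=regions,
        sam_paths=sam_paths,
        hit_paths={k: v for k, v in hit_paths.items()},
        env=env,
        paths=paths,
    )
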