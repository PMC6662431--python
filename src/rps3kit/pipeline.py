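"""End-to-end orchestration of the marker-gene profiling pipeline.

``run_profiling`` executes hit screening -> alignment QC -> identity
clustering -> coverage quantification and returns the site-level abundance
matrix with a stage-by-stage run report; ``run_ecology`` computes distance
matrices, ordinations, BIOENV, its Mantel validation, and covariate
statistics. Both are driven by a :class:`PipelineConfig` that can be loaded
from YAML; every default mirrors the method's published parameterization
(gap fraction 0.95, retention 0.5, identity 0.99, query/target coverage
1.0/0.5, 2 kbp flanks, 1 kbp minimum, breadth grid 0.1-1, e-value 1e-5,
999 permutations).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml
from Bio import SeqIO
from skbio import TreeNode

from . import align_qc, cluster, ecology, marker_screen, quant
from .errors import ConfigError, InputError

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths and parameters for a full pipeline run."""

    # inputs
    hits_dir: str = ""
    alignment: str = ""
    scaffolds: str = ""
    genes: str = ""
    sam_dir: str = ""
    metadata: str = ""
    geochem: str = ""
    tree: str = ""
    besthits: str = ""
    lineages: str = ""
    out_dir: str = "."
    # screening
    model_cutoffs: dict = field(default_factory=lambda: {"rpS3": 100.0})
    evalue_max: float = 1e-5
    taxonomy_evalue_max: float = 1e-5
    reference_prefix: str = align_qc.DEFAULT_REFERENCE_PREFIX
    # alignment QC
    max_gap_fraction: float = 0.95
    retention_fraction: float = 0.5
    # clustering
    identity_threshold: float = 0.99
    query_cov: float = 1.0
    target_cov: float = 0.5
    exhaustive: bool = True
    # quantification
    flank_bp: int = 2000
    min_scaffold_bp: int = 1000
    breadth_grid_lo: float = 0.1
    breadth_grid_hi: float = 1.0
    breadth_grid_step: float = 0.01
    # ecology
    correlation_method: str = "pearson"
    weighted_unifrac_normalized: bool = True
    n_perm: int = 999
    seed: int = 0
    nmds_starts: int = 4
    bioenv_max_subset_size: int | None = None
    bioenv_strategy: str = "exhaustive"
    stats_group_keyword: str = "Candidat"
    stats_covariate: str = "depth_cm"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def cluster_params(self) -> cluster.ClusterParams:
        return cluster.ClusterParams(
            self.identity_threshold, self.query_cov, self.target_cov, self.exhaustive
        )

    def quant_config(self) -> quant.QuantConfig:
        return quant.QuantConfig(
            self.flank_bp,
            self.min_scaffold_bp,
            self.breadth_grid_lo,
            self.breadth_grid_hi,
            self.breadth_grid_step,
        )

    def config_hash(self) -> str:
        fields = dataclasses.asdict(self)
        fields.pop("out_dir")  # output location does not affect results
        payload = json.dumps(fields, sort_keys=True, default=str)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]

    def header_comment(self) -> str:
        return f"config={self.config_hash()} seed={self.seed}"

    def validate_profiling(self) -> None:
        """Check that every profiling input resolves before any stage runs."""
        for name in ("hits_dir", "alignment", "scaffolds", "genes", "sam_dir", "metadata"):
            value = getattr(self, name)
            if not value:
                raise ConfigError(f"config field {name} is required for profiling")
            if not Path(value).exists():
                raise ConfigError(f"{name} path does not exist: {value}")
        meta = read_metadata(self.metadata)
        for sample in meta.index:
            sam = Path(self.sam_dir) / f"{sample}.sam"
            if not sam.exists():
                raise ConfigError(f"missing SAM for sample {sample}: {sam}")


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Sample metadata indexed by sample_id (site, depth, distance, bp)."""
    meta = pd.read_csv(path, sep="\t", comment="#")
    required = {"sample_id", "site_id", "depth_cm", "distance_m", "library_bp"}
    if not required.issubset(meta.columns):
        raise InputError(f"metadata missing columns {sorted(required - set(meta.columns))}")
    return meta.set_index("sample_id")


@dataclass
class ProfilingResult:
    """Site-level abundance plus intermediate artifacts and the run report."""

    abundance: quant.AbundanceMatrix  # site-level, normalized
    sample_abundance: quant.AbundanceMatrix  # per-sample, normalized
    clusters: list[cluster.SeqCluster]
    taxonomy: list[marker_screen.TaxonomyAssignment]
    cluster_taxonomy: dict[str, marker_screen.TaxonomyAssignment]
    coverage: list[quant.CoverageRecord]
    breadth_cutoff: float
    report: dict


def run_profiling(config: PipelineConfig) -> ProfilingResult:
    """Execute screening -> alignment QC -> clustering -> quantification."""
    config.validate_profiling()
    report: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
    }
    t0 = time.time()

    # --- stage 1: hit screening ------------------------------------------
    hits: list[marker_screen.MarkerHit] = []
    for path in sorted(Path(config.hits_dir).glob("*.domtbl")):
        hits.extend(marker_screen.parse_hit_table(path, origin_sample=path.stem))
    retained = marker_screen.filter_hits(hits, config.model_cutoffs, config.evalue_max)
    report["stages"]["screen"] = {
        "hits_parsed": len(hits),
        "hits_retained": len(retained),
    }
    logger.info("screen: %d/%d hits retained", len(retained), len(hits))
    hit_of_gene = {h.gene_id: h for h in retained}

    # --- stage 2: alignment QC -------------------------------------------
    msa = align_qc.MultipleAlignment.from_fasta(config.alignment, config.reference_prefix)
    trimmed = align_qc.trim_gappy_columns(msa, config.max_gap_fraction)
    filtered, threshold = align_qc.filter_short_sequences(trimmed, config.retention_fraction)
    nonref = align_qc.drop_references(filtered)
    seqs = [
        (sid, seq)
        for sid, seq in align_qc.ungapped_sequences(nonref)
        if sid in hit_of_gene
    ]
    report["stages"]["align_qc"] = {
        "rows_in": len(msa),
        "columns_in": msa.n_columns,
        "columns_kept": trimmed.n_columns,
        "retention_threshold": threshold,
        "rows_removed_short": len(trimmed) - len(filtered),
        "sequences_clustered": len(seqs),
    }

    # --- stage 3: clustering ---------------------------------------------
    clusters = cluster.greedy_cluster(seqs, config.cluster_params())
    membership = cluster.cluster_membership(clusters)
    report["stages"]["cluster"] = {
        "clusters": len(clusters),
        "largest": max((len(c.member_ids) for c in clusters), default=0),
    }
    logger.info("cluster: %d clusters from %d sequences", len(clusters), len(seqs))

    taxonomy: list[marker_screen.TaxonomyAssignment] = []
    if config.besthits and config.lineages:
        rows = marker_screen.read_besthit_table(config.besthits)
        lineage_map = marker_screen.read_lineage_map(config.lineages)
        reps = {c.representative_id for c in clusters}
        rows = rows[rows["query"].isin(reps)]
        taxonomy = marker_screen.assign_taxonomy_tophit(
            rows, lineage_map, config.taxonomy_evalue_max
        )
    report["stages"]["taxonomy"] = {"assigned": sum(1 for t in taxonomy if t.lineage)}
    # abundance rows are centroid ids; taxonomy is assigned to representatives
    by_query = {t.query_id: t for t in taxonomy}
    cluster_taxonomy = {
        c.centroid_id: by_query[c.representative_id]
        for c in clusters
        if c.representative_id in by_query
    }

    # --- stage 4: quantification -----------------------------------------
    qcfg = config.quant_config()
    scaffolds = {
        rec.id: str(rec.seq) for rec in SeqIO.parse(config.scaffolds, "fasta")
    }
    regions: list[quant.TrimmedScaffold] = []
    n_filtered_short = 0
    for gene_id in membership:
        hit = hit_of_gene[gene_id]
        if hit.scaffold_id not in scaffolds:
            raise InputError(f"scaffold {hit.scaffold_id} (gene {gene_id}) not in FASTA")
        region = quant.trim_to_flanks((hit.scaffold_id, scaffolds[hit.scaffold_id]), hit, qcfg)
        if region is None:
            n_filtered_short += 1
            continue
        regions.append(region)
    meta = read_metadata(config.metadata)
    sam_paths = {s: Path(config.sam_dir) / f"{s}.sam" for s in meta.index}
    records = quant.compute_coverage_table(sam_paths, regions)
    cluster_of = {r.id: membership[r.gene_id] for r in regions}
    cutoff = quant.calibrate_breadth_cutoff(records, cluster_of, qcfg)
    cut_records = quant.apply_breadth_cutoff(records, cutoff)
    n_zeroed = sum(
        1
        for before, after in zip(records, cut_records)
        if before.average_coverage > 0 and after.average_coverage == 0
    )
    library_bp = meta["library_bp"].astype(int).to_dict()
    matrix = quant.abundance_from_records(cut_records, cluster_of, library_bp)
    normalized = quant.depth_normalize(matrix)
    replicate_map = meta["site_id"].to_dict()
    site_matrix = quant.average_replicates(normalized, replicate_map)
    report["stages"]["quant"] = {
        "scaffolds_trimmed": len(regions),
        "scaffolds_filtered_short": n_filtered_short,
        "coverage_records": len(records),
        "breadth_cutoff": cutoff,
        "records_zeroed": n_zeroed,
        "sites": site_matrix.data.shape[1],
    }
    report["runtime_s"] = round(time.time() - t0, 3)

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    header = config.header_comment()
    quant.write_coverage_tsv(records, out_dir / "coverage.tsv", header)
    cluster.write_clusters_tsv(clusters, out_dir / "clusters.tsv", header)
    normalized.to_tsv(out_dir / "abundance_samples.tsv", header)
    site_matrix.to_tsv(out_dir / "abundance_sites.tsv", header)
    (out_dir / "report.json").write_text(json.dumps(report, indent=2))

    return ProfilingResult(
        abundance=site_matrix,
        sample_abundance=normalized,
        clusters=clusters,
        taxonomy=taxonomy,
        cluster_taxonomy=cluster_taxonomy,
        coverage=records,
        breadth_cutoff=cutoff,
        report=report,
    )


@dataclass
class EcologyResult:
    """Distance matrices, ordinations, BIOENV + Mantel, covariate stats."""

    bray_curtis: "ecology.DistanceMatrix"
    unweighted_unifrac: "ecology.DistanceMatrix | None"
    weighted_unifrac: "ecology.DistanceMatrix | None"
    pcoa: ecology.OrdinationResult
    nmds: ecology.OrdinationResult
    bioenv: ecology.BioenvResult | None
    mantel: ecology.StatResult | None
    covariate: ecology.CovariateStats | None
    report: dict


def _env_distance(env: pd.DataFrame, subset, labels) -> "ecology.DistanceMatrix":
    from scipy.spatial.distance import pdist, squareform
    from skbio import DistanceMatrix

    z = env.loc[labels, list(subset)]
    z = (z - z.mean()) / z.std(ddof=1)
    return DistanceMatrix(squareform(pdist(z.values)), ids=list(labels))


def run_ecology(
    config: PipelineConfig,
    abundance: quant.AbundanceMatrix,
    tree: TreeNode | None = None,
    env: pd.DataFrame | None = None,
    leaf_of: Mapping[str, str] | None = None,
    metadata: pd.DataFrame | None = None,
    group_rows: list[str] | None = None,
) -> EcologyResult:
    """Compute the ecological statistics downstream of profiling.

    ``leaf_of`` maps abundance rows to tree leaf labels when the two differ
    (e.g. cluster ids vs taxon labels); rows mapping to the same leaf are
    summed. ``env`` rows are averaged to the abundance columns' level when
    they are per-sample and the abundance is per-site (requires
    ``metadata``). ``group_rows`` names the abundance rows whose summed
    site abundance is regressed on the configured covariate; by default
    rows whose taxonomy lineage matches ``stats_group_keyword``.
    """
    report: dict = {"config_hash": config.config_hash(), "seed": config.seed}
    labels = list(abundance.data.columns)

    bc = ecology.bray_curtis(abundance)

    uu = wu = None
    if tree is not None:
        frame = abundance.data
        if leaf_of is not None:
            missing = [r for r in frame.index if r not in leaf_of]
            if missing:
                raise InputError(f"abundance rows without a tree-leaf mapping: {missing}")
            frame = frame.groupby([leaf_of[r] for r in frame.index]).sum()
        uu = ecology.unifrac(tree, frame, weighted=False)
        wu = ecology.unifrac(
            tree, frame, weighted=True, normalized=config.weighted_unifrac_normalized
        )

    ord_input = uu if uu is not None else bc
    pcoa_res = ecology.pcoa(ord_input, k=min(2, ord_input.shape[0] - 1))
    nmds_res = ecology.nmds(
        ord_input, k=2, n_starts=config.nmds_starts, seed=config.seed
    )
    report["nmds_stress"] = nmds_res.stress

    bioenv_res = mantel_res = None
    if env is not None:
        env_aligned = env
        if not set(labels).issubset(env.index):
            if metadata is None:
                raise InputError(
                    "environment rows do not match abundance columns and no "
                    "metadata was given to aggregate replicates"
                )
            site_of = metadata["site_id"].to_dict()
            env_aligned = env.groupby([site_of[s] for s in env.index]).mean()
            missing = [s for s in labels if s not in env_aligned.index]
            if missing:
                raise InputError(f"environment table missing labels: {missing}")
        bioenv_res = ecology.bioenv(
            bc,
            env_aligned,
            method=config.correlation_method,
            max_subset_size=config.bioenv_max_subset_size,
            strategy=config.bioenv_strategy,
        )
        mantel_res = ecology.mantel(
            bc,
            _env_distance(env_aligned, bioenv_res.best_subset, labels),
            method=config.correlation_method,
            n_perm=config.n_perm,
            seed=config.seed,
        )
        report["bioenv_best_subset"] = list(bioenv_res.best_subset)
        report["bioenv_correlation"] = bioenv_res.correlation
        report["mantel_r"] = mantel_res.estimate
        report["mantel_p"] = mantel_res.p_value

    covariate_res = None
    if group_rows and metadata is not None:
        totals = abundance.data.loc[
            [r for r in group_rows if r in abundance.data.index]
        ].sum(axis=0)
        site_cov = (
            metadata.groupby("site_id")[config.stats_covariate].mean()
            if config.stats_covariate in metadata.columns
            else None
        )
        if site_cov is None:
            raise ConfigError(f"covariate {config.stats_covariate!r} not in metadata")
        cov = site_cov.reindex(totals.index)
        covariate_res = ecology.covariate_stats(totals.values, cov.values)
        report["covariate_r"] = covariate_res.r
        report["covariate_slope"] = covariate_res.slope
        report["covariate_r_squared"] = covariate_res.r_squared

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    header = config.header_comment()
    ecology.write_distance_tsv(bc, out_dir / "bray_curtis.tsv", header)
    if uu is not None:
        ecology.write_distance_tsv(uu, out_dir / "unweighted_unifrac.tsv", header)
        ecology.write_distance_tsv(wu, out_dir / "weighted_unifrac.tsv", header)
    with open(out_dir / "ordination.tsv", "w") as fh:
        fh.write(f"# {header}\n# nmds_stress={nmds_res.stress:.6f}\n")
        joined = pcoa_res.coordinates.join(nmds_res.coordinates)
        joined.rename_axis("sample").to_csv(fh, sep="\t")
    (out_dir / "ecology_report.json").write_text(json.dumps(report, indent=2, default=str))

    return EcologyResult(
        bray_curtis=bc,
        unweighted_unifrac=uu,
        weighted_unifrac=wu,
        pcoa=pcoa_res,
        nmds=nmds_res,
        bioenv=bioenv_res,
        mantel=mantel_res,
        covariate=covariate_res,
        report=report,
    )
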