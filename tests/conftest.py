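"""Shared fixtures: one seeded synthetic transect scenario per session."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from rps3kit import pipeline, synthetic_data

SCENARIO_SEED = 1


@pytest.fixture(scope="session")
def scenario(tmp_path_factory):
    """A complete synthetic hillslope transect at default study conditions."""
    out = tmp_path_factory.mktemp("scenario")
    return synthetic_data.generate_scenario(out, seed=SCENARIO_SEED)


@pytest.fixture(scope="session")
def profiling_config(scenario, tmp_path_factory):
    out = tmp_path_factory.mktemp("profiling_out")
    return pipeline.PipelineConfig(
        hits_dir=str(scenario.out_dir / "hits"),
        alignment=str(scenario.paths["alignment"]),
        scaffolds=str(scenario.paths["scaffolds"]),
        genes=str(scenario.paths["genes"]),
        sam_dir=str(scenario.out_dir / "sam"),
        metadata=str(scenario.paths["metadata"]),
        geochem=str(scenario.paths["geochem"]),
        tree=str(scenario.paths["tree"]),
        besthits=str(scenario.hit_paths["besthits"]),
        lineages=str(scenario.hit_paths["lineages"]),
        out_dir=str(out),
        seed=SCENARIO_SEED,
    )


@pytest.fixture(scope="session")
def profiling_result(profiling_config):
    return pipeline.run_profiling(profiling_config)


@pytest.fixture(scope="session")
def ecology_result(scenario, profiling_config, profiling_result):
    """Full ecology stage on the session scenario's profiling output."""
    from io import StringIO

    from skbio import TreeNode

    tree = TreeNode.read(StringIO(scenario.genomes.tree_newick))
    meta = pipeline.read_metadata(scenario.paths["metadata"])
    leaf_of = {
        cid: t.lineage[-1]
        for cid, t in profiling_result.cluster_taxonomy.items()
        if t.lineage
    }
    group = [
        cid
        for cid, t in profiling_result.cluster_taxonomy.items()
        if any("Candidat" in r for r in t.lineage)
    ]
    return pipeline.run_ecology(
        profiling_config,
        profiling_result.abundance,
        tree=tree,
        env=scenario.env,
        leaf_of=leaf_of,
        metadata=meta,
        group_rows=group,
    )


def taxon_abundance(scenario, matrix: pd.DataFrame) -> pd.DataFrame:
    """Collapse a cluster-level matrix to taxa using the generator's truth."""
    taxon_of = {
        cid: scenario.genomes.taxon_of_gene[cid] for cid in matrix.index
    }
    out = matrix.groupby([taxon_of[c] for c in matrix.index]).sum()
    return out.reindex(scenario.truth.true_abundance.index).fillna(0.0)


def site_truth(scenario) -> pd.DataFrame:
    """True abundances averaged over replicate samples per site."""
    reps = pd.Series(scenario.truth.replicate_map)
    return scenario.truth.true_abundance.T.groupby(reps).mean().T


def pearson(a, b) -> float:
    return float(np.corrcoef(np.asarray(a, float), np.asarray(b, float))[0, 1])
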