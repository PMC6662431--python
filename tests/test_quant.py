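"""Flank trimming, coverage/breadth, cutoff calibration, normalization."""

import numpy as np
import pandas as pd
import pysam
import pytest

from rps3kit.errors import ConfigError, InputError
from rps3kit.marker_screen import MarkerHit
from rps3kit.quant import (
    AbundanceMatrix,
    CoverageRecord,
    QuantConfig,
    TrimmedScaffold,
    apply_breadth_cutoff,
    average_replicates,
    calibrate_breadth_cutoff,
    compute_coverage_table,
    coverage_breadth,
    depth_normalize,
    trim_to_flanks,
)


def hit(start, end, gene_id="g1", scaffold_id="scf"):
    return MarkerHit(
        scaffold_id=scaffold_id, gene_id=gene_id, model_id="rpS3",
        bit_score=200.0, e_value=1e-30, gene_start=start, gene_end=end,
        strand="+", sample_of_origin="s1",
    )


def region(region_id="r1", length=1000):
    return TrimmedScaffold(
        id=region_id, source_scaffold="scf", window_start=1,
        window_end=length, sequence="A" * length, origin_sample="s1",
    )


def write_sam(path, region_id, length, reads):
    """reads: list of (start0, cigar, flag)."""
    header = {"HD": {"VN": "1.6"}, "SQ": [{"SN": region_id, "LN": length}]}
    with pysam.AlignmentFile(str(path), "w", header=header) as sam:
        for i, (start0, cigar, flag) in enumerate(reads):
            rec = pysam.AlignedSegment()
            rec.query_name = f"read{i}"
            rec.flag = flag
            rec.reference_id = 0
            rec.reference_start = start0
            rec.mapping_quality = 60
            rec.cigarstring = cigar
            sam.write(rec)


def read_sam(path):
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        return list(sam)


class TestTrimToFlanks:
    def test_interior_gene_gets_2kb_flanks(self):
        ts = trim_to_flanks(("scf", "A" * 10_000), hit(5001, 5700))
        assert (ts.window_start, ts.window_end) == (3001, 7700)
        assert ts.length == 4700
        assert len(ts.sequence) == 4700

    def test_short_scaffold_kept_entirely(self):
        ts = trim_to_flanks(("scf", "A" * 3000), hit(1001, 1700))
        assert (ts.window_start, ts.window_end) == (1, 3000)

    def test_window_below_minimum_keeps_whole_scaffold(self):
        cfg = QuantConfig(flank_bp=100)
        ts = trim_to_flanks(("scf", "A" * 5000), hit(2001, 2300), cfg)
        # window would be 500 bp < 1000 minimum -> entire scaffold
        assert (ts.window_start, ts.window_end) == (1, 5000)

    def test_gene_outside_scaffold_is_error(self):
        with pytest.raises(InputError):
            trim_to_flanks(("scf", "A" * 2000), hit(1500, 2500))

    def test_short_scaffold_filtered_returns_none(self, caplog):
        with caplog.at_level("INFO"):
            assert trim_to_flanks(("scf", "A" * 1000), hit(100, 500)) is None
        assert "filtered" in caplog.text


class TestCoverageBreadth:
    def test_disjoint_tiling_gives_unit_coverage(self, tmp_path):
        reads = [(i * 100, "100M", 0) for i in range(10)]
        path = tmp_path / "a.sam"
        write_sam(path, "r1", 1000, reads)
        rec = coverage_breadth(read_sam(path), region())
        assert rec.average_coverage == pytest.approx(1.0)
        assert rec.breadth == pytest.approx(1.0)

    def test_stacked_reads(self, tmp_path):
        reads = [(0, "100M", 0)] * 5
        path = tmp_path / "a.sam"
        write_sam(path, "r1", 1000, reads)
        rec = coverage_breadth(read_sam(path), region())
        assert rec.average_coverage == pytest.approx(0.5)
        assert rec.breadth == pytest.approx(0.1)

    def test_no_reads_gives_zeroes(self, tmp_path):
        path = tmp_path / "a.sam"
        write_sam(path, "r1", 1000, [])
        rec = coverage_breadth(read_sam(path), region())
        assert (rec.average_coverage, rec.breadth) == (0.0, 0.0)

    def test_secondary_supplementary_unmapped_skipped(self, tmp_path):
        reads = [(0, "100M", 0), (0, "100M", 256), (0, "100M", 2048), (0, "100M", 4)]
        path = tmp_path / "a.sam"
        write_sam(path, "r1", 1000, reads)
        rec = coverage_breadth(read_sam(path), region())
        assert rec.average_coverage == pytest.approx(0.1)

    def test_matches_bruteforce_depth_array_with_mixed_cigars(self, tmp_path):
        rng = np.random.default_rng(11)
        L = 2000
        ops_pool = ["100M", "40M20D40M", "50M10I50M", "5S90M5S", "30M500N30M"]
        reads = []
        for _ in range(120):
            cigar = ops_pool[int(rng.integers(len(ops_pool)))]
            start = int(rng.integers(0, L - 700))
            reads.append((start, cigar, 0))
        path = tmp_path / "a.sam"
        write_sam(path, "r1", L, reads)
        rec = coverage_breadth(read_sam(path), region("r1", L))

        # brute force from the construction: walk each CIGAR by hand
        import re

        depth = np.zeros(L, dtype=int)
        for start, cigar, _flag in reads:
            pos = start
            for n, op in re.findall(r"(\d+)([MIDNSHP=X])", cigar):
                n = int(n)
                if op in "M=X":
                    depth[pos : pos + n] += 1
                    pos += n
                elif op in "DN":
                    pos += n
        assert rec.average_coverage == pytest.approx(depth.sum() / L)
        assert rec.breadth == pytest.approx((depth > 0).sum() / L)

    def test_coverage_table_covers_all_pairs(self, tmp_path):
        regions = [region("r1", 500), region("r2", 800)]
        write_sam(tmp_path / "s1.sam", "r1", 500, [(0, "100M", 0)])
        write_sam(tmp_path / "s2.sam", "r2", 800, [])
        recs = compute_coverage_table(
            {"s1": tmp_path / "s1.sam", "s2": tmp_path / "s2.sam"}, regions
        )
        assert len(recs) == 4
        by_key = {(r.trimmed_scaffold_id, r.sample_id): r for r in recs}
        assert by_key[("r1", "s1")].average_coverage == pytest.approx(0.2)
        assert by_key[("r2", "s2")].average_coverage == 0.0


class TestBreadthCutoff:
    def recs(self, breadths_by_cluster):
        records, cluster_of = [], {}
        for cl, breadths in breadths_by_cluster.items():
            for i, b in enumerate(breadths):
                sid = f"{cl}_scf{i}"
                cluster_of[sid] = cl
                records.append(CoverageRecord(sid, f"s{i}", b * 10, b))
        return records, cluster_of

    def test_weakest_cluster_sets_cutoff(self):
        records, cluster_of = self.recs(
            {"c1": [0.95, 0.2], "c2": [0.80], "c3": [0.73, 0.5]}
        )
        assert calibrate_breadth_cutoff(records, cluster_of) == pytest.approx(0.73)

    def test_all_perfect_breadth_gives_one(self):
        records, cluster_of = self.recs({"c1": [1.0], "c2": [1.0]})
        assert calibrate_breadth_cutoff(records, cluster_of) == pytest.approx(1.0)

    def test_single_cluster_half_breadth(self):
        records, cluster_of = self.recs({"c1": [0.5]})
        assert calibrate_breadth_cutoff(records, cluster_of) == pytest.approx(0.5)

    def test_cluster_without_positive_record_is_error(self):
        records, cluster_of = self.recs({"c1": [0.9], "c2": [0.0]})
        with pytest.raises(InputError, match="c2"):
            calibrate_breadth_cutoff(records, cluster_of)

    def test_retention_flips_one_step_above(self):
        records, cluster_of = self.recs({"c1": [0.95], "c2": [0.66]})
        cfg = QuantConfig()
        c = calibrate_breadth_cutoff(records, cluster_of, cfg)
        retained_at = lambda cut: len(
            {cluster_of[r.trimmed_scaffold_id] for r in records if r.breadth >= cut}
        )
        assert retained_at(c) == 2
        assert retained_at(c + cfg.breadth_grid_step) < 2

    def test_apply_cutoff_boundary(self):
        records = [
            CoverageRecord("a", "s", 5.0, 0.71),
            CoverageRecord("b", "s", 5.0, 0.72),
        ]
        out = apply_breadth_cutoff(records, 0.72)
        assert out[0].average_coverage == 0.0  # below cutoff zeroed
        assert out[1].average_coverage == 5.0  # at cutoff retained

    def test_cutoff_zero_rejected(self):
        with pytest.raises(InputError):
            apply_breadth_cutoff([], 0.0)


class TestNormalizeAndAverage:
    def test_depth_factors_from_library_ratio(self):
        data = pd.DataFrame({"s1": [2.0, 4.0], "s2": [1.0, 3.0]}, index=["a", "b"])
        m = AbundanceMatrix(data, pd.Series({"s1": 100e9, "s2": 50e9}))
        out = depth_normalize(m)
        assert out.data["s1"].tolist() == [2.0, 4.0]  # largest library: factor 1
        assert out.data["s2"].tolist() == [2.0, 6.0]  # factor 2

    def test_equal_libraries_unchanged_and_rank_preserved(self):
        rng = np.random.default_rng(0)
        data = pd.DataFrame(rng.uniform(0, 5, (6, 3)), columns=list("xyz"))
        m = AbundanceMatrix(data, pd.Series({"x": 10, "y": 10, "z": 10}))
        out = depth_normalize(m)
        assert np.allclose(out.data.values, data.values)
        m2 = AbundanceMatrix(data, pd.Series({"x": 10, "y": 7, "z": 3}))
        out2 = depth_normalize(m2)
        for c in "xyz":
            assert (out2.data[c].rank() == data[c].rank()).all()

    def test_zero_library_is_error(self):
        m = AbundanceMatrix(
            pd.DataFrame({"s1": [1.0]}), pd.Series({"s1": 0})
        )
        with pytest.raises(InputError):
            depth_normalize(m)

    def test_replicate_means_include_zeros(self):
        data = pd.DataFrame(
            {"r1": [4.0, 0.0], "r2": [6.0, 10.0], "r3": [0.0, 5.0], "q1": [7.0, 1.0]},
            index=["a", "b"],
        )
        m = AbundanceMatrix(data)
        out = average_replicates(
            m, {"r1": "site1", "r2": "site1", "r3": "site1", "q1": "site2"}
        )
        assert out.data.loc["a", "site1"] == pytest.approx(10 / 3)
        assert out.data.loc["b", "site1"] == pytest.approx(5.0)
        assert out.data.loc["a", "site2"] == pytest.approx(7.0)  # single replicate

    def test_unmapped_sample_is_config_error(self):
        m = AbundanceMatrix(pd.DataFrame({"s1": [1.0]}))
        with pytest.raises(ConfigError):
            average_replicates(m, {})
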