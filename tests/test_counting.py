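import numpy as np
import pandas as pd
import pytest

from rqcsirna.annotation import GeneModel
from rqcsirna.counting import (
    CountTensor,
    GeneIndex,
    ReadAlignment,
    SampleInfo,
    assign_read,
    build_count_tensor,
    effective_library_sizes,
    normalize_rptm,
    read_alignment_bam,
    read_alignment_tsv,
    read_sample_sheet,
    write_alignment_tsv,
    write_sample_sheet,
)
from rqcsirna.tracks import strand_coverage, write_bedgraph

from ._oracles import brute_force_count, brute_force_coverage
from .conftest import random_reads


def _read(start, end, strand="+", n_hits=1, chrom="Chr1", rid="r1"):
    return ReadAlignment(rid, chrom, start, end, strand, n_hits)


class TestReadAlignment:
    def test_length_bounds(self):
        with pytest.raises(ValueError):
            _read(0, 10)  # 10 nt too short
        with pytest.raises(ValueError):
            _read(0, 40)  # 40 nt too long
        assert _read(0, 21).length == 21

    def test_n_hits_positive(self):
        with pytest.raises(ValueError):
            _read(0, 21, n_hits=0)


class TestAssignRead:
    def test_union_mode_semantics(self, tiny_genes):
        idx = GeneIndex(tiny_genes)
        # inside gA exon, same strand -> sense
        res = assign_read(_read(150, 171, "+"), idx)
        assert (res.category, res.gene_id, res.orientation) == ("assigned", "gA", "sense")
        # opposite strand -> antisense
        assert assign_read(_read(150, 171, "-"), idx).orientation == "antisense"
        # intronic-only read -> no_feature (exon-union semantics)
        assert assign_read(_read(450, 471, "+"), idx).category == "no_feature"
        # intergenic -> no_feature
        assert assign_read(_read(5000, 5021, "+"), idx).category == "no_feature"
        # multimapper excluded by default
        assert assign_read(_read(150, 171, "+", n_hits=3), idx).category == "multimapper"
        # unknown chromosome -> no_feature
        assert assign_read(_read(150, 171, chrom="ChrX"), idx).category == "no_feature"

    def test_ambiguous_when_two_genes_overlap(self):
        a = GeneModel("a", "Chr1", 100, 300, "+", "protein_coding", ((100, 300),))
        b = GeneModel("b", "Chr1", 280, 500, "-", "protein_coding", ((280, 500),))
        idx = GeneIndex([a, b])
        assert assign_read(_read(270, 291), idx).category == "ambiguous"


class TestBuildCountTensor:
    def test_matches_brute_force_oracle(self, tiny_genes):
        reads = random_reads(tiny_genes, 2000, seed=3)
        samples = [SampleInfo("s1", "wt", 1)]
        tensor, stats = build_count_tensor({"s1": reads}, tiny_genes, samples)
        oracle_counts, oracle_tally = brute_force_count(reads, tiny_genes)
        assert stats.loc["s1"].to_dict() == oracle_tally
        for (gid, orient, length), n in oracle_counts.items():
            mat = tensor.collapse((length, length), orient)
            assert mat.loc[gid, "s1"] == n
        assert tensor.total() == sum(oracle_counts.values())

    def test_categories_partition_reads(self, tiny_genes):
        reads = random_reads(tiny_genes, 1000, seed=5)
        samples = [SampleInfo("s1", "wt", 1)]
        _, stats = build_count_tensor({"s1": reads}, tiny_genes, samples)
        assert stats.loc["s1"].sum() == 1000

    def test_determinism_and_zero_sample(self, tiny_genes):
        reads = random_reads(tiny_genes, 500, seed=11)
        samples = [SampleInfo("s1", "wt", 1), SampleInfo("s2", "mut", 1)]
        t1, _ = build_count_tensor({"s1": list(reads), "s2": []}, tiny_genes, samples)
        t2, _ = build_count_tensor({"s1": list(reads), "s2": []}, tiny_genes, samples)
        np.testing.assert_array_equal(t1.counts, t2.counts)
        assert t1.collapse()["s2"].sum() == 0  # empty source -> all-zero column

    def test_duplicate_sample_errors(self, tiny_genes):
        samples = [SampleInfo("s1", "wt", 1), SampleInfo("s1", "wt", 2)]
        with pytest.raises(ValueError, match="duplicate"):
            build_count_tensor({"s1": []}, tiny_genes, samples)

    def test_fractional_multimapper_mode(self, tiny_genes):
        reads = [_read(150, 171, "+", n_hits=2, rid=f"m{i}") for i in range(4)]
        samples = [SampleInfo("s1", "wt", 1)]
        t, _ = build_count_tensor({"s1": reads}, tiny_genes, samples, count_multimappers=True)
        assert t.collapse().loc["gA", "s1"] == pytest.approx(2.0)  # 4 hits * 1/2


class TestCollapse:
    @pytest.fixture
    def tensor(self):
        t = CountTensor.zeros(["g1", "g2"], ["s1", "s2"])
        t.add("g1", "s1", "sense", 21, 5)
        t.add("g1", "s1", "antisense", 24, 3)
        t.add("g2", "s2", "sense", 24, 7)
        return t

    def test_conservation_and_additivity(self, tensor):
        total = tensor.collapse(None, "both").to_numpy().sum()
        assert total == tensor.total() == 15
        parts = [
            tensor.collapse((15, 20), "both"),
            tensor.collapse((21, 22), "both"),
            tensor.collapse((23, 35), "both"),
        ]
        pd.testing.assert_frame_equal(sum(parts), tensor.collapse(None, "both"))

    def test_length_restriction(self, tensor):
        only24 = tensor.collapse((21, 22), "both")
        assert only24.loc["g2", "s2"] == 0  # 24-nt counts fall outside 21-22
        assert only24.loc["g1", "s1"] == 5

    def test_orientation_collapse(self, tensor):
        assert tensor.collapse(None, "sense").loc["g1", "s1"] == 5
        assert tensor.collapse(None, "antisense").loc["g1", "s1"] == 3

    def test_empty_selection_errors(self, tensor):
        with pytest.raises(ValueError):
            tensor.collapse((36, 40), "both")
        with pytest.raises(ValueError):
            tensor.collapse((22, 21), "both")
        with pytest.raises(ValueError):
            tensor.collapse(None, "sideways")

    def test_tsv_round_trip(self, tensor, tmp_path):
        p = tmp_path / "c.tsv"
        tensor.to_tsv(str(p))
        back = CountTensor.from_tsv(str(p), tensor.gene_ids, tensor.sample_ids)
        np.testing.assert_array_equal(back.counts, tensor.counts)


class TestNormalizeRptm:
    def test_scalar_examples(self):
        assert normalize_rptm(5, 10_000_000) == pytest.approx(5.0)
        assert normalize_rptm(0, 123) == 0.0

    def test_linearity(self):
        a, b, lib = 13.0, 29.0, 2_000_000
        assert normalize_rptm(a + b, lib) == pytest.approx(
            normalize_rptm(a, lib) + normalize_rptm(b, lib)
        )

    def test_invalid_library_size(self):
        with pytest.raises(ValueError):
            normalize_rptm(5, 0)


class TestBedgraph:
    def test_values_match_brute_force_coverage(self, tmp_path):
        reads = [
            _read(10, 31, "+", rid=f"r{i}") for i in range(6)
        ] + [_read(50, 74, "+", rid=f"q{i}") for i in range(4)]
        cov = strand_coverage(reads, {"Chr1": 200})
        lib = 1000
        paths = write_bedgraph(cov, lib, str(tmp_path / "t_{strand}.bedGraph"))
        oracle = brute_force_coverage(reads, "Chr1", 200) * 1e7 / lib
        # reconstruct per-base values from the bedGraph intervals
        rebuilt = np.zeros(200)
        with open(paths[0]) as fh:
            next(fh)  # track line
            for line in fh:
                chrom, s, e, v = line.split("\t")
                rebuilt[int(s):int(e)] = float(v)
        np.testing.assert_allclose(rebuilt, oracle, rtol=1e-6)


class TestIO:
    def test_alignment_tsv_round_trip(self, tmp_path):
        reads = [_read(100, 121, "+", rid="a"), _read(200, 224, "-", rid="b", n_hits=2)]
        p = tmp_path / "aln.tsv"
        write_alignment_tsv(reads, str(p))
        assert list(read_alignment_tsv(str(p))) == reads

    def test_alignment_tsv_header_required(self, tmp_path):
        p = tmp_path / "aln.tsv"
        p.write_text("a\tChr1\t100\t121\t+\t1\n")
        with pytest.raises(ValueError, match="header"):
            list(read_alignment_tsv(str(p)))

    def test_sam_reading_via_pysam(self, tmp_path):
        sam = tmp_path / "a.sam"
        sam.write_text(
            "@HD\tVN:1.6\n@SQ\tSN:Chr1\tLN:10000\n"
            "r1\t0\tChr1\t101\t255\t21M\t*\t0\t0\t" + "A" * 21 + "\t*\tNH:i:1\n"
            "r2\t16\tChr1\t201\t255\t24M\t*\t0\t0\t" + "A" * 24 + "\t*\tNH:i:3\n"
        )
        reads = list(read_alignment_bam(str(sam)))
        assert reads[0] == ReadAlignment("r1", "Chr1", 100, 121, "+", 1)
        assert reads[1] == ReadAlignment("r2", "Chr1", 200, 224, "-", 3)

    def test_sample_sheet_round_trip(self, tmp_path):
        samples = [SampleInfo("s1", "wt", 1, 1000), SampleInfo("s2", "mut", 1)]
        p = tmp_path / "samples.tsv"
        write_sample_sheet(samples, str(p), paths={"s1": "s1.tsv"})
        back, paths = read_sample_sheet(str(p))
        assert back == samples
        assert paths == {"s1": "s1.tsv"}

    def test_effective_library_sizes(self, tiny_genes):
        samples = [SampleInfo("s1", "wt", 1, 5000), SampleInfo("s2", "mut", 1)]
        t = CountTensor.zeros([g.gene_id for g in tiny_genes], ["s1", "s2"])
        t.add("gA", "s2", "sense", 21, 7)
        libs = effective_library_sizes(t, samples)
        assert libs["s1"] == 5000  # sheet override
        assert libs["s2"] == 7  # assigned total fallback
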