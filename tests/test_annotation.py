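import numpy as np
import pytest

from rqcsirna.annotation import (
    AnnotationParseError,
    ConvergencePartner,
    GeneModel,
    classify_biotype,
    convergence_table,
    distance_class_of,
    find_convergent_partner,
    merge_intervals,
    read_annotation,
    read_bed12,
    read_gff3,
    sort_genes,
    write_gff3,
)


class TestGeneModel:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            GeneModel("g", "c", 200, 100, "+", "protein_coding", ((100, 200),))
        with pytest.raises(ValueError):
            GeneModel("g", "c", 100, 200, "+", "protein_coding", ())
        with pytest.raises(ValueError):
            GeneModel("g", "c", 100, 200, "+", "protein_coding", ((50, 150),))
        with pytest.raises(ValueError):
            GeneModel("g", "c", 100, 200, ".", "protein_coding", ((100, 200),))

    def test_three_prime_end_by_strand(self):
        plus = GeneModel("g", "c", 100, 200, "+", "protein_coding", ((100, 200),))
        minus = GeneModel("h", "c", 100, 200, "-", "protein_coding", ((100, 200),))
        assert plus.three_prime == 200
        assert minus.three_prime == 100


class TestGff3:
    def test_coordinate_convention_and_round_trip(self, tmp_path):
        # 1-based closed [101,200] in GFF3 becomes 0-based half-open [100,200)
        p = tmp_path / "a.gff3"
        p.write_text(
            "##gff-version 3\n"
            "Chr1\tsrc\tgene\t101\t200\t.\t+\t.\tID=g1;biotype=protein_coding\n"
            "Chr1\tsrc\texon\t101\t200\t.\t+\t.\tParent=g1\n"
        )
        (gene,) = read_gff3(str(p))
        assert (gene.start, gene.end) == (100, 200)
        # write and re-read: exact inverse
        out = tmp_path / "b.gff3"
        write_gff3([gene], str(out))
        (back,) = read_gff3(str(out))
        assert back == gene

    def test_exon_union_across_isoforms(self, tmp_path):
        p = tmp_path / "a.gff3"
        p.write_text(
            "Chr1\ts\tgene\t101\t300\t.\t+\t.\tID=g1;biotype=protein_coding\n"
            "Chr1\ts\tmRNA\t101\t300\t.\t+\t.\tID=g1.1;Parent=g1\n"
            "Chr1\ts\tmRNA\t101\t300\t.\t+\t.\tID=g1.2;Parent=g1\n"
            "Chr1\ts\texon\t101\t150\t.\t+\t.\tParent=g1.1\n"
            "Chr1\ts\texon\t141\t180\t.\t+\t.\tParent=g1.2\n"
        )
        (gene,) = read_gff3(str(p))
        assert gene.exons == ((100, 180),)

    def test_gene_without_exons_gets_body(self, tmp_path):
        p = tmp_path / "a.gff3"
        p.write_text("Chr1\ts\tgene\t1\t100\t.\t-\t.\tID=g1;biotype=protein_coding\n")
        (gene,) = read_gff3(str(p))
        assert gene.exons == ((0, 100),)

    def test_malformed_record_names_line(self, tmp_path):
        p = tmp_path / "a.gff3"
        p.write_text("Chr1\ts\tgene\t1\t100\n")
        with pytest.raises(AnnotationParseError, match=":1:"):
            read_gff3(str(p))

    def test_biotype_table_lookup(self):
        assert classify_biotype("transposable_element_gene") == "pseudogene_te"
        assert classify_biotype("tRNA") == "structural_rna"

    def test_unmapped_biotype_warns_to_other(self, caplog):
        with caplog.at_level("WARNING"):
            assert classify_biotype("weird_new_type") == "other"
        assert "unmapped biotype" in caplog.text


class TestBed12:
    def test_blocks_become_exons(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text(
            "Chr1\t100\t500\tg1\t0\t+\t100\t500\t0\t2\t100,100\t0,300\tprotein_coding\n"
        )
        (gene,) = read_bed12(str(p))
        assert gene.start == 100 and gene.end == 500
        assert gene.exons == ((100, 200), (400, 500))
        assert gene.biotype == "protein_coding"

    def test_dispatch_and_malformed(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("Chr1\t100\t500\tg1\n")
        with pytest.raises(AnnotationParseError):
            read_annotation(str(p), format="bed12")
        with pytest.raises(ValueError):
            read_annotation(str(p), format="nope")


def _gene(gid, start, end, strand, chrom="Chr1", biotype="protein_coding"):
    return GeneModel(gid, chrom, start, end, strand, biotype, ((start, end),))


class TestConvergentPartner:
    def test_near_partner_is_lt_class(self):
        focal = _gene("f", 200, 1000, "+")
        partner = _gene("p", 1300, 2000, "-")
        genes = sort_genes([focal, partner])
        rec = find_convergent_partner(focal, genes)
        assert rec.partner_gene_id == "p"
        assert rec.distance_bp == 300
        assert rec.distance_class == "convergent_lt_threshold"

    def test_far_partner_is_ge_class(self):
        focal = _gene("f", 200, 1000, "+")
        partner = _gene("p", 1500, 2000, "-")
        rec = find_convergent_partner(focal, sort_genes([focal, partner]))
        assert rec.distance_bp == 500
        assert rec.distance_class == "convergent_ge_threshold"

    def test_same_strand_downstream_is_no_partner(self):
        focal = _gene("f", 200, 1000, "+")
        other = _gene("p", 1300, 2000, "+")
        rec = find_convergent_partner(focal, sort_genes([focal, other]))
        assert rec.partner_gene_id is None
        assert rec.distance_class == "no_partner"

    def test_overlapping_tail_to_tail_negative_distance(self):
        focal = _gene("f", 200, 1000, "+")
        partner = _gene("p", 900, 2000, "-")
        rec = find_convergent_partner(focal, sort_genes([focal, partner]))
        assert rec.distance_bp == -100
        assert rec.distance_class == "convergent_lt_threshold"

    def test_minus_strand_focal_symmetric(self):
        a = _gene("a", 200, 1000, "+")
        b = _gene("b", 1300, 2000, "-")
        genes = sort_genes([a, b])
        rec_b = find_convergent_partner(b, genes)
        rec_a = find_convergent_partner(a, genes)
        assert rec_b.partner_gene_id == "a"
        assert rec_a.partner_gene_id == "b"
        assert rec_a.distance_bp == rec_b.distance_bp == 300

    def test_nearest_tie_breaks_lexicographically(self):
        focal = _gene("f", 200, 1000, "+")
        p1 = _gene("zz", 1300, 2000, "-")
        p2 = _gene("aa", 1300, 2100, "-")
        rec = find_convergent_partner(focal, sort_genes([focal, p1, p2]))
        assert rec.partner_gene_id == "aa"

    def test_errors(self):
        focal = _gene("f", 200, 1000, "+")
        other = _gene("p", 1300, 2000, "-")
        with pytest.raises(ValueError, match="sorted"):
            find_convergent_partner(focal, [other, focal])
        with pytest.raises(ValueError, match="absent"):
            find_convergent_partner(_gene("x", 5, 50, "+"), sort_genes([focal, other]))
        with pytest.raises(ValueError):
            find_convergent_partner(focal, sort_genes([focal, other]), max_scan_bp=0)

    def test_beyond_scan_window_is_no_partner(self):
        focal = _gene("f", 200, 1000, "+")
        far = _gene("p", 20000, 21000, "-")
        rec = find_convergent_partner(focal, sort_genes([focal, far]), max_scan_bp=10_000)
        assert rec.distance_class == "no_partner"

    def test_distance_class_pure_function(self):
        assert distance_class_of(None) == "no_partner"
        assert distance_class_of(399) == "convergent_lt_threshold"
        assert distance_class_of(400) == "convergent_ge_threshold"
        assert distance_class_of(-50, threshold=400) == "convergent_lt_threshold"


class TestConvergenceTable:
    def test_matches_single_gene_search(self):
        rng = np.random.default_rng(42)
        genes = []
        cursor = 0
        for i in range(60):
            length = int(rng.integers(500, 3000))
            gap = int(rng.integers(50, 4000))
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(_gene(f"g{i:03d}", cursor, cursor + length, strand))
            cursor += length + gap
        genes = sort_genes(genes)
        table = convergence_table(genes, max_scan_bp=5000)
        for g in genes:
            assert table[g.gene_id] == find_convergent_partner(g, genes, max_scan_bp=5000)

    def test_classes_partition_gene_set(self):
        rng = np.random.default_rng(0)
        genes = sort_genes(
            [_gene(f"g{i}", 10_000 * i, 10_000 * i + int(rng.integers(500, 3000)),
                   "+" if rng.random() < 0.5 else "-") for i in range(40)]
        )
        table = convergence_table(genes)
        classes = [table[g.gene_id].distance_class for g in genes]
        counts = {c: classes.count(c) for c in set(classes)}
        assert sum(counts.values()) == len(genes)


def test_merge_intervals_union():
    assert merge_intervals([(100, 150), (140, 180)]) == ((100, 180),)
    assert merge_intervals([(0, 10), (20, 30)]) == ((0, 10), (20, 30))
    assert merge_intervals([(0, 10), (10, 20)]) == ((0, 20),)
    assert merge_intervals([]) == ()


def test_convergence_partner_record_invariants():
    with pytest.raises(ValueError):
        ConvergencePartner("f", None, 100, "no_partner")
    with pytest.raises(ValueError):
        ConvergencePartner("f", "p", 100, "bogus_class")
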