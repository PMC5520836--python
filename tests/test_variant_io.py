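"""Parsing, writing and round-trip behaviour of the variant table formats."""

import dataclasses

import pysam
import pytest

from conftest import make_snp
from ricevar import variant_io
from ricevar.records import CoverageMask, IndelRecord, SnpRecord, SvRecord

SNP_LINE = "Chr01 1203 A G 40 G 40 12 15 A 5 1 2 17 1&40 1.0 0 350\n"


class TestSnpTable:
    def test_parse_single_line_field_semantics(self, tmp_path):
        path = tmp_path / "snp.tsv"
        path.write_text(SNP_LINE)
        records = variant_io.read_snp_table(path)
        assert len(records) == 1 and records.skipped == 0
        r = records[0]
        assert (r.chrom, r.pos, r.ref_base, r.genotype) == ("Chr01", 1203, "A", "G")
        assert (r.quality, r.best_base, r.best_quality) == (40, "G", 40)
        assert (r.best_unique_reads, r.best_all_reads) == (12, 15)
        assert (r.second_base, r.second_quality) == ("A", 5)
        assert (r.total_reads, r.rank_field, r.copy_number) == (17, "1&40", 1.0)
        assert (r.in_dbsnp, r.nearest_snp_distance) == (0, 350)

    def test_empty_file_gives_empty_list(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("")
        records = variant_io.read_snp_table(path)
        assert list(records) == [] and records.skipped == 0

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            variant_io.read_snp_table(tmp_path / "nope.tsv")

    @pytest.mark.parametrize(
        "bad_line",
        [
            "Chr01 1203 A G 40\n",  # wrong column count
            SNP_LINE.replace(" G 40 G", " Z 40 G"),  # non-IUPAC genotype
            "Chr01 0 A G 40 G 40 12 15 A 5 1 2 17 x 1.0 0 350\n",  # pos < 1
        ],
    )
    def test_strict_rejects_lenient_skips(self, tmp_path, bad_line):
        path = tmp_path / "snp.tsv"
        path.write_text(SNP_LINE + bad_line)
        with pytest.raises(ValueError):
            variant_io.read_snp_table(path, strict=True)
        records = variant_io.read_snp_table(path, strict=False)
        assert len(records) == 1 and records.skipped == 1

    def test_mixed_delimiters_read_single_tab_written(self, tmp_path):
        path = tmp_path / "snp.tsv"
        path.write_text(SNP_LINE.replace(" ", "\t \t", 3))
        records = variant_io.read_snp_table(path)
        out = tmp_path / "out.tsv"
        variant_io.write_snp_table(out, records)
        line = out.read_text().rstrip("\n")
        assert line.count("\t") == 17 and " " not in line.replace("1&40", "")


def test_round_trip_identity_all_three_formats(default_sim, tmp_path):
    """write then read reproduces every record field-for-field, for all
    three custom table dialects, on simulator-generated tables."""
    _, _, _, lines = default_sim
    cases = [
        ("snp", lines.snp_tables["focal"],
         variant_io.write_snp_table, variant_io.read_snp_table),
        ("indel", lines.indel_tables["focal"],
         variant_io.write_indel_table, variant_io.read_indel_table),
        ("sv", lines.sv_tables["focal"],
         variant_io.write_sv_table, variant_io.read_sv_table),
    ]
    for name, records, write, read in cases:
        assert len(records) > 50 or name == "sv"
        path = tmp_path / f"{name}.tsv"
        write(path, records)
        back = read(path)
        assert [dataclasses.asdict(r) for r in back] == [
            dataclasses.asdict(r) for r in records
        ]


class TestIndelTable:
    def test_type_field_dialects(self, tmp_path):
        path = tmp_path / "indel.tsv"
        path.write_text(
            "chr01\t10\tI2\tAT\t+\thom\t30.0\t4\t9\n"
            "chr01\t20\t+3\tGGG\t*\thet\t30.0\t4\t9\n"
            "chr01\t30\tD1\tC\t-\thom\t30.0\t4\t9\n"
            "chr01\t40\t-2\tCA\t+\thom\t30.0\t4\t9\n"
        )
        kinds = [(r.indel_kind, r.indel_length) for r in variant_io.read_indel_table(path)]
        assert kinds == [
            ("insertion", 2), ("insertion", 3), ("deletion", 1), ("deletion", 2)
        ]

    def test_bases_length_mismatch_rejected(self, tmp_path):
        path = tmp_path / "indel.tsv"
        path.write_text("chr01\t10\tI2\tATG\t+\thom\t30.0\t4\t9\n")
        with pytest.raises(ValueError, match="indel_length"):
            variant_io.read_indel_table(path)


class TestSvTable:
    def test_breakpoint_only_for_insertion(self, tmp_path):
        path = tmp_path / "sv.tsv"
        path.write_text(
            "chr01\tinsertion\t90\t220\t100\t200\t101\t100\tFR\t5\n"
            "chr01\tdeletion\t90\t220\t100\t200\t101\t.\tRR\t5\n"
        )
        recs = variant_io.read_sv_table(path)
        assert recs[0].insertion_breakpoint == 100
        assert recs[1].insertion_breakpoint is None
        # a deletion carrying a breakpoint violates the invariant
        path.write_text("chr01\tdeletion\t90\t220\t100\t200\t101\t100\tFR\t5\n")
        with pytest.raises(ValueError):
            variant_io.read_sv_table(path)

    def test_cluster_bound_ordering_enforced(self, tmp_path):
        path = tmp_path / "sv.tsv"
        path.write_text("chr01\tdeletion\t150\t220\t100\t200\t101\t.\tF\t5\n")
        with pytest.raises(ValueError):
            variant_io.read_sv_table(path)


class TestFastaGff3:
    def test_fasta_round_trip(self, tmp_path):
        genome = {"chr01": "ACGT" * 30, "chr02": "TTTTACGT"}
        path = tmp_path / "ref.fa"
        variant_io.write_fasta(path, genome)
        assert variant_io.read_fasta(path) == genome

    def test_gff3_split_cds_lengths(self, tmp_path):
        path = tmp_path / "g.gff3"
        path.write_text(
            "##gff-version 3\n"
            "chr01\tx\tgene\t1\t100\t.\t+\t.\tID=g1\n"
            "chr01\tx\tmRNA\t1\t100\t.\t+\t.\tID=m1;Parent=g1\n"
            "chr01\tx\texon\t1\t40\t.\t+\t.\tParent=m1\n"
            "chr01\tx\texon\t60\t100\t.\t+\t.\tParent=m1\n"
            "chr01\tx\tCDS\t10\t15\t.\t+\t0\tParent=m1\n"
            "chr01\tx\tCDS\t60\t62\t.\t+\t0\tParent=m1\n"
        )
        (model,) = variant_io.read_gff3(path)
        assert model.valid and model.cds_length == 9

    def test_overlapping_exons_rejected_in_strict_mode(self, tmp_path):
        path = tmp_path / "g.gff3"
        path.write_text(
            "chr01\tx\tmRNA\t1\t100\t.\t+\t.\tID=m1;Parent=g1\n"
            "chr01\tx\texon\t1\t50\t.\t+\t.\tParent=m1\n"
            "chr01\tx\texon\t40\t100\t.\t+\t.\tParent=m1\n"
        )
        with pytest.raises(ValueError, match="overlap"):
            variant_io.read_gff3(path, strict=True)
        (model,) = variant_io.read_gff3(path, strict=False)
        assert not model.valid

    def test_cds_not_multiple_of_three_flagged(self, tmp_path):
        path = tmp_path / "g.gff3"
        path.write_text(
            "chr01\tx\tmRNA\t1\t100\t.\t-\t.\tID=m1;Parent=g1\n"
            "chr01\tx\texon\t1\t100\t.\t-\t.\tParent=m1\n"
            "chr01\tx\tCDS\t10\t17\t.\t-\t0\tParent=m1\n"
        )
        (model,) = variant_io.read_gff3(path)
        assert not model.valid and "divisible by 3" in model.invalid_reason


class TestBedMask:
    def test_coordinate_conversion(self, tmp_path):
        path = tmp_path / "m.bed"
        path.write_text("chr1\t0\t100\n")
        mask = variant_io.read_bed_mask(path)
        assert mask.covered_bases("chr1") == 100
        assert mask.intervals("chr1") == [(1, 100)]
        assert mask.is_covered("chr1", 1) and mask.is_covered("chr1", 100)
        assert not mask.is_covered("chr1", 101)

    def test_bed_round_trip_is_self_inverse(self, tmp_path):
        mask = CoverageMask({"chr1": [(1, 100), (201, 250)], "chr2": [(5, 7)]})
        p1 = tmp_path / "a.bed"
        variant_io.write_bed_mask(p1, mask)
        back = variant_io.read_bed_mask(p1)
        assert back == mask
        p2 = tmp_path / "b.bed"
        variant_io.write_bed_mask(p2, back)
        assert p1.read_text() == p2.read_text()

    def test_covered_in_window_partial_overlap(self):
        mask = CoverageMask({"c": [(11, 20), (31, 40)]})
        assert mask.covered_in("c", 1, 100) == 20
        assert mask.covered_in("c", 15, 35) == 11
        assert mask.covered_in("c", 21, 30) == 0


class TestVcfExport:
    @pytest.mark.parametrize(
        "genotype,alt,gt",
        [("R", "G", "0/1"), ("G", "G", "1/1"), ("Y", "C,T", "1/2")],
    )
    def test_iupac_expansion_and_gt(self, genotype, alt, gt):
        text = variant_io.export_vcf([make_snp(ref="A", genotype=genotype)])
        body = [l for l in text.splitlines() if not l.startswith("#")]
        fields = body[0].split("\t")
        assert fields[3] == "A" and fields[4] == alt and fields[9] == gt

    def test_reference_genotype_skipped(self, caplog):
        text = variant_io.export_vcf([make_snp(ref="A", genotype="A")])
        assert not [l for l in text.splitlines() if not l.startswith("#")]

    def test_output_is_valid_vcf_for_pysam(self, default_sim, tmp_path):
        _, genome, _, lines = default_sim
        records = lines.snp_tables["focal"][:200]
        path = tmp_path / "out.vcf"
        path.write_text(variant_io.export_vcf(records, genome, sample="focal"))
        with pysam.VariantFile(str(path)) as vf:
            parsed = list(vf)
        assert len(parsed) == len(records)
        by_locus = {(r.chrom, r.pos): r for r in records}
        for v in parsed:
            rec = by_locus[(v.chrom, v.pos)]
            assert v.ref == rec.ref_base
            assert set(v.alts) == set(rec.alt_alleles)
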