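"""Variant normalization, catalog reading, gene assignment and cohort I/O."""

import pytest
from hypothesis import given, settings, strategies as st

from pvarch.catalog_io import (CohortVariantTable, GeneCatalog, GeneRecord,
                               assign_gene, merge_intervals, normalize_variant,
                               read_clinvar_table, read_cohort_variants,
                               read_gene_catalog, write_cohort_variants,
                               ClinicalClass)
from pvarch.errors import FormatError, NotASNVError, ValidationError


class TestNormalizeVariant:
    @pytest.mark.parametrize("chrom,pos,ref,alt,expected", [
        ("chr17", 43051071, "g", "a", ("17", 43051071, "G", "A")),
        ("1", 100, "C", "T", ("1", 100, "C", "T")),
        ("chrX", 5, "a", "G", ("X", 5, "A", "G")),
    ])
    def test_canonicalization(self, chrom, pos, ref, alt, expected):
        v = normalize_variant(chrom, pos, ref, alt)
        assert v.key == expected

    @pytest.mark.parametrize("ref,alt,exc", [
        ("AT", "A", NotASNVError),     # deletion
        ("A", "AT", NotASNVError),     # insertion
        ("C", "C", ValidationError),   # identity
        ("N", "A", ValidationError),   # alphabet
    ])
    def test_rejects_non_snvs(self, ref, alt, exc):
        with pytest.raises(exc):
            normalize_variant("1", 100, ref, alt)

    @given(chrom=st.sampled_from(["1", "chr1", "X", "chrMT"]),
           pos=st.integers(1, 10**9),
           ref=st.sampled_from("ACGT"), alt=st.sampled_from("acgt"))
    @settings(max_examples=200)
    def test_idempotent(self, chrom, pos, ref, alt):
        if ref.upper() == alt.upper():
            return
        v = normalize_variant(chrom, pos, ref, alt)
        again = normalize_variant(v.chrom, v.pos, v.ref, v.alt)
        assert again == v and again.chrom == v.chrom


class TestGeneCatalog:
    def test_packaged_catalog_shape(self, ddr_catalog):
        assert len(ddr_catalog) == 169
        assert len(ddr_catalog.pathways["Fanconi anemia"]) == 49
        assert set(ddr_catalog.pathways) == {
            "Homologous Recombination", "DNA damage response", "Fanconi anemia",
            "Mismatch Repair", "Nonhomologous end joining",
            "Nucleotide excision repair", "Base excision repair", "DNA replication"}

    def test_empty_file_is_format_error(self, tmp_path):
        p = tmp_path / "empty.tsv"
        p.write_text("")
        with pytest.raises(FormatError):
            read_gene_catalog(p)

    def test_missing_column_is_format_error(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("gene\tpathway\tchrom\n")
        with pytest.raises(FormatError):
            read_gene_catalog(p)

    def test_unknown_pathway_reported(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("gene\tpathway\tchrom\tstart\tend\nG1\tNot A Pathway\t1\t0\t10\n")
        with pytest.raises(ValidationError, match="Not A Pathway"):
            read_gene_catalog(p)

    def test_gene_in_two_pathways_listed_once(self, tmp_path):
        p = tmp_path / "cat.tsv"
        p.write_text("gene\tpathway\tchrom\tstart\tend\n"
                     "G1\tFanconi anemia\t1\t0\t10\n"
                     "G1\tHomologous Recombination\t1\t0\t10\n")
        cat = read_gene_catalog(p)
        assert len(cat) == 1
        assert "G1" in cat.pathways["Fanconi anemia"]
        assert "G1" in cat.pathways["Homologous Recombination"]

    def test_case_insensitive_lookup(self, ddr_catalog):
        assert "brca1" in ddr_catalog
        assert ddr_catalog["tp53"].symbol == "TP53"

    def test_interval_merge(self):
        merged = merge_intervals([("1", 10, 20), ("1", 15, 30), ("2", 0, 5)])
        assert merged == [("1", 10, 30), ("2", 0, 5)]


class TestAssignGene:
    def test_three_base_interval_boundaries(self):
        cat = GeneCatalog({"G": GeneRecord("G", ("Mismatch Repair",), [("1", 10, 13)])})
        # 0-based [10,13) covers 1-based positions 11..13 exactly
        for pos in range(8, 17):
            v = normalize_variant("1", pos, "A", "C")
            got = assign_gene(v, cat)
            assert (got == ("G", True)) == (11 <= pos <= 13)

    def test_absent_chromosome(self, toy_catalog):
        assert assign_gene(normalize_variant("9", 150, "A", "G"), toy_catalog) is None

    def test_nested_interval_inner_gene_wins(self, toy_catalog):
        inner = assign_gene(normalize_variant("1", 130, "A", "G"), toy_catalog)
        outer = assign_gene(normalize_variant("1", 105, "A", "G"), toy_catalog)
        assert inner == ("GB", True)
        assert outer == ("GA", True)

    @given(data=st.data())
    @settings(max_examples=50, deadline=None)
    def test_agrees_with_brute_force(self, data):
        n = data.draw(st.integers(1, 30))
        genes = {}
        for i in range(n):
            start = data.draw(st.integers(0, 500))
            length = data.draw(st.integers(1, 60))
            sym = f"G{i:02d}"
            genes[sym] = GeneRecord(sym, ("DNA replication",),
                                    [("1", start, start + length)])
        cat = GeneCatalog(genes)
        pos = data.draw(st.integers(1, 600))
        v = normalize_variant("1", pos, "A", "T")
        hits = [s for s, r in genes.items()
                if r.coding_intervals[0][1] <= pos - 1 < r.coding_intervals[0][2]]
        expected = min(hits, key=lambda s: (
            genes[s].coding_intervals[0][2] - genes[s].coding_intervals[0][1], s)) \
            if hits else None
        got = assign_gene(v, cat)
        assert (got[0] if got else None) == expected


VCF_HEADER = """##fileformat=VCFv4.2
##INFO=<ID=AC,Number=A,Type=Integer,Description="Allele count">
##INFO=<ID=AN,Number=1,Type=Integer,Description="Allele number">
##contig=<ID=1>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


class TestCohortIO:
    def test_vcf_indel_dropped(self, tmp_path):
        p = tmp_path / "c.vcf"
        p.write_text(VCF_HEADER +
                     "1\t100\t.\tA\tG\t.\t.\tAC=3;AN=100\n"
                     "1\t200\t.\tAT\tA\t.\t.\tAC=1;AN=100\n"
                     "1\t300\t.\tC\tT\t.\t.\tAC=0;AN=100\n")
        table = read_cohort_variants(p, "toy", 50)
        assert len(table.rows) == 2
        # AC=0 row retained; presence is decided downstream
        assert [ac for _, ac, _, _ in table.rows] == [3, 0]

    def test_tsv_and_vcf_agree(self, tmp_path):
        vcf = tmp_path / "c.vcf"
        vcf.write_text(VCF_HEADER +
                       "1\t100\t.\tA\tG\t.\t.\tAC=3;AN=100\n"
                       "1\t300\t.\tC\tT\t.\t.\tAC=7;AN=100\n")
        tsv = tmp_path / "c.tsv"
        tsv.write_text("chrom\tpos\tref\talt\tallele_count\tallele_number\n"
                       "1\t100\tA\tG\t3\t100\n1\t300\tC\tT\t7\t100\n")
        t1 = read_cohort_variants(vcf, "toy", 50, consequence_field=None)
        t2 = read_cohort_variants(tsv, "toy", 50)
        assert [(v.key, ac, an) for v, ac, an, _ in t1.rows] == \
               [(v.key, ac, an) for v, ac, an, _ in t2.rows]

    def test_ac_exceeding_an_rejected(self, tmp_path):
        tsv = tmp_path / "c.tsv"
        tsv.write_text("chrom\tpos\tref\talt\tallele_count\tallele_number\n"
                       "1\t100\tA\tG\t101\t100\n")
        with pytest.raises(ValidationError):
            read_cohort_variants(tsv, "toy", 50)

    def test_round_trip(self, tmp_path):
        rows = [(normalize_variant("2", 50, "G", "C"), 4, 40, "stopgain"),
                (normalize_variant("1", 10, "A", "G"), 1, 40, "")]
        table = CohortVariantTable("toy", 20, sorted(
            rows, key=lambda r: (r[0].chrom, r[0].pos)))
        p = tmp_path / "out.tsv"
        write_cohort_variants(table, p)
        back = read_cohort_variants(p, "toy", 20)
        assert [(v.key, ac, an, c) for v, ac, an, c in back.rows] == \
               [(v.key, ac, an, c) for v, ac, an, c in table.rows]

    def test_an_exceeding_sample_size_rejected(self):
        with pytest.raises(ValidationError):
            CohortVariantTable("toy", 10, [(normalize_variant("1", 1, "A", "C"),
                                            1, 30, "")])


class TestClinvarTable:
    def test_merge_rules(self, tmp_path):
        p = tmp_path / "cv.tsv"
        p.write_text("chrom\tpos\tref\talt\tsignificance\n"
                     "1\t10\tA\tG\tPathogenic\n"
                     "1\t10\tA\tG\tPathogenic\n"        # identical dup: collapses
                     "1\t20\tC\tT\tPathogenic\n"
                     "1\t20\tC\tT\tBenign\n"            # conflicting dup
                     "1\t30\tG\tA\tPathogenic/Likely pathogenic\n")
        out = read_clinvar_table(p)
        assert len(out) == 3
        key = normalize_variant("1", 20, "C", "T")
        assert out[key].clinical_class is ClinicalClass.CONFLICTING
        assert out[normalize_variant("1", 10, "A", "G")].clinical_class is ClinicalClass.PV
        assert out[normalize_variant("1", 30, "G", "A")].clinical_class is ClinicalClass.PV

    def test_empty_table(self, tmp_path):
        p = tmp_path / "cv.tsv"
        p.write_text("chrom\tpos\tref\talt\tsignificance\n")
        assert read_clinvar_table(p) == {}
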