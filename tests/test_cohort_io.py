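"""Table reading/writing and packaged fixture integrity."""

import hashlib

import pytest

from vus_triage.cohort_io import (
    CohortTable,
    fixture_path,
    load_fixture,
    read_report,
    read_variant_table,
    write_report,
)
from vus_triage.domain import Tier, VusSubclass
from vus_triage.errors import RowError, SchemaError
from vus_triage.pipeline import reproduce_study

# sha256 of the packaged fixtures; a mismatch means a silent edit
FIXTURE_CHECKSUMS = {
    "table2": "7ec5b9c240bca119a15679990812e5617d1c1d1acf0ef4e1117af715c1dc9020",
    "table3": "e43d970a30937f68b6c3708115f467f27375a0368b88beef69f319b55ba120fb",
    "table4": "8376a463db710a45bfb72e81a9367b87d58815ba92eeff17bd621fce558b09f5",
}


class TestFixtures:
    @pytest.mark.parametrize("name", sorted(FIXTURE_CHECKSUMS))
    def test_fixture_checksum_pinned(self, name):
        digest = hashlib.sha256(fixture_path(name).read_bytes()).hexdigest()
        assert digest == FIXTURE_CHECKSUMS[name]

    def test_table2_counts(self, table2):
        assert len(table2.records) == 20
        assert len(table2.patient_ids()) == 22
        assert all(rec.tier in (Tier.P, Tier.LP) for rec in table2.records)

    def test_table3_counts(self, table3):
        assert len(table3.records) == 39
        splice = [r for r in table3.records if r.subclass is VusSubclass.SPLICE]
        assert len(splice) == 4
        excluded = [r for r in table3.records if r.excluded_reclass]
        assert len(excluded) == 3
        assert all(r.exclusion_reason for r in excluded)

    def test_table4_counts(self, table4):
        assert len(table4.records) == 13
        assert all(rec.evidence is not None for rec in table4.records)

    def test_gnomad_presence_absence_semantics(self, table3):
        by_c = {r.variant.hgvs_c: r for r in table3.records if r.variant.gene == "SPTBN2"}
        assert by_c["c.7109G>A"].variant.population == (24, 245754)
        assert by_c["c.6169G>T"].variant.population is None

    def test_unknown_fixture_rejected(self):
        with pytest.raises(SchemaError):
            load_fixture("table99")


class TestReadVariantTable:
    HEADER = "patient_ids\tgene\ttranscript\thgvs_c\tconsequence\n"

    def test_header_only_gives_empty_table(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text(self.HEADER)
        table = read_variant_table(path, cohort_size=10)
        assert len(table.records) == 0

    def test_missing_mandatory_column_names_absentees(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("patient_ids\tgene\thgvs_c\n1\tMME\tc.1A>T\n")
        with pytest.raises(SchemaError, match="transcript"):
            read_variant_table(path)

    def test_unparseable_numeric_cell_reports_line(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            self.HEADER.rstrip("\n") + "\tdepth\n"
            + "1\tMME\tNM_1\tc.1A>T\tmissense\tforty\n"
        )
        with pytest.raises(RowError, match="row 2"):
            read_variant_table(path)

    def test_extra_columns_preserved_as_opaque_attributes(self, tmp_path):
        path = tmp_path / "extra.tsv"
        path.write_text(
            self.HEADER.rstrip("\n") + "\tlab_note\n"
            + "1\tMME\tNM_1\tc.1A>T\tmissense\thello\n"
        )
        table = read_variant_table(path, cohort_size=1)
        assert table.records[0].variant.extras["lab_note"] == "hello"

    def test_combined_ac_an_string_parsed(self, tmp_path):
        path = tmp_path / "af.tsv"
        path.write_text(
            self.HEADER.rstrip("\n") + "\tgnomad_af\n"
            + "1\tMME\tNM_1\tc.1A>T\tmissense\t24/245754\n"
            + "2\tMME\tNM_1\tc.2A>T\tmissense\t—\n"
        )
        table = read_variant_table(path, cohort_size=2)
        assert table.records[0].variant.population == (24, 245754)
        assert table.records[1].variant.population is None

    def test_cohort_size_must_cover_patients(self, table2):
        with pytest.raises(Exception):
            CohortTable(records=table2.records, cohort_size=5)


class TestVcfDialect:
    def test_minimal_annotated_vcf(self, tmp_path):
        vcf = tmp_path / "mini.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##INFO=<ID=PATIENTS,Number=.,Type=String,Description="carriers">\n'
            '##INFO=<ID=GENE,Number=1,Type=String,Description="gene">\n'
            '##INFO=<ID=TRANSCRIPT,Number=1,Type=String,Description="tx">\n'
            '##INFO=<ID=HGVSC,Number=1,Type=String,Description="cdna">\n'
            '##INFO=<ID=CSQ_CLASS,Number=1,Type=String,Description="csq">\n'
            '##INFO=<ID=DP,Number=1,Type=Integer,Description="depth">\n'
            "##contig=<ID=19>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "19\t13318673\t.\tC\tT\t50\tPASS\t"
            "PATIENTS=1;GENE=CACNA1A;TRANSCRIPT=NM_023035.2;"
            "HGVSC=c.835C>T;CSQ_CLASS=missense;DP=88\n"
        )
        table = read_variant_table(vcf, dialect="vcf", cohort_size=1)
        assert len(table.records) == 1
        rec = table.records[0]
        assert rec.variant.gene == "CACNA1A"
        assert rec.variant.read_depth == 88
        assert rec.variant.hgvs_c == "c.835C>T"


class TestReportSerialization:
    def test_round_trip_identity_both_formats(self, tmp_path):
        report = reproduce_study().report
        for fmt in ("tsv", "json"):
            path = tmp_path / f"report.{fmt}"
            write_report(report, path, fmt)
            back = read_report(path, fmt)
            assert back.tier_counts == report.tier_counts
            assert back.subclass_counts == report.subclass_counts
            assert back.per_gene == report.per_gene
            assert back.diagnosed_patients_before == report.diagnosed_patients_before
            assert back.yield_after_pct == report.yield_after_pct

    def test_json_and_tsv_numerically_identical(self, tmp_path):
        report = reproduce_study().report
        write_report(report, tmp_path / "r.tsv", "tsv")
        write_report(report, tmp_path / "r.json", "json")
        a = read_report(tmp_path / "r.tsv", "tsv")
        b = read_report(tmp_path / "r.json", "json")
        assert a == b

    def test_empty_report_round_trips(self, tmp_path):
        from vus_triage.report import CohortReport

        empty = CohortReport(cohort_size=348)
        write_report(empty, tmp_path / "e.tsv", "tsv")
        back = read_report(tmp_path / "e.tsv", "tsv")
        assert sum(back.tier_counts.values()) == 0
        assert back.yield_before_pct == 0.0
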