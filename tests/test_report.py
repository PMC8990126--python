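"""Cohort counting and diagnostic-yield arithmetic."""

import pytest

from vus_triage.cohort_io import PANEL_GENES, CohortTable
from vus_triage.domain import Tier
from vus_triage.errors import DataError
from vus_triage.pipeline import (
    classify_record,
    curated_lookup_from_fixture,
    join_evidence,
)
from vus_triage.report import count_report, diagnostic_yield, truncate_pct


class TestDiagnosticYield:
    @pytest.mark.parametrize(
        "n_diagnosed, cohort, expected",
        [(22, 348, 6.3), (0, 348, 0.0), (26, 348, 7.4), (348, 348, 100.0)],
    )
    def test_yields_truncated_to_one_decimal(self, n_diagnosed, cohort, expected):
        diagnosed = {f"p{i}" for i in range(n_diagnosed)}
        assert diagnostic_yield(diagnosed, cohort) == expected

    def test_truncation_not_rounding(self):
        # 26/348 = 7.4712...% prints as 7.4, and 4/13 = 30.7% as 30
        assert diagnostic_yield({f"p{i}" for i in range(26)}, 348) == 7.4
        assert truncate_pct(100 * 4 / 13, decimals=0) == 30

    def test_zero_cohort_is_an_error(self):
        with pytest.raises(DataError):
            diagnostic_yield(set(), 0)

    def test_more_diagnosed_than_cohort_is_an_error(self):
        with pytest.raises(DataError):
            diagnostic_yield({"a", "b"}, 1)


def classify_all(table, lookup=None):
    return [classify_record(rec, lookup) for rec in table.records]


class TestCountReport:
    def test_table2_tier_counts_and_patients(self, table2):
        report = count_report(table2, classify_all(table2))
        assert report.tier_counts["P"] == 15
        assert report.tier_counts["LP"] == 5
        assert len(report.diagnosed_patients_before) == 22
        assert report.yield_before_pct == 6.3

    def test_table3_subclass_counts(self, table3):
        report = count_report(table3, classify_all(table3))
        assert report.subclass_counts == {
            "low": 0, "semi_high": 23, "high": 12, "splice": 4,
        }

    def test_empty_cohort_gives_zero_report(self):
        empty = CohortTable(records=[], cohort_size=348)
        report = count_report(empty, [])
        assert sum(report.tier_counts.values()) == 0
        assert report.yield_before_pct == 0.0
        assert report.yield_delta_pct == 0.0

    def test_multi_patient_variant_counts_once_but_diagnoses_all(self, table2):
        """20 unique variants diagnose 22 patients (two 2-patient variants)."""
        report = count_report(table2, classify_all(table2))
        assert sum(report.tier_counts.values()) == 20
        assert len(report.diagnosed_patients_before) == 22

    def test_yield_monotonicity(self, table2, table3, table4):
        combined = CohortTable(
            records=table2.records + table3.records, cohort_size=348
        )
        evidence = join_evidence(combined, table4)
        report = count_report(
            combined, classify_all(combined, curated_lookup_from_fixture()), evidence
        )
        assert report.yield_after_pct >= report.yield_before_pct
        assert report.yield_delta_pct == truncate_pct(
            report.yield_after_pct - report.yield_before_pct
        )

    def test_misaligned_classifications_rejected(self, table2):
        with pytest.raises(DataError):
            count_report(table2, [])


class TestPerGene:
    def test_cacna1a_carries_most_variants(self, table2, table3):
        combined = CohortTable(records=table2.records + table3.records, cohort_size=348)
        report = count_report(
            combined,
            classify_all(combined, curated_lookup_from_fixture()),
            panel_genes=PANEL_GENES,
        )
        assert report.per_gene["CACNA1A"]["total"] == 10
        assert report.per_gene["DAB1"]["total"] == 1

    def test_every_panel_gene_appears(self, table2):
        report = count_report(
            table2, classify_all(table2), panel_genes=PANEL_GENES
        )
        assert set(report.per_gene) >= set(PANEL_GENES)
        assert report.per_gene["ATXN1"]["total"] == 0

    def test_sorted_by_gene_size_when_supplied(self, table2):
        from vus_triage.report import per_gene_distribution

        sizes = {"DAB1": 1_551_957, "NOP56": 5_801, "CACNA1A": 300_000}
        dist = per_gene_distribution(
            [r.variant for r in table2.records],
            classify_all(table2),
            panel_genes=("DAB1", "NOP56", "CACNA1A"),
            gene_sizes=sizes,
        )
        assert list(dist)[:3] == ["DAB1", "CACNA1A", "NOP56"]
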