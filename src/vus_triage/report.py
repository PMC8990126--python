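"""Cohort-level counting and diagnostic-yield arithmetic.

Counts are over unique variants (one record = one variant, however many
patients carry it), while diagnostic yield is over patients: a patient is
diagnosed when they carry at least one P or LP variant.  Percentages are
*truncated* — not rounded — to the reported precision, the convention under
which 26/348 prints as 7.4% and 4/13 as 30%.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .domain import Tier, VusSubclass
from .errors import DataError
from .reclassify import FollowUpEvidence, followed_up, reclassify
from .subclass import ClassificationRecord

PRIORITIZED_SUBCLASSES = (VusSubclass.SEMI_HIGH, VusSubclass.HIGH, VusSubclass.SPLICE)


def truncate_pct(value: float, decimals: int = 1) -> float:
    """Truncate a percentage to ``decimals`` places (toward zero)."""
    scale = 10 ** decimals
    # small epsilon guards against 7.4000000001-style float artifacts
    return math.floor(value * scale + 1e-9) / scale


def diagnostic_yield(
    diagnosed: Iterable[str], cohort_size: int, decimals: int = 1
) -> float:
    """Percentage of the cohort with a (likely) pathogenic finding, truncated."""
    if cohort_size <= 0:
        raise DataError("cohort_size must be positive")
    diagnosed = set(diagnosed)
    if len(diagnosed) > cohort_size:
        raise DataError("more diagnosed patients than the cohort size")
    return truncate_pct(100.0 * len(diagnosed) / cohort_size, decimals)


@dataclass
class CohortReport:
    """Counts, per-gene distribution and diagnostic yields for one cohort."""

    tier_counts: dict[str, int] = field(
        default_factory=lambda: {t.value: 0 for t in Tier}
    )
    subclass_counts: dict[str, int] = field(
        default_factory=lambda: {s.value: 0 for s in VusSubclass}
    )
    per_gene: dict[str, dict[str, int]] = field(default_factory=dict)
    diagnosed_patients_before: list[str] = field(default_factory=list)
    diagnosed_patients_after: list[str] = field(default_factory=list)
    cohort_size: int = 0
    n_followed_up: int = 0
    n_reclassified_lp: int = 0
    yield_before_pct: float = 0.0
    yield_after_pct: float = 0.0
    yield_delta_pct: float = 0.0

    def __post_init__(self):
        if not set(self.diagnosed_patients_before) <= set(self.diagnosed_patients_after):
            raise DataError("diagnosed-before must be a subset of diagnosed-after")


def per_gene_distribution(
    records,
    classifications: Sequence[ClassificationRecord],
    panel_genes: Iterable[str] | None = None,
    gene_sizes: Mapping[str, int] | None = None,
) -> dict[str, dict[str, int]]:
    """Per-gene counts of P/LP variants and prioritized VUSes.

    Every panel gene appears (zero-filled) when ``panel_genes`` is given;
    genes are ordered by descending size when ``gene_sizes`` is supplied,
    otherwise alphabetically.
    """
    genes = {g: {"p_lp": 0, "prioritized_vus": 0, "total": 0} for g in (panel_genes or ())}
    for rec, cls in zip(records, classifications):
        entry = genes.setdefault(rec.gene, {"p_lp": 0, "prioritized_vus": 0, "total": 0})
        if cls.tier in (Tier.P, Tier.LP):
            entry["p_lp"] += 1
            entry["total"] += 1
        elif cls.tier is Tier.VUS and cls.vus_subclass in PRIORITIZED_SUBCLASSES:
            entry["prioritized_vus"] += 1
            entry["total"] += 1
    if gene_sizes:
        order = sorted(genes, key=lambda g: (-gene_sizes.get(g, 0), g))
    else:
        order = sorted(genes)
    return {g: genes[g] for g in order}


def count_report(
    cohort,
    classifications: Sequence[ClassificationRecord],
    evidence: Sequence[FollowUpEvidence | None] | None = None,
    panel_genes: Iterable[str] | None = None,
    gene_sizes: Mapping[str, int] | None = None,
) -> CohortReport:
    """Build the cohort report from per-variant classifications.

    ``classifications`` (and ``evidence``, when given) align with
    ``cohort.records``.  The "after" diagnosed set additionally counts
    patients whose VUS was promoted to LP by follow-up evidence; records
    flagged ``excluded_reclass`` (patient re-diagnosed with another
    condition) are skipped in follow-up counting and reclassification.
    """
    records = cohort.records
    if len(classifications) != len(records):
        raise DataError("classifications must align with cohort records")
    if evidence is None:
        evidence = [None] * len(records)
    if len(evidence) != len(records):
        raise DataError("evidence must align with cohort records")

    report = CohortReport(cohort_size=cohort.cohort_size)
    diagnosed_before: set[str] = set()
    diagnosed_after: set[str] = set()

    for rec, cls, ev in zip(records, classifications, evidence):
        report.tier_counts[cls.tier.value] += 1
        if cls.vus_subclass is not None:
            report.subclass_counts[cls.vus_subclass.value] += 1
        if cls.tier in (Tier.P, Tier.LP):
            diagnosed_before |= rec.variant.patient_ids
            diagnosed_after |= rec.variant.patient_ids
            continue
        if cls.tier is not Tier.VUS or ev is None or rec.excluded_reclass:
            continue
        if followed_up(ev):
            report.n_followed_up += 1
        if reclassify(cls, ev) is Tier.LP:
            report.n_reclassified_lp += 1
            diagnosed_after |= rec.variant.patient_ids

    report.per_gene = per_gene_distribution(
        [r.variant for r in records], classifications, panel_genes, gene_sizes
    )
    report.diagnosed_patients_before = sorted(diagnosed_before)
    report.diagnosed_patients_after = sorted(diagnosed_after)
    if cohort.cohort_size > 0:
        report.yield_before_pct = diagnostic_yield(diagnosed_before, cohort.cohort_size)
        report.yield_after_pct = diagnostic_yield(diagnosed_after, cohort.cohort_size)
    report.yield_delta_pct = truncate_pct(
        report.yield_after_pct - report.yield_before_pct
    )
    return report
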