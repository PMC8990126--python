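"""Pre-classification exclusion filters: read depth and population frequency.

Both filters mirror routine diagnostic practice: calls supported by fewer
than 20 reads are unreliable in pooled panel data and are dropped, and
variants seen at > 0.1% minor allele frequency in the reference population
are too common to cause a rare dominant ataxia and are dropped as benign.
Boundary values (depth exactly 20, MAF exactly 0.1%) are retained.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .domain import VariantRecord
from .errors import DataError


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for the exclusion filters.

    min_depth: minimum read depth (reads) to keep a call; default 20.
    max_maf: maximum population allele frequency to keep a variant;
        default 0.001 (0.1%).  Strictly greater frequencies are excluded.
    """

    min_depth: int = 20
    max_maf: float = 0.001

    def __post_init__(self):
        if self.min_depth <= 0:
            raise DataError("min_depth must be positive")
        if not (0.0 < self.max_maf < 1.0):
            raise DataError("max_maf must lie in (0, 1)")


@dataclass(frozen=True)
class Exclusion:
    """One excluded record with the reason it was dropped."""

    variant_id: str
    reason: str  # "low_depth" | "high_maf"
    value: float
    threshold: float


def filter_by_depth(
    records: Sequence[VariantRecord], config: FilterConfig = FilterConfig()
) -> tuple[list[VariantRecord], list[Exclusion]]:
    """Drop records with read depth below ``config.min_depth``.

    Depth must be present on every record (the filter runs on called
    variants, which always carry a depth).
    """
    kept: list[VariantRecord] = []
    excluded: list[Exclusion] = []
    for rec in records:
        if rec.read_depth is None:
            raise DataError(f"{rec.variant_id}: read_depth missing; cannot depth-filter")
        if rec.read_depth < config.min_depth:
            excluded.append(
                Exclusion(rec.variant_id, "low_depth", rec.read_depth, config.min_depth)
            )
        else:
            kept.append(rec)
    return kept, excluded


def filter_by_frequency(
    records: Sequence[VariantRecord], config: FilterConfig = FilterConfig()
) -> tuple[list[VariantRecord], list[Exclusion]]:
    """Drop records with population allele frequency above ``config.max_maf``.

    Records absent from the population database are retained (absence is
    evidence of rarity, not of unreliability).  A frequency exactly at the
    threshold is retained.
    """
    kept: list[VariantRecord] = []
    excluded: list[Exclusion] = []
    for rec in records:
        maf = rec.maf  # validates allele_number > 0 at construction
        if maf is not None and maf > config.max_maf:
            excluded.append(Exclusion(rec.variant_id, "high_maf", maf, config.max_maf))
        else:
            kept.append(rec)
    return kept, excluded


def apply_filters(
    records: Sequence[VariantRecord], config: FilterConfig = FilterConfig()
) -> tuple[list[VariantRecord], list[Exclusion]]:
    """Depth filter then frequency filter; the composition is order-independent."""
    kept, excl_depth = filter_by_depth(records, config)
    kept, excl_maf = filter_by_frequency(kept, config)
    return kept, excl_depth + excl_maf


def exclusion_log_frame(exclusions: Iterable[Exclusion]) -> pd.DataFrame:
    """Exclusion log as a table (variant_id, reason, value, threshold)."""
    return pd.DataFrame(
        [
            {
                "variant_id": e.variant_id,
                "reason": e.reason,
                "value": e.value,
                "threshold": e.threshold,
            }
            for e in exclusions
        ],
        columns=["variant_id", "reason", "value", "threshold"],
    )
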