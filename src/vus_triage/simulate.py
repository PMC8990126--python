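"""Synthetic panel cohorts with the statistical structure the pipeline assumes.

No patient-level data from the study cohort can be shared, so every stage of
the pipeline is exercised against simulated cohorts instead.  The generator
emulates the observed cohort structure: patients pooled four per sequencing
pool with occasional pool failures; roughly one rare panel variant per
patient; a five-tier mixture matching the reported 15 P / 5 LP / 105 VUS /
203 LB over 328 variants; VUS subclass structure 66 low / 23 semi-high /
12 high / 4 splice; class-conditional predictor scores drawn on the
normalized [0,1] scale; gnomAD presence/absence with MAF below 0.1% for
retained variants (plus a configurable fraction of common variants to
exercise the frequency filter); overdispersed read depths with a tail below
20; splice-tool score deltas; and sparse follow-up evidence (families are
available for only ~2 of 39 prioritized VUSes).

Ground-truth labels travel in a separate ``truth_*`` column namespace that a
``--blind`` flag strips, so the pipeline can never consume them by accident.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .cohort_io import PANEL_GENES, CohortTable, read_variant_table
from .domain import VusSubclass
from .errors import ConfigError
from .scoring import PREDICTORS
from .splicing import SPLICE_TOOLS
from .subclass import ClassificationRecord

#: Native score ranges of the four splice tools (used to place WT scores).
_TOOL_RANGES = {"nnsplice": 1.0, "maxentscan": 12.0, "genesplicer": 15.0, "ssf_like": 100.0}

_BASES = ("A", "C", "G", "T")

TRUTH_LABELS = ("P", "LP", "LB", "vus_low", "vus_semi_high", "vus_high", "vus_splice")


@dataclass(frozen=True)
class CohortSimConfig:
    """Study-condition parameters of the simulated cohort.

    Defaults reproduce the structure of the emulated cohort: 368 patients in
    92 pools of 4, a pool failure probability of 5/92 (so on average five
    pools drop, leaving ~348 analyzable patients), tier mixture proportional
    to the reported 15/5/105/203 variant counts and VUS subclass mixture
    66/23/12/4.
    """

    n_patients: int = 368
    pool_size: int = 4
    pool_failure_prob: float = 5 / 92
    mean_variants_per_patient: float = 1.0
    tier_probs: Mapping[str, float] = field(
        default_factory=lambda: {
            "P": 15 / 328, "LP": 5 / 328, "VUS": 105 / 328, "LB": 203 / 328,
        }
    )
    vus_subclass_probs: Mapping[str, float] = field(
        default_factory=lambda: {
            "low": 66 / 105, "semi_high": 23 / 105, "high": 12 / 105, "splice": 4 / 105,
        }
    )
    #: Class-conditional Beta(a, b) shapes for normalized predictor scores.
    predictor_beta: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "P": (8.0, 2.0), "LP": (8.0, 2.0), "LB": (1.5, 6.0),
            "vus_low": (2.0, 4.0), "vus_semi_high": (6.0, 2.0), "vus_high": (6.0, 2.0),
        }
    )
    #: Probability a variant of each truth class is present in gnomAD.
    gnomad_presence: Mapping[str, float] = field(
        default_factory=lambda: {
            "P": 0.3, "LP": 0.3, "LB": 0.9, "vus_low": 0.7,
            "vus_semi_high": 1.0, "vus_high": 0.0, "vus_splice": 0.5,
        }
    )
    #: log10 MAF range for database-present rare variants (below 0.1%).
    rare_maf_log10_range: tuple[float, float] = (-6.0, np.log10(9.9e-4))
    #: Fraction of raw variants that are common polymorphisms (MAF > 0.1%),
    #: present purely to exercise the frequency filter.
    common_variant_prob: float = 0.15
    common_maf_log10_range: tuple[float, float] = (np.log10(1.1e-3), np.log10(5e-2))
    depth_mean: float = 50.0
    depth_dispersion: float = 5.0  # negative-binomial n; smaller = heavier tail
    #: Splice-tool behavior for truth-splice variants.
    splice_delta_range: tuple[float, float] = (0.15, 0.6)
    neutral_delta_sd: float = 0.02
    neutral_splice_panel_prob: float = 0.1
    #: Follow-up availability and verdict probabilities.
    family_availability_prob: float = 2 / 39
    seg_support_prob: float = 1.0
    protein_model_prob: float = 8 / 35
    pm_lp_prob: float = 0.5
    functional_prob_missense: float = 2 / 35
    functional_prob_splice: float = 1.0
    ft_lp_prob: float = 0.5

    def validate(self) -> None:
        if self.n_patients <= 0 or self.pool_size <= 0:
            raise ConfigError("n_patients and pool_size must be positive")
        if self.n_patients % self.pool_size != 0:
            raise ConfigError(
                f"pool_size {self.pool_size} does not divide n_patients "
                f"{self.n_patients}; choose n_patients as a multiple of pool_size"
            )
        for name, probs in (("tier_probs", self.tier_probs),
                            ("vus_subclass_probs", self.vus_subclass_probs)):
            total = sum(probs.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigError(f"{name} must sum to 1 (got {total})")
            if any(p < 0 for p in probs.values()):
                raise ConfigError(f"{name} must be non-negative")
        for p in (self.pool_failure_prob, self.common_variant_prob,
                  self.family_availability_prob, self.seg_support_prob,
                  self.protein_model_prob, self.pm_lp_prob,
                  self.functional_prob_missense, self.functional_prob_splice,
                  self.ft_lp_prob, self.neutral_splice_panel_prob):
            if not (0.0 <= p <= 1.0):
                raise ConfigError(f"probability {p} outside [0, 1]")


def degenerate_config() -> CohortSimConfig:
    """A config under which subclass assignment is deterministic.

    Truth-high/semi-high variants get all predictor scores at the pathogenic
    extreme, truth-low at the benign extreme; no common variants; depths far
    above the filter threshold.  Used to verify perfect truth recovery.
    """
    return replace(
        CohortSimConfig(),
        predictor_beta={
            "P": (1e6, 1e-3), "LP": (1e6, 1e-3), "LB": (1e-3, 1e6),
            "vus_low": (1e-3, 1e6), "vus_semi_high": (1e6, 1e-3),
            "vus_high": (1e6, 1e-3),
        },
        common_variant_prob=0.0,
        depth_mean=500.0,
        depth_dispersion=50.0,
    )


@dataclass
class SimulatedCohort:
    """A generated cohort, its ground truth, and the pooling outcome."""

    cohort: CohortTable
    truth: pd.DataFrame  # columns: variant_id, truth_tier, truth_subclass, truth_common
    failed_pools: list[int]
    excluded_patients: list[str]
    frame: pd.DataFrame  # the full observable table (with truth_* columns)


def _sample_truth_label(rng: np.random.Generator, config: CohortSimConfig) -> str:
    tiers = list(config.tier_probs)
    tier = rng.choice(tiers, p=[config.tier_probs[t] for t in tiers])
    if tier != "VUS":
        return tier
    subs = list(config.vus_subclass_probs)
    sub = rng.choice(subs, p=[config.vus_subclass_probs[s] for s in subs])
    return f"vus_{sub}"


def _splice_panel(rng: np.random.Generator, config: CohortSimConfig, affected: bool) -> dict:
    """WT/variant scores for the four tools, plus HSF consensus values."""
    cells: dict[str, float] = {}
    n_tools_affected = int(rng.choice([3, 4])) if affected else 0
    affected_tools = set(
        rng.choice(len(SPLICE_TOOLS), size=n_tools_affected, replace=False)
    )
    for i, tool in enumerate(SPLICE_TOOLS):
        hi = _TOOL_RANGES[tool]
        wt = rng.uniform(0.5 * hi, hi)
        if i in affected_tools:
            delta = rng.uniform(*config.splice_delta_range)
            var = wt * (1.0 - delta)
        else:
            var = wt * (1.0 + rng.normal(0.0, config.neutral_delta_sd))
        cells[f"{tool}_wt"] = round(wt, 3)
        cells[f"{tool}_var"] = round(max(var, 0.0), 3)
    wt_cv = rng.uniform(65.0, 95.0)
    if affected:
        var_cv = wt_cv * (1.0 - rng.uniform(0.15, 0.4))
    else:
        var_cv = min(100.0, wt_cv * (1.0 + rng.normal(0.0, config.neutral_delta_sd)))
    cells["hsf_wt_cv"] = round(wt_cv, 1)
    cells["hsf_mut_cv"] = round(var_cv, 1)
    return cells


def _evidence_cells(rng: np.random.Generator, config: CohortSimConfig, label: str) -> dict:
    cells = {"segregation": "", "protein_model": "", "functional": ""}
    if label not in ("vus_semi_high", "vus_high", "vus_splice"):
        return cells
    if rng.random() < config.family_availability_prob:
        cells["segregation"] = (
            "supports_lp" if rng.random() < config.seg_support_prob else "not_informative"
        )
    if label in ("vus_semi_high", "vus_high") and rng.random() < config.protein_model_prob:
        cells["protein_model"] = (
            "predicts_lp" if rng.random() < config.pm_lp_prob else "predicts_lb"
        )
    ft_prob = (
        config.functional_prob_splice if label == "vus_splice"
        else config.functional_prob_missense
    )
    if rng.random() < ft_prob:
        cells["functional"] = (
            "indicates_lp" if rng.random() < config.ft_lp_prob else "indicates_lb"
        )
    return cells


_AA = "ARNDCQEGHILKMFPSTWYV"


def generate_cohort(
    config: CohortSimConfig | None = None, seed: int = 0
) -> SimulatedCohort:
    """Generate a cohort table with ground-truth labels; deterministic per seed."""
    config = config or CohortSimConfig()
    config.validate()
    rng = np.random.default_rng(seed)

    n_pools = config.n_patients // config.pool_size
    pool_failed = rng.random(n_pools) < config.pool_failure_prob
    patients = [f"S{i + 1:04d}" for i in range(config.n_patients)]
    excluded: list[str] = []
    analyzable: list[str] = []
    for pool_idx in range(n_pools):
        members = patients[pool_idx * config.pool_size:(pool_idx + 1) * config.pool_size]
        (excluded if pool_failed[pool_idx] else analyzable).extend(members)

    rows: list[dict] = []
    position_counter = 100
    for patient in analyzable:
        for _ in range(rng.poisson(config.mean_variants_per_patient)):
            position_counter += int(rng.integers(3, 30))
            gene = str(rng.choice(PANEL_GENES))
            is_common = rng.random() < config.common_variant_prob
            label = "LB" if is_common else _sample_truth_label(rng, config)
            tier = label if label in ("P", "LP", "LB") else "VUS"

            row: dict = {
                "patient_ids": patient,
                "gene": gene,
                "sca_type": "",
                "transcript": f"NM_{900000 + PANEL_GENES.index(gene)}.1",
                "depth": int(
                    rng.negative_binomial(
                        config.depth_dispersion,
                        config.depth_dispersion / (config.depth_dispersion + config.depth_mean),
                    )
                ),
                "tier": tier,
                "truth_tier": tier,
                "truth_subclass": label[4:] if label.startswith("vus_") else "",
                "truth_common": str(is_common).lower(),
            }

            # cDNA notation and consequence
            ref, alt = rng.choice(_BASES, size=2, replace=False)
            if label == "vus_splice":
                if rng.random() < 0.5:
                    offset = int(rng.integers(3, 21)) * int(rng.choice([-1, 1]))
                    row["hgvs_c"] = f"c.{position_counter}{offset:+d}{ref}>{alt}"
                    row["consequence"] = "intronic"
                    row["hgvs_p"] = ""
                else:
                    row["hgvs_c"] = f"c.{position_counter}{ref}>{alt}"
                    row["consequence"] = "synonymous"
                    row["hgvs_p"] = ""
            else:
                row["hgvs_c"] = f"c.{position_counter}{ref}>{alt}"
                # protein-level classes need predictor scores, hence missense;
                # only LB variants may be synonymous
                if label != "LB" or rng.random() < 0.85:
                    row["consequence"] = "missense"
                    aa_from, aa_to = rng.choice(list(_AA), size=2, replace=False)
                    row["hgvs_p"] = f"p.{aa_from}{(position_counter + 2) // 3}{aa_to}"
                else:
                    row["consequence"] = "synonymous"
                    row["hgvs_p"] = ""

            # normalized predictor scores (protein-level classes only)
            if label in config.predictor_beta and row["consequence"] == "missense":
                a, b = config.predictor_beta[label]
                for tool in PREDICTORS:
                    row[tool] = round(float(rng.beta(a, b)), 4)
            else:
                for tool in PREDICTORS:
                    row[tool] = ""

            # gnomAD presence and frequency
            if is_common:
                lo, hi = config.common_maf_log10_range
                maf = 10 ** rng.uniform(lo, hi)
                present = True
            else:
                present = rng.random() < config.gnomad_presence.get(label, 0.5)
                lo, hi = config.rare_maf_log10_range
                maf = 10 ** rng.uniform(lo, hi)
            if present:
                an = int(rng.integers(220_000, 283_000))
                row["gnomad_ac"] = max(1, round(maf * an))
                row["gnomad_an"] = an
            else:
                row["gnomad_ac"] = ""
                row["gnomad_an"] = ""

            # splice-tool panel
            if label == "vus_splice":
                row.update(_splice_panel(rng, config, affected=True))
            elif rng.random() < config.neutral_splice_panel_prob:
                row.update(_splice_panel(rng, config, affected=False))

            row.update(_evidence_cells(rng, config, label))
            rows.append(row)

    columns = [
        "patient_ids", "gene", "sca_type", "transcript", "hgvs_c", "hgvs_p",
        "consequence", "depth", "tier", "gnomad_ac", "gnomad_an",
        *PREDICTORS,
        *(c for t in SPLICE_TOOLS for c in (f"{t}_wt", f"{t}_var")),
        "hsf_wt_cv", "hsf_mut_cv", "segregation", "protein_model", "functional",
        "truth_tier", "truth_subclass", "truth_common",
    ]
    frame = pd.DataFrame(rows).reindex(columns=columns).fillna("")

    cohort = _table_from_frame(frame, cohort_size=len(analyzable))
    truth = pd.DataFrame(
        {
            "variant_id": [r.variant_id for r in cohort.records],
            "truth_tier": frame["truth_tier"].tolist(),
            "truth_subclass": frame["truth_subclass"].tolist(),
            "truth_common": (frame["truth_common"] == "true").tolist(),
        }
    )
    return SimulatedCohort(
        cohort=cohort,
        truth=truth,
        failed_pools=[i for i, failed in enumerate(pool_failed) if failed],
        excluded_patients=excluded,
        frame=frame,
    )


def _table_from_frame(frame: pd.DataFrame, cohort_size: int) -> CohortTable:
    """Round-trip a simulated frame through the standard TSV reader."""
    import tempfile

    observable = frame.drop(columns=[c for c in frame.columns if c.startswith("truth_")])
    with tempfile.NamedTemporaryFile("w", suffix=".tsv", delete=False) as fh:
        observable.to_csv(fh, sep="\t", index=False)
        tmp = fh.name
    try:
        table = read_variant_table(
            tmp, dialect="tsv", cohort_size=cohort_size, predictors_scale="unit"
        )
    finally:
        Path(tmp).unlink(missing_ok=True)
    return table


def write_cohort(sim: SimulatedCohort, path: str | Path, blind: bool = False) -> None:
    """Write the simulated table as TSV; ``blind`` strips the truth_* columns."""
    frame = sim.frame
    if blind:
        frame = frame.drop(columns=[c for c in frame.columns if c.startswith("truth_")])
    frame.to_csv(path, sep="\t", index=False)


@dataclass
class ConfusionSummary:
    """Truth-vs-assigned subclass confusion over the simulated VUSes."""

    subclass_confusion: dict[tuple[str, str], int]
    recovery_high: float
    n_truth: dict[str, int]


def recovery_check(
    sim: SimulatedCohort, classifications: list[ClassificationRecord],
    record_ids: list[str] | None = None,
) -> ConfusionSummary:
    """Compare pipeline subclass assignments against the generator's truth.

    ``classifications`` align with ``record_ids`` (variant ids of pipeline
    output; defaults to all simulated records in order).  The headline
    metric is the fraction of truth-VUS-high variants assigned subclass
    high among those the pipeline classified.
    """
    if record_ids is None:
        record_ids = [r.variant_id for r in sim.cohort.records]
    assigned = dict(zip(record_ids, classifications))
    confusion: dict[tuple[str, str], int] = {}
    n_truth: dict[str, int] = {}
    n_high = n_high_recovered = 0
    for _, row in sim.truth.iterrows():
        if not row["truth_subclass"]:
            continue
        cls = assigned.get(row["variant_id"])
        if cls is None:
            continue  # removed by QC before subclassification
        truth_sub = row["truth_subclass"]
        got = cls.vus_subclass.value if cls.vus_subclass else cls.tier.value
        confusion[(truth_sub, got)] = confusion.get((truth_sub, got), 0) + 1
        n_truth[truth_sub] = n_truth.get(truth_sub, 0) + 1
        if truth_sub == VusSubclass.HIGH.value:
            n_high += 1
            n_high_recovered += got == VusSubclass.HIGH.value
    return ConfusionSummary(
        subclass_confusion=confusion,
        recovery_high=(n_high_recovered / n_high) if n_high else float("nan"),
        n_truth=n_truth,
    )
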