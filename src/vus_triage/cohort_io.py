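"""Reading and writing the tabular inputs and outputs of the pipeline.

The unit of exchange is a tab-separated annotation table, one row per
variant (possibly carried by several patients).  Mandatory columns are
``patient_ids, gene, transcript, hgvs_c, consequence``; everything else —
depth, gnomAD counts, the six predictor outputs, the four splice tools'
WT/variant scores, HSF consensus values, follow-up evidence and routine
classification — is optional and attached to the record when present.
Unknown columns are preserved verbatim in ``extras``.

Packaged fixtures transcribe the three main result tables of the study the
pipeline reproduces: the P/LP variants (``table2``), the prioritized VUSes
(``table3``) and the follow-up/reclassification outcomes (``table4``).

A VCF 4.x dialect is accepted read-only: configured INFO keys are mapped
onto the same schema.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import pandas as pd

from .domain import (
    Consequence,
    Tier,
    VariantRecord,
    VusSubclass,
    make_variant_id,
)
from .errors import DataError, RowError, SchemaError
from .reclassify import (
    FollowUpEvidence,
    Functional,
    ProteinModel,
    Segregation,
)
from .report import CohortReport
from .scoring import PREDICTORS, PredictorProfile
from .splicing import SPLICE_TOOLS, SplicePredictionSet, SpliceSite, ToolScore

MANDATORY_COLUMNS = ("patient_ids", "gene", "transcript", "hgvs_c", "consequence")

#: The 36 genes of the ataxia panel (33 established plus 3 candidate genes).
PANEL_GENES = (
    "AFG3L2", "ATN1", "ATXN1", "ATXN2", "ATXN3", "ATXN7", "ATXN10", "BEAN1",
    "CACNA1A", "CACNA1G", "CCDC88C", "DAB1", "EEF2", "ELOVL4", "ELOVL5",
    "EP300", "FAT1", "FAT2", "FGF14", "GRM1", "ITPR1", "KCNC3", "KCND3",
    "KIF26B", "MME", "NOP56", "PDYN", "PLD3", "PRKCG", "PUM1", "SPTBN2",
    "TBP", "TGM6", "TMEM240", "TRPC3", "TTBK2",
)

#: Number of patients whose pools passed sequencing QC in the study cohort.
DEFAULT_COHORT_SIZE = 348

REPORT_SCHEMA_VERSION = 1


@dataclass
class CohortRecord:
    """A variant joined to whatever annotation layers the source provided."""

    variant: VariantRecord
    tier: Tier | None = None
    pathogenicity_score: float | None = None
    subclass: VusSubclass | None = None
    splice_consensus: bool | None = None
    predictors: PredictorProfile | None = None
    splice: SplicePredictionSet | None = None
    evidence: FollowUpEvidence | None = None
    excluded_reclass: bool = False
    exclusion_reason: str | None = None
    line: int | None = None  # 1-based source line, for error reporting

    @property
    def variant_id(self) -> str:
        return self.variant.variant_id


@dataclass
class CohortTable:
    """All records read from one source plus the cohort size they came from."""

    records: list[CohortRecord]
    cohort_size: int = DEFAULT_COHORT_SIZE

    def __post_init__(self):
        n_patients = len(self.patient_ids())
        if self.cohort_size < n_patients:
            raise DataError(
                f"cohort_size {self.cohort_size} is smaller than the "
                f"{n_patients} distinct patients in the table"
            )

    def patient_ids(self) -> set[str]:
        ids: set[str] = set()
        for rec in self.records:
            ids |= rec.variant.patient_ids
        return ids

    def __len__(self) -> int:
        return len(self.records)


# --------------------------------------------------------------------------
# cell parsing helpers
# --------------------------------------------------------------------------

_ABSENT = {"", "-", "—", "na", "nan", "none", "."}


def _norm_cell(value) -> str | None:
    """Normalize a raw cell; em-dashes and blanks mean 'absent'."""
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    text = str(value).strip().replace("—", "-").replace("≥", ">=")
    return None if text.lower() in _ABSENT or text == "-" else text


def _parse_float(text: str, column: str, line: int) -> float:
    try:
        return float(text)
    except ValueError:
        raise RowError(f"column {column!r}: cannot parse number from {text!r}", line)


def _parse_int(text: str, column: str, line: int) -> int:
    try:
        return int(text)
    except ValueError:
        raise RowError(f"column {column!r}: cannot parse integer from {text!r}", line)


def _parse_bool(text: str, column: str, line: int) -> bool:
    low = text.lower()
    if low in ("true", "t", "yes", "1"):
        return True
    if low in ("false", "f", "no", "0"):
        return False
    raise RowError(f"column {column!r}: cannot parse boolean from {text!r}", line)


def _parse_population(row: Mapping[str, str | None], line: int) -> tuple[int, int] | None:
    """gnomAD counts from gnomad_ac/gnomad_an columns or an 'AC/AN' string."""
    combined = row.get("gnomad_af")
    if combined is not None and "/" in combined:
        ac_s, an_s = combined.split("/", 1)
        return (_parse_int(ac_s, "gnomad_af", line), _parse_int(an_s, "gnomad_af", line))
    ac, an = row.get("gnomad_ac"), row.get("gnomad_an")
    if ac is None and an is None:
        return None
    if ac is None or an is None:
        raise RowError("gnomad_ac and gnomad_an must be given together", line)
    return (_parse_int(ac, "gnomad_ac", line), _parse_int(an, "gnomad_an", line))


def _parse_predictors(row: Mapping[str, str | None], line: int) -> PredictorProfile | None:
    raw: dict[str, object] = {}
    for tool in PREDICTORS:
        cell = row.get(tool)
        if cell is None:
            continue
        if tool == "mutation_taster":
            if ":" in cell:
                call, prob = cell.split(":", 1)
                raw[tool] = (call.strip(), _parse_float(prob, tool, line))
            else:
                raise RowError(
                    f"column 'mutation_taster': expected 'call:probability', got {cell!r}",
                    line,
                )
        elif tool == "align_gvgd":
            raw[tool] = cell
        else:
            raw[tool] = _parse_float(cell, tool, line)
    if not raw:
        return None
    try:
        return PredictorProfile.from_raw(raw)
    except DataError as exc:
        raise RowError(str(exc), line) from exc


def _parse_unit_predictors(
    row: Mapping[str, str | None], line: int
) -> PredictorProfile | None:
    scores = {
        tool: _parse_float(row[tool], tool, line)
        for tool in PREDICTORS
        if row.get(tool) is not None
    }
    if not scores:
        return None
    try:
        return PredictorProfile(**scores)
    except DataError as exc:
        raise RowError(str(exc), line) from exc


def _parse_splice(row: Mapping[str, str | None], line: int) -> SplicePredictionSet | None:
    site_cell = row.get("splice_site")
    site = SpliceSite(site_cell) if site_cell is not None else SpliceSite.DONOR
    scores = []
    for tool in SPLICE_TOOLS:
        wt, var = row.get(f"{tool}_wt"), row.get(f"{tool}_var")
        if wt is None and var is None:
            continue
        if wt is None or var is None:
            raise RowError(f"{tool}: WT and variant scores must be given together", line)
        scores.append(
            ToolScore(
                tool=tool,
                wt_score=_parse_float(wt, f"{tool}_wt", line),
                variant_score=_parse_float(var, f"{tool}_var", line),
                site=site,
            )
        )
    hsf_wt, hsf_mut = row.get("hsf_wt_cv"), row.get("hsf_mut_cv")
    if not scores and hsf_wt is None and hsf_mut is None:
        return None
    try:
        return SplicePredictionSet(
            tool_scores=scores,
            hsf_wt_cv=_parse_float(hsf_wt, "hsf_wt_cv", line) if hsf_wt else None,
            hsf_variant_cv=_parse_float(hsf_mut, "hsf_mut_cv", line) if hsf_mut else None,
        )
    except DataError as exc:
        raise RowError(str(exc), line) from exc


def _parse_evidence(row: Mapping[str, str | None], line: int) -> FollowUpEvidence | None:
    cells = {k: row.get(k) for k in ("segregation", "protein_model", "functional")}
    if all(v is None for v in cells.values()):
        return None
    try:
        return FollowUpEvidence(
            segregation=Segregation(cells["segregation"] or "unavailable"),
            protein_model=ProteinModel(cells["protein_model"] or "unavailable"),
            functional=Functional(cells["functional"] or "unavailable"),
        )
    except ValueError as exc:
        raise RowError(f"follow-up evidence: {exc}", line) from exc


_KNOWN_COLUMNS = set(MANDATORY_COLUMNS) | {
    "hgvs_p", "sca_type", "depth", "gnomad_ac", "gnomad_an", "gnomad_af",
    "tier", "pathogenicity_score", "subclass", "splice_consensus",
    "excluded_reclass", "exclusion_reason", "splice_site",
    "hsf_wt_cv", "hsf_mut_cv", "segregation", "protein_model", "functional",
    *PREDICTORS,
    *(f"{t}_wt" for t in SPLICE_TOOLS),
    *(f"{t}_var" for t in SPLICE_TOOLS),
}


def _record_from_row(
    row: Mapping[str, str | None], line: int, predictors_scale: str
) -> CohortRecord:
    for col in MANDATORY_COLUMNS:
        if row.get(col) is None:
            raise RowError(f"mandatory column {col!r} is empty", line)
    patient_ids = frozenset(
        p.strip() for p in row["patient_ids"].split(",") if p.strip()
    )
    try:
        consequence = Consequence(row["consequence"])
    except ValueError:
        raise RowError(f"unknown consequence {row['consequence']!r}", line)
    depth_cell = row.get("depth")
    extras = {k: v for k, v in row.items() if k not in _KNOWN_COLUMNS and v is not None}
    try:
        variant = VariantRecord(
            variant_id=make_variant_id(row["transcript"], row["hgvs_c"]),
            patient_ids=patient_ids,
            gene=row["gene"],
            transcript=row["transcript"],
            hgvs_c=row["hgvs_c"],
            hgvs_p=row.get("hgvs_p"),
            sca_type=row.get("sca_type"),
            consequence=consequence,
            read_depth=_parse_int(depth_cell, "depth", line) if depth_cell else None,
            population=_parse_population(row, line),
            extras=extras,
        )
    except DataError as exc:
        raise RowError(str(exc), line) from exc

    tier_cell = row.get("tier")
    score_cell = row.get("pathogenicity_score")
    subclass_cell = row.get("subclass")
    consensus_cell = row.get("splice_consensus")
    excluded_cell = row.get("excluded_reclass")
    parse_predictors = (
        _parse_unit_predictors if predictors_scale == "unit" else _parse_predictors
    )
    return CohortRecord(
        variant=variant,
        tier=Tier(tier_cell) if tier_cell else None,
        pathogenicity_score=(
            _parse_float(score_cell, "pathogenicity_score", line) if score_cell else None
        ),
        subclass=VusSubclass(subclass_cell) if subclass_cell else None,
        splice_consensus=(
            _parse_bool(consensus_cell, "splice_consensus", line)
            if consensus_cell is not None
            else None
        ),
        predictors=parse_predictors(row, line),
        splice=_parse_splice(row, line),
        evidence=_parse_evidence(row, line),
        excluded_reclass=(
            _parse_bool(excluded_cell, "excluded_reclass", line) if excluded_cell else False
        ),
        exclusion_reason=row.get("exclusion_reason"),
        line=line,
    )


# --------------------------------------------------------------------------
# readers
# --------------------------------------------------------------------------

def read_variant_table(
    path: str | Path,
    dialect: str = "tsv",
    cohort_size: int | None = None,
    info_map: Mapping[str, str] | None = None,
    predictors_scale: str = "raw",
) -> CohortTable:
    """Read an annotation table (TSV) or annotated VCF into a CohortTable.

    ``predictors_scale`` says whether the six predictor columns carry the
    tools' raw outputs ("raw", normalized at load) or already-normalized
    unit scores ("unit", as emitted by the cohort simulator).
    """
    if dialect == "tsv":
        return _read_tsv(Path(path), cohort_size, predictors_scale)
    if dialect == "vcf":
        return _read_vcf(Path(path), cohort_size, info_map or {})
    raise SchemaError(f"unknown dialect {dialect!r}")


def _read_tsv(path: Path, cohort_size: int | None, predictors_scale: str) -> CohortTable:
    if not path.exists():
        raise SchemaError(f"no such file: {path}")
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False,
                        encoding="utf-8")
    missing = [c for c in MANDATORY_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory columns {missing}")
    records = []
    for idx, raw_row in enumerate(frame.to_dict("records")):
        line = idx + 2  # 1-based, after the header line
        row = {k: _norm_cell(v) for k, v in raw_row.items()}
        records.append(_record_from_row(row, line, predictors_scale))
    n_patients = len({p for r in records for p in r.variant.patient_ids})
    return CohortTable(
        records=records,
        cohort_size=cohort_size if cohort_size is not None else max(
            DEFAULT_COHORT_SIZE, n_patients
        ),
    )


#: Default INFO-key mapping for VCF ingestion; override via ``info_map``.
DEFAULT_VCF_INFO_MAP = {
    "patient_ids": "PATIENTS",
    "gene": "GENE",
    "transcript": "TRANSCRIPT",
    "hgvs_c": "HGVSC",
    "hgvs_p": "HGVSP",
    "consequence": "CSQ_CLASS",
    "gnomad_ac": "GNOMAD_AC",
    "gnomad_an": "GNOMAD_AN",
}


def _read_vcf(path: Path, cohort_size: int | None, info_map: Mapping[str, str]) -> CohortTable:
    import pysam

    if not path.exists():
        raise SchemaError(f"no such file: {path}")
    keys = {**DEFAULT_VCF_INFO_MAP, **info_map}
    records = []
    with pysam.VariantFile(str(path)) as vcf:
        for i, rec in enumerate(vcf):
            info = rec.info
            row: dict[str, str | None] = {}
            for schema_field, info_key in keys.items():
                try:
                    value = info.get(info_key)
                except (KeyError, ValueError):
                    value = None  # key absent from this file's header
                if isinstance(value, tuple):
                    value = ",".join(str(v) for v in value)
                row[schema_field] = _norm_cell(value)
            depth = rec.info.get("DP")
            row["depth"] = _norm_cell(depth)
            records.append(_record_from_row(row, i + 1, "raw"))
    n_patients = len({p for r in records for p in r.variant.patient_ids})
    return CohortTable(
        records=records,
        cohort_size=cohort_size if cohort_size is not None else max(
            DEFAULT_COHORT_SIZE, n_patients
        ),
    )


FIXTURES = ("table2", "table3", "table4")


def fixture_path(name: str) -> Path:
    if name not in FIXTURES:
        raise SchemaError(f"unknown fixture {name!r}; expected one of {FIXTURES}")
    return Path(str(resources.files("vus_triage").joinpath("data", f"{name}.tsv")))


def load_fixture(name: str) -> CohortTable:
    """Load a packaged result-table transcription (table2, table3 or table4).

    All three fixtures come from the same 348-patient cohort, so
    ``cohort_size`` is 348 regardless of how many patients the table lists.
    """
    return _read_tsv(fixture_path(name), DEFAULT_COHORT_SIZE, "raw")


# --------------------------------------------------------------------------
# report serialization
# --------------------------------------------------------------------------

def _report_flat(report: CohortReport) -> dict:
    flat: dict[str, object] = {"schema_version": REPORT_SCHEMA_VERSION}
    for tier, n in sorted(report.tier_counts.items()):
        flat[f"tier_counts.{tier}"] = n
    for sub, n in sorted(report.subclass_counts.items()):
        flat[f"subclass_counts.{sub}"] = n
    for gene in report.per_gene:
        for key, n in sorted(report.per_gene[gene].items()):
            flat[f"per_gene.{gene}.{key}"] = n
    flat["diagnosed_patients_before"] = ",".join(report.diagnosed_patients_before)
    flat["diagnosed_patients_after"] = ",".join(report.diagnosed_patients_after)
    flat["cohort_size"] = report.cohort_size
    flat["n_followed_up"] = report.n_followed_up
    flat["n_reclassified_lp"] = report.n_reclassified_lp
    flat["yield_before_pct"] = f"{report.yield_before_pct:.1f}"
    flat["yield_after_pct"] = f"{report.yield_after_pct:.1f}"
    flat["yield_delta_pct"] = f"{report.yield_delta_pct:.1f}"
    return flat


def write_report(report: CohortReport, path: str | Path, format: str = "tsv") -> None:
    """Serialize a report deterministically as TSV (key/value) or JSON."""
    path = Path(path)
    flat = _report_flat(report)
    if format == "tsv":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("key\tvalue\n")
            for key, value in flat.items():
                fh.write(f"{key}\t{value}\n")
    elif format == "json":
        path.write_text(json.dumps(flat, indent=2, sort_keys=False) + "\n",
                        encoding="utf-8")
    else:
        raise SchemaError(f"unknown report format {format!r}")


def read_report(path: str | Path, format: str = "tsv") -> CohortReport:
    """Read a serialized report back; inverse of :func:`write_report`."""
    path = Path(path)
    if format == "tsv":
        frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        flat = dict(zip(frame["key"], frame["value"]))
    elif format == "json":
        flat = {k: v for k, v in json.loads(path.read_text(encoding="utf-8")).items()}
    else:
        raise SchemaError(f"unknown report format {format!r}")

    report = CohortReport()
    per_gene: dict[str, dict[str, int]] = {}
    for key, value in flat.items():
        if key == "schema_version":
            continue
        if key.startswith("tier_counts."):
            report.tier_counts[key.split(".", 1)[1]] = int(value)
        elif key.startswith("subclass_counts."):
            report.subclass_counts[key.split(".", 1)[1]] = int(value)
        elif key.startswith("per_gene."):
            _, gene, metric = key.split(".", 2)
            per_gene.setdefault(gene, {})[metric] = int(value)
        elif key in ("diagnosed_patients_before", "diagnosed_patients_after"):
            ids = [p for p in str(value).split(",") if p]
            setattr(report, key, ids)
        elif key in ("cohort_size", "n_followed_up", "n_reclassified_lp"):
            setattr(report, key, int(value))
        else:
            setattr(report, key, float(value))
    report.per_gene = per_gene
    return report
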