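"""Pathogenicity score: six in-silico predictors normalized to [0,1] and summed.

In-silico predictions are insufficient for clinical classification, but they
rank VUSes for follow-up.  Each of six predictors (SIFT, PolyPhen-2,
MutationTaster, AlignGVGD, PhyloP, Grantham distance) is mapped onto a unit
score — 1 = pathogenic, 0 = benign — and the unit scores are summed, giving a
variant score between 0 and 6.  Every normalization map is monotone in the
tool's pathogenic direction and overridable; predictors missing for a variant
contribute 0 and are tracked in ``n_contributing``.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

from .errors import DataError

PREDICTORS = ("sift", "polyphen", "mutation_taster", "align_gvgd", "phylop", "grantham")

#: AlignGVGD classes, most benign (C0) to most deleterious (C65).
ALIGN_GVGD_CLASSES = ("C0", "C15", "C25", "C35", "C45", "C55", "C65")


def _clamp01(x: float) -> float:
    return 0.0 if x < 0.0 else 1.0 if x > 1.0 else x


def normalize_sift(raw: float) -> float:
    # SIFT reports a tolerance probability; < 0.05 is called deleterious.
    # Piecewise linear: the deleterious band [0, 0.05] spans unit scores
    # [1.0, 0.75]; the tolerated band (0.05, 1] spans (0.75, 0.0].
    if not (0.0 <= raw <= 1.0):
        raise DataError(f"SIFT value {raw} outside [0, 1]")
    if raw <= 0.05:
        return 1.0 - (raw / 0.05) * 0.25
    return 0.75 * (1.0 - raw) / 0.95


def normalize_polyphen(raw: float) -> float:
    # PolyPhen-2 probability is already a unit damaging score.
    if not (0.0 <= raw <= 1.0):
        raise DataError(f"PolyPhen value {raw} outside [0, 1]")
    return raw


def normalize_mutation_taster(raw: tuple[str, float]) -> float:
    # MutationTaster emits a call plus its probability; fold into one scale:
    # disease_causing keeps the probability, polymorphism inverts it.
    call, prob = raw
    if call not in ("disease_causing", "polymorphism"):
        raise DataError(f"unknown MutationTaster call {call!r}")
    if not (0.0 <= prob <= 1.0):
        raise DataError(f"MutationTaster probability {prob} outside [0, 1]")
    return prob if call == "disease_causing" else 1.0 - prob


def normalize_align_gvgd(raw: str) -> float:
    # Ordinal C-classes map onto an even grid 0, 1/6, ..., 1.
    try:
        idx = ALIGN_GVGD_CLASSES.index(raw)
    except ValueError:
        raise DataError(f"unknown AlignGVGD class {raw!r}") from None
    return idx / (len(ALIGN_GVGD_CLASSES) - 1)


def normalize_phylop(raw: float) -> float:
    # PhyloP conservation roughly spans -14..+6; positive = conserved.
    # Scores above +6 saturate, non-positive scores floor at 0.
    if not (-15.0 <= raw <= 10.0):
        raise DataError(f"PhyloP value {raw} outside plausible range")
    return _clamp01(raw / 6.0)


def normalize_grantham(raw: float) -> float:
    # Grantham distance 0..215 (most radical substitution = 215).
    if not (0.0 <= raw <= 215.0):
        raise DataError(f"Grantham distance {raw} outside [0, 215]")
    return raw / 215.0


DEFAULT_NORMALIZATION: dict[str, Callable] = {
    "sift": normalize_sift,
    "polyphen": normalize_polyphen,
    "mutation_taster": normalize_mutation_taster,
    "align_gvgd": normalize_align_gvgd,
    "phylop": normalize_phylop,
    "grantham": normalize_grantham,
}


def normalize_predictor(
    tool: str, raw, normalization: Mapping[str, Callable] | None = None
) -> float:
    """Map one predictor's raw output to its [0,1] unit score."""
    maps = DEFAULT_NORMALIZATION if normalization is None else normalization
    if tool not in maps:
        raise DataError(f"unknown predictor {tool!r}")
    score = maps[tool](raw)
    if not (0.0 <= score <= 1.0):
        raise DataError(f"{tool} normalization produced {score} outside [0, 1]")
    return score


@dataclass(frozen=True)
class PathogenicityScore:
    """Sum of unit predictor scores: 0 (all benign) .. 6 (all pathogenic)."""

    value: float
    n_contributing: int

    def __post_init__(self):
        if not (0.0 <= self.value <= 6.0):
            raise DataError(f"pathogenicity score {self.value} outside [0, 6]")
        if not (0 <= self.n_contributing <= 6):
            raise DataError("n_contributing must lie in 0..6")


@dataclass
class PredictorProfile:
    """Unit scores for the six predictors; None marks a missing predictor."""

    sift: float | None = None
    polyphen: float | None = None
    mutation_taster: float | None = None
    align_gvgd: float | None = None
    phylop: float | None = None
    grantham: float | None = None

    def __post_init__(self):
        for name in PREDICTORS:
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise DataError(f"normalized {name} score {v} outside [0, 1]")

    @classmethod
    def from_raw(
        cls, raw: Mapping[str, object], normalization: Mapping[str, Callable] | None = None
    ) -> "PredictorProfile":
        """Build a profile from raw tool outputs, normalizing each one."""
        scores = {
            tool: normalize_predictor(tool, value, normalization)
            for tool, value in raw.items()
            if value is not None
        }
        return cls(**scores)

    def unit_scores(self) -> dict[str, float | None]:
        return {name: getattr(self, name) for name in PREDICTORS}


def pathogenicity_score(profile: PredictorProfile) -> PathogenicityScore:
    """Sum the unit scores; missing predictors contribute 0."""
    present = [v for v in profile.unit_scores().values() if v is not None]
    return PathogenicityScore(value=float(sum(present)), n_contributing=len(present))
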