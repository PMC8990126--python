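"""Splice-effect consensus, HSF verification and minigene-assay arithmetic.

Four splice-site predictors (NNsplice, MaxEntScan, GeneSplicer and a
SpliceSiteFinder-like scorer) each score the wild-type and variant alleles at
a candidate donor/acceptor.  A variant is flagged as a predicted splice
effect when at least three tools agree on a relative score change of at
least 10% in the same direction at the same site.  Human Splicing Finder
consensus values (0-100) provide an independent verification of site loss or
gain.  Minigene exon-trapping constructs are modeled just enough to predict
the cDNA fragment sizes a splicing assay produces and whether an observed
exon skip shifts the reading frame.
"""
from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from .domain import ExonContext
from .errors import DataError, InsufficientDataError

SPLICE_TOOLS = ("nnsplice", "maxentscan", "genesplicer", "ssf_like")


class SpliceSite(str, Enum):
    DONOR = "donor"
    ACCEPTOR = "acceptor"


class HsfVerdict(str, Enum):
    CONFIRMED_LOSS = "confirmed_loss"
    CONFIRMED_GAIN = "confirmed_gain"
    NOT_CONFIRMED = "not_confirmed"


@dataclass(frozen=True)
class ToolScore:
    """One predictor's wild-type and variant-allele scores at a site."""

    tool: str
    wt_score: float
    variant_score: float
    site: SpliceSite = SpliceSite.DONOR

    def __post_init__(self):
        if self.tool not in SPLICE_TOOLS:
            raise DataError(f"unknown splice tool {self.tool!r}")
        if self.wt_score < 0 or self.variant_score < 0:
            raise DataError(f"{self.tool}: splice scores must be non-negative")

    def relative_change(self) -> float:
        """(variant - WT)/WT; site creation from a null WT counts as full gain."""
        if self.wt_score == 0:
            return float("inf") if self.variant_score > 0 else 0.0
        return (self.variant_score - self.wt_score) / self.wt_score


@dataclass
class SplicePredictionSet:
    """The four tools' scores plus HSF consensus values for one candidate site."""

    tool_scores: list[ToolScore]
    hsf_wt_cv: float | None = None
    hsf_variant_cv: float | None = None
    event: str | None = None  # "site_loss" | "site_gain" annotation, optional

    def __post_init__(self):
        tools = [t.tool for t in self.tool_scores]
        if len(tools) != len(set(tools)):
            raise DataError("each splice tool may appear at most once")
        for cv in (self.hsf_wt_cv, self.hsf_variant_cv):
            if cv is not None and not (0.0 <= cv <= 100.0):
                raise DataError(f"HSF consensus value {cv} outside [0, 100]")


def consensus_splice_effect(
    predictions: SplicePredictionSet,
    min_tools: int = 3,
    min_delta: float = 0.10,
) -> bool:
    """True when >= ``min_tools`` predictors agree on a splice effect.

    Agreement means a relative WT-to-variant score change of at least
    ``min_delta`` in the same direction (loss or gain) at the same site.
    Raises :class:`InsufficientDataError` when fewer than ``min_tools``
    tools have scores at all.
    """
    if len(predictions.tool_scores) < min_tools:
        raise InsufficientDataError(
            f"only {len(predictions.tool_scores)} splice tools scored; "
            f"{min_tools} required for a consensus"
        )
    votes: dict[tuple[SpliceSite, str], int] = {}
    for ts in predictions.tool_scores:
        change = ts.relative_change()
        if change <= -min_delta:
            key = (ts.site, "loss")
        elif change >= min_delta:
            key = (ts.site, "gain")
        else:
            continue
        votes[key] = votes.get(key, 0) + 1
    return any(n >= min_tools for n in votes.values())


def in_followup_region(
    context: ExonContext,
    window: int = 20,
    canonical_excluded: bool = True,
) -> bool:
    """Is a position within the minigene follow-up window of a junction?

    Intronic positions qualify at offsets of magnitude 3..``window``
    (canonical +/-1,2 positions classify directly as splice variants and are
    excluded unless ``canonical_excluded`` is False).  Exonic positions
    qualify within ``window`` bp of a junction, which requires the distance
    to have been resolved from an exon map.
    """
    if context.is_intronic:
        magnitude = abs(context.signed_offset)
        lower = 3 if canonical_excluded else 1
        return lower <= magnitude <= window
    if context.exonic_distance is None:
        raise InsufficientDataError(
            "exonic distance to the nearest junction is unresolved; supply an exon map"
        )
    return context.exonic_distance <= window


def hsf_verify(
    predictions: SplicePredictionSet,
    min_cv_delta_pct: float = 0.10,
) -> HsfVerdict:
    """Check the predicted effect against HSF consensus values.

    A relative CV drop of at least ``min_cv_delta_pct`` confirms site loss;
    a rise of at least that much confirms gain of a (novel) site; smaller
    changes leave the prediction unconfirmed.
    """
    if predictions.hsf_wt_cv is None or predictions.hsf_variant_cv is None:
        raise InsufficientDataError("both HSF consensus values are required")
    wt, var = predictions.hsf_wt_cv, predictions.hsf_variant_cv
    if wt == 0:
        change = float("inf") if var > 0 else 0.0
    else:
        change = (var - wt) / wt
    if change <= -min_cv_delta_pct:
        return HsfVerdict.CONFIRMED_LOSS
    if change >= min_cv_delta_pct:
        return HsfVerdict.CONFIRMED_GAIN
    return HsfVerdict.NOT_CONFIRMED


@dataclass
class MinigeneConstruct:
    """An exon-trapping construct: vector flanks plus candidate exons.

    ``flank_total`` is the constant vector-derived portion of the amplified
    product; ``exon_lengths``/``inclusion`` describe which candidate exons
    end up in the mature transcript; ``intron_retention`` optionally adds
    retained intronic bases (intron id, retained bp).
    """

    flank_total: int
    exon_lengths: list[int]
    inclusion: list[bool]
    intron_retention: tuple[str, int] | None = None

    def __post_init__(self):
        if self.flank_total <= 0:
            raise DataError("flank_total must be positive")
        if any(length <= 0 for length in self.exon_lengths):
            raise DataError("exon lengths must be positive")
        if len(self.inclusion) != len(self.exon_lengths):
            raise DataError("inclusion must align with exon_lengths")
        if self.intron_retention is not None and self.intron_retention[1] <= 0:
            raise DataError("retained intron length must be positive")


def fragment_length(construct: MinigeneConstruct) -> int:
    """cDNA fragment size (bp) the construct produces on a gel."""
    length = construct.flank_total
    length += sum(
        exon for exon, included in zip(construct.exon_lengths, construct.inclusion)
        if included
    )
    if construct.intron_retention is not None:
        length += construct.intron_retention[1]
    return length


def frameshift_from_skip(skipped_bp: int) -> bool:
    """Does skipping ``skipped_bp`` coding bases shift the reading frame?"""
    if skipped_bp <= 0:
        raise DataError("skipped_bp must be positive")
    return skipped_bp % 3 != 0
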