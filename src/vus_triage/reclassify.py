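"""Integration of follow-up evidence into final classifications.

Three kinds of follow-up can be attempted for a prioritized VUS: segregation
analysis in affected relatives, 3D protein modeling, and a functional test
(cellular assay or minigene splicing assay).  The promotion rule is the
minimal one consistent with observed diagnostic practice:

* co-segregation with disease, or a functional test indicating pathogenicity,
  promotes the VUS to likely pathogenic (LP);
* protein modeling alone never promotes — it selects variants worth
  functional follow-up but carries too little weight on its own;
* benign-direction follow-up never demotes below VUS (a single negative
  assay is not sufficient benign evidence).

The promotion rule is a data-driven table so labs can re-weight evidence.
"""
from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Collection

from .domain import Tier
from .errors import ContractError
from .subclass import ClassificationRecord


class Segregation(str, Enum):
    SUPPORTS_LP = "supports_lp"
    NOT_INFORMATIVE = "not_informative"
    UNAVAILABLE = "unavailable"


class ProteinModel(str, Enum):
    PREDICTS_LP = "predicts_lp"
    PREDICTS_LB = "predicts_lb"
    UNAVAILABLE = "unavailable"


class Functional(str, Enum):
    INDICATES_LP = "indicates_lp"
    INDICATES_LB = "indicates_lb"
    UNAVAILABLE = "unavailable"


@dataclass(frozen=True)
class FollowUpEvidence:
    """Verdicts of the follow-up studies attempted for one variant."""

    segregation: Segregation = Segregation.UNAVAILABLE
    protein_model: ProteinModel = ProteinModel.UNAVAILABLE
    functional: Functional = Functional.UNAVAILABLE


#: Evidence (field, verdict) pairs any one of which promotes a VUS to LP.
DEFAULT_PROMOTION_RULE: frozenset[tuple[str, str]] = frozenset(
    {
        ("segregation", Segregation.SUPPORTS_LP.value),
        ("functional", Functional.INDICATES_LP.value),
    }
)


def followed_up(evidence: FollowUpEvidence) -> bool:
    """True when at least one follow-up study was performed."""
    return (
        evidence.segregation is not Segregation.UNAVAILABLE
        or evidence.protein_model is not ProteinModel.UNAVAILABLE
        or evidence.functional is not Functional.UNAVAILABLE
    )


def reclassify(
    initial: ClassificationRecord,
    evidence: FollowUpEvidence,
    promotion_rule: Collection[tuple[str, str]] = DEFAULT_PROMOTION_RULE,
) -> Tier:
    """Final tier of a VUS after follow-up; never demotes below VUS."""
    if initial.tier is not Tier.VUS:
        raise ContractError(
            f"reclassify applies to VUS records, got tier {initial.tier.value}"
        )
    for field_name, verdict in promotion_rule:
        value = getattr(evidence, field_name)
        if value.value == verdict:
            return Tier.LP
    return Tier.VUS
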