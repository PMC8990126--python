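"""Five-tier classification by combining weighted ACMG/AMP evidence codes.

The engine evaluates a data-driven rule table of minimum evidence counts per
strength category (the published ACMG/AMP combining criteria by default).
Rules for stronger tiers take precedence; if both a pathogenic-direction and
a benign-direction rule fire, or neither does, the result is VUS.  Labs that
deviate from the published algebra can supply their own rule table and
code-strength map.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .domain import Tier, VariantRecord, make_variant_id
from .errors import ConfigError

PATHOGENIC_CATEGORIES = (
    "pathogenic_very_strong",
    "pathogenic_strong",
    "pathogenic_moderate",
    "pathogenic_supporting",
)
BENIGN_CATEGORIES = (
    "benign_standalone",
    "benign_strong",
    "benign_supporting",
)
CATEGORIES = PATHOGENIC_CATEGORIES + BENIGN_CATEGORIES

#: Default strength category per standard evidence code.
DEFAULT_CODE_STRENGTHS: dict[str, str] = {
    "PVS1": "pathogenic_very_strong",
    **{f"PS{i}": "pathogenic_strong" for i in range(1, 5)},
    **{f"PM{i}": "pathogenic_moderate" for i in range(1, 7)},
    **{f"PP{i}": "pathogenic_supporting" for i in range(1, 6)},
    "BA1": "benign_standalone",
    **{f"BS{i}": "benign_strong" for i in range(1, 5)},
    **{f"BP{i}": "benign_supporting" for i in range(1, 8)},
}

#: Published combining criteria as minimum counts per category.  A tier is
#: reached when any one of its rules is satisfied; P is tried before LP and
#: B before LB, so overlapping rules resolve to the stronger tier.
DEFAULT_COMBINING_RULES: dict[str, list[dict[str, int]]] = {
    "P": [
        {"pathogenic_very_strong": 1, "pathogenic_strong": 1},
        {"pathogenic_very_strong": 1, "pathogenic_moderate": 2},
        {"pathogenic_very_strong": 1, "pathogenic_moderate": 1, "pathogenic_supporting": 1},
        {"pathogenic_very_strong": 1, "pathogenic_supporting": 2},
        {"pathogenic_strong": 2},
        {"pathogenic_strong": 1, "pathogenic_moderate": 3},
        {"pathogenic_strong": 1, "pathogenic_moderate": 2, "pathogenic_supporting": 2},
        {"pathogenic_strong": 1, "pathogenic_moderate": 1, "pathogenic_supporting": 4},
    ],
    "LP": [
        {"pathogenic_very_strong": 1, "pathogenic_moderate": 1},
        {"pathogenic_strong": 1, "pathogenic_moderate": 1},
        {"pathogenic_strong": 1, "pathogenic_supporting": 2},
        {"pathogenic_moderate": 3},
        {"pathogenic_moderate": 2, "pathogenic_supporting": 2},
        {"pathogenic_moderate": 1, "pathogenic_supporting": 4},
    ],
    "B": [
        {"benign_standalone": 1},
        {"benign_strong": 2},
    ],
    "LB": [
        {"benign_strong": 1, "benign_supporting": 1},
        {"benign_supporting": 2},
    ],
}


@dataclass(frozen=True)
class AcmgEvidence:
    """A set of evidence codes; each code contributes its strength category once."""

    codes: frozenset[str]
    strengths: Mapping[str, str] = field(default_factory=lambda: DEFAULT_CODE_STRENGTHS)

    def __post_init__(self):
        object.__setattr__(self, "codes", frozenset(self.codes))
        for code in self.codes:
            cat = self.strengths.get(code)
            if cat is None:
                raise ConfigError(f"unknown evidence code {code!r}")
            if cat not in CATEGORIES:
                raise ConfigError(f"code {code!r} has unknown category {cat!r}")

    def category_counts(self) -> Counter:
        return Counter(self.strengths[c] for c in self.codes)


def _rule_fires(counts: Mapping[str, int], rule: Mapping[str, int]) -> bool:
    return all(counts.get(cat, 0) >= n for cat, n in rule.items())


def combine_evidence(
    evidence: AcmgEvidence,
    rules: Mapping[str, Sequence[Mapping[str, int]]] | None = None,
) -> Tier:
    """Combine evidence categories into one of the five tiers.

    Returns VUS when no rule fires or when pathogenic- and benign-direction
    rules both fire (conflicting evidence).
    """
    rules = DEFAULT_COMBINING_RULES if rules is None else rules
    for tier_name, tier_rules in rules.items():
        if tier_name not in ("P", "LP", "B", "LB"):
            raise ConfigError(f"rule table has unknown tier {tier_name!r}")
        for rule in tier_rules:
            for cat in rule:
                if cat not in CATEGORIES:
                    raise ConfigError(f"rule references unknown category {cat!r}")
    counts = evidence.category_counts()
    pathogenic = next(
        (t for t in ("P", "LP") if any(_rule_fires(counts, r) for r in rules.get(t, ()))),
        None,
    )
    benign = next(
        (t for t in ("B", "LB") if any(_rule_fires(counts, r) for r in rules.get(t, ()))),
        None,
    )
    if pathogenic and benign:
        return Tier.VUS
    if pathogenic:
        return Tier(pathogenic)
    if benign:
        return Tier(benign)
    return Tier.VUS


def literature_override(
    record: VariantRecord, known_classifications: Mapping[str, Tier]
) -> Tier | None:
    """Curated-literature tier for a variant, if one is known.

    The lookup is keyed by ``transcript:hgvs_c``; a curated classification
    takes precedence over evidence combination.  Returns None when the
    variant is not curated.
    """
    return known_classifications.get(make_variant_id(record.transcript, record.hgvs_c))
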