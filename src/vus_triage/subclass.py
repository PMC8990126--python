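"""VUS sub-classification for follow-up prioritization.

VUSes are partitioned into four priority subclasses:

* **VUS-splice** — no protein-level score, but a consensus in-silico splice
  effect (3+ tools agreeing); prioritized for splicing assays.
* **VUS-low** — pathogenicity score < 3; not followed up.
* **VUS-semi-high** — score >= 3, present in the population database at
  MAF < 0.1%.
* **VUS-high** — score >= 3 and absent from the population database
  (rarest, highest priority).

Non-VUS tiers pass through unchanged.  A variant carrying both a protein
score and a splice consensus takes the score branch, with the splice
consensus recorded on ``splice_flagged``.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

from .domain import Tier, VusSubclass
from .errors import ClassificationError
from .scoring import PathogenicityScore


@dataclass
class ClassificationRecord:
    """Five-tier class plus, for VUSes, the follow-up priority subclass."""

    tier: Tier
    vus_subclass: VusSubclass | None = None
    pathogenicity: PathogenicityScore | None = None
    splice_flagged: bool = False

    def __post_init__(self):
        if (self.vus_subclass is not None) != (self.tier is Tier.VUS):
            raise ClassificationError(
                "vus_subclass must be present exactly when tier is VUS"
            )


def subclassify(
    tier: Tier,
    score: PathogenicityScore | float | None,
    population: tuple[int, int] | None,
    splice_consensus: bool,
    *,
    score_cutoff: float = 3.0,
    max_maf: float = 0.001,
) -> ClassificationRecord:
    """Assign the follow-up priority subclass to a VUS.

    ``score`` may be a :class:`PathogenicityScore` or a bare number (e.g. a
    score transcribed from an annotation table); ``population`` is the
    (allele_count, allele_number) pair, or None if absent from the database.
    Exactly one subclass is assigned per VUS.  Raises
    :class:`ClassificationError` for a VUS with neither score nor splice
    consensus.
    """
    if isinstance(score, (int, float)):
        score = PathogenicityScore(value=float(score), n_contributing=6)

    if tier is not Tier.VUS:
        return ClassificationRecord(
            tier=tier, pathogenicity=score, splice_flagged=splice_consensus
        )

    if score is None:
        if not splice_consensus:
            raise ClassificationError(
                "VUS with neither a pathogenicity score nor a splice consensus"
            )
        return ClassificationRecord(
            tier=Tier.VUS, vus_subclass=VusSubclass.SPLICE, splice_flagged=True
        )

    if score.value < score_cutoff:
        sub = VusSubclass.LOW
    elif population is not None:
        ac, an = population
        if ac / an > max_maf:
            # Upstream frequency filtering should have removed such variants;
            # keep the database-present branch but flag the anomaly.
            warnings.warn(
                f"VUS with population MAF {ac / an:.2%} above {max_maf:.2%} "
                "reached subclassification; routed to semi_high",
                stacklevel=2,
            )
        sub = VusSubclass.SEMI_HIGH
    else:
        sub = VusSubclass.HIGH

    return ClassificationRecord(
        tier=Tier.VUS,
        vus_subclass=sub,
        pathogenicity=score,
        splice_flagged=splice_consensus,
    )
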