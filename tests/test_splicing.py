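"""Splice consensus, HSF verification and minigene arithmetic."""

import pytest

from vus_triage.domain import parse_cdna_offset
from vus_triage.errors import DataError, InsufficientDataError
from vus_triage.splicing import (
    HsfVerdict,
    MinigeneConstruct,
    SplicePredictionSet,
    SpliceSite,
    ToolScore,
    consensus_splice_effect,
    fragment_length,
    frameshift_from_skip,
    hsf_verify,
    in_followup_region,
)


def panel(deltas, site=SpliceSite.DONOR):
    """Build a four-tool prediction set from relative WT->variant changes."""
    tools = ("nnsplice", "maxentscan", "genesplicer", "ssf_like")
    return SplicePredictionSet(
        tool_scores=[
            ToolScore(tool=t, wt_score=10.0, variant_score=10.0 * (1 + d), site=site)
            for t, d in zip(tools, deltas)
        ]
    )


class TestConsensus:
    def test_three_of_four_dropping_is_consensus(self):
        assert consensus_splice_effect(panel([-0.3, -0.2, -0.15, 0.0]))

    def test_two_of_four_changed_is_not(self):
        assert not consensus_splice_effect(panel([-0.3, -0.2, 0.0, 0.0]))

    def test_no_change_is_not(self):
        assert not consensus_splice_effect(panel([0.0, 0.0, 0.0, 0.0]))

    def test_mixed_directions_do_not_pool(self):
        # two losses + two gains is no consensus for either event
        assert not consensus_splice_effect(panel([-0.3, -0.3, 0.3, 0.3]))

    def test_gain_consensus_detected(self):
        assert consensus_splice_effect(panel([0.4, 0.5, 0.2, 0.0]))

    def test_fewer_tools_than_required_is_an_error(self):
        two_tools = SplicePredictionSet(
            tool_scores=[
                ToolScore(tool="nnsplice", wt_score=1.0, variant_score=0.5),
                ToolScore(tool="maxentscan", wt_score=8.0, variant_score=4.0),
            ]
        )
        with pytest.raises(InsufficientDataError):
            consensus_splice_effect(two_tools)

    @pytest.mark.parametrize("min_delta", [0.05, 0.10, 0.2, 0.5])
    def test_monotone_in_min_delta(self, min_delta):
        """Raising the threshold never flips a negative call to positive."""
        for deltas in ([-0.3, -0.2, -0.15, 0.0], [-0.08, -0.08, -0.08, 0.0]):
            loose = consensus_splice_effect(panel(deltas), min_delta=min_delta)
            strict = consensus_splice_effect(panel(deltas), min_delta=min_delta + 0.1)
            assert loose or not strict


class TestFollowupRegion:
    @pytest.mark.parametrize(
        "hgvs, expected",
        [
            ("c.100-5A>C", True),    # inside the 3..20 window
            ("c.100-3A>C", True),
            ("c.100+20A>C", True),
            ("c.1095-2A>C", False),  # canonical site: classifies directly
            ("c.100-50A>C", False),  # outside the window
        ],
    )
    def test_intronic_window(self, hgvs, expected):
        assert in_followup_region(parse_cdna_offset(hgvs)) is expected

    def test_canonical_included_when_not_excluded(self):
        ctx = parse_cdna_offset("c.1095-2A>C")
        assert in_followup_region(ctx, canonical_excluded=False)

    def test_unresolved_exonic_distance_is_an_error(self):
        with pytest.raises(InsufficientDataError):
            in_followup_region(parse_cdna_offset("c.909G>A"))


class TestHsfVerify:
    def _set(self, wt, var):
        return SplicePredictionSet(tool_scores=[], hsf_wt_cv=wt, hsf_variant_cv=var)

    def test_cv_drop_confirms_loss(self):
        # 85 -> 60 is a -29.4% relative change
        assert hsf_verify(self._set(85, 60)) is HsfVerdict.CONFIRMED_LOSS

    def test_zero_delta_not_confirmed(self):
        assert hsf_verify(self._set(80, 80)) is HsfVerdict.NOT_CONFIRMED

    def test_cv_rise_confirms_gain(self):
        # 40 -> 75 is +87.5%
        assert hsf_verify(self._set(40, 75)) is HsfVerdict.CONFIRMED_GAIN

    def test_cv_out_of_range_rejected(self):
        with pytest.raises(DataError):
            self._set(120, 50)


class TestMinigene:
    def test_exon_skip_worked_example(self):
        """488-bp product with the 124-bp exon; 364 bp when it is skipped."""
        included = MinigeneConstruct(
            flank_total=364, exon_lengths=[124], inclusion=[True]
        )
        skipped = MinigeneConstruct(
            flank_total=364, exon_lengths=[124], inclusion=[False]
        )
        assert fragment_length(included) == 488
        assert fragment_length(skipped) == 364
        assert fragment_length(included) - fragment_length(skipped) == 124

    def test_no_exons_gives_flank_only(self):
        construct = MinigeneConstruct(flank_total=263, exon_lengths=[], inclusion=[])
        assert fragment_length(construct) == 263

    def test_intron_retention_adds_retained_bases(self):
        construct = MinigeneConstruct(
            flank_total=263,
            exon_lengths=[90],
            inclusion=[True],
            intron_retention=("intron6", 30),
        )
        assert fragment_length(construct) == 263 + 90 + 30

    def test_additivity_per_included_exon(self):
        base = MinigeneConstruct(
            flank_total=300, exon_lengths=[100, 77], inclusion=[True, False]
        )
        plus = MinigeneConstruct(
            flank_total=300, exon_lengths=[100, 77], inclusion=[True, True]
        )
        assert fragment_length(plus) - fragment_length(base) == 77

    @pytest.mark.parametrize(
        "skipped, shifts", [(124, True), (123, False), (1, True), (3, False)]
    )
    def test_frameshift_from_skip(self, skipped, shifts):
        assert frameshift_from_skip(skipped) is shifts

    def test_nonpositive_skip_rejected(self):
        with pytest.raises(DataError):
            frameshift_from_skip(0)
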