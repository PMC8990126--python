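"""Evidence combination and curated-literature override."""

import itertools

import pytest
from hypothesis import given
from hypothesis import strategies as st

from vus_triage.acmg import (
    CATEGORIES,
    AcmgEvidence,
    combine_evidence,
    literature_override,
)
from vus_triage.domain import Tier, make_variant_id
from vus_triage.errors import ConfigError
from vus_triage.pipeline import curated_lookup_from_fixture

# Independent oracle: literal transcription of the published combining
# criteria, evaluated directly on category counts.


def oracle(pvs, ps, pm, pp, ba, bs, bp):
    pathogenic = (
        (pvs >= 1 and (ps >= 1 or pm >= 2 or (pm >= 1 and pp >= 1) or pp >= 2))
        or ps >= 2
        or (ps >= 1 and (pm >= 3 or (pm >= 2 and pp >= 2) or (pm >= 1 and pp >= 4)))
    )
    likely_pathogenic = (
        (pvs >= 1 and pm >= 1)
        or (ps >= 1 and pm >= 1)
        or (ps >= 1 and pp >= 2)
        or pm >= 3
        or (pm >= 2 and pp >= 2)
        or (pm >= 1 and pp >= 4)
    )
    benign = ba >= 1 or bs >= 2
    likely_benign = (bs >= 1 and bp >= 1) or bp >= 2
    path_dir = pathogenic or likely_pathogenic
    ben_dir = benign or likely_benign
    if path_dir and ben_dir:
        return Tier.VUS
    if pathogenic:
        return Tier.P
    if likely_pathogenic:
        return Tier.LP
    if benign:
        return Tier.B
    if likely_benign:
        return Tier.LB
    return Tier.VUS


def evidence_from_counts(counts):
    # synthesize distinct codes with explicit strengths for given counts
    codes, strengths = [], {}
    for cat, n in zip(CATEGORIES, counts):
        for i in range(n):
            code = f"X_{cat}_{i}"
            codes.append(code)
            strengths[code] = cat
    return AcmgEvidence(frozenset(codes), strengths=strengths)


class TestCombineEvidence:
    def test_no_evidence_is_vus(self):
        assert combine_evidence(AcmgEvidence(frozenset())) is Tier.VUS

    def test_very_strong_plus_strong_is_pathogenic(self):
        assert combine_evidence(AcmgEvidence({"PVS1", "PS3"})) is Tier.P

    def test_strong_plus_moderate_is_likely_pathogenic(self):
        assert combine_evidence(AcmgEvidence({"PS3", "PM2"})) is Tier.LP

    def test_unknown_code_is_config_error(self):
        with pytest.raises(ConfigError):
            AcmgEvidence({"XYZ9"})

    def test_agrees_with_oracle_on_all_count_vectors(self):
        """Exhaustive enumeration up to 3 tags per category matches the oracle."""
        for counts in itertools.product(range(4), repeat=len(CATEGORIES)):
            got = combine_evidence(evidence_from_counts(counts))
            assert got is oracle(*counts), f"counts={counts}"

    def test_conflicting_evidence_is_vus(self):
        evidence = AcmgEvidence({"PVS1", "PS1", "BA1"})
        assert combine_evidence(evidence) is Tier.VUS

    @given(st.lists(st.sampled_from(range(len(CATEGORIES))), max_size=8))
    def test_monotone_in_pathogenic_direction(self, extra_cats):
        """Adding a pathogenic tag never moves the result toward benign."""
        order = {Tier.B: -2, Tier.LB: -1, Tier.VUS: 0, Tier.LP: 1, Tier.P: 2}
        counts = [0] * len(CATEGORIES)
        for c in extra_cats:
            counts[c] += 1
        base = combine_evidence(evidence_from_counts(counts))
        for i, cat in enumerate(CATEGORIES):
            bumped = list(counts)
            bumped[i] += 1
            new = combine_evidence(evidence_from_counts(bumped))
            if cat.startswith("pathogenic"):
                assert order[new] >= order[base]
            else:
                assert order[new] <= order[base]


class TestLiteratureOverride:
    def test_curated_tier_returned(self, table2):
        lookup = curated_lookup_from_fixture()
        by_c = {r.variant.hgvs_c: r.variant for r in table2.records}
        assert literature_override(by_c["c.835C>T"], lookup) is Tier.P
        assert literature_override(by_c["c.1095-2A>C"], lookup) is Tier.LP

    def test_absent_variant_returns_none(self, table3):
        lookup = curated_lookup_from_fixture()
        vus = table3.records[0].variant
        assert literature_override(vus, lookup) is None

    def test_lookup_covers_all_twenty_diagnostic_calls(self):
        lookup = curated_lookup_from_fixture()
        assert len(lookup) == 20
        assert sorted(t.value for t in lookup.values()).count("P") == 15
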