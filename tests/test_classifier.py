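"""Actuarial classification rules, cohort tallies and APOE flag coding."""

import itertools

import pytest

from gwmci.battery import DOMAINS, ZProfile
from gwmci.classifier import (
    CN,
    INTERMEDIATE,
    MCI,
    UNCLASSIFIABLE,
    DomainStatus,
    apoe_flags,
    classify,
    classify_cohort,
    classify_subject,
    domain_status,
)

# domain of each default-battery measure, battery order
_MEASURE_DOMAINS = (
    "episodic_memory", "episodic_memory",
    "executive_function", "executive_function",
    "attention", "attention",
    "language", "visuospatial",
)


def profile_from_pattern(pattern, subject_id="s"):
    """ZProfile from an 8-tuple of impairment booleans (battery order)."""
    ids = ("cvlt_total", "cvlt_ldfr", "tmt_b", "cw_inhibition",
           "digit_span", "tmt_a", "boston_naming", "block_design")
    z = {m: (-1.5 if imp else 0.0) for m, imp in zip(ids, pattern)}
    return ZProfile(subject_id, z, {m: v <= -1.0 for m, v in z.items()})


def oracle_label(pattern):
    """Literal, independent restatement of the classification rules."""
    impaired_by_domain = {}
    for dom, imp in zip(_MEASURE_DOMAINS, pattern):
        impaired_by_domain.setdefault(dom, []).append(imp)
    full_pair = any(
        all(impaired_by_domain[d])
        for d in ("episodic_memory", "executive_function", "attention")
    )
    touched = sum(1 for flags in impaired_by_domain.values() if any(flags))
    if full_pair or touched >= 4:
        return MCI
    if touched == 0:
        return CN
    return INTERMEDIATE


class TestDomainStatus:
    def test_no_flags_all_untouched(self, battery):
        statuses = domain_status(profile_from_pattern([False] * 8), battery)
        assert [s.domain for s in statuses] == list(DOMAINS)
        assert not any(s.touched for s in statuses)

    def test_attention_full_hit(self, battery):
        pattern = [False] * 8
        pattern[4] = pattern[5] = True  # both attention measures
        statuses = {s.domain: s for s in domain_status(profile_from_pattern(pattern), battery)}
        assert statuses["attention"].full_hit
        assert all(not statuses[d].touched for d in DOMAINS if d != "attention")

    def test_language_full_hit_is_not_an_mci_rule(self, battery):
        # a 1-measure domain is trivially "fully" impaired but only counts
        # as touched; the pair rule is restricted to the 2-measure domains
        pattern = [False] * 8
        pattern[6] = True  # boston_naming
        statuses = domain_status(profile_from_pattern(pattern), battery)
        lang = next(s for s in statuses if s.domain == "language")
        assert lang.touched and lang.full_hit
        assert classify(statuses).label == INTERMEDIATE

    def test_unknown_measure_rejected(self, battery):
        prof = ZProfile("s", {"mystery": -2.0}, {"mystery": True})
        with pytest.raises(KeyError, match="mystery"):
            domain_status(prof, battery)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            DomainStatus("attention", n_measures=2, n_available=1, n_impaired=2)


class TestClassify:
    def test_memory_pair_is_amnestic_mci(self, battery):
        pattern = [True, True] + [False] * 6
        status = classify(domain_status(profile_from_pattern(pattern), battery))
        assert status.label == MCI
        assert status.rule == "two_measure_memory"

    def test_four_touched_domains_is_mci(self, battery):
        # one impairment in memory, executive, language, visuospatial
        pattern = [True, False, True, False, False, False, True, True]
        status = classify(domain_status(profile_from_pattern(pattern), battery))
        assert status.label == MCI
        assert status.rule == "multidomain_4plus"
        assert status.n_touched == 4

    def test_three_touched_is_intermediate(self, battery):
        pattern = [True, False, True, False, True, False, False, False]
        status = classify(domain_status(profile_from_pattern(pattern), battery))
        assert status.label == INTERMEDIATE
        assert status.n_touched == 3

    def test_clean_profile_is_cn(self, battery):
        status = classify(domain_status(profile_from_pattern([False] * 8), battery))
        assert status.label == CN and status.n_touched == 0

    def test_precedence_affects_trace_not_label(self, battery):
        # memory pair AND >=4 touched: label MCI, memory rule traces first
        pattern = [True, True, True, False, False, False, True, True]
        status = classify(domain_status(profile_from_pattern(pattern), battery))
        assert status.label == MCI and status.rule == "two_measure_memory"

    def test_wrong_status_count_rejected(self, battery):
        statuses = domain_status(profile_from_pattern([False] * 8), battery)
        with pytest.raises(ValueError, match="one status per domain"):
            classify(statuses[:4])

    def test_exhaustive_agreement_with_oracle(self, battery):
        """All 256 impairment patterns agree with the brute-force rules."""
        for pattern in itertools.product([False, True], repeat=8):
            got = classify(domain_status(profile_from_pattern(pattern), battery))
            assert got.label == oracle_label(pattern), pattern

    def test_monotone_under_added_impairment(self, battery):
        """Adding one impairment never improves the label."""
        severity = {CN: 0, INTERMEDIATE: 1, MCI: 2}
        for pattern in itertools.product([False, True], repeat=8):
            base = severity[classify(domain_status(profile_from_pattern(pattern), battery)).label]
            for i in range(8):
                if pattern[i]:
                    continue
                worse = list(pattern)
                worse[i] = True
                lab = classify(domain_status(profile_from_pattern(worse), battery)).label
                assert severity[lab] >= base, (pattern, i)


class TestCohortClassification:
    def test_empty_cohort(self, battery):
        clf = classify_cohort([], battery)
        assert clf.counts == {MCI: 0, INTERMEDIATE: 0, CN: 0}

    def test_single_cn_profile(self, battery):
        clf = classify_cohort([profile_from_pattern([False] * 8)], battery)
        assert clf.counts[CN] == 1

    def test_duplicate_subject_rejected(self, battery):
        p = profile_from_pattern([False] * 8)
        with pytest.raises(ValueError, match="duplicate"):
            classify_cohort([p, p], battery)

    def test_breakdown_sums_to_intermediate_count(self, battery):
        profiles = [
            profile_from_pattern([True] + [False] * 7, "a"),
            profile_from_pattern([True, False, True] + [False] * 5, "b"),
            profile_from_pattern([False] * 8, "c"),
        ]
        clf = classify_cohort(profiles, battery)
        assert sum(clf.intermediate_breakdown.values()) == clf.counts[INTERMEDIATE] == 2

    def test_sparse_profile_is_unclassifiable_not_cn(self, battery):
        # only 2 of 8 measures scored: "no impaired score" must not be
        # conflated with "no score"
        prof = ZProfile("s", {"cvlt_total": 0.0, "tmt_b": 0.0},
                        {"cvlt_total": False, "tmt_b": False})
        assert classify_subject(prof, battery).label == UNCLASSIFIABLE
        assert classify_subject(prof, battery, min_measures_present=2).label == CN


class TestApoeFlags:
    @pytest.mark.parametrize(
        "genotype,expected",
        [
            ((3, 4), (True, False)),
            ((4, 4), (True, False)),
            ((2, 4), (False, True)),  # protective allele overrides
            ((2, 3), (False, True)),
            ((3, 3), (False, False)),
            ("3/4", (True, False)),
            ("2/4", (False, True)),
        ],
    )
    def test_flag_coding(self, genotype, expected):
        assert apoe_flags(genotype) == expected

    def test_unknown_allele_rejected(self):
        with pytest.raises(ValueError, match="allele"):
            apoe_flags((1, 3))
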