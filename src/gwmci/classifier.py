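"""Actuarial neuropsychological classification of cognitive status.

A subject is labelled **MCI** if both measures in a two-measure domain
(episodic memory, executive function, or attention) are impaired, or if
at least four of the five cognitive domains contain at least one impaired
measure.  A subject with one to three "touched" domains (at least one
impaired measure each) and no two-measure domain fully impaired is
labelled **intermediate**; a subject with no impaired score in any domain
is **cognitively normal** (CN).

The single-measure domains (language, visuospatial) can only contribute
a touched domain; they can never satisfy the two-measure rule.

Rule precedence affects only the recorded trace, never the label: a
profile satisfying several MCI rules is traced to the first that fires,
in battery order (memory, executive, attention, then the multidomain
rule).

Missing-data policy: a two-measure rule requires both measures present
and impaired; a domain with no scored measures counts as untouched; and
a subject with fewer than ``min_measures_present`` scored measures
(default 6 of 8) is marked UNCLASSIFIABLE rather than CN, so that "no
impaired score" is never conflated with "no score".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

from .battery import DOMAINS, TWO_MEASURE_DOMAINS, BatterySpec, ZProfile

__all__ = [
    "MCI",
    "INTERMEDIATE",
    "CN",
    "UNCLASSIFIABLE",
    "LABELS",
    "DomainStatus",
    "CognitiveStatus",
    "CohortClassification",
    "domain_status",
    "classify",
    "classify_subject",
    "classify_cohort",
    "apoe_flags",
]

MCI = "MCI"
INTERMEDIATE = "INTERMEDIATE"
CN = "CN"
UNCLASSIFIABLE = "UNCLASSIFIABLE"
LABELS = (MCI, INTERMEDIATE, CN)

#: Trace tokens, in precedence order for the MCI rules.
RULE_TWO_MEASURE = {
    "episodic_memory": "two_measure_memory",
    "executive_function": "two_measure_executive",
    "attention": "two_measure_attention",
}
RULE_MULTIDOMAIN = "multidomain_4plus"
RULE_INTERMEDIATE = "intermediate"
RULE_NORMAL = "normal"
RULE_UNCLASSIFIABLE = "unclassifiable"

#: Minimum scored measures for a subject to be classifiable at all.
DEFAULT_MIN_MEASURES_PRESENT = 6


@dataclass(frozen=True)
class DomainStatus:
    """Impairment summary for one cognitive domain."""

    domain: str
    n_measures: int
    n_available: int
    n_impaired: int

    def __post_init__(self) -> None:
        if not (0 <= self.n_impaired <= self.n_available <= self.n_measures):
            raise ValueError(
                f"inconsistent counts for domain {self.domain!r}: "
                f"impaired={self.n_impaired}, available={self.n_available}, "
                f"measures={self.n_measures}"
            )

    @property
    def touched(self) -> bool:
        return self.n_impaired >= 1

    @property
    def full_hit(self) -> bool:
        """All of the domain's battery measures are present and impaired."""
        return self.n_measures > 0 and self.n_impaired == self.n_measures


@dataclass(frozen=True)
class CognitiveStatus:
    """Three-way cognitive label plus a trace of the rule that fired."""

    label: str
    rule: str
    touched_domains: frozenset[str]
    n_touched: int


@dataclass
class CohortClassification:
    """Cohort-level classification: per-subject labels plus marginal counts."""

    per_subject: dict[str, CognitiveStatus]
    counts: dict[str, int]
    intermediate_breakdown: dict[int, int]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "subject_id": sid,
                "label": st.label,
                "rule": st.rule,
                "n_touched": st.n_touched,
                "touched_domains": ";".join(
                    sorted(st.touched_domains, key=DOMAINS.index)
                ),
            }
            for sid, st in self.per_subject.items()
        ]
        return pd.DataFrame(rows, columns=["subject_id", "label", "rule", "n_touched", "touched_domains"])


def domain_status(profile: ZProfile, battery: BatterySpec) -> list[DomainStatus]:
    """Summarize a subject's impairment flags per domain, in canonical order."""
    unknown = set(profile.z) - set(battery.measure_ids)
    if unknown:
        raise KeyError(
            f"profile {profile.subject_id!r} references measures not in "
            f"battery: {sorted(unknown)}"
        )
    statuses = []
    for domain in DOMAINS:
        measures = battery.domain_measures(domain)
        avail = [m.measure_id for m in measures if m.measure_id in profile.z]
        n_imp = sum(profile.impaired[m] for m in avail)
        statuses.append(
            DomainStatus(
                domain=domain,
                n_measures=len(measures),
                n_available=len(avail),
                n_impaired=n_imp,
            )
        )
    return statuses


def classify(statuses: Iterable[DomainStatus]) -> CognitiveStatus:
    """Apply the actuarial rules to five per-domain summaries."""
    statuses = list(statuses)
    by_domain = {s.domain: s for s in statuses}
    if len(statuses) != len(DOMAINS) or set(by_domain) != set(DOMAINS):
        raise ValueError(
            f"classify requires exactly one status per domain {DOMAINS}; "
            f"got {[s.domain for s in statuses]}"
        )

    touched = frozenset(d for d in DOMAINS if by_domain[d].touched)
    n_touched = len(touched)

    for domain in TWO_MEASURE_DOMAINS:
        s = by_domain[domain]
        if s.n_measures >= 2 and s.full_hit:
            return CognitiveStatus(MCI, RULE_TWO_MEASURE[domain], touched, n_touched)
    if n_touched >= 4:
        return CognitiveStatus(MCI, RULE_MULTIDOMAIN, touched, n_touched)
    if n_touched == 0:
        return CognitiveStatus(CN, RULE_NORMAL, touched, n_touched)
    return CognitiveStatus(INTERMEDIATE, RULE_INTERMEDIATE, touched, n_touched)


def classify_subject(
    profile: ZProfile,
    battery: BatterySpec,
    min_measures_present: int = DEFAULT_MIN_MEASURES_PRESENT,
) -> CognitiveStatus:
    """Classify one subject, applying the minimum-data policy."""
    statuses = domain_status(profile, battery)
    if len(profile.z) < min_measures_present:
        touched = frozenset(d for d in DOMAINS if statuses[DOMAINS.index(d)].touched)
        return CognitiveStatus(UNCLASSIFIABLE, RULE_UNCLASSIFIABLE, touched, len(touched))
    return classify(statuses)


def classify_cohort(
    profiles: Iterable[ZProfile],
    battery: BatterySpec,
    min_measures_present: int = DEFAULT_MIN_MEASURES_PRESENT,
) -> CohortClassification:
    """Classify every subject in a cohort and tally the marginals."""
    per_subject: dict[str, CognitiveStatus] = {}
    for profile in profiles:
        if profile.subject_id in per_subject:
            raise ValueError(f"duplicate subject_id {profile.subject_id!r}")
        per_subject[profile.subject_id] = classify_subject(
            profile, battery, min_measures_present
        )
    counts = {label: 0 for label in LABELS}
    breakdown = {1: 0, 2: 0, 3: 0}
    for status in per_subject.values():
        counts[status.label] = counts.get(status.label, 0) + 1
        if status.label == INTERMEDIATE:
            breakdown[status.n_touched] += 1
    return CohortClassification(per_subject, counts, breakdown)


def apoe_flags(genotype: tuple[int, int] | str) -> tuple[bool, bool]:
    """APOE risk/protective flags: ``(e4_positive, e2_positive)``.

    Genotypes 3/4 and 4/4 are e4-positive; 2/3 and 2/4 are e2-positive.
    The 2/4 genotype counts as e2-positive only (the protective allele
    overrides the risk allele for flagging purposes).  Accepts a pair of
    integer alleles or a string like ``"3/4"``.
    """
    if isinstance(genotype, str):
        parts = genotype.replace("e", "").split("/")
        if len(parts) != 2:
            raise ValueError(f"cannot parse APOE genotype {genotype!r}")
        try:
            alleles = (int(parts[0]), int(parts[1]))
        except ValueError:
            raise ValueError(f"cannot parse APOE genotype {genotype!r}") from None
    else:
        alleles = (int(genotype[0]), int(genotype[1]))
    if any(a not in (2, 3, 4) for a in alleles):
        raise ValueError(f"unknown APOE allele in genotype {genotype!r}")
    pair = frozenset(alleles) if alleles[0] != alleles[1] else frozenset({alleles[0]})
    e2 = 2 in pair
    e4 = 4 in pair and not e2
    return e4, e2
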