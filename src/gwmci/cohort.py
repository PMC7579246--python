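"""Seeded synthetic cohort generator with planted cognitive status.

Emulates a 202-veteran study cohort: each subject carries a planted
cognitive label (MCI / intermediate / CN), an 8-measure z-score profile
guaranteed to classify to that label, demographics and clinical flags
drawn at group-conditional rates, deployment-exposure frequency
categories drawn through a latent-Gaussian copula, and imaging scalars
(intracranial volume, bilateral hippocampal volume, five lobar/insular
cortical thicknesses) with planted group effects.

Cognitive status is treated as the latent cause: every other variable is
sampled conditionally on the planted group.  That is a simulation
convenience — the emulated study is cross-sectional and asserts no
causal direction.

Test-score correlation structure is exchangeable by block: measures
within a domain correlate at ``within_domain_rho`` (default 0.6) and
across domains at ``cross_domain_rho`` (default 0.3).  Target impairment
patterns are enforced on the correlated draw by reflecting offending
coordinates about the impairment threshold, which preserves the
half-normal shape of each constrained margin.

Raw scores are obtained by inverting the age-banded norm-table transform
at the subject's age, so re-standardizing a generated cohort recovers
its z-profiles exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import norm, truncnorm

from .battery import (
    DOMAINS,
    BatterySpec,
    NormTable,
    ZProfile,
    default_battery,
    default_norms,
    raw_from_z,
)
from .classifier import (
    CN,
    INTERMEDIATE,
    MCI,
    CognitiveStatus,
    apoe_flags,
    classify,
    domain_status,
)
from .stats import ContingencyTable

__all__ = [
    "GROUPS",
    "EXPOSURE_ITEMS",
    "EXPOSURE_CATEGORIES",
    "FIXTURE_SEED",
    "CohortConfig",
    "SubjectRecord",
    "plant_profile",
    "generate_cohort",
    "generate_fixture",
    "contingency_fixtures",
    "cohort_to_frame",
]

GROUPS = (MCI, INTERMEDIATE, CN)

#: Default fixture seed (date-derived, fixed; below 2**31).
FIXTURE_SEED = 20200930

EXPOSURE_CATEGORIES = ("none", "d1_6", "d7_30", "d30plus")

EXPOSURE_ITEMS = (
    "smoke_oil_fires",
    "heard_chemical_alarms",
    "scud_missile_1mile",
    "contact_pows",
    "dead_animals",
    "destroyed_enemy_vehicles",
    "friendly_fire_vehicles",
    "cream_liquid_pesticides",
    "powdered_pesticide",
    "pesticide_treated_uniform",
    "flea_collar",
    "living_area_sprayed",
    "pb_pills",
    "carc_paint",
    "tent_fuel_heater",
)

# Per-group probabilities of each binary clinical/demographic flag,
# anchored to the emulated study's printed per-group counts over group
# sizes (25, 98, 79).
_GROUP_N = {MCI: 25, INTERMEDIATE: 98, CN: 79}

_BINARY_RATES: dict[str, dict[str, float]] = {
    "male": {MCI: 22 / 25, INTERMEDIATE: 76 / 98, CN: 68 / 79},
    "rank_enlisted": {MCI: 24 / 25, INTERMEDIATE: 77 / 98, CN: 49 / 79},
    "ptsd_current": {MCI: 10 / 25, INTERMEDIATE: 12 / 98, CN: 6 / 79},
    "mdd_current": {MCI: 6 / 25, INTERMEDIATE: 8 / 98, CN: 5 / 79},
    "etoh_history": {MCI: 11 / 25, INTERMEDIATE: 19 / 98, CN: 18 / 79},
    "substance_history": {MCI: 4 / 25, INTERMEDIATE: 5 / 98, CN: 7 / 79},
    "psychotropics": {MCI: 9 / 25, INTERMEDIATE: 18 / 98, CN: 13 / 79},
    "cmi_mild_moderate": {MCI: 20 / 25, INTERMEDIATE: 64 / 98, CN: 43 / 79},
    "cmi_severe": {MCI: 10 / 25, INTERMEDIATE: 19 / 98, CN: 7 / 79},
    "kansas_gwi": {MCI: 14 / 25, INTERMEDIATE: 41 / 98, CN: 28 / 79},
    "kansas_exclusionary": {MCI: 7 / 25, INTERMEDIATE: 31 / 98, CN: 21 / 79},
    "khamisiyah_exposed": {MCI: 11 / 25, INTERMEDIATE: 44 / 98, CN: 33 / 79},
}

_RACE_LEVELS = ("caucasian", "african_american", "other")
_RACE_COUNTS = {MCI: (15, 6, 4), INTERMEDIATE: (66, 11, 21), CN: (67, 1, 11)}

_SERVICE_LEVELS = ("active_duty", "reserves", "national_guard")
_SERVICE_COUNTS = {MCI: (18, 6, 1), INTERMEDIATE: (78, 15, 5), CN: (59, 17, 3)}

_BRANCH_LEVELS = ("army", "marines", "navy", "air_force")
_BRANCH_COUNTS = {MCI: (17, 4, 2, 2), INTERMEDIATE: (61, 20, 9, 8), CN: (48, 15, 9, 7)}

_TBI_LEVELS = ("improbable", "possible", "mild", "moderate")
_TBI_COUNTS = {MCI: (13, 4, 8, 0), INTERMEDIATE: (50, 20, 16, 2), CN: (42, 15, 22, 0)}

_APOE_LEVELS = ("2/3", "2/4", "3/3", "3/4", "4/4")
_APOE_COUNTS = {MCI: (3, 2, 15, 5, 0), INTERMEDIATE: (12, 3, 58, 18, 5), CN: (6, 3, 56, 10, 2)}

# Age (years) per group: means/SDs from the emulated study's demographic
# table, truncated to the norm-table-covered range.
_AGE_PARAMS = {MCI: (51.8, 6.7), INTERMEDIATE: (53.7, 7.3), CN: (55.4, 8.4)}
_AGE_RANGE = (35.0, 79.0)

_EDU_PARAMS = {MCI: (14.8, 2.2), INTERMEDIATE: (15.5, 2.3), CN: (16.0, 2.3)}

# Imaging scalars: per-group (mean, sd) for bilateral hippocampal volume
# (cc) and mean lobar/insular cortical thickness (mm).
_HIPPO_PARAMS = {MCI: (8.05, 0.98), INTERMEDIATE: (8.59, 0.80), CN: (8.68, 0.79)}

THICKNESS_REGIONS = ("frontal", "parietal", "temporal", "occipital", "insula")
_THICK_PARAMS = {
    "frontal": {MCI: (2.54, 0.09), INTERMEDIATE: (2.59, 0.10), CN: (2.59, 0.10)},
    "parietal": {MCI: (2.33, 0.11), INTERMEDIATE: (2.38, 0.09), CN: (2.40, 0.09)},
    "temporal": {MCI: (2.87, 0.11), INTERMEDIATE: (2.95, 0.12), CN: (2.95, 0.11)},
    "occipital": {MCI: (1.90, 0.11), INTERMEDIATE: (1.92, 0.10), CN: (1.95, 0.10)},
    "insula": {MCI: (2.98, 0.15), INTERMEDIATE: (3.03, 0.13), CN: (3.06, 0.14)},
}

_ICV_MEAN, _ICV_SD = 1500.0, 140.0
#: Hippocampal volume loads on standardized ICV and on age (cc per year);
#: residual SD is chosen so the marginal group SD matches its target.
_HIPPO_ICV_LOADING = 0.35
_HIPPO_AGE_SLOPE = -0.02
#: Cortical thickness declines slightly with age (mm per year).
_THICK_AGE_SLOPE = -0.003
#: Exchangeable correlation of thickness residuals across the 5 regions.
_THICKNESS_RHO = 0.58
#: Exchangeable latent correlation across the 15 exposure items.
_EXPOSURE_RHO = 0.21

# Per-group exposure-category percentages (none, 1-6 d, 7-30 d, >30 d),
# normalized at sampling time.
_EXPOSURE_PCT: dict[str, dict[str, tuple[float, float, float, float]]] = {
    "smoke_oil_fires": {MCI: (4, 16, 20, 60), INTERMEDIATE: (14, 20, 34, 32), CN: (29, 14, 29, 28)},
    "heard_chemical_alarms": {MCI: (12, 28, 24, 36), INTERMEDIATE: (25, 37, 27, 11), CN: (27, 39, 28, 6)},
    "scud_missile_1mile": {MCI: (29, 58, 8, 4), INTERMEDIATE: (55, 33, 8, 4), CN: (56, 33, 9, 3)},
    "contact_pows": {MCI: (48, 28, 12, 12), INTERMEDIATE: (45, 28, 19, 8), CN: (52, 30, 11, 6)},
    "dead_animals": {MCI: (32, 44, 8, 16), INTERMEDIATE: (63, 16, 14, 6), CN: (62, 32, 5, 1)},
    "destroyed_enemy_vehicles": {MCI: (20, 44, 20, 16), INTERMEDIATE: (35, 30, 27, 9), CN: (39, 34, 22, 5)},
    "friendly_fire_vehicles": {MCI: (60, 28, 4, 8), INTERMEDIATE: (76, 18, 3, 3), CN: (82, 16, 1, 1)},
    "cream_liquid_pesticides": {MCI: (28, 8, 16, 48), INTERMEDIATE: (36, 5, 21, 38), CN: (51, 9, 13, 27)},
    "powdered_pesticide": {MCI: (60, 8, 4, 28), INTERMEDIATE: (86, 3, 4, 6), CN: (89, 1, 4, 6)},
    "pesticide_treated_uniform": {MCI: (58, 0, 13, 29), INTERMEDIATE: (67, 2, 9, 22), CN: (64, 8, 8, 21)},
    "flea_collar": {MCI: (88, 0, 0, 12), INTERMEDIATE: (95, 1, 2, 2), CN: (96, 0, 3, 1)},
    "living_area_sprayed": {MCI: (52, 8, 12, 28), INTERMEDIATE: (78, 9, 8, 5), CN: (76, 13, 8, 4)},
    "pb_pills": {MCI: (20, 36, 24, 20), INTERMEDIATE: (26, 22, 25, 28), CN: (23, 26, 28, 23)},
    "carc_paint": {MCI: (44, 16, 12, 28), INTERMEDIATE: (77, 11, 4, 8), CN: (72, 10, 9, 9)},
    "tent_fuel_heater": {MCI: (24, 8, 12, 56), INTERMEDIATE: (39, 5, 7, 49), CN: (46, 9, 10, 35)},
}


def _probs(counts) -> np.ndarray:
    arr = np.asarray(counts, dtype=float)
    return arr / arr.sum()


@dataclass
class CohortConfig:
    """Generator configuration; defaults emulate the reference study."""

    n_subjects: int = 202
    status_counts: dict[str, int] = field(
        default_factory=lambda: {MCI: 25, INTERMEDIATE: 98, CN: 79}
    )
    intermediate_breakdown: dict[int, int] = field(
        default_factory=lambda: {1: 68, 2: 25, 3: 5}
    )
    within_domain_rho: float = 0.6
    cross_domain_rho: float = 0.3
    impairment_threshold: float = -1.0
    clinical_rates: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in _BINARY_RATES.items()}
    )
    age_range: tuple[float, float] = _AGE_RANGE
    thickness_rho: float = _THICKNESS_RHO
    exposure_rho: float = _EXPOSURE_RHO
    seed: int = FIXTURE_SEED

    def validate(self) -> None:
        if sum(self.status_counts.values()) != self.n_subjects:
            raise ValueError(
                f"status_counts {self.status_counts} do not sum to "
                f"n_subjects={self.n_subjects}"
            )
        if any(c < 0 for c in self.status_counts.values()):
            raise ValueError("status counts must be non-negative")
        n_int = self.status_counts.get(INTERMEDIATE, 0)
        if sum(self.intermediate_breakdown.values()) != n_int:
            raise ValueError(
                f"intermediate_breakdown {self.intermediate_breakdown} does not "
                f"sum to the intermediate count {n_int}"
            )
        if not set(self.intermediate_breakdown) <= {1, 2, 3}:
            raise ValueError("intermediate n_touched must be 1, 2 or 3")
        for flag, rates in self.clinical_rates.items():
            for g, p in rates.items():
                if not 0 <= p <= 1:
                    raise ValueError(f"rate {flag}[{g}]={p} outside [0, 1]")
        # block template must be positive definite
        np.linalg.cholesky(_score_correlation(default_battery(),
                                              self.within_domain_rho,
                                              self.cross_domain_rho))


@dataclass
class SubjectRecord:
    """One synthetic subject: demographics, clinical flags, exposures,
    raw test scores, imaging scalars, and the planted ground truth."""

    subject_id: str
    age: float
    male: bool
    education_years: float
    race: str
    rank_enlisted: bool
    service_type: str
    branch: str
    ptsd_current: bool
    mdd_current: bool
    etoh_history: bool
    substance_history: bool
    psychotropics: bool
    tbi_category: str
    apoe_genotype: str
    cmi_mild_moderate: bool
    cmi_severe: bool
    kansas_gwi: bool
    kansas_exclusionary: bool
    khamisiyah_exposed: bool
    exposures: dict[str, str]
    raw_scores: dict[str, float]
    z_scores: dict[str, float]
    icv: float
    hippocampus_cc: float
    thickness_mm: dict[str, float]
    planted_status: CognitiveStatus

    def __post_init__(self) -> None:
        if not self.hippocampus_cc > 0:
            raise ValueError("hippocampal volume must be positive")
        if not self.icv > 0:
            raise ValueError("ICV must be positive")
        for region, t in self.thickness_mm.items():
            if not 1.0 < t < 4.0:
                raise ValueError(f"{region} thickness {t} outside (1, 4) mm")


def _score_correlation(
    battery: BatterySpec, within: float, cross: float
) -> np.ndarray:
    """Exchangeable-block correlation template over battery measures."""
    doms = [m.domain for m in battery]
    k = len(doms)
    corr = np.full((k, k), cross)
    for i in range(k):
        for j in range(k):
            if doms[i] == doms[j]:
                corr[i, j] = within
        corr[i, i] = 1.0
    return corr


def _exchangeable(k: int, rho: float) -> np.ndarray:
    return np.full((k, k), rho) + (1 - rho) * np.eye(k)


def _reflect(z: np.ndarray, idx_impair, idx_clear, thr: float) -> np.ndarray:
    """Enforce a target impairment pattern by reflecting about ``thr``."""
    z = z.copy()
    for i in idx_impair:
        if z[i] > thr:
            z[i] = 2 * thr - z[i]
    for i in idx_clear:
        if z[i] <= thr:
            z[i] = 2 * thr - z[i]
            if z[i] <= thr:  # original draw exactly at the threshold
                z[i] = thr + 1e-9
    return z


def plant_profile(
    label: str,
    battery: BatterySpec | None = None,
    rng: np.random.Generator | None = None,
    n_touched: int | None = None,
    rule: str | None = None,
    within_domain_rho: float = 0.6,
    cross_domain_rho: float = 0.3,
    threshold: float = -1.0,
) -> dict[str, float]:
    """Draw one correlated z-vector classifying to the planted label.

    For CN all measures are forced above the threshold.  For MCI a rule
    is chosen at random (or fixed via ``rule``): a full hit on one of the
    three two-measure domains, or at least one impairment in >= 4
    domains.  For intermediate, exactly ``n_touched`` (1-3, random if
    omitted) domains receive a single impairment and no two-measure
    domain is fully hit.  The planted label is guaranteed: the returned
    profile classifies to ``label``.
    """
    battery = battery if battery is not None else default_battery()
    rng = rng if rng is not None else np.random.default_rng()
    corr = _score_correlation(battery, within_domain_rho, cross_domain_rho)
    chol = np.linalg.cholesky(corr)
    z = chol @ rng.standard_normal(len(battery))
    z = _plant_on_draw(z, label, battery, rng, n_touched, rule, threshold)
    return dict(zip(battery.measure_ids, z))


def _plant_on_draw(
    z: np.ndarray,
    label: str,
    battery: BatterySpec,
    rng: np.random.Generator,
    n_touched: int | None,
    rule: str | None,
    thr: float,
) -> np.ndarray:
    mids = battery.measure_ids
    dom_idx = {
        d: [mids.index(m.measure_id) for m in battery.domain_measures(d)]
        for d in DOMAINS
    }
    two_measure = [d for d in DOMAINS if len(dom_idx[d]) >= 2]
    all_idx = list(range(len(mids)))

    if label == CN:
        return _reflect(z, [], all_idx, thr)

    if label == MCI:
        if rule is None:
            choices = [f"two_measure:{d}" for d in two_measure] + ["multidomain_4plus"]
            rule = choices[rng.integers(len(choices))]
        if rule.startswith("two_measure"):
            domain = rule.split(":", 1)[1] if ":" in rule else rule
            if domain not in two_measure:
                raise ValueError(f"two-measure rule needs a two-measure domain, got {domain!r}")
            return _reflect(z, dom_idx[domain], [], thr)
        if rule == "multidomain_4plus":
            k = 4 if rng.random() < 0.8 or len(DOMAINS) < 5 else 5
            chosen = list(rng.choice(len(DOMAINS), size=k, replace=False))
            impair, clear = [], []
            for di, d in enumerate(DOMAINS):
                idxs = dom_idx[d]
                if di in chosen:
                    pick = idxs[rng.integers(len(idxs))]
                    impair.append(pick)
                    clear.extend(i for i in idxs if i != pick)
                else:
                    clear.extend(idxs)
            return _reflect(z, impair, clear, thr)
        raise ValueError(f"unknown MCI rule {rule!r}")

    if label == INTERMEDIATE:
        if n_touched is None:
            n_touched = int(rng.integers(1, 4))
        if not 1 <= n_touched <= 3:
            raise ValueError(f"intermediate requires 1 <= n_touched <= 3, got {n_touched}")
        chosen = list(rng.choice(len(DOMAINS), size=n_touched, replace=False))
        impair, clear = [], []
        for di, d in enumerate(DOMAINS):
            idxs = dom_idx[d]
            if di in chosen:
                pick = idxs[rng.integers(len(idxs))]
                impair.append(pick)
                clear.extend(i for i in idxs if i != pick)
            else:
                clear.extend(idxs)
        return _reflect(z, impair, clear, thr)

    raise ValueError(f"cannot plant label {label!r}")


def _sample_categorical(rng, levels, counts, n) -> np.ndarray:
    return rng.choice(levels, size=n, p=_probs(counts))


def _sample_exposures(rng, group_of: np.ndarray, rho: float) -> list[dict[str, str]]:
    """Latent-Gaussian copula draw of the 15 exposure categories."""
    n = len(group_of)
    k = len(EXPOSURE_ITEMS)
    chol = np.linalg.cholesky(_exchangeable(k, rho))
    latent = rng.standard_normal((n, k)) @ chol.T
    u = norm.cdf(latent)
    # per-group cumulative category probabilities per item
    cum = {
        item: {
            g: np.cumsum(_probs(_EXPOSURE_PCT[item][g]))
            for g in GROUPS
        }
        for item in EXPOSURE_ITEMS
    }
    out: list[dict[str, str]] = []
    for i in range(n):
        g = group_of[i]
        rec = {}
        for j, item in enumerate(EXPOSURE_ITEMS):
            cat = int(np.searchsorted(cum[item][g], u[i, j], side="right"))
            rec[item] = EXPOSURE_CATEGORIES[min(cat, 3)]
        out.append(rec)
    return out


def generate_cohort(
    config: CohortConfig | None = None,
    battery: BatterySpec | None = None,
    norms: NormTable | None = None,
) -> list[SubjectRecord]:
    """Generate a full synthetic cohort, deterministic given the seed."""
    config = config if config is not None else CohortConfig()
    config.validate()
    battery = battery if battery is not None else default_battery()
    norms = norms if norms is not None else default_norms()
    rng = np.random.default_rng(config.seed)
    thr = config.impairment_threshold

    # roster of (label, intermediate n_touched target)
    roster: list[tuple[str, int | None]] = []
    roster += [(MCI, None)] * config.status_counts.get(MCI, 0)
    for k in sorted(config.intermediate_breakdown):
        roster += [(INTERMEDIATE, k)] * config.intermediate_breakdown[k]
    roster += [(CN, None)] * config.status_counts.get(CN, 0)
    order = rng.permutation(len(roster))
    roster = [roster[i] for i in order]
    n = len(roster)
    labels = np.array([r[0] for r in roster])

    # ages and education per group (vectorized per group)
    age = np.empty(n)
    edu = np.empty(n)
    lo, hi = config.age_range
    for g in GROUPS:
        mask = labels == g
        m = int(mask.sum())
        if m == 0:
            continue
        mu, sd = _AGE_PARAMS[g]
        a, b = (lo - mu) / sd, (hi - mu) / sd
        age[mask] = truncnorm.rvs(a, b, loc=mu, scale=sd, size=m, random_state=rng)
        emu, esd = _EDU_PARAMS[g]
        edu[mask] = np.clip(np.round(rng.normal(emu, esd, size=m)), 10, 20)

    # binary clinical flags
    flags: dict[str, np.ndarray] = {}
    for flag, rates in config.clinical_rates.items():
        p = np.array([rates[g] for g in labels])
        flags[flag] = rng.random(n) < p

    # categorical fields
    race = np.empty(n, dtype=object)
    service = np.empty(n, dtype=object)
    branch = np.empty(n, dtype=object)
    tbi = np.empty(n, dtype=object)
    apoe = np.empty(n, dtype=object)
    for g in GROUPS:
        mask = labels == g
        m = int(mask.sum())
        if m == 0:
            continue
        race[mask] = _sample_categorical(rng, _RACE_LEVELS, _RACE_COUNTS[g], m)
        service[mask] = _sample_categorical(rng, _SERVICE_LEVELS, _SERVICE_COUNTS[g], m)
        branch[mask] = _sample_categorical(rng, _BRANCH_LEVELS, _BRANCH_COUNTS[g], m)
        tbi[mask] = _sample_categorical(rng, _TBI_LEVELS, _TBI_COUNTS[g], m)
        apoe[mask] = _sample_categorical(rng, _APOE_LEVELS, _APOE_COUNTS[g], m)

    # imaging scalars with planted group effects and covariate structure
    icv = rng.normal(_ICV_MEAN, _ICV_SD, size=n)
    z_icv = (icv - _ICV_MEAN) / _ICV_SD
    hippo = np.empty(n)
    thick = {r: np.empty(n) for r in THICKNESS_REGIONS}
    chol_t = np.linalg.cholesky(_exchangeable(len(THICKNESS_REGIONS), config.thickness_rho))
    for g in GROUPS:
        mask = labels == g
        m = int(mask.sum())
        if m == 0:
            continue
        mu_a, sd_a = _AGE_PARAMS[g]
        hm, hs = _HIPPO_PARAMS[g]
        resid_var = hs**2 - _HIPPO_ICV_LOADING**2 - (_HIPPO_AGE_SLOPE * sd_a) ** 2
        hippo[mask] = (
            hm
            + _HIPPO_ICV_LOADING * z_icv[mask]
            + _HIPPO_AGE_SLOPE * (age[mask] - mu_a)
            + rng.normal(0, np.sqrt(resid_var), size=m)
        )
        u = rng.standard_normal((m, len(THICKNESS_REGIONS))) @ chol_t.T
        for j, region in enumerate(THICKNESS_REGIONS):
            tm, ts = _THICK_PARAMS[region][g]
            resid_sd = np.sqrt(max(ts**2 - (_THICK_AGE_SLOPE * sd_a) ** 2, 1e-6))
            thick[region][mask] = (
                tm
                + _THICK_AGE_SLOPE * (age[mask] - mu_a)
                + resid_sd * u[:, j]
            )
    hippo = np.clip(hippo, 4.0, 13.0)
    for region in THICKNESS_REGIONS:
        thick[region] = np.clip(thick[region], 1.05, 3.95)

    exposures = _sample_exposures(rng, labels, config.exposure_rho)

    # planted z-profiles (correlated draw + pattern enforcement)
    corr = _score_correlation(battery, config.within_domain_rho, config.cross_domain_rho)
    chol = np.linalg.cholesky(corr)
    base = rng.standard_normal((n, len(battery))) @ chol.T

    records: list[SubjectRecord] = []
    width = len(str(n))
    for i, (label, k_touched) in enumerate(roster):
        z = _plant_on_draw(base[i], label, battery, rng, k_touched, None, thr)
        z_map = dict(zip(battery.measure_ids, (float(v) for v in z)))
        profile = ZProfile(
            subject_id=f"gw{i + 1:0{width}d}",
            z=z_map,
            impaired={m: v <= thr for m, v in z_map.items()},
            threshold=thr,
        )
        status = classify(domain_status(profile, battery))
        if status.label != label or (
            label == INTERMEDIATE and status.n_touched != k_touched
        ):
            raise AssertionError(
                f"planting failed for subject {profile.subject_id}: "
                f"target {label}/{k_touched}, got {status.label}/{status.n_touched}"
            )
        raw = {
            m.measure_id: float(raw_from_z(z_map[m.measure_id], m, float(age[i]), norms))
            for m in battery
        }
        records.append(
            SubjectRecord(
                subject_id=profile.subject_id,
                age=float(age[i]),
                male=bool(flags["male"][i]),
                education_years=float(edu[i]),
                race=str(race[i]),
                rank_enlisted=bool(flags["rank_enlisted"][i]),
                service_type=str(service[i]),
                branch=str(branch[i]),
                ptsd_current=bool(flags["ptsd_current"][i]),
                mdd_current=bool(flags["mdd_current"][i]),
                etoh_history=bool(flags["etoh_history"][i]),
                substance_history=bool(flags["substance_history"][i]),
                psychotropics=bool(flags["psychotropics"][i]),
                tbi_category=str(tbi[i]),
                apoe_genotype=str(apoe[i]),
                cmi_mild_moderate=bool(flags["cmi_mild_moderate"][i]),
                cmi_severe=bool(flags["cmi_severe"][i]),
                kansas_gwi=bool(flags["kansas_gwi"][i]),
                kansas_exclusionary=bool(flags["kansas_exclusionary"][i]),
                khamisiyah_exposed=bool(flags["khamisiyah_exposed"][i]),
                exposures=exposures[i],
                raw_scores=raw,
                z_scores=z_map,
                icv=float(icv[i]),
                hippocampus_cc=float(hippo[i]),
                thickness_mm={r: float(thick[r][i]) for r in THICKNESS_REGIONS},
                planted_status=status,
            )
        )
    return records


def generate_fixture() -> list[SubjectRecord]:
    """The packaged 202-subject cohort at the pinned fixture seed.

    Planted marginals: 25 MCI, 98 intermediate (68/25/5 touching one,
    two, three domains), 79 CN.  Identical across runs and platforms
    for a given numpy version.
    """
    return generate_cohort(CohortConfig(seed=FIXTURE_SEED))


def cohort_to_frame(records: list[SubjectRecord]) -> pd.DataFrame:
    """Serialize a cohort to a wide per-subject DataFrame."""
    rows = []
    for r in records:
        e4, e2 = apoe_flags(r.apoe_genotype)
        row: dict = {
            "subject_id": r.subject_id,
            "age": r.age,
            "male": int(r.male),
            "education_years": r.education_years,
            "race": r.race,
            "rank_enlisted": int(r.rank_enlisted),
            "service_type": r.service_type,
            "branch": r.branch,
            "ptsd_current": int(r.ptsd_current),
            "mdd_current": int(r.mdd_current),
            "etoh_history": int(r.etoh_history),
            "substance_history": int(r.substance_history),
            "psychotropics": int(r.psychotropics),
            "tbi_category": r.tbi_category,
            "apoe_genotype": r.apoe_genotype,
            "apoe_e4": int(e4),
            "apoe_e2": int(e2),
            "cmi_mild_moderate": int(r.cmi_mild_moderate),
            "cmi_severe": int(r.cmi_severe),
            "kansas_gwi": int(r.kansas_gwi),
            "kansas_exclusionary": int(r.kansas_exclusionary),
            "khamisiyah_exposed": int(r.khamisiyah_exposed),
            "icv": r.icv,
            "hippocampus_cc": r.hippocampus_cc,
            "planted_label": r.planted_status.label,
            "planted_n_touched": r.planted_status.n_touched,
            "planted_rule": r.planted_status.rule,
        }
        for region in THICKNESS_REGIONS:
            row[f"thickness_{region}"] = r.thickness_mm[region]
        for item in EXPOSURE_ITEMS:
            row[f"exposure_{item}"] = r.exposures[item]
        for mid, raw in r.raw_scores.items():
            row[mid] = raw
        rows.append(row)
    return pd.DataFrame(rows)


def contingency_fixtures() -> dict[str, ContingencyTable]:
    """The printed group-by-category tables of the emulated study.

    Columns are the three cognitive groups (MCI, intermediate, CN with
    sizes 25/98/79); rows are the variable categories.  These integer
    tables back the chi-square reproduction checks.
    """
    sizes = np.array([25, 98, 79])

    def binary(yes):
        yes = np.array(yes)
        return ContingencyTable(
            row_labels=("yes", "no"),
            col_labels=GROUPS,
            counts=np.vstack([yes, sizes - yes]),
        )

    tables = {
        "current_ptsd": binary([10, 12, 6]),
        "current_mdd": binary([6, 8, 5]),
        "etoh_history": binary([11, 19, 18]),
        "enlisted": binary([24, 77, 49]),
        "cmi_severe": binary([10, 19, 7]),
        "kansas_gwi": binary([14, 41, 28]),
        "race": ContingencyTable(
            row_labels=_RACE_LEVELS,
            col_labels=GROUPS,
            counts=np.array([[15, 66, 67], [6, 11, 1], [4, 21, 11]]),
        ),
    }
    return tables
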