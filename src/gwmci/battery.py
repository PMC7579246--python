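"""Neuropsychological battery structure and age-adjusted z-scoring.

The battery covers five cognitive domains — episodic memory, executive
function, attention, language, and visuospatial function — with two
measures in each of the first three domains and one in each of the last
two (eight measures total).  Raw test scores are standardized against an
age-banded normative table; a score at or below the impairment threshold
(default one standard deviation below the age-adjusted norm, i.e.
z <= -1.0) is flagged as impaired.

Z-scores follow the convention that more negative always means worse:
for tests where higher raw scores are better, ``z = (raw - mean) / sd``;
for timed tests where lower is better (e.g. trail making, in seconds),
``z = (mean - raw) / sd``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "DOMAINS",
    "TWO_MEASURE_DOMAINS",
    "MeasureSpec",
    "BatterySpec",
    "NormEntry",
    "NormTable",
    "RawScoreRecord",
    "ZProfile",
    "NormCoverageError",
    "NormFormatError",
    "default_battery",
    "default_norms",
    "load_norms",
    "zscore",
    "raw_from_z",
    "impairment_flags",
]

#: Canonical domain order.  The first three carry two measures each and can
#: trigger the two-measure impairment rule; language and visuospatial carry
#: a single measure and can only contribute a "touched" domain.
DOMAINS = (
    "episodic_memory",
    "executive_function",
    "attention",
    "language",
    "visuospatial",
)

TWO_MEASURE_DOMAINS = ("episodic_memory", "executive_function", "attention")

DIRECTIONS = ("higher_better", "lower_better")

#: Default impairment threshold: one SD below the age-adjusted norm,
#: boundary inclusive (z exactly at the threshold counts as impaired).
DEFAULT_THRESHOLD = -1.0


class NormFormatError(ValueError):
    """A norm table file does not conform to the expected CSV contract."""


class NormCoverageError(LookupError):
    """No normative age band covers the requested (measure, age) pair."""


@dataclass(frozen=True)
class MeasureSpec:
    """One neuropsychological measure and the domain it belongs to."""

    measure_id: str
    name: str
    domain: str
    direction: str

    def __post_init__(self) -> None:
        if self.domain not in DOMAINS:
            raise ValueError(
                f"unknown domain {self.domain!r} for measure {self.measure_id!r}; "
                f"expected one of {DOMAINS}"
            )
        if self.direction not in DIRECTIONS:
            raise ValueError(
                f"unknown direction {self.direction!r} for measure "
                f"{self.measure_id!r}; expected one of {DIRECTIONS}"
            )


@dataclass(frozen=True)
class BatterySpec:
    """An ordered collection of measures spanning the five domains."""

    measures: tuple[MeasureSpec, ...]

    def __post_init__(self) -> None:
        ids = [m.measure_id for m in self.measures]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate measure_ids in battery: {dupes}")

    def __iter__(self):
        return iter(self.measures)

    def __len__(self) -> int:
        return len(self.measures)

    @property
    def measure_ids(self) -> tuple[str, ...]:
        return tuple(m.measure_id for m in self.measures)

    def measure(self, measure_id: str) -> MeasureSpec:
        for m in self.measures:
            if m.measure_id == measure_id:
                return m
        raise KeyError(f"measure {measure_id!r} not in battery")

    def domain_measures(self, domain: str) -> tuple[MeasureSpec, ...]:
        return tuple(m for m in self.measures if m.domain == domain)


@dataclass(frozen=True)
class NormEntry:
    """Normative mean/SD for one measure over an inclusive age band."""

    measure_id: str
    age_min: float
    age_max: float
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if not self.sd > 0:
            raise ValueError(
                f"sd must be strictly positive (measure {self.measure_id!r}, "
                f"band {self.age_min}-{self.age_max}, sd={self.sd})"
            )
        if self.age_min > self.age_max:
            raise ValueError(
                f"age_min > age_max for measure {self.measure_id!r} "
                f"({self.age_min} > {self.age_max})"
            )

    def covers(self, age: float) -> bool:
        return self.age_min <= age <= self.age_max


class NormTable:
    """Age-banded normative means and SDs for a set of measures.

    Bands for each measure must be non-overlapping.  Lookups are by
    (measure_id, age) with inclusive band edges.
    """

    def __init__(self, entries: Iterable[NormEntry]):
        self.entries: tuple[NormEntry, ...] = tuple(entries)
        self._by_measure: dict[str, list[NormEntry]] = {}
        for e in self.entries:
            self._by_measure.setdefault(e.measure_id, []).append(e)
        for mid, bands in self._by_measure.items():
            bands.sort(key=lambda e: e.age_min)
            for a, b in zip(bands, bands[1:]):
                if b.age_min <= a.age_max:
                    raise ValueError(
                        f"overlapping age bands for measure {mid!r}: "
                        f"{a.age_min}-{a.age_max} and {b.age_min}-{b.age_max}"
                    )

    @property
    def measure_ids(self) -> tuple[str, ...]:
        return tuple(self._by_measure)

    def lookup(self, measure_id: str, age: float) -> NormEntry:
        """Find the band covering ``age``.

        Ages are matched in completed years (floored), the usual
        convention for integer-banded norms, so age 64.4 falls in a
        55-64 band.
        """
        bands = self._by_measure.get(measure_id)
        if bands is None:
            raise NormCoverageError(f"no norms for measure {measure_id!r}")
        whole = math.floor(age)
        for band in bands:
            if band.covers(whole):
                return band
        raise NormCoverageError(
            f"no norm band covers age {age} for measure {measure_id!r} "
            f"(available: {[(b.age_min, b.age_max) for b in bands]})"
        )

    def age_range(self, measure_id: str) -> tuple[float, float]:
        bands = self._by_measure[measure_id]
        return bands[0].age_min, bands[-1].age_max

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "measure_id": e.measure_id,
                    "age_min": e.age_min,
                    "age_max": e.age_max,
                    "mean": e.mean,
                    "sd": e.sd,
                }
                for e in self.entries
            ]
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class RawScoreRecord:
    """A single raw test score for one subject.

    ``raw`` may be None (explicitly missing); NaN is normalized to None.
    """

    subject_id: str
    measure_id: str
    raw: float | None

    def __post_init__(self) -> None:
        raw = self.raw
        if raw is not None:
            if isinstance(raw, float) and math.isnan(raw):
                object.__setattr__(self, "raw", None)
            elif not math.isfinite(raw):
                raise ValueError(
                    f"raw score must be finite or missing "
                    f"(subject {self.subject_id!r}, measure {self.measure_id!r})"
                )


@dataclass
class ZProfile:
    """Per-subject standardized scores and impairment flags.

    ``impaired[m]`` holds exactly when ``z[m] <= threshold``; measures
    with missing raw scores appear in neither map.
    """

    subject_id: str
    z: dict[str, float]
    impaired: dict[str, bool]
    threshold: float = DEFAULT_THRESHOLD

    def __post_init__(self) -> None:
        for m, zv in self.z.items():
            expect = zv <= self.threshold
            if self.impaired.get(m) != expect:
                raise ValueError(
                    f"impaired flag inconsistent with z for measure {m!r} "
                    f"(z={zv}, threshold={self.threshold})"
                )
        extra = set(self.impaired) - set(self.z)
        if extra:
            raise ValueError(f"impaired flags without z values: {sorted(extra)}")


# ---------------------------------------------------------------------------
# Default battery (CVLT-II, TMT, D-KEFS, WAIS-III, Boston Naming)

_DEFAULT_MEASURES = (
    MeasureSpec("cvlt_total", "CVLT-II Trials 1-5 total recall", "episodic_memory", "higher_better"),
    MeasureSpec("cvlt_ldfr", "CVLT-II long-delay free recall", "episodic_memory", "higher_better"),
    MeasureSpec("tmt_b", "Trail Making Test Part B (s)", "executive_function", "lower_better"),
    MeasureSpec("cw_inhibition", "D-KEFS Color-Word inhibition (s)", "executive_function", "lower_better"),
    MeasureSpec("digit_span", "WAIS-III Digit Span total", "attention", "higher_better"),
    MeasureSpec("tmt_a", "Trail Making Test Part A (s)", "attention", "lower_better"),
    MeasureSpec("boston_naming", "Boston Naming Test total correct", "language", "higher_better"),
    MeasureSpec("block_design", "WAIS-III Block Design total", "visuospatial", "higher_better"),
)


def default_battery() -> BatterySpec:
    """The default 8-measure, 5-domain battery."""
    return BatterySpec(_DEFAULT_MEASURES)


def load_norms(path) -> NormTable:
    """Load a norm table from CSV.

    Expected header: ``measure_id,age_min,age_max,mean,sd`` (UTF-8, dot
    decimal).  Raises :class:`NormFormatError` on missing columns and
    ``ValueError`` on invalid rows (sd <= 0, inverted or overlapping bands).
    """
    df = pd.read_csv(path)
    required = ["measure_id", "age_min", "age_max", "mean", "sd"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise NormFormatError(
            f"norm table {path!r} is missing required columns {missing}; "
            f"found {list(df.columns)}"
        )
    entries = [
        NormEntry(
            measure_id=str(row.measure_id),
            age_min=float(row.age_min),
            age_max=float(row.age_max),
            mean=float(row.mean),
            sd=float(row.sd),
        )
        for row in df.itertuples(index=False)
    ]
    return NormTable(entries)


def default_norms() -> NormTable:
    """The packaged synthetic default norm table.

    Age bands of width 10 covering ages 35-84 for every default-battery
    measure, with plausible means/SDs per measure.  These are synthetic
    stand-in norms shipped so the pipeline runs end-to-end; published
    norms can be substituted through the same CSV contract.
    """
    ref = resources.files("gwmci").joinpath("data/default_norms.csv")
    with resources.as_file(ref) as path:
        return load_norms(path)


# ---------------------------------------------------------------------------
# Standardization


def zscore(raw: float, spec: MeasureSpec, age: float, norms: NormTable) -> float:
    """Age-adjusted z-score with worse-is-more-negative orientation."""
    band = norms.lookup(spec.measure_id, age)
    if spec.direction == "higher_better":
        return (raw - band.mean) / band.sd
    return (band.mean - raw) / band.sd


def raw_from_z(z: float, spec: MeasureSpec, age: float, norms: NormTable) -> float:
    """Invert :func:`zscore`: the raw score whose z-score equals ``z``."""
    band = norms.lookup(spec.measure_id, age)
    if spec.direction == "higher_better":
        return band.mean + z * band.sd
    return band.mean - z * band.sd


def impairment_flags(
    scores: Iterable[RawScoreRecord] | Mapping[str, float | None],
    battery: BatterySpec,
    norms: NormTable,
    age: float,
    threshold: float = DEFAULT_THRESHOLD,
    subject_id: str | None = None,
) -> ZProfile:
    """Standardize one subject's raw scores and flag impairments.

    ``scores`` is either a mapping ``measure_id -> raw`` or an iterable of
    :class:`RawScoreRecord` for a single subject.  Measures absent from
    ``scores`` (or with missing raw values) carry neither a z value nor an
    impaired flag.  A z exactly at the threshold counts as impaired.
    """
    if not threshold < 0:
        raise ValueError(f"impairment threshold must be negative, got {threshold}")

    if isinstance(scores, Mapping):
        raw_map = dict(scores)
        sid = subject_id if subject_id is not None else "subject"
    else:
        records = list(scores)
        sids = {r.subject_id for r in records}
        if len(sids) > 1:
            raise ValueError(f"scores mix multiple subjects: {sorted(sids)}")
        raw_map = {r.measure_id: r.raw for r in records}
        sid = records[0].subject_id if records else (subject_id or "subject")

    unknown = set(raw_map) - set(battery.measure_ids)
    if unknown:
        raise KeyError(f"scores reference measures not in battery: {sorted(unknown)}")

    z: dict[str, float] = {}
    impaired: dict[str, bool] = {}
    for spec in battery:
        raw = raw_map.get(spec.measure_id)
        if raw is None or (isinstance(raw, float) and math.isnan(raw)):
            continue
        zv = zscore(float(raw), spec, age, norms)
        z[spec.measure_id] = zv
        impaired[spec.measure_id] = zv <= threshold
    return ZProfile(subject_id=sid, z=z, impaired=impaired, threshold=threshold)
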