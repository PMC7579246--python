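"""End-to-end orchestration: classify -> tabulate -> test -> adjust -> report.

Consumes a wide per-subject cohort CSV (raw test scores plus
demographics, clinical flags, exposures and imaging scalars, as written
by :func:`gwmci.cohort.cohort_to_frame`) and a norm-table CSV, and
produces labelled subjects, the full battery of group comparisons
(chi-square / ANOVA for demographics, covariate-adjusted group tests
with planned contrasts for imaging), the hierarchical and stepwise
regressions, and the correlated-endpoints significance ledger for the
two adjustment families (5 cortical regions; 15 deployment exposures).

Each analysis runs independently; a failure in one is recorded in the
report rather than aborting the rest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import stats as st
from .battery import BatterySpec, NormTable, default_battery, default_norms, impairment_flags, load_norms
from .classifier import (
    CN,
    INTERMEDIATE,
    MCI,
    DEFAULT_MIN_MEASURES_PRESENT,
    CohortClassification,
    classify_cohort,
)
from .cohort import EXPOSURE_CATEGORIES, EXPOSURE_ITEMS, THICKNESS_REGIONS

__all__ = [
    "AnalysisConfig",
    "ReportTables",
    "profiles_from_frame",
    "run_classify",
    "run_analysis",
    "write_report",
]

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1

GROUP_ORDER = (MCI, INTERMEDIATE, CN)

#: Chi-square comparisons in the demographics table: column -> kind.
_DEMOGRAPHIC_CATEGORICALS = (
    "male",
    "race",
    "rank_enlisted",
    "service_type",
    "branch",
    "ptsd_current",
    "mdd_current",
    "etoh_history",
    "substance_history",
    "psychotropics",
    "tbi_category",
    "apoe_genotype",
    "cmi_mild_moderate",
    "cmi_severe",
    "kansas_gwi",
    "kansas_exclusionary",
    "khamisiyah_exposed",
)
_DEMOGRAPHIC_CONTINUOUS = ("age", "education_years")

_IMAGING_MEASURES = ("hippocampus_cc",) + tuple(
    f"thickness_{r}" for r in THICKNESS_REGIONS
)

#: ANCOVA covariate set for imaging group tests; ICV only for volume.
_IMAGING_COVARIATES = (
    "age",
    "male",
    "education_years",
    "rank_enlisted",
    "cmi_case",
    "kansas_exclusionary",
    "khamisiyah_exposed",
    "ptsd_current",
    "mdd_current",
    "etoh_history",
    "apoe_e4",
    "apoe_e2",
)


@dataclass
class AnalysisConfig:
    """Pipeline configuration, loadable from a versioned JSON file."""

    cohort_csv: str | None = None
    norms_csv: str | None = None
    output_dir: str = "gwmci_out"
    impairment_threshold: float = -1.0
    min_measures_present: int = DEFAULT_MIN_MEASURES_PRESENT
    alpha_family: float = 0.05
    p_enter: float = 0.05
    p_remove: float = 0.10
    seed: int = 0
    schema_version: int = SCHEMA_VERSION

    @classmethod
    def from_json(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            payload = json.load(fh)
        version = payload.pop("schema_version", SCHEMA_VERSION)
        if version != SCHEMA_VERSION:
            raise ValueError(
                f"config schema_version {version} not supported (expected {SCHEMA_VERSION})"
            )
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


@dataclass
class ReportTables:
    """All pipeline outputs, serializable to tidy CSV plus a text report."""

    counts: dict[str, int]
    intermediate_breakdown: dict[int, int]
    labels: pd.DataFrame
    demographics: pd.DataFrame
    imaging: pd.DataFrame
    contrasts: pd.DataFrame
    exposures: pd.DataFrame
    adjusted_alphas: pd.DataFrame
    regressions: pd.DataFrame
    errors: dict[str, str] = field(default_factory=dict)


def profiles_from_frame(
    df: pd.DataFrame,
    battery: BatterySpec,
    norms: NormTable,
    threshold: float = -1.0,
):
    """Build per-subject z-profiles from a wide cohort frame."""
    missing = [c for c in ("subject_id", "age") if c not in df.columns]
    missing += [m for m in battery.measure_ids if m not in df.columns]
    if missing:
        raise KeyError(f"cohort frame is missing columns: {missing}")
    profiles = []
    for row in df.itertuples(index=False):
        scores = {m: getattr(row, m) for m in battery.measure_ids}
        profiles.append(
            impairment_flags(
                scores,
                battery,
                norms,
                age=float(row.age),
                threshold=threshold,
                subject_id=str(row.subject_id),
            )
        )
    return profiles


def run_classify(
    df: pd.DataFrame,
    battery: BatterySpec | None = None,
    norms: NormTable | None = None,
    threshold: float = -1.0,
    min_measures_present: int = DEFAULT_MIN_MEASURES_PRESENT,
) -> CohortClassification:
    """Standardize, flag and classify every subject in a cohort frame."""
    if len(df) == 0:
        raise ValueError("empty cohort")
    battery = battery if battery is not None else default_battery()
    norms = norms if norms is not None else default_norms()
    profiles = profiles_from_frame(df, battery, norms, threshold)
    return classify_cohort(profiles, battery, min_measures_present)


def _exposure_codes(df: pd.DataFrame, item: str) -> pd.Series:
    col = df[f"exposure_{item}"]
    mapping = {c: i for i, c in enumerate(EXPOSURE_CATEGORIES)}
    return col.map(mapping)


def run_analysis(
    df: pd.DataFrame,
    config: AnalysisConfig | None = None,
    battery: BatterySpec | None = None,
    norms: NormTable | None = None,
) -> ReportTables:
    """Run the full reported analysis set on a cohort frame."""
    config = config if config is not None else AnalysisConfig()
    battery = battery if battery is not None else default_battery()
    norms = norms if norms is not None else default_norms()
    errors: dict[str, str] = {}

    clf = run_classify(
        df, battery, norms, config.impairment_threshold, config.min_measures_present
    )
    labels_df = clf.to_frame()
    df = df.merge(labels_df[["subject_id", "label"]], on="subject_id", how="left")
    df["mci_status"] = (df["label"] == MCI).astype(float)
    df["race_nonwhite"] = (df["race"] != "caucasian").astype(float)
    df["cmi_case"] = ((df["cmi_mild_moderate"] == 1) | (df["cmi_severe"] == 1)).astype(float)

    group = df["label"]

    # ---- demographics: chi-square / ANOVA per variable -------------------
    demo_rows = []
    for var in _DEMOGRAPHIC_CONTINUOUS:
        try:
            res = st.one_way_anova(df[var], group)
            demo_rows.append(
                {"variable": var, "test": "anova", "statistic": res.F,
                 "df": f"{res.df_between},{res.df_within}", "p": res.p}
            )
        except Exception as exc:  # recorded, not fatal
            errors[f"demographics:{var}"] = str(exc)
    for var in _DEMOGRAPHIC_CATEGORICALS:
        if var not in df.columns:
            continue
        try:
            tab = st.contingency(group, df[var], name=var)
            res = st.chi_square(tab)
            demo_rows.append(
                {"variable": var, "test": "chi_square", "statistic": res.statistic,
                 "df": str(res.df), "p": res.p}
            )
        except Exception as exc:
            errors[f"demographics:{var}"] = str(exc)
    demographics = pd.DataFrame(demo_rows, columns=["variable", "test", "statistic", "df", "p"])

    # ---- adjusted alpha families -----------------------------------------
    alpha_rows = []
    thick_cols = [f"thickness_{r}" for r in THICKNESS_REGIONS]
    r_bar_imaging = st.average_intercorrelation(df[thick_cols])
    adj_imaging = st.effective_alpha(len(thick_cols), max(r_bar_imaging, 0.0), config.alpha_family)
    alpha_rows.append(
        {"family": "cortical_regions", "n_tests": adj_imaging.n_tests,
         "r_bar": adj_imaging.r_bar, "m_eff": adj_imaging.m_eff,
         "alpha_adj": adj_imaging.alpha_adj}
    )
    expo_codes = pd.DataFrame({item: _exposure_codes(df, item) for item in EXPOSURE_ITEMS})
    r_bar_expo = st.average_intercorrelation(expo_codes)
    adj_expo = st.effective_alpha(len(EXPOSURE_ITEMS), max(r_bar_expo, 0.0), config.alpha_family)
    alpha_rows.append(
        {"family": "exposures", "n_tests": adj_expo.n_tests,
         "r_bar": adj_expo.r_bar, "m_eff": adj_expo.m_eff,
         "alpha_adj": adj_expo.alpha_adj}
    )
    adjusted_alphas = pd.DataFrame(alpha_rows)

    # ---- imaging: ANCOVA with planned contrasts --------------------------
    imaging_rows, contrast_rows = [], []
    for measure in _IMAGING_MEASURES:
        covs = list(_IMAGING_COVARIATES)
        if measure == "hippocampus_cc":
            covs = ["icv"] + covs
        try:
            anova, fit = st.ancova_group_test(
                df[measure], group, df[covs], reference=CN
            )
            alpha = adj_imaging.alpha_adj if measure.startswith("thickness") else config.alpha_family
            imaging_rows.append(
                {"measure": measure, "F": anova.F,
                 "df": f"{anova.df_between},{anova.df_within}", "p": anova.p,
                 "alpha": alpha, "significant": anova.p < alpha}
            )
            for c in st.planned_contrasts(fit, [(MCI, CN), (MCI, INTERMEDIATE), (INTERMEDIATE, CN)]):
                contrast_rows.append(
                    {"measure": measure, "pair": f"{c.pair[0]}-{c.pair[1]}",
                     "estimate": c.estimate, "t": c.t, "p": c.p}
                )
        except Exception as exc:
            errors[f"imaging:{measure}"] = str(exc)
    imaging = pd.DataFrame(
        imaging_rows, columns=["measure", "F", "df", "p", "alpha", "significant"]
    )
    contrasts = pd.DataFrame(
        contrast_rows, columns=["measure", "pair", "estimate", "t", "p"]
    )

    # ---- exposures: chi-square per item against the exposure alpha -------
    expo_rows = []
    for item in EXPOSURE_ITEMS:
        try:
            tab = st.contingency(group, df[f"exposure_{item}"], name=item)
            res = st.chi_square(tab)
            expo_rows.append(
                {"exposure": item, "statistic": res.statistic, "df": res.df,
                 "p": res.p, "alpha_adj": adj_expo.alpha_adj,
                 "significant": res.p < adj_expo.alpha_adj}
            )
        except Exception as exc:
            errors[f"exposure:{item}"] = str(exc)
    exposures = pd.DataFrame(
        expo_rows, columns=["exposure", "statistic", "df", "p", "alpha_adj", "significant"]
    )

    # ---- hierarchical and stepwise regressions ---------------------------
    reg_rows = []

    def add_steps(analysis: str, steps):
        for s in steps:
            for term in ("const", *s.fit.terms):
                if term not in s.fit.coefficients:
                    continue
                reg_rows.append(
                    {"analysis": analysis, "step": s.step_index, "term": term,
                     "estimate": s.fit.coefficients[term],
                     "std_beta": s.fit.std_beta.get(term, np.nan),
                     "t": s.fit.t[term], "df": s.fit.residual_df,
                     "p": s.fit.p[term], "r2": s.fit.r2, "delta_r2": s.delta_r2}
                )

    data = df.copy()
    data["male"] = data["male"].astype(float)
    try:
        steps = st.hierarchical_regression(
            data["mci_status"],
            [["race_nonwhite", "rank_enlisted"],
             ["ptsd_current", "mdd_current", "etoh_history"]],
            data,
        )
        add_steps("mci_status~demographics+clinical", steps)
    except Exception as exc:
        errors["regression:mci_status"] = str(exc)

    base_covs = ["age", "male", "education_years", "ptsd_current", "mdd_current",
                 "etoh_history", "apoe_e4", "apoe_e2", "cmi_case", "khamisiyah_exposed"]
    try:
        steps = st.hierarchical_regression(
            data["hippocampus_cc"], [["icv"] + base_covs, ["mci_status"]], data
        )
        add_steps("hippocampus~covariates+mci", steps)
    except Exception as exc:
        errors["regression:hippocampus"] = str(exc)
    try:
        steps = st.hierarchical_regression(
            data["thickness_parietal"], [base_covs, ["mci_status"]], data
        )
        add_steps("parietal~covariates+mci", steps)
    except Exception as exc:
        errors["regression:parietal"] = str(exc)

    try:
        data["dead_animals_code"] = _exposure_codes(df, "dead_animals").astype(float)
        data["living_area_sprayed_code"] = _exposure_codes(df, "living_area_sprayed").astype(float)
        final, order = st.stepwise_regression(
            data["mci_status"],
            ["race_nonwhite", "rank_enlisted", "ptsd_current", "mdd_current",
             "etoh_history", "cmi_case", "dead_animals_code", "living_area_sprayed_code"],
            data,
            p_enter=config.p_enter,
            p_remove=config.p_remove,
        )
        if final is not None:
            for term in ("const", *final.terms):
                reg_rows.append(
                    {"analysis": "stepwise:mci_status", "step": len(order),
                     "term": term, "estimate": final.coefficients[term],
                     "std_beta": final.std_beta.get(term, np.nan),
                     "t": final.t[term], "df": final.residual_df,
                     "p": final.p[term], "r2": final.r2, "delta_r2": np.nan}
                )
    except Exception as exc:
        errors["regression:stepwise"] = str(exc)

    regressions = pd.DataFrame(
        reg_rows,
        columns=["analysis", "step", "term", "estimate", "std_beta", "t", "df", "p", "r2", "delta_r2"],
    )

    for key, msg in errors.items():
        logger.warning("analysis %s failed: %s", key, msg)

    return ReportTables(
        counts=clf.counts,
        intermediate_breakdown=clf.intermediate_breakdown,
        labels=labels_df,
        demographics=demographics,
        imaging=imaging,
        contrasts=contrasts,
        exposures=exposures,
        adjusted_alphas=adjusted_alphas,
        regressions=regressions,
        errors=errors,
    )


def _render_text_report(report: ReportTables) -> str:
    lines = ["gwmci analysis report", "=" * 60, ""]
    n = sum(report.counts.values())
    lines.append("Cognitive status counts")
    for label in (*GROUP_ORDER, "UNCLASSIFIABLE"):
        c = report.counts.get(label, 0)
        if c or label in GROUP_ORDER:
            pct = 100 * c / n if n else 0.0
            lines.append(f"  {label:<14} {c:>4}  ({pct:.0f}%)")
    lines.append("  intermediate by touched domains: "
                 + ", ".join(f"{k}->{v}" for k, v in sorted(report.intermediate_breakdown.items())))
    lines.append("")

    lines.append("Adjusted significance thresholds (correlated endpoints)")
    for row in report.adjusted_alphas.itertuples(index=False):
        lines.append(
            f"  {row.family:<18} n={row.n_tests:<3} r_bar={row.r_bar:.2f} "
            f"m_eff={row.m_eff:.2f} alpha_adj={row.alpha_adj:.4f}"
        )
    lines.append("")

    lines.append("Group comparisons (demographic / clinical)")
    for row in report.demographics.itertuples(index=False):
        stat = "F" if row.test == "anova" else "chi2"
        lines.append(f"  {row.variable:<24} {stat}={row.statistic:7.2f}  df={row.df:<8} p={row.p:.4f}")
    lines.append("")

    lines.append("Imaging group tests (covariate-adjusted)")
    for row in report.imaging.itertuples(index=False):
        mark = " *" if row.significant else ""
        lines.append(f"  {row.measure:<22} F={row.F:6.2f}  df={row.df:<8} p={row.p:.4f}{mark}")
    lines.append("")

    lines.append("Deployment exposures (chi-square vs adjusted alpha)")
    for row in report.exposures.itertuples(index=False):
        mark = " *" if row.significant else ""
        lines.append(f"  {row.exposure:<26} chi2={row.statistic:6.2f}  p={row.p:.4f}{mark}")
    lines.append("")

    if report.errors:
        lines.append("Analyses with errors")
        for key, msg in report.errors.items():
            lines.append(f"  {key}: {msg}")
        lines.append("")
    return "\n".join(lines) + "\n"


def write_report(
    report: ReportTables,
    out_dir,
    config: AnalysisConfig | None = None,
) -> dict[str, str]:
    """Serialize all report tables; returns a manifest of written files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, str] = {}

    def save(name: str, frame: pd.DataFrame):
        path = out / name
        frame.to_csv(path, index=False)
        written[name] = hashlib.sha256(path.read_bytes()).hexdigest()

    save("labels.csv", report.labels)
    save("demographics.csv", report.demographics)
    save("imaging.csv", report.imaging)
    save("contrasts.csv", report.contrasts)
    save("exposures.csv", report.exposures)
    save("adjusted_alphas.csv", report.adjusted_alphas)
    save("regressions.csv", report.regressions)

    text = _render_text_report(report)
    (out / "report.txt").write_text(text)
    written["report.txt"] = hashlib.sha256(text.encode()).hexdigest()

    manifest = {
        "schema_version": SCHEMA_VERSION,
        "counts": report.counts,
        "intermediate_breakdown": {str(k): v for k, v in report.intermediate_breakdown.items()},
        "files": written,
        "errors": report.errors,
    }
    if config is not None:
        manifest["config"] = dataclasses.asdict(config)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return written
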