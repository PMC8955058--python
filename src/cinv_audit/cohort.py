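"""First-course cohort construction from registry + claims + procedures.

Selects the analyzable cohort: adults (≥20 y at diagnosis) diagnosed in the
configured year who started chemotherapy, keeping only the first course — the
earliest chemotherapy administration on/after diagnosis plus every chemotherapy
claim in the 8-day inclusive window that starts there. Patients are excluded
when the course contains interferon-alpha, when chemotherapy shares a date with
surgery or thoracic/abdominal/pericardial drainage (the drug may have been
applied topically), when any course drug is given arterially, or when a
haematopoietic stem cell transplantation follows course chemotherapy within
three weeks.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import pandas as pd

from .risk import Route

logger = logging.getLogger(__name__)

CANCER_TYPES = (
    "non_small_cell_lung", "colorectal", "breast", "gastric",
    "malignant_lymphoma", "pancreatic", "oesophageal", "small_cell_lung",
    "other",
)
STAGES = ("0", "I", "II", "III", "IV", "unknown")
PROCEDURE_KINDS = (
    "surgery", "thoracic_drainage", "abdominal_drainage",
    "pericardial_drainage", "hsct",
)
_DRAINAGE_OR_SURGERY = frozenset(PROCEDURE_KINDS[:4])


class ExclusionReason(str, Enum):
    INTERFERON_ALPHA = "interferon_alpha"
    SAME_DAY_SURGERY_OR_DRAINAGE = "same_day_surgery_or_drainage"
    ARTERIAL_ROUTE = "arterial_route"
    HSCT_WITHIN_3_WEEKS = "hsct_within_3_weeks"
    UNDER_20 = "under_20"
    NO_CHEMO = "no_chemo"


class RouteGroup(str, Enum):
    INTRAVENOUS = "intravenous_group"
    ORAL = "oral_group"


@dataclass
class AuditConfig:
    """Knobs of the selection and attribution procedure, with study defaults."""

    diagnosis_year: Optional[int] = 2016
    window_days: int = 8                 # first-course window, inclusive of start
    hsct_lookout_days: int = 21          # HSCT within this many days after course chemo
    hsct_symmetric: bool = False         # also look 21 d before course chemo
    oral_lookback_days: int = 30         # oral antiemetic prophylaxis lookback
    bsa_m2: float = 1.48
    guideline: str = "JSCO"
    ci_method: str = "clopper_pearson"
    escalation_categories: tuple[str, ...] = ("high",)
    adjuvant_heuristic: bool = False     # infer adjuvant flag from resection date
    interferon_drug_id: str = "interferon-alpha"


@dataclass
class CourseWindow:
    """The first chemotherapy course: start date plus the 8-day window events."""

    patient_id: str
    start_date: dt.date
    events: pd.DataFrame            # chemotherapy claims inside the window
    window_days: int = 8

    @property
    def end_date(self) -> dt.date:
        return self.start_date + dt.timedelta(days=self.window_days - 1)


@dataclass
class ExclusionResult:
    reasons: frozenset[ExclusionReason]

    @property
    def excluded(self) -> bool:
        return bool(self.reasons)


REGISTRY_COLUMNS = ["patient_id", "sex", "age_at_dx", "cancer_type", "dx_date",
                    "clinical_stage", "pathological_stage", "resection_date",
                    "adjuvant_flag"]
CLAIMS_COLUMNS = ["patient_id", "date", "drug_id", "drug_class", "route", "dose_mg"]
PROCEDURE_COLUMNS = ["patient_id", "date", "kind"]


def _as_date(value) -> Optional[dt.date]:
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        return None
    if isinstance(value, dt.date) and not isinstance(value, dt.datetime):
        return value
    return pd.Timestamp(value).date()


def identify_first_course(chemo_events: pd.DataFrame, dx_date: dt.date,
                          window_days: int = 8) -> Optional[CourseWindow]:
    """Build the first-course window from one patient's chemotherapy claims.

    The window spans ``window_days`` calendar days inclusive of the start
    (day 1 = start, day 8 = start + 7). Returns None when the patient has no
    chemotherapy on/after diagnosis (the ``no_chemo`` case, logged upstream).
    """
    if chemo_events.empty:
        return None
    eligible = chemo_events[chemo_events["date"] >= dx_date]
    if eligible.empty:
        return None
    start = eligible["date"].min()
    end = start + dt.timedelta(days=window_days - 1)
    in_window = eligible[(eligible["date"] >= start) & (eligible["date"] <= end)]
    return CourseWindow(
        patient_id=str(chemo_events["patient_id"].iloc[0]),
        start_date=start,
        events=in_window.sort_values(["date", "drug_id"]).reset_index(drop=True),
        window_days=window_days,
    )


def apply_exclusions(record: pd.Series, course: CourseWindow,
                     procedures: pd.DataFrame, all_events: pd.DataFrame,
                     config: Optional[AuditConfig] = None) -> ExclusionResult:
    """Evaluate every exclusion criterion for one retained-candidate patient."""
    config = config or AuditConfig()
    reasons: set[ExclusionReason] = set()
    if record["age_at_dx"] < 20:
        reasons.add(ExclusionReason.UNDER_20)
    if (course.events["drug_id"] == config.interferon_drug_id).any():
        reasons.add(ExclusionReason.INTERFERON_ALPHA)
    if (course.events["route"] == Route.ARTERIAL.value).any():
        reasons.add(ExclusionReason.ARTERIAL_ROUTE)
    course_dates = set(course.events["date"])
    if not procedures.empty:
        proc = procedures
        surg_dates = set(proc.loc[proc["kind"].isin(_DRAINAGE_OR_SURGERY), "date"])
        if course_dates & surg_dates:
            reasons.add(ExclusionReason.SAME_DAY_SURGERY_OR_DRAINAGE)
        lookout = dt.timedelta(days=config.hsct_lookout_days)
        for hsct_date in proc.loc[proc["kind"] == "hsct", "date"]:
            for chemo_date in course_dates:
                delta = hsct_date - chemo_date
                if dt.timedelta(0) <= delta <= lookout or (
                        config.hsct_symmetric and dt.timedelta(0) <= -delta <= lookout):
                    reasons.add(ExclusionReason.HSCT_WITHIN_3_WEEKS)
    return ExclusionResult(frozenset(reasons))


def assign_route_group(course: CourseWindow) -> RouteGroup:
    """Intravenous group if any course drug is IV, oral group otherwise."""
    if course.events.empty:
        raise ValueError("route group undefined for an empty course")
    if (course.events["route"] == Route.IV.value).any():
        return RouteGroup.INTRAVENOUS
    return RouteGroup.ORAL


def combine_stage(clinical_stage: str, pathological_stage: str,
                  resection_date: Optional[dt.date]) -> str:
    """Combined stage: pathological when resected and known, else clinical."""
    if clinical_stage not in STAGES or pathological_stage not in STAGES:
        raise ValueError(
            f"invalid stage: {clinical_stage!r} / {pathological_stage!r}")
    if resection_date is not None and pathological_stage != "unknown":
        return pathological_stage
    return clinical_stage


@dataclass
class CohortMember:
    patient_id: str
    record: pd.Series
    course: CourseWindow
    route_group: RouteGroup
    combined_stage: str
    adjuvant: Optional[bool]
    antiemetic_events: Optional[pd.DataFrame] = None   # attached downstream


@dataclass
class Cohort:
    members: list[CohortMember]
    flow_log: dict

    def __len__(self) -> int:
        return len(self.members)


def _validate_frame(df: pd.DataFrame, columns: list[str], name: str) -> pd.DataFrame:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{name} is missing columns: {missing}")
    return df


def load_inputs(registry_path, claims_path, procedures_path):
    """Read the three delimited inputs with ISO-8601 dates."""
    registry = pd.read_csv(registry_path, dtype={"patient_id": str})
    claims = pd.read_csv(claims_path, dtype={"patient_id": str})
    procedures = pd.read_csv(procedures_path, dtype={"patient_id": str})
    return registry, claims, procedures


def build_cohort(registry: pd.DataFrame, claims: pd.DataFrame,
                 procedures: pd.DataFrame,
                 config: Optional[AuditConfig] = None) -> Cohort:
    """Run the full selection and return retained members plus a flow log.

    The flow log counts patients at every step: registry input, the
    diagnosis-year filter, chemotherapy recipients, each exclusion reason (a
    patient may carry several; unique exclusions are counted once) and the
    final N. Shuffling input row order never changes the result.
    """
    config = config or AuditConfig()
    registry = _validate_frame(registry.copy(), REGISTRY_COLUMNS[:7], "registry")
    claims = _validate_frame(claims.copy(), CLAIMS_COLUMNS[:5], "claims")
    procedures = _validate_frame(procedures.copy(), PROCEDURE_COLUMNS, "procedures")

    if registry["patient_id"].duplicated().any():
        dupes = registry.loc[registry["patient_id"].duplicated(), "patient_id"]
        raise ValueError(f"duplicate patient_id in registry: {sorted(set(dupes))[:5]}")
    bad = procedures.loc[~procedures["kind"].isin(PROCEDURE_KINDS), "kind"]
    if len(bad):
        raise ValueError(f"invalid procedure kind(s): {sorted(set(bad))[:5]}")

    known = set(registry["patient_id"])
    orphan = ~claims["patient_id"].isin(known)
    if orphan.any():
        logger.warning("dropping %d claims rows with unknown patient_id", orphan.sum())
        claims = claims[~orphan]

    for frame, cols in ((registry, ["dx_date", "resection_date"]),
                        (claims, ["date"]), (procedures, ["date"])):
        for col in cols:
            if col in frame.columns:
                frame[col] = frame[col].map(_as_date)
    if "dose_mg" not in claims.columns:
        claims["dose_mg"] = float("nan")
    if "adjuvant_flag" not in registry.columns:
        registry["adjuvant_flag"] = None

    flow: dict = {"input": int(len(registry))}
    if config.diagnosis_year is not None:
        in_year = registry["dx_date"].map(
            lambda d: d is not None and d.year == config.diagnosis_year)
        registry = registry[in_year.astype(bool)]
    flow["diagnosis_year"] = int(len(registry))

    registry = registry.sort_values("patient_id")
    chemo = claims[claims["drug_class"] == "chemotherapy"]
    chemo_by_patient = dict(tuple(chemo.groupby("patient_id", sort=False)))
    proc_by_patient = dict(tuple(procedures.groupby("patient_id", sort=False)))
    empty_proc = procedures.iloc[0:0]

    members: list[CohortMember] = []
    reason_counts = {r.value: 0 for r in ExclusionReason}
    n_chemo = 0
    n_excluded_unique = 0
    for _, record in registry.iterrows():
        pid = record["patient_id"]
        course = identify_first_course(
            chemo_by_patient.get(pid, chemo.iloc[0:0]), record["dx_date"],
            config.window_days)
        if course is None:
            reason_counts[ExclusionReason.NO_CHEMO.value] += 1
            continue
        n_chemo += 1
        result = apply_exclusions(record, course,
                                  proc_by_patient.get(pid, empty_proc),
                                  claims, config)
        if result.excluded:
            n_excluded_unique += 1
            for r in result.reasons:
                reason_counts[r.value] += 1
            continue
        adjuvant = record.get("adjuvant_flag")
        if pd.isna(adjuvant):
            adjuvant = None
        if adjuvant is None and config.adjuvant_heuristic:
            resection = record.get("resection_date")
            adjuvant = (resection is not None and
                        dt.timedelta(0) <= (course.start_date - resection)
                        <= dt.timedelta(days=180))
        members.append(CohortMember(
            patient_id=pid,
            record=record,
            course=course,
            route_group=assign_route_group(course),
            combined_stage=combine_stage(str(record["clinical_stage"]),
                                         str(record["pathological_stage"]),
                                         record.get("resection_date")),
            adjuvant=None if adjuvant is None else bool(adjuvant),
        ))
    flow["chemo_recipients"] = n_chemo
    flow["exclusion_reasons"] = reason_counts
    flow["excluded_unique"] = n_excluded_unique
    flow["final"] = len(members)
    return Cohort(members, flow)
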