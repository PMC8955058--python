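"""End-to-end audit pipeline: inputs -> cohort -> risk -> prophylaxis -> tables.

`run_audit` wires the stages together and writes one delimited file per output
table plus a machine-readable flow log and a run manifest (configuration echo
and rule-table version). `EmesisAudit` is a thin object wrapper over the same
pipeline for interactive use.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import tables as tab
from .cohort import (AuditConfig, Cohort, CohortMember, build_cohort,
                     load_inputs)
from .prophylaxis import ANTIEMETIC_CLASSES, ProphylaxisProfile, attribute_prophylaxis
from .regimen import RiskAssignment, assemble_regimen, classify_regimen
from .risk import Guideline, load_guideline_table

logger = logging.getLogger(__name__)


@dataclass
class AuditResult:
    """Everything the audit produces, as in-memory DataFrames."""

    config: AuditConfig
    flow_log: dict
    cohort_frame: pd.DataFrame         # one row per retained patient
    assignments: pd.DataFrame          # patient_id, regimen, risk category, ...
    profiles: pd.DataFrame             # patient_id, prophylaxis category, ...
    characteristics: pd.DataFrame = field(default=None)
    risk_distribution: pd.DataFrame = field(default=None)
    top_regimens: pd.DataFrame = field(default=None)
    prophylaxis: pd.DataFrame = field(default=None)
    per_cancer: pd.DataFrame = field(default=None)
    prophylaxis_per_cancer: pd.DataFrame = field(default=None)
    rule_version: str = ""

    def summary(self) -> str:
        """Human-readable digest of the audit."""
        lines = [
            "Chemotherapy emetogenicity / antiemetic prophylaxis audit",
            f"  guideline: {self.config.guideline}   CI method: {self.config.ci_method}",
            f"  rule tables: {self.rule_version}",
            "  patient flow:",
        ]
        for key, val in self.flow_log.items():
            if key == "exclusion_reasons":
                for reason, n in val.items():
                    if n:
                        lines.append(f"      excluded ({reason}): {n}")
            else:
                lines.append(f"    {key}: {val}")
        n = len(self.assignments)
        if n:
            lines.append("  emetic risk (all routes):")
            counts = self.assignments["category"].value_counts()
            for cat in tab.RISK_ORDER:
                k = int(counts.get(cat, 0))
                lines.append(f"    {cat:<10} {k:>7}  ({100.0 * k / n:5.1f}%)")
        return "\n".join(lines)

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        outputs = {
            "table2_characteristics.csv": self.characteristics,
            "table3_risk_distribution.csv": self.risk_distribution,
            "table4_top_regimens.csv": self.top_regimens,
            "table5_prophylaxis.csv": self.prophylaxis,
            "fig1_per_cancer.csv": self.per_cancer,
            "fig2_prophylaxis_per_cancer.csv": self.prophylaxis_per_cancer,
            "assignments.csv": self.assignments,
            "profiles.csv": self.profiles,
        }
        for name, frame in outputs.items():
            if frame is not None:
                frame.to_csv(out / name, index=False)
        with open(out / "flow_log.json", "w", encoding="utf-8") as fh:
            json.dump(self.flow_log, fh, indent=2, sort_keys=True)
        with open(out / "run_manifest.json", "w", encoding="utf-8") as fh:
            json.dump({"config": dataclasses.asdict(self.config),
                       "rule_tables": self.rule_version},
                      fh, indent=2, sort_keys=True)


def _member_rows(cohort: Cohort, config: AuditConfig):
    """Classify each retained member and attribute prophylaxis."""
    table = load_guideline_table(config.guideline)
    assign_rows, profile_rows, cohort_rows = [], [], []
    for m in cohort.members:
        episode = assemble_regimen(m.course, str(m.record["cancer_type"]))
        assignment = classify_regimen(episode, table=table, bsa_m2=config.bsa_m2)
        profile = attribute_prophylaxis(
            episode, m.course, m.antiemetic_events,
            oral_lookback_days=config.oral_lookback_days,
            table=table, bsa_m2=config.bsa_m2,
            escalation_categories=config.escalation_categories)
        assign_rows.append({
            "patient_id": m.patient_id,
            "cancer_type": episode.cancer_type,
            "route_group": m.route_group.value,
            "regimen_label": (assignment.fired_rule
                              if assignment.fired_rule not in ("max-of-components",
                                                               "unknown")
                              else episode.label),
            "components": episode.label,
            "guideline": assignment.guideline.value,
            "category": assignment.category.value,
            "fired_rule": assignment.fired_rule,
        })
        profile_rows.append({
            "patient_id": m.patient_id,
            "classes_present": "|".join(sorted(profile.classes_present)),
            "prophylaxis_category": profile.category.value,
            "nk1_without_partners": profile.nk1_without_partners,
        })
        cohort_rows.append({
            "patient_id": m.patient_id,
            "sex": m.record["sex"],
            "age_at_dx": m.record["age_at_dx"],
            "cancer_type": m.record["cancer_type"],
            "route_group": m.route_group.value,
            "combined_stage": m.combined_stage,
            "adjuvant": m.adjuvant,
            "course_start": m.course.start_date,
        })
    empty_assign = pd.DataFrame(columns=[
        "patient_id", "cancer_type", "route_group", "regimen_label",
        "components", "guideline", "category", "fired_rule"])
    empty_prof = pd.DataFrame(columns=["patient_id", "classes_present",
                                       "prophylaxis_category",
                                       "nk1_without_partners"])
    empty_cohort = pd.DataFrame(columns=["patient_id", "sex", "age_at_dx",
                                         "cancer_type", "route_group",
                                         "combined_stage", "adjuvant",
                                         "course_start"])
    return (pd.DataFrame(assign_rows) if assign_rows else empty_assign,
            pd.DataFrame(profile_rows) if profile_rows else empty_prof,
            pd.DataFrame(cohort_rows) if cohort_rows else empty_cohort)


def run_audit_frames(registry: pd.DataFrame, claims: pd.DataFrame,
                     procedures: pd.DataFrame,
                     config: Optional[AuditConfig] = None) -> AuditResult:
    """Run the full audit on in-memory inputs."""
    config = config or AuditConfig()
    try:
        cohort = build_cohort(registry, claims, procedures, config)
    except ValueError as err:
        raise ValueError(f"cohort selection failed: {err}") from err

    # hand each member its antiemetic claims once, for the attribution stage
    anti = claims[claims["drug_class"].isin(ANTIEMETIC_CLASSES)].copy()
    if not anti.empty:
        anti["date"] = pd.to_datetime(anti["date"]).dt.date
    by_patient = dict(tuple(anti.groupby("patient_id", sort=False))) if not anti.empty else {}
    empty_anti = anti.iloc[0:0]
    for m in cohort.members:
        m.antiemetic_events = by_patient.get(m.patient_id, empty_anti)

    assignments, profiles, cohort_frame = _member_rows(cohort, config)
    table = load_guideline_table(config.guideline)
    result = AuditResult(
        config=config, flow_log=cohort.flow_log, cohort_frame=cohort_frame,
        assignments=assignments, profiles=profiles, rule_version=table.version)
    if len(assignments):
        result.characteristics = tab.characteristics_table(cohort_frame)
        result.risk_distribution = tab.risk_distribution_table(assignments)
        result.top_regimens = tab.top_regimens(assignments)
        result.prophylaxis = tab.prophylaxis_table(profiles, assignments,
                                                   method=config.ci_method)
        result.per_cancer = tab.per_cancer_distribution(assignments)
        result.prophylaxis_per_cancer = tab.prophylaxis_per_cancer(
            profiles, assignments)
    else:
        result.characteristics = tab.characteristics_table(cohort_frame)
        result.risk_distribution = tab.risk_distribution_table(assignments)
        result.top_regimens = pd.DataFrame()
        result.prophylaxis = pd.DataFrame()
        result.per_cancer = pd.DataFrame()
        result.prophylaxis_per_cancer = pd.DataFrame()
    return result


def run_audit(registry_path, claims_path, procedures_path,
              config: Optional[AuditConfig] = None,
              out_dir=None) -> AuditResult:
    """Run the audit from the three delimited input files.

    Deterministic given inputs; when ``out_dir`` is set, writes every table,
    the flow log and the run manifest there.
    """
    registry, claims, procedures = load_inputs(registry_path, claims_path,
                                               procedures_path)
    result = run_audit_frames(registry, claims, procedures, config)
    if out_dir is not None:
        result.write(out_dir)
    return result


class EmesisAudit:
    """Object-style entry point: construct from inputs, ``run()`` for results."""

    def __init__(self, registry: pd.DataFrame, claims: pd.DataFrame,
                 procedures: pd.DataFrame,
                 config: Optional[AuditConfig] = None):
        self.registry = registry
        self.claims = claims
        self.procedures = procedures
        self.config = config or AuditConfig()

    @classmethod
    def from_files(cls, registry_path, claims_path, procedures_path,
                   config: Optional[AuditConfig] = None) -> "EmesisAudit":
        registry, claims, procedures = load_inputs(registry_path, claims_path,
                                                   procedures_path)
        return cls(registry, claims, procedures, config)

    def run(self) -> AuditResult:
        return run_audit_frames(self.registry, self.claims, self.procedures,
                                self.config)
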