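"""Temporal attribution of antiemetic claims to the first chemotherapy course.

An antiemetic claim (NK1 receptor antagonist, serotonin receptor antagonist, or
any systemic corticosteroid) counts as prophylactic when

(a) it is dated on the course start date (any route);
(b) a high-emetic-risk component of the regimen is first administered later in
    the window and the claim shares that administration's date — the
    S-1 day 1 / cisplatin day 8 escalation pattern for gastric cancer; or
(c) it is an oral drug dated within the 30 days before the start (inclusive of
    day start-30), capturing oral antiemetics dispensed in preparation.

The classes present are then collapsed into five mutually exclusive categories:
triple (NK1 + serotonin antagonist + steroid), serotonin antagonist +
dexamethasone, serotonin antagonist alone, dexamethasone alone, or none. An
NK1 antagonist without both partners matches no printed category; it falls
through to the row determined by the serotonin/steroid pair and is flagged in a
dedicated audit field so the ambiguity stays measurable.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from enum import Enum
from typing import Optional

import pandas as pd

from .cohort import CourseWindow
from .regimen import RegimenEpisode
from .risk import (Guideline, RiskCategory, Route, RuleTable,
                   classify_single_agent, load_guideline_table)

ANTIEMETIC_CLASSES = ("NK1", "serotonin_antagonist", "steroid")


class ProphylaxisCategory(str, Enum):
    TRIPLE = "triple"
    SEROTONIN_PLUS_DEX = "serotonin_plus_dex"
    SEROTONIN_ONLY = "serotonin_only"
    DEX_ONLY = "dex_only"
    NONE_OF_ABOVE = "none_of_above"


@dataclass
class ProphylaxisProfile:
    patient_id: str
    classes_present: frozenset[str]
    category: ProphylaxisCategory
    nk1_without_partners: bool      # audit flag: NK1 present but not a triple


def escalation_dates(episode: RegimenEpisode, course: CourseWindow,
                     *,
                     guideline: Guideline | str = Guideline.JSCO,
                     table: Optional[RuleTable] = None,
                     bsa_m2: float = 1.48,
                     escalation_categories: tuple[str, ...] = ("high",)
                     ) -> set[dt.date]:
    """Dates after the start on which a high-risk component was administered.

    These carry rule (b): antiemetics on such a date are prophylactic. The set
    of triggering categories is configurable but defaults to high only.
    """
    if table is None:
        table = load_guideline_table(guideline)
    cats = {(c.drug_id, c.route.value):
            classify_single_agent(c.drug_id, c.dose_mg, c.route, table.guideline,
                                  bsa_m2=bsa_m2, table=table).value
            for c in episode.components}
    dates: set[dt.date] = set()
    for row in course.events.itertuples(index=False):
        if row.date > course.start_date and \
                cats.get((row.drug_id, row.route)) in escalation_categories:
            dates.add(row.date)
    return dates


def collect_prophylactic_events(episode: RegimenEpisode, course: CourseWindow,
                                antiemetic_events: pd.DataFrame,
                                *,
                                oral_lookback_days: int = 30,
                                escalation: Optional[set[dt.date]] = None,
                                guideline: Guideline | str = Guideline.JSCO,
                                table: Optional[RuleTable] = None,
                                bsa_m2: float = 1.48,
                                escalation_categories: tuple[str, ...] = ("high",)
                                ) -> frozenset[str]:
    """Antiemetic classes attributable as prophylaxis for this course."""
    if antiemetic_events.empty:
        return frozenset()
    if escalation is None:
        escalation = escalation_dates(
            episode, course, guideline=guideline, table=table, bsa_m2=bsa_m2,
            escalation_categories=escalation_categories)
    start = course.start_date
    lookback_start = start - dt.timedelta(days=oral_lookback_days)
    classes: set[str] = set()
    for row in antiemetic_events.itertuples(index=False):
        if row.drug_class not in ANTIEMETIC_CLASSES:
            continue
        counted = (row.date == start or row.date in escalation or
                   (row.route == Route.PO.value and
                    lookback_start <= row.date < start))
        if counted:
            classes.add(row.drug_class)
    return frozenset(classes)


def categorize_prophylaxis(classes_present) -> ProphylaxisCategory:
    """Collapse the class set to the five mutually exclusive categories."""
    classes = frozenset(classes_present)
    unexpected = classes - set(ANTIEMETIC_CLASSES)
    if unexpected:
        raise ValueError(f"unknown antiemetic class(es): {sorted(unexpected)}")
    serotonin = "serotonin_antagonist" in classes
    steroid = "steroid" in classes
    if "NK1" in classes and serotonin and steroid:
        return ProphylaxisCategory.TRIPLE
    if serotonin and steroid:
        return ProphylaxisCategory.SEROTONIN_PLUS_DEX
    if serotonin:
        return ProphylaxisCategory.SEROTONIN_ONLY
    if steroid:
        return ProphylaxisCategory.DEX_ONLY
    return ProphylaxisCategory.NONE_OF_ABOVE


def attribute_prophylaxis(episode: RegimenEpisode, course: CourseWindow,
                          antiemetic_events: pd.DataFrame,
                          **kwargs) -> ProphylaxisProfile:
    """Full attribution for one patient: collect classes, then categorize."""
    classes = collect_prophylactic_events(episode, course, antiemetic_events,
                                          **kwargs)
    category = categorize_prophylaxis(classes)
    return ProphylaxisProfile(
        patient_id=episode.patient_id,
        classes_present=classes,
        category=category,
        nk1_without_partners=("NK1" in classes
                              and category != ProphylaxisCategory.TRIPLE),
    )
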