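"""Regimen assembly and emetic-risk assignment for the first course.

Every chemotherapy claim in the 8-day first-course window is collapsed into a
single combination regimen. Risk assignment tries named combination overrides
first (FOLFOXIRI, FOLFIRINOX, GS, GEM/nab-PTX, ICE, the anthracycline +
cyclophosphamide pair, and the single-oral-agent lymphoma overrides); when no
override fires, the regimen takes the maximum single-agent category of its
components under the risk order, ignoring unclassifiable components.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

from .cohort import CourseWindow
from .risk import (CombinationRule, Guideline, RiskCategory, Route, RuleTable,
                   classify_single_agent, load_guideline_table, max_category,
                   DEFAULT_BSA_M2)

logger = logging.getLogger(__name__)

MAX_OF_COMPONENTS = "max-of-components"


@dataclass(frozen=True)
class Component:
    drug_id: str
    route: Route
    dose_mg: Optional[float]    # max dose observed in the window (conservative)


@dataclass
class RegimenEpisode:
    patient_id: str
    start_date: object
    components: tuple[Component, ...]
    cancer_type: str

    @property
    def label(self) -> str:
        return "+".join(sorted(c.drug_id for c in self.components))


@dataclass
class RiskAssignment:
    episode: RegimenEpisode
    guideline: Guideline
    category: RiskCategory
    fired_rule: str             # combination-rule name, "max-of-components" or "unknown"


def assemble_regimen(course: CourseWindow, cancer_type: str) -> RegimenEpisode:
    """Collapse a course window to one component per distinct (drug, route).

    The recorded dose is the maximum observed in the window, which is
    conservative for dose-tiered drugs.
    """
    if course.events.empty:
        raise ValueError("cannot assemble a regimen from an empty course")
    seen: dict[tuple[str, str], Optional[float]] = {}
    for row in course.events.itertuples(index=False):
        key = (row.drug_id, row.route)
        dose = None if row.dose_mg is None or row.dose_mg != row.dose_mg else float(row.dose_mg)
        prev = seen.get(key)
        if key not in seen or (dose is not None and (prev is None or dose > prev)):
            seen[key] = dose
    components = tuple(sorted(
        (Component(d, Route(r), dose) for (d, r), dose in seen.items()),
        key=lambda c: (c.drug_id, c.route.value)))
    return RegimenEpisode(course.patient_id, course.start_date, components, cancer_type)


def _rule_applies(rule: CombinationRule, episode: RegimenEpisode) -> bool:
    if rule.cancer_context is not None and rule.cancer_context != episode.cancer_type:
        return False
    present = {(c.drug_id, c.route) for c in episode.components}
    drugs_present = {d for d, _ in present}
    for drug, route in rule.components:
        if route is None:
            if drug not in drugs_present:
                return False
        elif (drug, route) not in present:
            return False
    return True


def match_combination_rule(episode: RegimenEpisode,
                           rules) -> Optional[CombinationRule]:
    """Most specific combination rule matching the episode, or None.

    Rules match by subset: the episode may contain extra drugs (rituximab +
    CHOP still fires the anthracycline + cyclophosphamide override).
    Specificity: more components first, then cancer-context-restricted before
    unrestricted, then lexicographic name as a deterministic tie-break.
    """
    candidates = [r for r in rules if _rule_applies(r, episode)]
    if not candidates:
        return None
    candidates.sort(key=lambda r: (-len(r.components),
                                   r.cancer_context is None, r.name))
    if len(candidates) > 1:
        top = candidates[0]
        rivals = [r.name for r in candidates[1:]
                  if (len(r.components), r.cancer_context is None)
                  == (len(top.components), top.cancer_context is None)]
        if rivals:
            logger.info("combination-rule tie for %s broken lexicographically: "
                        "%s over %s", episode.patient_id, top.name, rivals)
    return candidates[0]


def classify_regimen(episode: RegimenEpisode,
                     guideline: Guideline | str = Guideline.JSCO,
                     bsa_m2: float = DEFAULT_BSA_M2,
                     *,
                     table: Optional[RuleTable] = None,
                     missing_dose: str = "fallback") -> RiskAssignment:
    """Assign the regimen's emetic-risk category under one guideline."""
    if table is None:
        table = load_guideline_table(guideline)
    combo = match_combination_rule(episode, table.combinations)
    if combo is not None:
        return RiskAssignment(episode, table.guideline, combo.category, combo.name)
    cats = [classify_single_agent(c.drug_id, c.dose_mg, c.route, table.guideline,
                                  bsa_m2=bsa_m2, missing_dose=missing_dose,
                                  table=table)
            for c in episode.components]
    category = max_category(cats)
    fired = MAX_OF_COMPONENTS if category != RiskCategory.UNKNOWN else "unknown"
    return RiskAssignment(episode, table.guideline, category, fired)
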