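"""Guideline knowledge base: emetic-risk classification of single agents.

Packaged, versioned rule tables map a canonical drug (with route and, where the
guideline requires it, dose) to one of four acute emetic-risk categories under
each of four guideline systems: the Japan Society of Clinical Oncology (JSCO,
2015 — the default used for all headline tabulations), ASCO (2020), NCCN
(v2.2020) and MASCC/ESMO (2016).

Dose-dependent rules are expressed per body surface area (mg/m²). Claims data
carry absolute mg, so doses are divided by a fixed reference BSA — 1.48 m², the
average Japanese adult — before tier lookup. A few NCCN rules use absolute mg
(doxorubicin, epirubicin) or the carboplatin AUC, which cannot be recovered
from an mg dose; an AUC may be supplied explicitly, otherwise carboplatin
resolves to moderate with a warning.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from typing import Iterable, Mapping, Optional, Sequence

logger = logging.getLogger(__name__)

#: Reference body surface area (m²) used to convert absolute mg doses to mg/m².
DEFAULT_BSA_M2 = 1.48


class RiskCategory(str, Enum):
    """Acute emetic-risk category.

    The four named categories are totally ordered (high > moderate > low >
    minimal). ``unknown`` sits outside the order and never wins a maximum.
    """

    HIGH = "high"
    MODERATE = "moderate"
    LOW = "low"
    MINIMAL = "minimal"
    UNKNOWN = "unknown"

    @property
    def rank(self) -> Optional[int]:
        return _RANK[self]


_RANK = {
    RiskCategory.HIGH: 4,
    RiskCategory.MODERATE: 3,
    RiskCategory.LOW: 2,
    RiskCategory.MINIMAL: 1,
    RiskCategory.UNKNOWN: None,
}


def max_category(categories: Iterable[RiskCategory]) -> RiskCategory:
    """Maximum under the risk order, ignoring ``unknown``.

    Returns ``unknown`` when every input is unknown (or the iterable is empty).
    """
    best = RiskCategory.UNKNOWN
    for cat in categories:
        if cat.rank is not None and (best.rank is None or cat.rank > best.rank):
            best = cat
    return best


class Guideline(str, Enum):
    JSCO = "JSCO"
    ASCO = "ASCO"
    NCCN = "NCCN"
    MASCC = "MASCC"


class Route(str, Enum):
    IV = "IV"
    PO = "PO"
    ARTERIAL = "arterial"


class RuleSchemaError(ValueError):
    """A packaged or user rule file failed schema validation."""


@dataclass(frozen=True)
class Tier:
    bound: float
    op: str            # "gt" or "ge"
    unit: str          # "mg_m2", "mg" or "auc"
    category: RiskCategory

    def matches(self, value: float) -> bool:
        return value > self.bound if self.op == "gt" else value >= self.bound


@dataclass(frozen=True)
class SingleAgentRule:
    """Risk rule for one (drug, route) under one guideline.

    ``tiers`` are evaluated from the highest bound down; the first matching
    tier wins, otherwise ``default_category`` applies.
    """

    drug_id: str
    route: Route
    guideline: Guideline
    tiers: tuple[Tier, ...]
    default_category: RiskCategory
    missing_dose_category: Optional[RiskCategory] = None

    @property
    def dose_dependent(self) -> bool:
        return any(t.unit in ("mg_m2", "mg") for t in self.tiers)


@dataclass(frozen=True)
class CombinationRule:
    """A named regimen classified as a unit (e.g. FOLFOXIRI -> high).

    ``components`` are (drug_id, route-or-None) pairs that must all be present
    in an episode for the rule to fire; an optional ``cancer_context``
    restricts the rule to one cancer type. Single-component rules are only
    legal when flagged as single-agent overrides (oral etoposide, nimustine,
    ranimustine for malignant lymphoma).
    """

    name: str
    components: frozenset[tuple[str, Optional[Route]]]
    cancer_context: Optional[str]
    category: RiskCategory
    single_agent_override: bool = False


@dataclass
class RuleTable:
    guideline: Guideline
    single_agents: dict[tuple[str, Route], SingleAgentRule]
    combinations: tuple[CombinationRule, ...]
    version: str = ""

    def get(self, drug_id: str, route: Route) -> Optional[SingleAgentRule]:
        return self.single_agents.get((drug_id, route))


def _data_path(name: str):
    return resources.files("cinv_audit.data").joinpath(name)


def _parse_category(raw: str, *, where: str) -> RiskCategory:
    try:
        return RiskCategory(raw)
    except ValueError:
        raise RuleSchemaError(f"{where}: invalid category {raw!r}") from None


_SINGLE_COLUMNS = ["drug_id", "route", "tier_bound", "bound_op", "bound_unit",
                   "category", "missing_dose_category"]


def _read_single_agent_rows(fh, guideline: Guideline, fname: str):
    reader = csv.DictReader(fh)
    if reader.fieldnames is None or list(reader.fieldnames) != _SINGLE_COLUMNS:
        raise RuleSchemaError(
            f"{fname}: header must be {','.join(_SINGLE_COLUMNS)}, "
            f"got {reader.fieldnames}")
    grouped: dict[tuple[str, Route], dict] = {}
    for i, row in enumerate(reader, start=2):
        where = f"{fname} row {i}"
        try:
            route = Route(row["route"])
        except ValueError:
            raise RuleSchemaError(f"{where} column route: invalid {row['route']!r}") from None
        key = (row["drug_id"].strip().lower(), route)
        entry = grouped.setdefault(key, {"tiers": [], "default": None, "missing": None})
        cat = _parse_category(row["category"], where=f"{where} column category")
        if row["tier_bound"].strip():
            try:
                bound = float(row["tier_bound"])
            except ValueError:
                raise RuleSchemaError(f"{where} column tier_bound: not numeric") from None
            if row["bound_op"] not in ("gt", "ge"):
                raise RuleSchemaError(f"{where} column bound_op: invalid {row['bound_op']!r}")
            if row["bound_unit"] not in ("mg_m2", "mg", "auc"):
                raise RuleSchemaError(f"{where} column bound_unit: invalid {row['bound_unit']!r}")
            entry["tiers"].append(Tier(bound, row["bound_op"], row["bound_unit"], cat))
        else:
            if entry["default"] is not None:
                raise RuleSchemaError(f"{where}: duplicate default row for {key}")
            entry["default"] = cat
        if row["missing_dose_category"].strip():
            entry["missing"] = _parse_category(
                row["missing_dose_category"], where=f"{where} column missing_dose_category")
    rules = {}
    for (drug, route), entry in grouped.items():
        if entry["default"] is None:
            raise RuleSchemaError(f"{fname}: no default row for ({drug}, {route.value})")
        tiers = tuple(sorted(entry["tiers"], key=lambda t: -t.bound))
        rules[(drug, route)] = SingleAgentRule(
            drug_id=drug, route=route, guideline=guideline, tiers=tiers,
            default_category=entry["default"], missing_dose_category=entry["missing"])
    return rules


def _read_combination_rows(fh, guideline: Guideline, fname: str):
    reader = csv.DictReader(fh)
    expected = ["guideline", "name", "components", "cancer_context", "category",
                "single_agent_override"]
    if reader.fieldnames is None or list(reader.fieldnames) != expected:
        raise RuleSchemaError(f"{fname}: header must be {','.join(expected)}")
    combos = []
    for i, row in enumerate(reader, start=2):
        if row["guideline"] != guideline.value:
            continue
        where = f"{fname} row {i}"
        comps = set()
        for token in row["components"].split("|"):
            token = token.strip().lower()
            if not token:
                raise RuleSchemaError(f"{where} column components: empty component")
            if ":" in token:
                drug, route_raw = token.split(":", 1)
                try:
                    comps.add((drug, Route(route_raw.upper() if route_raw.upper() in
                                           ("IV", "PO") else route_raw)))
                except ValueError:
                    raise RuleSchemaError(
                        f"{where} column components: bad route in {token!r}") from None
            else:
                comps.add((token, None))
        override = row["single_agent_override"].strip().lower() == "true"
        if len(comps) < 2 and not override:
            raise RuleSchemaError(
                f"{where}: combination {row['name']!r} has <2 components and is "
                "not flagged as a single-agent override")
        combos.append(CombinationRule(
            name=row["name"],
            components=frozenset(comps),
            cancer_context=row["cancer_context"].strip() or None,
            category=_parse_category(row["category"], where=f"{where} column category"),
            single_agent_override=override,
        ))
    return tuple(combos)


_TABLE_CACHE: dict[Guideline, RuleTable] = {}


def load_guideline_table(guideline: Guideline | str, *, refresh: bool = False) -> RuleTable:
    """Load (and cache) the packaged rule table for one guideline."""
    guideline = Guideline(guideline)
    if not refresh and guideline in _TABLE_CACHE:
        return _TABLE_CACHE[guideline]
    fname = f"single_agents_{guideline.value.lower()}.csv"
    with _data_path(fname).open(encoding="utf-8") as fh:
        singles = _read_single_agent_rows(fh, guideline, fname)
    with _data_path("combinations.csv").open(encoding="utf-8") as fh:
        combos = _read_combination_rows(fh, guideline, "combinations.csv")
    version = _data_path("rules_version.txt").read_text(encoding="utf-8").strip()
    table = RuleTable(guideline, singles, combos, version)
    _TABLE_CACHE[guideline] = table
    return table


def dose_per_bsa(dose_mg: float, bsa_m2: float = DEFAULT_BSA_M2) -> float:
    """Convert an absolute dose (mg) to mg/m² at the reference BSA."""
    if dose_mg < 0:
        raise ValueError(f"dose_mg must be non-negative, got {dose_mg}")
    if bsa_m2 <= 0:
        raise ValueError(f"bsa_m2 must be positive, got {bsa_m2}")
    return dose_mg / bsa_m2


def classify_single_agent(
    drug_id: str,
    dose_mg: Optional[float] = None,
    route: Route | str = Route.IV,
    guideline: Guideline | str = Guideline.JSCO,
    *,
    bsa_m2: float = DEFAULT_BSA_M2,
    auc: Optional[float] = None,
    missing_dose: str = "fallback",
    table: Optional[RuleTable] = None,
) -> RiskCategory:
    """Classify a single agent's acute emetic risk.

    Dose-tiered drugs are resolved through :func:`dose_per_bsa` against the
    guideline's tiers. A drug absent from the table maps to ``unknown``. When a
    dose-tiered drug arrives without a dose (common in claims), the drug's
    documented fallback tier applies (``missing_dose="fallback"``, default) or
    ``unknown`` (``missing_dose="unknown"``); either way a warning is logged.
    """
    if dose_mg is not None and dose_mg < 0:
        raise ValueError(f"dose_mg must be non-negative, got {dose_mg}")
    route = Route(route)
    if table is None:
        table = load_guideline_table(guideline)
    rule = table.get(drug_id.strip().lower(), route)
    if rule is None:
        return RiskCategory.UNKNOWN
    skipped_dose = skipped_auc = False
    for tier in rule.tiers:
        if tier.unit == "auc":
            value = auc
        elif tier.unit == "mg":
            value = dose_mg
        else:
            value = dose_per_bsa(dose_mg, bsa_m2) if dose_mg is not None else None
        if value is None:
            if tier.unit == "auc":
                skipped_auc = True
            else:
                skipped_dose = True
            continue
        if tier.matches(value):
            return tier.category
    if skipped_dose:
        logger.warning(
            "dose-tiered drug %s (%s, %s) classified without a dose; using %s",
            rule.drug_id, route.value, table.guideline.value, missing_dose)
        if missing_dose == "unknown":
            return RiskCategory.UNKNOWN
        return rule.missing_dose_category or rule.default_category
    if skipped_auc:
        logger.warning(
            "%s (%s) has an AUC-based tier but no AUC was supplied; "
            "using default category %s", rule.drug_id, table.guideline.value,
            rule.default_category.value)
    return rule.default_category


def compare_guidelines(
    drug_id: str,
    dose_mg: Optional[float] = None,
    route: Route | str = Route.IV,
    *,
    bsa_m2: float = DEFAULT_BSA_M2,
    auc: Optional[float] = None,
) -> dict[Guideline, RiskCategory]:
    """Classify one drug under all four guidelines (the differences view)."""
    return {
        g: classify_single_agent(drug_id, dose_mg, route, g, bsa_m2=bsa_m2, auc=auc)
        for g in Guideline
    }


def load_drug_dictionary() -> dict[str, tuple[str, str]]:
    """Canonicalization dictionary: raw claim name -> (drug_id, drug_class).

    Classes: chemotherapy | NK1 | serotonin_antagonist | steroid | other.
    """
    mapping: dict[str, tuple[str, str]] = {}
    with _data_path("drug_classes.csv").open(encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        expected = ["raw_name", "drug_id", "drug_class"]
        if list(reader.fieldnames or []) != expected:
            raise RuleSchemaError("drug_classes.csv: header must be raw_name,drug_id,drug_class")
        for i, row in enumerate(reader, start=2):
            if row["drug_class"] not in (
                    "chemotherapy", "NK1", "serotonin_antagonist", "steroid", "other"):
                raise RuleSchemaError(
                    f"drug_classes.csv row {i} column drug_class: invalid "
                    f"{row['drug_class']!r}")
            mapping[row["raw_name"].strip().lower()] = (
                row["drug_id"].strip().lower(), row["drug_class"])
    return mapping


def canonicalize(raw_name: str,
                 dictionary: Optional[Mapping[str, tuple[str, str]]] = None
                 ) -> tuple[str, str]:
    """Map a raw claim drug name to (canonical drug_id, drug_class).

    Unrecognized names pass through lowercased with class ``other``.
    """
    if dictionary is None:
        dictionary = load_drug_dictionary()
    key = raw_name.strip().lower()
    return dictionary.get(key, (key, "other"))
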