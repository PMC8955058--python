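"""Synthetic linked registry + claims + procedures generator with ground truth.

Emulates the kind of hospital-based cancer registry / fee-for-service claims
linkage the audit consumes, with a known per-patient truth channel: each
patient draws a cancer type, a named regimen from that cancer's mixture, and a
prophylaxis category; drug claims are laid out at the regimen's administration
day offsets (e.g. S-1 daily on days 1-8 with cisplatin added on day 8) and
antiemetic claims are placed on dates that satisfy the attribution rules.
Optional timing noise displaces antiemetics outside every attribution window,
and exclusion-triggering events (interferon-alpha lines, same-day surgery,
arterial routes, early stem-cell transplant, under-age patients) are injected
at configurable rates.

Default parameters are derived from the published cancer-type marginals,
regimen mixtures and prophylaxis rates of the 2016 Japanese audit this package
re-implements; the generator itself is general. Nothing in the analysis
pipeline reads the truth channel.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

from .prophylaxis import categorize_prophylaxis

PROPHYLAXIS_CATEGORIES = ("triple", "serotonin_plus_dex", "serotonin_only",
                          "dex_only", "none_of_above")
EXCLUSION_REASONS = ("interferon_alpha", "same_day_surgery_or_drainage",
                     "arterial_route", "hsct_within_3_weeks", "under_20")


@dataclass(frozen=True)
class ComponentSpec:
    drug_id: str
    drug_class: str          # chemotherapy | steroid
    route: str               # IV | PO
    dose_mg: float
    days: tuple[int, ...]    # administration days, day 1 = course start


@dataclass(frozen=True)
class RegimenSpec:
    """A named regimen: components, routes, doses and day offsets."""

    name: str
    components: tuple[ComponentSpec, ...]
    risk: str                       # intended emetic-risk category
    escalation_day: Optional[int] = None  # day the high-risk drug is added, if late

    @property
    def route_group(self) -> str:
        chemo_iv = any(c.route == "IV" and c.drug_class == "chemotherapy"
                       for c in self.components)
        return "intravenous_group" if chemo_iv else "oral_group"


def _c(drug, route, dose, days, drug_class="chemotherapy"):
    return ComponentSpec(drug, drug_class, route, dose, tuple(days))


#: Named regimens available to the generator (doses in absolute mg for a
#: 1.48 m² reference adult; day 1 is the course start).
REGIMEN_LIBRARY: dict[str, RegimenSpec] = {r.name: r for r in [
    # non-small cell lung
    RegimenSpec("CDDP+pemetrexed", (_c("cisplatin", "IV", 111, [1]),
                                    _c("pemetrexed", "IV", 740, [1])), "high"),
    RegimenSpec("NP", (_c("cisplatin", "IV", 118, [1]),
                       _c("vinorelbine", "IV", 37, [1, 8])), "high"),
    RegimenSpec("TC", (_c("carboplatin", "IV", 600, [1]),
                       _c("paclitaxel", "IV", 296, [1])), "moderate"),
    RegimenSpec("UFT", (_c("tegafur-uracil", "PO", 400, range(1, 9)),), "low"),
    RegimenSpec("pemetrexed", (_c("pemetrexed", "IV", 740, [1]),), "low"),
    RegimenSpec("gefitinib", (_c("gefitinib", "PO", 250, range(1, 9)),), "minimal"),
    RegimenSpec("erlotinib", (_c("erlotinib", "PO", 150, range(1, 9)),), "minimal"),
    # colorectal
    RegimenSpec("FOLFOXIRI", (_c("fluorouracil", "IV", 2368, [1]),
                              _c("levofolinate", "IV", 296, [1]),
                              _c("oxaliplatin", "IV", 125, [1]),
                              _c("irinotecan", "IV", 244, [1])), "high"),
    RegimenSpec("CAPOX", (_c("capecitabine", "PO", 2960, range(1, 9)),
                          _c("oxaliplatin", "IV", 192, [1])), "moderate"),
    RegimenSpec("FOLFOX", (_c("fluorouracil", "IV", 2960, [1]),
                           _c("levofolinate", "IV", 296, [1]),
                           _c("oxaliplatin", "IV", 125, [1])), "moderate"),
    RegimenSpec("capecitabine", (_c("capecitabine", "PO", 2960, range(1, 9)),), "low"),
    RegimenSpec("UFT+LV", (_c("tegafur-uracil", "PO", 400, range(1, 9)),
                           _c("folinate", "PO", 75, range(1, 9))), "low"),
    RegimenSpec("panitumumab", (_c("panitumumab", "IV", 888, [1]),), "minimal"),
    RegimenSpec("regorafenib", (_c("regorafenib", "PO", 160, range(1, 9)),), "minimal"),
    # breast
    RegimenSpec("FEC", (_c("fluorouracil", "IV", 740, [1]),
                        _c("epirubicin", "IV", 148, [1]),
                        _c("cyclophosphamide", "IV", 740, [1])), "high"),
    RegimenSpec("EC", (_c("epirubicin", "IV", 133, [1]),
                       _c("cyclophosphamide", "IV", 888, [1])), "high"),
    RegimenSpec("AC", (_c("doxorubicin", "IV", 89, [1]),
                       _c("cyclophosphamide", "IV", 888, [1])), "high"),
    RegimenSpec("TC-breast", (_c("docetaxel", "IV", 111, [1]),
                              _c("cyclophosphamide", "IV", 888, [1])), "moderate"),
    RegimenSpec("PTX", (_c("paclitaxel", "IV", 133, [1, 8]),), "low"),
    RegimenSpec("trastuzumab+PTX", (_c("trastuzumab", "IV", 296, [1]),
                                    _c("paclitaxel", "IV", 133, [1, 8])), "low"),
    RegimenSpec("DTX", (_c("docetaxel", "IV", 111, [1]),), "low"),
    RegimenSpec("trastuzumab", (_c("trastuzumab", "IV", 296, [1]),), "minimal"),
    # gastric
    RegimenSpec("S-1+CDDP", (_c("s-1", "PO", 120, range(1, 9)),
                             _c("cisplatin", "IV", 89, [8])), "high",
                escalation_day=8),
    RegimenSpec("Cape+CDDP", (_c("capecitabine", "PO", 2960, range(1, 9)),
                              _c("cisplatin", "IV", 118, [1])), "high"),
    RegimenSpec("SOX", (_c("s-1", "PO", 120, range(1, 9)),
                        _c("oxaliplatin", "IV", 192, [1])), "moderate"),
    RegimenSpec("S-1", (_c("s-1", "PO", 120, range(1, 9)),), "low"),
    RegimenSpec("nivolumab", (_c("nivolumab", "IV", 240, [1]),), "minimal"),
    RegimenSpec("ramucirumab", (_c("ramucirumab", "IV", 473, [1]),), "minimal"),
    # malignant lymphoma
    RegimenSpec("CHOP", (_c("cyclophosphamide", "IV", 1110, [1]),
                         _c("doxorubicin", "IV", 74, [1]),
                         _c("vincristine", "IV", 2, [1]),
                         _c("prednisolone", "PO", 100, range(1, 6), "steroid")),
                "high"),
    RegimenSpec("R-CHOP", (_c("rituximab", "IV", 555, [1]),
                           _c("cyclophosphamide", "IV", 1110, [1]),
                           _c("doxorubicin", "IV", 74, [1]),
                           _c("vincristine", "IV", 2, [1]),
                           _c("prednisolone", "PO", 100, range(1, 6), "steroid")),
                "high"),
    RegimenSpec("CPM", (_c("cyclophosphamide", "IV", 1110, [1]),), "moderate"),
    RegimenSpec("oral etoposide", (_c("etoposide", "PO", 50, range(1, 9)),),
                "moderate"),
    # pancreatic
    RegimenSpec("FOLFIRINOX", (_c("oxaliplatin", "IV", 125, [1]),
                               _c("irinotecan", "IV", 266, [1]),
                               _c("fluorouracil", "IV", 2960, [1]),
                               _c("levofolinate", "IV", 296, [1])), "high"),
    RegimenSpec("GEM+nab-PTX", (_c("gemcitabine", "IV", 1480, [1, 8]),
                                _c("nab-paclitaxel", "IV", 185, [1, 8])),
                "moderate"),
    RegimenSpec("GS", (_c("gemcitabine", "IV", 1480, [1]),
                       _c("s-1", "PO", 120, range(1, 9))), "moderate"),
    RegimenSpec("GEM", (_c("gemcitabine", "IV", 1480, [1, 8]),), "low"),
    # oesophageal
    RegimenSpec("FP", (_c("fluorouracil", "IV", 1184, [1]),
                       _c("cisplatin", "IV", 118, [1])), "high"),
    RegimenSpec("DCF", (_c("docetaxel", "IV", 104, [1]),
                        _c("cisplatin", "IV", 104, [1]),
                        _c("fluorouracil", "IV", 1110, [1])), "high"),
    RegimenSpec("nedaplatin+5-FU", (_c("nedaplatin", "IV", 133, [1]),
                                    _c("fluorouracil", "IV", 1184, [1])),
                "moderate"),
    # small cell lung
    RegimenSpec("PE", (_c("cisplatin", "IV", 118, [1]),
                       _c("etoposide", "IV", 148, [1, 2, 3])), "high"),
    RegimenSpec("PI", (_c("cisplatin", "IV", 89, [1]),
                       _c("irinotecan", "IV", 89, [1, 8])), "high"),
    RegimenSpec("CBDCA+etoposide", (_c("carboplatin", "IV", 625, [1]),
                                    _c("etoposide", "IV", 148, [1, 2, 3])),
                "moderate"),
    RegimenSpec("CBDCA+CPT11", (_c("carboplatin", "IV", 625, [1]),
                                _c("irinotecan", "IV", 89, [1])), "moderate"),
    RegimenSpec("CPT11", (_c("irinotecan", "IV", 148, [1, 8]),), "low"),
]}


class SimulationConfig(BaseModel):
    """Everything the generator needs; every vector must be a distribution."""

    n_patients: int = Field(gt=0)
    cancer_mix: dict[str, float]
    regimen_mix: dict[str, dict[str, float]]         # cancer -> regimen -> p
    prophylaxis_probs: dict[str, dict[str, float]]   # regimen -> category -> p
    timing_noise: float = Field(default=0.0, ge=0.0, le=1.0)
    exclusion_rates: dict[str, float] = Field(default_factory=dict)
    oral_lookback_fraction: float = Field(default=0.2, ge=0.0, le=1.0)
    age_mean: float = 65.9
    age_sd: float = Field(default=12.0, gt=0)
    male_fraction: float = Field(default=0.547, ge=0.0, le=1.0)
    stage_probs: dict[str, float] = Field(default_factory=lambda: {
        "0": 0.021, "I": 0.143, "II": 0.182, "III": 0.246, "IV": 0.313,
        "unknown": 0.095})
    resection_fraction: float = Field(default=0.4, ge=0.0, le=1.0)
    diagnosis_year: int = 2016

    @staticmethod
    def _check_dist(vec: dict[str, float], name: str) -> None:
        if abs(sum(vec.values()) - 1.0) > 1e-9:
            raise ValueError(f"{name} must sum to 1, got {sum(vec.values())!r}")
        if any(p < 0 for p in vec.values()):
            raise ValueError(f"{name} has negative probabilities")

    @model_validator(mode="after")
    def _validate(self) -> "SimulationConfig":
        self._check_dist(self.cancer_mix, "cancer_mix")
        self._check_dist(self.stage_probs, "stage_probs")
        for cancer, mix in self.regimen_mix.items():
            self._check_dist(mix, f"regimen_mix[{cancer}]")
            for name in mix:
                if name not in REGIMEN_LIBRARY:
                    raise ValueError(f"unknown regimen {name!r} for {cancer}")
        for regimen, probs in self.prophylaxis_probs.items():
            self._check_dist(probs, f"prophylaxis_probs[{regimen}]")
            if set(probs) - set(PROPHYLAXIS_CATEGORIES):
                raise ValueError(f"bad prophylaxis category for {regimen}")
        for reason, rate in self.exclusion_rates.items():
            if reason not in EXCLUSION_REASONS:
                raise ValueError(f"unknown exclusion reason {reason!r}")
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"exclusion rate for {reason} outside [0, 1]")
        for cancer in self.cancer_mix:
            if cancer not in self.regimen_mix:
                raise ValueError(f"no regimen mixture for cancer type {cancer!r}")
        return self

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.model_dump(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.model_validate(yaml.safe_load(fh))


# Published per-cancer risk-tier shares (text and figure); gaps filled with
# round, plausible values so each cancer's tiers form a distribution.
_RISK_SHARES = {
    "non_small_cell_lung": {"high": 0.35, "moderate": 0.30, "low": 0.20, "minimal": 0.15},
    "colorectal": {"high": 0.020, "moderate": 0.404, "low": 0.552, "minimal": 0.024},
    "breast": {"high": 0.538, "moderate": 0.250, "low": 0.170, "minimal": 0.042},
    "gastric": {"high": 0.200, "moderate": 0.150, "low": 0.602, "minimal": 0.048},
    "malignant_lymphoma": {"high": 0.602, "moderate": 0.398},
    "pancreatic": {"high": 0.042, "moderate": 0.442, "low": 0.516},
    "oesophageal": {"high": 0.803, "moderate": 0.120, "low": 0.077},
    "small_cell_lung": {"high": 0.350, "moderate": 0.599, "low": 0.051},
    "other": {"high": 0.10, "moderate": 0.35, "low": 0.40, "minimal": 0.15},
}

# Within-tier shares of the named regimens (printed percentages, renormalized
# over the regimens modelled here).
_TIER_REGIMENS = {
    "non_small_cell_lung": {"high": {"CDDP+pemetrexed": 35.3, "NP": 35.6},
                            "moderate": {"TC": 48.8},
                            "low": {"UFT": 53.0, "pemetrexed": 38.6},
                            "minimal": {"gefitinib": 49.6, "erlotinib": 30.4}},
    "colorectal": {"high": {"FOLFOXIRI": 30.2},
                   "moderate": {"CAPOX": 58.7, "FOLFOX": 22.1},
                   "low": {"capecitabine": 38.5, "UFT+LV": 36.5},
                   "minimal": {"panitumumab": 17.9, "regorafenib": 14.9}},
    "breast": {"high": {"FEC": 43.1, "EC": 31.9, "AC": 24.6},
               "moderate": {"TC-breast": 85.8},
               "low": {"PTX": 35.0, "trastuzumab+PTX": 17.0, "DTX": 12.9},
               "minimal": {"trastuzumab": 74.7}},
    "gastric": {"high": {"S-1+CDDP": 64.4, "Cape+CDDP": 17.7},
                "moderate": {"SOX": 68.4},
                "low": {"S-1": 88.7},
                "minimal": {"nivolumab": 3.9, "ramucirumab": 3.6}},
    "malignant_lymphoma": {"high": {"CHOP": 42.0, "R-CHOP": 42.1},
                           "moderate": {"CPM": 65.1, "oral etoposide": 10.0}},
    "pancreatic": {"high": {"FOLFIRINOX": 79.8},
                   "moderate": {"GEM+nab-PTX": 80.0, "GS": 11.3},
                   "low": {"S-1": 69.6, "GEM": 29.2}},
    "oesophageal": {"high": {"FP": 77.5, "DCF": 17.6},
                    "moderate": {"nedaplatin+5-FU": 63.8},
                    "low": {"DTX": 12.4, "S-1": 50.0}},
    "small_cell_lung": {"high": {"PE": 69.0, "PI": 30.3},
                        "moderate": {"CBDCA+etoposide": 88.8, "CBDCA+CPT11": 5.8},
                        "low": {"CPT11": 41.3}},
    "other": {"high": {"FP": 50.0, "AC": 50.0},
              "moderate": {"TC": 60.0, "FOLFOX": 40.0},
              "low": {"S-1": 50.0, "DTX": 30.0, "GEM": 20.0},
              "minimal": {"trastuzumab": 50.0, "nivolumab": 50.0}},
}

# Prophylaxis-category rates (percent) by route group x risk tier, renormalized
# to distributions at config-build time.
_PROPHYLAXIS_RATES = {
    ("intravenous_group", "high"): {"triple": 70.7, "serotonin_plus_dex": 24.7,
                                    "serotonin_only": 1.8, "dex_only": 0.5,
                                    "none_of_above": 1.2},
    ("intravenous_group", "moderate"): {"triple": 24.0, "serotonin_plus_dex": 59.1,
                                        "serotonin_only": 3.7, "dex_only": 2.7,
                                        "none_of_above": 8.6},
    ("intravenous_group", "low"): {"triple": 2.1, "serotonin_plus_dex": 31.6,
                                   "serotonin_only": 4.7, "dex_only": 46.9,
                                   "none_of_above": 13.3},
    ("intravenous_group", "minimal"): {"triple": 0.2, "serotonin_plus_dex": 5.0,
                                       "serotonin_only": 0.9, "dex_only": 30.0,
                                       "none_of_above": 63.1},
    ("oral_group", "high"): {"triple": 4.6, "serotonin_plus_dex": 34.9,
                             "serotonin_only": 10.5, "dex_only": 16.4,
                             "none_of_above": 32.9},
    ("oral_group", "moderate"): {"triple": 0.05, "serotonin_plus_dex": 10.6,
                                 "serotonin_only": 13.7, "dex_only": 10.6,
                                 "none_of_above": 64.6},
    ("oral_group", "low"): {"triple": 0.4, "serotonin_plus_dex": 0.8,
                            "serotonin_only": 0.6, "dex_only": 3.6,
                            "none_of_above": 93.8},
    ("oral_group", "minimal"): {"triple": 0.02, "serotonin_plus_dex": 0.1,
                                "serotonin_only": 0.2, "dex_only": 2.6,
                                "none_of_above": 96.8},
}

_CANCER_MIX = {
    "non_small_cell_lung": 0.141, "colorectal": 0.129, "breast": 0.099,
    "gastric": 0.093, "malignant_lymphoma": 0.080, "pancreatic": 0.064,
    "oesophageal": 0.043, "small_cell_lung": 0.025, "other": 0.326,
}


def _normalize(vec: dict[str, float]) -> dict[str, float]:
    total = sum(vec.values())
    out = {k: v / total for k, v in vec.items()}
    # absorb float residue into the largest entry so the vector sums exactly to 1
    key = max(out, key=out.get)
    out[key] += 1.0 - sum(out.values())
    return out


def default_config(n_patients: int = 20_000, **overrides) -> SimulationConfig:
    """The study-default simulation configuration.

    Cancer-type marginals, per-cancer regimen mixtures and prophylaxis-category
    rates follow the published 2016 audit tables (within-tier regimen shares
    renormalized over the regimens modelled here); keyword overrides replace
    whole fields.
    """
    regimen_mix: dict[str, dict[str, float]] = {}
    for cancer, tiers in _TIER_REGIMENS.items():
        weights: dict[str, float] = {}
        for tier, regs in tiers.items():
            tier_share = _RISK_SHARES[cancer].get(tier, 0.0)
            if tier_share == 0.0 or not regs:
                continue
            reg_total = sum(regs.values())
            for name, w in regs.items():
                weights[name] = weights.get(name, 0.0) + tier_share * w / reg_total
        regimen_mix[cancer] = _normalize(weights)
    prophylaxis_probs = {
        name: _normalize(dict(_PROPHYLAXIS_RATES[(spec.route_group, spec.risk)]))
        for name, spec in REGIMEN_LIBRARY.items()}
    params = dict(
        n_patients=n_patients,
        cancer_mix=_normalize(dict(_CANCER_MIX)),
        regimen_mix=regimen_mix,
        prophylaxis_probs=prophylaxis_probs,
        timing_noise=0.0,
        exclusion_rates={"interferon_alpha": 0.002,
                         "same_day_surgery_or_drainage": 0.005,
                         "arterial_route": 0.002,
                         "hsct_within_3_weeks": 0.002,
                         "under_20": 0.003},
    )
    params.update(overrides)
    return SimulationConfig(**params)


@dataclass
class SyntheticDataset:
    registry: pd.DataFrame
    claims: pd.DataFrame
    procedures: pd.DataFrame
    ground_truth: pd.DataFrame

    def write(self, out_dir) -> None:
        from pathlib import Path
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.registry.to_csv(out / "registry.csv", index=False)
        self.claims.to_csv(out / "claims.csv", index=False)
        self.procedures.to_csv(out / "procedures.csv", index=False)
        self.ground_truth.to_csv(out / "ground_truth.csv", index=False)


_ANTIEMETIC_FOR_CLASS = {"NK1": "aprepitant", "serotonin_antagonist": "granisetron",
                         "steroid": "dexamethasone"}
_CATEGORY_CLASSES = {
    "triple": ("NK1", "serotonin_antagonist", "steroid"),
    "serotonin_plus_dex": ("serotonin_antagonist", "steroid"),
    "serotonin_only": ("serotonin_antagonist",),
    "dex_only": ("steroid",),
    "none_of_above": (),
}


def _draw(rng: np.random.Generator, dist: dict[str, float]) -> str:
    keys = sorted(dist)
    return keys[rng.choice(len(keys), p=np.array([dist[k] for k in keys]))]


def generate_dataset(config: SimulationConfig, seed: int) -> SyntheticDataset:
    """Deterministically generate one linked dataset plus its truth channel."""
    rng = np.random.default_rng(seed)
    year_start = dt.date(config.diagnosis_year, 1, 1)
    registry_rows, claims_rows, truth_rows = [], [], []

    for i in range(config.n_patients):
        pid = f"P{i:06d}"
        cancer = _draw(rng, config.cancer_mix)
        regimen = REGIMEN_LIBRARY[_draw(rng, config.regimen_mix[cancer])]
        sex = "male" if rng.random() < config.male_fraction else "female"
        age = int(np.clip(round(rng.normal(config.age_mean, config.age_sd)), 20, 99))
        dx = year_start + dt.timedelta(days=int(rng.integers(0, 365)))
        start = dx + dt.timedelta(days=int(rng.integers(3, 61)))
        clinical_stage = _draw(rng, config.stage_probs)
        resected = rng.random() < config.resection_fraction
        resection_date = (start - dt.timedelta(days=int(rng.integers(20, 90)))
                          if resected else None)
        pathological_stage = _draw(rng, config.stage_probs) if resected else "unknown"

        for comp in regimen.components:
            for day in comp.days:
                claims_rows.append((pid, start + dt.timedelta(days=day - 1),
                                    comp.drug_id, comp.drug_class, comp.route,
                                    comp.dose_mg))

        # antiemetic placement on the attribution-relevant date
        category = _draw(rng, config.prophylaxis_probs[regimen.name])
        attribution_date = start
        if regimen.escalation_day is not None:
            attribution_date = start + dt.timedelta(days=regimen.escalation_day - 1)
        use_lookback = (attribution_date == start
                        and rng.random() < config.oral_lookback_fraction)
        intended: list[tuple[str, dt.date, str]] = []  # (class, date, route)
        for cls in _CATEGORY_CLASSES[category]:
            if use_lookback:
                date = start - dt.timedelta(days=int(rng.integers(1, 31)))
                intended.append((cls, date, "PO"))
            else:
                intended.append((cls, attribution_date, "IV"))
        for cls, date, route in intended:
            placed_date = date
            if config.timing_noise and rng.random() < config.timing_noise:
                placed_date = start + dt.timedelta(days=14 + int(rng.integers(0, 10)))
            claims_rows.append((pid, placed_date, _ANTIEMETIC_FOR_CLASS[cls],
                                cls, route, 10.0))

        # truth: intended antiemetic classes plus regimen steroids that land on
        # an attribution-relevant date (e.g. prednisolone inside CHOP on day 1)
        truth_classes = {cls for cls, _, _ in intended}
        for comp in regimen.components:
            if comp.drug_class == "steroid":
                dates = {start + dt.timedelta(days=d - 1) for d in comp.days}
                if start in dates or attribution_date in dates:
                    truth_classes.add("steroid")
        true_category = categorize_prophylaxis(truth_classes).value

        registry_rows.append((pid, sex, age, cancer, dx.isoformat(),
                              clinical_stage, pathological_stage,
                              resection_date.isoformat() if resection_date else "",
                              ""))
        truth_rows.append((pid, cancer, regimen.name, regimen.risk,
                           regimen.route_group, true_category, ""))

    registry = pd.DataFrame(registry_rows, columns=[
        "patient_id", "sex", "age_at_dx", "cancer_type", "dx_date",
        "clinical_stage", "pathological_stage", "resection_date", "adjuvant_flag"])
    claims = pd.DataFrame(claims_rows, columns=[
        "patient_id", "date", "drug_id", "drug_class", "route", "dose_mg"])
    claims["date"] = claims["date"].map(lambda d: d.isoformat())
    procedures = pd.DataFrame(columns=["patient_id", "date", "kind"])
    ground_truth = pd.DataFrame(truth_rows, columns=[
        "patient_id", "cancer_type", "regimen", "risk_category", "route_group",
        "prophylaxis_category", "exclusion_reasons"])
    dataset = SyntheticDataset(registry, claims, procedures, ground_truth)
    if any(config.exclusion_rates.values()):
        dataset = inject_exclusion_noise(dataset, config.exclusion_rates,
                                         seed=(seed + 1) % 2**31)
    return dataset


def inject_exclusion_noise(dataset: SyntheticDataset, rates: dict[str, float],
                           seed: int) -> SyntheticDataset:
    """Mark a random patient subset with exclusion-triggering events.

    Adds interferon-alpha course lines, same-day surgery procedures,
    arterial-route chemotherapy lines or an early stem-cell transplant, or
    rewrites the registry age below 20; the truth channel records the injected
    reasons.
    """
    for reason, rate in rates.items():
        if reason not in EXCLUSION_REASONS:
            raise ValueError(f"unknown exclusion reason {reason!r}")
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"rate for {reason} outside [0, 1]")
    rng = np.random.default_rng(seed)
    registry = dataset.registry.copy()
    truth = dataset.ground_truth.copy()
    claims_new, proc_new = [], []
    # course start per patient = earliest chemotherapy claim date
    chemo = dataset.claims[dataset.claims["drug_class"] == "chemotherapy"]
    start_by_pid = chemo.groupby("patient_id")["date"].min().to_dict()
    reasons_by_pid: dict[str, list[str]] = {}
    for pid in registry["patient_id"]:
        start_raw = start_by_pid.get(pid)
        if start_raw is None:
            continue
        start = dt.date.fromisoformat(start_raw)
        hit = [r for r in EXCLUSION_REASONS
               if rates.get(r, 0.0) and rng.random() < rates[r]]
        if not hit:
            continue
        reasons_by_pid[pid] = hit
        for reason in hit:
            if reason == "interferon_alpha":
                claims_new.append((pid, start.isoformat(), "interferon-alpha",
                                   "chemotherapy", "IV", 9.0))
            elif reason == "same_day_surgery_or_drainage":
                proc_new.append((pid, start.isoformat(), "surgery"))
            elif reason == "arterial_route":
                claims_new.append((pid, start.isoformat(), "cisplatin",
                                   "chemotherapy", "arterial", 89.0))
            elif reason == "hsct_within_3_weeks":
                proc_new.append((pid, (start + dt.timedelta(days=14)).isoformat(),
                                 "hsct"))
            elif reason == "under_20":
                registry.loc[registry["patient_id"] == pid, "age_at_dx"] = \
                    int(rng.integers(15, 20))
    claims = dataset.claims
    if claims_new:
        claims = pd.concat([claims, pd.DataFrame(claims_new, columns=claims.columns)],
                           ignore_index=True)
    procedures = dataset.procedures
    if proc_new:
        procedures = pd.concat(
            [procedures, pd.DataFrame(proc_new, columns=procedures.columns)],
            ignore_index=True)
    truth["exclusion_reasons"] = truth["patient_id"].map(
        lambda p: "|".join(reasons_by_pid.get(p, []))).fillna("")
    return SyntheticDataset(registry, claims, procedures, truth)
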