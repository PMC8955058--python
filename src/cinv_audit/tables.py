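"""Stratified proportion tables with exact binomial confidence intervals.

Output surfaces of the audit: cohort characteristics, emetic-risk distribution
by route of administration with per-agent drill-down, top regimens per cancer
type and risk category, prophylaxis categories with 95% CIs, and per-cancer
risk distributions. Percentages are presented rounded half-up to one decimal;
all arithmetic is carried at full precision. The default interval is the exact
Clopper–Pearson interval (Wilson available by configuration).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Optional

import pandas as pd
from statsmodels.stats.proportion import proportion_confint

CI_METHODS = {"clopper_pearson": "beta", "wilson": "wilson"}


def round_half_up(value: float, decimals: int = 1) -> float:
    """Decimal rounding with ties away from zero (presentation rounding)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ProportionEstimate:
    """A binomial proportion on the percent scale with its 95% CI.

    ``percent``/``ci_low``/``ci_high`` are rounded half-up to one decimal for
    presentation; the ``*_exact`` fields keep full precision.
    """

    numerator: int
    denominator: int
    percent: float
    ci_low: float
    ci_high: float
    method: str
    percent_exact: float
    ci_low_exact: float
    ci_high_exact: float

    def __str__(self) -> str:
        return f"{self.percent:.1f} ({self.ci_low:.1f}–{self.ci_high:.1f})"


def proportion_with_ci(k: int, n: int, method: str = "clopper_pearson",
                       alpha: float = 0.05) -> ProportionEstimate:
    """Exact (Clopper–Pearson) or Wilson interval for k successes out of n."""
    if n <= 0:
        raise ValueError("proportion undefined for n = 0")
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if method not in CI_METHODS:
        raise ValueError(f"method must be one of {sorted(CI_METHODS)}")
    low, high = proportion_confint(k, n, alpha=alpha, method=CI_METHODS[method])
    pct = 100.0 * k / n
    return ProportionEstimate(
        numerator=int(k), denominator=int(n),
        percent=round_half_up(pct), ci_low=round_half_up(100.0 * low),
        ci_high=round_half_up(100.0 * high), method=method,
        percent_exact=pct, ci_low_exact=100.0 * low, ci_high_exact=100.0 * high,
    )


RISK_ORDER = ["high", "moderate", "low", "minimal", "unknown"]
ROUTE_GROUPS = ["intravenous_group", "oral_group"]
PROPHYLAXIS_ORDER = ["triple", "serotonin_plus_dex", "serotonin_only",
                     "dex_only", "none_of_above"]


def _pct(k: int, n: int) -> float:
    return round_half_up(100.0 * k / n) if n else float("nan")


def risk_distribution_table(assignments: pd.DataFrame) -> pd.DataFrame:
    """Risk-category counts and percentages by route group, with drill-down.

    ``assignments`` needs columns patient_id, route_group, category and
    regimen_label. Category rows use the route-group N as denominator;
    drill-down rows (one per regimen label) use the category count within the
    route group, mirroring the two-level layout of the published distribution.
    """
    rows = []
    if assignments.empty:
        return pd.DataFrame(columns=["route_group", "category", "regimen_label",
                                     "level", "n", "denominator", "percent"])
    groups: list[tuple[str, pd.DataFrame]] = [
        (rg, assignments[assignments["route_group"] == rg]) for rg in ROUTE_GROUPS]
    groups.append(("total", assignments))
    for rg_name, sub in groups:
        n_group = len(sub)
        for cat in RISK_ORDER:
            cat_sub = sub[sub["category"] == cat]
            n_cat = len(cat_sub)
            rows.append({"route_group": rg_name, "category": cat,
                         "regimen_label": "", "level": "category",
                         "n": n_cat, "denominator": n_group,
                         "percent": _pct(n_cat, n_group)})
            if n_cat == 0:
                continue
            counts = cat_sub["regimen_label"].value_counts()
            for label, n_reg in counts.sort_index().sort_values(
                    ascending=False, kind="stable").items():
                rows.append({"route_group": rg_name, "category": cat,
                             "regimen_label": label, "level": "regimen",
                             "n": int(n_reg), "denominator": n_cat,
                             "percent": _pct(int(n_reg), n_cat)})
    return pd.DataFrame(rows)


def prophylaxis_table(profiles: pd.DataFrame, assignments: pd.DataFrame,
                      method: str = "clopper_pearson",
                      alpha: float = 0.05) -> pd.DataFrame:
    """Five prophylaxis categories per risk category × route group, with CIs.

    ``profiles`` needs patient_id and prophylaxis_category; denominators are
    the (route group × risk category) cell sizes, so each cell's five
    percentages sum to 100 up to rounding.
    """
    merged = assignments.merge(profiles[["patient_id", "prophylaxis_category"]],
                               on="patient_id", validate="one_to_one")
    rows = []
    strata: list[tuple[str, pd.DataFrame]] = [
        (rg, merged[merged["route_group"] == rg]) for rg in ROUTE_GROUPS]
    strata.append(("total", merged))
    for rg_name, sub in strata:
        for risk in RISK_ORDER:
            cell = sub[sub["category"] == risk]
            n = len(cell)
            if n == 0:
                continue
            counts = cell["prophylaxis_category"].value_counts()
            for pcat in PROPHYLAXIS_ORDER:
                k = int(counts.get(pcat, 0))
                est = proportion_with_ci(k, n, method=method, alpha=alpha)
                rows.append({"route_group": rg_name, "risk_category": risk,
                             "prophylaxis_category": pcat, "n": k,
                             "denominator": n, "percent": est.percent,
                             "ci_low": est.ci_low, "ci_high": est.ci_high,
                             "display": str(est)})
    return pd.DataFrame(rows)


def per_cancer_distribution(assignments: pd.DataFrame) -> pd.DataFrame:
    """Risk-category percentage within each cancer type (stacked-bar shape)."""
    rows = []
    for cancer, sub in assignments.groupby("cancer_type", sort=True):
        n = len(sub)
        counts = sub["category"].value_counts()
        for cat in RISK_ORDER:
            k = int(counts.get(cat, 0))
            rows.append({"cancer_type": cancer, "category": cat, "n": k,
                         "denominator": n, "percent": _pct(k, n)})
    return pd.DataFrame(rows)


def prophylaxis_per_cancer(profiles: pd.DataFrame, assignments: pd.DataFrame,
                           risk_category: str = "high") -> pd.DataFrame:
    """Prophylaxis-category percentages by cancer type within one risk tier."""
    merged = assignments.merge(profiles[["patient_id", "prophylaxis_category"]],
                               on="patient_id", validate="one_to_one")
    merged = merged[merged["category"] == risk_category]
    rows = []
    for cancer, sub in merged.groupby("cancer_type", sort=True):
        n = len(sub)
        counts = sub["prophylaxis_category"].value_counts()
        for pcat in PROPHYLAXIS_ORDER:
            k = int(counts.get(pcat, 0))
            rows.append({"cancer_type": cancer, "risk_category": risk_category,
                         "prophylaxis_category": pcat, "n": k,
                         "denominator": n, "percent": _pct(k, n)})
    return pd.DataFrame(rows)


def top_regimens(assignments: pd.DataFrame, k: int = 3) -> pd.DataFrame:
    """The k most frequent regimen labels per cancer type × risk category.

    Percentages use the (cancer, category) cell count as denominator. Ties are
    broken lexicographically on the label (deterministic).
    """
    rows = []
    for (cancer, cat), sub in assignments.groupby(["cancer_type", "category"],
                                                  sort=True):
        n_cell = len(sub)
        counts = (sub["regimen_label"].value_counts().rename_axis("label")
                  .reset_index(name="n"))
        counts = counts.sort_values(["n", "label"],
                                    ascending=[False, True], kind="stable")
        for rank, row in enumerate(counts.head(k).itertuples(index=False), 1):
            rows.append({"cancer_type": cancer, "category": cat, "rank": rank,
                         "regimen_label": row.label, "n": int(row.n),
                         "denominator": n_cell,
                         "percent": _pct(int(row.n), n_cell)})
    return pd.DataFrame(rows)


def characteristics_table(cohort_frame: pd.DataFrame) -> pd.DataFrame:
    """Cohort characteristics by route group: sex, age, cancer type, stage."""
    rows = []
    strata: list[tuple[str, pd.DataFrame]] = [
        (rg, cohort_frame[cohort_frame["route_group"] == rg])
        for rg in ROUTE_GROUPS]
    strata.append(("total", cohort_frame))
    for rg_name, sub in strata:
        n = len(sub)
        rows.append({"route_group": rg_name, "variable": "n", "levels": "",
                     "n": n, "percent": 100.0 if n else float("nan")})
        if n == 0:
            continue
        k_male = int((sub["sex"] == "male").sum())
        rows.append({"route_group": rg_name, "variable": "sex", "levels": "male",
                     "n": k_male, "percent": _pct(k_male, n)})
        rows.append({"route_group": rg_name, "variable": "age_mean", "levels": "",
                     "n": n, "percent": round_half_up(float(sub["age_at_dx"].mean()))})
        for var, order in (("cancer_type", None), ("combined_stage",
                                                   ["0", "I", "II", "III", "IV",
                                                    "unknown"])):
            counts = sub[var].value_counts()
            levels = order if order else sorted(counts.index)
            for level in levels:
                k = int(counts.get(level, 0))
                rows.append({"route_group": rg_name, "variable": var,
                             "levels": level, "n": k, "percent": _pct(k, n)})
        if sub["adjuvant"].notna().any():
            k_adj = int((sub["adjuvant"] == True).sum())  # noqa: E712 — NaN-safe
            rows.append({"route_group": rg_name, "variable": "adjuvant",
                         "levels": "true", "n": k_adj, "percent": _pct(k_adj, n)})
    return pd.DataFrame(rows)


def expected_vomiting_frequency(p_prophylaxis: float, p_vomit_with: float,
                                p_vomit_without: float) -> float:
    """Population vomiting frequency under partial prophylaxis coverage.

    A mixture of two known rates: patients covered by prophylaxis vomit at
    ``p_vomit_with``, the uncovered remainder at ``p_vomit_without``:

        p = c·p_with + (1 − c)·p_without.

    With 90% coverage, a 30% rate under prophylaxis and 90% without, the
    population frequency is 0.36 — the "approximately 35%" back-of-envelope
    for high-emetic-risk chemotherapy.
    """
    for name, val in (("p_prophylaxis", p_prophylaxis),
                      ("p_vomit_with", p_vomit_with),
                      ("p_vomit_without", p_vomit_without)):
        if not 0.0 <= val <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {val}")
    return p_prophylaxis * p_vomit_with + (1.0 - p_prophylaxis) * p_vomit_without
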