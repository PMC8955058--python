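"""First-course selection, exclusions, route grouping and stage combination."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from cinv_audit.cohort import (AuditConfig, ExclusionReason, RouteGroup,
                               apply_exclusions, assign_route_group,
                               build_cohort, combine_stage,
                               identify_first_course)

D = dt.date
START = D(2016, 3, 1)


CLAIM_COLS = ["patient_id", "date", "drug_id", "drug_class", "route", "dose_mg"]


def chemo(days, drug="cisplatin", route="IV", pid="p1", dose=100.0):
    rows = [(pid, START + dt.timedelta(days=d - 1), drug, "chemotherapy",
             route, dose) for d in days]
    return pd.DataFrame(rows, columns=CLAIM_COLS)


def record(age=60, **kw):
    base = {"patient_id": "p1", "sex": "male", "age_at_dx": age,
            "cancer_type": "other", "dx_date": D(2016, 1, 1),
            "clinical_stage": "III", "pathological_stage": "unknown",
            "resection_date": None}
    base.update(kw)
    return pd.Series(base)


EMPTY_PROC = pd.DataFrame(columns=["patient_id", "date", "kind"])


def proc(day_offset, kind):
    return pd.DataFrame([{"patient_id": "p1",
                          "date": START + dt.timedelta(days=day_offset),
                          "kind": kind}])


class TestFirstCourse:
    def test_eight_day_window_is_inclusive(self):
        """Day 8 sits inside the course; day 9 and day 30 do not."""
        course = identify_first_course(chemo([1, 8, 30]), D(2016, 1, 1))
        assert course.start_date == START
        assert sorted(course.events["date"]) == [START, START + dt.timedelta(days=7)]
        course = identify_first_course(chemo([1, 9]), D(2016, 1, 1))
        assert list(course.events["date"]) == [START]

    def test_singleton(self):
        course = identify_first_course(chemo([1]), D(2016, 1, 1))
        assert len(course.events) == 1
        assert course.end_date == START + dt.timedelta(days=7)

    def test_pre_diagnosis_chemotherapy_ignored(self):
        events = chemo([1, 40])
        course = identify_first_course(events, START + dt.timedelta(days=10))
        assert course.start_date == START + dt.timedelta(days=39)

    def test_no_chemo_returns_none(self):
        assert identify_first_course(chemo([]), D(2016, 1, 1)) is None
        assert identify_first_course(chemo([1]), D(2017, 1, 1)) is None


class TestExclusions:
    def course(self, events=None):
        return identify_first_course(events if events is not None else chemo([1]),
                                     D(2016, 1, 1))

    def test_clean_record_not_excluded(self):
        res = apply_exclusions(record(), self.course(), EMPTY_PROC, None)
        assert not res.excluded and res.reasons == frozenset()

    def test_interferon_alpha(self):
        events = pd.concat([chemo([1]), chemo([1], drug="interferon-alpha")])
        res = apply_exclusions(record(), self.course(events), EMPTY_PROC, None)
        assert res.reasons == {ExclusionReason.INTERFERON_ALPHA}

    def test_same_day_surgery_or_drainage(self):
        for kind in ("surgery", "abdominal_drainage", "pericardial_drainage"):
            res = apply_exclusions(record(), self.course(), proc(0, kind), None)
            assert ExclusionReason.SAME_DAY_SURGERY_OR_DRAINAGE in res.reasons
        res = apply_exclusions(record(), self.course(), proc(1, "surgery"), None)
        assert not res.excluded

    def test_arterial_route(self):
        res = apply_exclusions(record(), self.course(chemo([1], route="arterial")),
                               EMPTY_PROC, None)
        assert ExclusionReason.ARTERIAL_ROUTE in res.reasons

    @pytest.mark.parametrize("offset,excluded", [(20, True), (21, True),
                                                 (22, False)])
    def test_hsct_three_week_boundary(self, offset, excluded):
        """Transplant within 21 days after course chemo excludes, inclusive."""
        res = apply_exclusions(record(), self.course(), proc(offset, "hsct"), None)
        assert (ExclusionReason.HSCT_WITHIN_3_WEEKS in res.reasons) is excluded

    def test_hsct_before_chemo_ignored_unless_symmetric(self):
        res = apply_exclusions(record(), self.course(), proc(-10, "hsct"), None)
        assert not res.excluded
        res = apply_exclusions(record(), self.course(), proc(-10, "hsct"), None,
                               AuditConfig(hsct_symmetric=True))
        assert ExclusionReason.HSCT_WITHIN_3_WEEKS in res.reasons

    @pytest.mark.parametrize("age,excluded", [(19, True), (20, False)])
    def test_adult_age_threshold(self, age, excluded):
        res = apply_exclusions(record(age=age), self.course(), EMPTY_PROC, None)
        assert (ExclusionReason.UNDER_20 in res.reasons) is excluded

    def test_multiple_reasons_all_logged(self):
        events = chemo([1], route="arterial")
        res = apply_exclusions(record(age=18), self.course(events),
                               proc(0, "surgery"), None)
        assert res.reasons == {ExclusionReason.UNDER_20,
                               ExclusionReason.ARTERIAL_ROUTE,
                               ExclusionReason.SAME_DAY_SURGERY_OR_DRAINAGE}


class TestRouteGroup:
    def test_mixed_route_is_intravenous(self):
        events = pd.concat([chemo([1], drug="s-1", route="PO"),
                            chemo([8], drug="cisplatin", route="IV")])
        course = identify_first_course(events, D(2016, 1, 1))
        assert assign_route_group(course) == RouteGroup.INTRAVENOUS

    def test_oral_only(self):
        course = identify_first_course(chemo([1], drug="s-1", route="PO"),
                                       D(2016, 1, 1))
        assert assign_route_group(course) == RouteGroup.ORAL

    def test_empty_course_rejected(self):
        course = identify_first_course(chemo([1]), D(2016, 1, 1))
        course.events = course.events.iloc[0:0]
        with pytest.raises(ValueError):
            assign_route_group(course)


class TestCombinedStage:
    @pytest.mark.parametrize("clin,path,resected,expected", [
        ("III", "II", True, "II"),
        ("IV", "unknown", False, "IV"),
        ("IV", "unknown", True, "IV"),      # resected but no path data
        ("II", "III", False, "II"),         # path data ignored without resection
        ("unknown", "unknown", False, "unknown"),
    ])
    def test_pathological_takes_precedence_after_resection(
            self, clin, path, resected, expected):
        resection = D(2016, 2, 1) if resected else None
        assert combine_stage(clin, path, resection) == expected

    def test_invalid_stage_rejected(self):
        with pytest.raises(ValueError):
            combine_stage("V", "I", None)


def _toy_inputs():
    registry = pd.DataFrame([
        {"patient_id": f"p{i}", "sex": "male", "age_at_dx": 60,
         "cancer_type": "other", "dx_date": "2016-01-01",
         "clinical_stage": "III", "pathological_stage": "unknown",
         "resection_date": "", "adjuvant_flag": ""}
        for i in range(10)])
    registry.loc[registry.patient_id == "p7", "age_at_dx"] = 19
    claims = pd.concat(
        [chemo([1], pid=f"p{i}") for i in range(9)], ignore_index=True)
    claims = pd.concat([claims, chemo([1], pid="p5", drug="interferon-alpha")],
                       ignore_index=True)
    procedures = pd.DataFrame([{"patient_id": "p6", "date": START.isoformat(),
                                "kind": "surgery"}])
    return registry, claims, procedures


class TestBuildCohort:
    def test_flow_log_conservation(self):
        """Input N = retained + unique exclusions + never-treated."""
        registry, claims, procedures = _toy_inputs()
        cohort = build_cohort(registry, claims, procedures)
        flow = cohort.flow_log
        # p9 has no claims, p5 interferon, p6 same-day surgery, p7 under 20
        assert flow["input"] == 10
        assert flow["chemo_recipients"] == 9
        assert flow["excluded_unique"] == 3
        assert flow["final"] == 6
        assert flow["chemo_recipients"] == flow["excluded_unique"] + flow["final"]
        assert flow["exclusion_reasons"]["no_chemo"] == 1

    def test_order_independence(self):
        registry, claims, procedures = _toy_inputs()
        cohort1 = build_cohort(registry, claims, procedures)
        rng = np.random.default_rng(0)
        cohort2 = build_cohort(
            registry.sample(frac=1, random_state=1),
            claims.sample(frac=1, random_state=2),
            procedures, None)
        assert {m.patient_id for m in cohort1.members} == \
            {m.patient_id for m in cohort2.members}
        assert cohort1.flow_log == cohort2.flow_log

    def test_only_first_course_contributes(self):
        registry, _, _ = _toy_inputs()
        registry = registry.iloc[:1]
        claims = pd.concat([chemo([1], pid="p0"),
                            chemo([60], pid="p0", drug="carboplatin")],
                           ignore_index=True)
        cohort = build_cohort(registry, claims, EMPTY_PROC)
        assert len(cohort) == 1
        assert set(cohort.members[0].course.events["drug_id"]) == {"cisplatin"}

    def test_duplicate_patient_id_rejected(self):
        registry, claims, procedures = _toy_inputs()
        registry = pd.concat([registry, registry.iloc[:1]], ignore_index=True)
        with pytest.raises(ValueError, match="duplicate patient_id"):
            build_cohort(registry, claims, procedures)

    def test_orphan_claims_dropped_with_warning(self, caplog):
        registry, claims, procedures = _toy_inputs()
        claims = pd.concat([claims, chemo([1], pid="ghost")], ignore_index=True)
        import logging
        with caplog.at_level(logging.WARNING, logger="cinv_audit.cohort"):
            cohort = build_cohort(registry, claims, procedures)
        assert any("unknown patient_id" in r.message for r in caplog.records)
        assert cohort.flow_log["final"] == 6

    def test_diagnosis_year_filter(self):
        registry, claims, procedures = _toy_inputs()
        registry.loc[registry.patient_id == "p0", "dx_date"] = "2015-12-31"
        cohort = build_cohort(registry, claims, procedures)
        assert cohort.flow_log["diagnosis_year"] == 9
        off = build_cohort(registry, claims, procedures,
                           AuditConfig(diagnosis_year=None))
        assert off.flow_log["diagnosis_year"] == 10

    def test_empty_claims_empty_cohort(self):
        registry, _, procedures = _toy_inputs()
        claims = chemo([]).iloc[0:0]
        cohort = build_cohort(registry, claims, procedures)
        assert len(cohort) == 0
        assert cohort.flow_log["final"] == 0
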