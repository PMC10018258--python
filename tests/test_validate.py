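"""Bundle assembly and conformance validation: soundness and defect recall."""

import copy
import random

import pytest

import mimic_fhir as mf
from mimic_fhir import validate as vl
from mimic_fhir.profiles import package_from_terminology


class TestBundleAssembly:
    def test_one_bundle_per_patient(self, db, bundled):
        bundles, _ = bundled
        assert len(bundles) == len(db.tables["patients"])
        for b in bundles:
            patients = [r for r in b.entries if r.resourceType == "Patient"]
            assert len(patients) == 1 and patients[0].id == b.patient_id

    def test_shared_set_holds_unattributed_resources(self, bundled):
        _, shared = bundled
        assert {r.profile for r in shared} == set(vl.SHARED_PROFILES)

    def test_patient_with_no_events_still_bundles(self, resources):
        patient = resources["MimicPatient"][0]
        b = vl.bundle_patient([patient], patient.id)
        assert len(b.entries) == 1

    def test_missing_patient_resource_is_an_error(self, resources):
        enc = resources["MimicEncounter"][0]
        with pytest.raises(ValueError, match="no Patient resource"):
            vl.bundle_patient([enc], "not-a-patient-id")

    def test_foreign_entry_rejected_at_construction(self, resources):
        p0, p1 = resources["MimicPatient"][:2]
        enc_of_p1 = next(
            r for r in resources["MimicEncounter"]
            if r.body["subject"]["reference"] == f"Patient/{p1.id}")
        with pytest.raises(ValueError, match="belongs to"):
            vl.bundle_patient([p0, enc_of_p1], p0.id)


class TestCleanBaseline:
    def test_clean_cohort_validates_with_zero_issues(self, bundled, pkg):
        bundles, shared = bundled
        issues, summary = vl.validate_cohort(bundles, pkg, shared)
        assert issues == []
        assert summary.n_errors == 0

    @pytest.mark.parametrize("seed", [2, 9])
    def test_soundness_across_seeds(self, seed):
        db = mf.generate_cohort(mf.CohortConfig(n_patients=10, seed=seed))
        pkg = package_from_terminology(db.terminology)
        res, _ = mf.transform_cohort(db, pkg)
        bundles, shared = mf.bundle_cohort(res)
        issues, _ = vl.validate_cohort(bundles, pkg, shared)
        assert issues == []

    def test_bundle_order_does_not_change_the_summary(self, bundled, pkg):
        bundles, shared = bundled
        _, forward = vl.validate_cohort(bundles, pkg, shared)
        shuffled = list(bundles)
        random.Random(1).shuffle(shuffled)
        issues_a, backward = vl.validate_cohort(shuffled, pkg, shared)
        issues_b, _ = vl.validate_cohort(list(reversed(bundles)), pkg, shared)
        assert forward == backward
        assert issues_a == issues_b

    def test_per_bundle_results_independent_of_partitioning(self, bundled, pkg):
        # embarrassingly parallel: cohort result == union of single-bundle runs
        bundles, shared = bundled
        union = []
        for b in bundles[:5]:
            union.extend(vl.validate_bundle(b, pkg, shared))
        cohort_issues, _ = vl.validate_cohort(bundles[:5], pkg, shared)
        assert sorted(union, key=lambda i: (i.resource_id, i.path, i.message)) == [
            i for i in cohort_issues]


class TestSingleResourceChecks:
    def test_conformant_patient_yields_no_issues(self, resources, pkg):
        assert vl.validate_resource(resources["MimicPatient"][0], pkg) == []

    def test_missing_required_status_is_a_cardinality_error(self, resources, pkg):
        r = copy.deepcopy(resources["MimicObservationChartevents"][0])
        del r.body["status"]
        issues = vl.validate_resource(r, pkg)
        assert [(i.category, i.path) for i in issues] == [("cardinality", "status")]

    def test_specimen_type_outside_shared_valueset_is_a_binding_error(
            self, resources, pkg):
        r = copy.deepcopy(resources["MimicSpecimen"][0])
        r.body["type"]["coding"][0]["code"] = "NOT-A-SPECIMEN"
        issues = vl.validate_resource(r, pkg)
        assert [i.category for i in issues] == ["binding"]
        assert issues[0].severity == "error"

    def test_fixed_value_violation_is_a_structure_error(self, resources, pkg):
        r = copy.deepcopy(resources["MimicMedicationRequest"][0])
        r.body["intent"] = "plan"
        assert [i.category for i in vl.validate_resource(r, pkg)] == ["structure"]

    def test_malformed_datetime_is_a_datatype_error(self, resources, pkg):
        r = copy.deepcopy(resources["MimicObservationChartevents"][0])
        r.body["effectiveDateTime"] = "03/01/2100 10:00"
        assert [i.category for i in vl.validate_resource(r, pkg)] == ["datatype"]

    def test_unknown_profile_is_an_error(self, resources, pkg):
        r = copy.deepcopy(resources["MimicPatient"][0])
        r.profile = "MimicNothing"
        with pytest.raises(KeyError):
            vl.validate_resource(r, pkg)


class TestReferences:
    def test_defect_free_bundle_has_no_reference_issues(self, bundled):
        bundles, shared = bundled
        assert vl.check_references(bundles[0], shared) == []

    def test_reference_to_shared_organization_resolves(self, bundled, resources):
        bundles, shared = bundled
        without_shared = vl.check_references(bundles[0], [])
        assert any("Organization/" in i.message for i in without_shared)

    def test_each_dangling_reference_is_reported(self, bundled, pkg):
        bundles, shared = bundled
        b = copy.deepcopy(bundles[0])
        victims = [r for r in b.entries if r.resourceType == "Observation"][:3]
        assert len(victims) == 3
        for v in victims:
            v.body["encounter"]["reference"] = f"Encounter/{v.id}"
        issues = vl.check_references(b, shared)
        assert len(issues) == 3
        assert {i.resource_id for i in issues} == {v.id for v in victims}


@pytest.fixture(scope="module")
def defect_run(db, pkg):
    spec = mf.DefectSpec(code_outside_valueset=5, dangling_reference=3,
                         missing_required_element=2)
    bad, ledger = mf.inject_defects(db, spec, seed=17)
    res, _ = mf.transform_cohort(bad, pkg)
    bundles, shared = mf.bundle_cohort(res)
    issues, summary = vl.validate_cohort(bundles, pkg, shared)
    return ledger, issues, summary


class TestDefectRecall:
    def test_every_ledger_entry_yields_a_matching_issue(self, defect_run):
        ledger, issues, _ = defect_run
        for rec in ledger:
            assert any(i.resource_id == rec.resource_id
                       and i.category == rec.expected_issue_class
                       for i in issues), rec

    def test_no_issues_on_untouched_resources(self, defect_run):
        ledger, issues, _ = defect_run
        touched = {rec.resource_id for rec in ledger}
        assert {i.resource_id for i in issues} <= touched

    def test_issue_classes_cover_all_injected_classes(self, defect_run):
        _, _, summary = defect_run
        assert summary.by_class["binding"] >= 5
        assert summary.by_class["reference"] >= 3
        assert summary.by_class["cardinality"] >= 2

    def test_duplicate_resource_defect_reported_as_cardinality(self, db, pkg):
        bad, ledger = mf.inject_defects(
            db, mf.DefectSpec(cardinality_violation=2), seed=23)
        res, _ = mf.transform_cohort(bad, pkg)
        bundles, shared = mf.bundle_cohort(res)
        issues, _ = vl.validate_cohort(bundles, pkg, shared)
        assert {i.resource_id for i in issues} == {r.resource_id for r in ledger}
        assert all(i.category == "cardinality" for i in issues)


def test_operation_outcome_shape(resources, pkg):
    r = copy.deepcopy(resources["MimicSpecimen"][0])
    del r.body["type"]
    issues = vl.validate_resource(r, pkg)
    oo = vl.issues_to_operation_outcome(issues)
    assert oo["resourceType"] == "OperationOutcome"
    assert len(oo["issue"]) == len(issues)
    assert oo["issue"][0]["severity"] == "error"
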