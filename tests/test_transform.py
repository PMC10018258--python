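"""Row-to-resource mapping: identity, aggregations, coverage, determinism."""

import numpy as np
import pandas as pd
import pytest

import mimic_fhir as mf
from mimic_fhir import transform as tf
from mimic_fhir.profiles import package_from_terminology

from conftest import make_micro_db


class TestAssignId:
    def test_deterministic_and_distinct(self):
        a = tf.assign_id("Patient", (42,))
        assert a == tf.assign_id("Patient", (42,))
        assert a != tf.assign_id("Patient", (43,))
        assert a != tf.assign_id("Encounter", (42,))

    def test_null_key_component_is_an_error(self):
        with pytest.raises(ValueError, match="null key"):
            tf.assign_id("Patient", (None,))
        with pytest.raises(ValueError, match="null key"):
            tf.assign_id("Patient", (1, pd.NA))

    def test_collision_scan_over_random_key_tuples(self):
        rng = np.random.default_rng(0)
        keys = {tuple(rng.integers(0, 10**9, size=3)) for _ in range(10_000)}
        ids = {tf.assign_id("Observation", k) for k in keys}
        assert len(ids) == len(keys)


class TestPatients:
    def test_one_resource_per_patient_row(self, db, resources):
        patients = resources["MimicPatient"]
        assert len(patients) == len(db.tables["patients"])
        profile_urls = {p for r in patients for p in r.body["meta"]["profile"]}
        assert len(profile_urls) == 1 and "MimicPatient" in profile_urls.pop()

    def test_demographics_and_extension_mapped(self, db, resources):
        row = db.tables["patients"].iloc[0]
        rid = tf.assign_id("Patient", (int(row["subject_id"]),))
        body = next(r.body for r in resources["MimicPatient"] if r.id == rid)
        assert body["gender"] in ("male", "female")
        assert body["birthDate"] == f"{int(row['anchor_year']) - int(row['anchor_age'])}-01-01"
        assert body["extension"][0]["valueString"] == row["anchor_year_group"]

    def test_duplicate_subject_id_is_an_error(self, db, pkg):
        broken = db.copy()
        broken.tables["patients"] = pd.concat(
            [broken.tables["patients"]] * 2, ignore_index=True)
        with pytest.raises(ValueError, match="duplicate subject_id"):
            mf.transform_cohort(broken, pkg)


class TestEncounters:
    def test_one_encounter_per_admission_icustay_edstay(self, db, resources):
        t = db.tables
        expected = len(t["admissions"]) + len(t["icustays"]) + len(t["edstays"])
        assert len(resources["MimicEncounter"]) == expected

    def test_icu_part_of_resolves_to_hospital_encounter(self, db, resources):
        by_id = {r.id: r.body for r in resources["MimicEncounter"]}
        for _, stay in db.tables["icustays"].iterrows():
            icu = by_id[tf.assign_id("Encounter", ("ICU", int(stay["stay_id"])))]
            parent = icu["partOf"]["reference"].split("/", 1)[1]
            assert parent == tf.assign_id("Encounter", (int(stay["hadm_id"]),))
            assert by_id[parent]["period"]["start"] <= icu["period"]["start"]

    def test_location_entries_match_transfer_row_count(self, db, resources):
        # row-count oracle: entries per encounter = admit/transfer rows with a unit
        tr = db.tables["transfers"]
        oracle = tr[tr["eventtype"].isin(["admit", "transfer"])
                    & tr["careunit"].notna()].groupby("hadm_id").size()
        by_id = {r.id: r.body for r in resources["MimicEncounter"]}
        for hadm, expected in oracle.items():
            body = by_id[tf.assign_id("Encounter", (int(hadm),))]
            assert len(body["location"]) == expected

    def test_unknown_admission_for_icustay_is_an_error(self, db, pkg):
        broken = db.copy()
        icu = broken.tables["icustays"].copy()
        icu.loc[icu.index[0], "hadm_id"] = 1
        broken.tables["icustays"] = icu
        with pytest.raises(ValueError, match="unknown admission"):
            mf.transform_cohort(broken, pkg)


def test_locations_collapse_to_distinct_units_plus_one_organization(db, resources):
    distinct = db.terminology["careunit"]["code"].nunique()
    assert len(resources["MimicLocation"]) == distinct
    assert len(resources["MimicOrganization"]) == 1
    org_id = resources["MimicOrganization"][0].id
    for loc in resources["MimicLocation"]:
        assert loc.body["managingOrganization"]["reference"] == f"Organization/{org_id}"


class TestOrders:
    def test_one_condition_per_diagnosis_row(self, db, resources):
        assert len(resources["MimicCondition"]) == len(db.tables["diagnoses"])

    def test_source_table_determines_procedure_profile(self, db, resources):
        assert len(resources["MimicProcedure"]) == len(db.tables["procedures_hosp"])
        assert len(resources["MimicProcedureICU"]) == len(db.tables["procedureevents"])
        assert len(resources["MimicProcedureED"]) == len(db.tables["ed_procedures"])
        for r in resources["MimicProcedureICU"]:
            assert "MimicProcedureICU" in r.body["meta"]["profile"][0]


class TestLab:
    def test_one_observation_per_row_one_specimen_per_distinct_id(self, db, resources):
        labs = db.tables["labevents"]
        assert len(resources["MimicObservationLabevents"]) == len(labs)
        # distinct-specimen oracle (lab + micro specimens share the profile)
        expected = labs["specimen_id"].nunique() + \
            db.tables["microbiologyevents"]["micro_specimen_id"].nunique()
        assert len(resources["MimicSpecimen"]) == expected

    def test_specimen_references_resolve(self, resources):
        specimen_ids = {r.id for r in resources["MimicSpecimen"]}
        for obs in resources["MimicObservationLabevents"]:
            assert obs.body["specimen"]["reference"].split("/", 1)[1] in specimen_ids

    def test_numeric_results_become_quantities(self, db, resources):
        labs = db.tables["labevents"]
        n_quantity = int(labs["valuenum"].notna().sum())
        got = sum("valueQuantity" in r.body for r in resources["MimicObservationLabevents"])
        assert got == n_quantity

    def test_fully_null_results_carry_data_absent_reason(self, db, resources):
        labs = db.tables["labevents"]
        n_absent = int((labs["valuenum"].isna() & labs["value"].isna()).sum())
        got = [r for r in resources["MimicObservationLabevents"]
               if "dataAbsentReason" in r.body]
        assert len(got) == n_absent
        for r in got:
            assert "valueQuantity" not in r.body and "valueString" not in r.body


class TestMicroHierarchy:
    def test_one_test_two_organisms_three_antibiotics_each(self):
        """1 test, 2 organisms, 3 antibiotics each -> 1 + 2 + 6 resources."""
        rows = []
        for org in ("80002", "80004"):
            for ab in ("90004", "90005", "90007"):
                rows.append({"micro_specimen_id": 1, "spec_type_desc": "URINE",
                             "test_itemid": "90039", "org_itemid": org,
                             "ab_itemid": ab, "interpretation": "S"})
        db = make_micro_db(rows)
        pkg = package_from_terminology(db.terminology)
        res, _ = mf.transform_cohort(db, pkg)
        assert len(res["MimicObservationMicroTest"]) == 1
        assert len(res["MimicObservationMicroOrg"]) == 2
        assert len(res["MimicObservationMicroSusc"]) == 6

    def test_no_growth_culture_yields_single_test(self):
        db = make_micro_db([{
            "micro_specimen_id": 1, "spec_type_desc": "SWAB",
            "test_itemid": "90100", "org_itemid": None,
            "ab_itemid": None, "interpretation": None}])
        pkg = package_from_terminology(db.terminology)
        res, _ = mf.transform_cohort(db, pkg)
        assert len(res["MimicObservationMicroTest"]) == 1
        assert len(res["MimicObservationMicroOrg"]) == 0
        assert len(res["MimicObservationMicroSusc"]) == 0

    def test_hierarchy_links_resolve(self, resources):
        tests = {r.id for r in resources["MimicObservationMicroTest"]}
        orgs = {r.id for r in resources["MimicObservationMicroOrg"]}
        for org in resources["MimicObservationMicroOrg"]:
            assert org.body["derivedFrom"][0]["reference"].split("/")[1] in tests
        for susc in resources["MimicObservationMicroSusc"]:
            assert susc.body["derivedFrom"][0]["reference"].split("/")[1] in orgs
        member_targets = {
            ref["reference"].split("/")[1]
            for r in resources["MimicObservationMicroTest"]
            for ref in r.body.get("hasMember", [])}
        assert member_targets == orgs

    def test_counts_equal_nested_groupby_oracle(self, db, resources):
        micro = db.tables["microbiologyevents"]
        tests = micro.groupby(["micro_specimen_id", "test_itemid"]).ngroups
        orgs = micro.dropna(subset=["org_itemid"]).groupby(
            ["micro_specimen_id", "test_itemid", "org_itemid"]).ngroups
        suscs = int(micro["ab_itemid"].notna().sum())
        assert len(resources["MimicObservationMicroTest"]) == tests
        assert len(resources["MimicObservationMicroOrg"]) == orgs
        assert len(resources["MimicObservationMicroSusc"]) == suscs

    def test_susceptibility_without_organism_recorded_as_error(self):
        db = make_micro_db([{
            "micro_specimen_id": 1, "spec_type_desc": "URINE",
            "test_itemid": "90039", "org_itemid": None,
            "ab_itemid": "90004", "interpretation": "S"}])
        pkg = package_from_terminology(db.terminology)
        _, report = mf.transform_cohort(db, pkg)
        assert any("without an organism" in e for e in report.errors)


class TestCharted:
    def test_one_resource_per_narrow_row(self, db, resources):
        t = db.tables
        assert len(resources["MimicObservationChartevents"]) == len(t["chartevents"])
        assert len(resources["MimicObservationDatetimeevents"]) == len(t["datetimeevents"])
        assert len(resources["MimicObservationOutputevents"]) == len(t["outputevents"])

    def test_vitals_unpivot_matches_nonnull_cell_oracle(self, db, resources):
        vs = db.tables["ed_vitalsign"]
        numeric = ["temperature", "heartrate", "resprate", "o2sat", "sbp", "dbp"]
        assert len(resources["MimicObservationVitalSigns"]) == \
            int(vs[numeric].notna().sum().sum())
        assert len(resources["MimicObservationED"]) == \
            int(vs[["rhythm", "pain"]].notna().sum().sum())

    def test_datetime_events_carry_datetime_values(self, resources):
        for r in resources["MimicObservationDatetimeevents"]:
            assert "valueDateTime" in r.body
            assert "valueQuantity" not in r.body


class TestMedications:
    def test_chain_resources_one_per_source_row(self, db, resources):
        t = db.tables
        assert len(resources["MimicMedicationRequest"]) == len(t["prescriptions"])
        assert len(resources["MimicMedicationDispense"]) == len(t["pharmacy"])
        assert len(resources["MimicMedicationAdministration"]) == len(t["emar"])
        assert len(resources["MimicMedicationAdministrationICU"]) == len(t["inputevents"])
        assert len(resources["MimicMedicationDispenseED"]) == len(t["ed_pyxis"])
        assert len(resources["MimicMedicationStatementED"]) == len(t["ed_medrecon"])

    def test_catalog_deduplicates_formulations(self, db, resources):
        # distinct-formulation oracle across every medication source column
        t = db.tables
        distinct = set(t["prescriptions"]["drug"].dropna()) \
            | set(t["pharmacy"]["medication"].dropna()) \
            | set(t["emar"]["medication"].dropna()) \
            | set(t["inputevents"]["itemid"].dropna()) \
            | set(t["ed_pyxis"]["name"].dropna()) \
            | set(t["ed_medrecon"]["name"].dropna())
        assert len(resources["MimicMedication"]) == len(distinct)

    def test_linked_administrations_reference_their_request(self, db, resources):
        emar = db.tables["emar"]
        linked = emar[emar["pharmacy_id"].notna()]
        request_ids = {r.id for r in resources["MimicMedicationRequest"]}
        by_id = {r.id: r.body for r in resources["MimicMedicationAdministration"]}
        for _, row in linked.iterrows():
            body = by_id[tf.assign_id("MedicationAdministration", (str(row["emar_id"]),))]
            assert body["request"]["reference"].split("/")[1] in request_ids
        stray = emar[emar["pharmacy_id"].isna()]
        for _, row in stray.iterrows():
            body = by_id[tf.assign_id("MedicationAdministration", (str(row["emar_id"]),))]
            assert "request" not in body  # stands alone


class TestStatusImputation:
    def test_null_becomes_unknown(self):
        report = tf.MappingReport()
        out = tf.impute_status({}, None, tf.MEDADMIN_STATUSES, report=report)
        assert out["status"] == "unknown"
        assert report.statuses_imputed == 1

    def test_known_raw_status_maps_through(self):
        out = tf.impute_status({}, "Administered", tf.MEDADMIN_STATUSES,
                               mapping=tf.EMAR_STATUS_MAP)
        assert out["status"] == "completed"
        assert tf.impute_status({}, "completed", tf.MEDADMIN_STATUSES)["status"] == "completed"

    def test_illegal_status_is_an_error(self):
        with pytest.raises(ValueError, match="bogus-status"):
            tf.impute_status({}, "bogus-status", tf.MEDADMIN_STATUSES)

    def test_imputation_count_matches_null_sources(self, db, report):
        t = db.tables
        expected = int(t["emar"]["event_txt"].isna().sum()) \
            + int(t["inputevents"]["statusdescription"].isna().sum()) \
            + int(t["prescriptions"]["status"].isna().sum()) \
            + int(t["pharmacy"]["status"].isna().sum()) \
            + len(t["ed_medrecon"])  # reconciliation carries no source status
        assert report.statuses_imputed == expected


class TestReportAndDeterminism:
    def test_rows_read_equals_table_sizes(self, db, report):
        assert report.rows_read == {n: len(df) for n, df in db.tables.items()}

    def test_dropped_field_ledger_is_empty(self, report):
        assert report.dropped_fields == {}

    def test_field_coverage_is_complete(self, db, report):
        assert tf.field_coverage(db, report) == 1.0

    def test_transform_is_a_pure_function_of_inputs(self, db, pkg, resources):
        again, _ = mf.transform_cohort(db, pkg)
        for profile in resources:
            assert [r.body for r in resources[profile]] == \
                [r.body for r in again[profile]]

    def test_nonnull_source_values_recoverable_from_resources(self, db, resources):
        """Spot audit: distinct source values reappear in the emitted elements."""
        labs = db.tables["labevents"]
        emitted = {r.body["valueQuantity"]["value"]
                   for r in resources["MimicObservationLabevents"]
                   if "valueQuantity" in r.body}
        for v in labs["valuenum"].dropna().head(50):
            assert float(v) in {float(e) for e in emitted}
        icd = {r.body["code"]["coding"][0]["code"] for r in resources["MimicCondition"]}
        assert set(db.tables["diagnoses"]["icd_code"]) == icd
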