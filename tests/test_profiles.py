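"""Conformance-package inventory, naming convention, and serialization."""

import pytest

import mimic_fhir as mf
from mimic_fhir import profiles as pf
from mimic_fhir.terminology import build_registry

TABLE1_PROFILES = {
    "MimicPatient", "MimicEncounter", "MimicLocation", "MimicOrganization",
    "MimicCondition", "MimicProcedure", "MimicProcedureED", "MimicProcedureICU",
    "MimicObservationLabevents", "MimicObservationMicroOrg",
    "MimicObservationMicroSusc", "MimicObservationMicroTest", "MimicSpecimen",
    "MimicObservationChartevents", "MimicObservationDatetimeevents",
    "MimicObservationED", "MimicObservationOutputevents",
    "MimicObservationVitalSigns", "MimicMedication",
    "MimicMedicationAdministration", "MimicMedicationAdministrationICU",
    "MimicMedicationDispense", "MimicMedicationDispenseED",
    "MimicMedicationRequest", "MimicMedicationStatementED",
}


class TestPackageInventory:
    def test_profile_names_match_published_inventory(self, pkg):
        assert set(pkg.profiles) == TABLE1_PROFILES
        assert len(pkg.profiles) == 25

    def test_artifact_counts(self, pkg):
        assert len(pkg.extensions) == 2
        assert len(pkg.terminology.codesystems) == 34
        assert len(pkg.terminology.valuesets) == 35

    def test_profiles_partition_into_six_categories(self, pkg):
        groups = pf.profiles_by_category(pkg)
        assert set(groups) == set(pf.CATEGORIES)
        assert all(groups[c] for c in groups)
        assert sorted(n for g in groups.values() for n in g) == sorted(pkg.profiles)
        assert groups["administration"] == ["MimicEncounter", "MimicPatient"]
        assert groups["organizational"] == ["MimicLocation", "MimicOrganization"]

    def test_every_binding_and_extension_resolves(self, pkg):
        for prof in pkg.profiles.values():
            for c in prof.constraints:
                if c.binding:
                    assert c.binding[0] in pkg.terminology.valuesets, (prof.name, c.path)
        ext_urls = {e.url for e in pkg.extensions}
        for prof in pkg.profiles.values():
            assert set(prof.extensions) <= ext_urls
        for ext in pkg.extensions:
            assert ext.context[0] in pkg.profiles

    def test_missing_valueset_fails_with_profile_and_path(self, db):
        plan = [row for row in pf.VALUESET_PLAN if row[0] != "lab-items"]
        reg = build_registry(
            {n: db.terminology[n] for n in pf.CODESYSTEM_NAMES}, plan)
        with pytest.raises(KeyError, match="MimicObservationLabevents.*code"):
            pf.build_package(reg)

    def test_specimen_valueset_spans_lab_and_micro_systems(self, pkg):
        from mimic_fhir.terminology import valueset_url, codesystem_url
        vs = pkg.terminology.valuesets[valueset_url("specimen-type")]
        assert {i.system for i in vs.includes} == {
            codesystem_url("lab-fluid"), codesystem_url("spec-type-desc")}


@pytest.mark.parametrize("name,ok", [
    ("MimicObservationMicroSusc", True),
    ("MimicPatient", True),
    ("MimicMedicationAdministrationICU", True),
    ("PatientMimic", False),
    ("MimicFoo", False),          # Foo is not an R4 resource
    ("Mimicpatient", False),
    ("MimicObservationmicro", False),  # context must be CamelCase
    ("Mimic", False),
])
def test_profile_naming_convention(name, ok):
    assert pf.check_profile_name(name) is ok


class TestTightenCardinality:
    def test_zero_missing_raises_min_to_one(self, pkg):
        prof = pkg.profiles["MimicPatient"]
        relaxed = pf.ProfileDef(prof.name, prof.base, prof.category, [
            pf.ElementConstraint("deceasedDateTime", min=0),
            pf.ElementConstraint("gender", min=0),
        ])
        tightened = pf.tighten_cardinality(
            relaxed, {"gender": 0, "deceasedDateTime": 3})
        assert tightened.constraint_for("gender").min == 1
        assert tightened.constraint_for("deceasedDateTime").min == 0

    def test_empty_completeness_map_is_identity(self, pkg):
        prof = pkg.profiles["MimicPatient"]
        assert pf.tighten_cardinality(prof, {}).constraints == prof.constraints

    def test_unknown_path_is_an_error(self, pkg):
        with pytest.raises(KeyError, match="not constrained"):
            pf.tighten_cardinality(pkg.profiles["MimicPatient"], {"bogus.path": 0})


class TestSerialization:
    def test_file_inventory_and_manifest(self, pkg, tmp_path):
        out = pf.serialize_package(pkg, tmp_path / "pkg")
        files = sorted(p.name for p in out.iterdir())
        # 25 profiles + 2 extensions + 34 CodeSystems + 35 ValueSets + manifest
        assert len(files) == 25 + 2 + 34 + 35 + 1
        manifest = pf.load_json(out / "package.json")
        listed = {f["filename"] for f in manifest["files"]}
        on_disk = {n for n in files if n != "package.json"}
        assert listed == on_disk
        assert len({f["url"] for f in manifest["files"]}) == len(manifest["files"])

    def test_serialize_load_serialize_is_byte_stable(self, pkg, tmp_path):
        d1 = pf.serialize_package(pkg, tmp_path / "p1")
        pkg2 = pf.load_package(d1)
        d2 = pf.serialize_package(pkg2, tmp_path / "p2")
        for p1 in sorted(d1.iterdir()):
            assert p1.read_bytes() == (d2 / p1.name).read_bytes(), p1.name

    def test_loaded_package_equals_original(self, pkg, tmp_path):
        out = pf.serialize_package(pkg, tmp_path / "pkg")
        pkg2 = pf.load_package(out)
        assert pkg2.profiles == pkg.profiles
        assert pkg2.extensions == pkg.extensions
        assert pkg2.manifest == pkg.manifest
        assert set(pkg2.terminology.codesystems) == set(pkg.terminology.codesystems)
        assert set(pkg2.terminology.valuesets) == set(pkg.terminology.valuesets)
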