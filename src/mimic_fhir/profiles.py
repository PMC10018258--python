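"""The conformance package: profiles, extensions, and their terminology plan.

A profile is a constrained view of a base FHIR R4 resource: element
cardinalities tightened to match what the source database actually
guarantees, terminology bindings pointing at the local ValueSets, and the
occasional fixed value.  Profile names follow the ``Mimic<Resource><Context>``
convention — a fixed ``Mimic`` prefix, the base R4 resource name, and an
optional CamelCase context for namespacing (e.g. ``MimicObservationMicroSusc``
is an Observation profiled for microbiology susceptibility results).

The package ships 25 profiles in six categories (administration,
organizational, orders, specimen observation, charted observation,
medication), 2 extensions, 34 CodeSystems and 35 ValueSets.  The shipped
minimum cardinalities reflect the completeness contract of the synthetic
source generator: an element whose source column is never null gets min 1;
``tighten_cardinality`` recomputes this for any other source database.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence

from .terminology import (
    DEFAULT_CANONICAL_BASE,
    TerminologyRegistry,
    codesystem_from_fhir,
    codesystem_to_fhir,
    dump_json,
    load_json,
    valueset_from_fhir,
    valueset_to_fhir,
    valueset_url,
)

PACKAGE_NAME = "mimic.fhir.synthetic"
PACKAGE_VERSION = "0.1.0"

#: All FHIR R4 resource type names (normative + trial-use), used to check the
#: Mimic<Resource><Context> naming convention.
R4_RESOURCE_NAMES = frozenset({
    "Account", "ActivityDefinition", "AdverseEvent", "AllergyIntolerance",
    "Appointment", "AppointmentResponse", "AuditEvent", "Basic", "Binary",
    "BiologicallyDerivedProduct", "BodyStructure", "Bundle",
    "CapabilityStatement", "CarePlan", "CareTeam", "CatalogEntry",
    "ChargeItem", "ChargeItemDefinition", "Claim", "ClaimResponse",
    "ClinicalImpression", "CodeSystem", "Communication",
    "CommunicationRequest", "CompartmentDefinition", "Composition",
    "ConceptMap", "Condition", "Consent", "Contract", "Coverage",
    "CoverageEligibilityRequest", "CoverageEligibilityResponse",
    "DetectedIssue", "Device", "DeviceDefinition", "DeviceMetric",
    "DeviceRequest", "DeviceUseStatement", "DiagnosticReport",
    "DocumentManifest", "DocumentReference", "EffectEvidenceSynthesis",
    "Encounter", "Endpoint", "EnrollmentRequest", "EnrollmentResponse",
    "EpisodeOfCare", "EventDefinition", "Evidence", "EvidenceVariable",
    "ExampleScenario", "ExplanationOfBenefit", "FamilyMemberHistory", "Flag",
    "Goal", "GraphDefinition", "Group", "GuidanceResponse",
    "HealthcareService", "ImagingStudy", "Immunization",
    "ImmunizationEvaluation", "ImmunizationRecommendation",
    "ImplementationGuide", "InsurancePlan", "Invoice", "Library", "Linkage",
    "List", "Location", "Measure", "MeasureReport", "Media", "Medication",
    "MedicationAdministration", "MedicationDispense", "MedicationKnowledge",
    "MedicationRequest", "MedicationStatement", "MedicinalProduct",
    "MedicinalProductAuthorization", "MedicinalProductContraindication",
    "MedicinalProductIndication", "MedicinalProductIngredient",
    "MedicinalProductInteraction", "MedicinalProductManufactured",
    "MedicinalProductPackaged", "MedicinalProductPharmaceutical",
    "MedicinalProductUndesirableEffect", "MessageDefinition", "MessageHeader",
    "MolecularSequence", "NamingSystem", "NutritionOrder", "Observation",
    "ObservationDefinition", "OperationDefinition", "OperationOutcome",
    "Organization", "OrganizationAffiliation", "Parameters", "Patient",
    "PaymentNotice", "PaymentReconciliation", "Person", "PlanDefinition",
    "Practitioner", "PractitionerRole", "Procedure", "Provenance",
    "Questionnaire", "QuestionnaireResponse", "RelatedPerson",
    "RequestGroup", "ResearchDefinition", "ResearchElementDefinition",
    "ResearchStudy", "ResearchSubject", "RiskAssessment",
    "RiskEvidenceSynthesis", "Schedule", "SearchParameter",
    "ServiceRequest", "Slot", "Specimen", "SpecimenDefinition",
    "StructureDefinition", "StructureMap", "Subscription", "Substance",
    "SubstanceNucleicAcid", "SubstancePolymer", "SubstanceProtein",
    "SubstanceReferenceInformation", "SubstanceSourceMaterial",
    "SubstanceSpecification", "SupplyDelivery", "SupplyRequest", "Task",
    "TerminologyCapabilities", "TestReport", "TestScript", "ValueSet",
    "VerificationResult", "VisionPrescription",
})

CATEGORIES = (
    "administration", "organizational", "orders",
    "specimen observation", "charted observation", "medication",
)

#: The 34 local vocabularies.  One terminology table (code, display) per name.
CODESYSTEM_NAMES = (
    # encounters / locations
    "admission-class", "admission-type", "admission-type-icu",
    "admission-location", "discharge-disposition",
    "ed-arrival-transport", "ed-disposition", "careunit",
    # diagnoses / procedures
    "diagnosis-icd9", "diagnosis-icd10", "procedure-icd9", "procedure-icd10",
    "procedure-ed", "procedureevents-items",
    # laboratory
    "d-labitems", "lab-fluid", "lab-flags", "lab-priority", "units",
    # microbiology
    "microbiology-test", "microbiology-organism", "microbiology-antibiotic",
    "microbiology-interpretation", "spec-type-desc",
    # charted events
    "chartevents-items", "datetimeevents-items", "outputevents-items",
    "vitalsign-ed", "observation-ed",
    # medications
    "medication-name", "medication-ndc", "medication-route",
    "medication-frequency", "medadmin-category-icu",
)

#: The 35 ValueSets: (name, [codesystem names], subset-or-None).  Seven compose
#: multiple CodeSystems — notably ``specimen-type``, which binds both the
#: laboratory and the microbiology specimen vocabularies so one ValueSet can
#: constrain Specimen.type for specimens referenced from either side.  The
#: rest encompass their entire parent CodeSystem.
VALUESET_PLAN: tuple[tuple[str, tuple[str, ...], None], ...] = tuple(
    (name, systems, None) for name, systems in [
        # multi-system compositions
        ("admission-type", ("admission-type", "admission-type-icu")),
        ("admit-source", ("admission-location", "ed-arrival-transport")),
        ("discharge-disposition", ("discharge-disposition", "ed-disposition")),
        ("specimen-type", ("lab-fluid", "spec-type-desc")),
        ("diagnosis-icd", ("diagnosis-icd9", "diagnosis-icd10")),
        ("procedure-icd", ("procedure-icd9", "procedure-icd10")),
        ("medication-code", ("medication-name", "medication-ndc")),
        # full-parent companions
        ("admission-class", ("admission-class",)),
        ("admission-type-icu", ("admission-type-icu",)),
        ("ed-arrival-transport", ("ed-arrival-transport",)),
        ("ed-disposition", ("ed-disposition",)),
        ("careunit", ("careunit",)),
        ("diagnosis-icd10", ("diagnosis-icd10",)),
        ("procedure-ed", ("procedure-ed",)),
        ("procedureevents-items", ("procedureevents-items",)),
        ("lab-items", ("d-labitems",)),
        ("lab-fluid", ("lab-fluid",)),
        ("lab-flags", ("lab-flags",)),
        ("lab-priority", ("lab-priority",)),
        ("units", ("units",)),
        ("microbiology-test", ("microbiology-test",)),
        ("microbiology-organism", ("microbiology-organism",)),
        ("microbiology-antibiotic", ("microbiology-antibiotic",)),
        ("microbiology-interpretation", ("microbiology-interpretation",)),
        ("spec-type-desc", ("spec-type-desc",)),
        ("chartevents-items", ("chartevents-items",)),
        ("datetimeevents-items", ("datetimeevents-items",)),
        ("outputevents-items", ("outputevents-items",)),
        ("vitalsign-ed", ("vitalsign-ed",)),
        ("observation-ed", ("observation-ed",)),
        ("medication-name", ("medication-name",)),
        ("medication-ndc", ("medication-ndc",)),
        ("medication-route", ("medication-route",)),
        ("medication-frequency", ("medication-frequency",)),
        ("medadmin-category-icu", ("medadmin-category-icu",)),
    ]
)


# ---------------------------------------------------------------------------
# Definition types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ElementConstraint:
    """Constraint on one dotted element path of the base resource."""

    path: str
    min: int = 0
    max: str = "1"            # "1" or "*"
    binding: Optional[tuple[str, str]] = None  # (valueset-url, strength)
    fixed: Optional[str] = None                # fixedCode value

    def __post_init__(self) -> None:
        if self.max not in ("0", "1", "*"):
            raise ValueError(f"max cardinality must be '0', '1' or '*', got {self.max!r}")
        if self.max != "*" and self.min > int(self.max):
            raise ValueError(f"{self.path}: min {self.min} exceeds max {self.max}")
        if self.binding is not None and self.binding[1] not in (
            "required", "extensible", "preferred", "example"
        ):
            raise ValueError(f"{self.path}: bad binding strength {self.binding[1]!r}")


@dataclass(frozen=True)
class ExtensionDef:
    """A custom element attached where the base resource has no home for it."""

    url: str
    name: str
    context: tuple[str, str]   # (resource name, element path; "" = root)
    value_type: str            # FHIR datatype of value[x]
    min: int = 0
    max: str = "1"


@dataclass
class ProfileDef:
    name: str
    base: str
    category: str
    constraints: list[ElementConstraint] = field(default_factory=list)
    extensions: list[str] = field(default_factory=list)  # extension urls

    def __post_init__(self) -> None:
        if not check_profile_name(self.name):
            raise ValueError(f"profile name {self.name!r} violates MimicResourceContext pattern")
        if self.base not in R4_RESOURCE_NAMES:
            raise ValueError(f"unknown base resource {self.base!r}")
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")

    def constraint_for(self, path: str) -> Optional[ElementConstraint]:
        for c in self.constraints:
            if c.path == path:
                return c
        return None


@dataclass
class ConformancePackage:
    profiles: dict[str, ProfileDef]
    extensions: list[ExtensionDef]
    terminology: TerminologyRegistry
    manifest: dict

    @property
    def canonical_base(self) -> str:
        return self.manifest["canonical"]

    def profile_url(self, name: str) -> str:
        return f"{self.canonical_base}/fhir/StructureDefinition/{name}"

    def profile_by_url(self, url: str) -> Optional[ProfileDef]:
        return self.profiles.get(url.rsplit("/", 1)[-1])


def check_profile_name(name: str) -> bool:
    """True iff ``name`` = 'Mimic' + R4 resource name + optional CamelCase context."""
    if not name.startswith("Mimic"):
        return False
    rest = name[len("Mimic"):]
    for rn in R4_RESOURCE_NAMES:
        if rest == rn:
            return True
        if rest.startswith(rn):
            ctx = rest[len(rn):]
            if ctx and ctx[0].isupper() and ctx.isalnum():
                return True
    return False


# ---------------------------------------------------------------------------
# The shipped profile inventory
# ---------------------------------------------------------------------------

def _ec(path, min=0, max="1", vs=None, strength="required", fixed=None, base=DEFAULT_CANONICAL_BASE):
    binding = (valueset_url(vs, base), strength) if vs else None
    return ElementConstraint(path=path, min=min, max=max, binding=binding, fixed=fixed)


def _profile_specs(base: str) -> list[ProfileDef]:
    """The 25 profile definitions with their shipped constraints."""
    E = lambda *a, **k: _ec(*a, base=base, **k)  # noqa: E731
    ext_anchor = extension_url("patient-anchor-age-group", base)
    ext_route = extension_url("medadmin-route-detail", base)

    return [
        # --- administration ------------------------------------------------
        ProfileDef("MimicPatient", "Patient", "administration", [
            E("identifier", min=1, max="*"),
            E("gender", min=1),
            E("birthDate", min=1),
            E("deceasedDateTime"),
            E("managingOrganization", min=1),
        ], [ext_anchor]),
        ProfileDef("MimicEncounter", "Encounter", "administration", [
            E("status", min=1),
            E("class", min=1, vs="admission-class"),
            E("type", min=1, max="*", vs="admission-type"),
            E("subject", min=1),
            E("period", min=1),
            E("hospitalization.admitSource", vs="admit-source"),
            E("hospitalization.dischargeDisposition", vs="discharge-disposition"),
            E("location", max="*"),
            E("partOf"),
        ]),
        # --- organizational ------------------------------------------------
        ProfileDef("MimicLocation", "Location", "organizational", [
            E("status", min=1),
            E("name", min=1),
            E("type", min=1, max="*", vs="careunit"),
            E("managingOrganization", min=1),
        ]),
        ProfileDef("MimicOrganization", "Organization", "organizational", [
            E("active", min=1),
            E("name", min=1),
        ]),
        # --- orders --------------------------------------------------------
        ProfileDef("MimicCondition", "Condition", "orders", [
            E("identifier", min=1, max="*"),
            E("subject", min=1),
            E("encounter", min=1),
            E("code", min=1, vs="diagnosis-icd"),
        ]),
        ProfileDef("MimicProcedure", "Procedure", "orders", [
            E("identifier", min=1, max="*"),
            E("status", min=1),
            E("subject", min=1),
            E("encounter", min=1),
            E("code", min=1, vs="procedure-icd"),
            E("performedDateTime", min=1),
        ]),
        ProfileDef("MimicProcedureED", "Procedure", "orders", [
            E("status", min=1),
            E("subject", min=1),
            E("encounter", min=1),
            E("code", min=1, vs="procedure-ed"),
            E("performedDateTime", min=1),
        ]),
        ProfileDef("MimicProcedureICU", "Procedure", "orders", [
            E("status", min=1),
            E("subject", min=1),
            E("encounter", min=1),
            E("code", min=1, vs="procedureevents-items"),
            E("performedPeriod", min=1),
        ]),
        # --- specimen observation -----------------------------------------
        ProfileDef("MimicSpecimen", "Specimen", "specimen observation", [
            E("subject", min=1),
            E("type", min=1, vs="specimen-type"),
        ]),
        ProfileDef("MimicObservationLabevents", "Observation", "specimen observation", [
            E("status", min=1),
            E("code", min=1, vs="lab-items"),
            E("subject", min=1),
            E("encounter", min=1),
            E("effectiveDateTime", min=1),
            E("specimen", min=1),
            E("valueQuantity"),
            E("valueString"),
            E("interpretation", max="*", vs="lab-flags"),
            E("dataAbsentReason"),
        ]),
        ProfileDef("MimicObservationMicroTest", "Observation", "specimen observation", [
            E("status", min=1),
            E("code", min=1, vs="microbiology-test"),
            E("subject", min=1),
            E("encounter", min=1),
            E("effectiveDateTime", min=1),
            E("specimen", min=1),
            E("hasMember", max="*"),
        ]),
        ProfileDef("MimicObservationMicroOrg", "Observation", "specimen observation", [
            E("status", min=1),
            E("code", min=1, vs="microbiology-organism"),
            E("subject", min=1),
            E("encounter", min=1),
            E("specimen", min=1),
            E("derivedFrom", min=1, max="*"),
        ]),
        ProfileDef("MimicObservationMicroSusc", "Observation", "specimen observation", [
            E("status", min=1),
            E("code", min=1, vs="microbiology-antibiotic"),
            E("subject", min=1),
            E("encounter", min=1),
            E("interpretation", min=1, max="*", vs="microbiology-interpretation"),
            E("derivedFrom", min=1, max="*"),
        ]),
        # --- charted observation ------------------------------------------
        ProfileDef("MimicObservationChartevents", "Observation", "charted observation", [
            E("status", min=1),
            E("code", min=1, vs="chartevents-items"),
            E("subject", min=1),
            E("encounter", min=1),
            E("effectiveDateTime", min=1),
            E("valueQuantity"),
            E("valueString"),
        ]),
        ProfileDef("MimicObservationDatetimeevents", "Observation", "charted observation", [
            E("status", min=1),
            E("code", min=1, vs="datetimeevents-items"),
            E("subject", min=1),
            E("encounter", min=1),
            E("effectiveDateTime", min=1),
            E("valueDateTime", min=1),
        ]),
        ProfileDef("MimicObservationOutputevents", "Observation", "charted observation", [
            E("status", min=1),
            E("code", min=1, vs="outputevents-items"),
            E("subject", min=1),
            E("encounter", min=1),
            E("effectiveDateTime", min=1),
            E("valueQuantity", min=1),
        ]),
        ProfileDef("MimicObservationED", "Observation", "charted observation", [
            E("status", min=1),
            E("code", min=1, vs="observation-ed"),
            E("subject", min=1),
            E("encounter", min=1),
            E("effectiveDateTime", min=1),
            E("valueString", min=1),
        ]),
        ProfileDef("MimicObservationVitalSigns", "Observation", "charted observation", [
            E("status", min=1),
            E("code", min=1, vs="vitalsign-ed"),
            E("subject", min=1),
            E("encounter", min=1),
            E("effectiveDateTime", min=1),
            E("valueQuantity", min=1),
        ]),
        # --- medication ----------------------------------------------------
        ProfileDef("MimicMedication", "Medication", "medication", [
            E("code", min=1, vs="medication-code"),
        ]),
        ProfileDef("MimicMedicationRequest", "MedicationRequest", "medication", [
            E("status", min=1),
            E("intent", min=1, fixed="order"),
            E("subject", min=1),
            E("encounter", min=1),
            E("medicationReference", min=1),
            E("authoredOn", min=1),
            E("dosageInstruction", max="*"),
            E("dosageInstruction.route", vs="medication-route"),
            E("dosageInstruction.timing.code", vs="medication-frequency"),
        ]),
        ProfileDef("MimicMedicationDispense", "MedicationDispense", "medication", [
            E("status", min=1),
            E("subject", min=1),
            E("context", min=1),
            E("medicationReference", min=1),
            E("whenHandedOver", min=1),
            E("authorizingPrescription", max="*"),
        ]),
        ProfileDef("MimicMedicationDispenseED", "MedicationDispense", "medication", [
            E("status", min=1),
            E("subject", min=1),
            E("context", min=1),
            E("medicationReference", min=1),
            E("whenHandedOver", min=1),
        ]),
        ProfileDef("MimicMedicationAdministration", "MedicationAdministration", "medication", [
            E("status", min=1),
            E("subject", min=1),
            E("context", min=1),
            E("medicationReference", min=1),
            E("effectiveDateTime", min=1),
            E("request"),
        ], [ext_route]),
        ProfileDef("MimicMedicationAdministrationICU", "MedicationAdministration", "medication", [
            E("status", min=1),
            E("subject", min=1),
            E("context", min=1),
            E("medicationReference", min=1),
            E("effectivePeriod", min=1),
            E("category", min=1, vs="medadmin-category-icu"),
            E("dosage"),
        ]),
        ProfileDef("MimicMedicationStatementED", "MedicationStatement", "medication", [
            E("status", min=1),
            E("subject", min=1),
            E("context", min=1),
            E("medicationReference", min=1),
            E("dateAsserted", min=1),
        ]),
    ]


def extension_url(name: str, base: str = DEFAULT_CANONICAL_BASE) -> str:
    return f"{base}/fhir/StructureDefinition/{name}"


def _extension_specs(base: str) -> list[ExtensionDef]:
    return [
        # Deidentified sources publish age as a coarse anchor group rather
        # than a date of birth; no Patient element carries that.
        ExtensionDef(
            url=extension_url("patient-anchor-age-group", base),
            name="patient-anchor-age-group",
            context=("MimicPatient", ""),
            value_type="string",
        ),
        # Free-text delivery-route detail (e.g. lumen/line used) recorded at
        # administration time; dosage.route only holds the coded route.
        ExtensionDef(
            url=extension_url("medadmin-route-detail", base),
            name="medadmin-route-detail",
            context=("MimicMedicationAdministration", ""),
            value_type="string",
        ),
    ]


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def build_package(
    reg: TerminologyRegistry,
    config: Optional[Mapping] = None,
) -> ConformancePackage:
    """Assemble the conformance package over a terminology registry.

    Fails with a message naming the profile and element path if any binding
    does not resolve in ``reg``.
    """
    config = dict(config or {})
    base = config.get("canonical_base", DEFAULT_CANONICAL_BASE)
    profiles = {p.name: p for p in _profile_specs(base)}
    extensions = sorted(_extension_specs(base), key=lambda e: e.name)
    for prof in profiles.values():
        for c in prof.constraints:
            if c.binding and c.binding[0] not in reg.valuesets:
                raise KeyError(
                    f"profile {prof.name}, path {c.path}: "
                    f"binding {c.binding[0]} not in terminology registry"
                )
    ext_by_url = {e.url: e for e in extensions}
    for prof in profiles.values():
        for url in prof.extensions:
            if url not in ext_by_url:
                raise KeyError(f"profile {prof.name}: unknown extension {url}")
    for ext in extensions:
        if ext.context[0] not in profiles:
            raise KeyError(f"extension {ext.name}: context {ext.context[0]} is not a package profile")
    manifest = {
        "name": PACKAGE_NAME,
        "version": config.get("version", PACKAGE_VERSION),
        "canonical": base,
    }
    return ConformancePackage(profiles=profiles, extensions=extensions,
                              terminology=reg, manifest=manifest)


def package_from_terminology(
    terminology: Mapping[str, "object"],
    config: Optional[Mapping] = None,
) -> ConformancePackage:
    """Build registry (34 CodeSystems, 35 ValueSets) and package in one step.

    ``terminology`` maps each name in :data:`CODESYSTEM_NAMES` to its
    (code, display) table, e.g. ``SourceDatabase.terminology``.
    """
    from .terminology import build_registry

    config = dict(config or {})
    base = config.get("canonical_base", DEFAULT_CANONICAL_BASE)
    missing = set(CODESYSTEM_NAMES) - set(terminology)
    if missing:
        raise KeyError(f"missing terminology tables: {sorted(missing)}")
    ordered = {name: terminology[name] for name in CODESYSTEM_NAMES}
    reg = build_registry(ordered, VALUESET_PLAN, base)
    return build_package(reg, config)


def tighten_cardinality(
    profile: ProfileDef, completeness: Mapping[str, int]
) -> ProfileDef:
    """Raise min to 1 exactly on paths with zero missing source values.

    ``completeness`` maps element path -> count of missing values observed in
    the source database for the column feeding that element.  Paths with a
    nonzero missing count keep their current min.
    """
    for path in completeness:
        if profile.constraint_for(path) is None:
            raise KeyError(f"path {path!r} not constrained in profile {profile.name}")
    new = []
    for c in profile.constraints:
        if completeness.get(c.path) == 0 and c.min == 0:
            c = replace(c, min=1)
        new.append(c)
    return ProfileDef(profile.name, profile.base, profile.category, new,
                      list(profile.extensions))


def profiles_by_category(pkg: ConformancePackage) -> dict[str, list[str]]:
    out: dict[str, list[str]] = {c: [] for c in CATEGORIES}
    for p in pkg.profiles.values():
        out[p.category].append(p.name)
    for names in out.values():
        names.sort()
    return out


# ---------------------------------------------------------------------------
# Serialization — FHIR R4 conformance JSON + manifest
# ---------------------------------------------------------------------------

def _profile_to_fhir(p: ProfileDef, pkg: ConformancePackage) -> dict:
    elements = []
    for c in p.constraints:
        el: dict = {"id": f"{p.base}.{c.path}", "path": f"{p.base}.{c.path}",
                    "min": c.min, "max": c.max}
        if c.binding:
            el["binding"] = {"strength": c.binding[1], "valueSet": c.binding[0]}
        if c.fixed is not None:
            el["fixedCode"] = c.fixed
        elements.append(el)
    return {
        "resourceType": "StructureDefinition",
        "id": p.name,
        "url": pkg.profile_url(p.name),
        "version": pkg.manifest["version"],
        "name": p.name,
        "status": "active",
        "kind": "resource",
        "abstract": False,
        "type": p.base,
        "baseDefinition": f"http://hl7.org/fhir/StructureDefinition/{p.base}",
        "derivation": "constraint",
        "keyword": [{"system": f"{pkg.canonical_base}/profile-category", "code": p.category}],
        "extension": [{"url": "supportedExtension", "valueUri": u} for u in p.extensions],
        "differential": {"element": elements},
    }


def _profile_from_fhir(obj: dict) -> ProfileDef:
    constraints = []
    base = obj["type"]
    for el in obj["differential"]["element"]:
        path = el["path"]
        if path.startswith(base + "."):
            path = path[len(base) + 1:]
        binding = None
        if "binding" in el:
            binding = (el["binding"]["valueSet"], el["binding"]["strength"])
        constraints.append(ElementConstraint(
            path=path, min=el["min"], max=el["max"],
            binding=binding, fixed=el.get("fixedCode"),
        ))
    category = obj["keyword"][0]["code"]
    exts = [e["valueUri"] for e in obj.get("extension", [])]
    return ProfileDef(obj["name"], base, category, constraints, exts)


def _extension_to_fhir(e: ExtensionDef, pkg: ConformancePackage) -> dict:
    ctx = e.context[0] if not e.context[1] else f"{e.context[0]}.{e.context[1]}"
    return {
        "resourceType": "StructureDefinition",
        "id": e.name,
        "url": e.url,
        "version": pkg.manifest["version"],
        "name": e.name,
        "status": "active",
        "kind": "complex-type",
        "abstract": False,
        "type": "Extension",
        "baseDefinition": "http://hl7.org/fhir/StructureDefinition/Extension",
        "derivation": "constraint",
        "context": [{"type": "element", "expression": ctx}],
        "differential": {"element": [
            {"id": "Extension.value[x]", "path": "Extension.value[x]",
             "min": e.min, "max": e.max,
             "type": [{"code": e.value_type}]},
        ]},
    }


def _extension_from_fhir(obj: dict) -> ExtensionDef:
    expr = obj["context"][0]["expression"]
    resource, _, path = expr.partition(".")
    el = obj["differential"]["element"][0]
    return ExtensionDef(
        url=obj["url"], name=obj["name"], context=(resource, path),
        value_type=el["type"][0]["code"], min=el["min"], max=el["max"],
    )


def serialize_package(pkg: ConformancePackage, outdir: str | Path) -> Path:
    """Write the package as one JSON conformance resource per artifact.

    Produces ``StructureDefinition-*.json`` for profiles and extensions,
    ``CodeSystem-*.json``, ``ValueSet-*.json`` and a ``package.json``
    manifest listing every file with its canonical url.  Re-loading with
    :func:`load_package` reproduces an equal package; re-serializing is
    byte-stable.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: list[dict] = []

    def emit(fname: str, obj: dict) -> None:
        dump_json(obj, outdir / fname)
        files.append({"filename": fname, "url": obj["url"],
                      "resourceType": obj["resourceType"]})

    for name in sorted(pkg.profiles):
        emit(f"StructureDefinition-{name}.json", _profile_to_fhir(pkg.profiles[name], pkg))
    for ext in sorted(pkg.extensions, key=lambda e: e.name):
        emit(f"StructureDefinition-{ext.name}.json", _extension_to_fhir(ext, pkg))
    for url in sorted(pkg.terminology.codesystems):
        cs = pkg.terminology.codesystems[url]
        emit(f"CodeSystem-{cs.name}.json", codesystem_to_fhir(cs))
    for url in sorted(pkg.terminology.valuesets):
        vs = pkg.terminology.valuesets[url]
        emit(f"ValueSet-{vs.name}.json", valueset_to_fhir(vs))

    manifest = dict(pkg.manifest)
    manifest["files"] = files
    dump_json(manifest, outdir / "package.json")
    return outdir


def load_package(pkgdir: str | Path) -> ConformancePackage:
    pkgdir = Path(pkgdir)
    manifest = load_json(pkgdir / "package.json")
    reg = TerminologyRegistry()
    profiles: dict[str, ProfileDef] = {}
    extensions: list[ExtensionDef] = []
    for entry in manifest["files"]:
        obj = load_json(pkgdir / entry["filename"])
        rt = obj["resourceType"]
        if rt == "CodeSystem":
            reg.add(codesystem_from_fhir(obj))
        elif rt == "ValueSet":
            reg.add(valueset_from_fhir(obj))
        elif rt == "StructureDefinition" and obj["type"] == "Extension":
            extensions.append(_extension_from_fhir(obj))
        elif rt == "StructureDefinition":
            p = _profile_from_fhir(obj)
            profiles[p.name] = p
        else:
            raise ValueError(f"{entry['filename']}: unexpected resourceType {rt}")
    reg.check_closure()
    core = {k: manifest[k] for k in ("name", "version", "canonical")}
    return ConformancePackage(profiles=profiles, extensions=extensions,
                              terminology=reg, manifest=core)
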