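"""Conformance validation of generated resources (the Validate stage).

Resources are assembled into per-patient bundles — every resource of one
patient plus references into a shared set (the Organization, Locations and
the Medication catalog) — and each bundle is checked independently against
the conformance package.  Per-bundle independence makes validation
embarrassingly parallel by patient and order-independent by construction.

Checks per resource: required elements present (min cardinality), max
cardinality, fixed values, required-strength terminology bindings resolved
through the package's ValueSets, and primitive datatype shape (date/dateTime
lexical form, UUID ids, quantities as value+unit pairs).  Per bundle:
duplicate resource ids and reference resolution.

Issues carry a severity (error/warning) and a class from {structure,
cardinality, binding, reference, datatype}.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping, Optional, Sequence

from .profiles import ConformancePackage, ProfileDef
from .terminology import validate_code
from .transform import FhirResource

ISSUE_CLASSES = ("structure", "cardinality", "binding", "reference", "datatype")

_UUID_RE = re.compile(r"^[0-9a-f]{8}-[0-9a-f]{4}-5[0-9a-f]{3}-[0-9a-f]{4}-[0-9a-f]{12}$")
_DATE_RE = re.compile(r"^\d{4}(-\d{2}(-\d{2})?)?$")
# FHIR dateTime permits reduced precision; a time requires an offset
_DATETIME_RE = re.compile(
    r"^\d{4}-\d{2}-\d{2}(T\d{2}:\d{2}:\d{2}(\.\d+)?(Z|[+-]\d{2}:\d{2}))?$")
_REFERENCE_RE = re.compile(r"^[A-Za-z]+/[A-Za-z0-9\-.]+$")

#: element names whose string values must be FHIR date / dateTime literals
_DATE_ELEMENTS = {"birthDate"}
_DATETIME_ELEMENTS = {
    "deceasedDateTime", "effectiveDateTime", "valueDateTime", "authoredOn",
    "whenHandedOver", "dateAsserted", "performedDateTime", "start", "end",
}

#: profiles not attributable to a single patient (validated outside bundles)
SHARED_PROFILES = ("MimicOrganization", "MimicLocation", "MimicMedication")


@dataclass(frozen=True)
class ValidationIssue:
    severity: str          # "error" | "warning"
    category: str          # one of ISSUE_CLASSES
    resource_id: str
    path: str
    message: str

    def __post_init__(self) -> None:
        if self.severity not in ("error", "warning"):
            raise ValueError(f"bad severity {self.severity!r}")
        if self.category not in ISSUE_CLASSES:
            raise ValueError(f"bad issue class {self.category!r}")


@dataclass
class Bundle:
    """All of one patient's resources, assembled for joint validation."""

    patient_id: str
    entries: list[FhirResource]
    kind: str = "transaction"


@dataclass
class ValidationSummary:
    n_resources: int = 0
    n_bundles: int = 0
    by_class: dict[str, int] = field(default_factory=dict)
    by_severity: dict[str, int] = field(default_factory=dict)

    @property
    def n_errors(self) -> int:
        return self.by_severity.get("error", 0)


# ---------------------------------------------------------------------------
# Bundle assembly
# ---------------------------------------------------------------------------

def _subject_ref(resource: FhirResource) -> Optional[str]:
    ref = resource.body.get("subject") or resource.body.get("patient")
    return ref.get("reference") if isinstance(ref, dict) else None


def bundle_patient(
    resources: Sequence[FhirResource],
    patient_id: str,
    shared: Sequence[FhirResource] = (),
) -> Bundle:
    """Assemble one patient's bundle; every entry must belong to the patient."""
    patients = [r for r in resources
                if r.resourceType == "Patient" and r.id == patient_id]
    if not patients:
        raise ValueError(f"no Patient resource with id {patient_id}")
    expected = f"Patient/{patient_id}"
    for r in resources:
        if r.resourceType == "Patient":
            if r.id != patient_id:
                raise ValueError(f"foreign Patient {r.id} in bundle for {patient_id}")
            continue
        subject = _subject_ref(r)
        if subject is not None and subject != expected:
            raise ValueError(
                f"entry {r.resourceType}/{r.id} belongs to {subject}, not {expected}")
    return Bundle(patient_id=patient_id, entries=list(resources))


def bundle_cohort(
    resources_by_profile: Mapping[str, Sequence[FhirResource]],
) -> tuple[list[Bundle], list[FhirResource]]:
    """Partition transform output into per-patient bundles plus the shared set."""
    shared: list[FhirResource] = []
    by_patient: dict[str, list[FhirResource]] = {}
    for profile, resources in resources_by_profile.items():
        for r in resources:
            if profile in SHARED_PROFILES:
                shared.append(r)
            elif r.resourceType == "Patient":
                by_patient.setdefault(r.id, []).append(r)
            else:
                subject = _subject_ref(r)
                if subject is None:
                    shared.append(r)
                else:
                    by_patient.setdefault(subject.split("/", 1)[1], []).append(r)
    bundles = [bundle_patient(entries, pid, shared)
               for pid, entries in sorted(by_patient.items())]
    return bundles, shared


# ---------------------------------------------------------------------------
# Element access
# ---------------------------------------------------------------------------

def _resolve(value: Any, path: Sequence[str]) -> list[Any]:
    """All values at a dotted path, flattening lists along the way."""
    if isinstance(value, list):
        out: list[Any] = []
        for v in value:
            out.extend(_resolve(v, path))
        return out
    if not path:
        return [value]
    if isinstance(value, dict) and path[0] in value:
        return _resolve(value[path[0]], path[1:])
    return []


def _codings(value: Any) -> list[tuple[str, str]]:
    """(system, code) pairs from a CodeableConcept, Coding, or list thereof."""
    pairs: list[tuple[str, str]] = []
    if isinstance(value, list):
        for v in value:
            pairs.extend(_codings(v))
    elif isinstance(value, dict):
        if "coding" in value:
            pairs.extend(_codings(value["coding"]))
        elif "system" in value or "code" in value:
            pairs.append((value.get("system", ""), value.get("code", "")))
    return pairs


# ---------------------------------------------------------------------------
# Per-resource validation
# ---------------------------------------------------------------------------

def validate_resource(
    resource: FhirResource, pkg: ConformancePackage
) -> list[ValidationIssue]:
    profile = pkg.profiles.get(resource.profile)
    if profile is None:
        raise KeyError(f"unknown profile {resource.profile!r}")
    issues: list[ValidationIssue] = []
    body = resource.body
    rid = resource.id

    if body.get("resourceType") != profile.base:
        issues.append(ValidationIssue(
            "error", "structure", rid, "resourceType",
            f"resourceType {body.get('resourceType')!r} does not match profile base {profile.base}"))
    if not _UUID_RE.match(str(body.get("id", ""))):
        issues.append(ValidationIssue(
            "error", "datatype", rid, "id", f"id {body.get('id')!r} is not a name-based UUID"))

    for c in profile.constraints:
        values = _resolve(body, c.path.split("."))
        n = len(values)
        if n < c.min:
            issues.append(ValidationIssue(
                "error", "cardinality", rid, c.path,
                f"required element missing ({n} < min {c.min})"))
        if c.max == "1" and n > 1:
            issues.append(ValidationIssue(
                "error", "cardinality", rid, c.path,
                f"{n} repetitions exceed max 1"))
        if c.fixed is not None and values and any(v != c.fixed for v in values):
            issues.append(ValidationIssue(
                "error", "structure", rid, c.path,
                f"value {values[0]!r} differs from fixed {c.fixed!r}"))
        if c.binding is not None and values:
            vs_url, strength = c.binding
            vs = pkg.terminology.valuesets[vs_url]
            severity = "error" if strength == "required" else "warning"
            for system, code in _codings(values):
                ok, reason = validate_code(system, code, vs, pkg.terminology)
                if not ok:
                    issues.append(ValidationIssue(
                        severity, "binding", rid, c.path,
                        f"terminology binding failed: {reason}"))

    issues.extend(_check_primitives(body, rid))
    return issues


def _check_primitives(node: Any, rid: str, path: str = "") -> list[ValidationIssue]:
    issues: list[ValidationIssue] = []
    if isinstance(node, dict):
        for key, value in node.items():
            sub = f"{path}.{key}" if path else key
            if key in _DATE_ELEMENTS and not (
                    isinstance(value, str) and _DATE_RE.match(value)):
                issues.append(ValidationIssue(
                    "error", "datatype", rid, sub, f"malformed date {value!r}"))
            elif key in _DATETIME_ELEMENTS and not (
                    isinstance(value, str) and _DATETIME_RE.match(value)):
                issues.append(ValidationIssue(
                    "error", "datatype", rid, sub, f"malformed dateTime {value!r}"))
            elif key == "reference" and not (
                    isinstance(value, str) and _REFERENCE_RE.match(value)):
                issues.append(ValidationIssue(
                    "error", "datatype", rid, sub, f"malformed reference {value!r}"))
            elif key.endswith(("Quantity", "dose")) and isinstance(value, dict):
                if not isinstance(value.get("value"), (int, float)) or not value.get("unit"):
                    issues.append(ValidationIssue(
                        "error", "datatype", rid, sub,
                        "quantity must carry a numeric value and a unit"))
                continue
            if isinstance(value, (dict, list)):
                issues.extend(_check_primitives(value, rid, sub))
    elif isinstance(node, list):
        for item in node:
            issues.extend(_check_primitives(item, rid, path))
    return issues


# ---------------------------------------------------------------------------
# Bundle-level validation
# ---------------------------------------------------------------------------

def _collect_references(node: Any, out: list[str]) -> None:
    if isinstance(node, dict):
        for key, value in node.items():
            if key == "reference" and isinstance(value, str):
                out.append(value)
            else:
                _collect_references(value, out)
    elif isinstance(node, list):
        for item in node:
            _collect_references(item, out)


def check_references(
    bundle: Bundle, shared: Sequence[FhirResource] = ()
) -> list[ValidationIssue]:
    """One reference-class issue per unresolvable target in the bundle."""
    targets = {f"{r.resourceType}/{r.id}" for r in bundle.entries}
    targets |= {f"{r.resourceType}/{r.id}" for r in shared}
    issues: list[ValidationIssue] = []
    for r in bundle.entries:
        refs: list[str] = []
        _collect_references(r.body, refs)
        for ref in refs:
            if ref not in targets:
                issues.append(ValidationIssue(
                    "error", "reference", r.id, "reference",
                    f"unresolvable reference {ref}"))
    return issues


def _check_duplicate_ids(entries: Iterable[FhirResource]) -> list[ValidationIssue]:
    counts = Counter((r.resourceType, r.id) for r in entries)
    return [
        ValidationIssue("error", "cardinality", rid, "id",
                        f"{n} resources share id {rtype}/{rid} (max 1)")
        for (rtype, rid), n in counts.items() if n > 1
    ]


def validate_bundle(
    bundle: Bundle,
    pkg: ConformancePackage,
    shared: Sequence[FhirResource] = (),
) -> list[ValidationIssue]:
    issues: list[ValidationIssue] = []
    for r in bundle.entries:
        issues.extend(validate_resource(r, pkg))
    issues.extend(_check_duplicate_ids(bundle.entries))
    issues.extend(check_references(bundle, shared))
    return issues


def validate_cohort(
    bundles: Sequence[Bundle],
    pkg: ConformancePackage,
    shared: Sequence[FhirResource] = (),
) -> tuple[list[ValidationIssue], ValidationSummary]:
    """Validate every bundle plus the shared set; results are order-independent."""
    issues: list[ValidationIssue] = []
    for bundle in bundles:
        issues.extend(validate_bundle(bundle, pkg, shared))
    for r in shared:
        issues.extend(validate_resource(r, pkg))
    issues.extend(_check_duplicate_ids(shared))
    shared_targets = {f"{r.resourceType}/{r.id}" for r in shared}
    for r in shared:
        refs: list[str] = []
        _collect_references(r.body, refs)
        for ref in refs:
            if ref not in shared_targets:
                issues.append(ValidationIssue(
                    "error", "reference", r.id, "reference",
                    f"unresolvable reference {ref}"))
    issues.sort(key=lambda i: (i.resource_id, i.path, i.category, i.message))
    summary = ValidationSummary(
        n_resources=sum(len(b.entries) for b in bundles) + len(shared),
        n_bundles=len(bundles),
        by_class=dict(sorted(Counter(i.category for i in issues).items())),
        by_severity=dict(sorted(Counter(i.severity for i in issues).items())),
    )
    return issues, summary


def issues_to_operation_outcome(issues: Sequence[ValidationIssue]) -> dict:
    """Issues as an OperationOutcome-shaped JSON object."""
    return {
        "resourceType": "OperationOutcome",
        "issue": [{
            "severity": i.severity,
            "code": "invariant",
            "details": {"text": i.message},
            "expression": [f"{i.resource_id}.{i.path}"],
            "extension": [{"url": "issue-class", "valueCode": i.category}],
        } for i in issues],
    }
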