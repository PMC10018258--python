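"""Relational rows -> profiled FHIR R4 resources (the Generate stage).

Every narrow event table maps one row to one resource; the only aggregations
are deliberate and documented: specimens deduplicate over their specimen id,
the medication catalog deduplicates over formulation, wide ED vital-sign rows
unpivot to one observation per non-null measurement, and microbiology rows
group into the test -> organism -> susceptibility hierarchy (member links
downward from test to organism, derived-from links upward from susceptibility
to organism).

Resource ids are name-based (version-5) UUIDs over the resource type and the
row's natural key, so the transform is a pure function of its inputs: the
same database always yields the same resources, and references can be built
from foreign keys without a lookup table.

A :class:`MappingReport` accounts for every table: rows read, resources
emitted, which columns each mapper consumed, statuses imputed, and per-row
errors.  Columns not consumed by any mapper appear in the dropped-field
ledger; the shipped mapping leaves it empty.  A source cell counts as
captured if its value appears in an emitted element or is recoverable
through the reference chain (e.g. an event's admission id via its
encounter's part-of link).
"""

from __future__ import annotations

import uuid
from dataclasses import dataclass, field
from typing import Any, Mapping, Optional

import pandas as pd

from .profiles import ConformancePackage
from .synthetic_source import SourceDatabase, TABLE_SCHEMAS, VITAL_UNITS
from .terminology import codesystem_url

#: Namespace for name-based resource ids; configurable so two conversions of
#: the same source cannot collide unless asked to.
DEFAULT_NAMESPACE = uuid.uuid5(uuid.NAMESPACE_URL, "http://example.org/mimic/fhir")

#: ISO-8601 offset appended to deidentified local timestamps.
DEFAULT_UTC_OFFSET = "+00:00"

DATA_ABSENT = {"coding": [{
    "system": "http://terminology.hl7.org/CodeSystem/data-absent-reason",
    "code": "unknown",
}]}

# raw source status vocabularies -> R4 status codes, per resource family
EMAR_STATUS_MAP = {"Administered": "completed", "Not Given": "not-done"}
INPUTEVENT_STATUS_MAP = {"FinishedRunning": "completed", "Stopped": "stopped"}
MEDADMIN_STATUSES = frozenset({
    "in-progress", "not-done", "on-hold", "completed", "entered-in-error",
    "stopped", "unknown"})
MEDREQUEST_STATUSES = frozenset({
    "active", "on-hold", "cancelled", "completed", "entered-in-error",
    "stopped", "draft", "unknown"})
MEDDISPENSE_STATUSES = frozenset({
    "preparation", "in-progress", "cancelled", "on-hold", "completed",
    "entered-in-error", "stopped", "declined", "unknown"})
MEDSTATEMENT_STATUSES = frozenset({
    "active", "completed", "entered-in-error", "intended", "stopped",
    "on-hold", "unknown", "not-taken"})

ADMISSION_TYPE_TO_CLASS = {
    "ELECTIVE": "IMP", "URGENT": "EMER", "EW EMER": "EMER",
    "OBSERVATION ADMIT": "AMB", "SURGICAL SAME DAY ADMISSION": "IMP",
}


@dataclass
class FhirResource:
    """One generated resource: its JSON body plus routing metadata."""

    resourceType: str
    id: str
    profile: str          # profile name, e.g. "MimicObservationLabevents"
    body: dict

    def __eq__(self, other: object) -> bool:
        return isinstance(other, FhirResource) and self.body == other.body

    def __hash__(self) -> int:  # pragma: no cover - containers only
        return hash((self.resourceType, self.id))


@dataclass
class MappingReport:
    rows_read: dict[str, int] = field(default_factory=dict)
    resources_emitted: dict[str, int] = field(default_factory=dict)
    consumed_columns: dict[str, list[str]] = field(default_factory=dict)
    dropped_fields: dict[str, list[str]] = field(default_factory=dict)
    statuses_imputed: int = 0
    errors: list[str] = field(default_factory=list)

    def count(self, profile: str, n: int = 1) -> None:
        self.resources_emitted[profile] = self.resources_emitted.get(profile, 0) + n


def field_coverage(db: SourceDatabase, report: MappingReport) -> float:
    """Fraction of non-null source cells in columns the mapping consumed."""
    covered = total = 0
    for name, df in db.tables.items():
        consumed = set(report.consumed_columns.get(name, []))
        for col in df.columns:
            n = int(df[col].notna().sum())
            total += n
            if col in consumed:
                covered += n
    return covered / total if total else 1.0


# ---------------------------------------------------------------------------
# Identity and primitives
# ---------------------------------------------------------------------------

def assign_id(
    resource_type: str,
    source_keys: tuple,
    namespace: uuid.UUID = DEFAULT_NAMESPACE,
) -> str:
    """Deterministic lowercase UUID for a resource's natural key."""
    parts = []
    for k in source_keys:
        if k is None or (pd.api.types.is_scalar(k) and pd.isna(k)):
            raise ValueError(f"null key component for {resource_type} id: {source_keys}")
        parts.append(str(k))
    return str(uuid.uuid5(namespace, resource_type + "|" + "|".join(parts)))


def iso(ts: Any, offset: str = DEFAULT_UTC_OFFSET) -> str:
    """'YYYY-MM-DD HH:MM:SS' -> ISO-8601 with explicit offset; dates pass through."""
    s = str(ts)
    return s if len(s) == 10 else s.replace(" ", "T") + offset


def _num(x: Any) -> float | int:
    f = float(x)
    return int(f) if f.is_integer() else f


class _Context:
    """Shared lookups for one transform run."""

    def __init__(self, db: SourceDatabase, pkg: ConformancePackage,
                 config: Optional[Mapping] = None):
        self.db = db
        self.pkg = pkg
        self.config = dict(config or {})
        self.base = pkg.canonical_base
        self.offset = self.config.get("utc_offset", DEFAULT_UTC_OFFSET)
        self.namespace = self.config.get("namespace", DEFAULT_NAMESPACE)
        self.displays = {
            name: dict(zip(df["code"], df["display"]))
            for name, df in db.terminology.items()
        }
        self.report = MappingReport()
        self.resources: dict[str, list[FhirResource]] = {
            name: [] for name in pkg.profiles
        }
        self.org_id = assign_id("Organization", ("hospital",), self.namespace)

    def uid(self, rtype: str, keys: tuple) -> str:
        return assign_id(rtype, keys, self.namespace)

    def coding(self, system_name: str, code: Any) -> dict:
        code = str(code)
        entry: dict = {"system": codesystem_url(system_name, self.base), "code": code}
        display = self.displays.get(system_name, {}).get(code)
        if display is not None and pd.notna(display) and display != "":
            entry["display"] = str(display)
        return {"coding": [entry]}

    def emit(self, profile: str, rid: str, body: dict) -> FhirResource:
        prof = self.pkg.profiles[profile]
        body = {"resourceType": prof.base, "id": rid,
                "meta": {"profile": [self.pkg.profile_url(profile)]}, **body}
        res = FhirResource(prof.base, rid, profile, body)
        self.resources[profile].append(res)
        self.report.count(profile)
        return res

    def consumed(self, table: str, *cols: str) -> None:
        self.report.rows_read[table] = len(self.db.tables[table])
        self.report.consumed_columns[table] = list(cols)
        dropped = [c for c in TABLE_SCHEMAS[table] if c not in cols]
        if dropped:
            self.report.dropped_fields[table] = dropped


def _ref(rtype: str, rid: str) -> dict:
    return {"reference": f"{rtype}/{rid}"}


def impute_status(
    resource: dict,
    raw_status: Any,
    allowed: frozenset,
    mapping: Optional[Mapping[str, str]] = None,
    report: Optional[MappingReport] = None,
) -> dict:
    """Set ``resource['status']`` from a raw source status.

    A null/absent raw status becomes ``unknown`` (the element is required by
    the profiles but the source often never recorded it); a present status is
    translated through ``mapping`` and must land in the resource's legal R4
    status code set.
    """
    if raw_status is None or (pd.api.types.is_scalar(raw_status) and pd.isna(raw_status)):
        resource["status"] = "unknown"
        if report is not None:
            report.statuses_imputed += 1
        return resource
    raw = str(raw_status)
    status = (mapping or {}).get(raw, raw)
    if status not in allowed:
        raise ValueError(f"status {raw!r} not mappable to a legal status code")
    resource["status"] = status
    return resource


# ---------------------------------------------------------------------------
# Mappers
# ---------------------------------------------------------------------------

def map_patient(row: Mapping, ctx: _Context) -> FhirResource:
    if pd.isna(row["subject_id"]):
        raise ValueError("patients row with missing subject_id")
    subject = int(row["subject_id"])
    birth_year = int(row["anchor_year"]) - int(row["anchor_age"])
    body: dict = {
        "identifier": [{"value": str(subject)}],
        "gender": {"M": "male", "F": "female"}.get(str(row["gender"]), "unknown"),
        "birthDate": f"{birth_year:04d}-01-01",
        "managingOrganization": _ref("Organization", ctx.org_id),
        "extension": [{
            "url": f"{ctx.base}/fhir/StructureDefinition/patient-anchor-age-group",
            "valueString": str(row["anchor_year_group"]),
        }],
    }
    if pd.notna(row["dod"]):
        body["deceasedDateTime"] = iso(row["dod"], ctx.offset)
    return ctx.emit("MimicPatient", ctx.uid("Patient", (subject,)), body)


def _map_patients(ctx: _Context) -> None:
    df = ctx.db.tables["patients"]
    if df["subject_id"].duplicated().any():
        raise ValueError("duplicate subject_id rows in patients table")
    for row in df.to_dict("records"):
        map_patient(row, ctx)
    ctx.consumed("patients", *TABLE_SCHEMAS["patients"])


def _map_encounters(ctx: _Context) -> None:
    t = ctx.db.tables
    known_hadm = set(t["admissions"]["hadm_id"].dropna())

    loc_by_hadm: dict[int, list[dict]] = {}
    for row in t["transfers"].to_dict("records"):
        if row["eventtype"] not in ("admit", "transfer") or pd.isna(row["careunit"]):
            continue
        entry = {
            "location": _ref("Location", ctx.uid("Location", (row["careunit"],))),
            "period": {"start": iso(row["intime"], ctx.offset),
                       "end": iso(row["outtime"], ctx.offset)},
        }
        loc_by_hadm.setdefault(int(row["hadm_id"]), []).append(entry)
    ctx.consumed("transfers", *TABLE_SCHEMAS["transfers"])

    for row in t["admissions"].to_dict("records"):
        hadm = int(row["hadm_id"])
        atype = str(row["admission_type"])
        body: dict = {
            "status": "finished",
            "class": ctx.coding("admission-class",
                                ADMISSION_TYPE_TO_CLASS.get(atype, "IMP"))["coding"][0],
            "type": [ctx.coding("admission-type", atype)],
            "subject": _ref("Patient", ctx.uid("Patient", (int(row["subject_id"]),))),
            "period": {"start": iso(row["admittime"], ctx.offset),
                       "end": iso(row["dischtime"], ctx.offset)},
            "hospitalization": {
                "admitSource": ctx.coding("admission-location", row["admission_location"]),
                "dischargeDisposition": ctx.coding("discharge-disposition",
                                                   row["discharge_location"]),
            },
        }
        if hadm in loc_by_hadm:
            body["location"] = loc_by_hadm[hadm]
        ctx.emit("MimicEncounter", ctx.uid("Encounter", (hadm,)), body)
    ctx.consumed("admissions", *TABLE_SCHEMAS["admissions"])

    for row in t["icustays"].to_dict("records"):
        if int(row["hadm_id"]) not in known_hadm:
            raise ValueError(f"icustay {row['stay_id']} references unknown admission {row['hadm_id']}")
        body = {
            "status": "finished",
            "class": ctx.coding("admission-class", "ICU")["coding"][0],
            "type": [ctx.coding("admission-type-icu", "ICU ADMIT")],
            "subject": _ref("Patient", ctx.uid("Patient", (int(row["subject_id"]),))),
            "period": {"start": iso(row["intime"], ctx.offset),
                       "end": iso(row["outtime"], ctx.offset)},
            "location": [{
                "location": _ref("Location", ctx.uid("Location", (row["first_careunit"],))),
                "period": {"start": iso(row["intime"], ctx.offset),
                           "end": iso(row["outtime"], ctx.offset)},
            }],
            "partOf": _ref("Encounter", ctx.uid("Encounter", (int(row["hadm_id"]),))),
        }
        ctx.emit("MimicEncounter", ctx.uid("Encounter", ("ICU", int(row["stay_id"]))), body)
    ctx.consumed("icustays", *TABLE_SCHEMAS["icustays"])

    for row in t["edstays"].to_dict("records"):
        body = {
            "status": "finished",
            "class": ctx.coding("admission-class", "EMER")["coding"][0],
            "type": [ctx.coding("admission-type", "EW EMER")],
            "subject": _ref("Patient", ctx.uid("Patient", (int(row["subject_id"]),))),
            "period": {"start": iso(row["intime"], ctx.offset),
                       "end": iso(row["outtime"], ctx.offset)},
            "hospitalization": {
                "admitSource": ctx.coding("ed-arrival-transport", row["arrival_transport"]),
                "dischargeDisposition": ctx.coding("ed-disposition", row["disposition"]),
            },
        }
        if pd.notna(row["hadm_id"]):  # ED visits without an admission stand alone
            body["partOf"] = _ref("Encounter", ctx.uid("Encounter", (int(row["hadm_id"]),)))
        ctx.emit("MimicEncounter", ctx.uid("Encounter", ("ED", int(row["stay_id"]))), body)
    ctx.consumed("edstays", *TABLE_SCHEMAS["edstays"])


def map_locations_org(careunits: pd.DataFrame, ctx: _Context) -> None:
    """One Location per distinct care unit plus the singleton Organization."""
    ctx.emit("MimicOrganization", ctx.org_id, {
        "active": True,
        "name": ctx.config.get("hospital_name", "Example Medical Center"),
    })
    seen: set[str] = set()
    for row in careunits.to_dict("records"):
        code = str(row["code"])
        if code in seen:
            continue
        seen.add(code)
        ctx.emit("MimicLocation", ctx.uid("Location", (code,)), {
            "status": "active",
            "name": str(row["display"]) or code,
            "type": [ctx.coding("careunit", code)],
            "managingOrganization": _ref("Organization", ctx.org_id),
        })


def _map_conditions(ctx: _Context) -> None:
    for row in ctx.db.tables["diagnoses"].to_dict("records"):
        hadm, seq = int(row["hadm_id"]), int(row["seq_num"])
        system = f"diagnosis-icd{int(row['icd_version'])}"
        ctx.emit("MimicCondition", ctx.uid("Condition", (hadm, seq)), {
            "identifier": [{"value": f"{hadm}-{seq}"}],
            "subject": _ref("Patient", ctx.uid("Patient", (int(row["subject_id"]),))),
            "encounter": _ref("Encounter", ctx.uid("Encounter", (hadm,))),
            "code": ctx.coding(system, row["icd_code"]),
        })
    ctx.consumed("diagnoses", *TABLE_SCHEMAS["diagnoses"])


def _map_procedures(ctx: _Context) -> None:
    t = ctx.db.tables
    for row in t["procedures_hosp"].to_dict("records"):
        hadm, seq = int(row["hadm_id"]), int(row["seq_num"])
        system = f"procedure-icd{int(row['icd_version'])}"
        ctx.emit("MimicProcedure", ctx.uid("Procedure", (hadm, seq)), {
            "identifier": [{"value": f"{hadm}-{seq}"}],
            "status": "completed",
            "subject": _ref("Patient", ctx.uid("Patient", (int(row["subject_id"]),))),
            "encounter": _ref("Encounter", ctx.uid("Encounter", (hadm,))),
            "code": ctx.coding(system, row["icd_code"]),
            "performedDateTime": iso(row["chartdate"], ctx.offset),
        })
    ctx.consumed("procedures_hosp", *TABLE_SCHEMAS["procedures_hosp"])

    for row in t["ed_procedures"].to_dict("records"):
        stay = int(row["stay_id"])
        rid = ctx.uid("Procedure", ("ED", stay, row["charttime"], row["code"]))
        ctx.emit("MimicProcedureED", rid, {
            "status": "completed",
            "subject": _ref("Patient", ctx.uid("Patient", (int(row["subject_id"]),))),
            "encounter": _ref("Encounter", ctx.uid("Encounter", ("ED", stay))),
            "code": ctx.coding("procedure-ed", row["code"]),
            "performedDateTime": iso(row["charttime"], ctx.offset),
        })
    ctx.consumed("ed_procedures", *TABLE_SCHEMAS["ed_procedures"])

    for row in t["procedureevents"].to_dict("records"):
        stay = int(row["stay_id"])
        rid = ctx.uid("Procedure", ("ICU", stay, row["starttime"], row["itemid"]))
        ctx.emit("MimicProcedureICU", rid, {
            "status": "completed",
            "subject": _ref("Patient", ctx.uid("Patient", (int(row["subject_id"]),))),
            "encounter": _ref("Encounter", ctx.uid("Encounter", ("ICU", stay))),
            "code": ctx.coding("procedureevents-items", row["itemid"]),
            "performedPeriod": {"start": iso(row["starttime"], ctx.offset),
                                "end": iso(row["endtime"], ctx.offset)},
        })
    ctx.consumed("procedureevents", *TABLE_SCHEMAS["procedureevents"])


def _map_lab(ctx: _Context) -> None:
    specimens_seen: set[int] = set()
    for row in ctx.db.tables["labevents"].to_dict("records"):
        spec_id = int(row["specimen_id"])
        spec_rid = ctx.uid("Specimen", ("lab", spec_id))
        subject_ref = _ref("Patient", ctx.uid("Patient", (int(row["subject_id"]),)))
        if spec_id not in specimens_seen:
            specimens_seen.add(spec_id)
            ctx.emit("MimicSpecimen", spec_rid, {
                "subject": subject_ref,
                "type": ctx.coding("lab-fluid", row["fluid"]),
            })
        body: dict = {
            "status": "final",
            "code": ctx.coding("d-labitems", row["itemid"]),
            "subject": subject_ref,
            "encounter": _ref("Encounter", ctx.uid("Encounter", (int(row["hadm_id"]),))),
            "specimen": _ref("Specimen", spec_rid),
        }
        if pd.notna(row["charttime"]):
            body["effectiveDateTime"] = iso(row["charttime"], ctx.offset)
        if pd.notna(row["valuenum"]):
            body["valueQuantity"] = {"value": _num(row["valuenum"]),
                                     "unit": str(row["valueuom"])}
        elif pd.notna(row["value"]):
            body["valueString"] = str(row["value"])
        else:
            body["dataAbsentReason"] = DATA_ABSENT
        if pd.notna(row["flag"]):
            body["interpretation"] = [ctx.coding("lab-flags", row["flag"])]
        ctx.emit("MimicObservationLabevents",
                 ctx.uid("Observation", (int(row["labevent_id"]),)), body)
    ctx.consumed("labevents", *TABLE_SCHEMAS["labevents"])


def _map_micro(ctx: _Context) -> None:
    df = ctx.db.tables["microbiologyevents"]
    specimens_seen: set[int] = set()
    tests_seen: set[tuple] = set()
    orgs_seen: set[tuple] = set()
    org_members: dict[str, list[dict]] = {}
    test_bodies: dict[str, dict] = {}

    for row in df.to_dict("records"):
        msid = int(row["micro_specimen_id"])
        subject_ref = _ref("Patient", ctx.uid("Patient", (int(row["subject_id"]),)))
        encounter_ref = _ref("Encounter", ctx.uid("Encounter", (int(row["hadm_id"]),)))
        spec_rid = ctx.uid("Specimen", ("micro", msid))
        if msid not in specimens_seen:
            specimens_seen.add(msid)
            ctx.emit("MimicSpecimen", spec_rid, {
                "subject": subject_ref,
                "type": ctx.coding("spec-type-desc", row["spec_type_desc"]),
            })
        test_key = (msid, str(row["test_itemid"]))
        test_rid = ctx.uid("Observation", ("microtest", msid, row["test_itemid"]))
        if test_key not in tests_seen:
            tests_seen.add(test_key)
            test_bodies[test_rid] = {
                "status": "final",
                "code": ctx.coding("microbiology-test", row["test_itemid"]),
                "subject": subject_ref,
                "encounter": encounter_ref,
                "effectiveDateTime": iso(row["charttime"], ctx.offset),
                "specimen": _ref("Specimen", spec_rid),
            }
        if pd.isna(row["org_itemid"]):
            if pd.notna(row["ab_itemid"]):
                ctx.report.errors.append(
                    f"microbiologyevents row {row['microevent_id']}: "
                    "susceptibility result without an organism")
            continue
        org_key = (msid, str(row["test_itemid"]), str(row["org_itemid"]))
        org_rid = ctx.uid("Observation",
                          ("microorg", msid, row["test_itemid"], row["org_itemid"]))
        if org_key not in orgs_seen:
            orgs_seen.add(org_key)
            ctx.emit("MimicObservationMicroOrg", org_rid, {
                "status": "final",
                "code": ctx.coding("microbiology-organism", row["org_itemid"]),
                "subject": subject_ref,
                "encounter": encounter_ref,
                "specimen": _ref("Specimen", spec_rid),
                "derivedFrom": [_ref("Observation", test_rid)],
            })
            org_members.setdefault(test_rid, []).append(_ref("Observation", org_rid))
        if pd.notna(row["ab_itemid"]):
            susc_rid = ctx.uid("Observation", ("microsusc", int(row["microevent_id"])))
            body = {
                "status": "final",
                "code": ctx.coding("microbiology-antibiotic", row["ab_itemid"]),
                "subject": subject_ref,
                "encounter": encounter_ref,
                "derivedFrom": [_ref("Observation", org_rid)],
            }
            if pd.notna(row["interpretation"]):
                body["interpretation"] = [
                    ctx.coding("microbiology-interpretation", row["interpretation"])]
            ctx.emit("MimicObservationMicroSusc", susc_rid, body)

    for test_rid, body in test_bodies.items():
        if test_rid in org_members:
            body["hasMember"] = org_members[test_rid]
        ctx.emit("MimicObservationMicroTest", test_rid, body)
    ctx.consumed("microbiologyevents", *TABLE_SCHEMAS["microbiologyevents"])


def _map_charted(ctx: _Context) -> None:
    t = ctx.db.tables
    icu_stays = set(t["icustays"]["stay_id"].dropna())

    for row in t["chartevents"].to_dict("records"):
        stay = int(row["stay_id"])
        if stay not in icu_stays:
            ctx.report.errors.append(f"chartevents: event outside any stay ({stay})")
        body: dict = {
            "status": "final",
            "code": ctx.coding("chartevents-items", row["itemid"]),
            "subject": _ref("Patient", ctx.uid("Patient", (int(row["subject_id"]),))),
            "encounter": _ref("Encounter", ctx.uid("Encounter", ("ICU", stay))),
            "effectiveDateTime": iso(row["charttime"], ctx.offset),
        }
        if pd.notna(row["valuenum"]):
            body["valueQuantity"] = {"value": _num(row["valuenum"]),
                                     "unit": str(row["valueuom"])}
        elif pd.notna(row["value"]):
            body["valueString"] = str(row["value"])
        rid = ctx.uid("Observation", (row["stay_id"], row["charttime"], row["itemid"]))
        ctx.emit("MimicObservationChartevents", rid, body)
    ctx.consumed("chartevents", *TABLE_SCHEMAS["chartevents"])

    for row in t["datetimeevents"].to_dict("records"):
        stay = int(row["stay_id"])
        rid = ctx.uid("Observation", ("dt", stay, row["charttime"], row["itemid"]))
        ctx.emit("MimicObservationDatetimeevents", rid, {
            "status": "final",
            "code": ctx.coding("datetimeevents-items", row["itemid"]),
            "subject": _ref("Patient", ctx.uid("Patient", (int(row["subject_id"]),))),
            "encounter": _ref("Encounter", ctx.uid("Encounter", ("ICU", stay))),
            "effectiveDateTime": iso(row["charttime"], ctx.offset),
            "valueDateTime": iso(row["value"], ctx.offset),
        })
    ctx.consumed("datetimeevents", *TABLE_SCHEMAS["datetimeevents"])

    for row in t["outputevents"].to_dict("records"):
        stay = int(row["stay_id"])
        rid = ctx.uid("Observation", ("out", stay, row["charttime"], row["itemid"]))
        ctx.emit("MimicObservationOutputevents", rid, {
            "status": "final",
            "code": ctx.coding("outputevents-items", row["itemid"]),
            "subject": _ref("Patient", ctx.uid("Patient", (int(row["subject_id"]),))),
            "encounter": _ref("Encounter", ctx.uid("Encounter", ("ICU", stay))),
            "effectiveDateTime": iso(row["charttime"], ctx.offset),
            "valueQuantity": {"value": _num(row["value"]), "unit": str(row["valueuom"])},
        })
    ctx.consumed("outputevents", *TABLE_SCHEMAS["outputevents"])

    # wide vitals: one VitalSigns observation per non-null measurement,
    # rhythm/pain (the non-numeric columns) become MimicObservationED
    for row in t["ed_vitalsign"].to_dict("records"):
        stay = int(row["stay_id"])
        subject_ref = _ref("Patient", ctx.uid("Patient", (int(row["subject_id"]),)))
        encounter_ref = _ref("Encounter", ctx.uid("Encounter", ("ED", stay)))
        for vital in VITAL_UNITS:
            if pd.isna(row[vital]):
                continue
            rid = ctx.uid("Observation", ("edvital", stay, row["charttime"], vital))
            ctx.emit("MimicObservationVitalSigns", rid, {
                "status": "final",
                "code": ctx.coding("vitalsign-ed", vital),
                "subject": subject_ref,
                "encounter": encounter_ref,
                "effectiveDateTime": iso(row["charttime"], ctx.offset),
                "valueQuantity": {"value": _num(row[vital]),
                                  "unit": VITAL_UNITS[vital]},
            })
        for name in ("rhythm", "pain"):
            if pd.isna(row[name]):
                continue
            rid = ctx.uid("Observation", ("edobs", stay, row["charttime"], name))
            ctx.emit("MimicObservationED", rid, {
                "status": "final",
                "code": ctx.coding("observation-ed", name),
                "subject": subject_ref,
                "encounter": encounter_ref,
                "effectiveDateTime": iso(row["charttime"], ctx.offset),
                "valueString": str(row[name]),
            })
    ctx.consumed("ed_vitalsign", *TABLE_SCHEMAS["ed_vitalsign"])


def _map_medications(ctx: _Context) -> None:
    t = ctx.db.tables
    ndc_by_drug: dict[str, str] = {}
    for row in t["prescriptions"].to_dict("records"):
        if pd.notna(row["ndc"]):
            ndc_by_drug.setdefault(str(row["drug"]), str(row["ndc"]))

    catalog: list[str] = []
    seen: set[str] = set()

    def med_ref(drug: Any) -> dict:
        drug = str(drug)
        if drug not in seen:
            seen.add(drug)
            catalog.append(drug)
        return _ref("Medication", ctx.uid("Medication", (drug,)))

    known_requests = {int(p) for p in t["prescriptions"]["pharmacy_id"].dropna()}

    for row in t["prescriptions"].to_dict("records"):
        pid = int(row["pharmacy_id"])
        body: dict = {
            "intent": "order",
            "subject": _ref("Patient", ctx.uid("Patient", (int(row["subject_id"]),))),
            "encounter": _ref("Encounter", ctx.uid("Encounter", (int(row["hadm_id"]),))),
            "medicationReference": med_ref(row["drug"]),
            "authoredOn": iso(row["starttime"], ctx.offset),
            "dosageInstruction": [{
                "route": ctx.coding("medication-route", row["route"]),
                "timing": {"code": ctx.coding("medication-frequency", row["frequency"])},
            }],
            "dispenseRequest": {"validityPeriod": {
                "start": iso(row["starttime"], ctx.offset),
                "end": iso(row["stoptime"], ctx.offset)}},
        }
        impute_status(body, row["status"], MEDREQUEST_STATUSES, report=ctx.report)
        ctx.emit("MimicMedicationRequest", ctx.uid("MedicationRequest", (pid,)), body)
    ctx.consumed("prescriptions", *TABLE_SCHEMAS["prescriptions"])

    for row in t["pharmacy"].to_dict("records"):
        pid = int(row["pharmacy_id"])
        body = {
            "subject": _ref("Patient", ctx.uid("Patient", (int(row["subject_id"]),))),
            "context": _ref("Encounter", ctx.uid("Encounter", (int(row["hadm_id"]),))),
            "medicationReference": med_ref(row["medication"]),
            "whenHandedOver": iso(row["starttime"], ctx.offset),
        }
        if pid in known_requests:
            body["authorizingPrescription"] = [
                _ref("MedicationRequest", ctx.uid("MedicationRequest", (pid,)))]
        impute_status(body, row["status"], MEDDISPENSE_STATUSES, report=ctx.report)
        ctx.emit("MimicMedicationDispense", ctx.uid("MedicationDispense", (pid,)), body)
    ctx.consumed("pharmacy", *TABLE_SCHEMAS["pharmacy"])

    for row in t["emar"].to_dict("records"):
        body = {
            "subject": _ref("Patient", ctx.uid("Patient", (int(row["subject_id"]),))),
            "context": _ref("Encounter", ctx.uid("Encounter", (int(row["hadm_id"]),))),
            "medicationReference": med_ref(row["medication"]),
            "effectiveDateTime": iso(row["charttime"], ctx.offset),
        }
        # administrations whose order link is missing stand alone
        if pd.notna(row["pharmacy_id"]) and int(row["pharmacy_id"]) in known_requests:
            body["request"] = _ref(
                "MedicationRequest", ctx.uid("MedicationRequest", (int(row["pharmacy_id"]),)))
        if pd.notna(row["route_detail"]):
            body["extension"] = [{
                "url": f"{ctx.base}/fhir/StructureDefinition/medadmin-route-detail",
                "valueString": str(row["route_detail"]),
            }]
        impute_status(body, row["event_txt"], MEDADMIN_STATUSES,
                      mapping=EMAR_STATUS_MAP, report=ctx.report)
        ctx.emit("MimicMedicationAdministration",
                 ctx.uid("MedicationAdministration", (str(row["emar_id"]),)), body)
    ctx.consumed("emar", *TABLE_SCHEMAS["emar"])

    for row in t["inputevents"].to_dict("records"):
        stay = int(row["stay_id"])
        body = {
            "subject": _ref("Patient", ctx.uid("Patient", (int(row["subject_id"]),))),
            "context": _ref("Encounter", ctx.uid("Encounter", ("ICU", stay))),
            "medicationReference": med_ref(row["itemid"]),
            "effectivePeriod": {"start": iso(row["starttime"], ctx.offset),
                                "end": iso(row["endtime"], ctx.offset)},
            "category": ctx.coding("medadmin-category-icu", row["ordercategoryname"]),
            "dosage": {"dose": {"value": _num(row["amount"]),
                                "unit": str(row["amountuom"])}},
        }
        impute_status(body, row["statusdescription"], MEDADMIN_STATUSES,
                      mapping=INPUTEVENT_STATUS_MAP, report=ctx.report)
        ctx.emit("MimicMedicationAdministrationICU",
                 ctx.uid("MedicationAdministration", ("icu", int(row["orderid"]))), body)
    ctx.consumed("inputevents", *TABLE_SCHEMAS["inputevents"])

    for row in t["ed_pyxis"].to_dict("records"):
        stay = int(row["stay_id"])
        rid = ctx.uid("MedicationDispense", ("edpyxis", stay, row["charttime"], row["name"]))
        ctx.emit("MimicMedicationDispenseED", rid, {
            "status": "completed",
            "subject": _ref("Patient", ctx.uid("Patient", (int(row["subject_id"]),))),
            "context": _ref("Encounter", ctx.uid("Encounter", ("ED", stay))),
            "medicationReference": med_ref(row["name"]),
            "whenHandedOver": iso(row["charttime"], ctx.offset),
        })
    ctx.consumed("ed_pyxis", *TABLE_SCHEMAS["ed_pyxis"])

    for row in t["ed_medrecon"].to_dict("records"):
        stay = int(row["stay_id"])
        rid = ctx.uid("MedicationStatement", ("edmedrecon", stay, row["charttime"], row["name"]))
        body = {
            "subject": _ref("Patient", ctx.uid("Patient", (int(row["subject_id"]),))),
            "context": _ref("Encounter", ctx.uid("Encounter", ("ED", stay))),
            "medicationReference": med_ref(row["name"]),
            "dateAsserted": iso(row["charttime"], ctx.offset),
        }
        # home-medication reconciliation carries no status in the source
        impute_status(body, None, MEDSTATEMENT_STATUSES, report=ctx.report)
        ctx.emit("MimicMedicationStatementED", rid, body)
    ctx.consumed("ed_medrecon", *TABLE_SCHEMAS["ed_medrecon"])

    for drug in catalog:
        codings = ctx.coding("medication-name", drug)["coding"]
        if drug in ndc_by_drug:
            codings = codings + ctx.coding("medication-ndc", ndc_by_drug[drug])["coding"]
        ctx.emit("MimicMedication", ctx.uid("Medication", (drug,)),
                 {"code": {"coding": codings}})


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def transform_cohort(
    db: SourceDatabase,
    pkg: ConformancePackage,
    config: Optional[Mapping] = None,
) -> tuple[dict[str, list[FhirResource]], MappingReport]:
    """Run every mapper; return resources grouped by profile plus the report."""
    ctx = _Context(db, pkg, config)
    _map_patients(ctx)
    _map_encounters(ctx)
    map_locations_org(db.terminology["careunit"], ctx)
    _map_conditions(ctx)
    _map_procedures(ctx)
    _map_lab(ctx)
    _map_micro(ctx)
    _map_charted(ctx)
    _map_medications(ctx)
    return ctx.resources, ctx.report
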