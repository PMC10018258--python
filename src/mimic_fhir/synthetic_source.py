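"""Deterministic synthetic critical-care relational database.

The conversion pipeline is developed and tested against a restricted source,
so this module fabricates a stand-in with the same shape: hospital tables
(patients, admissions, transfers, diagnoses, procedures, labs, microbiology,
medications), ICU event tables keyed by stay, ED tables, and one
``(code, display)`` terminology table per local vocabulary.  Structure is
what matters — foreign keys resolve, event timestamps sit inside their stay,
microbiology rows nest test -> organism -> susceptibility, and medications
follow the request -> dispense -> administration chain.  Value distributions
are plausible, not clinically calibrated.

Generation is a pure function of :class:`CohortConfig`; the same seed always
yields byte-identical CSVs.  Dates are shifted into the 22nd century, the
convention deidentified sources use to make clear no real timeline survives.

:func:`inject_defects` deliberately corrupts a database and returns a ledger
of what was broken where, so validator recall can be measured exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .profiles import CODESYSTEM_NAMES

# ---------------------------------------------------------------------------
# Vocabularies — one code pool per CodeSystem
# ---------------------------------------------------------------------------

CODE_POOLS: dict[str, list[tuple[str, str]]] = {
    "admission-class": [
        ("AMB", "Ambulatory"), ("EMER", "Emergency"), ("IMP", "Inpatient"),
        ("ICU", "Intensive care"),
    ],
    "admission-type": [
        ("ELECTIVE", "Elective admission"), ("URGENT", "Urgent admission"),
        ("EW EMER", "Emergency ward admission"),
        ("OBSERVATION ADMIT", "Observation admission"),
        ("SURGICAL SAME DAY ADMISSION", "Surgical same day admission"),
    ],
    "admission-type-icu": [
        ("ICU ADMIT", "Intensive care unit admission"),
        ("ICU READMIT", "Intensive care unit readmission"),
    ],
    "admission-location": [
        ("EMERGENCY ROOM", "Emergency room"),
        ("PHYSICIAN REFERRAL", "Physician referral"),
        ("TRANSFER FROM HOSPITAL", "Transfer from another hospital"),
        ("WALK-IN/SELF REFERRAL", "Walk-in / self referral"),
        ("CLINIC REFERRAL", "Clinic referral"),
    ],
    "discharge-disposition": [
        ("HOME", "Home"), ("HOME HEALTH CARE", "Home with health care"),
        ("SKILLED NURSING FACILITY", "Skilled nursing facility"),
        ("REHAB", "Rehabilitation facility"), ("DIED", "Died in hospital"),
        ("HOSPICE", "Hospice"),
    ],
    "ed-arrival-transport": [
        ("AMBULANCE", "Ambulance"), ("WALK IN", "Walk in"),
        ("HELICOPTER", "Helicopter"), ("OTHER", "Other transport"),
    ],
    "ed-disposition": [
        ("ADMITTED", "Admitted to hospital"), ("HOME", "Discharged home"),
        ("TRANSFER", "Transferred"), ("ELOPED", "Eloped"),
        ("LEFT WITHOUT BEING SEEN", "Left without being seen"),
    ],
    "careunit": [
        ("MICU", "Medical Intensive Care Unit"),
        ("SICU", "Surgical Intensive Care Unit"),
        ("CCU", "Coronary Care Unit"),
        ("TSICU", "Trauma Surgical Intensive Care Unit"),
        ("MED", "Medicine Ward"), ("CARD", "Cardiology Ward"),
        ("NEURO", "Neurology Ward"), ("ED", "Emergency Department"),
    ],
    "diagnosis-icd9": [
        ("4019", "Unspecified essential hypertension"),
        ("25000", "Diabetes mellitus without complication, type II"),
        ("41401", "Coronary atherosclerosis of native coronary artery"),
        ("42731", "Atrial fibrillation"),
        ("5849", "Acute kidney failure, unspecified"),
        ("486", "Pneumonia, organism unspecified"),
        ("2724", "Other and unspecified hyperlipidemia"),
        ("53081", "Esophageal reflux"),
    ],
    "diagnosis-icd10": [
        ("I10", "Essential (primary) hypertension"),
        ("E119", "Type 2 diabetes mellitus without complications"),
        ("I2510", "Atherosclerotic heart disease of native coronary artery"),
        ("I4891", "Unspecified atrial fibrillation"),
        ("N179", "Acute kidney failure, unspecified"),
        ("J189", "Pneumonia, unspecified organism"),
        ("E785", "Hyperlipidemia, unspecified"),
        ("K219", "Gastro-esophageal reflux disease without esophagitis"),
    ],
    "procedure-icd9": [
        ("3893", "Venous catheterization, not elsewhere classified"),
        ("9604", "Insertion of endotracheal tube"),
        ("9671", "Continuous invasive mechanical ventilation, <96 hours"),
        ("3995", "Hemodialysis"),
        ("8856", "Coronary arteriography using two catheters"),
    ],
    "procedure-icd10": [
        ("02HV33Z", "Insertion of infusion device into superior vena cava"),
        ("5A1945Z", "Respiratory ventilation, 24-96 consecutive hours"),
        ("5A1D70Z", "Performance of urinary filtration, intermittent"),
        ("0BH17EZ", "Insertion of endotracheal airway into trachea"),
        ("B2111ZZ", "Fluoroscopy of multiple coronary arteries"),
    ],
    "procedure-ed": [
        ("SUTURE", "Laceration repair with sutures"),
        ("SPLINT", "Splint application"),
        ("REDUCTION", "Closed fracture reduction"),
        ("INCISION-DRAINAGE", "Incision and drainage"),
        ("INTUBATION-ED", "Emergency endotracheal intubation"),
    ],
    "procedureevents-items": [
        ("225792", "Invasive Ventilation"),
        ("225794", "Non-invasive Ventilation"),
        ("224385", "Intubation"),
        ("225454", "Arterial Line Insertion"),
        ("229351", "Foley Catheter Insertion"),
    ],
    "d-labitems": [
        ("50912", "Creatinine"), ("50971", "Potassium"), ("50983", "Sodium"),
        ("51221", "Hematocrit"), ("51301", "White Blood Cells"),
        ("50820", "pH"), ("51265", "Platelet Count"), ("50931", "Glucose"),
    ],
    "lab-fluid": [
        ("BLOOD", "Blood"), ("URINE", "Urine"),
        ("CEREBROSPINAL FLUID", "Cerebrospinal fluid"),
        ("OTHER BODY FLUID", "Other body fluid"),
    ],
    "lab-flags": [("abnormal", "Abnormal result"), ("delta", "Large change from prior")],
    "lab-priority": [("ROUTINE", "Routine"), ("STAT", "Stat")],
    "units": [
        ("mg/dL", "Milligrams per decilitre"), ("mEq/L", "Milliequivalents per litre"),
        ("%", "Percent"), ("K/uL", "Thousands per microlitre"),
        ("units", "Arbitrary units"), ("mL", "Millilitres"),
        ("mmHg", "Millimetres of mercury"), ("bpm", "Beats per minute"),
        ("insp/min", "Inspirations per minute"), ("degF", "Degrees Fahrenheit"),
        ("mg", "Milligrams"),
    ],
    "microbiology-test": [
        ("90039", "URINE CULTURE"), ("90201", "BLOOD CULTURE"),
        ("90276", "SPUTUM CULTURE"), ("90100", "MRSA SCREEN"),
    ],
    "microbiology-organism": [
        ("80002", "ESCHERICHIA COLI"), ("80004", "STAPH AUREUS COAG +"),
        ("80026", "PSEUDOMONAS AERUGINOSA"), ("80023", "KLEBSIELLA PNEUMONIAE"),
        ("80017", "ENTEROCOCCUS SP."),
    ],
    "microbiology-antibiotic": [
        ("90004", "GENTAMICIN"), ("90005", "CEFTAZIDIME"),
        ("90007", "CIPROFLOXACIN"), ("90012", "TOBRAMYCIN"),
        ("90016", "VANCOMYCIN"), ("90025", "MEROPENEM"),
    ],
    "microbiology-interpretation": [
        ("S", "Sensitive"), ("R", "Resistant"), ("I", "Intermediate"),
        ("P", "Pending"),
    ],
    "spec-type-desc": [
        ("URINE", "Urine"), ("BLOOD CULTURE", "Blood culture"),
        ("SPUTUM", "Sputum"), ("SWAB", "Swab"), ("MRSA SCREEN", "MRSA screen"),
    ],
    "chartevents-items": [
        ("220045", "Heart Rate"),
        ("220179", "Non Invasive Blood Pressure systolic"),
        ("220180", "Non Invasive Blood Pressure diastolic"),
        ("220210", "Respiratory Rate"),
        ("220277", "O2 saturation pulseoxymetry"),
        ("223761", "Temperature Fahrenheit"),
        ("224639", "Daily Weight"),
        ("223900", "GCS - Verbal Response"),
    ],
    "datetimeevents-items": [
        ("224288", "Arterial Line Insertion Date"),
        ("225318", "Foley Insertion Date"),
        ("224289", "Multi Lumen Insertion Date"),
    ],
    "outputevents-items": [
        ("226559", "Foley"), ("226560", "Void"),
        ("226573", "Chest Tube"), ("226588", "Emesis"),
    ],
    "vitalsign-ed": [
        ("temperature", "Temperature"), ("heartrate", "Heart Rate"),
        ("resprate", "Respiratory Rate"), ("o2sat", "Oxygen Saturation"),
        ("sbp", "Systolic Blood Pressure"), ("dbp", "Diastolic Blood Pressure"),
    ],
    "observation-ed": [("rhythm", "Heart Rhythm"), ("pain", "Pain Score")],
    "medication-name": [
        ("Acetaminophen", "Acetaminophen"), ("Heparin", "Heparin"),
        ("Vancomycin", "Vancomycin"), ("Metoprolol Tartrate", "Metoprolol Tartrate"),
        ("Insulin", "Insulin"), ("Furosemide", "Furosemide"),
        ("Norepinephrine", "Norepinephrine"), ("Propofol", "Propofol"),
        ("Aspirin", "Aspirin"), ("Lisinopril", "Lisinopril"),
    ],
    "medication-ndc": [
        ("00904198861", "Acetaminophen"), ("63323026201", "Heparin"),
        ("00409653501", "Vancomycin"), ("55111046705", "Metoprolol Tartrate"),
        ("00002821501", "Insulin"), ("00054829725", "Furosemide"),
        ("00409337501", "Norepinephrine"), ("63323026965", "Propofol"),
        ("63981056310", "Aspirin"), ("68180051301", "Lisinopril"),
    ],
    "medication-route": [
        ("PO", "Oral"), ("IV", "Intravenous"), ("IM", "Intramuscular"),
        ("SC", "Subcutaneous"), ("NG", "Nasogastric"),
    ],
    "medication-frequency": [
        ("QD", "Once daily"), ("BID", "Twice daily"), ("TID", "Three times daily"),
        ("Q4H", "Every 4 hours"), ("Q6H", "Every 6 hours"), ("PRN", "As needed"),
    ],
    "medadmin-category-icu": [
        ("DRIPS", "Continuous infusions"), ("BOLUS", "Bolus medications"),
        ("FLUIDS", "Intravenous fluids"),
    ],
}

NDC_BY_DRUG = {disp: code for code, disp in CODE_POOLS["medication-ndc"]}
ICU_UNITS = ["MICU", "SICU", "CCU", "TSICU"]
WARD_UNITS = ["MED", "CARD", "NEURO"]

# numeric lab/chart item -> (unit, mean, sd); None = text-valued item
LAB_VALUE_MODEL = {
    "50912": ("mg/dL", 1.1, 0.5), "50971": ("mEq/L", 4.1, 0.5),
    "50983": ("mEq/L", 139.0, 3.0), "51221": ("%", 36.0, 5.0),
    "51301": ("K/uL", 9.0, 3.5), "50820": ("units", 7.38, 0.06),
    "51265": ("K/uL", 250.0, 80.0), "50931": ("mg/dL", 120.0, 35.0),
}
CHART_VALUE_MODEL = {
    "220045": ("bpm", 85.0, 15.0), "220179": ("mmHg", 120.0, 18.0),
    "220180": ("mmHg", 70.0, 12.0), "220210": ("insp/min", 18.0, 4.0),
    "220277": ("%", 96.0, 2.5), "223761": ("degF", 98.6, 1.0),
    "224639": ("units", 80.0, 15.0),
}
GCS_VERBAL = ["Oriented", "Confused", "Inappropriate Words", "No Response"]
ED_RHYTHMS = ["Sinus Rhythm", "Atrial Fibrillation", "Sinus Tachycardia"]
VITAL_MODEL = {
    "temperature": (98.6, 1.0), "heartrate": (85.0, 15.0),
    "resprate": (17.0, 4.0), "o2sat": (97.0, 2.0),
    "sbp": (125.0, 18.0), "dbp": (72.0, 12.0),
}
#: Fixed unit per unpivoted ED vital-sign measurement.
VITAL_UNITS = {
    "temperature": "degF", "heartrate": "bpm", "resprate": "insp/min",
    "o2sat": "%", "sbp": "mmHg", "dbp": "mmHg",
}

HOSPITAL_TABLES = (
    "patients", "admissions", "transfers", "diagnoses", "procedures_hosp",
    "labevents", "microbiologyevents", "prescriptions", "pharmacy", "emar",
)
ICU_TABLES = ("icustays", "chartevents", "datetimeevents", "outputevents",
              "procedureevents", "inputevents")
ED_TABLES = ("edstays", "ed_vitalsign", "ed_medrecon", "ed_pyxis", "ed_procedures")
ALL_TABLES = HOSPITAL_TABLES + ICU_TABLES + ED_TABLES

#: Column order and dtype per table ("int" -> nullable Int64, "float" ->
#: float64, "str" -> pandas string; empty CSV field = null for all three).
TABLE_SCHEMAS: dict[str, dict[str, str]] = {
    "patients": {"subject_id": "int", "gender": "str", "anchor_age": "int",
                 "anchor_year": "int", "anchor_year_group": "str", "dod": "str"},
    "admissions": {"subject_id": "int", "hadm_id": "int", "admittime": "str",
                   "dischtime": "str", "admission_type": "str",
                   "admission_location": "str", "discharge_location": "str"},
    "transfers": {"subject_id": "int", "hadm_id": "int", "transfer_id": "int",
                  "eventtype": "str", "careunit": "str", "intime": "str",
                  "outtime": "str"},
    "diagnoses": {"subject_id": "int", "hadm_id": "int", "seq_num": "int",
                  "icd_code": "str", "icd_version": "int"},
    "procedures_hosp": {"subject_id": "int", "hadm_id": "int", "seq_num": "int",
                        "chartdate": "str", "icd_code": "str", "icd_version": "int"},
    "labevents": {"labevent_id": "int", "subject_id": "int", "hadm_id": "int",
                  "specimen_id": "int", "itemid": "str", "fluid": "str",
                  "charttime": "str", "value": "str", "valuenum": "float",
                  "valueuom": "str", "flag": "str"},
    "microbiologyevents": {"microevent_id": "int", "subject_id": "int",
                           "hadm_id": "int", "micro_specimen_id": "int",
                           "spec_type_desc": "str", "charttime": "str",
                           "test_itemid": "str", "org_itemid": "str",
                           "ab_itemid": "str", "interpretation": "str"},
    "prescriptions": {"subject_id": "int", "hadm_id": "int", "pharmacy_id": "int",
                      "drug": "str", "ndc": "str", "starttime": "str",
                      "stoptime": "str", "route": "str", "frequency": "str",
                      "status": "str"},
    "pharmacy": {"pharmacy_id": "int", "subject_id": "int", "hadm_id": "int",
                 "medication": "str", "starttime": "str", "status": "str"},
    "emar": {"emar_id": "str", "subject_id": "int", "hadm_id": "int",
             "pharmacy_id": "int", "charttime": "str", "medication": "str",
             "event_txt": "str", "route_detail": "str"},
    "icustays": {"subject_id": "int", "hadm_id": "int", "stay_id": "int",
                 "first_careunit": "str", "intime": "str", "outtime": "str"},
    "chartevents": {"subject_id": "int", "hadm_id": "int", "stay_id": "int",
                    "charttime": "str", "itemid": "str", "value": "str",
                    "valuenum": "float", "valueuom": "str"},
    "datetimeevents": {"subject_id": "int", "hadm_id": "int", "stay_id": "int",
                       "charttime": "str", "itemid": "str", "value": "str"},
    "outputevents": {"subject_id": "int", "hadm_id": "int", "stay_id": "int",
                     "charttime": "str", "itemid": "str", "value": "float",
                     "valueuom": "str"},
    "procedureevents": {"subject_id": "int", "hadm_id": "int", "stay_id": "int",
                        "starttime": "str", "endtime": "str", "itemid": "str"},
    "inputevents": {"orderid": "int", "subject_id": "int", "hadm_id": "int",
                    "stay_id": "int", "starttime": "str", "endtime": "str",
                    "itemid": "str", "amount": "float", "amountuom": "str",
                    "ordercategoryname": "str", "statusdescription": "str"},
    "edstays": {"subject_id": "int", "hadm_id": "int", "stay_id": "int",
                "intime": "str", "outtime": "str", "arrival_transport": "str",
                "disposition": "str"},
    "ed_vitalsign": {"subject_id": "int", "stay_id": "int", "charttime": "str",
                     "temperature": "float", "heartrate": "float",
                     "resprate": "float", "o2sat": "float", "sbp": "float",
                     "dbp": "float", "rhythm": "str", "pain": "str"},
    "ed_medrecon": {"subject_id": "int", "stay_id": "int", "charttime": "str",
                    "name": "str"},
    "ed_pyxis": {"subject_id": "int", "stay_id": "int", "charttime": "str",
                 "name": "str"},
    "ed_procedures": {"subject_id": "int", "stay_id": "int", "charttime": "str",
                      "code": "str"},
}

_DTYPE = {"int": "Int64", "float": "float64", "str": "string"}


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class SourceDatabase:
    """All relational tables plus the terminology tables, as DataFrames."""

    tables: dict[str, pd.DataFrame]
    terminology: dict[str, pd.DataFrame]

    def equals(self, other: "SourceDatabase") -> bool:
        if set(self.tables) != set(other.tables):
            return False
        if set(self.terminology) != set(other.terminology):
            return False
        return all(
            self.tables[t].equals(other.tables[t]) for t in self.tables
        ) and all(
            self.terminology[t].equals(other.terminology[t]) for t in self.terminology
        )

    def copy(self) -> "SourceDatabase":
        return SourceDatabase(
            {k: v.copy() for k, v in self.tables.items()},
            {k: v.copy() for k, v in self.terminology.items()},
        )


@dataclass
class CohortConfig:
    """Knobs of the generator; defaults define the shipped study conditions."""

    n_patients: int = 100
    seed: int = 7
    missing_status_rate: float = 0.1     # null administration statuses
    mean_admissions: float = 1.5         # per patient (>= 1 enforced)
    mean_transfers: float = 1.0          # extra ward moves per admission
    mean_diagnoses: float = 5.0          # per admission (>= 1 enforced)
    mean_procedures: float = 1.5         # hospital billed, per admission
    mean_lab_specimens: float = 2.0      # per admission (>= 1 enforced)
    mean_labs_per_specimen: float = 4.0  # (>= 1 enforced)
    mean_micro_cultures: float = 0.7     # per admission
    mean_med_orders: float = 3.0         # per admission (>= 1 enforced)
    mean_administrations: float = 2.0    # per medication order
    icu_fraction: float = 0.3            # patients with an ICU stay
    ed_fraction: float = 0.4             # patients with an ED stay
    mean_chartevents: float = 30.0       # per ICU stay (>= 1 enforced)
    mean_datetimeevents: float = 4.0
    mean_outputevents: float = 8.0
    mean_procedureevents: float = 1.5
    mean_inputevents: float = 4.0
    mean_ed_vitals: float = 2.0          # per ED stay (>= 1 enforced)
    mean_ed_pyxis: float = 1.5
    mean_ed_medrecon: float = 2.0
    mean_ed_procedures: float = 0.8

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if not 0.0 <= self.missing_status_rate <= 1.0:
            raise ValueError("missing_status_rate must lie in [0, 1]")
        for name, value in self.__dict__.items():
            if name.startswith("mean_") and (not np.isfinite(value) or value < 0):
                raise ValueError(f"{name} must be finite and non-negative")
        for name in ("icu_fraction", "ed_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass
class DefectSpec:
    """How many defects of each class to inject.

    Each class corrupts source rows so the downstream validator must flag the
    mapped resource with a specific issue class:

    - ``missing_required_element`` -> cardinality (required element absent)
    - ``code_outside_valueset``    -> binding
    - ``dangling_reference``       -> reference
    - ``cardinality_violation``    -> cardinality (duplicate resource)
    """

    missing_required_element: int = 0
    code_outside_valueset: int = 0
    dangling_reference: int = 0
    cardinality_violation: int = 0

    def __post_init__(self) -> None:
        for name, v in self.__dict__.items():
            if v < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def total(self) -> int:
        return (self.missing_required_element + self.code_outside_valueset
                + self.dangling_reference + self.cardinality_violation)


@dataclass(frozen=True)
class DefectRecord:
    defect_class: str
    expected_issue_class: str
    table: str
    row_index: int
    column: str
    resource_profile: str
    resource_id: str
    detail: str


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

_EPOCH = datetime(2100, 1, 1)


def _ts(dt: datetime) -> str:
    return dt.strftime("%Y-%m-%d %H:%M:%S")


def _pois1(rng: np.random.Generator, mean: float) -> int:
    """Poisson with a floor of one event (mean refers to the total)."""
    return 1 + int(rng.poisson(max(mean - 1.0, 0.0)))


def generate_cohort(config: CohortConfig) -> SourceDatabase:
    """Generate the full relational database for one synthetic cohort."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    rows: dict[str, list[dict]] = {t: [] for t in ALL_TABLES}

    hadm_counter = 20_000_000
    transfer_counter = 30_000_000
    labevent_counter = 40_000_000
    specimen_counter = 50_000_000
    microevent_counter = 60_000_000
    micro_specimen_counter = 65_000_000
    pharmacy_counter = 70_000_000
    icu_stay_counter = 80_000_000
    ed_stay_counter = 90_000_000
    order_counter = 95_000_000

    year_groups = ["2008 - 2010", "2011 - 2013", "2014 - 2016", "2017 - 2019"]
    drugs = [d for d, _ in CODE_POOLS["medication-name"]]

    def pick(pool_name: str) -> str:
        pool = CODE_POOLS[pool_name]
        return pool[rng.integers(len(pool))][0]

    for i in range(config.n_patients):
        subject_id = 10_000_000 + i
        gender = "M" if rng.random() < 0.5 else "F"
        anchor_age = int(rng.integers(18, 91))
        anchor_year = 2100 + int(rng.integers(0, 5))
        has_icu = rng.random() < config.icu_fraction
        has_ed = rng.random() < config.ed_fraction

        n_adm = _pois1(rng, config.mean_admissions)
        cursor = datetime(anchor_year, 1, 1) + timedelta(
            days=int(rng.integers(0, 120)), hours=int(rng.integers(0, 24)))
        admissions: list[tuple[int, datetime, datetime]] = []
        last_disch = cursor
        for _ in range(n_adm):
            hadm_counter += 1
            hadm = hadm_counter
            admit = cursor
            los_days = 2 + int(rng.integers(0, 12))
            disch = admit + timedelta(days=los_days, hours=int(rng.integers(0, 24)))
            admissions.append((hadm, admit, disch))
            last_disch = disch
            cursor = disch + timedelta(days=14 + int(rng.integers(0, 60)))

        dod = None
        if rng.random() < 0.10:
            dod = _ts(last_disch + timedelta(days=int(rng.integers(0, 365))))
        rows["patients"].append({
            "subject_id": subject_id, "gender": gender, "anchor_age": anchor_age,
            "anchor_year": anchor_year,
            "anchor_year_group": year_groups[rng.integers(len(year_groups))],
            "dod": dod,
        })

        for adm_ix, (hadm, admit, disch) in enumerate(admissions):
            stay_minutes = int((disch - admit).total_seconds() // 60)
            died = dod is not None and adm_ix == len(admissions) - 1 and rng.random() < 0.3
            rows["admissions"].append({
                "subject_id": subject_id, "hadm_id": hadm,
                "admittime": _ts(admit), "dischtime": _ts(disch),
                "admission_type": pick("admission-type"),
                "admission_location": pick("admission-location"),
                "discharge_location": "DIED" if died else pick("discharge-disposition"),
            })

            # ward trajectory: admit row plus zero or more moves
            n_moves = int(rng.poisson(config.mean_transfers))
            cuts = sorted(rng.integers(1, max(stay_minutes - 1, 2), size=n_moves).tolist())
            bounds = [0] + cuts + [stay_minutes]
            for k in range(len(bounds) - 1):
                transfer_counter += 1
                rows["transfers"].append({
                    "subject_id": subject_id, "hadm_id": hadm,
                    "transfer_id": transfer_counter,
                    "eventtype": "admit" if k == 0 else "transfer",
                    "careunit": WARD_UNITS[rng.integers(len(WARD_UNITS))],
                    "intime": _ts(admit + timedelta(minutes=bounds[k])),
                    "outtime": _ts(admit + timedelta(minutes=bounds[k + 1])),
                })

            for seq in range(_pois1(rng, config.mean_diagnoses)):
                version = 9 if rng.random() < 0.4 else 10
                rows["diagnoses"].append({
                    "subject_id": subject_id, "hadm_id": hadm, "seq_num": seq + 1,
                    "icd_code": pick(f"diagnosis-icd{version}"),
                    "icd_version": version,
                })

            for seq in range(int(rng.poisson(config.mean_procedures))):
                version = 9 if rng.random() < 0.4 else 10
                day = int(rng.integers(0, max((disch - admit).days, 1)))
                rows["procedures_hosp"].append({
                    "subject_id": subject_id, "hadm_id": hadm, "seq_num": seq + 1,
                    "chartdate": (admit + timedelta(days=day)).strftime("%Y-%m-%d"),
                    "icd_code": pick(f"procedure-icd{version}"),
                    "icd_version": version,
                })

            # laboratory: a few specimens, several results each
            for _ in range(_pois1(rng, config.mean_lab_specimens)):
                specimen_counter += 1
                fluid = pick("lab-fluid")
                spec_time = admit + timedelta(minutes=int(rng.integers(0, stay_minutes)))
                for _ in range(_pois1(rng, config.mean_labs_per_specimen)):
                    labevent_counter += 1
                    itemid = pick("d-labitems")
                    u = rng.random()
                    value = valuenum = valueuom = None
                    if u < 0.02:
                        pass  # result never filed -> data-absent downstream
                    elif u < 0.07:
                        value = "POSITIVE" if rng.random() < 0.5 else "NEGATIVE"
                    else:
                        unit, mean, sd = LAB_VALUE_MODEL[itemid]
                        valuenum = round(float(rng.normal(mean, sd)), 2)
                        valueuom = unit
                    rows["labevents"].append({
                        "labevent_id": labevent_counter, "subject_id": subject_id,
                        "hadm_id": hadm, "specimen_id": specimen_counter,
                        "itemid": itemid, "fluid": fluid,
                        "charttime": _ts(min(
                            spec_time + timedelta(minutes=int(rng.integers(0, 240))),
                            disch)),
                        "value": value, "valuenum": valuenum, "valueuom": valueuom,
                        "flag": "abnormal" if rng.random() < 0.2 else None,
                    })

            # microbiology: test -> organism -> susceptibility nesting
            for _ in range(int(rng.poisson(config.mean_micro_cultures))):
                micro_specimen_counter += 1
                spec_type = pick("spec-type-desc")
                test = pick("microbiology-test")
                ctime = _ts(admit + timedelta(minutes=int(rng.integers(0, stay_minutes))))
                common = {
                    "subject_id": subject_id, "hadm_id": hadm,
                    "micro_specimen_id": micro_specimen_counter,
                    "spec_type_desc": spec_type, "charttime": ctime,
                    "test_itemid": test,
                }
                if rng.random() < 0.4:  # culture with no growth
                    microevent_counter += 1
                    rows["microbiologyevents"].append({
                        "microevent_id": microevent_counter, **common,
                        "org_itemid": None, "ab_itemid": None, "interpretation": None,
                    })
                    continue
                orgs = rng.choice(
                    [c for c, _ in CODE_POOLS["microbiology-organism"]],
                    size=int(rng.integers(1, 3)), replace=False)
                for org in orgs:
                    abx = rng.choice(
                        [c for c, _ in CODE_POOLS["microbiology-antibiotic"]],
                        size=int(rng.integers(2, 4)), replace=False)
                    for ab in abx:
                        microevent_counter += 1
                        rows["microbiologyevents"].append({
                            "microevent_id": microevent_counter, **common,
                            "org_itemid": str(org), "ab_itemid": str(ab),
                            "interpretation": pick("microbiology-interpretation"),
                        })

            # medication chain: request -> dispense -> administrations
            for _ in range(_pois1(rng, config.mean_med_orders)):
                pharmacy_counter += 1
                drug = drugs[rng.integers(len(drugs))]
                start = admit + timedelta(minutes=int(rng.integers(0, max(stay_minutes - 1440, 60))))
                stop = min(start + timedelta(days=int(rng.integers(1, 6))), disch)
                rows["prescriptions"].append({
                    "subject_id": subject_id, "hadm_id": hadm,
                    "pharmacy_id": pharmacy_counter, "drug": drug,
                    "ndc": NDC_BY_DRUG[drug], "starttime": _ts(start),
                    "stoptime": _ts(stop), "route": pick("medication-route"),
                    "frequency": pick("medication-frequency"),
                    "status": "completed" if rng.random() < 0.7 else "active",
                })
                if rng.random() < 0.9:
                    rows["pharmacy"].append({
                        "pharmacy_id": pharmacy_counter, "subject_id": subject_id,
                        "hadm_id": hadm, "medication": drug,
                        "starttime": _ts(start + timedelta(minutes=int(rng.integers(10, 120)))),
                        "status": "completed",
                    })
                for k in range(int(rng.poisson(config.mean_administrations))):
                    event = None
                    if rng.random() >= config.missing_status_rate:
                        event = "Administered" if rng.random() < 0.9 else "Not Given"
                    rows["emar"].append({
                        "emar_id": f"{subject_id}-{pharmacy_counter}-{k + 1}",
                        "subject_id": subject_id, "hadm_id": hadm,
                        "pharmacy_id": pharmacy_counter,
                        "charttime": _ts(start + timedelta(hours=6 * k + int(rng.integers(0, 6)))),
                        "medication": drug, "event_txt": event,
                        "route_detail": "via peripheral line" if rng.random() < 0.3 else None,
                    })
            # administrations recorded outside any order
            for k in range(int(rng.poisson(0.3))):
                drug = drugs[rng.integers(len(drugs))]
                rows["emar"].append({
                    "emar_id": f"{subject_id}-{hadm}-stray-{k + 1}",
                    "subject_id": subject_id, "hadm_id": hadm, "pharmacy_id": None,
                    "charttime": _ts(admit + timedelta(minutes=int(rng.integers(0, stay_minutes)))),
                    "medication": drug,
                    "event_txt": None if rng.random() < config.missing_status_rate else "Administered",
                    "route_detail": None,
                })

        # ---------------- ICU stay ----------------
        if has_icu:
            hadm, admit, disch = admissions[int(rng.integers(len(admissions)))]
            icu_stay_counter += 1
            stay_id = icu_stay_counter
            adm_minutes = int((disch - admit).total_seconds() // 60)
            start_min = int(rng.integers(0, adm_minutes // 4 + 1))
            icu_in = admit + timedelta(minutes=start_min)
            icu_out = min(icu_in + timedelta(days=int(rng.integers(1, 5)),
                                             hours=int(rng.integers(0, 24))), disch)
            icu_minutes = max(int((icu_out - icu_in).total_seconds() // 60), 10)
            rows["icustays"].append({
                "subject_id": subject_id, "hadm_id": hadm, "stay_id": stay_id,
                "first_careunit": ICU_UNITS[rng.integers(len(ICU_UNITS))],
                "intime": _ts(icu_in), "outtime": _ts(icu_out),
            })

            def offsets(n: int) -> list[int]:
                n = min(n, icu_minutes - 1)
                return sorted(rng.choice(icu_minutes - 1, size=n, replace=False).tolist())

            n_chart = _pois1(rng, config.mean_chartevents)
            for m in offsets(n_chart):
                itemid = pick("chartevents-items")
                ctime = _ts(icu_in + timedelta(minutes=1 + m))
                if itemid == "223900":
                    rows["chartevents"].append({
                        "subject_id": subject_id, "hadm_id": hadm, "stay_id": stay_id,
                        "charttime": ctime, "itemid": itemid,
                        "value": GCS_VERBAL[rng.integers(len(GCS_VERBAL))],
                        "valuenum": None, "valueuom": None,
                    })
                else:
                    unit, mean, sd = CHART_VALUE_MODEL[itemid]
                    rows["chartevents"].append({
                        "subject_id": subject_id, "hadm_id": hadm, "stay_id": stay_id,
                        "charttime": ctime, "itemid": itemid, "value": None,
                        "valuenum": round(float(rng.normal(mean, sd)), 1),
                        "valueuom": unit,
                    })
            for m in offsets(int(rng.poisson(config.mean_datetimeevents))):
                rows["datetimeevents"].append({
                    "subject_id": subject_id, "hadm_id": hadm, "stay_id": stay_id,
                    "charttime": _ts(icu_in + timedelta(minutes=1 + m)),
                    "itemid": pick("datetimeevents-items"),
                    "value": _ts(icu_in + timedelta(minutes=int(rng.integers(0, m + 1)))),
                })
            for m in offsets(int(rng.poisson(config.mean_outputevents))):
                rows["outputevents"].append({
                    "subject_id": subject_id, "hadm_id": hadm, "stay_id": stay_id,
                    "charttime": _ts(icu_in + timedelta(minutes=1 + m)),
                    "itemid": pick("outputevents-items"),
                    "value": float(rng.integers(10, 600)), "valueuom": "mL",
                })
            for m in offsets(int(rng.poisson(config.mean_procedureevents))):
                dur = int(rng.integers(30, max(icu_minutes - m, 31)))
                rows["procedureevents"].append({
                    "subject_id": subject_id, "hadm_id": hadm, "stay_id": stay_id,
                    "starttime": _ts(icu_in + timedelta(minutes=1 + m)),
                    "endtime": _ts(min(icu_in + timedelta(minutes=1 + m + dur), icu_out)),
                    "itemid": pick("procedureevents-items"),
                })
            for m in offsets(int(rng.poisson(config.mean_inputevents))):
                order_counter += 1
                dur = int(rng.integers(30, max(icu_minutes - m, 31)))
                status = None
                if rng.random() >= config.missing_status_rate:
                    status = "FinishedRunning" if rng.random() < 0.8 else "Stopped"
                rows["inputevents"].append({
                    "orderid": order_counter, "subject_id": subject_id,
                    "hadm_id": hadm, "stay_id": stay_id,
                    "starttime": _ts(icu_in + timedelta(minutes=1 + m)),
                    "endtime": _ts(min(icu_in + timedelta(minutes=1 + m + dur), icu_out)),
                    "itemid": drugs[rng.integers(len(drugs))],
                    "amount": round(float(rng.uniform(1, 500)), 1), "amountuom": "mg",
                    "ordercategoryname": pick("medadmin-category-icu"),
                    "statusdescription": status,
                })

        # ---------------- ED stay ----------------
        if has_ed:
            ed_stay_counter += 1
            stay_id = ed_stay_counter
            linked = rng.random() < 0.5
            if linked:
                hadm, admit, _ = admissions[0]
                ed_in = admit - timedelta(hours=int(rng.integers(2, 10)))
                ed_out = admit
            else:
                hadm = None
                ed_in = datetime(anchor_year, 1, 1) + timedelta(
                    days=int(rng.integers(200, 300)), hours=int(rng.integers(0, 24)))
                ed_out = ed_in + timedelta(hours=int(rng.integers(2, 12)))
            ed_minutes = max(int((ed_out - ed_in).total_seconds() // 60), 10)
            rows["edstays"].append({
                "subject_id": subject_id, "hadm_id": hadm, "stay_id": stay_id,
                "intime": _ts(ed_in), "outtime": _ts(ed_out),
                "arrival_transport": pick("ed-arrival-transport"),
                "disposition": "ADMITTED" if linked else pick("ed-disposition"),
            })

            def ed_offsets(n: int) -> list[int]:
                n = min(n, ed_minutes - 1)
                return sorted(rng.choice(ed_minutes - 1, size=n, replace=False).tolist())

            for m in ed_offsets(_pois1(rng, config.mean_ed_vitals)):
                vit: dict = {"subject_id": subject_id, "stay_id": stay_id,
                             "charttime": _ts(ed_in + timedelta(minutes=1 + m))}
                present = [v for v in VITAL_MODEL if rng.random() < 0.85]
                if not present:
                    present = ["heartrate"]
                for name, (mean, sd) in VITAL_MODEL.items():
                    vit[name] = round(float(rng.normal(mean, sd)), 1) if name in present else None
                vit["rhythm"] = ED_RHYTHMS[rng.integers(len(ED_RHYTHMS))] if rng.random() < 0.5 else None
                vit["pain"] = str(int(rng.integers(0, 11))) if rng.random() < 0.7 else None
                rows["ed_vitalsign"].append(vit)
            for m in ed_offsets(int(rng.poisson(config.mean_ed_pyxis))):
                rows["ed_pyxis"].append({
                    "subject_id": subject_id, "stay_id": stay_id,
                    "charttime": _ts(ed_in + timedelta(minutes=1 + m)),
                    "name": drugs[rng.integers(len(drugs))],
                })
            for m in ed_offsets(int(rng.poisson(config.mean_ed_medrecon))):
                rows["ed_medrecon"].append({
                    "subject_id": subject_id, "stay_id": stay_id,
                    "charttime": _ts(ed_in + timedelta(minutes=1 + m)),
                    "name": drugs[rng.integers(len(drugs))],
                })
            for m in ed_offsets(int(rng.poisson(config.mean_ed_procedures))):
                rows["ed_procedures"].append({
                    "subject_id": subject_id, "stay_id": stay_id,
                    "charttime": _ts(ed_in + timedelta(minutes=1 + m)),
                    "code": pick("procedure-ed"),
                })

    tables = {name: _frame(name, rows[name]) for name in ALL_TABLES}
    terminology = {
        name: pd.DataFrame(CODE_POOLS[name], columns=["code", "display"]).astype("string")
        for name in CODESYSTEM_NAMES
    }
    return SourceDatabase(tables=tables, terminology=terminology)


def _frame(name: str, records: list[dict]) -> pd.DataFrame:
    schema = TABLE_SCHEMAS[name]
    df = pd.DataFrame(records, columns=list(schema))
    for col, kind in schema.items():
        df[col] = df[col].astype(_DTYPE[kind])
    return df


# ---------------------------------------------------------------------------
# Referential integrity
# ---------------------------------------------------------------------------

def check_integrity(db: SourceDatabase) -> list[str]:
    """Return human-readable violations; empty list means the database is sound."""
    t = db.tables
    problems: list[str] = []
    subjects = set(t["patients"]["subject_id"].dropna())
    hadms = set(t["admissions"]["hadm_id"].dropna())
    icu_stays = set(t["icustays"]["stay_id"].dropna())
    ed_stays = set(t["edstays"]["stay_id"].dropna())

    if t["patients"]["subject_id"].duplicated().any():
        problems.append("patients: duplicate subject_id")
    if (t["patients"]["subject_id"] <= 0).any():
        problems.append("patients: non-positive subject_id")

    def fk(table: str, col: str, target: set, allow_null: bool = False) -> None:
        s = t[table][col]
        bad = s.dropna()[~s.dropna().isin(target)]
        if len(bad):
            problems.append(f"{table}.{col}: {len(bad)} unresolved foreign keys")
        if not allow_null and s.isna().any():
            problems.append(f"{table}.{col}: nulls not allowed")

    for table in ALL_TABLES:
        if table == "patients":
            continue
        fk(table, "subject_id", subjects)
    for table in ("admissions", "transfers", "diagnoses", "procedures_hosp",
                  "labevents", "microbiologyevents", "prescriptions",
                  "pharmacy", "icustays", "chartevents", "datetimeevents",
                  "outputevents", "procedureevents", "inputevents", "emar"):
        fk(table, "hadm_id", hadms)
    fk("edstays", "hadm_id", hadms, allow_null=True)
    for table in ("chartevents", "datetimeevents", "outputevents",
                  "procedureevents", "inputevents"):
        fk(table, "stay_id", icu_stays)
    for table in ED_TABLES[1:]:
        fk(table, "stay_id", ed_stays)

    # interval containment: event in stay, stay in admission
    adm = t["admissions"].set_index("hadm_id")
    for _, stay in t["icustays"].iterrows():
        a = adm.loc[stay["hadm_id"]]
        if not (a["admittime"] <= stay["intime"] <= stay["outtime"] <= a["dischtime"]):
            problems.append(f"icustays {stay['stay_id']}: interval outside admission")
    icu = t["icustays"].set_index("stay_id")
    for table, col in (("chartevents", "charttime"), ("datetimeevents", "charttime"),
                       ("outputevents", "charttime"), ("procedureevents", "starttime"),
                       ("inputevents", "starttime")):
        for _, ev in t[table].iterrows():
            s = icu.loc[ev["stay_id"]]
            if pd.notna(ev[col]) and not (s["intime"] <= ev[col] <= s["outtime"]):
                problems.append(f"{table}: event at {ev[col]} outside stay {ev['stay_id']}")
    eds = t["edstays"].set_index("stay_id")
    for table in ED_TABLES[1:]:
        for _, ev in t[table].iterrows():
            s = eds.loc[ev["stay_id"]]
            if not (s["intime"] <= ev["charttime"] <= s["outtime"]):
                problems.append(f"{table}: event at {ev['charttime']} outside stay {ev['stay_id']}")
    for table, col in (("labevents", "charttime"), ("microbiologyevents", "charttime"),
                       ("diagnoses", None)):
        if col is None:
            continue
        for _, ev in t[table].iterrows():
            if pd.isna(ev["hadm_id"]) or pd.isna(ev[col]):
                continue
            a = adm.loc[ev["hadm_id"]]
            if not (a["admittime"] <= ev[col] <= a["dischtime"]):
                problems.append(f"{table}: event at {ev[col]} outside admission {ev['hadm_id']}")
    return problems


# ---------------------------------------------------------------------------
# Defect injection
# ---------------------------------------------------------------------------

def inject_defects(
    db: SourceDatabase, spec: DefectSpec, seed: int
) -> tuple[SourceDatabase, list[DefectRecord]]:
    """Corrupt ``db`` per ``spec``; return the corrupted copy plus a ledger.

    The ledger records, for every defect, the table cell touched and the
    deterministic id of the FHIR resource that must fail validation, with the
    issue class the validator is expected to raise.
    """
    from .transform import assign_id  # deferred: transform imports this module

    db = db.copy()
    rng = np.random.default_rng(seed)
    ledger: list[DefectRecord] = []

    def sample(table: str, n: int, taken: set[int] = frozenset()) -> list[int]:
        eligible = [i for i in range(len(db.tables[table])) if i not in taken]
        if n > len(eligible):
            raise ValueError(
                f"requested {n} defects but only {len(eligible)} eligible rows in {table}")
        picked = rng.choice(len(eligible), size=n, replace=False) if n else []
        return [eligible[int(i)] for i in picked]

    # binding: replace a chartevents item code with one outside every ValueSet
    for j, ix in enumerate(sample("chartevents", spec.code_outside_valueset)):
        ce = db.tables["chartevents"]
        bogus = f"NOTACODE{j}"
        ce.loc[ix, "itemid"] = bogus
        rid = assign_id("Observation", (ce.loc[ix, "stay_id"], ce.loc[ix, "charttime"], bogus))
        ledger.append(DefectRecord(
            "code-outside-valueset", "binding", "chartevents", ix, "itemid",
            "MimicObservationChartevents", rid, f"itemid set to {bogus}"))

    # reference: point a lab event at an admission that does not exist
    lab_taken: set[int] = set()
    max_hadm = int(db.tables["admissions"]["hadm_id"].max())
    for j, ix in enumerate(sample("labevents", spec.dangling_reference)):
        lab_taken.add(ix)
        le = db.tables["labevents"]
        bogus_hadm = max_hadm + 1000 + j
        le.loc[ix, "hadm_id"] = bogus_hadm
        rid = assign_id("Observation", (le.loc[ix, "labevent_id"],))
        ledger.append(DefectRecord(
            "dangling-reference", "reference", "labevents", ix, "hadm_id",
            "MimicObservationLabevents", rid, f"hadm_id set to {bogus_hadm}"))

    # cardinality (min): drop a required timestamp
    for ix in sample("labevents", spec.missing_required_element, taken=lab_taken):
        le = db.tables["labevents"]
        le.loc[ix, "charttime"] = pd.NA
        rid = assign_id("Observation", (le.loc[ix, "labevent_id"],))
        ledger.append(DefectRecord(
            "missing-required-element", "cardinality", "labevents", ix, "charttime",
            "MimicObservationLabevents", rid, "charttime nulled"))

    # cardinality (duplicate): clone an admission row -> two encounters, one id
    dup_ixs = sample("admissions", spec.cardinality_violation)
    if dup_ixs:
        adm = db.tables["admissions"]
        clones = adm.iloc[dup_ixs].copy()
        db.tables["admissions"] = pd.concat([adm, clones], ignore_index=True)
        for ix in dup_ixs:
            hadm = adm.loc[ix, "hadm_id"]
            rid = assign_id("Encounter", (hadm,))
            ledger.append(DefectRecord(
                "cardinality-violation", "cardinality", "admissions", ix, "hadm_id",
                "MimicEncounter", rid, f"admission {hadm} duplicated"))
    return db, ledger


# ---------------------------------------------------------------------------
# CSV I/O  (loader hook: real demo-style CSVs read through the same path)
# ---------------------------------------------------------------------------

def write_csv(db: SourceDatabase, directory: str | Path) -> Path:
    """One comma-delimited file per table; empty field = null."""
    directory = Path(directory)
    (directory / "terminology").mkdir(parents=True, exist_ok=True)
    for name, df in db.tables.items():
        df.to_csv(directory / f"{name}.csv", index=False)
    for name, df in db.terminology.items():
        df.to_csv(directory / "terminology" / f"{name}.csv", index=False)
    return directory


def read_csv(directory: str | Path) -> SourceDatabase:
    """Inverse of :func:`write_csv`; accepts ``.csv`` or ``.csv.gz`` files."""
    directory = Path(directory)
    tables: dict[str, pd.DataFrame] = {}
    for name, schema in TABLE_SCHEMAS.items():
        path = _find(directory, name)
        dtypes = {col: _DTYPE[kind] for col, kind in schema.items()}
        try:
            df = pd.read_csv(path, dtype=dtypes)
        except (ValueError, pd.errors.ParserError) as exc:
            raise ValueError(f"malformed CSV {path.name}: {exc}") from exc
        missing = set(schema) - set(df.columns)
        if missing:
            raise ValueError(f"{path.name}: missing columns {sorted(missing)}")
        tables[name] = df[list(schema)]
    terminology: dict[str, pd.DataFrame] = {}
    for name in CODESYSTEM_NAMES:
        path = _find(directory / "terminology", name)
        df = pd.read_csv(path, dtype="string", keep_default_na=False)
        if list(df.columns[:2]) != ["code", "display"]:
            raise ValueError(f"{path.name}: expected header 'code,display'")
        terminology[name] = df[["code", "display"]].astype("string")
    return SourceDatabase(tables=tables, terminology=terminology)


def _find(directory: Path, name: str) -> Path:
    for suffix in (".csv", ".csv.gz"):
        p = directory / f"{name}{suffix}"
        if p.exists():
            return p
    raise FileNotFoundError(f"mandatory table file {name}.csv not found in {directory}")
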