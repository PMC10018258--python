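# mimic-fhir

Convert a MIMIC-shaped relational critical-care database — hospital, ICU and
emergency-department tables plus local terminology tables — into validated,
profile-conformant FHIR R4 resources.

Critical-care EHR extracts are distributed as relational CSVs whose schema
and vocabularies are local to the source hospital. Exchanging them, loading
them into FHIR servers, or developing against them requires reorganizing the
rows into FHIR resources *and* a conformance package that says precisely
what a valid resource looks like. This package implements that conversion in
four stages, for data engineers and health-informatics researchers working
with MIMIC-style sources:

- **Model** — build the conformance package: 25 profiles derived from base
  FHIR R4 resources (named `Mimic<Resource><Context>`, e.g. `MimicPatient`,
  `MimicObservationMicroSusc`), 2 extensions, and terminology generated
  dynamically from `(code, display)` tables — 34 CodeSystems composed into
  35 ValueSets, including a shared specimen-type ValueSet spanning the
  laboratory and microbiology specimen vocabularies. Element minimum
  cardinalities are raised to 1 exactly where the source column has no
  missing data.
- **Generate** — map relational rows to resources. One row, one resource,
  except four documented aggregations: specimen deduplication, the
  medication catalog, the wide-vitals unpivot, and the microbiology
  test → organism → susceptibility hierarchy (linked by `hasMember` /
  `derivedFrom`). Ids are name-based UUIDs over natural keys, so the
  transform is deterministic. Required statuses absent from the source are
  imputed as `unknown`.
- **Validate** — assemble each patient's resources into a bundle and check
  every resource in-process against the package: cardinalities, fixed
  values, ValueSet bindings, primitive datatype shape, duplicate ids, and
  reference resolution. Bundles validate independently (embarrassingly
  parallel by patient); results are order-invariant.
- **Publish** — bulk-export as NDJSON (one file per profile, one resource
  per line), with a manifest, per-profile totals, median resources per
  patient, and a storage/compression report.

Because the real source is access-restricted, the package includes a
deterministic synthetic generator that emulates the relational schema, the
referential structure (patient → admission → ICU/ED stay → events), the
microbiology hierarchy, the medication request → dispense → administration
workflow, and configurable status missingness — plus a defect injector that
corrupts a database in ledgered ways so validator recall can be measured
exactly. Real demo-shaped CSVs load through the same `read_csv` hook.

## Worked example

The CLI runs the stages end to end:

```sh
mimic-fhir synth --n 100 --seed 7 --out source
mimic-fhir model --terminology source/terminology --out package
mimic-fhir transform --src source --package package --out fhir
mimic-fhir validate --src source --package package --report outcome.json
mimic-fhir stats --src fhir
```

which prints:

```
wrote 21 tables + 34 terminology tables to source
package: 25 profiles, 2 extensions, 34 CodeSystems, 35 ValueSets -> package
read 6448 rows, wrote 7115 resources to fhir
7115 resources in 100 bundles: 0 errors (clean)
Profile                                Total  Median/patient
MimicCondition                           800  7
MimicEncounter                           222  2
MimicLocation                              8  -
...
MimicPatient                             100  1
MimicSpecimen                            441  3
All profiles                            7115
storage: 4366647 bytes (372672 gzipped, ratio 11.72)
```

Reading it: the 100-patient synthetic cohort's 6 448 source rows became
7 115 resources (more than rows, because wide vital-sign rows unpivot and
specimens/medications are added; encounters merge admissions, ICU stays and
ED visits). Every resource validated against the package with zero errors —
the clean-baseline contract of the generator. Medians are per patient over
all 100 patients; shared resources (the Organization, the 8 care-unit
Locations, the 10-formulation Medication catalog) report totals only (`-`).

The same pipeline is available as a library:

```python
import mimic_fhir as mf
from mimic_fhir.profiles import package_from_terminology

db = mf.generate_cohort(mf.CohortConfig(n_patients=100, seed=7))
pkg = package_from_terminology(db.terminology)
resources, report = mf.transform_cohort(db, pkg)
bundles, shared = mf.bundle_cohort(resources)
issues, summary = mf.validate_cohort(bundles, pkg, shared)
assert summary.n_errors == 0 and report.dropped_fields == {}
```

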