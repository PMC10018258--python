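# Methods

`mimic_fhir` converts a MIMIC-shaped relational critical-care database into
FHIR R4 resources in four stages — Model, Generate, Validate, Publish — and
ships a deterministic synthetic source generator so the whole pipeline is
testable without access to the restricted dataset. This note records the
model behind each stage, the choices made where the design was genuinely
open, and what passing tests do and do not establish.

## The conformance model

A *profile* is a constrained view of a base FHIR R4 resource: element
cardinalities, terminology bindings, and occasional fixed values. Profiles
parent directly to base R4 resources (not US Core, whose ValueSet bindings
would force terminology mapping that is explicitly out of scope here) and
follow the naming convention `Mimic<Resource><Context>`: the fixed prefix,
the base resource name, and an optional CamelCase context
(`MimicObservationMicroSusc` is an Observation profiled for microbiology
susceptibility results). The package holds 25 profiles grouped into six
categories — administration (patient, encounters), organizational (hospital,
care units), orders (diagnoses, billed procedures), specimen observations
(labs, microbiology, specimens), charted observations (ICU and ED events),
and medications (the request/dispense/administration family).

**Cardinality tightening.** The minimum cardinality of an element is raised
to 1 exactly when its source column has no missing data; otherwise the base
minimum stands. The shipped constraint set encodes the completeness contract
of the synthetic generator (e.g. `Encounter.period` min 1, because generated
stays always have both endpoints; `hospitalization.admitSource` min 0,
because ICU encounters have none). `tighten_cardinality` recomputes this for
any other source database from a per-path missing-value count.

**Extensions.** Exactly two, both defined here because no base element
houses the information: a Patient-context extension carrying the
deidentification anchor-age-group string, and a MedicationAdministration
extension carrying free-text delivery-route detail (the coded route lives in
`dosage.route`). Both are synthetic stand-ins that preserve the published
artifact count; the source they model does not name its extensions.

**Terminology.** Each local vocabulary becomes a CodeSystem built
dynamically from a two-column `(code, display)` terminology table: codes are
trimmed of surrounding whitespace, case-preserved (hospital codes are
case-significant), deduplicated keeping input order, first display winning
on conflict with a logged warning. ValueSets compose CodeSystems into
bindable code sets. The inventory is 34 CodeSystems and 35 ValueSets: 28
ValueSets encompass exactly their parent CodeSystem, and seven compose
multiple systems where one element legitimately draws on several
vocabularies —

- `specimen-type` = lab fluids + microbiology specimen types, bound at
  `Specimen.type` so specimens referenced from either side validate against
  one set;
- `admission-type`, `admit-source`, `discharge-disposition` merge the
  hospital and ED vocabularies bound at the shared MimicEncounter paths;
- `diagnosis-icd` and `procedure-icd` merge the ICD-9 and ICD-10 eras;
- `medication-code` merges drug names and NDCs for `Medication.code`.

Singleton companions for vocabularies worth querying on their own bring the
total to 35. External standard systems (ICD, NDC) are represented as opaque
CodeSystems populated from the terminology tables, not from official
distributions; mapping local codes to standard ontologies (ConceptMap) is
out of scope. Canonical URLs follow
`http://<base>/fhir/CodeSystem/<name>` (and `/ValueSet/`,
`/StructureDefinition/`); the base defaults to a documentation domain and is
configurable.

## The synthetic source

The generator emulates the relational *structure* the pipeline assumes, not
clinical value distributions: 21 tables with public-schema column names
(`subject_id`, `hadm_id`, `stay_id`, `charttime`, …), terminology tables
generated jointly so every code used by an event has a `(code, display)`
row, and these invariants, asserted by tests on every generated cohort:

- every foreign key resolves; subject ids are positive integers;
- event timestamps lie inside their stay, stays inside their admission;
- microbiology rows encode the test → organism → susceptibility nesting
  (a susceptibility row always carries its organism);
- medications realize request → dispense → administration chains keyed by a
  pharmacy id, with a configurable fraction of standalone administrations;
- a `missing_status_rate` fraction of administration rows (medication
  administration records and ICU infusions) have null status.

Generation is a pure function of `CohortConfig`; identical configs produce
byte-identical CSVs. Dates sit in the 22nd century, mimicking the
deidentification convention of shifted timelines; no real identifiers are
synthesized. Default event rates (per admission: ~5 diagnoses, ~2 lab
specimens × ~4 results, ~0.7 cultures, ~3 medication orders × ~2
administrations; per ICU stay: ~30 chart events; 30% of patients with an
ICU stay, 40% with an ED visit) are structural plausibility choices sized so
a 100-patient cohort (~7 000 resources) exercises every profile while the
full suite runs in seconds. They are free parameters of the generator, not
claims about any real database, whose event volumes are orders of magnitude
larger. Consequently, passing tests establish correctness of the mapping,
validation and export logic on realistic *shapes*; they say nothing about
clinical realism of values, real terminology inventories, or throughput at
full-database scale.

Wide ED vital-sign rows carry the six numeric vitals plus `rhythm` and
`pain`; the numeric columns unpivot to `MimicObservationVitalSigns` (one
observation per non-null measurement, with a fixed unit per vital) and the
two non-numeric columns become `MimicObservationED`. This is the committed
interpretation of the vital-signs/ED-observation split, chosen because the
public ED schema records rhythm and pain in the same charting row.

**Defect injection** corrupts a database in four controlled ways and
returns a ledger naming the table cell touched, the deterministic id of the
affected resource, and the issue class the validator must raise: a chart
item code replaced with one outside every ValueSet (binding), a lab event
pointed at a nonexistent admission (reference), a required timestamp nulled
(cardinality, missing element), and an admission row duplicated so two
encounters share one id (cardinality, max exceeded). Recall is measured
exactly against this ledger.

## Generate

Resource ids are name-based (version-5) UUIDs over `(resource type, natural
key)` under a configurable namespace. This makes the transform a pure
function of its inputs, lets references be built from foreign keys without
lookup tables — and means a corrupted foreign key deterministically yields a
dangling reference the validator can attribute.

One row maps to one resource everywhere except four documented
aggregations: specimen deduplication over specimen id, medication-catalog
deduplication over formulation, the vital-sign unpivot, and microbiology
grouping (one test observation per specimen×test, one organism observation
per test×organism linked from its test via `hasMember`, one susceptibility
observation per row linked to its organism via `derivedFrom`; a no-growth
culture yields a lone test observation). Each aggregation is tested against
a brute-force group-by oracle.

Numerical and degenerate-input choices:

- a lab row with neither numeric nor text result is emitted with
  `dataAbsentReason` rather than dropped, so every source row is captured;
- timestamps serialize as ISO-8601 with an explicit fixed offset (default
  `+00:00`; the source's deidentified local times carry no zone);
- null or absent required statuses are imputed as `unknown`; present raw
  statuses are translated to the R4 code set and an untranslatable status is
  an error, not a silent pass-through;
- administrations whose order link is missing stand alone (no `request`
  reference); ED stays with no resolvable admission get no `partOf`;
- hospital `Encounter.class` is derived from the admission type (the source
  has no class column); ICU and ED encounters carry fixed class/type codes
  from the local vocabularies.

The `MappingReport` records rows read, resources emitted per profile,
columns consumed per table, statuses imputed, and per-row errors. A column
counts as consumed when its value appears in an emitted element or is
recoverable through the reference chain (an event's `hadm_id` via its ICU
encounter's `partOf`; every `subject_id` via the subject reference). The
shipped mapping consumes every generated column, so the dropped-field ledger
is empty and field coverage is 100%.

## Validate

Validation is an in-process library call, not an HTTP server round-trip.
Resources are assembled into per-patient bundles — the patient, everything
whose subject reference names them, plus a shared set (Organization,
Locations, the Medication catalog) visible to all bundles. Per-resource
checks: required elements present, max cardinality, fixed values,
required-strength bindings resolved through ValueSet expansion, and
primitive shape (FHIR date/dateTime lexical form including reduced
precision, version-5 UUID ids, quantities as numeric value + unit).
Per-bundle checks: duplicate resource ids and reference resolution. Binding
failures are errors at required strength, warnings otherwise. Issues carry a
class from {structure, cardinality, binding, reference, datatype}.

Bundles are validated independently, so validation is embarrassingly
parallel by patient; results are sorted before summarizing, making the
outcome invariant to bundle order and partitioning (both asserted). Slicing
and discriminator semantics, FHIRPath invariants, and external terminology
services are out of scope.

## Publish

Resources export as NDJSON, one file per profile, one JSON object per line,
UTF-8, LF endings — strict on write, lenient on read (missing trailing
newline accepted, malformed lines reported with file and line number). The
manifest records per-file counts and byte sizes; export → import → export is
byte-stable. The statistics table reports per-profile totals and the median
resource count per patient, medians taken over *all* patients including
zero-count patients (the denominator convention committed here); shared
resources report totals only. The storage report gives raw and
gzip-compressed sizes — reported, never asserted, since compression ratios
are corpus- and environment-dependent.

## Known limitations

- The synthetic terminology stands in for the real (supplementary)
  vocabularies; `read_csv` is the loader hook through which real
  demo-shaped CSVs and terminology tables would enter the same pipeline.
- Constraint lists per profile are reconstructed from the mapping's needs;
  the source material does not print element-level constraints.
- `MimicProcedure` and `MimicProcedureICU` are deliberately kept separate
  (provenance over simplicity), mirroring the published modeling decision.
- No FHIR-server deployment, HTTP bulk-export API, ShortHand tooling, or
  implementation-guide HTML rendering; the package directory of JSON
  conformance resources plus the NDJSON export replace them at file level.
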