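"""Bulk export as NDJSON and inventory statistics (the Publish stage).

Resources are written one JSON object per line, one file per profile,
following the bulk-data interchange convention: UTF-8, LF line endings,
strict on write, lenient on read (a missing trailing newline is accepted).
The export manifest records per-file counts and byte sizes; the statistics
table reports per-profile totals and the median resource count per patient,
with shared resources (Organization, Locations, the Medication catalog)
reported as totals only.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from .transform import FhirResource
from .validate import SHARED_PROFILES


@dataclass
class ExportManifest:
    files: list[dict] = field(default_factory=list)  # profile, filename, count, bytes
    total_resources: int = 0
    total_bytes: int = 0


@dataclass
class StatsTable:
    """Per-profile totals and per-patient medians, plus the grand total."""

    rows: list[dict] = field(default_factory=list)  # profile, total, median
    grand_total: int = 0

    def row(self, profile: str) -> dict:
        for r in self.rows:
            if r["profile"] == profile:
                return r
        raise KeyError(profile)

    def to_text(self) -> str:
        lines = [f"{'Profile':<36}{'Total':>8}  Median/patient"]
        for r in self.rows:
            med = "-" if r["median"] is None else f"{r['median']:g}"
            lines.append(f"{r['profile']:<36}{r['total']:>8}  {med}")
        lines.append(f"{'All profiles':<36}{self.grand_total:>8}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# NDJSON
# ---------------------------------------------------------------------------

def export_ndjson(
    resources_by_profile: Mapping[str, Sequence[FhirResource]],
    outdir: str | Path,
) -> ExportManifest:
    """Write ``<ProfileName>.ndjson`` per profile plus ``manifest.json``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = ExportManifest()
    for profile in sorted(resources_by_profile):
        fname = f"{profile}.ndjson"
        lines = [json.dumps(r.body, ensure_ascii=False, separators=(",", ":"))
                 for r in resources_by_profile[profile]]
        payload = ("\n".join(lines) + "\n" if lines else "").encode("utf-8")
        (outdir / fname).write_bytes(payload)
        manifest.files.append({
            "profile": profile, "filename": fname,
            "count": len(lines), "bytes": len(payload),
        })
        manifest.total_resources += len(lines)
        manifest.total_bytes += len(payload)
    (outdir / "manifest.json").write_text(
        json.dumps({"files": manifest.files,
                    "total_resources": manifest.total_resources,
                    "total_bytes": manifest.total_bytes}, indent=2) + "\n",
        encoding="utf-8")
    return manifest


def import_ndjson(directory: str | Path) -> dict[str, list[FhirResource]]:
    """Round-trip inverse of :func:`export_ndjson`."""
    directory = Path(directory)
    out: dict[str, list[FhirResource]] = {}
    for path in sorted(directory.glob("*.ndjson")):
        profile = path.stem
        resources: list[FhirResource] = []
        with path.open("r", encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line:
                    continue
                try:
                    body = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise ValueError(f"{path.name}:{lineno}: malformed NDJSON line: {exc}") from exc
                resources.append(FhirResource(
                    resourceType=body["resourceType"], id=body["id"],
                    profile=profile, body=body))
        out[profile] = resources
    return out


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

def summary_stats(
    resources_by_profile: Mapping[str, Sequence[FhirResource]],
    patient_ids: Sequence[str],
    shared_profiles: Sequence[str] = SHARED_PROFILES,
) -> StatsTable:
    """Per-profile totals and median resource count per patient.

    Medians are taken over all patients, including those with zero resources
    of a profile; shared profiles get a total only (median ``None``).
    """
    table = StatsTable()
    patient_index = {f"Patient/{pid}": i for i, pid in enumerate(patient_ids)}
    for profile in sorted(resources_by_profile):
        resources = resources_by_profile[profile]
        total = len(resources)
        table.grand_total += total
        if profile in shared_profiles:
            table.rows.append({"profile": profile, "total": total, "median": None})
            continue
        counts = np.zeros(len(patient_ids), dtype=int)
        for r in resources:
            if r.resourceType == "Patient":
                key = f"Patient/{r.id}"
            else:
                ref = r.body.get("subject") or r.body.get("patient") or {}
                key = ref.get("reference", "")
            if key in patient_index:
                counts[patient_index[key]] += 1
        median = float(np.median(counts)) if len(patient_ids) else 0.0
        table.rows.append({"profile": profile, "total": total, "median": median})
    return table


# ---------------------------------------------------------------------------
# Storage
# ---------------------------------------------------------------------------

def size_report(directory: str | Path) -> dict:
    """Per-file and total byte sizes, raw and gzip-compressed."""
    directory = Path(directory)
    files = []
    total = total_gz = 0
    for path in sorted(directory.glob("*.ndjson")):
        raw = path.read_bytes()
        compressed = len(gzip.compress(raw))
        files.append({"filename": path.name, "bytes": len(raw),
                      "gzip_bytes": compressed})
        total += len(raw)
        total_gz += compressed
    return {
        "files": files,
        "total_bytes": total,
        "total_gzip_bytes": total_gz,
        "compression_ratio": (total / total_gz) if total_gz else None,
    }
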