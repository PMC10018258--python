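"""Local terminology as FHIR CodeSystem / ValueSet definitions.

A hospital EHR carries dozens of local vocabularies — admission types, care
units, lab item identifiers, microorganism names, drug formularies.  Each one
becomes a CodeSystem (the complete enumeration of codes with human-readable
displays) and is composed into ValueSets (the subset of codes legal for a
particular resource element).  Validation of coded elements reduces to
membership queries against expanded ValueSets, which this module answers.

CodeSystems are built dynamically from terminology tables: two-column
(code, display) CSVs, one per vocabulary.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

logger = logging.getLogger("mimic_fhir")

#: Base of every canonical URL minted by this package.  Configurable because
#: canonical URLs are institution-specific; the default is a documentation
#: domain so synthetic artifacts can never collide with a real server.
DEFAULT_CANONICAL_BASE = "http://example.org/mimic"

TERMINOLOGY_VERSION = "0.1.0"


def codesystem_url(name: str, base: str = DEFAULT_CANONICAL_BASE) -> str:
    return f"{base}/fhir/CodeSystem/{name}"


def valueset_url(name: str, base: str = DEFAULT_CANONICAL_BASE) -> str:
    return f"{base}/fhir/ValueSet/{name}"


# ---------------------------------------------------------------------------
# Definitions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Concept:
    """A single code with its human-readable display."""

    code: str
    display: str

    def __post_init__(self) -> None:
        if not self.code:
            raise ValueError("Concept code must be non-empty")


@dataclass
class CodeSystemDef:
    """Complete enumeration of one local vocabulary."""

    url: str
    name: str
    concepts: list[Concept]
    version: str = TERMINOLOGY_VERSION

    def __post_init__(self) -> None:
        codes = [c.code for c in self.concepts]
        if not codes:
            raise ValueError(f"CodeSystem {self.name!r} must contain at least one concept")
        if len(set(codes)) != len(codes):
            raise ValueError(f"CodeSystem {self.name!r} contains duplicate codes")

    @property
    def codes(self) -> set[str]:
        return {c.code for c in self.concepts}

    def __contains__(self, code: str) -> bool:
        return code in self.codes


@dataclass(frozen=True)
class ValueSetInclude:
    """One compose.include entry: a CodeSystem, optionally restricted."""

    system: str
    codes: Optional[tuple[str, ...]] = None  # None = whole system


@dataclass
class ValueSetDef:
    """Composition of one or more CodeSystems into a bindable code set."""

    url: str
    name: str
    includes: list[ValueSetInclude]
    version: str = TERMINOLOGY_VERSION


@dataclass
class TerminologyRegistry:
    """All terminology of one conformance package, closed under reference."""

    codesystems: dict[str, CodeSystemDef] = field(default_factory=dict)
    valuesets: dict[str, ValueSetDef] = field(default_factory=dict)

    def add(self, defn: CodeSystemDef | ValueSetDef) -> None:
        if isinstance(defn, CodeSystemDef):
            if defn.url in self.codesystems:
                raise ValueError(f"duplicate CodeSystem url {defn.url}")
            self.codesystems[defn.url] = defn
        else:
            if defn.url in self.valuesets:
                raise ValueError(f"duplicate ValueSet url {defn.url}")
            self.valuesets[defn.url] = defn

    def check_closure(self) -> None:
        """Raise if any ValueSet include references an absent CodeSystem."""
        for vs in self.valuesets.values():
            for inc in vs.includes:
                if inc.system not in self.codesystems:
                    raise KeyError(
                        f"ValueSet {vs.name!r} includes unknown CodeSystem {inc.system}"
                    )
                if inc.codes is not None:
                    missing = set(inc.codes) - self.codesystems[inc.system].codes
                    if missing:
                        raise KeyError(
                            f"ValueSet {vs.name!r} subset codes absent from "
                            f"{inc.system}: {sorted(missing)}"
                        )


# ---------------------------------------------------------------------------
# Construction
# ---------------------------------------------------------------------------

def build_codesystem(
    table: pd.DataFrame | Iterable[tuple[str, str]],
    name: str,
    url: str,
) -> CodeSystemDef:
    """Build a CodeSystem from a (code, display) terminology table.

    Codes are trimmed of surrounding whitespace and deduplicated keeping
    input order; the first display wins on conflict (warning logged).  Codes
    are case-significant — local hospital vocabularies distinguish case.
    """
    if isinstance(table, pd.DataFrame):
        rows = [(r[0], r[1]) for r in table.itertuples(index=False)]
    else:
        rows = list(table)
    seen: dict[str, str] = {}
    order: list[str] = []
    for raw_code, display in rows:
        code = str(raw_code).strip()
        if not code:
            continue
        display = "" if display is None or (isinstance(display, float) and pd.isna(display)) else str(display)
        if code in seen:
            if seen[code] != display:
                logger.warning(
                    "CodeSystem %s: conflicting displays for code %r "
                    "(%r vs %r); keeping first", name, code, seen[code], display
                )
            continue
        seen[code] = display
        order.append(code)
    if not order:
        raise ValueError(f"terminology table for CodeSystem {name!r} is empty")
    return CodeSystemDef(url=url, name=name, concepts=[Concept(c, seen[c]) for c in order])


def build_valueset(
    name: str,
    url: str,
    codesystems: Sequence[CodeSystemDef],
    subset: Optional[Sequence[str]] = None,
) -> ValueSetDef:
    """Compose CodeSystems into a ValueSet.

    With no ``subset`` the whole of every listed system is included.  A
    subset code must exist in at least one listed system; each include only
    lists the subset codes its own system actually contains.
    """
    if not codesystems:
        raise ValueError(f"ValueSet {name!r} must include at least one CodeSystem")
    includes: list[ValueSetInclude] = []
    if subset is None:
        includes = [ValueSetInclude(cs.url) for cs in codesystems]
    else:
        subset = [str(c).strip() for c in subset]
        unclaimed = set(subset)
        for cs in codesystems:
            here = tuple(c for c in subset if c in cs.codes)
            unclaimed -= set(here)
            if here:
                includes.append(ValueSetInclude(cs.url, here))
        if unclaimed:
            raise KeyError(
                f"ValueSet {name!r}: subset codes {sorted(unclaimed)} not found "
                f"in any listed CodeSystem"
            )
    return ValueSetDef(url=url, name=name, includes=includes)


def expand_valueset(
    vs: ValueSetDef, reg: TerminologyRegistry
) -> set[tuple[str, str]]:
    """Expand to the full set of (system-url, code) pairs the ValueSet admits."""
    out: set[tuple[str, str]] = set()
    for inc in vs.includes:
        cs = reg.codesystems.get(inc.system)
        if cs is None:
            raise KeyError(f"ValueSet {vs.name!r} references unknown CodeSystem {inc.system}")
        codes = cs.codes if inc.codes is None else set(inc.codes)
        out.update((inc.system, c) for c in codes)
    return out


def validate_code(
    system: str, code: str, vs: ValueSetDef, reg: TerminologyRegistry
) -> tuple[bool, str]:
    """Membership verdict for a (system, code) pair against a ValueSet.

    Returns ``(ok, reason)``; never raises for an unknown system — that is a
    false verdict with a reason, matching how binding validation reports it.
    """
    code = str(code).strip()
    if system not in reg.codesystems:
        return False, f"unknown CodeSystem {system}"
    if (system, code) in expand_valueset(vs, reg):
        return True, "ok"
    return False, f"code {code!r} not in ValueSet {vs.name}"


# ---------------------------------------------------------------------------
# I/O — terminology tables and FHIR R4 conformance JSON
# ---------------------------------------------------------------------------

def read_terminology_table(path: str | Path) -> pd.DataFrame:
    """Read one `code,display` CSV (header required)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if list(df.columns[:2]) != ["code", "display"]:
        raise ValueError(f"{path}: expected header 'code,display', got {list(df.columns)}")
    return df[["code", "display"]]


def build_registry(
    terminology: Mapping[str, pd.DataFrame],
    valueset_plan: Sequence[tuple[str, Sequence[str], Optional[Sequence[str]]]],
    base: str = DEFAULT_CANONICAL_BASE,
) -> TerminologyRegistry:
    """Build a registry from named terminology tables plus a ValueSet plan.

    ``valueset_plan`` rows are ``(vs_name, [codesystem names], subset|None)``.
    """
    reg = TerminologyRegistry()
    for name, table in terminology.items():
        reg.add(build_codesystem(table, name, codesystem_url(name, base)))
    by_name = {cs.name: cs for cs in reg.codesystems.values()}
    for vs_name, cs_names, subset in valueset_plan:
        systems = [by_name[n] for n in cs_names]
        reg.add(build_valueset(vs_name, valueset_url(vs_name, base), systems, subset))
    reg.check_closure()
    return reg


def codesystem_to_fhir(cs: CodeSystemDef) -> dict:
    return {
        "resourceType": "CodeSystem",
        "id": cs.name,
        "url": cs.url,
        "version": cs.version,
        "name": _fhir_name(cs.name),
        "status": "active",
        "content": "complete",
        "count": len(cs.concepts),
        "concept": [{"code": c.code, "display": c.display} for c in cs.concepts],
    }


def valueset_to_fhir(vs: ValueSetDef) -> dict:
    includes = []
    for inc in vs.includes:
        entry: dict = {"system": inc.system}
        if inc.codes is not None:
            entry["concept"] = [{"code": c} for c in inc.codes]
        includes.append(entry)
    return {
        "resourceType": "ValueSet",
        "id": vs.name,
        "url": vs.url,
        "version": vs.version,
        "name": _fhir_name(vs.name),
        "status": "active",
        "compose": {"include": includes},
    }


def codesystem_from_fhir(obj: dict) -> CodeSystemDef:
    return CodeSystemDef(
        url=obj["url"],
        name=obj["id"],
        version=obj.get("version", TERMINOLOGY_VERSION),
        concepts=[Concept(c["code"], c.get("display", "")) for c in obj["concept"]],
    )


def valueset_from_fhir(obj: dict) -> ValueSetDef:
    includes = []
    for inc in obj["compose"]["include"]:
        codes = tuple(c["code"] for c in inc["concept"]) if "concept" in inc else None
        includes.append(ValueSetInclude(inc["system"], codes))
    return ValueSetDef(
        url=obj["url"], name=obj["id"],
        version=obj.get("version", TERMINOLOGY_VERSION), includes=includes,
    )


def _fhir_name(name: str) -> str:
    """kebab-case artifact id -> PascalCase computable name."""
    return "".join(part.capitalize() for part in name.replace("_", "-").split("-"))


def dump_json(obj: dict, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, ensure_ascii=False) + "\n", encoding="utf-8")


def load_json(path: Path) -> dict:
    return json.loads(Path(path).read_text(encoding="utf-8"))
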