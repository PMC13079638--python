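"""Questionnaire instrument model: item definitions, domains, and codebook I/O.

The instrument has four sections. Symptom items are 4-point Likert severities
(0 none .. 3 severe) grouped into physiological systems; risk items are binary
exposures grouped into hazard categories; protective-measure items are coded
0 (not used) .. 3 (high effectiveness) grouped into hierarchy-of-controls
levels; demographics are categorical against a controlled vocabulary.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

SECTIONS = ("symptom", "risk", "protection", "demographic")

#: legal code range per section (demographics are string-valued)
SECTION_RANGES = {"symptom": (0, 3), "risk": (0, 1), "protection": (0, 3)}

#: string answer -> code maps, applied when loading CSVs with labelled answers
SYMPTOM_LABELS = {"none": 0, "mild": 1, "moderate": 2, "severe": 3}
RISK_LABELS = {"absent": 0, "present": 1}
PROTECTION_LABELS = {"not_used": 0, "poor": 1, "moderate": 2, "high": 3}
SECTION_LABEL_MAPS = {
    "symptom": SYMPTOM_LABELS,
    "risk": RISK_LABELS,
    "protection": PROTECTION_LABELS,
}


class CodebookError(ValueError):
    """Raised when a codebook fails validation."""


@dataclass(frozen=True)
class ItemDef:
    """One questionnaire item.

    ``domain`` is the physiological system for symptom items, the hazard
    category for risk items, and the control-hierarchy level for protective
    measures.
    """

    id: str
    label: str
    section: str
    domain: str
    scale_min: int
    scale_max: int
    vocabulary: tuple[str, ...] | None = None


@dataclass
class Codebook:
    """Maps every item to its section, domain, and legal value range."""

    items: list[ItemDef]
    systems: list[str]
    risk_categories: list[str]
    protection_categories: list[str]
    name: str = "codebook"

    def __post_init__(self) -> None:
        self.validate()

    # -- accessors ---------------------------------------------------------
    def section_items(self, section: str) -> list[ItemDef]:
        return [it for it in self.items if it.section == section]

    @property
    def symptom_items(self) -> list[ItemDef]:
        return self.section_items("symptom")

    @property
    def risk_items(self) -> list[ItemDef]:
        return self.section_items("risk")

    @property
    def protection_items(self) -> list[ItemDef]:
        return self.section_items("protection")

    @property
    def demographic_items(self) -> list[ItemDef]:
        return self.section_items("demographic")

    def section_ids(self, section: str) -> list[str]:
        return [it.id for it in self.section_items(section)]

    def item(self, item_id: str) -> ItemDef:
        for it in self.items:
            if it.id == item_id:
                return it
        raise KeyError(item_id)

    def domain_of(self, item_id: str) -> str:
        return self.item(item_id).domain

    def system_item_ids(self, system: str) -> list[str]:
        if system not in self.systems:
            raise CodebookError(f"unknown physiological system: {system!r}")
        return [it.id for it in self.symptom_items if it.domain == system]

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        errors: list[str] = []
        seen: set[str] = set()
        for it in self.items:
            if it.id in seen:
                errors.append(f"duplicate item id: {it.id!r}")
            seen.add(it.id)
            if it.section not in SECTIONS:
                errors.append(f"{it.id!r}: unknown section {it.section!r}")
                continue
            if it.section in SECTION_RANGES:
                lo, hi = SECTION_RANGES[it.section]
                if (it.scale_min, it.scale_max) != (lo, hi):
                    errors.append(
                        f"{it.id!r}: {it.section} items must use range "
                        f"{lo}..{hi}, got {it.scale_min}..{it.scale_max}"
                    )
            domains = {
                "symptom": self.systems,
                "risk": self.risk_categories,
                "protection": self.protection_categories,
            }.get(it.section)
            if domains is not None and it.domain not in domains:
                errors.append(f"{it.id!r}: domain {it.domain!r} not declared")
        if errors:
            raise CodebookError("; ".join(errors))


def _codebook_from_dict(raw: Mapping, source: str) -> Codebook:
    try:
        items = [
            ItemDef(
                id=str(d["id"]),
                label=str(d.get("label", d["id"])),
                section=str(d["section"]),
                domain=str(d["domain"]),
                scale_min=int(d.get("scale_min", 0)),
                scale_max=int(d.get("scale_max", 0)),
                vocabulary=tuple(d["vocabulary"]) if d.get("vocabulary") else None,
            )
            for d in raw["items"]
        ]
        return Codebook(
            items=items,
            systems=list(raw["systems"]),
            risk_categories=list(raw["risk_categories"]),
            protection_categories=list(raw["protection_categories"]),
            name=str(raw.get("name", Path(source).stem)),
        )
    except KeyError as exc:
        raise CodebookError(f"{source}: missing required key {exc}") from exc


def load_codebook(path: str | Path) -> Codebook:
    """Load and validate a codebook from JSON or YAML (by file extension)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text(encoding="utf-8")
    suffix = path.suffix.lower()
    if suffix == ".json":
        try:
            raw = json.loads(text)
        except json.JSONDecodeError as exc:
            raise CodebookError(
                f"{path}: malformed JSON at line {exc.lineno}: {exc.msg}"
            ) from exc
    elif suffix in (".yaml", ".yml"):
        try:
            raw = yaml.safe_load(text)
        except yaml.YAMLError as exc:
            mark = getattr(exc, "problem_mark", None)
            line = mark.line + 1 if mark is not None else "?"
            raise CodebookError(f"{path}: malformed YAML at line {line}") from exc
    else:
        raise CodebookError(f"{path}: unsupported codebook format {suffix!r}")
    return _codebook_from_dict(raw, str(path))


def write_codebook(codebook: Codebook, path: str | Path) -> None:
    """Write a codebook as JSON (round-trips through :func:`load_codebook`)."""
    path = Path(path)
    raw = {
        "name": codebook.name,
        "systems": codebook.systems,
        "risk_categories": codebook.risk_categories,
        "protection_categories": codebook.protection_categories,
        "items": [
            {
                "id": it.id,
                "label": it.label,
                "section": it.section,
                "domain": it.domain,
                "scale_min": it.scale_min,
                "scale_max": it.scale_max,
                **({"vocabulary": list(it.vocabulary)} if it.vocabulary else {}),
            }
            for it in codebook.items
        ],
    }
    path.write_text(json.dumps(raw, indent=1) + "\n", encoding="utf-8")


def default_codebook() -> Codebook:
    """The packaged default instrument: 66 symptom items across 10 systems,
    47 binary risk items in 6 hazard categories, 26 protective measures in
    3 control-hierarchy levels, and 6 demographic variables."""
    ref = resources.files("ohsurvey.data").joinpath("default_codebook.json")
    with resources.as_file(ref) as p:
        return load_codebook(p)
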