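"""Respondent-level survey dataset: loading, validation, and result tables.

A :class:`SurveyDataset` holds four aligned tables (symptoms, risks,
protections, demographics) indexed by respondent id, with every cell already
validated against the codebook. Validation is total: a cell either passes or
is named in the error; nothing is silently coerced.
"""
from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Mapping

import numpy as np
import pandas as pd

from .instrument import Codebook, SECTION_LABEL_MAPS, SECTION_RANGES

log = logging.getLogger(__name__)

ID_COLUMN = "respondent_id"

MissingPolicy = Literal["error", "drop", "impute_zero"]


class SurveyValidationError(ValueError):
    """Raised when a survey file fails cell-level validation."""


@dataclass
class SurveyDataset:
    """Aligned respondent-level matrices in codebook item order."""

    respondent_ids: list[str]
    symptoms: pd.DataFrame
    risks: pd.DataFrame
    protections: pd.DataFrame
    demographics: pd.DataFrame

    @property
    def n(self) -> int:
        return len(self.respondent_ids)

    def __post_init__(self) -> None:
        for name in ("symptoms", "risks", "protections", "demographics"):
            frame = getattr(self, name)
            if len(frame) != self.n:
                raise SurveyValidationError(
                    f"{name} has {len(frame)} rows for {self.n} respondents"
                )

    def validate(self, codebook: Codebook) -> None:
        for section, frame in (
            ("symptom", self.symptoms),
            ("risk", self.risks),
            ("protection", self.protections),
        ):
            expected = codebook.section_ids(section)
            if list(frame.columns) != expected:
                missing = sorted(set(expected) - set(frame.columns))
                extra = sorted(set(frame.columns) - set(expected))
                raise SurveyValidationError(
                    f"{section} columns do not match codebook"
                    + (f"; missing {missing}" if missing else "")
                    + (f"; unexpected {extra}" if extra else "")
                )
            lo, hi = SECTION_RANGES[section]
            values = frame.to_numpy()
            bad = np.argwhere((values < lo) | (values > hi))
            if bad.size:
                r, c = bad[0]
                raise SurveyValidationError(
                    f"{section} item {frame.columns[c]!r}, respondent "
                    f"{self.respondent_ids[r]!r}: value {values[r, c]} outside "
                    f"{lo}..{hi} ({len(bad)} offending cell(s) in total)"
                )


def _decode_cell(raw: str, section: str) -> int | None:
    """Map one CSV cell to an integer code, or None if missing."""
    text = str(raw).strip()
    if text == "" or text.lower() in ("nan", "na"):
        return None
    labels = SECTION_LABEL_MAPS[section]
    key = text.lower().replace(" ", "_")
    if key in labels:
        return labels[key]
    try:
        return int(text)
    except ValueError:
        return -(10**9)  # sentinel: guaranteed out of range, reported by caller


def load_survey(
    path: str | Path,
    codebook: Codebook,
    missing: MissingPolicy = "error",
) -> SurveyDataset:
    """Load a wide CSV (one row per respondent, one column per item id).

    Labelled answers ("mild", "present", ...) are mapped to codes via the
    codebook's section coding schemes. ``missing`` selects the missingness
    policy: ``error`` (default), ``drop`` (complete-case, dropped respondents
    logged), or ``impute_zero``.
    """
    path = Path(path)
    frame = pd.read_csv(path, dtype=str)
    if ID_COLUMN not in frame.columns:
        raise SurveyValidationError(f"{path}: missing {ID_COLUMN!r} column")
    ids = frame[ID_COLUMN].astype(str).tolist()
    if len(set(ids)) != len(ids):
        raise SurveyValidationError(f"{path}: duplicate respondent ids")

    scored_ids = {
        s: codebook.section_ids(s) for s in ("symptom", "risk", "protection")
    }
    demo_ids = codebook.section_ids("demographic")
    known = {ID_COLUMN, *demo_ids, *(i for ids_ in scored_ids.values() for i in ids_)}
    unknown = [c for c in frame.columns if c not in known]
    if unknown:
        warnings.warn(f"{path}: ignoring unknown columns {unknown}", stacklevel=2)

    for section, item_ids in scored_ids.items():
        absent = [i for i in item_ids if i not in frame.columns]
        if absent:
            raise SurveyValidationError(f"{path}: missing {section} columns {absent}")
    absent_demo = [i for i in demo_ids if i not in frame.columns]
    if absent_demo:
        raise SurveyValidationError(f"{path}: missing demographic columns {absent_demo}")

    # decode cells section by section, collecting missing / invalid addresses
    decoded: dict[str, pd.DataFrame] = {}
    missing_cells: list[tuple[str, str]] = []
    for section, item_ids in scored_ids.items():
        lo, hi = SECTION_RANGES[section]
        block = np.zeros((len(ids), len(item_ids)), dtype=float)
        for j, item_id in enumerate(item_ids):
            for i, raw in enumerate(frame[item_id]):
                code = _decode_cell(raw, section)
                if code is None:
                    block[i, j] = np.nan
                    missing_cells.append((ids[i], item_id))
                elif code < lo or code > hi:
                    raise SurveyValidationError(
                        f"{path}: {section} item {item_id!r}, respondent "
                        f"{ids[i]!r}: value {raw!r} outside {lo}..{hi}"
                    )
                else:
                    block[i, j] = code
        decoded[section] = pd.DataFrame(block, columns=item_ids)

    demo = frame[demo_ids].astype(str).apply(lambda c: c.str.strip())
    for item in codebook.demographic_items:
        if item.vocabulary:
            bad = sorted(set(demo[item.id]) - set(item.vocabulary) - {"", "nan"})
            if bad:
                raise SurveyValidationError(
                    f"{path}: demographic {item.id!r} has values {bad} outside "
                    f"the controlled vocabulary {list(item.vocabulary)}"
                )

    keep = np.ones(len(ids), dtype=bool)
    if missing_cells:
        if missing == "error":
            rid, item = missing_cells[0]
            raise SurveyValidationError(
                f"{path}: missing answer for item {item!r}, respondent {rid!r} "
                f"({len(missing_cells)} missing cell(s) in total); set a "
                f"missingness policy ('drop' or 'impute_zero') to proceed"
            )
        if missing == "drop":
            dropped = sorted({rid for rid, _ in missing_cells})
            log.warning("dropping %d respondent(s) with missing answers: %s",
                        len(dropped), dropped)
            keep = np.array([rid not in set(dropped) for rid in ids])
        elif missing == "impute_zero":
            for section in decoded:
                decoded[section] = decoded[section].fillna(0.0)

    ids_kept = [rid for rid, k in zip(ids, keep) if k]
    out = {
        section: block.loc[keep].reset_index(drop=True).astype(int)
        for section, block in decoded.items()
    }
    ds = SurveyDataset(
        respondent_ids=ids_kept,
        symptoms=out["symptom"],
        risks=out["risk"],
        protections=out["protection"],
        demographics=demo.loc[keep].reset_index(drop=True),
    )
    ds.validate(codebook)
    return ds


def write_survey(dataset: SurveyDataset, path: str | Path) -> None:
    """Write a dataset as one wide CSV that :func:`load_survey` round-trips."""
    path = Path(path)
    frame = pd.concat(
        [
            pd.DataFrame({ID_COLUMN: dataset.respondent_ids}),
            dataset.symptoms.reset_index(drop=True),
            dataset.risks.reset_index(drop=True),
            dataset.protections.reset_index(drop=True),
            dataset.demographics.reset_index(drop=True),
        ],
        axis=1,
    )
    frame.to_csv(path, index=False, lineterminator="\n")


def config_hash(config: Mapping) -> str:
    """Stable SHA-256 over a JSON-serialisable configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


def write_results(
    tables: Mapping[str, pd.DataFrame],
    out_dir: str | Path,
    config: Mapping | None = None,
) -> dict:
    """Write named result tables as CSVs plus a JSON manifest.

    The manifest lists file names, row counts, and (when a config mapping is
    given) the config hash; reruns with identical inputs produce byte-identical
    files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for name, table in tables.items():
        fname = f"{name}.csv"
        table.to_csv(out_dir / fname, index=False, lineterminator="\n")
        entries.append({"file": fname, "rows": int(len(table))})
    manifest = {
        "tables": entries,
        "config_hash": config_hash(config) if config is not None else None,
    }
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True) + "\n", encoding="utf-8"
    )
    return manifest
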