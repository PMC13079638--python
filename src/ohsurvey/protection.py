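"""Composite protective-effectiveness scoring.

Each protective measure is coded 0 (not used) to 3 (high effectiveness).
The implementation rate IR is the fraction of respondents using the measure
(code >= 1); the mean protective effectiveness MPE is the mean code among
users (range 1..3); the composite protective effectiveness combines both:

    CPE = w_ir * IR + w_mpe * (MPE / 3),   defaults (w_ir, w_mpe) = (0.4, 0.6)

so CPE lies in [0, 1]. Tables report CPE rounded to two decimals; full
precision is retained internally.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .instrument import Codebook
from .dataset import SurveyDataset

DEFAULT_WEIGHTS = {"ir": 0.4, "mpe": 0.6}

#: maximum effectiveness code; MPE is normalized by this scale maximum
SCALE_MAX = 3.0


def _check(protections: pd.DataFrame) -> np.ndarray:
    values = protections.to_numpy()
    if values.shape[0] == 0:
        raise ValueError("protection matrix has no respondents")
    if np.any((values < 0) | (values > 3)):
        raise ValueError("protection codes must lie in 0..3")
    return values


def implementation_rate(protections: pd.DataFrame) -> pd.Series:
    """Per-measure fraction of respondents with code >= 1."""
    values = _check(protections)
    return pd.Series((values >= 1).mean(axis=0), index=protections.columns,
                     name="ir")


def mean_protective_effectiveness(protections: pd.DataFrame) -> pd.Series:
    """Per-measure mean code among users; NaN where nobody uses the measure."""
    values = _check(protections).astype(float)
    used = values >= 1
    counts = used.sum(axis=0)
    if np.any(counts == 0):
        unused = [c for c, k in zip(protections.columns, counts) if k == 0]
        warnings.warn(f"MPE undefined (no users) for: {unused}", stacklevel=2)
    sums = np.where(used, values, 0.0).sum(axis=0)
    means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return pd.Series(means, index=protections.columns, name="mpe")


def composite_protective_effectiveness(
    ir: float,
    mpe: float | None,
    weights: dict[str, float] | None = None,
) -> float | None:
    """CPE = w_ir * IR + w_mpe * MPE / 3; None when MPE is undefined."""
    w = dict(DEFAULT_WEIGHTS if weights is None else weights)
    if abs(sum(w.values()) - 1.0) > 1e-9:
        raise ValueError(f"weights must sum to 1, got {w}")
    if mpe is None or (isinstance(mpe, float) and np.isnan(mpe)):
        return None
    return w["ir"] * ir + w["mpe"] * (mpe / SCALE_MAX)


def rank_measures(
    dataset: SurveyDataset,
    codebook: Codebook,
    weights: dict[str, float] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-measure IR / MPE / CPE ranked by CPE (descending, ties by item
    id), plus category-level mean IR and MPE per control-hierarchy level."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ir = implementation_rate(dataset.protections)
        mpe = mean_protective_effectiveness(dataset.protections)
    rows = []
    for item in codebook.protection_items:
        cpe = composite_protective_effectiveness(
            float(ir[item.id]), float(mpe[item.id]), weights=weights
        )
        rows.append(
            {
                "item": item.id,
                "category": item.domain,
                "ir": float(ir[item.id]),
                "ir_pct": round(100 * float(ir[item.id]), 2),
                "mpe": float(mpe[item.id]),
                "cpe": cpe,
                "cpe_2dp": None if cpe is None else round(cpe, 2),
            }
        )
    table = pd.DataFrame(rows).sort_values(
        ["cpe", "item"], ascending=[False, True], na_position="last"
    ).reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)

    category = (
        table.groupby("category", sort=False)
        .agg(n_measures=("item", "size"), mean_ir=("ir", "mean"),
             mean_mpe=("mpe", "mean"), mean_cpe=("cpe", "mean"))
        .reset_index()
    )
    return table, category
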