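"""Composite risk-factor scoring.

Each binary hazard is scored on three components: exposure prevalence (EP),
the standardized mean difference in total symptom burden between exposed and
unexposed respondents (ES, Cohen's d with pooled SD), and the breadth of
affected physiological systems (BAPS: the number of systems whose scores
differ by exposure under a two-sided Mann-Whitney U test at p < alpha, with
no multiple-testing correction, mirroring the assessment framework). The
composite risk score weights normalized components 50% ES, 30% BAPS, 20% EP.

ES enters the composite as |ES| normalized by the cohort maximum |ES|; BAPS
is normalized by the number of systems. The normalization is a declared,
configurable convention.
"""
from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .instrument import Codebook
from .dataset import SurveyDataset
from .symptoms import system_scores, total_symptom_burden

DEFAULT_WEIGHTS = {"es": 0.5, "baps": 0.3, "ep": 0.2}

#: use exact enumeration of the Mann-Whitney null when both groups are small
EXACT_MAX_GROUP = 8


def exposure_prevalence(risks: pd.DataFrame) -> pd.Series:
    """Per-factor fraction of exposed respondents (column mean)."""
    values = risks.to_numpy()
    if values.shape[0] == 0:
        raise ValueError("risk matrix has no respondents")
    if not np.isin(values, (0, 1)).all():
        raise ValueError("risk codes must be 0 or 1")
    return pd.Series(values.mean(axis=0), index=risks.columns, name="ep")


def effect_size(tsb: np.ndarray | pd.Series, exposure: np.ndarray | pd.Series) -> float | None:
    """Cohen's d for TSB, exposed minus unexposed, pooled SD with
    (n1-1, n2-1) weighting. None (with a warning) when a group is empty or
    the pooled SD is zero."""
    tsb = np.asarray(tsb, dtype=float)
    exposure = np.asarray(exposure)
    a = tsb[exposure == 1]
    b = tsb[exposure == 0]
    if len(a) == 0 or len(b) == 0:
        warnings.warn("effect size undefined: one exposure group is empty",
                      stacklevel=2)
        return None
    if len(a) < 2 and len(b) < 2:
        warnings.warn("effect size undefined: no variance information",
                      stacklevel=2)
        return None
    var_a = a.var(ddof=1) if len(a) > 1 else 0.0
    var_b = b.var(ddof=1) if len(b) > 1 else 0.0
    pooled = ((len(a) - 1) * var_a + (len(b) - 1) * var_b) / (len(a) + len(b) - 2)
    if pooled <= 0:
        warnings.warn("effect size undefined: pooled SD is zero", stacklevel=2)
        return None
    return float((a.mean() - b.mean()) / math.sqrt(pooled))


def _midranks(values: np.ndarray) -> np.ndarray:
    return stats.rankdata(values, method="average")


def mann_whitney_exact(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided exact Mann-Whitney U via full enumeration of group labels.

    Handles ties through midranks: the null distribution of U is built over
    all C(n1+n2, n1) assignments of the observed pooled values to groups, and
    the two-sided p-value is the probability of a U at least as far from its
    null mean as observed. Intended for small groups (enumeration grows
    combinatorially).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    mu = n1 * n2 / 2
    dev = abs(u_obs - mu)
    total = math.comb(n1 + n2, n1)
    hits = 0
    for combo in itertools.combinations(range(n1 + n2), n1):
        u = ranks[list(combo)].sum() - n1 * (n1 + 1) / 2
        if abs(u - mu) >= dev - 1e-12:
            hits += 1
    return float(u_obs), hits / total


def mann_whitney(x, y, exact_max_group: int = EXACT_MAX_GROUP) -> tuple[float, float]:
    """Two-sided Mann-Whitney U: exact enumeration when both groups are
    small, tie-corrected normal approximation (with continuity correction)
    otherwise."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be nonempty")
    if len(x) <= exact_max_group and len(y) <= exact_max_group:
        return mann_whitney_exact(x, y)
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic",
                             use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def baps(
    system_scores_: pd.DataFrame,
    exposure: np.ndarray | pd.Series,
    alpha: float = 0.05,
) -> tuple[int | None, pd.Series]:
    """Breadth of affected physiological systems.

    For each system, compares exposed vs unexposed per-respondent system
    scores with a two-sided Mann-Whitney U test; BAPS counts systems with
    p < alpha. Returns (None, all-NaN p) when a group is empty.
    """
    exposure = np.asarray(exposure)
    mask = exposure == 1
    if mask.all() or not mask.any():
        warnings.warn("BAPS undefined: one exposure group is empty", stacklevel=2)
        return None, pd.Series(np.nan, index=system_scores_.columns, name="p")
    pvals = {}
    for system in system_scores_.columns:
        scores = system_scores_[system].to_numpy(dtype=float)
        _, p = mann_whitney(scores[mask], scores[~mask])
        pvals[system] = p
    p_series = pd.Series(pvals, name="p")
    return int((p_series < alpha).sum()), p_series


def composite_risk_score(
    ep: float,
    es_norm: float | None,
    baps_norm: float | None,
    weights: dict[str, float] | None = None,
) -> float | None:
    """Weighted composite of normalized components (each in [0, 1])."""
    w = dict(DEFAULT_WEIGHTS if weights is None else weights)
    if abs(sum(w.values()) - 1.0) > 1e-9:
        raise ValueError(f"weights must sum to 1, got {w}")
    if es_norm is None or baps_norm is None:
        return None
    return w["es"] * es_norm + w["baps"] * baps_norm + w["ep"] * ep


@dataclass
class RiskTable:
    scores: pd.DataFrame          # item, category, ep, es, baps, crs, rank
    system_pvalues: pd.DataFrame  # long format: item, system, p


def rank_risk_factors(
    dataset: SurveyDataset,
    codebook: Codebook,
    alpha: float = 0.05,
    weights: dict[str, float] | None = None,
) -> RiskTable:
    """Score every risk factor and rank by composite score (descending,
    ties broken by item id). Factors whose ES is undefined (e.g. nobody or
    everybody exposed) carry a null composite and sort last."""
    tsb = total_symptom_burden(dataset.symptoms).to_numpy()
    sys_scores = system_scores(dataset.symptoms, codebook)
    n_systems = len(codebook.systems)
    ep = exposure_prevalence(dataset.risks)

    rows = []
    pval_rows = []
    for item in codebook.risk_items:
        exposure = dataset.risks[item.id].to_numpy()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            es = effect_size(tsb, exposure)
            b, pvals = baps(sys_scores, exposure, alpha=alpha)
        rows.append(
            {"item": item.id, "category": item.domain, "ep": float(ep[item.id]),
             "es": es, "baps": b}
        )
        for system, p in pvals.items():
            pval_rows.append({"item": item.id, "system": system, "p": p})

    table = pd.DataFrame(rows)
    abs_es = table["es"].abs()
    max_es = abs_es.max(skipna=True)
    if pd.isna(max_es) or max_es == 0:
        table["es_norm"] = np.where(table["es"].notna(), 0.0, np.nan)
    else:
        table["es_norm"] = abs_es / max_es
    table["baps_norm"] = table["baps"] / n_systems
    table["protective_direction"] = table["es"] < 0
    table["crs"] = [
        composite_risk_score(r.ep, r.es_norm, r.baps_norm, weights=weights)
        if not (pd.isna(r.es_norm) or pd.isna(r.baps_norm))
        else None
        for r in table.itertuples()
    ]
    table = table.sort_values(
        ["crs", "item"], ascending=[False, True], na_position="last"
    ).reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return RiskTable(scores=table, system_pvalues=pd.DataFrame(pval_rows))
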