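"""Scale reliability and two-sample t-test power.

Cronbach's alpha is computed per multi-item scale with sample variances
(divisor n-1), with a 95% confidence interval from Feldt's F-distribution
method. Power calculations use the noncentral t distribution: for group
sizes n1, n2 and standardized effect d, the noncentrality parameter is
d * sqrt(n1 n2 / (n1 + n2)) with n1 + n2 - 2 degrees of freedom.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class AlphaResult:
    alpha: float
    ci_low: float
    ci_high: float
    n_items: int
    n_respondents: int

    def band(self) -> str:
        """Conventional qualitative reliability band."""
        a = self.alpha
        if a >= 0.8:
            return "good"
        if a >= 0.7:
            return "acceptable"
        if a >= 0.6:
            return "adequate"
        return "poor"


def cronbach_alpha(items: np.ndarray | pd.DataFrame, ci: float = 0.95) -> AlphaResult | None:
    """Cronbach's alpha with Feldt confidence interval.

    alpha = m/(m-1) * (1 - sum of item variances / variance of item sums);
    the CI scales (1 - alpha) by F quantiles with (n-1, (n-1)(m-1)) degrees
    of freedom. Returns None (with a warning) when the total score has zero
    variance.
    """
    values = np.asarray(items, dtype=float)
    if values.ndim != 2:
        raise ValueError("need a 2-D respondents x items matrix")
    n, m = values.shape
    if m < 2:
        raise ValueError("alpha needs at least 2 items")
    if n < 3:
        raise ValueError("alpha needs at least 3 respondents")
    item_vars = values.var(axis=0, ddof=1)
    total_var = values.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        warnings.warn("alpha undefined: total score has zero variance",
                      stacklevel=2)
        return None
    alpha = m / (m - 1) * (1 - item_vars.sum() / total_var)
    df1 = n - 1
    df2 = (n - 1) * (m - 1)
    tail = (1 - ci) / 2
    low = 1 - (1 - alpha) * stats.f.ppf(1 - tail, df1, df2)
    high = 1 - (1 - alpha) * stats.f.ppf(tail, df1, df2)
    return AlphaResult(alpha=float(alpha), ci_low=float(low), ci_high=float(high),
                       n_items=m, n_respondents=n)


def reliability_report(symptoms: pd.DataFrame, codebook) -> pd.DataFrame:
    """Cronbach's alpha per physiological system on the symptom matrix."""
    rows = []
    for system in codebook.systems:
        ids = codebook.system_item_ids(system)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = cronbach_alpha(symptoms[ids])
            except ValueError:
                res = None
        rows.append(
            {
                "system": system,
                "n_items": len(ids),
                "alpha": None if res is None else round(res.alpha, 3),
                "ci_low": None if res is None else round(res.ci_low, 3),
                "ci_high": None if res is None else round(res.ci_high, 3),
                "band": None if res is None else res.band(),
            }
        )
    return pd.DataFrame(rows)


def posthoc_power(
    n1: int, n2: int, d: float, alpha: float = 0.05, tails: int = 2
) -> float:
    """Achieved power of the two-sample t-test via the noncentral t."""
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need at least 2 observations")
    if d < 0:
        raise ValueError("d must be nonnegative")
    if tails not in (1, 2):
        raise ValueError("tails must be 1 or 2")
    df = n1 + n2 - 2
    nc = d * math.sqrt(n1 * n2 / (n1 + n2))
    if tails == 2:
        crit = stats.t.ppf(1 - alpha / 2, df)
        power = stats.nct.sf(crit, df, nc) + stats.nct.cdf(-crit, df, nc)
    else:
        crit = stats.t.ppf(1 - alpha, df)
        power = stats.nct.sf(crit, df, nc)
    return float(power)


def required_sample_size(
    target_power: float = 0.80,
    d: float = 0.5,
    alpha: float = 0.05,
    ratio: float = 1.0,
    tails: int = 2,
    max_total: int = 10_000_000,
) -> int:
    """Smallest total n whose achieved power reaches the target.

    ``ratio`` is n2 / n1; at the default 1:1 allocation the search steps over
    even totals. Raises for d = 0 (unattainable above alpha).
    """
    if not 0 < target_power < 1:
        raise ValueError("target_power must lie in (0, 1)")
    if d <= 0:
        raise ValueError("d must be positive: target power is unattainable at d=0")
    n1 = 2
    while True:
        n2 = max(2, math.ceil(ratio * n1))
        if posthoc_power(n1, n2, d, alpha=alpha, tails=tails) >= target_power:
            return n1 + n2
        n1 += 1
        if n1 + math.ceil(ratio * n1) > max_total:
            raise ValueError("required sample size exceeds search bound")


@dataclass
class PowerReport:
    d: float
    alpha: float
    scenarios: pd.DataFrame   # n1, n2, power
    required_total_n: int

    def to_dict(self) -> dict:
        return {
            "d": self.d,
            "alpha": self.alpha,
            "scenarios": self.scenarios.to_dict(orient="records"),
            "required_total_n": self.required_total_n,
        }


def power_report(
    allocations: list[tuple[int, int]],
    d: float = 0.5,
    alpha: float = 0.05,
    target_power: float = 0.80,
) -> PowerReport:
    rows = [
        {"n1": n1, "n2": n2, "power": round(posthoc_power(n1, n2, d, alpha), 4)}
        for n1, n2 in allocations
    ]
    return PowerReport(
        d=d,
        alpha=alpha,
        scenarios=pd.DataFrame(rows),
        required_total_n=required_sample_size(target_power, d, alpha),
    )
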