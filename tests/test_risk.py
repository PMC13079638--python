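import itertools
import math
import warnings

import numpy as np
import pandas as pd
import pytest

from ohsurvey import (
    baps,
    composite_risk_score,
    effect_size,
    exposure_prevalence,
    mann_whitney,
    rank_risk_factors,
    system_scores,
    total_symptom_burden,
)
from ohsurvey.risk import mann_whitney_exact


def brute_force_cohens_d(a, b):
    """Independent oracle: plain-Python pooled-SD standardized difference."""
    ma = sum(a) / len(a)
    mb = sum(b) / len(b)
    va = sum((x - ma) ** 2 for x in a) / (len(a) - 1) if len(a) > 1 else 0.0
    vb = sum((x - mb) ** 2 for x in b) / (len(b) - 1) if len(b) > 1 else 0.0
    pooled = ((len(a) - 1) * va + (len(b) - 1) * vb) / (len(a) + len(b) - 2)
    return (ma - mb) / math.sqrt(pooled)


def brute_force_mw_p(x, y):
    """Independent oracle: two-sided exact Mann-Whitney by enumerating all
    label permutations with scipy's rankdata only."""
    from scipy.stats import rankdata

    pooled = list(x) + list(y)
    ranks = rankdata(pooled)
    n1 = len(x)
    mu = n1 * len(y) / 2
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    total = hits = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        u = sum(ranks[i] for i in combo) - n1 * (n1 + 1) / 2
        total += 1
        if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
            hits += 1
    return hits / total


class TestExposurePrevalence:
    def test_counting(self):
        col = np.zeros(62, dtype=int)
        col[:37] = 1
        ep = exposure_prevalence(pd.DataFrame({"hypoxia": col, "zero": 0 * col}))
        assert ep["hypoxia"] == pytest.approx(37 / 62)  # 59.7%
        assert ep["zero"] == 0.0

    def test_nonbinary_rejected(self):
        with pytest.raises(ValueError, match="0 or 1"):
            exposure_prevalence(pd.DataFrame({"a": [0, 2]}))


class TestEffectSize:
    def test_identical_means_zero(self):
        assert effect_size([1, 2, 3, 1, 2, 3], [1, 1, 1, 0, 0, 0]) == pytest.approx(0)

    def test_hand_computed_pooled_sd(self):
        # exposed {3,5,7}, unexposed {2,4}: pooled var ((2*4)+(1*2))/3 = 10/3
        d = effect_size([3, 5, 7, 2, 4], [1, 1, 1, 0, 0])
        assert d == pytest.approx(2 / math.sqrt(10 / 3))

    def test_scale_invariance(self):
        tsb = np.array([3.0, 5, 7, 2, 4])
        expo = np.array([1, 1, 1, 0, 0])
        assert effect_size(10 * tsb, expo) == pytest.approx(effect_size(tsb, expo))

    def test_empty_group_is_null(self):
        with pytest.warns(UserWarning, match="empty"):
            assert effect_size([1, 2, 3], [1, 1, 1]) is None

    def test_zero_pooled_sd_is_null(self):
        with pytest.warns(UserWarning, match="pooled SD"):
            assert effect_size([2, 2, 2, 2], [1, 1, 0, 0]) is None

    def test_agrees_with_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        checked = 0
        while checked < 1000:
            n1 = rng.integers(2, 8)
            n2 = rng.integers(2, 8)
            a = rng.integers(0, 20, n1).astype(float)
            b = rng.integers(0, 20, n2).astype(float)
            if a.var(ddof=1) + b.var(ddof=1) == 0:
                continue
            tsb = np.concatenate([a, b])
            expo = np.r_[np.ones(n1, int), np.zeros(n2, int)]
            assert effect_size(tsb, expo) == pytest.approx(
                brute_force_cohens_d(a.tolist(), b.tolist()), abs=1e-12
            )
            checked += 1


class TestMannWhitney:
    def test_identical_tied_groups_p_one(self):
        u, p = mann_whitney_exact([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0)

    def test_maximal_separation_small_groups(self):
        u, p = mann_whitney_exact([4, 5, 6], [1, 2, 3])
        assert u == pytest.approx(9.0)
        assert p == pytest.approx(0.1)  # 2/20 arrangements

    @pytest.mark.parametrize("seed", range(15))
    def test_exact_agrees_with_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 6, rng.integers(2, 7)).astype(float)
        y = rng.integers(0, 6, rng.integers(2, 7)).astype(float)
        _, p = mann_whitney_exact(x, y)
        assert p == pytest.approx(brute_force_mw_p(x, y), abs=1e-12)

    def test_large_groups_use_tie_corrected_normal(self):
        rng = np.random.default_rng(0)
        x = rng.integers(0, 4, 40).astype(float)
        y = rng.integers(0, 4, 45).astype(float) + 1
        from scipy.stats import mannwhitneyu

        u, p = mann_whitney(x, y)
        ref = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert (u, p) == (ref.statistic, ref.pvalue)


class TestBaps:
    def test_strong_shift_affects_all_systems(self):
        rng = np.random.default_rng(42)
        expo = np.r_[np.ones(31, int), np.zeros(31, int)]
        base = rng.normal(0, 1, size=(62, 10))
        base[expo == 1] += 3.0  # 3 SD shift everywhere
        scores = pd.DataFrame(base, columns=[f"sys{i}" for i in range(10)])
        b, pvals = baps(scores, expo)
        assert b == 10
        assert (pvals < 0.05).all()

    def test_empty_group_null(self):
        scores = pd.DataFrame(np.ones((4, 2)), columns=["a", "b"])
        with pytest.warns(UserWarning, match="empty"):
            b, pvals = baps(scores, np.ones(4, dtype=int))
        assert b is None
        assert pvals.isna().all()

    def test_type_one_error_calibration(self, cohort, codebook):
        """Under exposure independent of symptoms, E[BAPS] ~ 10 * alpha."""
        scores = system_scores(cohort.symptoms, codebook)
        rng = np.random.default_rng(2024)
        total = 0
        n_sim = 400
        for _ in range(n_sim):
            expo = rng.integers(0, 2, len(scores))
            while expo.sum() in (0, len(scores)):
                expo = rng.integers(0, 2, len(scores))
            b, _ = baps(scores, expo, alpha=0.05)
            total += b
        mean_baps = total / n_sim
        assert 0.25 <= mean_baps <= 0.75  # 10 * alpha = 0.5, +-50% relative


class TestCompositeScore:
    def test_upper_bound(self):
        assert composite_risk_score(1.0, 1.0, 1.0) == pytest.approx(1.0)

    def test_weighted_arithmetic(self):
        assert composite_risk_score(0.4, 0.8, 0.6) == pytest.approx(0.66)

    def test_zero_components(self):
        assert composite_risk_score(0.0, 0.0, 0.0) == 0.0

    def test_bad_weights_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            composite_risk_score(0.5, 0.5, 0.5,
                                 weights={"es": 0.5, "baps": 0.3, "ep": 0.3})

    def test_monotone_property(self):
        from hypothesis import given, settings
        from hypothesis import strategies as st

        unit = st.floats(0, 1, allow_nan=False)

        @settings(max_examples=200, deadline=None, derandomize=True)
        @given(ep=unit, es=unit, baps_=unit, bump=st.floats(0.01, 0.5))
        def check(ep, es, baps_, bump):
            base = composite_risk_score(ep, es, baps_)
            assert 0 <= base <= 1 + 1e-12
            for kwargs in (
                dict(ep=min(1, ep + bump), es_norm=es, baps_norm=baps_),
                dict(ep=ep, es_norm=min(1, es + bump), baps_norm=baps_),
                dict(ep=ep, es_norm=es, baps_norm=min(1, baps_ + bump)),
            ):
                assert composite_risk_score(**kwargs) >= base - 1e-12

        check()

    @pytest.mark.parametrize("component", ["ep", "es", "baps"])
    def test_monotone_in_each_component(self, component):
        base = {"ep": 0.3, "es_norm": 0.5, "baps_norm": 0.4}
        lo = composite_risk_score(base["ep"], base["es_norm"], base["baps_norm"])
        bumped = dict(base)
        key = {"ep": "ep", "es": "es_norm", "baps": "baps_norm"}[component]
        bumped[key] += 0.2
        hi = composite_risk_score(bumped["ep"], bumped["es_norm"], bumped["baps_norm"])
        assert hi > lo


class TestRanking:
    def test_dominant_factor_ranks_first(self, codebook):
        rng = np.random.default_rng(5)
        n = 80
        symptoms = pd.DataFrame(
            rng.integers(0, 2, size=(n, 66)), columns=codebook.section_ids("symptom")
        )
        risks = pd.DataFrame(
            rng.integers(0, 2, size=(n, 47)), columns=codebook.section_ids("risk")
        )
        strong = codebook.section_ids("risk")[0]
        # make the first factor track a heavy across-the-board burden shift
        risks[strong] = 0
        risks.loc[: n // 2, strong] = 1
        symptoms.loc[risks[strong] == 1] = np.minimum(
            symptoms.loc[risks[strong] == 1] + 2, 3
        )
        ds = _dataset(symptoms, risks, codebook, n)
        table = rank_risk_factors(ds, codebook).scores
        assert table.iloc[0]["item"] == strong

    def test_never_present_factor_flagged(self, cohort, codebook):
        risks = cohort.risks.copy()
        dead = risks.columns[0]
        risks[dead] = 0
        ds = _dataset(cohort.symptoms, risks, codebook, cohort.n)
        table = rank_risk_factors(ds, codebook).scores.set_index("item")
        assert table.loc[dead, "ep"] == 0.0
        assert pd.isna(table.loc[dead, "es"])
        assert pd.isna(table.loc[dead, "crs"])

    def test_configured_strongest_factor_recovered(self):
        """The factor with the largest configured effect ranks in the top 3
        of the composite ranking on sizeable generated cohorts."""
        from dataclasses import replace

        from ohsurvey import default_config, generate

        hits = 0
        n_seeds = 10
        for seed in range(n_seeds):
            cfg = replace(default_config(), n=2000, seed=seed)
            strongest = cfg.codebook.risk_items[
                int(np.argmax(cfg.risk_effects))
            ].id
            ds = generate(cfg)
            table = rank_risk_factors(ds, cfg.codebook).scores
            if strongest in set(table.head(3)["item"]):
                hits += 1
        assert hits >= 0.8 * n_seeds


def _dataset(symptoms, risks, codebook, n):
    from ohsurvey.dataset import SurveyDataset

    ids = [f"R{i:03d}" for i in range(n)]
    prot = pd.DataFrame(
        np.zeros((n, 26), dtype=int), columns=codebook.section_ids("protection")
    )
    demo = pd.DataFrame({"gender": ["male"] * n})
    return SurveyDataset(ids, symptoms.reset_index(drop=True),
                         risks.reset_index(drop=True), prot, demo)
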