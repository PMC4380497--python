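"""Group statistics: exact-test oracles, effect sizes, mixed models."""

import itertools

import numpy as np
import pandas as pd
import pytest

from hydromap.group_stats import (bonferroni, cohens_d, correlate, d_band,
                                  effects_table, fisher_exact, mixed_model,
                                  summary_ttest, wilcoxon_ranksum)


def _enumeration_p(x, y):
    """Exact two-sided rank-sum p by full enumeration of group assignments."""
    pooled = np.concatenate([x, y])
    nx = len(x)
    ranks = pd.Series(pooled).rank().to_numpy()

    def u_of(idx):
        r = ranks[list(idx)].sum()
        return r - nx * (nx + 1) / 2

    mu = nx * len(y) / 2
    obs = abs(u_of(range(nx)) - mu)
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), nx):
        total += 1
        if abs(u_of(idx) - mu) >= obs - 1e-12:
            count += 1
    return count / total


def test_ranksum_matches_the_small_sample_worked_example():
    u, p = wilcoxon_ranksum([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
    assert p == pytest.approx(0.1, abs=1e-12)   # 2 / C(6,3)


def test_ranksum_exact_path_equals_full_enumeration():
    rng = np.random.default_rng(4)
    for nx, ny in [(2, 2), (2, 4), (3, 3), (3, 5), (4, 4), (2, 6)]:
        for _ in range(5):
            x = rng.normal(size=nx)
            y = rng.normal(0.5, size=ny)
            _, p = wilcoxon_ranksum(x, y)
            assert p == pytest.approx(_enumeration_p(x, y), abs=1e-12)


def test_ranksum_requires_two_observations_per_group():
    with pytest.raises(ValueError):
        wilcoxon_ranksum([1.0], [2.0, 3.0])


def test_cohens_d_unit_difference_is_large():
    x = np.array([0.0, 1.0, 2.0]) + 1.0
    y = np.array([0.0, 1.0, 2.0])
    d, band = cohens_d(x, y)
    assert d == pytest.approx(1.0)
    assert band == "large"


def test_effect_size_bands_are_inclusive_upward():
    assert d_band(0.29) == "negligible"
    assert d_band(0.3) == "small"
    assert d_band(0.5) == "medium"
    assert d_band(0.9) == "large"
    assert d_band(-0.95) == "large"


def test_cohens_d_rejects_zero_pooled_sd():
    with pytest.raises(ValueError):
        cohens_d([1.0, 1.0], [1.0, 1.0])


def test_bonferroni_caps_at_one_and_scales_by_m():
    adj = bonferroni([0.01, 0.2, 0.5], m=3)
    assert np.allclose(adj, [0.03, 0.6, 1.0])
    with pytest.raises(ValueError):
        bonferroni([0.01, 0.02], m=1)


def test_summary_ttest_reproduces_published_demographic_rows():
    # age: 45.80 (12.67) vs 50.30 (14.44), n=10/10 -> p = .47
    _, df, p = summary_ttest(45.80, 12.67, 10, 50.30, 14.44, 10)
    assert df == 18
    assert round(p, 2) == 0.47
    # education: 12.00 (3.06) vs 14.00 (2.16) -> p = .11
    _, _, p = summary_ttest(12.00, 3.06, 10, 14.00, 2.16, 10)
    assert round(p, 2) == 0.11


def test_summary_ttest_equals_raw_data_ttest():
    from scipy import stats
    rng = np.random.default_rng(8)
    x, y = rng.normal(0, 1, 12), rng.normal(0.4, 1.3, 9)
    t, _, p = summary_ttest(x.mean(), x.std(ddof=1), x.size,
                            y.mean(), y.std(ddof=1), y.size)
    ref = stats.ttest_ind(x, y, equal_var=True)
    assert t == pytest.approx(ref.statistic, abs=1e-12)
    assert p == pytest.approx(ref.pvalue, abs=1e-12)


def test_fisher_exact_reproduces_published_proportions():
    assert fisher_exact(2, 8, 0, 10) == pytest.approx(0.4737, abs=5e-5)
    assert fisher_exact(3, 7, 0, 10) == pytest.approx(0.2105, abs=5e-5)
    assert fisher_exact(4, 6, 4, 6) == pytest.approx(1.0, abs=1e-12)
    assert fisher_exact(9, 1, 2, 8) == pytest.approx(0.0055, abs=5e-5)


def test_fisher_exact_is_symmetric_under_row_and_column_swaps():
    p = fisher_exact(9, 1, 2, 8)
    assert fisher_exact(2, 8, 9, 1) == pytest.approx(p, abs=1e-12)
    assert fisher_exact(1, 9, 8, 2) == pytest.approx(p, abs=1e-12)


def test_fisher_exact_rejects_negative_counts():
    with pytest.raises(ValueError):
        fisher_exact(-1, 2, 3, 4)


def _long_data(rng, n_per_group=8, group_effect=0.0, interaction=0.0):
    rows = []
    for g in ("hd", "control"):
        for i in range(n_per_group):
            sid = f"{g}{i}"
            b = rng.normal(0, 1)
            for tp in ("1", "2"):
                val = b + rng.normal(0, 1)
                if g == "hd":
                    val += group_effect
                    if tp == "2":
                        val += interaction
                rows.append({"subject": sid, "group": g, "time": tp,
                             "value": val})
    return pd.DataFrame(rows)


def test_mixed_model_detects_a_strong_group_effect():
    rng = np.random.default_rng(2)
    res = mixed_model(_long_data(rng, 10, group_effect=3.0))
    assert res.p_of("group") < 0.01
    assert {"group", "time", "group:time"} <= set(res.effects["effect"])
    with pytest.raises(KeyError):
        res.p_of("site")


def test_mixed_model_handles_missing_repeated_measures():
    rng = np.random.default_rng(6)
    df = _long_data(rng, 10, group_effect=3.0)
    df.loc[df.sample(4, random_state=1).index, "value"] = np.nan
    res = mixed_model(df)
    assert res.p_of("group") < 0.05


def test_mixed_model_requires_multiple_subjects():
    df = pd.DataFrame({"subject": ["a", "a"], "group": ["hd", "hd"],
                       "time": ["1", "2"], "value": [1.0, 2.0]})
    with pytest.raises(ValueError):
        mixed_model(df)


def test_correlations_support_pearson_and_spearman():
    x = np.arange(10.0)
    y = x ** 2
    r_p, _ = correlate(x, y, "pearson")
    r_s, _ = correlate(x, y, "spearman")
    assert r_s == pytest.approx(1.0)
    assert r_p < 1.0
    with pytest.raises(ValueError):
        correlate(x, np.full(10, 2.0))
    with pytest.raises(ValueError):
        correlate(x, y, "kendall")


def test_effects_table_flags_group_difference_with_effect_size():
    rng = np.random.default_rng(12)
    rows = []
    for g, mu in (("hd", 73.0), ("control", 71.5)):
        for i in range(10):
            sid = f"{g}{i}"
            b = rng.normal(0, 0.5)
            for tp in (1, 2):
                rows.append({"subject": sid, "group": g, "timepoint": tp,
                             "roi": "global", "tissue": "wm",
                             "mean_water": mu + b + rng.normal(0, 0.2)})
    out = effects_table(pd.DataFrame(rows))
    grp = out[(out["effect"] == "group")].iloc[0]
    assert grp["p"] < 0.01
    assert grp["band"] == "large"
    assert grp["p_adjusted"] >= grp["p"]
    inter = out[out["effect"] == "group:time"].iloc[0]
    assert inter["p"] > 0.05
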