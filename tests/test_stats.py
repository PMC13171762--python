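"""Grouped binomial GLM, Williams correction, deviance tests, ANOVA, Tukey."""

import itertools
import math
import warnings

import numpy as np
import pytest
from scipy import stats as sps

from femcost import (GroupedBinomialData, compact_letter_display,
                     deviance_test, fit_anova, fit_logistic,
                     overdispersed_group_test, planned_contrast,
                     refit_with_weights, tukey_hsd, williams_correction)
from femcost.stats import SeparationWarning


def gbd(trials, failures, group):
    return GroupedBinomialData(trials=np.asarray(trials),
                               failures=np.asarray(failures),
                               group=np.asarray(group))


def two_group_exact():
    # group proportions exactly 0.20 and 0.04
    return gbd([20] * 5 + [25] * 4, [4] * 5 + [1] * 4,
               ["A"] * 5 + ["B"] * 4)


def test_saturated_two_group_fit_matches_closed_form():
    fit = fit_logistic(two_group_exact(), reference="A")
    logit_a = math.log(0.2 / 0.8)
    logit_b = math.log(0.04 / 0.96)
    assert fit.params[0] == pytest.approx(logit_a, abs=1e-10)
    assert fit.params[0] + fit.params[1] == pytest.approx(logit_b, abs=1e-10)
    odds_ratio = math.exp(-fit.params[1])
    assert odds_ratio == pytest.approx(6.0, abs=1e-8)


def test_one_observation_per_group_is_saturated():
    fit = fit_logistic(gbd([20, 25], [4, 1], ["A", "B"]))
    assert fit.deviance == pytest.approx(0.0, abs=1e-8)
    assert fit.df_resid == 0


def test_deviance_invariant_to_reference_level():
    data = two_group_exact()
    fa = fit_logistic(data, reference="A")
    fb = fit_logistic(data, reference="B")
    assert fa.deviance == pytest.approx(fb.deviance, abs=1e-10)
    assert fa.pearson_chi2 == pytest.approx(fb.pearson_chi2, abs=1e-8)


def test_separation_is_flagged_and_capped():
    data = gbd([20, 20, 20, 20], [0, 0, 5, 4], ["A", "A", "B", "B"])
    with pytest.warns(SeparationWarning):
        fit = fit_logistic(data)
    assert fit.separated
    assert np.all(np.abs(fit.params) <= 15.0 + 1e-9)


def test_coefficient_recovery_simulation(rng):
    """True two-group log-odds are recovered within 2 SE in most replicates."""
    beta0, beta1 = math.log(0.05 / 0.95), 1.5
    p = [1 / (1 + math.exp(-beta0)), 1 / (1 + math.exp(-(beta0 + beta1)))]
    hits = 0
    reps = 200
    for _ in range(reps):
        trials = rng.integers(10, 30, size=200)
        grp = np.repeat(["A", "B"], 100)
        probs = np.where(grp == "A", p[0], p[1])
        fails = rng.binomial(trials, probs)
        fit = fit_logistic(gbd(trials, fails, grp), reference="A")
        # Wald SE from the grouped binomial information at the fitted values
        mu = fit.fitted
        w = trials * mu * (1 - mu)
        X = np.column_stack([np.ones(200), (grp == "B").astype(float)])
        cov = np.linalg.inv(X.T @ (X * w[:, None]))
        se1 = math.sqrt(cov[1, 1])
        hits += abs(fit.params[1] - beta1) < 2 * se1
    assert hits / reps >= 0.90


def test_williams_delta_zero_recovers_uncorrected_fit():
    data = two_group_exact()
    plain = fit_logistic(data)
    weighted = fit_logistic(data, weights=np.ones(data.n_obs))
    assert np.allclose(plain.params, weighted.params, atol=1e-12)
    assert plain.deviance == pytest.approx(weighted.deviance, abs=1e-12)


def test_williams_delta_near_zero_under_pure_binomial(rng):
    reps, small = 200, 0
    for _ in range(reps):
        trials = np.full(100, 20)
        grp = np.repeat(["A", "B"], 50)
        fails = rng.binomial(trials, np.where(grp == "A", 0.15, 0.05))
        fit = williams_correction(gbd(trials, fails, grp))
        small += fit.delta <= 0.01
    assert small / reps >= 0.90


def test_williams_recovers_beta_binomial_heterogeneity(rng):
    """Beta-binomial intra-class correlation 0.1 is recovered within 50%."""
    icc, n_broods = 0.1, 500
    trials = rng.integers(12, 25, size=n_broods)
    grp = np.repeat(["A", "B"], n_broods // 2)
    p = np.where(grp == "A", 0.2, 0.1)
    a = p * (1 - icc) / icc
    b = (1 - p) * (1 - icc) / icc
    probs = rng.beta(a, b)
    fails = rng.binomial(trials, probs)
    fit = williams_correction(gbd(trials, fails, grp))
    assert 0.05 <= fit.delta <= 0.15


def test_williams_unidentifiable_with_single_egg_broods():
    data = gbd([1] * 40, [0, 1] * 20, ["A", "B"] * 20)
    with pytest.warns(UserWarning, match="unidentifiable"):
        fit = williams_correction(data)
    assert fit.delta == 0.0
    assert np.all(fit.weights == 1.0)


def test_williams_pearson_matches_df_at_solution(rng):
    trials = rng.integers(10, 30, size=120)
    grp = np.repeat(["A", "B", "C"], 40)
    p = rng.beta(4, 16, size=120)  # heterogeneous: forces delta > 0
    fails = rng.binomial(trials, p)
    fit = williams_correction(gbd(trials, fails, grp))
    assert fit.delta > 0
    assert fit.pearson_chi2 == pytest.approx(fit.df_resid, abs=1e-4)


def test_deviance_test_trivials():
    data = two_group_exact()
    full = fit_logistic(data)
    t = deviance_test(full, full)
    assert t == (0.0, 0, 1.0)


def test_deviance_test_null_two_groups(rng):
    # identical group proportions: tiny deviance difference, p near 1
    data = gbd([50, 50, 50, 50], [5, 5, 5, 5], ["A", "A", "B", "B"])
    full = fit_logistic(data)
    reduced = fit_logistic(data, design={"A": "all", "B": "all"})
    t = deviance_test(full, reduced)
    assert t.delta_deviance == pytest.approx(0.0, abs=1e-8)
    assert t.p_value > 0.99


def test_deviance_monotone_under_nesting(rng):
    for _ in range(20):
        trials = rng.integers(5, 30, size=60)
        grp = np.repeat(["A", "B", "C"], 20)
        fails = rng.binomial(trials, rng.uniform(0.05, 0.3, size=60))
        full = fit_logistic(gbd(trials, fails, grp))
        reduced = fit_logistic(gbd(trials, fails, grp),
                               design={"A": "x", "B": "x", "C": "C"})
        assert reduced.deviance >= full.deviance - 1e-8


def test_deviance_test_requires_shared_weights():
    data = two_group_exact()
    full = fit_logistic(data, weights=np.full(data.n_obs, 0.5))
    reduced = fit_logistic(data, design={"A": "all", "B": "all"})
    with pytest.raises(ValueError):
        deviance_test(full, reduced)


def test_corrected_test_restores_type_I_error(rng):
    """Under beta-binomial overdispersion with no group effect, the
    Williams-corrected deviance test is closer to nominal size than the
    uncorrected one (paired moderate-rep check; full reps in acceptance)."""
    reps, icc = 300, 0.08
    rej_corr = rej_raw = 0
    for _ in range(reps):
        trials = rng.integers(10, 25, size=60)
        grp = np.repeat(["A", "B"], 30)
        a, b = 0.15 * (1 - icc) / icc, 0.85 * (1 - icc) / icc
        fails = rng.binomial(trials, rng.beta(a, b, size=60))
        data = gbd(trials, fails, grp)
        t_corr, _, _ = overdispersed_group_test(data)
        t_raw, _, _ = overdispersed_group_test(data, correct=False)
        rej_corr += t_corr.p_value < 0.05
        rej_raw += t_raw.p_value < 0.05
    assert abs(rej_corr / reps - 0.05) < abs(rej_raw / reps - 0.05)
    assert rej_corr / reps < 0.12


# ---------------------------------------------------------------------------
# one-way linear model


def test_anova_hand_computed_toy():
    # SSB = 3*(2-3.5)^2 + 3*(5-3.5)^2 = 13.5 on 1 df; SSE = 4 on 4 df
    fit = fit_anova([1, 2, 3, 4, 5, 6], ["a"] * 3 + ["b"] * 3)
    assert fit.F == pytest.approx(13.5, abs=1e-12)
    assert (fit.df_between, fit.df_resid) == (1, 4)
    assert fit.ss_between == pytest.approx(13.5)
    assert fit.ss_resid == pytest.approx(4.0)
    ref = sps.f_oneway([1, 2, 3], [4, 5, 6])
    assert fit.F == pytest.approx(ref.statistic, abs=1e-12)
    assert fit.p_value == pytest.approx(ref.pvalue, abs=1e-12)


def test_anova_degenerate_inputs():
    fit = fit_anova([5.0] * 6, ["a"] * 3 + ["b"] * 3)
    assert fit.F == 0.0
    with pytest.raises(ValueError):  # group difference but zero residual noise
        fit_anova([1, 1, 1, 2, 2, 2], ["a"] * 3 + ["b"] * 3)
    with pytest.raises(ValueError):
        fit_anova([1, 2, 3], ["a"] * 3)


def test_anova_null_p_values_uniform(rng):
    ps = []
    for _ in range(1000):
        y = rng.normal(size=30)
        g = np.repeat(["a", "b", "c"], 10)
        ps.append(fit_anova(y, g).p_value)
    stat, p = sps.kstest(ps, "uniform")
    assert p > 0.01


def test_planned_contrast_properties():
    y = [10, 11, 12, 20, 21, 22, 15, 14, 16]
    g = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
    fit = fit_anova(y, g)
    c1 = planned_contrast(fit, ["a"], ["b"])
    c2 = planned_contrast(fit, ["b"], ["a"])
    assert c1.t == pytest.approx(-c2.t)
    assert c1.df == fit.df_resid
    # equal set means: zero statistic
    fit2 = fit_anova([1, 2, 3, 1, 2, 3, 9, 9, 8], g)
    assert planned_contrast(fit2, ["a"], ["b"]).t == pytest.approx(0.0)
    with pytest.raises(ValueError):
        planned_contrast(fit, ["a"], [])
    with pytest.raises(ValueError):
        planned_contrast(fit, ["a"], ["a", "b"])


def test_planned_contrast_matches_two_sample_when_balanced(rng):
    # with two groups, the contrast t equals the pooled two-sample t
    y = rng.normal(size=40) + np.repeat([0.0, 1.0], 20)
    g = np.repeat(["a", "b"], 20)
    fit = fit_anova(y, g)
    con = planned_contrast(fit, ["a"], ["b"])
    t, p = sps.ttest_ind(y[:20], y[20:])
    assert con.t == pytest.approx(t, abs=1e-10)
    assert con.p_value == pytest.approx(p, abs=1e-10)


# ---------------------------------------------------------------------------
# Tukey-Kramer and compact letter display


def test_tukey_identical_groups_share_one_letter(rng):
    y = np.concatenate([rng.normal(0, 1, 10) for _ in range(3)])
    g = np.repeat(["a", "b", "c"], 10)
    res = tukey_hsd(fit_anova(y, g))
    assert set(res.letters.values()) == {"A"}


def test_tukey_separated_groups_get_distinct_letters(rng):
    y = np.concatenate([rng.normal(0, 1, 10), rng.normal(100, 1, 10)])
    g = np.repeat(["lo", "hi"], 10)
    res = tukey_hsd(fit_anova(y, g))
    assert res.letters["hi"] == "A" and res.letters["lo"] == "B"
    assert res.table["reject"].all()


def test_tukey_matches_scipy_p_values(rng):
    y = rng.normal(size=40) + np.repeat([0, 0.5, 1.0, 2.0], 10)
    g = np.repeat(["a", "b", "c", "d"], 10)
    res = tukey_hsd(fit_anova(y, g))
    ref = sps.tukey_hsd(*(y[g == lev] for lev in "abcd"))
    for _, row in res.table.iterrows():
        i, j = "abcd".index(row["group1"]), "abcd".index(row["group2"])
        assert row["p"] == pytest.approx(ref.pvalue[i, j], abs=1e-6)


def _brute_force_letters(groups, sig_pairs):
    """Oracle: letters = maximal cliques of the non-significance graph."""
    sig = {frozenset(p) for p in sig_pairs}
    cliques = []
    for r in range(1, len(groups) + 1):
        for sub in itertools.combinations(groups, r):
            if all(frozenset(p) not in sig
                   for p in itertools.combinations(sub, 2)):
                cliques.append(set(sub))
    return [c for c in cliques
            if not any(c < other for other in cliques)]


@pytest.mark.parametrize("n_groups,seed", [(3, 0), (4, 1), (5, 2), (6, 3),
                                           (6, 4), (6, 5), (5, 6), (4, 7)])
def test_letter_display_matches_clique_cover_oracle(n_groups, seed):
    """Insert-and-absorb letters equal the exhaustive maximal-clique cover
    for random significance patterns on up to six groups."""
    r = np.random.default_rng(seed)
    groups = [f"g{i}" for i in range(n_groups)]
    sig = {(a, b) for a, b in itertools.combinations(groups, 2)
           if r.random() < 0.4}
    letters = compact_letter_display(groups, sig)
    got = {}
    for g, ls in letters.items():
        for letter in ls:
            got.setdefault(letter, set()).add(g)
    expected = _brute_force_letters(groups, sig)
    assert sorted(map(sorted, got.values())) == sorted(map(sorted, expected))
    # semantic check: share a letter iff not significant
    for a, b in itertools.combinations(groups, 2):
        share = bool(set(letters[a]) & set(letters[b]))
        assert share == ((a, b) not in sig and (b, a) not in sig)


def test_tukey_letters_consistent_with_significance_matrix(rng):
    y = np.concatenate([rng.normal(m, 1.0, 12) for m in (0, 0.6, 1.4, 3.0, 3.1)])
    g = np.repeat(list("abcde"), 12)
    res = tukey_hsd(fit_anova(y, g))
    for _, row in res.table.iterrows():
        share = bool(set(res.letters[row["group1"]])
                     & set(res.letters[row["group2"]]))
        assert share != row["reject"]
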