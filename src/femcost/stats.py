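"""Inferential statistics for brood-level egg-viability data.

Egg development is analysed as grouped binomial counts (per brood: eggs
laid, eggs undeveloped) with a logistic link. Brood-level heterogeneity
beyond binomial sampling is handled by Williams' moment correction: a
heterogeneity parameter ``delta`` is estimated so that, after refitting
with weights ``w_i = 1 / (1 + delta * (n_i - 1))``, the Pearson chi-square
of the weighted fit equals its residual degrees of freedom. Nested model
comparisons are deviance-difference (chi-square) tests with the full
model's Williams weights held fixed, so the deviances are comparable.

Total eggs per brood are compared with a one-way fixed-effects linear
model, a planned contrast on the pooled residual mean square, and
Tukey-Kramer all-pairs comparisons summarised as a compact letter display.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, NamedTuple, Sequence, Set, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

_LOGODDS_CAP = 15.0  # reporting cap for separated (all-0 / all-1) groups


class SeparationWarning(UserWarning):
    """A group with all-developed or all-undeveloped eggs was fitted."""


@dataclass(frozen=True)
class GroupedBinomialData:
    """Per-brood trials (eggs laid), failures (undeveloped) and group label."""

    trials: np.ndarray
    failures: np.ndarray
    group: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.trials, dtype=np.int64)
        f = np.asarray(self.failures, dtype=np.int64)
        g = np.asarray(self.group)
        if not (t.shape == f.shape == g.shape):
            raise ValueError("trials, failures and group must have equal length")
        if (t < 1).any():
            raise ValueError("all trials must be >= 1")
        if ((f < 0) | (f > t)).any():
            raise ValueError("failures must satisfy 0 <= failures <= trials")
        object.__setattr__(self, "trials", t)
        object.__setattr__(self, "failures", f)
        object.__setattr__(self, "group", g)

    @classmethod
    def from_broods(cls, broods: pd.DataFrame) -> "GroupedBinomialData":
        return cls(trials=broods["eggs_laid"].to_numpy(),
                   failures=broods["eggs_undeveloped"].to_numpy(),
                   group=broods["symbiotype"].to_numpy())

    @property
    def n_obs(self) -> int:
        return int(self.trials.size)


@dataclass(frozen=True)
class GlmFit:
    """A (possibly Williams-weighted) grouped binomial logistic fit."""

    params: np.ndarray            # coefficients on the logit scale
    param_names: Tuple[str, ...]
    deviance: float
    pearson_chi2: float
    df_resid: int
    delta: float                  # Williams heterogeneity (0 = uncorrected)
    weights: np.ndarray = field(repr=False)
    fitted: np.ndarray = field(repr=False)  # fitted failure probability per brood
    n_params: int = 0
    separated: bool = False


class DevianceTest(NamedTuple):
    delta_deviance: float
    df: int
    p_value: float


def _design_matrix(group: np.ndarray, design: Mapping[str, str] | None,
                   reference: str | None) -> Tuple[np.ndarray, Tuple[str, ...]]:
    """Reference-coded dummy design from group labels.

    ``design`` optionally coarsens groups into factor levels (e.g. mapping
    every symbiotype to "feminized"/"unfeminized"); ``None`` keeps groups
    as-is. An all-constant mapping yields the intercept-only design.
    """
    levels_per_obs = np.array([design[g] if design is not None else g for g in group])
    levels = sorted(set(levels_per_obs.tolist()))
    if reference is not None:
        if reference not in levels:
            raise ValueError(f"reference level {reference!r} not among {levels}")
        levels = [reference] + [l for l in levels if l != reference]
    n = levels_per_obs.size
    X = np.ones((n, len(levels)))
    names = ["intercept"]
    for j, lev in enumerate(levels[1:], start=1):
        X[:, j] = (levels_per_obs == lev).astype(float)
        names.append(str(lev))
    return X, tuple(names)


def _check_separation(data: GroupedBinomialData,
                      design: Mapping[str, str] | None) -> bool:
    levels = np.array([design[g] if design is not None else g for g in data.group])
    for lev in set(levels.tolist()):
        m = levels == lev
        tot_f, tot_t = data.failures[m].sum(), data.trials[m].sum()
        if tot_f == 0 or tot_f == tot_t:
            return True
    return False


def fit_logistic(data: GroupedBinomialData,
                 design: Mapping[str, str] | None = None,
                 weights: np.ndarray | None = None,
                 reference: str | None = None,
                 delta: float = 0.0,
                 max_iter: int = 100) -> GlmFit:
    """Maximum-likelihood grouped binomial logistic regression (IRLS).

    The response is the per-brood proportion of undeveloped eggs; optional
    per-observation weights (e.g. Williams weights) scale each brood's
    effective trial count. Deviance and Pearson chi-square are on the
    grouped binomial scale. Groups whose eggs all developed (or all failed)
    produce infinite maximum-likelihood log-odds; such fits are flagged and
    the reported coefficients are capped at +/- 15 on the logit scale.
    """
    X, names = _design_matrix(data.group, design, reference)
    if data.n_obs <= X.shape[1] - 1:
        raise ValueError("need more observations than non-intercept parameters")
    w = np.ones(data.n_obs) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != (data.n_obs,) or (w <= 0).any() or (w > 1).any():
        raise ValueError("weights must be per-observation values in (0, 1]")

    separated = _check_separation(data, design)
    y = data.failures / data.trials
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # statsmodels warns on its own separation path
        model = sm.GLM(y, X, family=sm.families.Binomial(),
                       var_weights=w * data.trials)
        res = model.fit(maxiter=max_iter, tol=1e-10)
    if not res.converged and not separated:
        raise RuntimeError(
            f"IRLS failed to converge in {max_iter} iterations; "
            f"last params {res.params}")

    params = np.asarray(res.params, dtype=float)
    if separated:
        warnings.warn("a group has all-0 or all-1 outcomes; coefficients are "
                      "reported on a capped logit scale", SeparationWarning,
                      stacklevel=2)
        params = np.clip(params, -_LOGODDS_CAP, _LOGODDS_CAP)

    return GlmFit(params=params, param_names=names,
                  deviance=float(res.deviance),
                  pearson_chi2=float(res.pearson_chi2),
                  df_resid=int(res.df_resid), delta=delta, weights=w,
                  fitted=np.asarray(res.fittedvalues, dtype=float),
                  n_params=X.shape[1], separated=separated)


def williams_correction(data: GroupedBinomialData,
                        design: Mapping[str, str] | None = None,
                        reference: str | None = None,
                        tol: float = 1e-8, max_iter: int = 50) -> GlmFit:
    """Williams' moment correction for brood-level overdispersion.

    Estimates ``delta`` such that the Pearson chi-square of the fit weighted
    by ``w_i = 1 / (1 + delta * (n_i - 1))`` equals its residual degrees of
    freedom. ``delta`` is floored at 0 (pure binomial data need no
    correction); with all broods of size 1 delta is unidentifiable and 0 is
    returned with a warning.
    """
    fit0 = fit_logistic(data, design=design, reference=reference)
    if fit0.df_resid < 1:
        raise ValueError("Williams correction needs residual df >= 1")
    if (data.trials == 1).all():
        warnings.warn("all broods have a single egg; heterogeneity is "
                      "unidentifiable, delta set to 0", UserWarning, stacklevel=2)
        return fit0
    if fit0.pearson_chi2 <= fit0.df_resid + tol:
        return fit0  # no excess dispersion; delta = 0

    def excess(delta: float) -> float:
        w = 1.0 / (1.0 + delta * (data.trials - 1.0))
        f = fit_logistic(data, design=design, weights=w, reference=reference,
                         delta=delta)
        return f.pearson_chi2 - f.df_resid

    lo, hi = 0.0, 0.01
    f_hi = excess(hi)
    n_expand = 0
    while f_hi > 0.0:
        lo, hi = hi, hi * 4.0
        n_expand += 1
        if n_expand > max_iter or hi > 1e6:
            raise RuntimeError(f"Williams delta iteration diverged; last delta {hi}")
        f_hi = excess(hi)
    from scipy.optimize import brentq
    delta = float(brentq(excess, lo, hi, xtol=tol, maxiter=max_iter * 4))
    w = 1.0 / (1.0 + delta * (data.trials - 1.0))
    return fit_logistic(data, design=design, weights=w, reference=reference,
                        delta=delta)


def refit_with_weights(data: GroupedBinomialData, fit: GlmFit,
                       design: Mapping[str, str] | None = None,
                       reference: str | None = None) -> GlmFit:
    """Refit a (reduced) design holding another fit's Williams weights fixed."""
    return fit_logistic(data, design=design, weights=fit.weights,
                        reference=reference, delta=fit.delta)


def deviance_test(full: GlmFit, reduced: GlmFit) -> DevianceTest:
    """Chi-square test on the deviance difference of nested fits.

    Both fits must use the same data and the same per-observation weights;
    the degrees of freedom are the difference in parameter counts.
    """
    if not np.allclose(full.weights, reduced.weights):
        raise ValueError("nested deviances are only comparable on identical weights")
    df = full.n_params - reduced.n_params
    if df < 0:
        raise ValueError("'full' has fewer parameters than 'reduced'")
    dd = reduced.deviance - full.deviance
    if dd < -1e-8:
        raise RuntimeError(f"negative deviance difference {dd}: a fit failed")
    dd = max(dd, 0.0)
    p = 1.0 if df == 0 else float(sps.chi2.sf(dd, df))
    return DevianceTest(delta_deviance=float(dd), df=df, p_value=p)


def overdispersed_group_test(data: GroupedBinomialData,
                             full_design: Mapping[str, str] | None = None,
                             reduced_design: Mapping[str, str] | None = None,
                             reference: str | None = None,
                             correct: bool = True
                             ) -> Tuple[DevianceTest, GlmFit, GlmFit]:
    """Williams-corrected deviance test of ``full_design`` against a reduction.

    ``reduced_design=None`` here means the intercept-only model (all groups
    mapped to one level). Returns (test, full fit, reduced fit).
    """
    if reduced_design is None:
        reduced_design = {g: "all" for g in set(np.asarray(data.group).tolist())}
    full = (williams_correction(data, design=full_design, reference=reference)
            if correct else fit_logistic(data, design=full_design,
                                         reference=reference))
    reduced = refit_with_weights(data, full, design=reduced_design)
    return deviance_test(full, reduced), full, reduced


# ---------------------------------------------------------------------------
# One-way linear model on total eggs


@dataclass(frozen=True)
class AnovaFit:
    levels: Tuple[str, ...]
    means: np.ndarray
    ns: np.ndarray
    ss_between: float
    ss_resid: float
    df_between: int
    df_resid: int
    F: float
    p_value: float

    @property
    def mse(self) -> float:
        return self.ss_resid / self.df_resid


class ContrastResult(NamedTuple):
    estimate: float
    t: float
    df: int
    p_value: float


def fit_anova(values: Sequence[float], group: Sequence[str]) -> AnovaFit:
    """One-way fixed-effects ANOVA (F = between-group MS / residual MS)."""
    y = np.asarray(values, dtype=float)
    g = np.asarray(group)
    levels = tuple(sorted(set(g.tolist())))
    if len(levels) < 2:
        raise ValueError("need at least two groups")
    if y.size < len(levels) + 2:
        raise ValueError("need at least two observations beyond the group count")
    means = np.array([y[g == lev].mean() for lev in levels])
    ns = np.array([int((g == lev).sum()) for lev in levels])
    grand = y.mean()
    ss_between = float((ns * (means - grand) ** 2).sum())
    ss_resid = float(sum(((y[g == lev] - m) ** 2).sum()
                         for lev, m in zip(levels, means)))
    df_between, df_resid = len(levels) - 1, y.size - len(levels)
    if ss_resid == 0.0:
        if ss_between == 0.0:
            # totally degenerate data: no variation at all
            return AnovaFit(levels, means, ns, 0.0, 0.0, df_between, df_resid,
                            F=0.0, p_value=1.0)
        raise ValueError("zero residual variance with group differences; "
                         "F is unbounded")
    F = (ss_between / df_between) / (ss_resid / df_resid)
    return AnovaFit(levels, means, ns, ss_between, ss_resid, df_between,
                    df_resid, F=float(F),
                    p_value=float(sps.f.sf(F, df_between, df_resid)))


def planned_contrast(fit: AnovaFit, set_a: Iterable[str],
                     set_b: Iterable[str]) -> ContrastResult:
    """t test of (mean of set_a group means) - (mean of set_b group means).

    Uses the pooled residual mean square of the full one-way model, so the
    degrees of freedom are the model's residual df.
    """
    a, b = list(set_a), list(set_b)
    if not a or not b:
        raise ValueError("both contrast sets must be non-empty")
    if set(a) & set(b):
        raise ValueError("contrast sets must be disjoint")
    unknown = (set(a) | set(b)) - set(fit.levels)
    if unknown:
        raise ValueError(f"unknown groups in contrast: {sorted(unknown)}")
    coef = np.array([(1.0 / len(a) if lev in a else
                      -1.0 / len(b) if lev in b else 0.0)
                     for lev in fit.levels])
    est = float(coef @ fit.means)
    se = float(np.sqrt(fit.mse * (coef ** 2 / fit.ns).sum()))
    t = est / se
    p = float(2.0 * sps.t.sf(abs(t), fit.df_resid))
    return ContrastResult(estimate=est, t=t, df=fit.df_resid, p_value=p)


# ---------------------------------------------------------------------------
# Tukey-Kramer all-pairs comparisons and compact letter display


@dataclass(frozen=True)
class TukeyResult:
    table: pd.DataFrame          # group1, group2, diff, se, q, p, reject
    letters: Dict[str, str]      # group -> letter string
    alpha: float


def tukey_hsd(fit: AnovaFit, alpha: float = 0.05) -> TukeyResult:
    """All-pairs Tukey comparisons with Tukey-Kramer unequal-n adjustment.

    Each pair is tested against the studentized-range distribution with
    ``k`` groups and the model's residual df. Two groups share a letter in
    the compact display iff they are not significantly different.
    """
    if fit.mse == 0.0:
        if fit.ss_between > 0.0:
            raise ValueError("zero residual variance; Tukey comparisons undefined")
        # all observations identical: nothing separates
        return TukeyResult(table=pd.DataFrame(
            columns=["group1", "group2", "diff", "se", "q", "p", "reject"]),
            letters={lev: "A" for lev in fit.levels}, alpha=alpha)
    k, df = len(fit.levels), fit.df_resid
    rows = []
    sig: Set[Tuple[str, str]] = set()
    for i in range(k):
        for j in range(i + 1, k):
            diff = fit.means[i] - fit.means[j]
            se = np.sqrt(fit.mse / 2.0 * (1.0 / fit.ns[i] + 1.0 / fit.ns[j]))
            q = abs(diff) / se
            p = float(sps.studentized_range.sf(q, k, df))
            reject = p < alpha
            rows.append((fit.levels[i], fit.levels[j], float(diff), float(se),
                         float(q), p, reject))
            if reject:
                sig.add((fit.levels[i], fit.levels[j]))
    table = pd.DataFrame(rows, columns=["group1", "group2", "diff", "se",
                                        "q", "p", "reject"])
    order = [fit.levels[i] for i in np.argsort(-fit.means, kind="stable")]
    letters = compact_letter_display(order, sig)
    return TukeyResult(table=table, letters=letters, alpha=alpha)


def compact_letter_display(groups_by_mean: Sequence[str],
                           significant_pairs: Set[Tuple[str, str]]
                           ) -> Dict[str, str]:
    """Insert-and-absorb compact letter display.

    ``groups_by_mean`` orders groups from highest to lowest mean;
    ``significant_pairs`` holds unordered significant pairs. Starts from a
    single column containing every group; for each significant pair, every
    column containing both is split into two copies (one without each
    member) and columns that became subsets of others are absorbed. The
    surviving columns are the letters: two groups share one iff they are
    not significantly different.
    """
    sig = sorted({frozenset(p) for p in significant_pairs}, key=sorted)
    columns: List[Set[str]] = [set(groups_by_mean)]
    for pair in sig:
        i, j = sorted(pair)
        new_cols: List[Set[str]] = []
        for col in columns:
            if i in col and j in col:
                new_cols.extend([col - {j}, col - {i}])
            else:
                new_cols.append(col)
        # absorb proper subsets and duplicates
        pruned: List[Set[str]] = []
        for col in new_cols:
            if not col or any(col < other for other in new_cols):
                continue
            if col not in pruned:
                pruned.append(col)
        columns = pruned
    rank = {g: i for i, g in enumerate(groups_by_mean)}
    columns.sort(key=lambda col: min(rank[g] for g in col))
    alphabet = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    letters: Dict[str, str] = {g: "" for g in groups_by_mean}
    for letter, col in zip(alphabet, columns):
        for g in groups_by_mean:
            if g in col:
                letters[g] += letter
    return letters
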