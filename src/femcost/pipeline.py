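"""End-to-end analysis pipeline for a brood table.

Stage order mirrors the study's analysis: exclusion filters; background
mortality from non-feminized broods; equilibrium XX/X0 mix and expected
undeveloped proportion per feminizing symbiotype; Monte Carlo confidence
interval per feminizing symbiotype conditioned on its observed egg counts;
and the inferential statistics (Williams-corrected deviance tests, one-way
linear model on total eggs with planned contrast and Tukey letters).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any, Dict, Mapping

import numpy as np
import pandas as pd

from . import stats as st
from .expectation import baseline_mortality, expected_undeveloped
from .karyotype import FeminizationParams, solve_equilibrium
from .monte_carlo import MCConfig, observed_within_ci, simulate_undeveloped_distribution
from .synthetic import DEFAULT_PHI, StudyDesign, apply_exclusions

log = logging.getLogger("femcost")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class PipelineConfig:
    """Resolved parameters of a full pipeline run."""

    phi: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_PHI))
    rho: float = 1.0
    b_override: float | None = None   # None: estimate from non-feminized broods
    n_draws: int = 500_000
    ci_level: float = 0.95
    alpha: float = 0.05
    seed: int = 0
    baseline_method: str = "pooled"
    mc_statistic: str = "mean_of_proportions"

    def __post_init__(self) -> None:
        for s, p in self.phi.items():
            if not 0.0 < p <= 1.0:
                raise ValueError(f"phi[{s!r}] must be in (0, 1], got {p}")
        if self.b_override is not None and not 0.0 <= self.b_override < 1.0:
            raise ValueError("b_override must be in [0, 1)")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")

    def as_dict(self) -> Dict[str, Any]:
        return {"phi": dict(self.phi), "rho": self.rho,
                "b_override": self.b_override, "n_draws": self.n_draws,
                "ci_level": self.ci_level, "alpha": self.alpha,
                "seed": self.seed, "baseline_method": self.baseline_method,
                "mc_statistic": self.mc_statistic}


def run_pipeline(broods: pd.DataFrame, config: PipelineConfig = PipelineConfig(),
                 design: StudyDesign = StudyDesign()) -> Dict[str, Any]:
    """Run the full analysis on a brood table; returns a results document.

    Every random stage draws from an independent stream spawned from
    ``config.seed``, so two runs with the same inputs are identical.
    """
    results: Dict[str, Any] = {"config": config.as_dict()}

    def stage(name):
        log.info("stage %s", name)

    try:
        stage("exclusions")
        filtered, tally = apply_exclusions(broods)
        results["exclusions"] = tally
        results["n_broods"] = int(len(filtered))
    except Exception as e:  # noqa: BLE001
        raise PipelineError("exclusions", e) from e

    feminizing = [s for s in design.symbiotypes if design.is_feminizing(s)]
    non_fem = [s for s in design.symbiotypes if not design.is_feminizing(s)]

    try:
        stage("baseline")
        if config.b_override is not None:
            b = config.b_override
        else:
            base = filtered[filtered["symbiotype"].isin(non_fem)]
            b = baseline_mortality(base, method=config.baseline_method)
        results["baseline_b"] = float(b)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("baseline", e) from e

    try:
        stage("expectation+mc")
        seeds = np.random.SeedSequence(config.seed).spawn(len(feminizing))
        per_symb: Dict[str, Dict[str, Any]] = {}
        for s, ss in zip(feminizing, seeds):
            if s not in config.phi:
                raise ValueError(f"no phi configured for feminizing symbiotype {s!r}")
            eq = solve_equilibrium(FeminizationParams(phi=config.phi[s],
                                                      rho=config.rho))
            exp = expected_undeveloped(eq.q_x0, b)
            grp = filtered[filtered["symbiotype"] == s]
            entry: Dict[str, Any] = {"phi": config.phi[s], "q_x0": eq.q_x0,
                                     "expected_undeveloped": exp}
            if len(grp):
                mc = simulate_undeveloped_distribution(
                    grp["eggs_laid"].to_numpy(), eq.q_x0, b,
                    MCConfig(n_draws=config.n_draws, ci_level=config.ci_level,
                             seed=ss, statistic=config.mc_statistic))
                obs = float((grp["eggs_undeveloped"] / grp["eggs_laid"]).mean())
                entry.update({
                    "n_broods": int(len(grp)),
                    "observed_mean_undeveloped": obs,
                    "mc_mean": mc.mean, "ci_lo": mc.ci_lo, "ci_hi": mc.ci_hi,
                    "observed_within_ci": observed_within_ci(obs, mc)})
            per_symb[s] = entry
        results["symbiotypes"] = per_symb
    except PipelineError:
        raise
    except Exception as e:  # noqa: BLE001
        raise PipelineError("expectation+mc", e) from e

    try:
        stage("stats")
        data = st.GroupedBinomialData.from_broods(filtered)
        groups = sorted(set(data.group.tolist()))
        fem_map = {g: ("feminized" if design.is_feminizing(g) else "unfeminized")
                   for g in groups}
        t_all, full_all, _ = st.overdispersed_group_test(data)
        t_fem, full_fem, _ = st.overdispersed_group_test(data, full_design=fem_map)
        stats_doc: Dict[str, Any] = {
            "delta_deviance_symbiotype": t_all.delta_deviance,
            "df_symbiotype": t_all.df, "p_symbiotype": t_all.p_value,
            "williams_delta": full_all.delta,
            "delta_deviance_feminized_vs_not": t_fem.delta_deviance,
            "df_feminized_vs_not": t_fem.df, "p_feminized_vs_not": t_fem.p_value,
        }
        if {"RTW1", "RT"} <= set(groups):
            sub = filtered[filtered["symbiotype"].isin(["RTW1", "RT"])]
            t_pair, _, _ = st.overdispersed_group_test(
                st.GroupedBinomialData.from_broods(sub))
            stats_doc["delta_deviance_RTW1_vs_RT"] = t_pair.delta_deviance
            stats_doc["p_RTW1_vs_RT"] = t_pair.p_value
        anova = st.fit_anova(filtered["eggs_laid"].to_numpy(),
                             filtered["symbiotype"].to_numpy())
        stats_doc["anova_F"] = anova.F
        stats_doc["anova_df"] = [anova.df_between, anova.df_resid]
        stats_doc["anova_p"] = anova.p_value
        fem_present = [g for g in groups if design.is_feminizing(g)]
        nonfem_present = [g for g in groups if not design.is_feminizing(g)]
        if fem_present and nonfem_present:
            con = st.planned_contrast(anova, fem_present, nonfem_present)
            stats_doc["contrast_t"] = con.t
            stats_doc["contrast_df"] = con.df
            stats_doc["contrast_p"] = con.p_value
            mean_fem = float(np.mean([anova.means[anova.levels.index(g)]
                                      for g in fem_present]))
            mean_non = float(np.mean([anova.means[anova.levels.index(g)]
                                      for g in nonfem_present]))
            stats_doc["egg_reduction_percent"] = 100.0 * (1.0 - mean_fem / mean_non)
        tukey = st.tukey_hsd(anova, alpha=config.alpha)
        stats_doc["tukey_letters"] = tukey.letters
        results["stats"] = stats_doc
    except PipelineError:
        raise
    except Exception as e:  # noqa: BLE001
        raise PipelineError("stats", e) from e

    return results
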