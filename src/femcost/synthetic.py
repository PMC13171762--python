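"""Synthetic brood-level datasets emulating the symbiotype experiment.

Six symbiont-combination lines ("symbiotypes") of 30 females each, three of
which carry the feminizing strain and therefore contain a latent mixture of
genetic XX and feminized X0 mothers at the transmission-model equilibrium.
Each mated female lays one eggmass; every egg fails independently at the
background rate (XX mothers) or at the 00-inflated rate (X0 mothers).
Mating failures, zero-development broods and symbiotype mismatches are
generated at the study's observed rates so the exclusion filters have
something to do.

Egg counts follow a negative binomial (mean/dispersion parameterisation,
truncated at one egg) with a pure-Poisson option; the default means encode
the observed ~16% egg reduction in feminized lines. The feminization
success values are calibration defaults chosen so the equilibrium chain
reproduces the study's per-symbiotype expected undeveloped proportions;
see docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Mapping, Tuple

import numpy as np
import pandas as pd

from .expectation import MortalityModel
from .karyotype import FeminizationParams, solve_equilibrium

#: Default feminization success per feminizing symbiotype (calibration
#: defaults; the third strain combination feminizes most reliably).
DEFAULT_PHI: Dict[str, float] = {"RTW1": 0.862, "RTW12": 0.874, "RTW123": 0.937}

REQUIRED_COLUMNS = ("female_id", "symbiotype", "mated", "eggs_laid",
                    "eggs_developed", "eggs_undeveloped", "excluded_reason")


@dataclass(frozen=True)
class StudyDesign:
    symbiotypes: Tuple[str, ...] = ("U", "R", "RT", "RTW1", "RTW12", "RTW123")
    females_per_symbiotype: int = 30

    def __post_init__(self) -> None:
        if len(set(self.symbiotypes)) != len(self.symbiotypes):
            raise ValueError("symbiotype labels must be unique")
        if self.females_per_symbiotype < 1:
            raise ValueError("females_per_symbiotype must be >= 1")

    def is_feminizing(self, symbiotype: str) -> bool:
        """A symbiotype feminizes iff it carries the first Wolbachia strain."""
        return "W1" in symbiotype


@dataclass(frozen=True)
class GeneratorParams:
    """Knobs of the brood generator; defaults are the study conditions."""

    phi: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_PHI))
    b: float = 0.04
    rho: float = 1.0
    mean_eggs_nonfeminized: float = 18.75
    mean_eggs_feminized: float = 15.75
    egg_dispersion: float = 20.0          # negative binomial size k; var = mu + mu^2/k
    count_model: str = "negative_binomial"  # or "poisson"
    mating_failure: float = 0.061
    mismatch_prob: float = 0.006
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("b", "mating_failure", "mismatch_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("mean_eggs_nonfeminized", "mean_eggs_feminized",
                     "egg_dispersion", "rho"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.count_model not in ("negative_binomial", "poisson"):
            raise ValueError(f"unknown count_model {self.count_model!r}")
        for s, p in self.phi.items():
            if not 0.0 < p <= 1.0:
                raise ValueError(f"phi[{s!r}] must be in (0, 1], got {p}")


def _draw_egg_counts(rng: np.random.Generator, n: int, mean: float,
                     params: GeneratorParams) -> np.ndarray:
    """Eggs per eggmass, truncated to >= 1 (a laid eggmass has eggs)."""
    def draw(m: int) -> np.ndarray:
        if params.count_model == "poisson":
            return rng.poisson(mean, size=m)
        k = params.egg_dispersion
        return rng.negative_binomial(n=k, p=k / (k + mean), size=m)

    counts = draw(n)
    while (zero := counts == 0).any():
        counts[zero] = draw(int(zero.sum()))
    return counts


def generate_study(design: StudyDesign = StudyDesign(),
                   params: GeneratorParams = GeneratorParams(),
                   reveal_latent: bool = False) -> pd.DataFrame:
    """One synthetic experiment: a brood table, one row per female.

    Deterministic given ``params.seed``. Latent maternal karyotypes are
    emitted in a ``karyotype`` column only when ``reveal_latent`` is set, so
    the default output mimics what the experimenters could observe.
    """
    rng = np.random.default_rng(params.seed)
    mortality = MortalityModel(b=params.b)
    q_x0: Dict[str, float] = {}
    for s in design.symbiotypes:
        if design.is_feminizing(s):
            if s not in params.phi:
                raise ValueError(f"no phi supplied for feminizing symbiotype {s!r}")
            st = solve_equilibrium(FeminizationParams(phi=params.phi[s],
                                                      rho=params.rho))
            q_x0[s] = st.q_x0
        else:
            q_x0[s] = 0.0

    rows = []
    fid = 0
    for s in design.symbiotypes:
        fem = design.is_feminizing(s)
        mean_eggs = params.mean_eggs_feminized if fem else params.mean_eggs_nonfeminized
        n = design.females_per_symbiotype
        mated = rng.random(n) >= params.mating_failure
        is_x0 = rng.random(n) < q_x0[s]
        eggs = _draw_egg_counts(rng, n, mean_eggs, params)
        p_fail = np.where(is_x0, mortality.e_x0, mortality.e_xx)
        undev = rng.binomial(eggs, p_fail)
        mismatch = rng.random(n) < params.mismatch_prob
        for i in range(n):
            fid += 1
            if not mated[i]:
                laid = dev = und = 0
                reason = "unmated"
            else:
                laid, und = int(eggs[i]), int(undev[i])
                dev = laid - und
                if mismatch[i]:
                    reason = "symbiotype_mismatch"
                elif dev == 0:
                    reason = "zero_development"
                else:
                    reason = "none"
            row = {"female_id": f"F{fid:04d}", "symbiotype": s,
                   "mated": bool(mated[i]), "eggs_laid": laid,
                   "eggs_developed": dev, "eggs_undeveloped": und,
                   "excluded_reason": reason}
            if reveal_latent:
                row["karyotype"] = "X0" if (fem and is_x0[i]) else "XX"
            rows.append(row)
    return pd.DataFrame(rows)


def apply_exclusions(table: pd.DataFrame) -> Tuple[pd.DataFrame, Dict[str, int]]:
    """Drop unmated, zero-development and mismatched broods; tally reasons.

    Reasons are recomputed from the observable columns (so the filter is
    idempotent and works on tables lacking a pre-filled ``excluded_reason``):
    unmated females (or zero eggs laid), mated females whose eggmass had a 0%
    development rate, and records already marked as symbiotype mismatches.
    """
    missing = [c for c in ("symbiotype", "mated", "eggs_laid", "eggs_developed",
                           "eggs_undeveloped") if c not in table.columns]
    if missing:
        raise KeyError(f"brood table is missing required columns: {missing}")
    mismatch = (table["excluded_reason"] == "symbiotype_mismatch"
                if "excluded_reason" in table.columns
                else pd.Series(False, index=table.index))
    unmated = (~table["mated"].astype(bool)) | (table["eggs_laid"] == 0)
    zero_dev = (~unmated) & (~mismatch) & (table["eggs_laid"] >= 1) \
        & (table["eggs_developed"] == 0)
    tally = {"unmated": int(unmated.sum()),
             "symbiotype_mismatch": int((mismatch & ~unmated).sum()),
             "zero_development": int(zero_dev.sum())}
    keep = ~(unmated | mismatch | zero_dev)
    return table.loc[keep].reset_index(drop=True), tally


def summarize_study(table: pd.DataFrame,
                    symbiotypes: Tuple[str, ...] | None = None) -> pd.DataFrame:
    """Per-symbiotype brood summary of a filtered table.

    Means and standard errors of total eggs and of the per-brood proportion
    of undeveloped eggs (proportions computed per brood, then averaged).
    Passing ``symbiotypes`` fixes the roster; any listed symbiotype with no
    broods is reported with n = 0 and null statistics.
    """
    if table.empty and symbiotypes is None:
        raise ValueError("empty table; nothing to summarise")
    out = []
    if symbiotypes is not None:
        for s in symbiotypes:
            if s not in set(table["symbiotype"]):
                out.append({"symbiotype": s, "n": 0, "mean_eggs": np.nan,
                            "se_eggs": np.nan, "mean_prop_undeveloped": np.nan,
                            "se_prop_undeveloped": np.nan})
    for s, grp in table.groupby("symbiotype", sort=False):
        n = len(grp)
        prop = grp["eggs_undeveloped"] / grp["eggs_laid"]
        out.append({
            "symbiotype": s, "n": n,
            "mean_eggs": grp["eggs_laid"].mean(),
            "se_eggs": grp["eggs_laid"].std(ddof=1) / np.sqrt(n) if n > 1 else np.nan,
            "mean_prop_undeveloped": prop.mean(),
            "se_prop_undeveloped": prop.std(ddof=1) / np.sqrt(n) if n > 1 else np.nan,
        })
    return pd.DataFrame(out)


def with_seed(params: GeneratorParams, seed: int) -> GeneratorParams:
    """A copy of ``params`` with the master seed replaced."""
    return replace(params, seed=seed)
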