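"""Expected undeveloped-egg proportions per symbiotype.

Combines the equilibrium X0 fraction among infected females with the rule
that X0 mothers lose a quarter of their eggs as inviable 00 zygotes, and
folds in background per-egg mortality (estimated from the non-feminized
symbiotypes) multiplicatively: an egg develops iff it is viable (not 00)
AND survives background mortality.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .karyotype import FeminizationParams, solve_equilibrium

#: Fraction of an X0 mother's eggs that are inviable 00 zygotes.
OO_FRACTION = 0.25


@dataclass(frozen=True)
class MortalityModel:
    """Per-egg failure probabilities for XX and X0 mothers.

    ``b`` is the background per-egg failure probability. XX mothers fail at
    the background rate only; X0 mothers additionally lose 25% of eggs as
    00 zygotes, composed multiplicatively:
    ``e_x0 = 1 - 0.75 * (1 - b) = 0.25 + 0.75 * b``.
    """

    b: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.b < 1.0:
            raise ValueError(f"background mortality b must be in [0, 1), got {self.b}")

    @property
    def e_xx(self) -> float:
        return self.b

    @property
    def e_x0(self) -> float:
        return 1.0 - (1.0 - OO_FRACTION) * (1.0 - self.b)


@dataclass(frozen=True)
class SymbiotypeExpectation:
    symbiotype: str
    phi: float
    q_x0: float
    expected_undeveloped: float


def baseline_mortality(broods: pd.DataFrame, method: str = "pooled") -> float:
    """Background per-egg failure from non-feminized broods.

    Parameters
    ----------
    broods
        Brood table restricted to non-feminized symbiotypes, already passed
        through the exclusion filters; needs ``eggs_laid`` and
        ``eggs_undeveloped`` columns.
    method
        ``"pooled"`` (default): total undeveloped over total eggs — the
        per-egg probability the multiplicative composition requires.
        ``"mean"``: mean of per-brood proportions, for sensitivity analysis.
    """
    if broods.empty:
        raise ValueError("no broods supplied for the baseline estimate")
    laid = broods["eggs_laid"].to_numpy(dtype=float)
    undev = broods["eggs_undeveloped"].to_numpy(dtype=float)
    if method == "pooled":
        total = laid.sum()
        if total <= 0:
            raise ValueError("zero total eggs; baseline undefined")
        return float(undev.sum() / total)
    if method == "mean":
        if (laid <= 0).any():
            raise ValueError("broods with zero eggs have undefined proportions")
        return float((undev / laid).mean())
    raise ValueError(f"unknown method {method!r}; use 'pooled' or 'mean'")


def expected_undeveloped(q_x0: float, b: float) -> float:
    """Expected undeveloped proportion for a population with X0 fraction q_x0.

    ``1 - (1 - 0.25 * q_x0) * (1 - b)``: an egg develops iff it avoids the
    00 class (probability ``1 - 0.25*q_x0``, averaging over the maternal
    karyotype mixture) and survives background mortality. Identical to the
    mixture ``q_x0 * e_x0 + (1 - q_x0) * e_xx`` of the per-karyotype rates.
    """
    if not 0.0 <= q_x0 <= 1.0:
        raise ValueError(f"q_x0 must be in [0, 1], got {q_x0}")
    if not 0.0 <= b <= 1.0:
        raise ValueError(f"b must be in [0, 1], got {b}")
    return 1.0 - (1.0 - OO_FRACTION * q_x0) * (1.0 - b)


def expectations_for_symbiotypes(phi_per_symbiotype: Mapping[str, float],
                                 b: float, rho: float = 1.0) -> pd.DataFrame:
    """Chain equilibrium -> expectation for each feminizing symbiotype.

    Returns a DataFrame with one row per symbiotype: its feminization
    success ``phi``, the equilibrium X0 fraction ``q_x0`` among infected
    females, and the expected proportion of undeveloped eggs.
    """
    rows = []
    for symbiotype, phi in phi_per_symbiotype.items():
        state = solve_equilibrium(FeminizationParams(phi=phi, rho=rho))
        rows.append(SymbiotypeExpectation(
            symbiotype=symbiotype, phi=phi, q_x0=state.q_x0,
            expected_undeveloped=expected_undeveloped(state.q_x0, b)))
    return pd.DataFrame([r.__dict__ for r in rows])
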