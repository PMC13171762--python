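"""Karyotype transmission model for a feminizing endosymbiont in an XX/X0 host.

The host has XX females and X0 males (the two distinct X chromosomes of the
spider are treated as one co-segregating linked unit). A maternally inherited
feminizing symbiont turns infected X0 individuals into functional females with
probability ``phi``; with probability ``1 - phi`` feminization fails and the
individual develops as a male. Transmission is perfect (every offspring of an
infected mother is infected) and all fathers are X0 males.

Because X0 mothers provision an X chromosome to only half of their eggs, a
quarter of their zygotes receive no X from either parent (00) and are
presumed inviable. This module encodes the gamete segregation, the offspring
class distributions, the generation-to-generation recursion for the XX/X0
composition of the infected female population, its equilibrium, and the
inverse problem of estimating ``phi`` from observed brood sex ratios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Dict, Mapping, NamedTuple


class Karyotype(Enum):
    """Composite sex-chromosome state (the two X chromosomes as one unit)."""

    XX = "XX"
    X0 = "X0"
    OO = "OO"  # no X from either parent; always inviable


class InviableKaryotypeError(ValueError):
    """Raised when an operation is requested for an OO (inviable) individual."""


class DegenerateModelError(ValueError):
    """Raised when parameters leave no infected females to iterate on."""


@dataclass(frozen=True)
class FeminizationParams:
    """Parameters of the feminization model.

    Parameters
    ----------
    phi
        Probability that an infected X0 individual develops as a functional
        female. ``1 - phi`` is the feminization failure rate.
    rho
        Egg number of X0 mothers relative to XX mothers (dimensionless).
    transmission
        Maternal transmission probability. The model assumes perfect
        transmission; any value other than 1 is rejected.
    """

    phi: float
    rho: float = 1.0
    transmission: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.phi <= 1.0:
            raise ValueError(f"phi must be in [0, 1], got {self.phi}")
        if not self.rho > 0.0:
            raise ValueError(f"rho must be positive, got {self.rho}")
        if self.transmission != 1.0:
            raise ValueError("the model assumes perfect maternal transmission "
                             f"(transmission = 1), got {self.transmission}")


class OffspringClass(NamedTuple):
    """One offspring category: karyotype, phenotype, and infection state."""

    karyotype: Karyotype
    phenotype: str  # "female" | "male" | "inviable"
    infected: bool


@dataclass(frozen=True)
class OffspringDistribution:
    """Probability mass over offspring classes; validates normalisation."""

    classes: Mapping[OffspringClass, float]

    _TOL = 1e-12

    def __post_init__(self) -> None:
        total = 0.0
        for cls, p in self.classes.items():
            if p < 0.0:
                raise ValueError(f"negative probability {p} for {cls}")
            total += p
        if abs(total - 1.0) > self._TOL:
            raise ValueError(f"offspring probabilities sum to {total}, not 1")

    def mass(self, karyotype: Karyotype | None = None,
             phenotype: str | None = None,
             infected: bool | None = None) -> float:
        """Total probability over classes matching the given filters."""
        return sum(
            p for cls, p in self.classes.items()
            if (karyotype is None or cls.karyotype is karyotype)
            and (phenotype is None or cls.phenotype == phenotype)
            and (infected is None or cls.infected == infected)
        )

    @property
    def inviable_fraction(self) -> float:
        return self.mass(phenotype="inviable")


@dataclass(frozen=True)
class EquilibriumState:
    """Composition of the infected female population at the recursion fixed point."""

    x_xx: float  # fraction of infected adult females that are genetic XX

    def __post_init__(self) -> None:
        if not 0.0 <= self.x_xx <= 1.0:
            raise ValueError(f"x_xx must be in [0, 1], got {self.x_xx}")

    @property
    def q_x0(self) -> float:
        """Fraction of infected adult females that are feminized X0."""
        return 1.0 - self.x_xx


def gamete_distribution(parent: Karyotype) -> Dict[str, float]:
    """Gamete probabilities under fair segregation of the linked X unit.

    XX parents transmit X always; X0 parents transmit X to half of their
    gametes and no sex chromosome to the other half.
    """
    if parent is Karyotype.XX:
        return {"X": 1.0, "0": 0.0}
    if parent is Karyotype.X0:
        return {"X": 0.5, "0": 0.5}
    raise InviableKaryotypeError("OO individuals are inviable and produce no gametes")


def offspring_distribution(mother: Karyotype, mother_infected: bool,
                           params: FeminizationParams) -> OffspringDistribution:
    """Offspring class distribution for a mother crossed to an X0 male.

    The cross of maternal gametes with X0-male gametes yields zygotes XX, X0
    and 00; infection follows the mother exactly (perfect maternal
    transmission). X0 offspring of infected mothers are phenotypic females
    with probability ``params.phi``; X0 offspring of uninfected mothers are
    males. 00 zygotes are inviable.
    """
    if mother is Karyotype.OO:
        raise InviableKaryotypeError("OO individuals are inviable and cannot be mothers")
    if mother is Karyotype.X0 and not mother_infected:
        raise ValueError("an uninfected X0 individual is male and cannot be a mother")

    father_gametes = gamete_distribution(Karyotype.X0)
    mother_gametes = gamete_distribution(mother)
    inf = mother_infected
    phi = params.phi

    classes: Dict[OffspringClass, float] = {}

    def add(cls: OffspringClass, p: float) -> None:
        if p > 0.0:
            classes[cls] = classes.get(cls, 0.0) + p

    for mg, pm in mother_gametes.items():
        for fg, pf in father_gametes.items():
            p = pm * pf
            if p == 0.0:
                continue
            n_x = (mg == "X") + (fg == "X")
            if n_x == 2:
                add(OffspringClass(Karyotype.XX, "female", inf), p)
            elif n_x == 1:
                if inf:
                    add(OffspringClass(Karyotype.X0, "female", True), p * phi)
                    add(OffspringClass(Karyotype.X0, "male", True), p * (1.0 - phi))
                else:
                    add(OffspringClass(Karyotype.X0, "male", False), p)
            else:
                add(OffspringClass(Karyotype.OO, "inviable", inf), p)

    return OffspringDistribution(classes)


def _daughter_weights(x_xx: float, params: FeminizationParams) -> tuple[float, float, float]:
    """Per-capita XX-daughter, X0-daughter and total-daughter production.

    Mothers are weighted by their egg output: XX mothers lay 1 unit of eggs,
    X0 mothers ``rho`` units. Returns (XX daughters, X0 daughters, total).
    """
    phi, rho = params.phi, params.rho
    xx_daughters = x_xx * 0.5 + rho * (1.0 - x_xx) * 0.25
    x0_daughters = x_xx * (phi * 0.5) + rho * (1.0 - x_xx) * (phi * 0.5)
    return xx_daughters, x0_daughters, xx_daughters + x0_daughters


def recursion_step(x_xx: float, params: FeminizationParams) -> float:
    """One generation of the infected-female composition recursion.

    Given the fraction ``x_xx`` of infected females that are XX, returns the
    next generation's fraction: XX-daughter production over total daughter
    production, with each mother class contributing offspring per the cross
    with an X0 father (infected XX mothers: 1/2 XX + 1/2 X0 offspring;
    infected X0 mothers: 1/4 XX + 1/2 X0 + 1/4 inviable 00) and X0 daughters
    discounted by the feminization success ``phi``.
    """
    if not 0.0 <= x_xx <= 1.0:
        raise ValueError(f"x_xx must be in [0, 1], got {x_xx}")
    if params.phi == 0.0 and x_xx == 0.0:
        # an infected female population made entirely of feminized X0
        # individuals cannot exist with zero feminization
        raise DegenerateModelError(
            "phi = 0 with x_xx = 0: no infected females exist to reproduce")
    xx_d, _, total = _daughter_weights(x_xx, params)
    if total <= 0.0:
        raise DegenerateModelError("no infected daughters are produced")
    return xx_d / total

def _equilibrium_quadratic(params: FeminizationParams) -> tuple[float, float, float]:
    # Fixed point x of recursion_step rearranges to a*x^2 + b*x + c = 0.
    phi, rho = params.phi, params.rho
    a = (1.0 + phi) / 2.0 - rho * (0.25 + phi / 2.0)
    b = rho * (0.25 + phi / 2.0) + rho / 4.0 - 0.5
    c = -rho / 4.0
    return a, b, c


def solve_equilibrium(params: FeminizationParams, tol: float = 1e-10) -> EquilibriumState:
    """Equilibrium fraction of XX among infected females.

    Solves the closed-form quadratic for the fixed point of
    :func:`recursion_step` and returns the admissible root in [0, 1],
    verified against the recursion within ``tol``. With ``rho = 1`` the
    quadratic reduces to ``x^2 + 2*phi*x - 1 = 0``; at ``phi = 1`` the
    equilibrium is ``sqrt(2) - 1``.
    """
    if not 0.0 < params.phi <= 1.0:
        raise ValueError(f"solve_equilibrium requires phi in (0, 1], got {params.phi}")
    if tol <= 0.0:
        raise ValueError("tol must be positive")

    a, b, c = _equilibrium_quadratic(params)
    roots = []
    if abs(a) < 1e-14:
        if b != 0.0:
            roots.append(-c / b)
    else:
        disc = b * b - 4.0 * a * c
        if disc >= 0.0:
            sq = math.sqrt(disc)
            roots.extend([(-b + sq) / (2.0 * a), (-b - sq) / (2.0 * a)])

    eps = 1e-12
    admissible = [r for r in roots if -eps <= r <= 1.0 + eps]
    for r in admissible:
        x = min(max(r, 0.0), 1.0)
        if abs(recursion_step(x, params) - x) < max(tol, 1e-9):
            return EquilibriumState(x_xx=x)
    raise RuntimeError(
        f"no admissible equilibrium root in [0, 1] for {params}; roots = {roots}")


def iterate_to_equilibrium(params: FeminizationParams, x0: float = 0.5,
                           n_steps: int = 10_000) -> float:
    """Fixed-point iteration of the recursion; verification path for the solver."""
    x = x0
    for _ in range(n_steps):
        x = recursion_step(x, params)
    return x


def expected_male_fraction(state: EquilibriumState, params: FeminizationParams) -> float:
    """Proportion of viable adult offspring of infected mothers that are male.

    Males arise only through feminization failure: X0 offspring (half of every
    infected mother's eggs) develop as males with probability ``1 - phi``.
    Viable output per XX mother is 1 (no inviable class) and per X0 mother
    3/4 (a quarter of eggs are 00), with X0 egg output scaled by ``rho``.
    """
    x, phi, rho = state.x_xx, params.phi, params.rho
    males = x * (1.0 - phi) / 2.0 + rho * (1.0 - x) * (1.0 - phi) / 2.0
    viable = x * 1.0 + rho * (1.0 - x) * 0.75
    return males / viable


def estimate_phi_from_sex_ratio(observed_male_fraction: float, rho: float = 1.0,
                                tol: float = 1e-8) -> FeminizationParams:
    """Invert the equilibrium sex ratio for the feminization success ``phi``.

    Finds phi such that the male fraction among viable adult offspring of
    infected mothers, at the equilibrium XX/X0 mix implied by that phi,
    equals the observation. The male fraction is strictly decreasing in phi
    (from 1/2 at phi -> 0 to 0 at phi = 1), so bisection on [0, 1] applies.
    """
    if not 0.0 <= observed_male_fraction < 0.5:
        raise ValueError(
            "observed male fraction must be in [0, 0.5) for a feminizer at "
            f"equilibrium, got {observed_male_fraction}")
    if observed_male_fraction == 0.0:
        return FeminizationParams(phi=1.0, rho=rho)

    def male_frac(phi: float) -> float:
        p = FeminizationParams(phi=phi, rho=rho)
        return expected_male_fraction(solve_equilibrium(p), p)

    lo, hi = 1e-9, 1.0  # male_frac decreasing: f(lo) ~ 0.5, f(hi) = 0
    f_lo = male_frac(lo) - observed_male_fraction
    f_hi = male_frac(hi) - observed_male_fraction
    if not (f_lo >= 0.0 >= f_hi):
        raise RuntimeError("male fraction not bracketed; monotonicity violated")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if male_frac(mid) - observed_male_fraction > 0.0:
            lo = mid
        else:
            hi = mid
    return FeminizationParams(phi=0.5 * (lo + hi), rho=rho)
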