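"""Monte Carlo distribution of the mean undeveloped-egg proportion.

For each feminizing symbiotype, the observed eggs-per-eggmass counts are
held fixed and the brood outcomes are resimulated: every draw assigns each
brood a maternal karyotype (X0 with probability ``q_x0``), samples its
undeveloped count from a binomial with the karyotype's per-egg failure
rate, and records the mean of per-brood undeveloped proportions. The
empirical quantiles of the resulting distribution give the confidence
interval against which the observed mean is judged.

Maternal karyotypes are redrawn on every draw, so the interval propagates
karyotype uncertainty as well as binomial sampling noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .expectation import MortalityModel

_CHUNK = 50_000  # draws per vectorised block; bounds peak memory


@dataclass(frozen=True)
class MCConfig:
    n_draws: int = 500_000
    ci_level: float = 0.95
    seed: int | np.random.SeedSequence | None = None
    statistic: str = "mean_of_proportions"  # or "pooled"

    def __post_init__(self) -> None:
        if self.n_draws < 1:
            raise ValueError("n_draws must be >= 1")
        if not 0.0 < self.ci_level < 1.0:
            raise ValueError("ci_level must be in (0, 1)")
        if self.statistic not in ("mean_of_proportions", "pooled"):
            raise ValueError(f"unknown statistic {self.statistic!r}")


@dataclass(frozen=True)
class MCResult:
    samples: np.ndarray = field(repr=False)
    mean: float
    ci_lo: float
    ci_hi: float

    def __post_init__(self) -> None:
        if not self.ci_lo <= self.mean <= self.ci_hi:
            raise ValueError("CI bounds must bracket the mean")


def simulate_undeveloped_distribution(egg_counts, q_x0: float, b: float,
                                      config: MCConfig = MCConfig()) -> MCResult:
    """Simulate the sampling distribution of the undeveloped-egg statistic.

    Parameters
    ----------
    egg_counts
        Per-brood egg totals (all >= 1); the conditioning information.
    q_x0
        Probability a brood's mother is a feminized X0 female.
    b
        Background per-egg failure probability.
    config
        Draw count, CI coverage, seed, and choice of statistic
        (mean of per-brood proportions, or pooled undeveloped/total).

    Egg counts are sorted internally so the sampled distribution does not
    depend on brood order (the statistic is symmetric in broods).
    """
    counts = np.asarray(egg_counts, dtype=np.int64)
    if counts.size == 0:
        raise ValueError("egg_counts is empty")
    if (counts < 1).any():
        raise ValueError("all egg counts must be >= 1")
    if not 0.0 <= q_x0 <= 1.0:
        raise ValueError(f"q_x0 must be in [0, 1], got {q_x0}")

    counts = np.sort(counts)
    mortality = MortalityModel(b=b)
    rng = np.random.default_rng(config.seed)

    samples = np.empty(config.n_draws, dtype=np.float64)
    total_eggs = counts.sum()
    done = 0
    while done < config.n_draws:
        block = min(_CHUNK, config.n_draws - done)
        is_x0 = rng.random((block, counts.size)) < q_x0
        p = np.where(is_x0, mortality.e_x0, mortality.e_xx)
        undev = rng.binomial(counts[None, :], p)
        if config.statistic == "mean_of_proportions":
            samples[done:done + block] = (undev / counts[None, :]).mean(axis=1)
        else:
            samples[done:done + block] = undev.sum(axis=1) / total_eggs
        done += block

    alpha = 1.0 - config.ci_level
    ci_lo, ci_hi = np.quantile(samples, [alpha / 2.0, 1.0 - alpha / 2.0],
                               method="linear")
    return MCResult(samples=samples, mean=float(samples.mean()),
                    ci_lo=float(ci_lo), ci_hi=float(ci_hi))


def observed_within_ci(observed_mean: float, result: MCResult) -> bool:
    """True iff the observed mean falls inside the simulated interval."""
    return bool(result.ci_lo <= observed_mean <= result.ci_hi)
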