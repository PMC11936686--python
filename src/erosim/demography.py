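"""Demographic scenarios, metapopulation layout and calendar-time mapping.

A :class:`Scenario` describes a metapopulation of ``n_demes`` demes whose
*total* diploid size declines from ``n_anc`` to ``n_bot`` over
``decline_generations`` generations and is then held constant.  The total is
apportioned equally across demes by the largest-remainder rule, so deme sizes
always sum exactly to the configured total.

A :class:`Timeline` maps calendar years to generations since the onset of
the decline and defines the four sampling bins used throughout: historical
(pre-onset), modern, ten years ahead and one hundred years ahead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .genome_model import ConfigurationError

__all__ = [
    "Scenario",
    "TimeBin",
    "Timeline",
    "BIN_LABELS",
    "total_size_at",
    "deme_sizes_at",
    "year_to_generation",
    "bin_of",
]

BIN_LABELS = ("historical", "modern", "ten_yr", "hundred_yr")


class ScenarioError(ValueError):
    """Raised when a demographic trajectory is infeasible (deme size < 2)."""


@dataclass(frozen=True)
class Scenario:
    """Demographic collapse scenario for a subdivided population."""

    n_anc: int = 12_000
    n_bot: int = 100
    decline_generations: int = 15
    n_demes: int = 3
    migration_rate: float = 0.02
    post_decline_generations: int = 35
    decline_shape: str = "exponential"

    def __post_init__(self) -> None:
        if self.n_bot >= self.n_anc:
            raise ConfigurationError("n_bot must be smaller than n_anc")
        if self.n_demes < 1:
            raise ConfigurationError("n_demes must be >= 1")
        if not 0.0 <= self.migration_rate < 1.0:
            raise ConfigurationError("migration_rate must be in [0, 1)")
        if self.decline_shape not in ("exponential", "linear"):
            raise ConfigurationError(f"unknown decline_shape {self.decline_shape!r}")
        if self.n_bot < 2 * self.n_demes:
            raise ScenarioError("bottleneck leaves a deme below 2 individuals")

    @property
    def horizon(self) -> int:
        return self.decline_generations + self.post_decline_generations


@dataclass(frozen=True)
class TimeBin:
    label: str
    start_year: float  # -inf allowed for the open-ended historical bin
    end_year: float

    def contains(self, year: float) -> bool:
        return self.start_year <= year <= self.end_year

    @property
    def midpoint(self) -> float:
        if math.isinf(self.start_year):
            return self.end_year
        return 0.5 * (self.start_year + self.end_year)


def _default_bins() -> tuple:
    return (
        TimeBin("historical", -math.inf, 1948),
        TimeBin("modern", 2009, 2016),
        TimeBin("ten_yr", 2026, 2033),
        TimeBin("hundred_yr", 2111, 2118),
    )


@dataclass(frozen=True)
class Timeline:
    """Calendar-year <-> generation mapping with sampling bins."""

    generation_time: float = 3.4
    onset_year: int = 1948
    bins: tuple = field(default_factory=_default_bins)

    def __post_init__(self) -> None:
        if self.generation_time <= 0:
            raise ConfigurationError("generation_time must be > 0")
        ends = [b.end_year for b in self.bins]
        starts = [b.start_year for b in self.bins]
        for i in range(1, len(self.bins)):
            if starts[i] <= ends[i - 1]:
                raise ConfigurationError("bins must be ordered and non-overlapping")

    def bin(self, label: str) -> TimeBin:
        for b in self.bins:
            if b.label == label:
                return b
        raise KeyError(label)

    def bin_sampling_generation(self, label: str) -> int:
        """Generation (post-onset) at which a bin's cohort is sampled.

        The historical bin is sampled at generation 0 (the pre-decline
        population); other bins at the rounded generation of their midpoint
        year.  With the defaults: modern -> 19, ten_yr -> 24, hundred_yr -> 49
        (i.e. roughly 25 and 50 generations of bottleneck for the two future
        bins).
        """
        if label == "historical":
            return 0
        mid = self.bin(label).midpoint
        return int(round((mid - self.onset_year) / self.generation_time))


def year_to_generation(timeline: Timeline, year: float) -> int:
    """Whole generations since decline onset: floor((year - onset) / T_gen)."""
    return math.floor((year - timeline.onset_year) / timeline.generation_time)


def bin_of(timeline: Timeline, year: float):
    """Label of the bin containing ``year``, or None if between bins."""
    for b in timeline.bins:
        if b.contains(year):
            return b.label
    return None


def total_size_at(scenario: Scenario, generation: int) -> int:
    """Total metapopulation diploid size at a generation (0 = pre-decline)."""
    g, d = generation, scenario.decline_generations
    if g <= 0:
        return scenario.n_anc
    if g >= d:
        return scenario.n_bot
    if scenario.decline_shape == "exponential":
        size = scenario.n_anc * (scenario.n_bot / scenario.n_anc) ** (g / d)
    else:  # linear
        size = scenario.n_anc + (scenario.n_bot - scenario.n_anc) * (g / d)
    return int(round(size))


def deme_sizes_at(scenario: Scenario, generation: int) -> list[int]:
    """Per-deme sizes at a generation, by largest-remainder apportionment.

    Ties between equal remainders are broken by deme index, so the split is
    deterministic and always sums exactly to the total.
    """
    if generation < 0:
        raise ValueError("generation must be >= 0")
    total = total_size_at(scenario, generation)
    k = scenario.n_demes
    base = total // k
    remainder = total - base * k
    sizes = [base + (1 if i < remainder else 0) for i in range(k)]
    if any(n < 2 for n in sizes):
        raise ScenarioError(
            f"deme size below 2 at generation {generation}: {sizes}"
        )
    return sizes


def size_trajectory(scenario: Scenario, upto_generation: int) -> np.ndarray:
    """Total sizes for generations 1..upto_generation (drift-relevant steps)."""
    return np.array(
        [total_size_at(scenario, g) for g in range(1, upto_generation + 1)],
        dtype=float,
    )
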