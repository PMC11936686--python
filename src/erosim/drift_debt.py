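"""Closed-form drift expectations: the analytic oracle for diversity loss.

Under pure drift, expected heterozygosity after generations with diploid
effective sizes N_1..N_T is the ancestral value times
``prod_t (1 - 1/(2 N_t))``.  Because most of this product is realized only
after a collapse has run its course, a recently bottlenecked population can
still look diverse: the unpaid part of the product is the population's
*drift debt*.  These expectations double as the simulator's neutral oracle.
"""

from __future__ import annotations

import numpy as np

from .demography import Scenario, Timeline, size_trajectory

__all__ = [
    "expected_het_retention",
    "expected_loss_for_scenario",
    "ne_nc_ratio",
]

#: conventional equilibrium ratio of effective to census size
NE_NC_EQUILIBRIUM = 0.1


def expected_het_retention(trajectory) -> float:
    """Fraction of ancestral heterozygosity retained after the trajectory.

    ``trajectory`` holds the diploid effective size for each elapsed
    generation; an empty trajectory means no drift (retention 1.0).
    """
    n = np.asarray(trajectory, dtype=float)
    if n.size == 0:
        return 1.0
    if np.any(n < 1):
        raise ValueError("all sizes must be >= 1")
    # exp-sum-log for numerical stability over long trajectories
    return float(np.exp(np.log1p(-1.0 / (2.0 * n)).sum()))


def expected_loss_for_scenario(
    scenario: Scenario, timeline: Timeline, bin_label: str
) -> float:
    """Expected percent loss of heterozygosity at a bin's sampling generation.

    Uses the pooled (total) size trajectory; exact for a panmictic scenario
    and a lower-bound approximation under deme subdivision, where
    within-deme heterozygosity decays somewhat faster.
    """
    g = timeline.bin_sampling_generation(bin_label)
    traj = size_trajectory(scenario, g)
    return 100.0 * (1.0 - expected_het_retention(traj))


def ne_nc_ratio(ne: float, nc: float):
    """Ne/Nc ratio and whether it exceeds the 0.1 equilibrium convention."""
    if nc <= 0:
        raise ValueError("census size must be > 0")
    ratio = ne / nc
    return ratio, bool(ratio > NE_NC_EQUILIBRIUM)
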