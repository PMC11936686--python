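"""Genomic-erosion metrics on genotype matrices.

Covers per-individual heterozygosity (with an explicit monomorphic-site
denominator so values are comparable across cohorts), percentage diversity
loss against an ancestral baseline, realized and masked genetic load, lethal
equivalents, excess-homozygosity F, and a rank-based cohort comparison
(Kruskal-Wallis).

Load definitions are on the linear fitness scale.  With multiplicative
fitness w = prod (1+s)^hom (1+hs)^het over deleterious genotypes:

* realized load  = 1 - mean(w): the fitness cost already expressed;
* masked load    = mean(w) - mean(w_hom), where w_hom treats every carried
  deleterious allele as homozygous (each locus counted once): the further
  cost that full homozygosity would expose;
* lethal equivalents = mean per-diploid sum of |s| over carried deleterious
  allele copies (a heterozygous copy contributes |s|, a homozygous pair 2|s|).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
from scipy import stats as sp_stats

from .engine import GenotypeMatrix
from .genome_model import DELETERIOUS

__all__ = [
    "SampleStats",
    "heterozygosity",
    "diversity_loss",
    "loads",
    "excess_homozygosity_F",
    "kruskal_wallis",
    "compute_sample_stats",
]


@dataclass
class SampleStats:
    """Per-sample erosion metrics for one cohort."""

    mean_H: float
    mean_H_all: float
    f_roh: float
    f_excess: float
    realized_load: float
    masked_load: float
    lethal_equivalents: float
    n_individuals: int
    pct_loss: float = np.nan
    bin: str = ""
    replicate: int = -1

    def to_dict(self) -> dict:
        return asdict(self)


def heterozygosity(gm: GenotypeMatrix, denominator_sites: int):
    """Per-individual heterozygosity and its mean.

    H_i = (# heterozygous sites) / (denominator_sites - # missing sites for
    individual i).  ``denominator_sites`` must cover all assayed sites
    including monomorphic ones (e.g. the functional genome length for
    simulator samples), and must be at least the number of matrix sites.
    """
    if denominator_sites < gm.n_sites:
        raise ValueError(
            "denominator_sites must be >= the number of segregating sites"
        )
    g = gm.genotypes
    n_het = (g == 1).sum(axis=1)
    n_miss = (g == -1).sum(axis=1)
    denom = denominator_sites - n_miss
    if np.any(denom <= 0):
        raise ValueError("zero heterozygosity denominator for an individual")
    h = n_het / denom
    return h, float(h.mean())


def diversity_loss(h_now: float, h_ancestral: float) -> float:
    """Percent loss of heterozygosity: 100 * (1 - H_now / H_ancestral)."""
    if h_ancestral <= 0:
        raise ValueError("ancestral heterozygosity must be > 0")
    return 100.0 * (1.0 - h_now / h_ancestral)


def loads(gm: GenotypeMatrix, fixed_since=None):
    """(realized_load, masked_load, lethal_equivalents) for a sample.

    Requires per-site (s, h) annotations.  ``fixed_since`` optionally adds
    deleterious mutations fixed during the simulated decline, which every
    individual carries homozygous and which a segregating-sites-only matrix
    cannot show.
    """
    if gm.s is None or gm.h is None:
        raise ValueError("loads requires s and h site annotations")
    s = np.asarray(gm.s, dtype=float)
    h = np.asarray(gm.h, dtype=float)
    del_mask = s < 0
    g = gm.genotypes[:, del_mask]
    s_d = s[del_mask]
    h_d = h[del_mask]
    hom_factor = np.where(g == 2, 1.0 + s_d, 1.0)
    het_factor = np.where(g == 1, 1.0 + h_d * s_d, 1.0)
    w = (hom_factor * het_factor).prod(axis=1)
    w_hom = np.where(g >= 1, 1.0 + s_d, 1.0).prod(axis=1)
    le = (np.clip(g, 0, 2) * np.abs(s_d)).sum(axis=1).astype(float)
    if fixed_since:
        s_fixed = np.array(
            [sf for sf, kind, _ in fixed_since if kind == DELETERIOUS], dtype=float
        )
        if s_fixed.size:
            factor = float(np.prod(1.0 + s_fixed))
            w = w * factor
            w_hom = w_hom * factor
            le = le + 2.0 * np.abs(s_fixed).sum()
    realized = 1.0 - float(w.mean())
    masked = float(w.mean()) - float(w_hom.mean())
    return realized, masked, float(le.mean())


def excess_homozygosity_F(gm: GenotypeMatrix) -> np.ndarray:
    """Per-individual F = 1 - H_obs / H_exp from sample allele frequencies.

    H_exp is the mean of 2p(1-p) over the individual's called polymorphic
    sites; F > 0 indicates excess homozygosity (inbreeding-like), F < 0
    excess heterozygosity.
    """
    if gm.n_individuals < 2:
        raise ValueError("excess_homozygosity_F needs >= 2 individuals")
    g = gm.genotypes
    called = g >= 0
    n_called = called.sum(axis=0)
    with np.errstate(invalid="ignore"):
        p = np.where(n_called > 0, np.where(called, g, 0).sum(axis=0) / (2.0 * n_called), 0.0)
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("all sites are monomorphic in the sample")
    het_exp = 2.0 * p[poly] * (1.0 - p[poly])
    gp = g[:, poly]
    cp = gp >= 0
    n_sites_i = cp.sum(axis=1)
    if np.any(n_sites_i == 0):
        raise ValueError("an individual has no called polymorphic sites")
    h_obs = (gp == 1).sum(axis=1) / n_sites_i
    h_exp = (cp * het_exp).sum(axis=1) / n_sites_i
    return 1.0 - h_obs / h_exp


def kruskal_wallis(groups):
    """Kruskal-Wallis rank statistic with tie correction.

    H = [12 / (N(N+1)) * sum_i R_i^2 / n_i - 3(N+1)] / (1 - sum(t^3-t)/(N^3-N))
    with p from the chi-square distribution on k-1 degrees of freedom.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(g.size == 0 for g in groups):
        raise ValueError("empty group")
    pooled = np.concatenate(groups)
    n_tot = pooled.size
    if n_tot < 3:
        raise ValueError("need at least three observations in total")
    ranks = sp_stats.rankdata(pooled)
    stat = 0.0
    offset = 0
    for g in groups:
        r = ranks[offset: offset + g.size]
        stat += r.sum() ** 2 / g.size
        offset += g.size
    stat = 12.0 / (n_tot * (n_tot + 1)) * stat - 3.0 * (n_tot + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie_corr = 1.0 - (counts**3 - counts).sum() / (n_tot**3 - n_tot)
    if tie_corr == 0:
        raise ValueError("all observations are identical")
    stat /= tie_corr
    p = float(sp_stats.chi2.sf(stat, len(groups) - 1))
    return float(stat), p


def compute_sample_stats(
    gm: GenotypeMatrix,
    denominator_sites: int,
    genome_length: int | None = None,
    compute_roh: bool = True,
    roh_params=None,
    fixed_since=None,
) -> dict:
    """All erosion metrics for one sampled cohort, as a flat dict.

    ``mean_H`` is computed on neutral sites when kind annotations are
    available (the comparable diversity measure across bins); ``mean_H_all``
    on all segregating sites.
    """
    from . import roh as roh_mod  # deferred, keeps the module graph acyclic

    gm_neutral = gm.neutral_only() if gm.kind is not None else gm
    _, mean_h = heterozygosity(gm_neutral, denominator_sites)
    _, mean_h_all = heterozygosity(gm, denominator_sites)
    try:
        f_excess = float(np.mean(excess_homozygosity_F(gm)))
    except ValueError:
        f_excess = np.nan
    if gm.s is not None:
        realized, masked, le = loads(gm, fixed_since=fixed_since)
    else:
        realized = masked = le = np.nan
    f_roh = np.nan
    if compute_roh and genome_length:
        params = roh_params if roh_params is not None else roh_mod.ROHParams()
        segments = roh_mod.call_roh_window(gm, params)
        f_roh = float(
            np.mean(
                [
                    roh_mod.froh(
                        [s for s in segments if s.individual == i], genome_length
                    )
                    for i in range(gm.n_individuals)
                ]
            )
        )
    return SampleStats(
        mean_H=mean_h,
        mean_H_all=mean_h_all,
        f_roh=f_roh,
        f_excess=f_excess,
        realized_load=realized,
        masked_load=masked,
        lethal_equivalents=le,
        n_individuals=gm.n_individuals,
    ).to_dict()
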