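"""Synthetic genotype data for the estimator stages and the test suite.

Emulates the post-filtering shape of a temporal resequencing comparison: two
diploid cohorts (historical and modern) with controlled mean per-site
heterozygosity, between-individual dispersion and missingness, where the
historical cohort is both more diverse and more variable between individuals.
Sequencing artefacts of historical specimens (DNA damage, transition excess)
are deliberately NOT emulated: upstream pipelines remove transitions before
any estimator sees the data, so cohorts are generated post-filtering.

Site frequencies follow a neutral-SFS-shaped density (mass proportional to
1/i for i derived copies) by default, so estimator behaviour resembles real
data; a uniform-frequency mode is available for worst-case tests.

Generators are pure functions of (spec, seed): a fixed seed reproduces the
matrix bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .engine import GenotypeMatrix
from .genome_model import ConfigurationError

__all__ = ["CohortSpec", "make_genotypes", "make_temporal_cohorts", "plant_roh"]


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for one cohort's genotype matrix."""

    n_individuals: int = 20
    n_sites: int = 100_000
    target_mean_H: float = 0.003
    h_sd: float = 0.0003
    missing_rate: float = 0.0
    genome_length: int = 12_000_000
    freq_mode: str = "sfs"  # "sfs" or "uniform"
    label: str = "cohort"

    def __post_init__(self) -> None:
        if not 0.0 <= self.target_mean_H <= 1.0:
            raise ConfigurationError("target_mean_H must be in [0, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigurationError("missing_rate must be in [0, 1)")
        if self.n_sites > self.genome_length:
            raise ConfigurationError("more sites than genome positions")
        if self.freq_mode not in ("sfs", "uniform"):
            raise ConfigurationError(f"unknown freq_mode {self.freq_mode!r}")


def _site_frequencies(spec: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    if spec.freq_mode == "uniform":
        return rng.uniform(0.05, 0.95, spec.n_sites)
    n_hap = 2 * spec.n_individuals
    classes = np.arange(1, n_hap)
    weights = 1.0 / classes
    i = rng.choice(classes, size=spec.n_sites, p=weights / weights.sum())
    return i / n_hap


def make_genotypes(spec: CohortSpec, rng: np.random.Generator) -> GenotypeMatrix:
    """Generate a genotype matrix realizing the cohort spec.

    Per-individual heterozygosity targets are drawn around the cohort mean,
    then genotypes are placed site-wise: individual i is heterozygous at
    site j with probability scaled from the site's 2p(1-p) so that the mean
    over sites hits the individual's target.  ``target_mean_H`` is on the
    per-assayed-site scale, i.e. the matching heterozygosity denominator is
    ``n_sites``.
    """
    p = _site_frequencies(spec, rng)
    base_het = 2.0 * p * (1.0 - p)
    mean_base = base_het.mean()
    h_target = np.clip(
        rng.normal(spec.target_mean_H, spec.h_sd, spec.n_individuals), 0.0, 0.95
    )
    prob_het = np.clip(np.outer(h_target / mean_base, base_het), 0.0, 1.0)
    u = rng.random((spec.n_individuals, spec.n_sites))
    het = u < prob_het
    # conditional on homozygosity, derived homozygote w.p. p^2 / (p^2 + q^2)
    p_hom_derived = p**2 / (p**2 + (1.0 - p) ** 2)
    hom_derived = rng.random((spec.n_individuals, spec.n_sites)) < p_hom_derived
    geno = np.where(het, 1, np.where(hom_derived, 2, 0)).astype(np.int8)
    if spec.missing_rate > 0:
        miss = rng.random(geno.shape) < spec.missing_rate
        geno[miss] = -1
    positions = np.sort(
        rng.choice(spec.genome_length, size=spec.n_sites, replace=False, shuffle=False)
    )
    return GenotypeMatrix(
        geno,
        positions,
        sample_ids=[f"{spec.label}{i}" for i in range(spec.n_individuals)],
    )


def make_temporal_cohorts(
    h_hist: float = 0.003,
    loss_pct: float = 9.0,
    *,
    n_hist: int = 24,
    n_modern: int = 18,
    n_sites: int = 200_000,
    hist_sd_frac: float = 0.09,
    modern_sd_frac: float = 0.05,
    missing_rate: float = 0.0,
    rng: np.random.Generator | int | None = None,
):
    """Historical and modern cohorts separated by a diversity loss.

    The modern target is H_hist * (1 - loss_pct/100); the historical cohort
    has the wider between-individual spread of heterozygosity, mirroring the
    structure of temporal museum-versus-contemporary comparisons.
    """
    if not 0.0 <= loss_pct < 100.0:
        raise ConfigurationError("loss_pct must be in [0, 100)")
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    h_mod = h_hist * (1.0 - loss_pct / 100.0)
    hist_spec = CohortSpec(
        n_individuals=n_hist,
        n_sites=n_sites,
        target_mean_H=h_hist,
        h_sd=hist_sd_frac * h_hist,
        missing_rate=missing_rate,
        label="hist",
    )
    modern_spec = CohortSpec(
        n_individuals=n_modern,
        n_sites=n_sites,
        target_mean_H=h_mod,
        h_sd=modern_sd_frac * h_hist,
        missing_rate=missing_rate,
        label="mod",
    )
    return make_genotypes(hist_spec, rng), make_genotypes(modern_spec, rng)


def plant_roh(gm: GenotypeMatrix, individual: int, tracts) -> GenotypeMatrix:
    """Copy of the matrix with tracts forced homozygous for one individual.

    Tracts are (start, end) half-open bp intervals; overlapping tracts are
    merged silently.  Heterozygous and missing calls inside a tract become
    homozygous-ancestral; all other entries are untouched.
    """
    geno = gm.genotypes.copy()
    for start, end in tracts:
        if start < 0 or end <= start:
            raise ValueError(f"invalid tract ({start}, {end})")
        in_tract = (gm.positions >= start) & (gm.positions < end)
        row = geno[individual]
        row[in_tract & (row != 0) & (row != 2)] = 0
    return GenotypeMatrix(
        geno, gm.positions, s=gm.s, h=gm.h, kind=gm.kind, sample_ids=gm.sample_ids
    )
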