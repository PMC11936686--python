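"""Runs of homozygosity: window caller, het-rate caller, FROH and dating.

Two callers are provided.  The SNP-window caller follows the classic
sliding-window sketch: windows of ``window_snp`` consecutive SNPs are
labelled homozygous when they contain at most ``window_het`` heterozygous and
``window_missing`` missing calls; a SNP is run-eligible when the fraction of
windows overlapping it that are homozygous is at least
``1 - window_threshold``; maximal eligible stretches are split at physical
gaps and then filtered by length, SNP count and SNP density.  Bit
compatibility with any particular external tool is not claimed; the caller is
validated against an exhaustive brute-force implementation instead.

The het-rate caller labels fixed-size genomic windows (default 500 kb) as ROH
when their per-bp heterozygosity rate is at or below ``rohmu`` and merges
adjacent ROH windows.

ROH age is estimated from tract length: a tract of L Mb on a map of cM
centimorgans per Mb coalesces on average t = (100 / (L * cM)) / 2 generations
ago -- long tracts are recent, short tracts old.

All coordinates are 0-based half-open; tract lengths are end - start.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .engine import GenotypeMatrix

__all__ = [
    "ROHParams",
    "ROHSegment",
    "DatingParams",
    "call_roh_window",
    "call_roh_hetrate",
    "froh",
    "date_roh",
    "merge_segments",
]


@dataclass(frozen=True)
class ROHParams:
    """Window-caller parameters (lengths in kb, counts in SNPs)."""

    min_length_kb: float = 10.0
    max_gap_kb: float = 100.0
    min_snps: int = 50
    min_density_kb_per_snp: float = 50.0
    window_snp: int = 30
    window_threshold: float = 0.05
    window_missing: int = 5
    window_het: int = 5

    def __post_init__(self) -> None:
        vals = (
            self.min_length_kb,
            self.max_gap_kb,
            self.min_snps,
            self.min_density_kb_per_snp,
            self.window_snp,
            self.window_threshold,
            self.window_missing,
            self.window_het,
        )
        if any(v < 0 for v in vals):
            raise ValueError("ROH parameters must be non-negative")
        if self.window_snp < self.window_het:
            raise ValueError("window_snp must be >= window_het")


@dataclass(frozen=True)
class ROHSegment:
    """A homozygous tract of one individual (0-based, half-open bp)."""

    individual: int
    start: int
    end: int
    n_snps: int = 0

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("segment end must exceed start")

    @property
    def length_bp(self) -> int:
        return self.end - self.start

    @property
    def length_kb(self) -> float:
        return self.length_bp / 1000.0


@dataclass(frozen=True)
class DatingParams:
    """Recombination map density and generation time for ROH dating."""

    cM_per_Mb: float = 1.86
    generation_time: float = 3.4

    def __post_init__(self) -> None:
        if self.cM_per_Mb <= 0:
            raise ValueError("cM_per_Mb must be > 0")


def _eligible_snps(geno_row: np.ndarray, params: ROHParams) -> np.ndarray:
    """Boolean run-eligibility per SNP for one individual."""
    n = geno_row.size
    w = params.window_snp
    if n < w:
        return np.zeros(n, dtype=bool)
    het = (geno_row == 1).astype(np.int64)
    miss = (geno_row == -1).astype(np.int64)
    kern = np.ones(w, dtype=np.int64)
    het_in_win = np.convolve(het, kern, mode="valid")
    miss_in_win = np.convolve(miss, kern, mode="valid")
    hom_win = (het_in_win <= params.window_het) & (miss_in_win <= params.window_missing)
    n_win = hom_win.size
    # windows overlapping SNP j start in [j - w + 1, j] intersected with [0, n_win)
    cum = np.concatenate(([0], np.cumsum(hom_win)))
    j = np.arange(n)
    lo = np.clip(j - w + 1, 0, n_win)
    hi = np.clip(j + 1, 0, n_win)
    n_cover = hi - lo
    n_hom = cum[hi] - cum[lo]
    frac = np.where(n_cover > 0, n_hom / np.maximum(n_cover, 1), 0.0)
    return (n_cover > 0) & (frac >= 1.0 - params.window_threshold)


def _runs_from_eligible(
    positions: np.ndarray, eligible: np.ndarray, params: ROHParams, individual: int
):
    """Maximal eligible stretches -> gap-split -> filtered segments."""
    segments = []
    idx = np.flatnonzero(eligible)
    if idx.size == 0:
        return segments
    # break where SNP indices are non-consecutive or the physical gap is large
    gap_bp = params.max_gap_kb * 1000.0
    breaks = np.flatnonzero(
        (np.diff(idx) > 1) | (np.diff(positions[idx]) > gap_bp)
    )
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [idx.size - 1]))
    for a, b in zip(starts, ends):
        first, last = idx[a], idx[b]
        n_snps = b - a + 1
        start_bp = int(positions[first])
        end_bp = int(positions[last]) + 1
        length_kb = (end_bp - start_bp) / 1000.0
        if length_kb < params.min_length_kb:
            continue
        if n_snps < params.min_snps:
            continue
        if length_kb / n_snps > params.min_density_kb_per_snp:
            continue
        segments.append(ROHSegment(individual, start_bp, end_bp, n_snps))
    return segments


def call_roh_window(gm: GenotypeMatrix, params: ROHParams | None = None):
    """SNP-window ROH caller over all individuals of a genotype matrix."""
    if params is None:
        params = ROHParams()
    if gm.positions.size > 1 and not np.all(np.diff(gm.positions) > 0):
        raise ValueError("sites must be position-sorted")
    segments = []
    for i in range(gm.n_individuals):
        eligible = _eligible_snps(gm.genotypes[i], params)
        segments.extend(_runs_from_eligible(gm.positions, eligible, params, i))
    return segments


def call_roh_hetrate(
    het_counts,
    window_bp: int = 500_000,
    rohmu: float = 2e-5,
    individual: int = 0,
):
    """Het-rate ROH caller on windows tiling the genome.

    ``het_counts[i]`` is the number of heterozygous sites in window i, which
    spans [i * window_bp, (i+1) * window_bp).  A window is ROH iff its
    heterozygosity rate het_counts / window_bp is <= rohmu (boundary
    inclusive); adjacent ROH windows are merged.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be > 0")
    het_counts = np.asarray(het_counts, dtype=float)
    is_roh = het_counts / window_bp <= rohmu
    segments = []
    start = None
    for i, flag in enumerate(is_roh):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            segments.append(
                ROHSegment(individual, start * window_bp, i * window_bp)
            )
            start = None
    if start is not None:
        segments.append(
            ROHSegment(individual, start * window_bp, is_roh.size * window_bp)
        )
    return segments


def window_het_counts(gm: GenotypeMatrix, individual: int, genome_length: int, window_bp: int = 500_000):
    """Per-window heterozygote counts for one individual (het-rate caller input)."""
    n_win = int(np.ceil(genome_length / window_bp))
    het_pos = gm.positions[gm.genotypes[individual] == 1]
    return np.bincount(het_pos // window_bp, minlength=n_win)


def merge_segments(segments):
    """Union of possibly overlapping segments (order-independent)."""
    if not segments:
        return []
    ordered = sorted(segments, key=lambda s: (s.start, s.end))
    merged = [[ordered[0].start, ordered[0].end]]
    for seg in ordered[1:]:
        if seg.start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], seg.end)
        else:
            merged.append([seg.start, seg.end])
    return [(a, b) for a, b in merged]


def froh(segments, genome_length: int) -> float:
    """Fraction of the genome covered by the union of ROH segments."""
    if genome_length <= 0:
        raise ValueError("genome_length must be > 0")
    for s in segments:
        if s.start < 0 or s.end > genome_length:
            raise ValueError(f"segment {s} extends beyond the genome")
    total = sum(b - a for a, b in merge_segments(segments))
    return total / genome_length


def date_roh(length_mb: float, dating: DatingParams | None = None):
    """Mean coalescence time of an ROH tract: t = (100 / (L * cM)) / 2.

    Returns (generations, years); strictly decreasing in both L and cM.
    """
    if dating is None:
        dating = DatingParams()
    if length_mb <= 0:
        raise ValueError("ROH length must be > 0")
    generations = (100.0 / (length_mb * dating.cM_per_Mb)) / 2.0
    return generations, generations * dating.generation_time
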