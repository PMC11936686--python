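"""Forward-in-time diploid simulator for genomic erosion scenarios.

Individuals are pairs of haplotypes; a haplotype is a numpy array of mutation
ids ordered by genomic position.  Mutation effects live in a single growing
:class:`MutationTable` (position, selection coefficient s, dominance h, kind).
Each generation applies, in order: migration (an offspring's parental deme is
the home deme with probability 1-m, otherwise uniform among the other demes),
soft selection (parents drawn with probability proportional to fitness within
the parental deme), meiosis (crossovers restricted to gene boundaries,
Poisson-distributed new mutations), and viability rejection of zero-fitness
offspring (so lethal-recessive homozygotes never survive).  Deme sizes follow
the configured trajectory exactly.

Generations are discrete and non-overlapping -- a deliberate simplification
with identical drift and selection expectations at these parameter scales.

Large ancestral populations are made tractable by *rescaling*: a population
lambda-fold smaller is simulated with mutation rate, crossover probability,
migration and fitness effects multiplied by lambda (diversity theta = 4*N*mu
and the strength of selection 2*N*s are preserved), then expanded by copying
to the nominal size.  Mutation tables always store the *unscaled* s so load
accounting is independent of the rescaling; only the fitness machinery sees
the scaled coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .demography import BIN_LABELS, Scenario, Timeline, deme_sizes_at
from .genome_model import (
    DELETERIOUS,
    NEUTRAL,
    ConfigurationError,
    DFESpec,
    GenomeArchitecture,
    sample_mutation_effects,
)

__all__ = [
    "MutationTable",
    "PopulationState",
    "GenotypeMatrix",
    "SimulationError",
    "initialize_equilibrium",
    "step_generation",
    "individual_fitness",
    "sample_individuals",
    "run_scenario",
    "expand_population",
    "lethal_equivalents_from_state",
]

_EMPTY_HAP = np.empty(0, dtype=np.int64)

try:  # optional JIT acceleration; the numpy paths below are the reference
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

#: generations between fixed/lost mutation cleanups
DEFAULT_COMPACT_EVERY = 25


class SimulationError(RuntimeError):
    """Raised when a step cannot be completed (empty deme, no viable parents)."""


# ---------------------------------------------------------------------------
# mutation bookkeeping
# ---------------------------------------------------------------------------

class MutationTable:
    """Append-only (until compaction) struct-of-arrays of mutations.

    ``s`` holds the true homozygous selection coefficient; ``s_fit`` the
    rescaled coefficient actually used in fitness, clip(s * lambda, -1, 0).
    """

    def __init__(self, capacity: int = 1024, fitness_scale: float = 1.0):
        self._cap = max(capacity, 16)
        self.n = 0
        self.fitness_scale = fitness_scale
        self._position = np.zeros(self._cap, dtype=np.int64)
        self._s = np.zeros(self._cap, dtype=float)
        self._h = np.zeros(self._cap, dtype=float)
        self._kind = np.zeros(self._cap, dtype=np.uint8)
        self._origin = np.zeros(self._cap, dtype=np.int64)
        self._s_fit = np.zeros(self._cap, dtype=float)
        self.n_deleterious = 0

    # live views ------------------------------------------------------------
    @property
    def position(self) -> np.ndarray:
        return self._position[: self.n]

    @property
    def s(self) -> np.ndarray:
        return self._s[: self.n]

    @property
    def h(self) -> np.ndarray:
        return self._h[: self.n]

    @property
    def kind(self) -> np.ndarray:
        return self._kind[: self.n]

    @property
    def origin_generation(self) -> np.ndarray:
        return self._origin[: self.n]

    @property
    def s_fit(self) -> np.ndarray:
        return self._s_fit[: self.n]

    # mutation --------------------------------------------------------------
    def _grow(self, need: int) -> None:
        if self.n + need <= self._cap:
            return
        while self._cap < self.n + need:
            self._cap *= 2
        for name in ("_position", "_s", "_h", "_kind", "_origin", "_s_fit"):
            old = getattr(self, name)
            new = np.zeros(self._cap, dtype=old.dtype)
            new[: self.n] = old[: self.n]
            setattr(self, name, new)

    def append(self, positions, s, h, kind, origin: int) -> np.ndarray:
        k = len(positions)
        self._grow(k)
        lo, hi = self.n, self.n + k
        self._position[lo:hi] = positions
        self._s[lo:hi] = s
        self._h[lo:hi] = h
        self._kind[lo:hi] = kind
        self._origin[lo:hi] = origin
        self._s_fit[lo:hi] = np.clip(np.asarray(s) * self.fitness_scale, -1.0, 0.0)
        self.n = hi
        self.n_deleterious += int(np.count_nonzero(kind))
        return np.arange(lo, hi, dtype=np.int64)

    def set_fitness_scale(self, lam: float) -> None:
        self.fitness_scale = lam
        self._s_fit[: self.n] = np.clip(self.s * lam, -1.0, 0.0)

    def compact(self, keep: np.ndarray) -> np.ndarray:
        """Keep only the masked mutations; return old-id -> new-id remap."""
        remap = np.full(self.n, -1, dtype=np.int64)
        idx = np.flatnonzero(keep)
        remap[idx] = np.arange(idx.size, dtype=np.int64)
        for name in ("_position", "_s", "_h", "_kind", "_origin", "_s_fit"):
            arr = getattr(self, name)
            arr[: idx.size] = arr[: self.n][idx]
        self.n = idx.size
        self.n_deleterious = int(np.count_nonzero(self.kind))
        return remap


# ---------------------------------------------------------------------------
# population state
# ---------------------------------------------------------------------------

class PopulationState:
    """Demes of diploid individuals plus the shared mutation table."""

    def __init__(
        self,
        arch: GenomeArchitecture,
        dfe: DFESpec,
        demes: list,
        muts: MutationTable,
        generation: int = 0,
        rescale_lambda: float = 1.0,
    ):
        self.arch = arch
        self.dfe = dfe
        self.demes = demes  # list of lists of (hap0, hap1)
        self.muts = muts
        self.generation = generation
        self.rescale_lambda = rescale_lambda
        self.fixed_since: list = []  # (s, kind, generation) fixed post-onset
        self._used_positions: set = set()
        self.fitness = [np.ones(len(d)) for d in demes]

    @classmethod
    def empty(
        cls,
        arch: GenomeArchitecture,
        dfe: DFESpec,
        sizes,
        rescale_lambda: float = 1.0,
    ) -> "PopulationState":
        demes = [[(_EMPTY_HAP, _EMPTY_HAP) for _ in range(n)] for n in sizes]
        muts = MutationTable(fitness_scale=rescale_lambda)
        return cls(arch, dfe, demes, muts, rescale_lambda=rescale_lambda)

    @property
    def deme_sizes(self) -> list[int]:
        return [len(d) for d in self.demes]

    @property
    def n_individuals(self) -> int:
        return sum(len(d) for d in self.demes)

    def individuals(self):
        for deme in self.demes:
            yield from deme

    def copy(self) -> "PopulationState":
        """Independent copy for replicate runs branching from one
        equilibrium.  Haplotype arrays are shared (they are never mutated
        in place); the mutation table and bookkeeping are duplicated."""
        muts = MutationTable(capacity=max(self.muts.n, 16),
                             fitness_scale=self.muts.fitness_scale)
        muts.append(self.muts.position.copy(), self.muts.s.copy(),
                    self.muts.h.copy(), self.muts.kind.copy(), origin=0)
        muts._origin[: muts.n] = self.muts.origin_generation
        new = PopulationState(
            self.arch, self.dfe,
            [list(deme) for deme in self.demes],
            muts, generation=self.generation,
            rescale_lambda=self.rescale_lambda,
        )
        new.fixed_since = list(self.fixed_since)
        new._used_positions = set(self._used_positions)
        new.fitness = [f.copy() for f in self.fitness]
        return new

    def allele_counts(self) -> np.ndarray:
        haps = [h for ind in self.individuals() for h in ind]
        if not haps or all(h.size == 0 for h in haps):
            return np.zeros(self.muts.n, dtype=np.int64)
        return np.bincount(np.concatenate(haps), minlength=self.muts.n)

    # internal ---------------------------------------------------------------
    def _draw_new_positions(self, k: int, rng: np.random.Generator) -> np.ndarray:
        """Infinite-sites positions: uniform over the exome, never reused."""
        length = self.arch.total_functional_length
        out = np.empty(k, dtype=np.int64)
        used = self._used_positions
        for i in range(k):
            p = int(rng.integers(length))
            while p in used:
                p = int(rng.integers(length))
            used.add(p)
            out[i] = p
        return out

    def recompute_fitness(self) -> None:
        self.fitness = [
            np.array([individual_fitness(ind, self.muts) for ind in deme])
            if self.muts.n_deleterious
            else np.ones(len(deme))
            for deme in self.demes
        ]

    def compact(self) -> None:
        """Drop lost mutations; fold fixed ones out of every haplotype.

        Deleterious fixations are logged with the current generation so load
        accounting can optionally include fixed-since-onset effects.  Relative
        fitness is unchanged by removing a fixed mutation (every individual
        shares its factor), so cached fitness stays valid for selection.
        """
        counts = self.allele_counts()
        n_haps = 2 * self.n_individuals
        fixed = counts == n_haps
        keep = (counts > 0) & ~fixed
        if keep.all():
            return
        for i in np.flatnonzero(fixed):
            if self.muts.kind[i] == DELETERIOUS:
                self.fixed_since.append(
                    (float(self.muts.s[i]), int(self.muts.kind[i]), self.generation)
                )
        remap = self.muts.compact(keep)
        seen: dict = {}
        for deme in self.demes:
            for j, (h0, h1) in enumerate(deme):
                k0 = seen.get(id(h0))
                if k0 is None:
                    m = remap[h0]
                    k0 = m[m >= 0]
                    seen[id(h0)] = k0
                k1 = seen.get(id(h1))
                if k1 is None:
                    m = remap[h1]
                    k1 = m[m >= 0]
                    seen[id(h1)] = k1
                deme[j] = (k0, k1)


# ---------------------------------------------------------------------------
# fitness
# ---------------------------------------------------------------------------

def _diplotype_split(h0, h1, position):
    """Split a diplotype into homozygous ids and per-haplotype het ids."""
    if h0.size == 0 or h1.size == 0:
        return _EMPTY_HAP, h0, h1
    pos0 = position[h0]
    pos1 = position[h1]
    i = np.searchsorted(pos1, pos0)
    np.minimum(i, h1.size - 1, out=i)
    hom_mask = pos1[i] == pos0
    j = np.searchsorted(pos0, pos1)
    np.minimum(j, h0.size - 1, out=j)
    het1 = h1[pos0[j] != pos1]
    return h0[hom_mask], h0[~hom_mask], het1


if _HAVE_NUMBA:

    @_njit(cache=False)
    def _fitness_kernel(h0, h1, position, s_fit, hdom):  # pragma: no cover
        w = 1.0
        i = j = 0
        n0, n1 = h0.size, h1.size
        while i < n0 and j < n1:
            a, b = h0[i], h1[j]
            p0, p1 = position[a], position[b]
            if p0 == p1:  # infinite sites: same position => same mutation
                s = s_fit[a]
                if s < 0.0:
                    w *= 1.0 + s
                i += 1
                j += 1
            elif p0 < p1:
                s = s_fit[a]
                if s < 0.0:
                    w *= 1.0 + hdom[a] * s
                i += 1
            else:
                s = s_fit[b]
                if s < 0.0:
                    w *= 1.0 + hdom[b] * s
                j += 1
        while i < n0:
            s = s_fit[h0[i]]
            if s < 0.0:
                w *= 1.0 + hdom[h0[i]] * s
            i += 1
        while j < n1:
            s = s_fit[h1[j]]
            if s < 0.0:
                w *= 1.0 + hdom[h1[j]] * s
            j += 1
        return w


def individual_fitness(haplotypes, muts: MutationTable) -> float:
    """Multiplicative fitness: w = prod (1+s) over homozygous deleterious
    sites times prod (1+h*s) over heterozygous ones (rescaled s)."""
    h0, h1 = haplotypes
    if muts.n_deleterious == 0 or (h0.size == 0 and h1.size == 0):
        return 1.0
    if _HAVE_NUMBA:
        return float(
            _fitness_kernel(h0, h1, muts.position, muts.s_fit, muts.h)
        )
    hom, het0, het1 = _diplotype_split(h0, h1, muts.position)
    w = 1.0
    if hom.size:
        s = muts.s_fit[hom]
        s = s[s < 0]
        if s.size:
            w *= float(np.prod(1.0 + s))
    for het in (het0, het1):
        if het.size:
            s = muts.s_fit[het]
            mask = s < 0
            if mask.any():
                w *= float(np.prod(1.0 + muts.h[het[mask]] * s[mask]))
    return w


# ---------------------------------------------------------------------------
# meiosis
# ---------------------------------------------------------------------------

if _HAVE_NUMBA:

    @_njit(cache=False)
    def _recombine_kernel(h0, h1, position, bp, start):  # pragma: no cover
        out = np.empty(h0.size + h1.size, dtype=np.int64)
        n = 0
        i = j = 0
        cur = start
        for seg in range(bp.size + 1):
            hi = bp[seg] if seg < bp.size else np.int64(2**62)
            if cur == 0:
                while i < h0.size and position[h0[i]] < hi:
                    out[n] = h0[i]
                    n += 1
                    i += 1
                while j < h1.size and position[h1[j]] < hi:
                    j += 1
            else:
                while j < h1.size and position[h1[j]] < hi:
                    out[n] = h1[j]
                    n += 1
                    j += 1
                while i < h0.size and position[h0[i]] < hi:
                    i += 1
            cur = 1 - cur
        return out[:n].copy()


def _make_gamete(parent, state: PopulationState, rng: np.random.Generator) -> np.ndarray:
    arch = state.arch
    muts = state.muts
    lam = state.rescale_lambda
    # rescaling multiplies mu, s and m but not r: crossovers stay at the
    # nominal per-boundary probability during burn-in
    r_eff = arch.boundary_crossover_prob
    h0, h1 = parent
    which = int(rng.integers(2))
    k = rng.binomial(arch.n_boundaries, r_eff) if arch.n_boundaries and r_eff > 0 else 0
    if k == 0:
        gam = h0 if which == 0 else h1
    else:
        b = rng.choice(arch.n_boundaries, size=k, replace=False)
        b.sort()
        bp = (b + 1) * arch.gene_length
        if _HAVE_NUMBA:
            gam = _recombine_kernel(h0, h1, muts.position, bp, which)
        else:
            pos0 = muts.position[h0]
            pos1 = muts.position[h1]
            c0 = np.searchsorted(pos0, bp)
            c1 = np.searchsorted(pos1, bp)
            parts = []
            lo0 = lo1 = 0
            cur = which
            for seg in range(k + 1):
                hi0 = c0[seg] if seg < k else h0.size
                hi1 = c1[seg] if seg < k else h1.size
                parts.append(h0[lo0:hi0] if cur == 0 else h1[lo1:hi1])
                lo0, lo1 = hi0, hi1
                cur ^= 1
            gam = np.concatenate(parts) if parts else _EMPTY_HAP

    mu_genome = state.dfe.mutation_rate_per_bp * lam * arch.total_functional_length
    n_new = rng.poisson(mu_genome) if mu_genome > 0 else 0
    if n_new:
        pos_new = np.sort(state._draw_new_positions(n_new, rng))
        kind, s, h = sample_mutation_effects(state.dfe, n_new, rng)
        ids = muts.append(pos_new, s, h, kind, state.generation)
        idx = np.searchsorted(muts.position[gam], pos_new)
        gam = np.insert(gam, idx, ids)
    return gam


# ---------------------------------------------------------------------------
# one generation
# ---------------------------------------------------------------------------

def _draw_parent_pairs(n_parents, count, weights, rng):
    if weights is None:
        p1 = rng.integers(0, n_parents, count)
        p2 = rng.integers(0, n_parents, count)
    else:
        p1 = rng.choice(n_parents, size=count, p=weights)
        p2 = rng.choice(n_parents, size=count, p=weights)
    if n_parents > 1:  # no selfing
        clash = p1 == p2
        while clash.any():
            k = int(clash.sum())
            p2[clash] = (
                rng.integers(0, n_parents, k)
                if weights is None
                else rng.choice(n_parents, size=k, p=weights)
            )
            clash = p1 == p2
    return p1, p2


def step_generation(
    state: PopulationState,
    target_sizes,
    migration_rate: float,
    rng: np.random.Generator,
    compact_every: int = DEFAULT_COMPACT_EVERY,
) -> PopulationState:
    """Advance the population by one generation (in place; also returned)."""
    k_demes = len(state.demes)
    if len(target_sizes) != k_demes:
        raise ConfigurationError("target_sizes must match the number of demes")
    for d, deme in enumerate(state.demes):
        if len(deme) == 0:
            raise SimulationError(f"deme {d} has no parents")

    muts = state.muts
    weights = []
    for d, deme in enumerate(state.demes):
        if muts.n_deleterious:
            w = state.fitness[d]
            tot = w.sum()
            if tot <= 0:
                raise SimulationError(f"no viable parents in deme {d}")
            weights.append(w / tot)
        else:
            weights.append(None)

    new_demes = [[] for _ in range(k_demes)]
    new_fit = [[] for _ in range(k_demes)]
    for dest in range(k_demes):
        t = int(target_sizes[dest])
        src = np.full(t, dest)
        if migration_rate > 0 and k_demes > 1:
            mig = rng.random(t) < migration_rate
            n_mig = int(mig.sum())
            if n_mig:
                o = rng.integers(0, k_demes - 1, n_mig)
                o[o >= dest] += 1
                src[mig] = o
        for s_deme in range(k_demes):
            count = int((src == s_deme).sum())
            if count == 0:
                continue
            pop = state.demes[s_deme]
            p1, p2 = _draw_parent_pairs(len(pop), count, weights[s_deme], rng)
            for a, b in zip(p1, p2):
                for _ in range(200):
                    g1 = _make_gamete(pop[a], state, rng)
                    g2 = _make_gamete(pop[b], state, rng)
                    w = (
                        individual_fitness((g1, g2), muts)
                        if muts.n_deleterious
                        else 1.0
                    )
                    if w > 0:
                        break
                else:
                    raise SimulationError(
                        f"no viable offspring from deme {s_deme} parents"
                    )
                new_demes[dest].append((g1, g2))
                new_fit[dest].append(w)

    state.demes = new_demes
    state.fitness = [np.array(f) for f in new_fit]
    state.generation += 1
    if compact_every and state.generation % compact_every == 0:
        state.compact()
    return state


# ---------------------------------------------------------------------------
# equilibrium initialization
# ---------------------------------------------------------------------------

def _seed_neutral_sfs(state: PopulationState, rng: np.random.Generator) -> None:
    """Seed neutral sites from the equilibrium frequency spectrum.

    Site counts per derived-copy class i are Poisson with mean theta_L / i
    (theta_L = 4 * N_total * mu_neutral * L, rescaling-invariant), and the i
    carrier haplotypes of each site are drawn uniformly without replacement.
    """
    arch, dfe = state.arch, state.dfe
    n_hap = 2 * state.n_individuals
    mu_neutral = dfe.mutation_rate_per_bp * state.rescale_lambda * (1.0 - dfe.p_deleterious)
    theta_l = 4.0 * state.n_individuals * mu_neutral * arch.total_functional_length
    if theta_l == 0 or n_hap < 2:
        return
    classes = np.arange(1, n_hap, dtype=float)
    n_sites_per_class = rng.poisson(theta_l / classes)
    site_counts = np.repeat(np.arange(1, n_hap), n_sites_per_class)
    n_sites = site_counts.size
    if n_sites == 0:
        return
    rng.shuffle(site_counts)
    positions = np.sort(state._draw_new_positions(n_sites, rng))
    ids = state.muts.append(
        positions,
        np.zeros(n_sites),
        np.full(n_sites, 0.5),
        np.full(n_sites, NEUTRAL, dtype=np.uint8),
        origin=-1,
    )
    carriers = [
        rng.choice(n_hap, size=int(c), replace=False, shuffle=False)
        for c in site_counts
    ]
    hap_of_copy = np.concatenate(carriers)
    site_of_copy = np.repeat(ids, site_counts)
    # one sort on a combined (haplotype, mutation-id) key: slices per
    # haplotype come out already ordered by id, i.e. by position
    span = ids[-1] + 1
    key = np.sort(hap_of_copy * span + site_of_copy)
    hap_sorted = key // span
    site_sorted = key % span
    bounds = np.searchsorted(hap_sorted, np.arange(n_hap + 1))
    haps = [site_sorted[bounds[i]: bounds[i + 1]] for i in range(n_hap)]
    i = 0
    for deme in state.demes:
        for j in range(len(deme)):
            deme[j] = (haps[i], haps[i + 1])
            i += 2


def _dfe_classes(dfe: DFESpec, n_classes: int = 64):
    """Discretize the DFE into (true s, h, influx fraction) classes.

    Gamma quantile midpoints plus, when configured, the recessive-lethal
    point mass.  Fractions are of the *deleterious* mutation influx.
    """
    from scipy import stats as sp_stats

    q = (np.arange(n_classes) + 0.5) / n_classes
    scale = -dfe.gamma_mean_s / dfe.gamma_shape
    s_true = -sp_stats.gamma.ppf(q, dfe.gamma_shape, scale=scale)
    h = np.asarray(dfe.dominance(s_true), dtype=float)
    frac = np.full(n_classes, (1.0 - dfe.lethal_fraction) / n_classes)
    if dfe.lethal_fraction > 0:
        s_true = np.append(s_true, -1.0)
        h = np.append(h, 0.0)
        frac = np.append(frac, dfe.lethal_fraction)
    return s_true, h, frac


def expected_selected_sfs(
    n_hap: int, s_eff: float, h: float, influx: float
) -> np.ndarray:
    """Expected equilibrium counts of segregating sites per copy class.

    Diffusion sojourn-time result for a new mutation entering at 1/(2N)
    under selection with dominance: with G(x) = exp(-a(x)),
    a(x) = 4*N*s*(h*x + (1-2h)*x^2/2), the expected density is

        n(x) = 2*influx/(x(1-x)) * Int_x^1 G / (G(x) * Int_0^1 G),

    which reduces to the neutral theta/i spectrum when s = 0.  ``influx``
    is the number of new mutations of this class per generation in the
    whole population (2*N*mu*L*fraction); evaluated in log space so very
    strong selection does not overflow.
    """
    n = n_hap // 2
    x = np.arange(1, n_hap) / n_hap
    grid = np.arange(n_hap + 1) / n_hap
    log_g = -(4.0 * n * s_eff) * (h * grid + (1.0 - 2.0 * h) * grid**2 / 2.0)
    # forward and reverse cumulative log-integrals of G (constant dx cancels)
    log_tail = np.logaddexp.accumulate(log_g[::-1])[::-1]
    log_total = log_tail[0]
    log_n = (
        np.log(2.0 * influx)
        - np.log(x * (1.0 - x))
        + log_tail[1:-1]
        - log_g[1:-1]
        - log_total
    )
    return np.exp(log_n) / n_hap


def _seed_selected_sfs(state: PopulationState, rng: np.random.Generator,
                       n_classes: int = 64) -> None:
    """Seed deleterious variation at mutation-selection-drift equilibrium.

    For each discretized DFE class the expected site-frequency spectrum is
    computed from the dominance-aware diffusion sojourn density (with the
    rescaled fitness effects the simulation actually uses), sites are
    Poisson-sampled per copy class and carriers drawn uniformly.  This puts
    the slowly-equilibrating recessive component of the load in place at
    initialization; the short burn-in then relaxes residual disequilibria.
    """
    arch, dfe = state.arch, state.dfe
    lam = state.rescale_lambda
    n_hap = 2 * state.n_individuals
    if n_hap < 4 or dfe.p_deleterious <= 0 or dfe.mutation_rate_per_bp <= 0:
        return
    mu_genome_del = (
        dfe.mutation_rate_per_bp * lam * arch.total_functional_length * dfe.p_deleterious
    )
    s_true, h_cls, frac = _dfe_classes(dfe, n_classes)
    site_s, site_h, site_counts = [], [], []
    for s_c, h_c, f_c in zip(s_true, h_cls, frac):
        s_eff = max(s_c * lam, -1.0)
        # class influx: new mutations entering the whole population per gen
        expected = expected_selected_sfs(n_hap, s_eff, h_c, n_hap * mu_genome_del * f_c)
        counts = rng.poisson(expected)
        idx = np.flatnonzero(counts)
        for i in idx:
            k = int(counts[i])
            site_s.extend([s_c] * k)
            site_h.extend([h_c] * k)
            site_counts.extend([i + 1] * k)
    n_sites = len(site_counts)
    if n_sites == 0:
        return
    site_s = np.array(site_s)
    site_h = np.array(site_h)
    site_counts = np.array(site_counts)
    order = rng.permutation(n_sites)
    site_s, site_h, site_counts = site_s[order], site_h[order], site_counts[order]
    positions = np.sort(state._draw_new_positions(n_sites, rng))
    ids = state.muts.append(
        positions,
        site_s,
        site_h,
        np.full(n_sites, DELETERIOUS, dtype=np.uint8),
        origin=-1,
    )
    carriers = [
        rng.choice(n_hap, size=int(c), replace=False, shuffle=False)
        for c in site_counts
    ]
    hap_of_copy = np.concatenate(carriers)
    site_of_copy = np.repeat(ids, site_counts)
    span = int(ids[-1]) + 1
    key = np.sort(hap_of_copy * span + site_of_copy)
    hap_sorted = key // span
    site_sorted = key % span
    bounds = np.searchsorted(hap_sorted, np.arange(n_hap + 1))
    i = 0
    for deme in state.demes:
        for j in range(len(deme)):
            h0, h1 = deme[j]
            add0 = site_sorted[bounds[i]: bounds[i + 1]]
            add1 = site_sorted[bounds[i + 1]: bounds[i + 2]]
            deme[j] = (_merge_by_position(h0, add0, state.muts.position),
                       _merge_by_position(h1, add1, state.muts.position))
            i += 2
    state.recompute_fitness()


def _merge_by_position(hap: np.ndarray, extra: np.ndarray, position: np.ndarray):
    if extra.size == 0:
        return hap
    if hap.size == 0:
        return extra.copy()
    merged = np.concatenate([hap, extra])
    return merged[np.argsort(position[merged], kind="stable")]


def expand_population(
    state: PopulationState, target_sizes, rng: np.random.Generator
) -> PopulationState:
    """Expand a rescaled population to nominal sizes by copying individuals
    and drop the fitness rescaling (s_fit becomes the true s)."""
    if len(target_sizes) != len(state.demes):
        raise ConfigurationError("target_sizes must match the number of demes")
    for d, t in enumerate(target_sizes):
        pop = state.demes[d]
        idx = np.resize(np.arange(len(pop)), int(t))
        rng.shuffle(idx)
        state.demes[d] = [pop[i] for i in idx]
    state.rescale_lambda = 1.0
    state.muts.set_fitness_scale(1.0)
    state.recompute_fitness()
    return state


def initialize_equilibrium(
    arch: GenomeArchitecture,
    dfe: DFESpec,
    sizes,
    mode: str = "analytic",
    rng: np.random.Generator | None = None,
    *,
    rescale_lambda: float = 1.0,
    burn_in_generations: int | None = None,
    migration_rate: float = 0.0,
    seed_deleterious: bool = True,
    compact_every: int = DEFAULT_COMPACT_EVERY,
) -> PopulationState:
    """Equilibrium population for the given per-deme sizes.

    ``burn_in`` mode runs 10 x (total rescaled N) generations from scratch;
    ``analytic`` mode seeds neutral variation from the equilibrium frequency
    spectrum (density theta/i) and, by default, deleterious variation from
    the dominance-aware diffusion spectrum, then runs a short relaxation
    burn-in (default 500 generations; 2,000 when deleterious variation must
    build up from scratch with ``seed_deleterious=False``).  With
    ``rescale_lambda`` > 1 the equilibration happens in the rescaled
    population, which is then expanded by copying to the requested sizes.
    """
    if rng is None:
        rng = np.random.default_rng()
    sizes = [int(n) for n in sizes]
    if any(n < 2 for n in sizes):
        raise ConfigurationError("all deme sizes must be >= 2")
    lam = float(rescale_lambda)
    red = [max(2, int(round(n / lam))) for n in sizes]
    m_red = min(migration_rate * lam, 0.95) if len(sizes) > 1 else 0.0

    state = PopulationState.empty(arch, dfe, red, rescale_lambda=lam)
    if mode == "analytic":
        _seed_neutral_sfs(state, rng)
        has_del = dfe.p_deleterious > 0 and dfe.mutation_rate_per_bp > 0
        if has_del and seed_deleterious:
            _seed_selected_sfs(state, rng)
        if burn_in_generations is None:
            if not has_del:
                burn_in_generations = 0
            else:
                burn_in_generations = 500 if seed_deleterious else 2000
    elif mode == "burn_in":
        if burn_in_generations is None:
            burn_in_generations = 10 * sum(red)
    else:
        raise ConfigurationError(f"unknown initialization mode {mode!r}")

    for _ in range(int(burn_in_generations)):
        step_generation(state, red, m_red, rng, compact_every=compact_every)
    state.compact()
    if lam != 1.0 or red != sizes:
        expand_population(state, sizes, rng)
    state.generation = 0
    state.fixed_since.clear()
    return state


# ---------------------------------------------------------------------------
# sampling and the genotype-matrix bridge to the estimators
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Individuals x sites genotypes (0/1/2 derived copies, -1 missing)."""

    genotypes: np.ndarray
    positions: np.ndarray
    s: np.ndarray | None = None
    h: np.ndarray | None = None
    kind: np.ndarray | None = None
    sample_ids: list | None = None

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be 2-D (individuals x sites)")
        if self.genotypes.shape[1] != self.positions.size:
            raise ValueError("positions must match the number of sites")
        if self.positions.size > 1 and not np.all(np.diff(self.positions) > 0):
            raise ValueError("site positions must be strictly increasing")
        for name in ("s", "h", "kind"):
            arr = getattr(self, name)
            if arr is not None and len(arr) != self.positions.size:
                raise ValueError(f"{name} annotation length mismatch")

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.genotypes.shape[1]

    def subset_sites(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        return GenotypeMatrix(
            self.genotypes[:, mask],
            self.positions[mask],
            None if self.s is None else np.asarray(self.s)[mask],
            None if self.h is None else np.asarray(self.h)[mask],
            None if self.kind is None else np.asarray(self.kind)[mask],
            self.sample_ids,
        )

    def neutral_only(self) -> "GenotypeMatrix":
        if self.kind is None:
            raise ValueError("matrix has no kind annotations")
        return self.subset_sites(np.asarray(self.kind) == NEUTRAL)


def sample_individuals(
    state: PopulationState, n: int, rng: np.random.Generator
) -> GenotypeMatrix:
    """Draw n diploids without replacement, pooled across demes in proportion
    to deme size, and code genotypes 0/1/2 at the sample's segregating sites."""
    total = state.n_individuals
    if n > total:
        raise SimulationError(f"cannot sample {n} of {total} individuals")
    flat = [ind for deme in state.demes for ind in deme]
    chosen = rng.choice(total, size=n, replace=False, shuffle=False)
    muts = state.muts
    haps = [h for i in chosen for h in flat[i]]
    nonempty = [h for h in haps if h.size]
    counts = (
        np.bincount(np.concatenate(nonempty), minlength=muts.n)
        if nonempty
        else np.zeros(muts.n, dtype=np.int64)
    )
    seg = np.flatnonzero((counts > 0) & (counts < 2 * n))
    order = np.argsort(muts.position[seg], kind="stable")
    seg = seg[order]
    col = np.full(muts.n, -1, dtype=np.int64)
    col[seg] = np.arange(seg.size)
    geno = np.zeros((n, seg.size), dtype=np.int8)
    for i, ind_idx in enumerate(chosen):
        for hap in flat[ind_idx]:
            if hap.size == 0:
                continue
            c = col[hap]
            c = c[c >= 0]
            geno[i, c] += 1
    return GenotypeMatrix(
        geno,
        muts.position[seg],
        s=muts.s[seg].copy(),
        h=muts.h[seg].copy(),
        kind=muts.kind[seg].copy(),
        sample_ids=[f"ind{i}" for i in range(n)],
    )


def lethal_equivalents_from_state(
    state: PopulationState, include_fixed: bool = False
) -> float:
    """Mean per-diploid sum of |s| over carried deleterious allele copies."""
    muts = state.muts
    abs_s = np.abs(muts.s)
    le = []
    fixed = 0.0
    if include_fixed:
        fixed = 2.0 * sum(abs(s) for s, kind, _ in state.fixed_since if kind == DELETERIOUS)
    for h0, h1 in state.individuals():
        tot = fixed
        if h0.size:
            tot += float(abs_s[h0].sum())
        if h1.size:
            tot += float(abs_s[h1].sum())
        le.append(tot)
    return float(np.mean(le)) if le else 0.0


# ---------------------------------------------------------------------------
# scenario driver
# ---------------------------------------------------------------------------

def run_scenario(
    scenario: Scenario,
    timeline: Timeline,
    arch: GenomeArchitecture,
    dfe: DFESpec,
    *,
    sample_size: int = 20,
    replicates: int = 20,
    rng: np.random.Generator | int | None = None,
    init_mode: str = "analytic",
    rescale_lambda: float = 1.0,
    burn_in_generations: int | None = None,
    seed_deleterious: bool = True,
    bins=BIN_LABELS,
    compute_roh: bool = True,
    roh_params=None,
    include_fixed_load: bool = True,
) -> pd.DataFrame:
    """Simulate a scenario and return per-replicate, per-bin sample metrics.

    Each replicate initializes at equilibrium, follows the decline and the
    sustained bottleneck, and draws ``sample_size`` diploids at each
    requested bin's sampling generation.  Percentage heterozygosity loss is
    relative to the same replicate's historical (pre-decline) sample.  Fully
    reproducible from the seed.
    """
    from . import erosion_stats  # deferred: erosion_stats imports this module

    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    gens = {b: timeline.bin_sampling_generation(b) for b in bins}
    horizon = max(gens.values())
    if scenario.horizon < horizon:
        raise ConfigurationError(
            f"scenario horizon {scenario.horizon} ends before the last "
            f"sampling generation {horizon}"
        )
    rows = []
    for rep, rep_rng in enumerate(rng.spawn(replicates)):
        state = initialize_equilibrium(
            arch,
            dfe,
            deme_sizes_at(scenario, 0),
            mode=init_mode,
            rng=rep_rng,
            rescale_lambda=rescale_lambda,
            burn_in_generations=burn_in_generations,
            migration_rate=scenario.migration_rate,
            seed_deleterious=seed_deleterious,
        )
        by_gen: dict[int, list[str]] = {}
        for b, g in gens.items():
            by_gen.setdefault(g, []).append(b)
        rep_rows = {}

        def take(g: int) -> None:
            if g not in by_gen:
                return
            gm = sample_individuals(state, sample_size, rep_rng)
            stats = erosion_stats.compute_sample_stats(
                gm,
                denominator_sites=arch.total_functional_length,
                genome_length=arch.total_functional_length,
                compute_roh=compute_roh,
                roh_params=roh_params,
                fixed_since=state.fixed_since if include_fixed_load else None,
            )
            for b in by_gen[g]:
                rep_rows[b] = dict(stats, bin=b, generation=g, replicate=rep)

        take(0)
        for g in range(1, horizon + 1):
            step_generation(
                state, deme_sizes_at(scenario, g), scenario.migration_rate, rep_rng
            )
            take(g)
        h_hist = rep_rows.get("historical", {}).get("mean_H", np.nan)
        for b, row in rep_rows.items():
            row["pct_loss"] = (
                100.0 * (1.0 - row["mean_H"] / h_hist) if h_hist and h_hist > 0 else np.nan
            )
            rows.append(row)
    df = pd.DataFrame(rows)
    order = {b: i for i, b in enumerate(BIN_LABELS)}
    return df.sort_values(
        ["replicate", "bin"], key=lambda c: c.map(order) if c.name == "bin" else c
    ).reset_index(drop=True)
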