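# Methods

`erosim` is a forward-in-time, individual-based simulator of genomic erosion
in collapsing metapopulations, together with the estimators used to measure
that erosion (heterozygosity and its percentage loss, runs of homozygosity
and their coalescence ages, realized/masked genetic load and lethal
equivalents) and closed-form drift expectations that serve as analytic
oracles.  This note records the model, its assumptions, the numerical
choices, and what the synthetic study conditions do and do not show.

## The simulation model

**Genome.** A single synthetic chromosome carries an exome of 30,000 genes
of 400 bp each (12 Mb of functional sequence).  Mutation is uniform over
the functional sequence at 2.30e-9 per bp per generation under an
infinite-sites rule (a position is never reused).  Recombination is
restricted to gene boundaries: each of the 29,999 boundaries is an
independent crossover point with probability 1e-4 per meiosis, giving ~3
crossovers per meiosis and no recombination within genes.  Coordinates are
0-based and half-open everywhere except the VCF/BED interfaces.

**Mutation effects.** New mutations are neutral or deleterious in a 1:2.3
ratio.  Deleterious homozygous selection coefficients follow a negated
gamma distribution (default shape 0.186, mean -0.01315 -- a widely used
human-derived parameterization) and dominance follows
h(s) = 0.5/(1 - k s) with k = 7071.07, so weak mutations are additive and
strong ones nearly recessive.  All four knobs are configurable, and a
`constant` dominance rule and an optional recessive-lethal point mass
(`lethal_fraction`, default 0) are available.  Fitness is multiplicative
across loci: w = prod(1+s) over homozygous and prod(1+hs) over heterozygous
deleterious genotypes.

**Demography.** A scenario holds the total diploid size at `n_anc` until
onset, declines to `n_bot` over 15 generations, and stays there.  The
decline shape is not uniquely determined by the study design; the default
is exponential (constant proportional decline per generation), with a
linear alternative.  The total is split equally over three demes by
largest remainder (deterministic tie-break by deme index).  Each offspring
draws its parental deme -- home with probability 1-m, otherwise uniform
among the other demes -- and then two distinct parents from that deme with
probability proportional to fitness (soft selection).  Migration is
constant over time.  Offspring with w = 0 are rejected and redrawn, so
lethal homozygotes never survive; deme sizes follow the trajectory exactly.

**Generations and calendar time.** Generations are discrete and
non-overlapping.  (An overlapping-generation formulation changes nothing
about expected drift or selection at these parameter scales; it is a
deliberate simplification.)  A generation time of 3.4 years maps calendar
years onto generations, with decline onset at 1948 and four sampling bins:
historical (pre-1948, sampled at generation 0), modern (2009-2016),
ten-years (2026-2033) and a-hundred-years (2111-2118).
`year_to_generation` floors the elapsed-time quotient; bin cohorts are
sampled at the *rounded* generation of the bin midpoint (19, 24 and 49
generations post-onset), which matches the convention that the future bins
represent ~25 and ~50 generations of bottleneck.

## Equilibrium initialization

Burn-in from scratch is available (`mode="burn_in"`, 10 x total N
generations) but is not the default, because the slowest component of the
standing variation -- rare, nearly recessive, strongly deleterious alleles
-- equilibrates on timescales of thousands of generations.  The default
`analytic` mode seeds:

* neutral sites from the equilibrium frequency spectrum (expected site
  count theta*L/i for i derived copies, theta = 4*N*mu);
* deleterious sites from the dominance-aware diffusion stationary spectrum:
  for each of 64 gamma-quantile classes (plus the lethal mass when
  configured), the expected number of segregating sites per copy class is
  n(x) = 2*influx/(x(1-x)) * Int_x^1 G / (G(x) Int_0^1 G), with
  G(x) = exp(-4Ns(hx + (1-2h)x^2/2)), evaluated in log space.  This
  reduces to theta/i when s = 0.

Carriers are drawn uniformly without replacement per site.  A short
relaxation burn-in (default 500 generations) then lets linkage, the deme
structure and any diffusion error at strong selection relax.  Seeded and
long-burn-in equilibria agree for the default DFE (per-diploid load 0.75
seeded vs ~0.8 after a 2,400-generation burn-in at the same condition).

**Rescaling.** Large ancestral populations are equilibrated at size
N/lambda with mu, s and m multiplied by lambda (theta and 2Ns preserved;
the crossover probability is left at its nominal value), then expanded to
nominal size by copying.  Two caveats, both measured: (i) s*lambda is
clipped at -1, so the strong tail of the DFE saturates; (ii) drift-limited
recessive load is *not* perfectly preserved by rescaling (a 600-diploid
population holds ~0.15 lethal equivalents at equilibrium versus ~0.22 for
its lambda=10 rescaled equivalent, default DFE).  Rescaled runs are
therefore treated as their own stated study condition, not as unbiased
stand-ins for full-size runs.

## Erosion metrics

Per-individual heterozygosity divides heterozygous calls by an explicit
denominator covering monomorphic sites (the functional genome length for
simulator samples), with missing calls removed from that individual's
denominator; diversity loss is 100*(1 - H/H_ancestral), computed on
neutral sites by default (all-sites values are reported alongside).
Realized load is 1 - mean(w); masked load is mean(w) - mean(w_hom), where
w_hom treats every carried deleterious allele as homozygous once; lethal
equivalents are the mean per-diploid sum of |s| over carried deleterious
copies (het |s|, hom 2|s|).  Loads are reported on the linear fitness
scale, which matches the verbal definition of "the portion of load
expressed"; orderings of relative increases are invariant to monotone
rescalings.  Mutations fixed after onset are folded into a tracked
constant and included in the load accounting; fixations during
equilibration are treated as ancestral substitutions and excluded.
Excess-homozygosity F is 1 - H_obs/H_exp with H_exp from sample allele
frequencies.  The cohort contrast uses a re-implemented Kruskal-Wallis
statistic with tie correction (cross-checked against an independent
implementation to 1e-10).

## ROH calling and dating

The SNP-window caller follows the classic sliding-window sketch with the
standard parameter set (30-SNP windows, at most 5 heterozygous and 5
missing calls per homozygous window, SNP eligibility when at least
1 - 0.05 of overlapping windows are homozygous, runs split at gaps over
100 kb and filtered at 10 kb minimum length, 50 minimum SNPs and at most
50 kb/SNP).  The eligibility convention makes the caller conservative near
tract edges: planted tracts are recovered trimmed by roughly a window's
width on each side, so recovery fixtures use tracts comfortably longer
than the minimum filters.  The caller is validated against an exhaustive
brute-force restatement of the same rules rather than against any external
binary, whose exact hit-rate convention differs and is not claimed here.
The heterozygosity-rate caller labels 500-kb windows as ROH when their
per-bp het rate is at most 2e-5 (boundary inclusive) and merges neighbours.
The two callers have different failure modes on simulated cohorts: the
window caller's SNP-count filters (min_snps, density) are tuned to
empirical SNP densities, so when cohorts of *different* diversity are
compared -- e.g. two ancestral sizes -- the lower-diversity cohort's IBD
tracts can fall under min_snps and be filtered away, biasing its F_ROH
downward.  Cross-diversity F_ROH comparisons therefore use the het-rate
caller, whose per-bp threshold is density-independent; within a single
scenario (fixed ancestral size) the window caller is used as configured.
Tract age is t = (100/(L_Mb * cM_per_Mb))/2 generations (times 3.4 years),
with the map density configurable over the 1.71-1.86 cM/Mb range.

## Drift debt

The analytic expectation for neutral heterozygosity retention is
prod_t (1 - 1/(2 N_t)) over the total-size trajectory, computed via
exp-sum-log.  This is exact for a panmictic population and a lower bound
on loss under subdivision (within-deme heterozygosity decays faster once
demes differentiate), so the simulator-versus-closed-form oracle test uses
a single-deme condition; in the three-deme scenarios the simulated loss
exceeds the pooled-trajectory expectation by a few percentage points at
the modern bin, which is the expected direction and magnitude of the
subdivision effect.  `ne_nc_ratio` flags ratios above the 0.1
mutation-drift-equilibrium convention.

## Synthetic cohorts

The cohort generator emulates the *post-filtering* shape of a temporal
resequencing comparison: per-individual heterozygosity targets drawn
around cohort means (historical higher and more dispersed than modern, 9%
apart by default at a historical mean of 0.003 -- bird-typical exome-scale
diversity), allele frequencies with a neutral-SFS-shaped density, optional
uniform missingness, and plantable homozygous tracts for ROH fixtures.  It
does not emulate DNA damage, reference bias, genotype likelihoods or
linkage structure; tests passing on these cohorts show estimator
correctness on clean genotypes, not robustness to historical-specimen
artefacts (which upstream filtering is assumed to have removed).
Generators are pure functions of (spec, seed).  Default cohort sizes
(24 historical vs 18 modern over 200,000 sites) give the rank test ~85-90%
power at the 9% contrast, so a significant modern deficit is the expected
outcome, not a certainty.

## Ancestral-load calibration

The exact DFE behind the printed ancestral load is delegated to an
external supplement and is not recoverable from the study design, so the
package ships two configurations.  The default `DFESpec()` keeps the
literature stand-in above.  Under that stand-in the dominance curve caps
h|s| near 0.5/k, which makes *every* deleterious mutation nearly neutral
in heterozygotes at these population sizes; the inbreeding load is then
drift-limited and equilibrates at ~0.7-0.8 lethal equivalents for an
N=12,000-equivalent population (closed-form stationary spectrum and
long-burn-in simulation agree), an order of magnitude below the 3-4.5
range typical of wild outbred populations that the simulated collapse is
meant to start from.  `ANCESTRAL_LOAD_CALIBRATED_DFE` therefore re-tunes
the single knob `gamma_mean_s` so that the lambda=10 rescaled
equilibration of an N=12,000-equivalent population carries a load inside
3-4.5; the calibrated mean of -0.075 was solved from the closed-form
spectrum and adjusted against verification simulations of the same
condition, which equilibrate at ~3.5-3.7 lethal equivalents (the closed
form under-predicts by ~25-30% at this calibration because much of the
scaled DFE mass saturates the s*lambda clip, where the diffusion
approximation degrades).  All load results state which configuration they
use.

## Problem sizes and numerical choices

Desk-scale study conditions used throughout the tests and the acceptance
script, chosen as the package's standard configuration: ancestral size
12,000 (the smallest of the published grid), 20 diploids sampled per bin,
20 replicates per scenario; neutral-equilibrium (analytic) initialization
for diversity-loss runs; lambda=10 rescaled equilibration with a
500-generation relaxation for load runs; the two-ancestral-size contrast
at lambda=20 with ten replicate declines branching from one equilibrium
per size (drift during the decline dominates that contrast).  Fixed and
lost mutations are compacted every 25 generations.  Random draws all flow
from one `numpy` Generator seeded at the call site, so every result is
bit-reproducible from its seed; replicate streams are spawned, never
shared.

## Known limitations

* No age structure, mate choice, spatial continuity or environmental
  stochasticity; the census trajectory is deterministic and treated as Ne.
* Rescaled equilibration distorts the drift-limited recessive load (see
  above); conclusions that depend on absolute load magnitudes should use
  the stated rescaled condition or full-size burn-ins.
* The window ROH caller implements the published algorithm sketch, not any
  specific tool's binary behaviour.
* Demographic inference, genotype-likelihood estimation and
  species-distribution modelling are out of scope.
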