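# erosim

Forward-in-time simulation and estimation of **genomic erosion** — the
progressive loss of genetic diversity and accumulation of harmful variation
in populations that have collapsed demographically.

The package is written for conservation and population geneticists who want
to ask: *given a reconstructed collapse (a large ancestral population
declining to a few hundred individuals within decades), how much diversity
loss, inbreeding (F_ROH) and realized genetic load should we expect now, in
ten years, and in a hundred years — and how much is still hidden as drift
debt?*

## What it computes

**Simulator.** Diploid individuals with a 30,000-gene exome (12 Mb),
mutation at μ = 2.3 × 10⁻⁹ per bp, crossovers only at gene boundaries
(10⁻⁴ per boundary per meiosis), neutral and deleterious mutations in a
1 : 2.3 ratio with gamma-distributed selection coefficients and dominance
h(s) = 0.5/(1 − ks).  A metapopulation of three demes exchanging migrants
(2% or 5% per generation) declines from N_anc ∈ {12,000, 28,000, 40,000}
to N_bot ∈ {1000, 100, 50} over 15 generations and stays collapsed.
Cohorts of diploids are sampled at four time bins (historical, modern,
+10 y, +100 y; generation time 3.4 y).

**Estimators.** Per-individual heterozygosity H with an explicit
monomorphic-site denominator; percentage diversity loss
100·(1 − H/H_hist); runs of homozygosity by a sliding-window caller
(validated against a brute-force oracle) and a 500-kb het-rate caller;
F_ROH; ROH coalescence dating t = (100/(L·cM))/2 generations; realized
load 1 − mean(w), masked load mean(w) − mean(w_hom), lethal equivalents
mean Σ|s| over carried deleterious copies; excess-homozygosity F; a
Kruskal–Wallis cohort contrast.

**Closed forms.** Expected heterozygosity retention Π(1 − 1/(2Nₜ)) over an
arbitrary size trajectory (the *drift debt* oracle) and Ne/Nc utilities.

See `docs/methods.md` for the model assumptions, the equilibrium-seeding
mathematics, rescaling caveats and the ancestral-load calibration.

## Worked example

Simulate the collapse 12,000 → 100 (three demes, 2% migration) and compare
the modern-bin diversity loss with the closed-form drift expectation:

```python
import numpy as np
from erosim import (Scenario, Timeline, DFESpec, build_exome_architecture,
                    run_scenario, expected_loss_for_scenario)

scenario = Scenario(n_anc=12_000, n_bot=100, migration_rate=0.02)
timeline = Timeline()
df = run_scenario(scenario, timeline, build_exome_architecture(), DFESpec(),
                  sample_size=20, replicates=6, rng=1234,
                  burn_in_generations=0, seed_deleterious=False,
                  bins=("historical", "modern"), compute_roh=False)
modern = df[df["bin"] == "modern"]
print(f"simulated loss: {modern['pct_loss'].mean():.2f}%")
print(f"panmictic drift expectation: "
      f"{expected_loss_for_scenario(scenario, timeline, 'modern'):.2f}%")
```

Output:

```
simulated loss: 5.59%
panmictic drift expectation: 3.75%
```

The simulated modern-bin loss (≈5.6% here; ≈12% when declining to N_bot =
50) exceeds the pooled-trajectory expectation because the three demes
differentiate during the bottleneck and within-deme heterozygosity decays
faster — yet both numbers are far below the >99% census decline: most of
the diversity loss is still unpaid drift debt.

The same machinery is scriptable from a shell:

```bash
erosim grid --config my_grid.yaml --seed 1 --out results/grid --plot fig4.png
erosim roh-date --length-mb 0.0226 --cm-per-mb 1.86
erosim synth --seed 4 --out cohort && erosim stats --vcf cohort_historical.vcf \
    --out h.csv --compare cohort_modern.vcf
```

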