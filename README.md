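# sfs2d

Two-population demographic model selection from the folded two-dimensional
joint site-frequency spectrum (2D-JSFS), for population geneticists working
with RADseq-style SNP data who want to ask: *did these two populations arise
by an old vicariant split, an old founder event, or a recent (postglacial)
founder event — and with what gene flow?*

## What it does

From a VCF of biallelic SNPs plus a population map, the package

1. **filters genotypes** the way RAD pipelines do — depth floor (default
   10×), per-site missingness cap (40%), observed-heterozygosity cap (0.65,
   a paralog guard), one SNP per RAD locus;
2. **builds the folded 2D-JSFS** with hypergeometric down-projection onto a
   smaller, even allele sample size `(n1, n2)`, chosen automatically to
   maximise the expected number of segregating sites retained;
3. **computes expected spectra** under any of eight two-population "island"
   histories with a structured-coalescent Monte Carlo engine.  All models
   share one parameterization: an ancestral population of relative size
   `nuA` splits at scaled time `T` (or `T1 + T2`); a founding fraction
   `s ≤ 0.5` starts the derived population at `nuA·s` while the mainland
   continues at `nuA·(1−s)`; daughter sizes are `nu1`, `nu2` (constant,
   two-epoch, or exponentially growing); gene flow `m12`, `m21` may be
   absent, ancestral-then-isolated, secondary-contact, or continuous.
   Sizes are in units of a reference size `N_ref`, times in `2·N_ref`
   generations, migration in `2·N_ref·m`;
4. **fits each model** by Poisson composite likelihood,
   `logL = Σ_cells [n_ij ln μ_ij − μ_ij − ln n_ij!]` with
   `μ_ij = θ · E[ξ_ij]`, where `θ = 4·N_ref·μ·L` is profiled analytically
   (`θ̂ = Σ obs / Σ model`) and so never counts as a free parameter;
5. **ranks the candidates** by `AIC = 2k − 2 logL`, ΔAIC and Akaike weights
   `ω_i = exp(−Δ_i/2) / Σ_j exp(−Δ_j/2)`.

A first-class synthetic-data generator simulates complete multi-locus
datasets (genealogies per RAD locus, infinite-sites mutations, missingness,
Poisson read depth) under any of the models, so the entire pipeline runs
self-contained, and parameter-recovery / model-discrimination experiments
are one function call.

## Worked example

```bash
cd examples
python 01_simulate_fixture.py
python 02_filter_and_build_sfs.py
python 04_model_selection.py
```

which prints (seeds fixed, so these exact numbers):

```
simulated under  : vic_no_mig {'nuA': 1.54, 'nu1': 1.64, 'nu2': 14.9, 'T': 0.4, 's': 0.3}
loci requested   : 800, SNPs emitted: 1656
...
sites after filtering : 688
projection chosen     : 16 x 12 alleles
folded spectrum mass  : 558.7
...
model                         logL  k       AIC    dAIC      w
vic_no_mig                 -134.36  5    278.71    0.00  0.979
founder_recent_no_mig      -138.19  5    286.38    7.66  0.021
founder_no_mig             -143.00  5    295.99   17.28  0.000
```

The data were simulated under a vicariance history; the ranking recovers
that: the vicariance model takes 97.9% of the Akaike weight, and the
recent-founder alternative (split forced younger than `T = 0.05`) is 7.7
AIC units worse.  A thin CLI wraps the same stages
(`sfs2d simulate | filter | build-sfs | models | fit | compare | run`).

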