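# Methods

## The inference problem

Two populations sampled for thousands of unlinked biallelic SNPs carry, in
their joint site-frequency spectrum, the imprint of how they split: a
vicariant division of a once-continuous population leaves both daughters
with comparable diversity and abundant shared polymorphism; a founder event
passes the derived population through a bottleneck that strips shared
variants and skews its marginal spectrum; gene flow after the split refills
particular off-diagonal cells.  The package casts the question as formal
model selection over an eight-member candidate set of two-population
"island" histories fitted to the folded 2D-JSFS.

## Candidate models

Every model starts from an ancestral population of relative size `nuA`
(units of an implicit reference `N_ref`) that splits into a mainland
fraction `nuA·(1−s)` (population 1) and a derived fraction `nuA·s`
(population 2), with `0 < s ≤ 0.5` enforced so "derived" always means the
minor founding fraction.  Three axes generate the set:

* **scenario** — old vicariance, old founder event, recent founder event
  (the recent case is the same topology with the split-time upper bound
  tightened to `T ≤ 0.05`, i.e. the scenarios differ by dated epoch
  structure, not by likelihood form);
* **size trajectory** — `constant` (daughter sizes jump to `nu1`, `nu2` at
  the split), `two_epoch` (founding sizes for the older interval `T1`, then
  `nu1`, `nu2` for the recent interval `T2`), `exp_growth` (exponential
  interpolation from founding sizes at the split to `nu1`, `nu2` now);
* **migration** — none, continuous, ancestral-then-isolation (gene flow
  only during the older interval) or secondary contact (only the recent
  interval).  `m12` is the scaled rate *into* population 1 *from*
  population 2, and vice versa for `m21`.

Four named models (`vic_no_mig`, `vic_sec_contact_asym_mig`,
`founder_sec_contact_asym_two_epoch`, `founder_anc_asym_two_epoch`) follow
published usage exactly, including their free-parameter lists (k = 5, 8, 8,
8; theta excluded — see below).  The remaining four
(`vic_anc_asym_mig`, `founder_no_mig`, `founder_continuous_asym_mig`,
`founder_recent_no_mig`) complete the scenario × growth × migration grid;
they are this package's reconstruction of a full island set, not a claim
about any particular published supplementary list.  Two open choices were
fixed deliberately: the first epoch of two-epoch founder models sits at the
founding sizes rather than estimating an extra size pair (fewest parameters
consistent with k = 8), and `nuA` is free in every model.

Default box bounds: sizes `[1e-3, 100]`, times `[1e-3, 15]` (`[1e-3,
0.05]` for the recent founder), migration `[0, 20]`, `s ∈ (0, 0.5]`.

## Expected spectra: structured-coalescent Monte Carlo

Expected spectra are computed by simulating genealogies backward in time
through the model's epoch schedule.  With time in units of `2·N_ref`
generations, a lineage pair inside a deme of current size `ν` coalesces at
rate `1/ν`; a lineage in population 1 jumps to population 2 at rate `m12`
(the scaled `2·N_ref·m` rate — with this time unit the per-unit-time
lineage-migration rate equals the scaled parameter itself, the same
correspondence diffusion-based SFS software uses); at the split all
lineages merge into the ancestral deme.  Exponential size trajectories are
handled by closed-form inversion of the integrated coalescence rate.  Each
branch accrues length to its leaf class `(i, j)`; the expected spectrum at
`θ = 1` is `E[ξ_ij] = E[L_ij]/2`, so a history predicts `θ·E[ξ_ij]` sites
per cell.  The convention was cross-validated against msprime (branch-mode
joint AFS) on an island model, and against the analytic single-population
limit `E[ξ_i] = θ/i`.

Two implementations share this event model: a numba-compiled kernel that
tracks only class counts (the fast path inside optimization, roughly 5 µs
per genealogy at 40 lineages) and a plain-Python simulator that also tracks
the leaf set under every branch.  The Python engine drives the dataset
simulator — per RAD locus one genealogy, `Poisson(θ_locus · L_total / 2)`
infinite-sites mutations placed on branches length-proportionally,
haplotypes paired into diploids — and the two engines are asserted to agree
in the test suite, which guards each against the other's bugs.

Monte Carlo error: with `R` replicates the per-cell standard error of the
expectation is returned on request (`return_se=True`); the engine defaults
to `R = 5·10^4` during fitting and `2·10^5` for verification checks, giving
relative SE well under 1% for the spectrum sizes used here.

## Fitting and model comparison

The objective is the Poisson composite likelihood over unmasked folded
cells, with `θ` profiled analytically at every evaluation
(`θ̂ = Σ obs / Σ model`, the exact MLE).  Because `θ` is profiled, it is
excluded from `k` in `AIC = 2k − 2 logL`; this convention is locked by an
arithmetic consistency check on the published pair of best models
(`2·8 − 2·175.33` minus `2·5 − 2·177.32` = 2.02).

Optimization searches `log10` parameter space (the parameters span orders
of magnitude) with Nelder–Mead under common random numbers: every
likelihood evaluation inside one fit reuses the same engine seed, so the
surface is deterministic and the simplex is not chasing noise.  The search
is multi-round in the style of published SFS pipelines — a cheap global
scan of `n_scan` log-uniform draws, a first round of local searches started
from the top-ranked scan basins, later rounds perturbing the incumbent best
by a shrinking multiplicative fold.  The library default schema is 4 rounds
of 10/20/30/40 replicates with folds 3/2/2/1 and 30/40/50/60 iterations;
the scan stage was added after observing that plain random-start
Nelder–Mead at desk-scale budgets regularly stalls in wrong basins of the
multimodal surface.  Out-of-bounds proposals are clipped with a quadratic
penalty; `s` therefore can never exceed 0.5 in any reported fit, and a
standing batch check verifies exactly that.

`compare_models` fits every registry model under its own deterministic seed
substream, ranks by AIC (ties: smaller k, then name), and normalises Akaike
weights over the full fitted set.  Pearson residuals
`(obs − μ)/√μ` per cell support fit diagnostics.

## Synthetic data: what it emulates, what it does not

The generator emulates the statistical structure the analysis assumes:
hundreds–thousands of independent single-copy RAD loci, no recombination
within a locus, infinite-sites mutation, diploid individuals, independent
per-genotype missingness at a configurable rate, per-genotype read depth
drawn `Poisson(mean_depth)`.  Four presets carry the published best-fit
parameter values so benchmarks run at realistic effect sizes; preset
sample sizes (12 + 8 diploids) support the published 24/16-allele
projections exactly.  Not emulated: locus-sharing structure across
individuals (missingness is independent, real RAD dropout is correlated by
allele), sequencing error, paralog collapse, selection, linkage.  Passing
tests therefore demonstrate correctness of the method's own assumptions,
not robustness to these real-data violations — the heterozygosity filter,
for instance, is exercised but has no true paralogs to remove.

## Benchmark configurations (desk scale)

All standing experiments run on one core in minutes; sizes are the
package's chosen configuration, stated here so results are interpretable:

* **s-bound batch** — one preset vicariance dataset (800 loci), folded
  12×8 spectrum, 20 seeded fits cycling over four founder/vicariance
  models, 2·10^3 engine replicates, 2-round schema; reports every fitted
  `s` against the 0.5 cap.
* **parameter recovery** — for each of the four published presets, 3
  Poisson spectra at `θ = 500` on the published 24×16 projection, fitted
  with 5·10^4 engine replicates starting from a 1.5-fold log-uniform
  perturbation of the generating values.  This measures *local*
  identifiability — whether the likelihood surface around the truth is
  sharp enough to pin sizes to ~30% and times to ~50% — which is the
  question a recovery benchmark at this compute scale can answer; global
  search quality is exercised separately by the discrimination experiment.
* **model discrimination** — spectra simulated under an archetypal
  vicariance (`nuA = 1, nu1 = 1, nu2 = 1.5, T = 0.5, s = 0.4`, `θ = 500`,
  12×8), chosen as the canonical "split into comparably sized fractions"
  scenario the vicariance-vs-founder contrast is about; 10 seeds, each
  fitting `vic_no_mig` against `founder_sec_contact_asym_two_epoch` from
  random starts (300-point scan, 3-round schema).  The founder model
  nearly nests the vicariance at `s → 0.5`, so wins are driven by the AIC
  penalty for its three extra parameters — the experiment checks that the
  machinery does not over-reward flexibility.
* **end-to-end consistency** — 3000 simulated loci under a vicariance
  history, folded full-sample spectrum compared cell-wise to
  `θ·E[ξ]` with a variance budget combining Poisson counting noise,
  genealogy-to-genealogy variance and engine MC error.

## Numerical details and limitations

Masked cells (fixed corners, the redundant folded half) hold zero and never
enter likelihoods.  Folding sends `(i, j)` and its complement
`(n1−i, n2−j)` to the minor-total member, lexicographic tie-break on the
hinge, self-complementary cells kept as-is; total mass is conserved and the
operation is idempotent.  Model-spectrum cells are floored at `1e-300`
inside logs.  Missing per-genotype depth is treated as *failing* any
positive depth floor (unverifiable coverage cannot pass a coverage filter).
Nucleotide diversity uses the unbiased `2p(1−p)·c/(c−1)` estimator averaged
over variant sites by default, with an all-sites denominator available when
the total surveyed length is known.

Composite likelihood treats spectrum cells as independent, which is valid
for point estimation and AIC ranking but understates uncertainty; the
package deliberately reports no parameter standard errors.  Parameters are
left unscaled (no conversion to years or census sizes).  The engine
supports at most 64 haplotypes in the dataset simulator (bitmask leaf
sets) and does not model recombination within loci.
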