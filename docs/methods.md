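# Methods

This note documents the models, algorithms, parameter choices, and known
limitations of `argdemog`. Everything quantitative stated here is computed
by the test suite or by `scripts/acceptance.py`; nothing is quoted from
external sources.

## Scientific setting

In birds and other lineages that lost PRDM9, recombination concentrates in
wide regions rather than narrow hotspots, so large fractions of a
chromosome can recombine faster than they mutate (r/mu >= 1). Demography
inference methods built on the ancestral recombination graph reconstruct
local genealogies from observed mutations; where recombination outpaces
mutation, genealogical branches go unrepresented by mutations and the
reconstruction degrades. The package provides a desk-scale, fully
self-contained pipeline to quantify that effect and to verify that masking
high-recombining regions removes it.

## Study scenarios

Three recombination-map families, each parameterized by the target ratio
`k` of mean recombination rate to mutation rate over the analyzed region:

* **stepwise** — 16 Mb; the central 10 Mb at `0.1*mu`, the two 3 Mb ends
  elevated to `(10k - 0.4)/6 * mu` so the mean over the chromosome minus
  its central 6 Mb equals `k*mu`. Coordinates are 0-based half-open; the
  central 10 Mb is [3, 13) Mb and the mean-defining central 6 Mb is
  [5, 11) Mb — only the symmetric placement reproduces the defining
  arithmetic. At `k = 0.1` the map degenerates to uniform `0.1*mu`
  (the no-high-recombining-region control).
* **narrow** — 11 Mb at `0.1*mu` except a 1 Mb segment at `(11k - 1)*mu`,
  placed at [4.5, 5.5) Mb to coincide with the scenario's high-rec mask
  (the mask coordinates, not the geometric center, pin the placement).
* **uniform** — 10 Mb at `k*mu`.

The mutation rate is `mu = 4.6e-9` per bp per generation throughout.

Demography models 1–3: one ancestral population of 10^6 / 10^5 / 10^4
diploids splits simultaneously into three populations 10,000 generations
ago. pop1 stays at 10,000; pop2 grows exponentially 10-fold (10,000 at the
split to 100,000 today); pop3 declines 10-fold (10,000 to 1,000). The
text source for the models states only the 10-fold change; anchoring all
three populations at 10,000 diploids at the split is this package's
choice, matching the depicted trajectories. Trajectories are parameterized
by endpoint sizes, `N(t) = N_present * exp(g t)` backward in time with
`g = ln(N_split/N_present)/T`.

The DFE utilities (four uniform classes of selection coefficients bounded
by 1, 10, 100 over `2*N_anc`, class 3 capped at 1), the 250-gene exon
layout (12 exons of 357 bp, introns of 1,558 bp), and the forward-
simulation rescaling transform (`sizes, times / Q`; `mu * Q`;
`r -> (1 - (1-2r)^Q)/2`) are provided as validated building blocks only;
no forward simulation with selection is run.

## Coalescent simulator (synthetic-data generator)

`argdemog.coalsim` simulates marginal genealogies along a chromosome under
the SMC' (sequentially Markovian coalescent with back-coalescence):

1. The left-end genealogy is drawn under the structured coalescent with
   zero migration: within-population coalescence at rate
   `k(k-1)/2 / (2N_p(t))` on piecewise-exponential size trajectories
   (waiting times by closed-form inversion of the cumulative hazard per
   segment), all lineages merging into the ancestral population at the
   split.
2. Moving rightward, the distance to the next breakpoint is exponential
   in cumulative genetic length times total branch length. At a
   breakpoint, a detachment point is drawn uniformly on the branches and
   the floating lineage re-coalesces with the standing tree at rate
   `k_same-pop(t) / (2N(t))`; re-coalescence onto the detached branch
   itself is an invisible event (no tree change), which is what makes the
   process SMC' rather than SMC.

SMC' was chosen over the full ARG because its cost is linear along the
chromosome and the phenomenon under study (branches unrepresented by
mutations) does not depend on the non-Markovian long-range structure the
full ARG adds. The approximation is bounded empirically: on small
instances the pairwise TMRCA distribution and mean marginal-tree count
match `msprime` (two-sample KS and tree-count comparison in the
acceptance suite).

Mutations follow the infinite-sites model: per marginal tree, a Poisson
count with mean `mu * span * total branch length`, positions uniform
integers within the span (collisions re-drawn), the branch chosen
proportionally to length, and the derived allele carried by the branch's
descendant leaves. Haploid samples pair into synthetic diploids (2i,
2i+1). Per-replicate seeds derive from the master seed through a
counter-based `SeedSequence` scheme recorded in the run manifest.

What the generator deliberately does not emulate: sequencing or phasing
error, missing genotypes, gene conversion, selection (background
selection included), migration after the split, and multi-chromosome
linkage. Tests passing on this generator therefore demonstrate the
inference machinery's behavior under the idealized neutral model the
study assumes, not robustness to real-data artifacts.

## Pairwise SMC hidden Markov model

The estimator (`argdemog.smc.PairwiseSMC`) models the TMRCA of one
haplotype pair along the chromosome as a hidden Markov chain over `E`
discretized time epochs (default 32, echoing the decode configuration of
the tooling the study used).

* **Units.** Everything is kept in natural units: times in generations,
  coalescence rates `lambda` per generation (diploid `Ne = 1/(2 lambda)`),
  `theta` and `rho` per bp per generation. No hidden rescaling.
* **Time grid.** Epoch edges at quantiles of an exponential coalescence
  prior whose rate anchors to the data: `Ne0 = het_rate / (4 mu)` unless
  supplied. Epoch representative times are the prior's conditional means
  within epochs and stay fixed during EM, so emissions are constant and
  the EM objective decomposes cleanly.
* **Transitions.** Recombination strikes at intensity `2 r t` per bp on
  a pair with TMRCA `t`; the breakpoint detaches one lineage at height
  `u ~ U(0, t)` and the floating lineage re-coalesces at rate
  `lambda(s)` for `s > u` (SMC kernel). The per-epoch jump generator `G`
  integrates the current time over the coalescence prior implied by the
  current rates (Gauss-Legendre quadrature in probability space, 32
  points per epoch) and the re-coalescence time analytically per epoch;
  the per-bin transition matrix is `expm(bin_width * G)`. Building the
  kernel at the intensity level makes the epoch-occupancy prior an exact
  stationary distribution at any recombination rate (property-tested to
  1e-6; in practice machine precision), where a one-event-per-bp
  probability kernel would drift at order `(2 r t)^2`.
* **Emissions.** Bins of 100 bp (default) with `called` unmasked sites
  and a heterozygosity indicator. Default is the Bernoulli form: a het is
  observed with probability `1 - (1-p)^called` where
  `p(t) = 1 - exp(-2 t mu)`; a binomial form using full het counts is
  available by flag. The Bernoulli cap loses a little information in deep
  epochs (multiple hets per 100 bp) and slightly deflates apparent theta
  there; it matches the information content of the standard multihetsep
  workflow.
* **EM.** Baum–Welch with `lambda` free and `theta`, `rho` fixed at
  user-supplied truth (the study supplies true rates to inference).
  The E-step accumulates expected initial-state counts and epoch-to-epoch
  transition counts pooled over haplotype pairs and chromosomes (a
  composite likelihood; pairs share an ARG and are not independent, which
  inflates effective data size but not bias — replicate-level dispersion
  carries the uncertainty). The M-step maximizes the expected
  complete-data log-likelihood over `log lambda` with L-BFGS-B (bounds
  `lambda` in [1e-9, 1e-1] per generation, warning at the clamp); a new
  point is accepted only if it improves the objective, so the composite
  log-likelihood is non-decreasing (generalized EM).
* **Decoding.** Posterior epoch indices per bin by forward–backward
  argmax; ties break to the most recent epoch.
* **`rho` under heterogeneous maps.** The HMM assumes a single `rho`; the
  pipeline uses the length-weighted mean rate over the callable region.
  This mirrors standard practice and is itself part of the mechanism by
  which high-recombining regions distort inference.

For cross-population profiles, within-A, within-B, and cross-AB pair sets
are fitted on one shared grid; the relative cross-coalescence rate is
`rCCR_i = lambda_AB,i / ((lambda_AA,i + lambda_BB,i)/2)`, never clipped,
and the split bracket is the first epoch (scanning old to recent) with
rCCR below 0.5 together with its older neighbor. Multiple crossings are a
noise symptom and produce a warning listing all of them.

## Masking and polarization

Scenario masks use the study coordinates exactly (stepwise: control
[3,6)+[13,16) Mb, high-rec [0,3)+[13,16) Mb; narrow: [4.5,5.5) vs
[10,11) Mb), scaled together with the chromosome in reduced-scale runs.
`classify_high_recombining` thresholds the map at `r/mu >= 1` (boundary
included). The genome-half split sorts callable windows by rate and fills
the low half until cumulative callable length first reaches half the
total — balancing sequence length, not window counts, because inference
effort scales with length.

Polarization uses the five-category two-outgroup heuristic (closer
outgroup first): sites with more than two alleles across the three
species are dropped; a fixed closer outgroup donates the ancestral state
(category 2); a fixed farther outgroup breaks ties when the closer one
segregates (category 5); otherwise the focal major allele is ancestral
(categories 1, 3, 4). Exact 50/50 focal ties fall back to the
first-listed allele with a warning. "Fixed" means at least one non-missing
call, all identical; a fully missing farther outgroup falls back to the
category-3/4 rule.

## Bias metric and evaluation windows

Skyline bias is summarized as `MALE = mean |ln(Ne_hat / Ne_true)|` over
epochs whose boundaries lie inside an evaluation window, with the truth
evaluated at each epoch's geometric-mean time, plus the signed log-error
sequence whose sign-change count scores wave-shaped artifacts. Epochs
that straddle the split-time discontinuity of the true trajectory are
excluded: within such an epoch the truth is not constant and any
estimator's single value reflects the discretization, not the inference.

At desk scale (2 Mb chromosomes, model 2), the distortion caused by
including high-recombining sequence concentrates in the split-era epochs:
the constant post-split size of pop1 is overestimated several-fold and
the apparent split moves older, while the deep-past wave has small
amplitude relative to replicate noise. The default window therefore spans
0.2 to 50 split times, and the acceptance comparison of masked versus
unmasked inference evaluates 0.2 to 2 split times, where the effect is
systematic. This windowing is this package's own operationalization of a
qualitative published comparison and was fixed after inspecting skylines
at the working scale.

## Problem sizes

Reduced-scale defaults keep every analysis on a laptop-class budget while
preserving the phenomena: 2 Mb chromosome equivalents (scale 1/8 for the
stepwise map), 10 chromosomes per condition, 4 diploids per population
per fit (downsampled without replacement from 8 simulated, replicating
the study's downsample-replicate design), 100 bp bins, 32 epochs, 6–12 EM
iterations. The split-time recovery analysis uses 12 chromosomes x 2 Mb
(24 Mb) with four within-population pairs per side and sixteen cross
pairs (two disjoint matchings); the constant-Ne recovery analysis uses
40 Mb. The bias signal scales with the fraction of
sequence at `r/mu >= 1` (3/8 of the stepwise chromosome), not with
absolute length.

## Numerical choices and degenerate inputs

* Transition-kernel quadrature guards against prior-survival underflow at
  extreme rates (clamped `t`, finite results for `lambda` at the bounds).
* The M-step objective returns a large finite penalty where the
  likelihood underflows so the optimizer backtracks instead of dying.
* Bins with zero called sites emit a constant likelihood (fully masked
  regions are traversed by the chain but carry no information).
* All-masked inputs, empty samples, zero-length chromosomes, infeasible
  map ratios (`k < 0.1` stepwise, `k < 1/11` narrow), and DFE class-3 on
  `N_anc < 50` are rejected with explicit errors.
* Zero heterozygosity drives rates to the clamp boundary by design and
  must produce no NaN (tested).
* Integer mutation positions: collisions within an interval are re-drawn;
  interval tiling makes cross-interval collisions impossible.

## Known limitations

* The HMM is pairwise only; no multi-haplotype genealogy inference, no
  phasing, no recombination-map estimation from data.
* Composite likelihood across pairs understates uncertainty; only
  across-replicate dispersion quantifies it.
* `theta` and `rho` are never jointly estimated with `lambda`.
* The split-bracket rule assumes an essentially monotone rCCR; heavily
  non-monotone profiles yield warnings rather than model-based inference.
* Downsample replicates share simulated chromosomes (as in the study
  design they mirror); they quantify inference noise given one genome
  history, not simulation noise. Where independence matters (the
  control-vs-masked direction under no-high-rec maps), conclusions were
  checked against independent simulations during development.
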