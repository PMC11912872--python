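# argdemog

Recombination-aware coalescent simulation and pairwise
sequentially-Markovian-coalescent (SMC) demography inference, built to
study a failure mode that matters for birds and other species without
PRDM9: when wide genomic regions recombine faster than they mutate
(r/mu >= 1), genealogical branches go unrepresented by mutations and
ARG-based demography inference becomes systematically biased. The package
simulates genomes under controlled demographies and recombination maps,
re-infers demography with a from-scratch pairwise SMC hidden Markov
model, quantifies the bias, and shows that masking regions with
r/mu >= 1 removes it.

Intended users: population geneticists evaluating whether SMC-based
demography inference can be trusted for a focal species' recombination
landscape, and methods developers who need a transparent, fully scripted
desk-scale replica of that evaluation.

## The model in brief

The hidden state at each 100 bp bin is the epoch containing the TMRCA
`T` of one haplotype pair. Transitions follow the SMC recombination
kernel: per bp, with probability `exp(-2 rho T)` the TMRCA persists;
otherwise a lineage detaches at height `u ~ U(0, T)` and re-coalesces at
rate `lambda(s)`, the per-generation pairwise coalescence rate of epoch
`s`. Emissions are bin heterozygosity with per-site probability
`p(T) = 1 - exp(-2 T mu)`. Baum-Welch EM re-estimates the per-epoch
`lambda` (with `mu`, `rho` fixed at truth); the skyline is
`Ne(t) = 1 / (2 lambda(t))` and the relative cross-coalescence rate
between populations A and B is
`rCCR = lambda_AB / ((lambda_AA + lambda_BB) / 2)`,
whose 0.5-crossing brackets the population split time.

The synthetic-data generator is an in-repo SMC' coalescent-with-
recombination simulator over piecewise recombination maps and a
three-population split demography (ancestral size 10^6/10^5/10^4 for
models 1/2/3; split 10,000 generations ago; constant, 10-fold growing
and 10-fold declining descendants; mu = 4.6e-9). See `docs/methods.md`
for the full specification.

## Worked example

Recover a constant effective population size from simulated data
(demography model 3: every population is 10,000 diploids at all times):

```python
import numpy as np
from argdemog.scenarios import build_demography, make_uniform_map
from argdemog.coalsim import simulate_arg, drop_mutations
from argdemog.smc import PairwiseSMC, observations_from_variants, disjoint_pairs

demog = build_demography(3)
recmap = make_uniform_map(4.6e-9, k=0.1, chrom_length=2e6)

obs = []
for chrom in range(10):                       # 10 chromosomes x 2 Mb
    ts = simulate_arg(demog, recmap, {"pop1": 8}, seed=100 + chrom)
    vt = drop_mutations(ts, 4.6e-9, seed=200 + chrom)
    obs += observations_from_variants(vt, disjoint_pairs(range(8)))

est = PairwiseSMC(mu=4.6e-9, rho=4.6e-10, n_iter=12).fit(obs)
T = est.grid_.boundaries
sel = (T[:-1] >= 2_000) & (T[1:] <= 50_000)
print(f"median Ne over 2,000-50,000 generations: {np.median(est.ne_[sel]):.0f}")
```

Output:

```
median Ne over 2,000-50,000 generations: 10076
```

i.e. the fitted skyline recovers the simulated truth of 10,000 diploids
to within 1% (the per-epoch values scatter around it; the median over the
well-covered window is the headline number).

The same machinery drives the bias experiment: simulate the 16 Mb
"stepwise" map whose 3 Mb ends recombine at up to 16.6x the mutation
rate, fit once with the high-recombining ends included and once with
them masked, and compare skyline error and posterior-decode concordance
by region (`argdemog.experiments.run_scenario`, or the `argdemog
experiment` CLI subcommand).

## Command line

```bash
argdemog simulate --model 2 --map stepwise --k 10 --scale 0.125 \
    --diploids-per-pop 4 --populations pop1 --seed 7 --out out/run
argdemog mask --scenario stepwise --mode highrec --out out/highrec.bed
argdemog infer --vcf out/run.vcf --population pop1 --out out/skyline.tsv
argdemog experiment --scenario fig3 --seed 7 --outdir out/exp
```

Every command writes a JSON run manifest (config, master seed, derived
seeds, output digests); re-running with the same seed reproduces outputs
bit for bit.

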