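"""Orchestration of the in-silico experiments at configurable scale.

A scenario is (demography model, recombination-map family, mean r/mu
ratio k, mask mode). ``run_scenario`` simulates replicate chromosomes,
applies the requested mask, fits the pairwise SMC HMM to within- and
cross-population haplotype pairs, and summarizes skylines, rCCR split
brackets, and decode-vs-truth concordance by region class.

``scale`` shrinks chromosome lengths (and the scenario mask coordinates)
proportionally; the bias under study is driven by the fraction of
sequence with r/mu >= 1, not by absolute length, so reduced-scale runs
preserve the qualitative signal while keeping runtimes desk-sized.

Skyline bias is summarized as the mean absolute log error
``MALE = mean |ln(Ne_inferred / Ne_true)|`` over epochs inside an
evaluation window, plus the signed log-error sequence (whose sign-change
count captures wave-shaped artifacts).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import intervals as iv
from .coalsim import (MarginalTreeSequence, VariantTable, drop_mutations,
                      extract_true_tmrca, simulate_arg)
from .masking import MaskSet, classify_high_recombining, scenario_masks
from .metrics import (CoalescenceRateProfile, SkylineEstimate, SplitBracket,
                      rccr, skyline_from_rates, split_time_from_rccr,
                      tmrca_concordance)
from .scenarios import (Demography, RecombinationMap, build_demography,
                        make_narrow_map, make_stepwise_map, make_uniform_map)
from .smc import (PairwiseSMC, cross_population_rates, disjoint_pairs,
                  observations_from_variants, posterior_decode)

__all__ = [
    "ScenarioResult",
    "make_map",
    "simulate_scenario",
    "run_scenario",
    "evaluate_bias",
    "decode_concordance_by_region",
]


@dataclass
class ScenarioResult:
    """Per-replicate inference summaries for one scenario."""

    model_id: int
    map_family: str
    k: float
    mask_mode: str  # "control" | "highrec" | "none"
    scale: float
    replicate: int
    skylines: dict = field(default_factory=dict)  # pop -> SkylineEstimate
    rccr: dict = field(default_factory=dict)  # (popA, popB) -> per-epoch array
    split_brackets: dict = field(default_factory=dict)  # (popA, popB) -> SplitBracket
    decode_spearman: dict = field(default_factory=dict)  # region label -> rho
    grid: object = None

    def __post_init__(self):
        if self.mask_mode not in ("control", "highrec", "none"):
            raise ValueError("mask_mode must be control, highrec or none")
        if not 0 < self.scale <= 1:
            raise ValueError("scale must be in (0, 1]")


def make_map(map_family: str, mu: float, k: float, scale: float = 1.0) -> RecombinationMap:
    """Build a scenario recombination map, optionally scaled down."""
    if map_family == "stepwise":
        m = make_stepwise_map(mu, k)
    elif map_family == "narrow":
        m = make_narrow_map(mu, k)
    elif map_family == "uniform":
        m = make_uniform_map(mu, k)
    else:
        raise ValueError(f"unknown map family {map_family!r}")
    return m.scaled(scale) if scale != 1.0 else m


def _mask_for(map_family: str, mask_mode: str, scale: float) -> MaskSet:
    if mask_mode == "none" or map_family == "uniform":
        return MaskSet(np.empty((0, 2)), label="none")
    return scenario_masks(map_family, mask_mode, scale=scale)


def simulate_scenario(model_id: int, map_family: str, k: float, scale: float,
                      n_chromosomes: int, diploids_per_pop: int, populations,
                      seed, keep_ts: int = 0):
    """Simulate replicate chromosomes for one scenario.

    Returns ``(demography, recmap, variant_tables, ts_list)`` where
    ``ts_list`` holds the marginal tree sequences of the first ``keep_ts``
    chromosomes (or None), kept for truth-track extraction.
    """
    demog = build_demography(model_id)
    recmap = make_map(map_family, demog.mutation_rate, k, scale)
    sample_config = {p: 2 * diploids_per_pop for p in populations}
    vts = []
    ts_list = [] if keep_ts else None
    for c in range(n_chromosomes):
        s_arg = int(np.random.SeedSequence([int(seed), 7, c, 0]).generate_state(1)[0] & 0x7FFFFFFF)
        s_mut = int(np.random.SeedSequence([int(seed), 7, c, 1]).generate_state(1)[0] & 0x7FFFFFFF)
        ts = simulate_arg(demog, recmap, sample_config, s_arg)
        vts.append(drop_mutations(ts, demog.mutation_rate, s_mut))
        if keep_ts and c < keep_ts:
            ts_list.append(ts)
    return demog, recmap, vts, ts_list


def _downsample_haps(vt: VariantTable, pop: str, diploids: int, rng) -> np.ndarray:
    """Haplotypes of ``diploids`` individuals drawn without replacement."""
    haps = vt.samples_of(pop)
    n_dip = len(haps) // 2
    if diploids > n_dip:
        raise ValueError(f"cannot downsample {diploids} diploids from {n_dip}")
    chosen = rng.choice(n_dip, size=diploids, replace=False)
    chosen.sort()
    return np.concatenate([[haps[2 * d], haps[2 * d + 1]] for d in chosen])


def run_scenario(model_id: int, map_family: str, k: float, mask_mode: str,
                 n_replicates: int, diploids_per_pop: int, scale: float, seed,
                 *, n_chromosomes: int = 10, sim_diploids_per_pop: int | None = None,
                 populations=("pop1", "pop2"), rccr_pairs=(), n_iter: int = 10,
                 bin_width: int = 100, n_pairs: int = 4, decode: bool = False,
                 _sim_cache=None) -> list:
    """Simulate one scenario and run the inference pipeline per replicate.

    Replicates are downsamples of ``diploids_per_pop`` individuals per
    population from a larger simulated sample, drawn without replacement
    with recorded per-replicate seeds. ``rccr_pairs`` lists population
    pairs for cross-coalescence fits; ``decode`` adds posterior-decode
    concordance by region class on the first chromosome.
    """
    if sim_diploids_per_pop is None:
        sim_diploids_per_pop = max(diploids_per_pop, min(2 * diploids_per_pop, 8))
    if _sim_cache is not None:
        demog, recmap, vts, ts_list = _sim_cache
    else:
        demog, recmap, vts, ts_list = simulate_scenario(
            model_id, map_family, k, scale, n_chromosomes, sim_diploids_per_pop,
            populations, seed, keep_ts=3 if decode else 0)
    mask = _mask_for(map_family, mask_mode, scale)
    mu = demog.mutation_rate
    callable_iv = iv.complement(mask.intervals, 0.0, recmap.chrom_length)
    rho = recmap.mean_rate(callable_iv)

    results = []
    for rep in range(n_replicates):
        rep_seed = int(np.random.SeedSequence([int(seed), 11, rep]).generate_state(1)[0] & 0x7FFFFFFF)
        rng = np.random.default_rng(rep_seed)
        res = ScenarioResult(model_id, map_family, k, mask_mode, scale, rep)
        hap_sets = {p: _downsample_haps(vts[0], p, diploids_per_pop, rng) for p in populations}

        for pop in populations:
            pairs = disjoint_pairs(hap_sets[pop])[:n_pairs]
            obs = [o for vt in vts
                   for o in observations_from_variants(vt, pairs, mask=mask.intervals,
                                                       bin_width=bin_width)]
            est = PairwiseSMC(mu=mu, rho=rho, n_iter=n_iter, bin_width=bin_width).fit(obs)
            res.skylines[pop] = skyline_from_rates(
                CoalescenceRateProfile(est.grid_, est.lambdas_, label=pop))
            if pop == populations[0]:
                res._pop0_estimator = est

        for pop_a, pop_b in rccr_pairs:
            sub = _subset_table_pair(vts, hap_sets[pop_a], hap_sets[pop_b], pop_a, pop_b)
            prof = cross_population_rates(sub, pop_a, pop_b, n_pairs=n_pairs,
                                          mask=mask.intervals, bin_width=bin_width,
                                          mu=mu, rho=rho, n_iter=n_iter)
            r = rccr(prof["AB"], prof["AA"], prof["BB"])
            res.rccr[(pop_a, pop_b)] = r
            res.split_brackets[(pop_a, pop_b)] = split_time_from_rccr(r, prof["grid"])
            res.grid = prof["grid"]

        if decode and ts_list:
            est = res._pop0_estimator
            haps = hap_sets[populations[0]]
            pairs = disjoint_pairs(haps)[: min(2, n_pairs)]
            per_region = {"highrec": [], "lowrec": []}
            for ts, vt in zip(ts_list, vts):
                for pair in pairs:
                    one = decode_concordance_by_region(
                        ts, vt, est, (int(pair[0]), int(pair[1])), recmap, mu,
                        mask=mask, bin_width=bin_width)
                    for key, val in one.items():
                        if np.isfinite(val):
                            per_region[key].append(val)
            res.decode_spearman = {
                key: float(np.mean(vals)) if vals else np.nan
                for key, vals in per_region.items()
            }
        results.append(res)
    return results


def _subset_table_pair(vts, haps_a, haps_b, pop_a, pop_b):
    """Variant tables restricted to the downsampled haplotypes of two pops."""
    keep = np.concatenate([haps_a, haps_b]).astype(int)
    out = []
    for vt in vts:
        geno = vt.genotypes[:, keep]
        seg = (geno.sum(axis=1) > 0) & (geno.sum(axis=1) < len(keep))
        out.append(VariantTable(
            positions=vt.positions[seg],
            ancestral=np.asarray(vt.ancestral)[seg],
            derived=np.asarray(vt.derived)[seg],
            genotypes=geno[seg],
            sample_populations=np.asarray(vt.sample_populations)[keep],
            population_names=vt.population_names,
            chrom_length=vt.chrom_length,
        ))
    return out


def region_classes(recmap: RecombinationMap, mu: float, threshold: float = 1.0):
    """(high, low) region MaskSets: map intervals with r/mu >= / < threshold.

    For maps without any elevated interval the ``high`` class falls back
    to the outermost map intervals so that region-wise comparisons remain
    defined (the comparison is then between equal-rate regions).
    """
    high = classify_high_recombining(recmap, mu, threshold)
    if len(high) == 0:
        bp = recmap.breakpoints
        if len(bp) > 2:
            spans = [(bp[0], bp[1]), (bp[-2], bp[-1])]
        else:
            spans = [(bp[0], bp[0] + 0.25 * recmap.chrom_length),
                     (bp[-1] - 0.25 * recmap.chrom_length, bp[-1])]
        high = MaskSet(iv.as_array(spans), label="ends")
    low = high.complement(recmap.chrom_length)
    return high, low


def decode_concordance_by_region(ts: MarginalTreeSequence, vt: VariantTable,
                                 est: PairwiseSMC, pair, recmap, mu,
                                 mask: MaskSet | None = None, bin_width: int = 100):
    """Spearman decode-vs-truth concordance inside high- and low-r/mu regions."""
    obs = observations_from_variants(
        vt, [pair], mask=None if mask is None or len(mask) == 0 else mask.intervals,
        bin_width=bin_width)[0]
    inferred = est.predict_track(obs)
    truth = extract_true_tmrca(ts, pair[0], pair[1])
    high, low = region_classes(recmap, mu)
    out = {}
    for label, region in (("highrec", high), ("lowrec", low)):
        reg_iv = region.intervals
        if mask is not None and len(mask):
            reg_iv = iv.intersect(reg_iv, iv.complement(mask.intervals, 0.0, ts.chrom_length))
        if len(reg_iv) == 0:
            out[label] = np.nan
            continue
        out[label] = tmrca_concordance(truth.restrict(reg_iv), inferred.restrict(reg_iv))
    return out


def evaluate_bias(skyline: SkylineEstimate, truth: Demography, pop: str,
                  window) -> tuple:
    """(MALE, signed log errors) of a skyline over an epoch window.

    Epochs whose boundaries both lie inside ``window = (lo, hi)``
    generations contribute one term ``ln(Ne_inferred / Ne_true)`` with the
    truth evaluated at the epoch's geometric-mean time. Epochs that
    straddle a discontinuity of the true size trajectory (the split time,
    where the descendant and ancestral sizes differ) are skipped: there
    the truth is not locally constant and any estimator's value is an
    artifact of the epoch discretization, not of the inference.
    """
    lo, hi = window
    sel = (skyline.starts >= lo) & (skyline.ends <= hi)
    if not np.any(sel):
        raise ValueError("no epochs inside the evaluation window")
    ts = truth.split_time
    jump = abs(np.log(truth.size_at(pop, ts * (1 - 1e-9)) / truth.ancestral_size)) > 1e-6
    errors = []
    for s, e, ne in zip(skyline.starts[sel], skyline.ends[sel], skyline.ne[sel]):
        if jump and s < ts < e:
            continue
        t_mid = float(np.sqrt(s * e)) if s > 0 else e / 2.0
        ne_true = truth.size_at(pop, t_mid)
        errors.append(float(np.log(ne / ne_true)))
    if not errors:
        raise ValueError("no usable epochs inside the evaluation window")
    errors = np.asarray(errors)
    return float(np.mean(np.abs(errors))), errors


def sign_changes(errors) -> int:
    """Number of sign changes in a signed error sequence (wave-shape score)."""
    sgn = np.sign(errors)
    sgn = sgn[sgn != 0]
    return int(np.sum(sgn[1:] != sgn[:-1]))
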