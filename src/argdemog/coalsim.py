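"""Coalescent-with-recombination simulator over heterogeneous maps.

The simulator generates marginal genealogies along a chromosome under the
sequentially Markovian coalescent with back-coalescence allowed (SMC'),
honoring a piecewise-constant recombination map and a multi-population
demography with one simultaneous split and piecewise-exponential sizes.

The process is:

1. Draw the genealogy at the left end of the chromosome under the
   structured coalescent (no migration; all populations merge into the
   ancestral population at the split time).
2. Move rightwards. The distance to the next recombination breakpoint is
   exponential in cumulative genetic length times the total branch length
   of the current tree. At a breakpoint a detachment point is chosen
   uniformly on the branches, and the floating lineage re-coalesces with
   the standing tree (including the branch it detached from; such events
   are invisible and produce no new marginal tree).

Mutations are dropped afterwards under the infinite-sites model with
integer positions.

Within-population coalescence below the split is restricted to lineages of
the same population because migration is zero; every internal node created
below the split therefore has a well-defined population label.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .scenarios import Demography, RecombinationMap

__all__ = [
    "MarginalTreeSequence",
    "VariantTable",
    "TmrcaTrack",
    "simulate_arg",
    "drop_mutations",
    "extract_true_tmrca",
    "sample_replicates",
]

ANC = -1  # population code for the ancestral population

_NUCS = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# Result containers
# ---------------------------------------------------------------------------


@dataclass
class TmrcaTrack:
    """Piecewise-constant values (TMRCA or epoch index) along a chromosome."""

    starts: np.ndarray
    ends: np.ndarray
    values: np.ndarray
    value_kind: str = "generations"  # or "epoch-index"

    def __post_init__(self):
        self.starts = np.asarray(self.starts, dtype=float)
        self.ends = np.asarray(self.ends, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if not (len(self.starts) == len(self.ends) == len(self.values)):
            raise ValueError("starts, ends, values must have equal length")
        if np.any(self.ends <= self.starts):
            raise ValueError("intervals must have positive length")
        if np.any(self.starts[1:] < self.ends[:-1]):
            raise ValueError("intervals must be sorted and non-overlapping")
        if np.any(self.values < 0):
            raise ValueError("values must be non-negative")

    def __len__(self) -> int:
        return len(self.starts)

    @property
    def span(self):
        return float(self.starts[0]), float(self.ends[-1])

    def merged(self) -> "TmrcaTrack":
        """Merge adjacent intervals carrying the same value."""
        if len(self) == 0:
            return self
        starts, ends, values = [self.starts[0]], [self.ends[0]], [self.values[0]]
        for s, e, v in zip(self.starts[1:], self.ends[1:], self.values[1:]):
            if v == values[-1] and s == ends[-1]:
                ends[-1] = e
            else:
                starts.append(s)
                ends.append(e)
                values.append(v)
        return TmrcaTrack(np.array(starts), np.array(ends), np.array(values), self.value_kind)

    def restrict(self, regions) -> "TmrcaTrack":
        """Intersect the track with a set of (start, end) intervals."""
        from . import intervals as iv

        regions = iv.normalize(regions)
        starts, ends, values = [], [], []
        for s, e, v in zip(self.starts, self.ends, self.values):
            for rs, re_ in regions:
                a, b = max(s, rs), min(e, re_)
                if a < b:
                    starts.append(a)
                    ends.append(b)
                    values.append(v)
        return TmrcaTrack(np.array(starts), np.array(ends), np.array(values), self.value_kind)

    def to_dataframe(self, chrom: str = "chr1"):
        import pandas as pd

        return pd.DataFrame(
            {"chrom": chrom, "start": self.starts, "end": self.ends, "value": self.values}
        )


class MarginalTreeSequence:
    """A sequence of marginal genealogies along one chromosome.

    Node ids 0..n-1 are sampled haplotypes (time 0); internal nodes follow.
    Each tree is stored as a parent pointer array (-1 at the root) plus node
    times in generations.
    """

    def __init__(self, chrom_length, breakpoints, parents, times, sample_populations,
                 population_names, split_time):
        self.chrom_length = float(chrom_length)
        self.breakpoints = np.asarray(breakpoints, dtype=float)
        self.parents = parents
        self.times = times
        self.sample_populations = np.asarray(sample_populations, dtype=np.int8)
        self.population_names = list(population_names)
        self.split_time = float(split_time)

    @property
    def n_samples(self) -> int:
        return len(self.sample_populations)

    @property
    def n_trees(self) -> int:
        return len(self.parents)

    @property
    def intervals(self) -> np.ndarray:
        return np.column_stack([self.breakpoints[:-1], self.breakpoints[1:]])

    def samples_of(self, pop_name: str) -> np.ndarray:
        code = self.population_names.index(pop_name)
        return np.flatnonzero(self.sample_populations == code)

    def tree_total_length(self, i: int) -> float:
        par = self.parents[i]
        t = self.times[i]
        nz = par >= 0
        return float(np.sum(t[par[nz]] - t[nz]))

    def mrca_time(self, i: int, a: int, b: int) -> float:
        """MRCA time of leaves a and b on marginal tree i."""
        par = self.parents[i]
        anc = set()
        x = a
        while x != -1:
            anc.add(x)
            x = par[x]
        x = b
        while x not in anc:
            x = par[x]
        return float(self.times[i][x])

    def to_newick(self, i: int) -> str:
        par = self.parents[i]
        tm = self.times[i]
        children = {}
        root = -1
        for v, p in enumerate(par):
            if p == -1:
                root = v
            else:
                children.setdefault(int(p), []).append(v)

        def rec(v):
            if v not in children:
                return f"n{v}"
            parts = ",".join(
                f"{rec(c)}:{tm[v] - tm[c]:.6f}" for c in children[v]
            )
            return f"({parts})"

        return rec(root) + ";"

    def validate(self):
        """Check structural invariants; raises AssertionError on violation."""
        assert self.breakpoints[0] == 0.0 and self.breakpoints[-1] == self.chrom_length
        assert np.all(np.diff(self.breakpoints) > 0)
        assert len(self.parents) == len(self.breakpoints) - 1
        n = self.n_samples
        for par, tm in zip(self.parents, self.times):
            assert np.sum(par == -1) == 1, "exactly one root"
            nz = par >= 0
            assert np.all(tm[par[nz]] > tm[nz]), "parents must be older than children"
            assert np.all(tm[:n] == 0.0)
            assert np.all(tm[n:] > 0.0)


@dataclass
class VariantTable:
    """Biallelic polarized variants with a phased haploid genotype matrix.

    Positions are 0-based internally; VCF emission converts to 1-based.
    Haplotypes 2i and 2i+1 form synthetic diploid individual i.
    """

    positions: np.ndarray  # int64, strictly increasing, 0-based
    ancestral: np.ndarray  # '<U1'
    derived: np.ndarray  # '<U1'
    genotypes: np.ndarray  # (n_sites, n_haplotypes) uint8, 0=ancestral
    sample_populations: np.ndarray  # per-haplotype population code
    population_names: list
    chrom_length: float

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.genotypes = np.asarray(self.genotypes, dtype=np.uint8)
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if self.genotypes.shape[0] != len(self.positions):
            raise ValueError("genotype matrix row count must match positions")

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    @property
    def n_haplotypes(self) -> int:
        return self.genotypes.shape[1]

    def samples_of(self, pop_name: str) -> np.ndarray:
        code = self.population_names.index(pop_name)
        return np.flatnonzero(np.asarray(self.sample_populations) == code)

    def derived_counts(self, haplotypes=None) -> np.ndarray:
        g = self.genotypes if haplotypes is None else self.genotypes[:, haplotypes]
        return g.sum(axis=1).astype(np.int64)

    def het_positions(self, hap_a: int, hap_b: int) -> np.ndarray:
        """Positions where the two haplotypes disagree."""
        diff = self.genotypes[:, hap_a] != self.genotypes[:, hap_b]
        return self.positions[diff]

    def subset_sites(self, keep_mask) -> "VariantTable":
        keep_mask = np.asarray(keep_mask, dtype=bool)
        return VariantTable(
            positions=self.positions[keep_mask],
            ancestral=np.asarray(self.ancestral)[keep_mask],
            derived=np.asarray(self.derived)[keep_mask],
            genotypes=self.genotypes[keep_mask],
            sample_populations=self.sample_populations,
            population_names=self.population_names,
            chrom_length=self.chrom_length,
        )


# ---------------------------------------------------------------------------
# Demography helpers
# ---------------------------------------------------------------------------


def _segments_for(demog: Demography, pop_code: int):
    """(t0, t1, N0, g) exponential segments, backward in time, for a pop code."""
    if pop_code == ANC:
        return [(demog.split_time, math.inf, demog.ancestral_size, 0.0)]
    pop = demog.populations[pop_code]
    out = []
    for seg in sorted(pop.segments, key=lambda s: s.t0):
        t1 = min(seg.t1, demog.split_time)
        if seg.t0 < t1:
            out.append((seg.t0, t1, seg.n0, seg.growth))
    return out


def _coal_wait(segments, t_start, t_stop, k_pairs, E):
    """Invert cumulative coalescence hazard for ``k_pairs`` pair-equivalents.

    The hazard is ``k_pairs / (2 N(t))`` on piecewise-exponential segments
    ``N(t) = N0 * exp(g (t - t0))``. Returns the event time, or None if the
    remaining hazard E is not exhausted before ``t_stop``.
    """
    if k_pairs <= 0:
        return None
    for t0, t1, n0, g in segments:
        a = max(t0, t_start)
        b = min(t1, t_stop)
        if a >= b:
            continue
        # N at segment-local time a
        na = n0 * math.exp(g * (a - t0))
        c = k_pairs / (2.0 * na)
        span = b - a
        if g == 0.0:
            h_max = c * span
            if E <= h_max:
                return a + E / c
            E -= h_max
        else:
            # rate(t) = c * exp(-g (t - a)); cumulative = c/g (1 - exp(-g dt))
            if math.isinf(span):
                h_max = c / g if g > 0 else math.inf
            else:
                h_max = (c / g) * (1.0 - math.exp(-g * span)) if g != 0 else c * span
            if g > 0 and E >= c / g:
                E -= h_max if not math.isinf(span) else 0.0
                if math.isinf(span):
                    return None
                continue
            if E <= h_max:
                return a - math.log1p(-g * E / c) / g
            E -= h_max
    return None


# ---------------------------------------------------------------------------
# Initial tree under the structured coalescent
# ---------------------------------------------------------------------------


def _first_tree(demog, sample_pops, rng):
    n = len(sample_pops)
    n_nodes = 2 * n - 1
    parent = np.full(n_nodes, -1, dtype=np.int32)
    time = np.zeros(n_nodes, dtype=np.float64)
    popv = np.full(n_nodes, ANC, dtype=np.int8)
    popv[:n] = sample_pops

    pools = {}
    for v, p in enumerate(sample_pops):
        pools.setdefault(int(p), []).append(v)
    t = 0.0
    next_node = n
    split = demog.split_time
    while sum(len(v) for v in pools.values()) > 1:
        if t < split:
            best = None
            for code, lineages in pools.items():
                k = len(lineages)
                if k < 2:
                    continue
                segs = _segments_for(demog, code)
                tc = _coal_wait(segs, t, split, k * (k - 1) / 2.0, rng.exponential())
                if tc is not None and (best is None or tc < best[0]):
                    best = (tc, code)
            if best is None:
                # no coalescence before the split: merge everything
                merged = [v for lin in pools.values() for v in lin]
                pools = {ANC: merged}
                t = split
                continue
            tc, code = best
        else:
            lineages = pools[ANC]
            k = len(lineages)
            segs = _segments_for(demog, ANC)
            tc = _coal_wait(segs, t, math.inf, k * (k - 1) / 2.0, rng.exponential())
            code = ANC
        lineages = pools[code]
        i, j = rng.choice(len(lineages), size=2, replace=False)
        a, b = lineages[i], lineages[j]
        node = next_node
        next_node += 1
        parent[a] = node
        parent[b] = node
        time[node] = tc
        popv[node] = code if tc < split else ANC
        for x in sorted((i, j), reverse=True):
            lineages.pop(x)
        lineages.append(node)
        t = tc
    return parent, time, popv


# ---------------------------------------------------------------------------
# The chromosome sweep
# ---------------------------------------------------------------------------


def simulate_arg(demography: Demography, recmap: RecombinationMap, sample_config: dict,
                 seed) -> MarginalTreeSequence:
    """Simulate marginal genealogies along one chromosome under SMC'.

    ``sample_config`` maps population names to haploid sample counts.
    Deterministic given ``seed``.
    """
    if recmap.chrom_length <= 0:
        raise ValueError("zero-length chromosome")
    names = demography.population_names
    sample_pops = []
    for pop_name, count in sample_config.items():
        if count < 1:
            raise ValueError(f"need at least one haplotype in {pop_name}")
        code = names.index(pop_name)
        sample_pops.extend([code] * int(count))
    if not sample_pops:
        raise ValueError("empty sample")
    sample_pops = np.asarray(sample_pops, dtype=np.int8)
    n = len(sample_pops)
    rng = np.random.default_rng(seed)
    split = demography.split_time

    parent, time, popv = _first_tree(demography, sample_pops, rng)
    root = int(np.flatnonzero(parent == -1)[0])

    # cumulative genetic length of the map
    bp = recmap.breakpoints
    seg_gen = recmap.rates * np.diff(bp)
    cum_gen = np.concatenate([[0.0], np.cumsum(seg_gen)])
    total_gen = cum_gen[-1]

    breakpoints = [0.0]
    parents_out = [parent.astype(np.int16).copy()]
    times_out = [time.copy()]

    def tree_length():
        nz = parent >= 0
        return float(np.sum(time[parent[nz]] - time[nz]))

    def genetic_at(x):
        i = min(int(np.searchsorted(bp, x, side="right")) - 1, len(seg_gen) - 1)
        return cum_gen[i] + recmap.rates[i] * (x - bp[i])

    def pos_at(gtarget):
        i = int(np.searchsorted(cum_gen, gtarget, side="right")) - 1
        i = min(i, len(seg_gen) - 1)
        while recmap.rates[i] == 0.0 and cum_gen[i] < gtarget:
            i += 1
        return bp[i] + (gtarget - cum_gen[i]) / recmap.rates[i]

    x = 0.0
    L_tree = tree_length()
    g_x = 0.0
    while True:
        if total_gen - g_x <= 0 or L_tree <= 0:
            break
        g_x = g_x + rng.exponential() / L_tree
        if g_x >= total_gen:
            break
        x = pos_at(g_x)
        if x >= recmap.chrom_length:
            break

        # --- choose detachment point uniformly on the branches
        nz = np.flatnonzero(parent >= 0)
        lens = time[parent[nz]] - time[nz]
        cuml = np.cumsum(lens)
        r1 = rng.random() * cuml[-1]
        ei = int(np.searchsorted(cuml, r1, side="right"))
        c = int(nz[ei])
        u = float(time[c] + (r1 - (cuml[ei - 1] if ei else 0.0)))
        p = int(parent[c])
        fpop = int(popv[c])  # floating pop below the split

        # --- re-coalesce the floating lineage with the standing tree
        node_times = np.unique(time)
        t_cur = u
        t_root = float(time[root])
        t_r = None
        while True:
            later = node_times[node_times > t_cur]
            cands_t = [float(later[0])] if len(later) else []
            if t_cur < split:
                cands_t.append(split)
            t_next = min(cands_t) if cands_t else math.inf
            # count standing lineages at t_cur
            if t_cur >= t_root:
                k = 1  # the lineage above the root
                code = ANC if t_cur >= split else int(popv[root])
            else:
                nzp = parent >= 0
                crossing = nzp & (time <= t_cur) & (time[np.where(nzp, parent, 0)] > t_cur)
                if t_cur < split:
                    crossing &= popv == fpop
                k = int(np.sum(crossing))
                code = fpop if t_cur < split else ANC
            segs = _segments_for(demography, code)
            tc = _coal_wait(segs, t_cur, t_next, float(k), rng.exponential())
            if tc is not None:
                t_r = tc
                break
            t_cur = t_next

        # --- pick the target lineage at t_r
        if t_r >= t_root:
            target = -2  # the lineage above the root
        else:
            nzp = parent >= 0
            crossing = nzp & (time <= t_r) & (time[np.where(nzp, parent, 0)] > t_r)
            if t_r < split:
                crossing &= popv == fpop
            cand = np.flatnonzero(crossing)
            target = int(cand[rng.integers(len(cand))])

        if target == c:
            continue  # invisible back-coalescence onto the detached branch

        # --- subtree prune and regraft
        sib_candidates = np.flatnonzero(parent == p)
        s = int(sib_candidates[0] if sib_candidates[0] != c else sib_candidates[1])
        g = int(parent[p])
        parent[s] = g
        if g == -1:
            root = s
        if target == -2:
            v = root
        else:
            v = s if target == p else target
        w = int(parent[v])
        parent[v] = p
        parent[c] = p
        time[p] = t_r
        parent[p] = w
        popv[p] = popv[v] if t_r < split else ANC
        if w == -1:
            root = p
        t_root = float(time[root])

        L_tree = tree_length()
        breakpoints.append(x)
        parents_out.append(parent.astype(np.int16).copy())
        times_out.append(time.copy())

    breakpoints.append(recmap.chrom_length)
    return MarginalTreeSequence(
        chrom_length=recmap.chrom_length,
        breakpoints=np.asarray(breakpoints),
        parents=parents_out,
        times=times_out,
        sample_populations=sample_pops,
        population_names=names,
        split_time=split,
    )


# ---------------------------------------------------------------------------
# Mutations
# ---------------------------------------------------------------------------


def drop_mutations(ts: MarginalTreeSequence, mu: float, seed) -> VariantTable:
    """Drop infinite-sites mutations on the marginal trees.

    Per tree interval the mutation count is Poisson in ``mu * span *
    total branch length``; each mutation falls on a branch proportional to
    its length and is carried by the branch's descendant leaves. Positions
    are integers; collisions within an interval are re-drawn.
    """
    if mu < 0:
        raise ValueError("mu must be >= 0")
    rng = np.random.default_rng(seed)
    n = ts.n_samples
    spans = np.diff(ts.breakpoints)
    tots = np.array([ts.tree_total_length(i) for i in range(ts.n_trees)])
    counts = rng.poisson(mu * spans * tots) if mu > 0 else np.zeros(len(spans), dtype=int)

    positions, rows = [], []
    for i in np.flatnonzero(counts):
        m = int(counts[i])
        lo = int(math.ceil(ts.breakpoints[i]))
        hi = int(math.ceil(ts.breakpoints[i + 1]))
        if hi <= lo:
            continue
        m = min(m, hi - lo)
        pos = rng.integers(lo, hi, size=m)
        for _ in range(64):
            pos = np.unique(pos)
            short = m - len(pos)
            if short == 0:
                break
            pos = np.concatenate([pos, rng.integers(lo, hi, size=short)])
        pos = np.unique(pos)[:m]

        par = ts.parents[i]
        tm = ts.times[i]
        nz = np.flatnonzero(par >= 0)
        lens = tm[par[nz]] - tm[nz]
        cuml = np.cumsum(lens)
        branch = nz[np.searchsorted(cuml, rng.random(len(pos)) * cuml[-1], side="right")]

        children = {}
        for v in range(len(par)):
            pp = int(par[v])
            if pp >= 0:
                children.setdefault(pp, []).append(v)
        for pp, b in zip(pos, branch):
            carriers = np.zeros(n, dtype=np.uint8)
            stack = [int(b)]
            while stack:
                v = stack.pop()
                if v < n:
                    carriers[v] = 1
                else:
                    stack.extend(children.get(v, ()))
            positions.append(int(pp))
            rows.append(carriers)

    if positions:
        order = np.argsort(positions, kind="stable")
        positions = np.asarray(positions, dtype=np.int64)[order]
        geno = np.asarray(rows, dtype=np.uint8)[order]
        # positions in distinct intervals are distinct by construction, but
        # guard against degenerate float-boundary duplicates
        keep = np.concatenate([[True], np.diff(positions) > 0])
        positions, geno = positions[keep], geno[keep]
    else:
        positions = np.empty(0, dtype=np.int64)
        geno = np.empty((0, n), dtype=np.uint8)

    anc_idx = rng.integers(0, 4, size=len(positions))
    der_off = rng.integers(1, 4, size=len(positions))
    ancestral = _NUCS[anc_idx]
    derived = _NUCS[(anc_idx + der_off) % 4]
    return VariantTable(
        positions=positions,
        ancestral=ancestral,
        derived=derived,
        genotypes=geno,
        sample_populations=ts.sample_populations.copy(),
        population_names=list(ts.population_names),
        chrom_length=ts.chrom_length,
    )


def extract_true_tmrca(ts: MarginalTreeSequence, hap_a: int, hap_b: int) -> TmrcaTrack:
    """True pairwise TMRCA as a piecewise-constant track along the chromosome."""
    if hap_a == hap_b:
        raise ValueError("need two distinct haplotypes")
    for h in (hap_a, hap_b):
        if not 0 <= h < ts.n_samples:
            raise ValueError(f"unknown haplotype id {h}")
    vals = np.array([ts.mrca_time(i, hap_a, hap_b) for i in range(ts.n_trees)])
    track = TmrcaTrack(ts.breakpoints[:-1], ts.breakpoints[1:], vals, "generations")
    return track.merged()


def sample_replicates(demography: Demography, recmap: RecombinationMap,
                      n_replicates: int, diploids_per_pop: int, seed,
                      mu: float | None = None, populations=None):
    """Independent replicate simulations with derived, recorded seeds.

    Returns ``(replicates, manifest)`` where each replicate is a
    ``(MarginalTreeSequence, VariantTable)`` pair. Seeds derive from the
    master seed via a counter-based SeedSequence scheme.
    """
    if n_replicates < 1 or diploids_per_pop < 1:
        raise ValueError("n_replicates and diploids_per_pop must be positive")
    mu = demography.mutation_rate if mu is None else mu
    pops = list(populations) if populations is not None else demography.population_names
    sample_config = {p: 2 * diploids_per_pop for p in pops}
    out = []
    manifest = {
        "master_seed": int(seed),
        "n_replicates": int(n_replicates),
        "diploids_per_pop": int(diploids_per_pop),
        "populations": pops,
        "mutation_rate": mu,
        "replicates": [],
    }
    for i in range(n_replicates):
        s_arg = int(np.random.SeedSequence([int(seed), 2 * i]).generate_state(1)[0] & 0x7FFFFFFF)
        s_mut = int(np.random.SeedSequence([int(seed), 2 * i + 1]).generate_state(1)[0] & 0x7FFFFFFF)
        ts = simulate_arg(demography, recmap, sample_config, s_arg)
        vt = drop_mutations(ts, mu, s_mut)
        manifest["replicates"].append({"index": i, "seed_arg": s_arg, "seed_mutations": s_mut})
        out.append((ts, vt))
    return out, manifest
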