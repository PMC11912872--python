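"""Study scenarios: recombination maps, demographies, DFEs, and gene layouts.

Three families of piecewise-constant recombination maps are provided, each
parameterized by the target ratio ``k`` of mean recombination rate to
mutation rate over the region that is actually analyzed:

* ``stepwise`` — a 16 Mb chromosome whose central 10 Mb recombines at one
  tenth of the mutation rate while the two 3 Mb ends are elevated so that
  the mean over the chromosome minus its central 6 Mb equals ``k * mu``.
* ``narrow`` — an 11 Mb chromosome at ``0.1 * mu`` everywhere except a 1 Mb
  elevated segment, with mean over the whole chromosome equal to ``k * mu``.
* ``uniform`` — a 10 Mb chromosome with a single rate ``k * mu``.

Demography models 1-3 describe one ancestral diploid population of size
1e6 / 1e5 / 1e4 splitting simultaneously into three populations 10,000
generations before present: pop1 constant at 10,000 diploids, pop2 growing
exponentially 10-fold (10,000 -> 100,000 forward in time), and pop3
declining 10-fold (10,000 -> 1,000).

The DFE sampler and the forward-simulation rescaling transform are
validated utilities only; no forward simulation with selection is run here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MUTATION_RATE",
    "SPLIT_TIME",
    "RecombinationMap",
    "SizeSegment",
    "Population",
    "Demography",
    "DfeConfig",
    "GeneAnnotation",
    "make_stepwise_map",
    "make_narrow_map",
    "make_uniform_map",
    "build_demography",
    "rescale_params",
    "sample_dfe",
    "make_gene_annotation",
]

#: Per-bp, per-generation mutation rate used throughout the study design.
MUTATION_RATE = 4.6e-9

#: Generations before present at which the three populations split.
SPLIT_TIME = 10_000.0

ANCESTRAL_SIZES = {1: 1_000_000.0, 2: 100_000.0, 3: 10_000.0}


# ---------------------------------------------------------------------------
# Recombination maps
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RecombinationMap:
    """Piecewise-constant per-bp recombination rates over one chromosome.

    ``breakpoints`` has length ``len(rates) + 1``, starts at 0, ends at
    ``chrom_length``, and is strictly increasing; interval ``i`` is
    ``[breakpoints[i], breakpoints[i+1])`` with rate ``rates[i]`` (per bp
    per generation).
    """

    chrom_length: float
    breakpoints: np.ndarray
    rates: np.ndarray

    def __post_init__(self):
        bp = np.asarray(self.breakpoints, dtype=float)
        rates = np.asarray(self.rates, dtype=float)
        object.__setattr__(self, "breakpoints", bp)
        object.__setattr__(self, "rates", rates)
        if self.chrom_length <= 0:
            raise ValueError("chrom_length must be positive")
        if len(bp) != len(rates) + 1:
            raise ValueError("need len(breakpoints) == len(rates) + 1")
        if bp[0] != 0 or bp[-1] != self.chrom_length:
            raise ValueError("breakpoints must span [0, chrom_length]")
        if np.any(np.diff(bp) <= 0):
            raise ValueError("breakpoints must be strictly increasing")
        if np.any(rates < 0):
            raise ValueError("rates must be non-negative")

    @property
    def n_intervals(self) -> int:
        return len(self.rates)

    def rate_at(self, positions) -> np.ndarray:
        """Rate at each position (vectorized)."""
        pos = np.asarray(positions, dtype=float)
        if np.any(pos < 0) or np.any(pos >= self.chrom_length):
            raise ValueError("position outside chromosome")
        idx = np.searchsorted(self.breakpoints, pos, side="right") - 1
        return self.rates[idx]

    def mean_rate(self, intervals=None) -> float:
        """Length-weighted mean rate over ``intervals`` (default: whole map)."""
        from . import intervals as iv

        if intervals is None:
            intervals = [(0.0, self.chrom_length)]
        region = iv.normalize(intervals)
        num = 0.0
        den = 0.0
        for s, e in region:
            s = max(s, 0.0)
            e = min(e, self.chrom_length)
            if s >= e:
                continue
            i0 = np.searchsorted(self.breakpoints, s, side="right") - 1
            i1 = np.searchsorted(self.breakpoints, e, side="left")
            for i in range(i0, i1):
                a = max(s, self.breakpoints[i])
                b = min(e, self.breakpoints[i + 1])
                if b > a:
                    num += self.rates[i] * (b - a)
                    den += b - a
        if den == 0:
            raise ValueError("empty region")
        return num / den

    def cumulative(self, positions) -> np.ndarray:
        """Cumulative genetic length (sum of rate * bp) from 0 to positions."""
        pos = np.atleast_1d(np.asarray(positions, dtype=float))
        cum = np.concatenate([[0.0], np.cumsum(self.rates * np.diff(self.breakpoints))])
        idx = np.clip(np.searchsorted(self.breakpoints, pos, side="right") - 1, 0, self.n_intervals - 1)
        return cum[idx] + self.rates[idx] * (pos - self.breakpoints[idx])

    def to_dataframe(self, chrom: str = "chr1") -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": chrom,
                "start": self.breakpoints[:-1].astype(int),
                "end": self.breakpoints[1:].astype(int),
                "rate_per_bp_per_gen": self.rates,
            }
        )

    def scaled(self, factor: float) -> "RecombinationMap":
        """Shrink the chromosome by ``factor`` in (0, 1], keeping rates."""
        if not 0 < factor <= 1:
            raise ValueError("scale factor must be in (0, 1]")
        return RecombinationMap(
            chrom_length=self.chrom_length * factor,
            breakpoints=self.breakpoints * factor,
            rates=self.rates.copy(),
        )


def make_stepwise_map(mu: float, k: float) -> RecombinationMap:
    """16 Mb map: central 10 Mb at ``0.1*mu``, 3 Mb ends elevated.

    The end rate ``x*mu`` solves ``(4*0.1 + 6*x)/10 = k`` so that the mean
    rate over the chromosome minus its central 6 Mb ([5, 11) Mb) equals
    ``k*mu``. Requires ``k >= 0.1`` (the end rate is negative otherwise).
    """
    if mu <= 0:
        raise ValueError("mu must be positive")
    end_ratio = (10.0 * k - 0.4) / 6.0
    if end_ratio < 0.1 - 1e-12:
        raise ValueError(f"k={k} < 0.1 would require end rate below the central rate")
    mb = 1e6
    return RecombinationMap(
        chrom_length=16 * mb,
        breakpoints=np.array([0.0, 3 * mb, 13 * mb, 16 * mb]),
        rates=np.array([end_ratio * mu, 0.1 * mu, end_ratio * mu]),
    )


def make_narrow_map(mu: float, k: float) -> RecombinationMap:
    """11 Mb map at ``0.1*mu`` except a 1 Mb segment at ``(11k - 1)*mu``.

    The segment sits at [4.5, 5.5) Mb so that the mean over the full 11 Mb
    equals ``k*mu``.
    """
    if mu <= 0:
        raise ValueError("mu must be positive")
    seg_ratio = 11.0 * k - 1.0
    if seg_ratio < 0:
        raise ValueError(f"k={k} infeasible for the narrow map (needs k >= 1/11)")
    mb = 1e6
    return RecombinationMap(
        chrom_length=11 * mb,
        breakpoints=np.array([0.0, 4.5 * mb, 5.5 * mb, 11 * mb]),
        rates=np.array([0.1 * mu, seg_ratio * mu, 0.1 * mu]),
    )


def make_uniform_map(mu: float, k: float, chrom_length: float = 10e6) -> RecombinationMap:
    """Single-interval map of ``chrom_length`` bp at rate ``k*mu``."""
    if mu <= 0 or k <= 0:
        raise ValueError("mu and k must be positive")
    return RecombinationMap(
        chrom_length=chrom_length,
        breakpoints=np.array([0.0, chrom_length]),
        rates=np.array([k * mu]),
    )


# ---------------------------------------------------------------------------
# Demography
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SizeSegment:
    """Exponential size trajectory on [t0, t1) backward in time.

    ``N(t) = n0 * exp(g * (t - t0))`` with ``g = ln(n1/n0) / (t1 - t0)``;
    ``n0`` is the diploid size at the recent edge ``t0``.
    """

    t0: float
    t1: float
    n0: float
    n1: float

    def __post_init__(self):
        if self.t1 <= self.t0:
            raise ValueError("segment needs t1 > t0")
        if self.n0 <= 0 or self.n1 <= 0:
            raise ValueError("sizes must be positive")

    @property
    def growth(self) -> float:
        return float(np.log(self.n1 / self.n0) / (self.t1 - self.t0))

    def size_at(self, t: float) -> float:
        return float(self.n0 * np.exp(self.growth * (t - self.t0)))


@dataclass(frozen=True)
class Population:
    name: str
    segments: tuple

    def size_at(self, t: float) -> float:
        for seg in self.segments:
            if seg.t0 <= t < seg.t1:
                return seg.size_at(t)
        raise ValueError(f"time {t} outside trajectory of {self.name}")


@dataclass(frozen=True)
class Demography:
    """Three-population split demography with piecewise-exponential sizes.

    All descendant populations merge into one ancestral population of
    constant diploid size ``ancestral_size`` at ``split_time`` generations
    before present.
    """

    populations: tuple
    split_time: float
    ancestral_size: float
    mutation_rate: float

    def __post_init__(self):
        if self.split_time <= 0 or self.ancestral_size <= 0:
            raise ValueError("split_time and ancestral_size must be positive")
        for pop in self.populations:
            cover = sorted((seg.t0, seg.t1) for seg in pop.segments)
            if not cover or cover[0][0] != 0:
                raise ValueError(f"{pop.name}: trajectory must start at 0")
            end = cover[0][1]
            for t0, t1 in cover[1:]:
                if t0 != end:
                    raise ValueError(f"{pop.name}: trajectory has a gap at {t0}")
                end = t1
            if end < self.split_time:
                raise ValueError(f"{pop.name}: trajectory must cover [0, split_time]")

    @property
    def population_names(self):
        return [p.name for p in self.populations]

    def population(self, name: str) -> Population:
        for p in self.populations:
            if p.name == name:
                return p
        raise KeyError(name)

    def size_at(self, pop_name: str, t: float) -> float:
        """Diploid size of the lineage-bearing population at backward time t."""
        if t >= self.split_time:
            return self.ancestral_size
        return self.population(pop_name).size_at(t)


def build_demography(model_id: int) -> Demography:
    """Demography models 1-3 (ancestral size 1e6, 1e5, 1e4 diploids)."""
    if model_id not in ANCESTRAL_SIZES:
        raise ValueError(f"unknown demography model {model_id!r}; choose 1, 2 or 3")
    T = SPLIT_TIME
    pops = (
        Population("pop1", (SizeSegment(0.0, T, 10_000.0, 10_000.0),)),
        # sizes at the recent edge are present-day; 10-fold change over the
        # 10,000 generations since the split (10,000 diploids at the split)
        Population("pop2", (SizeSegment(0.0, T, 100_000.0, 10_000.0),)),
        Population("pop3", (SizeSegment(0.0, T, 1_000.0, 10_000.0),)),
    )
    return Demography(
        populations=pops,
        split_time=T,
        ancestral_size=ANCESTRAL_SIZES[model_id],
        mutation_rate=MUTATION_RATE,
    )


def rescale_params(demography: Demography, recmap: RecombinationMap, mu: float, Q: int):
    """Rescale parameters for forward simulation by a factor ``Q``.

    Sizes and times are divided by ``Q``, the mutation rate multiplied by
    ``Q``, and each recombination rate ``r`` mapped to
    ``(1 - (1 - 2r)**Q) / 2`` (the probability of an odd number of
    crossovers in ``Q`` generations).
    """
    if not (isinstance(Q, (int, np.integer)) and Q > 0):
        raise ValueError("Q must be a positive integer")
    if np.any(recmap.rates >= 0.5):
        raise ValueError("recombination rates must be < 0.5 to rescale")
    new_pops = tuple(
        Population(
            p.name,
            tuple(
                SizeSegment(s.t0 / Q, s.t1 / Q, s.n0 / Q, s.n1 / Q) for s in p.segments
            ),
        )
        for p in demography.populations
    )
    new_demog = Demography(
        populations=new_pops,
        split_time=demography.split_time / Q,
        ancestral_size=demography.ancestral_size / Q,
        mutation_rate=demography.mutation_rate * Q,
    )
    new_rates = 0.5 * (1.0 - (1.0 - 2.0 * recmap.rates) ** Q)
    new_map = RecombinationMap(recmap.chrom_length, recmap.breakpoints.copy(), new_rates)
    return new_demog, new_map, mu * Q


# ---------------------------------------------------------------------------
# DFE
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DfeConfig:
    """Four-class DFE with uniform selection coefficients per class.

    Class ``i`` draws ``s`` uniformly on ``[lower_i/(2*n_anc),
    upper_i/(2*n_anc))`` with (lower, upper) bounds (0,1), (1,10),
    (10,100); class 3 spans ``[100/(2*n_anc), 1]``.
    """

    fractions: tuple
    n_anc: float

    def __post_init__(self):
        frac = tuple(float(f) for f in self.fractions)
        object.__setattr__(self, "fractions", frac)
        if len(frac) != 4:
            raise ValueError("need exactly four class fractions")
        if any(f < 0 for f in frac):
            raise ValueError("fractions must be non-negative")
        if abs(sum(frac) - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")
        if self.n_anc <= 0:
            raise ValueError("n_anc must be positive")
        if frac[3] > 0 and 100.0 / (2.0 * self.n_anc) > 1.0:
            raise ValueError("class-3 interval empty: need n_anc >= 50 when f3 > 0")

    def class_bounds(self, i: int):
        two_n = 2.0 * self.n_anc
        lo = [0.0, 1.0 / two_n, 10.0 / two_n, 100.0 / two_n][i]
        hi = [1.0 / two_n, 10.0 / two_n, 100.0 / two_n, 1.0][i]
        return lo, hi


def sample_dfe(config: DfeConfig, n: int, seed) -> np.ndarray:
    """Draw ``n`` selection coefficients from the four-class DFE.

    Returns a ``(n, 2)`` array of (class index, coefficient).
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed)
    classes = rng.choice(4, size=n, p=np.asarray(config.fractions))
    out = np.empty((n, 2), dtype=float)
    out[:, 0] = classes
    u = rng.random(n)
    for i in range(4):
        lo, hi = config.class_bounds(i)
        sel = classes == i
        out[sel, 1] = lo + u[sel] * (hi - lo)
    return out


# ---------------------------------------------------------------------------
# Gene annotation
# ---------------------------------------------------------------------------

EXON_LENGTH = 357
INTRON_LENGTH = 1_558
EXONS_PER_GENE = 12
GENE_SPAN = EXONS_PER_GENE * EXON_LENGTH + (EXONS_PER_GENE - 1) * INTRON_LENGTH


@dataclass(frozen=True)
class GeneAnnotation:
    """Non-overlapping gene spans with exon sub-intervals (0-based half-open)."""

    chrom_length: float
    genes: tuple  # tuple of (gene_start, gene_end, tuple of exon (start, end))

    def exon_intervals(self) -> np.ndarray:
        out = []
        for _, _, exons in self.genes:
            out.extend(exons)
        return np.asarray(out, dtype=float)

    def to_bed(self, chrom: str = "chr1") -> pd.DataFrame:
        ex = self.exon_intervals()
        return pd.DataFrame({"chrom": chrom, "start": ex[:, 0].astype(int), "end": ex[:, 1].astype(int)})

    def to_gff_frame(self, chrom: str = "chr1") -> pd.DataFrame:
        rows = []
        for gi, (gs, ge, exons) in enumerate(self.genes):
            rows.append((chrom, "gene", int(gs), int(ge), f"gene_{gi}"))
            for ei, (es, ee) in enumerate(exons):
                rows.append((chrom, "exon", int(es), int(ee), f"gene_{gi}.exon_{ei}"))
        return pd.DataFrame(rows, columns=["chrom", "feature", "start", "end", "name"])


def make_gene_annotation(chrom_length: float, n_genes: int = 250) -> GeneAnnotation:
    """Evenly place ``n_genes`` genes of 12 x 357 bp exons / 1,558 bp introns."""
    chrom_length = float(chrom_length)
    if n_genes * GENE_SPAN > chrom_length:
        raise ValueError(f"{n_genes} genes of {GENE_SPAN} bp do not fit in {chrom_length:.0f} bp")
    slack = chrom_length - n_genes * GENE_SPAN
    gap = slack / n_genes
    genes = []
    for i in range(n_genes):
        gs = int(round(i * (GENE_SPAN + gap) + gap / 2.0))
        exons = []
        pos = gs
        for _ in range(EXONS_PER_GENE):
            exons.append((pos, pos + EXON_LENGTH))
            pos += EXON_LENGTH + INTRON_LENGTH
        ge = exons[-1][1]
        genes.append((gs, ge, tuple(exons)))
    return GeneAnnotation(chrom_length=chrom_length, genes=tuple(genes))
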