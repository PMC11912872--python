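"""Demography summaries: Ne skylines, rCCR, split brackets, concordance, SFS.

Converts fitted coalescence-rate profiles into the quantities a
demography study reports: effective-population-size skylines (the inverse
of twice the pairwise coalescence rate), relative cross-coalescence rate
between population pairs, the epoch bracket where rCCR crosses one half
(a split-time estimate), rank concordance between true and inferred TMRCA
tracks, Watterson's theta, and the unfolded site frequency spectrum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .coalsim import TmrcaTrack, VariantTable
from .smc import TimeGrid

__all__ = [
    "CoalescenceRateProfile",
    "SkylineEstimate",
    "SfsTable",
    "SplitBracket",
    "skyline_from_rates",
    "rccr",
    "split_time_from_rccr",
    "tmrca_concordance",
    "watterson_theta",
    "unfolded_sfs",
]


@dataclass(frozen=True)
class CoalescenceRateProfile:
    """Per-epoch pairwise coalescence rates (per generation) on a TimeGrid."""

    grid: TimeGrid
    rates: np.ndarray
    label: str = ""

    def __post_init__(self):
        r = np.asarray(self.rates, dtype=float)
        object.__setattr__(self, "rates", r)
        if len(r) != self.grid.n_epochs:
            raise ValueError("rates length must match grid epochs")
        if np.any(r <= 0):
            raise ValueError("rates must be positive")

    def to_dataframe(self) -> pd.DataFrame:
        T = self.grid.boundaries
        return pd.DataFrame(
            {
                "epoch_start_gen": T[:-1],
                "epoch_end_gen": T[1:],
                "lambda_per_gen": self.rates,
                "ne_diploid": 1.0 / (2.0 * self.rates),
            }
        )


@dataclass(frozen=True)
class SkylineEstimate:
    """Piecewise-constant diploid Ne over contiguous epochs."""

    starts: np.ndarray
    ends: np.ndarray
    ne: np.ndarray
    label: str = ""

    def __post_init__(self):
        for name in ("starts", "ends", "ne"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if not (len(self.starts) == len(self.ends) == len(self.ne)):
            raise ValueError("length mismatch")
        if np.any(self.ne <= 0):
            raise ValueError("ne must be positive")
        if np.any(self.starts[1:] != self.ends[:-1]):
            raise ValueError("epochs must be contiguous")

    def ne_at(self, t: float) -> float:
        idx = np.searchsorted(self.ends, t, side="right")
        if idx >= len(self.ne):
            return float(self.ne[-1])
        return float(self.ne[idx])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"epoch_start": self.starts, "epoch_end": self.ends, "ne": self.ne}
        )


@dataclass(frozen=True)
class SfsTable:
    """Unfolded SFS: counts of sites with derived-allele count 1..n-1."""

    n_haplotypes: int
    counts: np.ndarray
    called_length: float
    n_fixed_ancestral: int = 0
    n_fixed_derived: int = 0

    def __post_init__(self):
        c = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "counts", c)
        if len(c) != self.n_haplotypes - 1:
            raise ValueError("counts must have length n_haplotypes - 1")
        if np.any(c < 0):
            raise ValueError("counts must be non-negative")

    @property
    def n_segregating(self) -> int:
        return int(self.counts.sum())

    def to_line(self) -> str:
        """One-line whitespace-separated count format (bins 1..n-1)."""
        return " ".join(str(int(c)) for c in self.counts)


@dataclass(frozen=True)
class SplitBracket:
    """rCCR threshold-crossing bracket between two consecutive epochs.

    ``status`` is "ok", "no_split" (rCCR never below threshold) or
    "older_than_grid" (rCCR below threshold everywhere).
    """

    status: str
    lower_gen: float = np.nan
    upper_gen: float = np.nan

    @property
    def midpoint(self) -> float:
        """Geometric midpoint of the bracket (generations)."""
        return float(np.sqrt(self.lower_gen * self.upper_gen))

    def contains(self, t: float) -> bool:
        return bool(self.status == "ok" and self.lower_gen <= t <= self.upper_gen)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def skyline_from_rates(profile: CoalescenceRateProfile, mu: float | None = None) -> SkylineEstimate:
    """Diploid Ne skyline as ``1 / (2 c)`` for per-generation rates ``c``.

    Rates in this package are always per generation, so ``mu`` is not used
    in the conversion; it is accepted for interface symmetry with scaled
    workflows and must match the profile's convention when given.
    """
    if np.any(profile.rates <= 0):
        raise ValueError("rates must be positive")
    T = profile.grid.boundaries
    return SkylineEstimate(
        starts=T[:-1], ends=T[1:], ne=1.0 / (2.0 * profile.rates), label=profile.label
    )


def rccr(lambda_ab: CoalescenceRateProfile, lambda_aa: CoalescenceRateProfile,
         lambda_bb: CoalescenceRateProfile) -> np.ndarray:
    """Relative cross-coalescence rate per epoch (not clipped to [0, 1])."""
    if not (
        np.array_equal(lambda_ab.grid.boundaries, lambda_aa.grid.boundaries)
        and np.array_equal(lambda_ab.grid.boundaries, lambda_bb.grid.boundaries)
    ):
        raise ValueError("profiles must share one time grid")
    return lambda_ab.rates / (0.5 * (lambda_aa.rates + lambda_bb.rates))


def split_time_from_rccr(rccr_values, grid: TimeGrid, threshold: float = 0.5) -> SplitBracket:
    """Bracket of the epoch pair straddling the rCCR threshold crossing.

    Scanning from the oldest epoch toward the present, the first epoch with
    rCCR below the threshold and its older neighbor form the bracket
    (start of the more recent epoch, end of the older epoch).
    """
    r = np.asarray(rccr_values, dtype=float)
    if len(r) != grid.n_epochs:
        raise ValueError("rccr length must match grid epochs")
    below = r < threshold
    if not np.any(below):
        return SplitBracket("no_split")
    if np.all(below):
        return SplitBracket("older_than_grid")
    e = int(np.flatnonzero(below)[-1])  # first below-threshold epoch, old -> recent
    if e == grid.n_epochs - 1:
        # the oldest epoch itself is below threshold while younger epochs
        # are not: there is no older neighbor to bracket with
        warnings.warn("rCCR below threshold in the oldest epoch; no bracket")
        return SplitBracket("older_than_grid")
    crossings = np.flatnonzero(np.diff(below.astype(int)) != 0)
    if len(crossings) > 1:
        warnings.warn(f"multiple rCCR threshold crossings at epochs {list(crossings)}")
    T = grid.boundaries
    return SplitBracket("ok", lower_gen=float(T[e]), upper_gen=float(T[e + 2]))


def tmrca_concordance(true_track: TmrcaTrack, inferred_track: TmrcaTrack,
                      length_weighted: bool = False) -> float:
    """Spearman rank correlation between two TMRCA tracks.

    The two interval sets are intersected; every intersected range is one
    observation (unweighted by default), and ties receive average ranks.
    """
    edges = np.unique(
        np.concatenate(
            [true_track.starts, true_track.ends, inferred_track.starts, inferred_track.ends]
        )
    )
    a_vals, b_vals, weights = [], [], []
    for s, e in zip(edges[:-1], edges[1:]):
        mid = 0.5 * (s + e)
        ia = np.searchsorted(true_track.ends, mid, side="right")
        ib = np.searchsorted(inferred_track.ends, mid, side="right")
        if ia >= len(true_track) or ib >= len(inferred_track):
            continue
        if true_track.starts[ia] > mid or inferred_track.starts[ib] > mid:
            continue
        a_vals.append(true_track.values[ia])
        b_vals.append(inferred_track.values[ib])
        weights.append(e - s)
    if not a_vals:
        raise ValueError("tracks do not overlap")
    a = np.asarray(a_vals)
    b = np.asarray(b_vals)
    if length_weighted:
        # replicate units proportionally to length (resolution: min length)
        w = np.asarray(weights)
        reps = np.maximum(1, np.round(w / w.min()).astype(int))
        a = np.repeat(a, reps)
        b = np.repeat(b, reps)
    with warnings.catch_warnings():
        # a constant track yields an undefined coefficient; surface the nan
        warnings.simplefilter("ignore")
        rho = spearmanr(a, b).statistic
    return float(rho)


def watterson_theta(S: int, n_hap: int, called_length: float) -> float:
    """Watterson's per-site theta, ``S / (a_n * L)``."""
    if n_hap < 2:
        raise ValueError("need at least two haplotypes")
    if called_length <= 0:
        raise ValueError("called_length must be positive")
    if S < 0:
        raise ValueError("S must be non-negative")
    a = np.sum(1.0 / np.arange(1, n_hap))
    return float(S / (a * called_length))


def unfolded_sfs(variants: VariantTable, population: str | None = None,
                 called_length: float | None = None) -> SfsTable:
    """Unfolded SFS of derived-allele counts within one population.

    Sites fixed ancestral or fixed derived within the population are
    excluded from the spectrum bins and reported separately.
    """
    if population is None:
        haps = np.arange(variants.n_haplotypes)
    else:
        haps = variants.samples_of(population)
    n = len(haps)
    if n < 1:
        raise ValueError(f"no haplotypes in population {population!r}")
    anc = np.asarray(variants.ancestral)
    if variants.n_sites and (np.any(anc == "") or np.any(anc == "N")):
        raise ValueError("unpolarized site encountered (missing ancestral allele)")
    counts = variants.derived_counts(haps)
    seg = (counts > 0) & (counts < n)
    hist = np.bincount(counts[seg], minlength=n)[1:n] if n > 1 else np.zeros(0, dtype=int)
    return SfsTable(
        n_haplotypes=n,
        counts=hist,
        called_length=called_length if called_length is not None else variants.chrom_length,
        n_fixed_ancestral=int(np.sum(counts == 0)),
        n_fixed_derived=int(np.sum(counts == n)),
    )
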