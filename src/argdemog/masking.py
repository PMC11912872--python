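"""Genome masks and ancestral-allele polarization.

Masks are sets of 0-based half-open intervals (BED semantics). The module
builds the study's scenario masks (control vs high-recombining), derives
high-recombining masks from a recombination map by thresholding r/mu,
splits a genome into low- and high-recombining halves of equal callable
length, applies masks to variant tables, and polarizes biallelic SNPs with
a five-category two-outgroup heuristic.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import intervals as iv
from .coalsim import VariantTable
from .scenarios import RecombinationMap

__all__ = [
    "MaskSet",
    "PolarizedSite",
    "scenario_masks",
    "classify_high_recombining",
    "split_genome_halves",
    "apply_mask",
    "polarize",
]


@dataclass(frozen=True)
class MaskSet:
    """Normalized genomic intervals (single chromosome, 0-based half-open)."""

    intervals: np.ndarray
    label: str = ""
    chrom: str = "chr1"

    def __post_init__(self):
        arr = iv.normalize(self.intervals) if np.size(self.intervals) else iv.as_array([])
        object.__setattr__(self, "intervals", arr)

    def __len__(self) -> int:
        return len(self.intervals)

    @property
    def total_length(self) -> float:
        return iv.total_length(self.intervals)

    def union(self, other: "MaskSet") -> "MaskSet":
        return MaskSet(iv.merge(self.intervals, other.intervals), self.label, self.chrom)

    def intersection(self, other: "MaskSet") -> "MaskSet":
        return MaskSet(iv.intersect(self.intervals, other.intervals), self.label, self.chrom)

    def complement(self, chrom_length: float) -> "MaskSet":
        return MaskSet(iv.complement(self.intervals, 0.0, chrom_length),
                       f"complement({self.label})", self.chrom)

    def contains(self, positions) -> np.ndarray:
        """Boolean membership for 0-based positions."""
        pos = np.asarray(positions, dtype=float)
        if len(self.intervals) == 0:
            return np.zeros(pos.shape, dtype=bool)
        idx = np.searchsorted(self.intervals[:, 0], pos, side="right") - 1
        ok = idx >= 0
        out = np.zeros(pos.shape, dtype=bool)
        out[ok] = pos[ok] < self.intervals[np.clip(idx[ok], 0, None), 1]
        return out

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chrom,
                "start": self.intervals[:, 0].astype(np.int64),
                "end": self.intervals[:, 1].astype(np.int64),
            }
        )


@dataclass(frozen=True)
class PolarizedSite:
    """One SNP with its inferred ancestral state and heuristic category."""

    position: int
    ancestral: str
    derived: str
    category: int  # 1..5
    kept: bool = True

    def __post_init__(self):
        if self.kept and self.category not in (1, 2, 3, 4, 5):
            raise ValueError("kept sites must have category 1-5")


# scenario mask coordinates (Mb -> bp), by (map family, mode)
_SCENARIO_MASKS = {
    ("stepwise", "control"): [(3e6, 6e6), (13e6, 16e6)],
    ("stepwise", "highrec"): [(0.0, 3e6), (13e6, 16e6)],
    ("narrow", "control"): [(10e6, 11e6)],
    ("narrow", "highrec"): [(4.5e6, 5.5e6)],
}


def scenario_masks(scenario: str, mode: str, scale: float = 1.0) -> MaskSet:
    """Mask coordinates for the stepwise/narrow scenarios.

    ``mode="highrec"`` masks the elevated-recombination regions,
    ``mode="control"`` masks the same total length away from them.
    ``scale`` shrinks coordinates proportionally for reduced-size runs.
    """
    key = (scenario, mode)
    if key not in _SCENARIO_MASKS:
        raise ValueError(f"unknown scenario/mode {key!r}")
    arr = iv.as_array(_SCENARIO_MASKS[key]) * scale
    return MaskSet(arr, label=f"{scenario}-{mode}")


def classify_high_recombining(recmap: RecombinationMap, mu: float,
                              threshold: float = 1.0) -> MaskSet:
    """Merged intervals of the map where ``rate / mu >= threshold``."""
    if mu <= 0:
        raise ValueError("mu must be positive")
    sel = recmap.rates / mu >= threshold
    spans = [
        (recmap.breakpoints[i], recmap.breakpoints[i + 1])
        for i in np.flatnonzero(sel)
    ]
    return MaskSet(iv.as_array(spans) if spans else np.empty((0, 2)), label="highrec")


def split_genome_halves(windows, callability: MaskSet):
    """Split windowed rates into low- and high-recombining halves.

    ``windows`` is an iterable of ((start, end), rate). Windows are
    intersected with the callable mask, sorted ascending by rate (ties by
    start coordinate), and assigned to the low half until its cumulative
    callable length first reaches half the total; the remainder forms the
    high half. Returns ``(low MaskSet, high MaskSet)``.
    """
    rows = []
    spans = []
    for (s, e), rate in windows:
        if e <= s:
            raise ValueError("windows must have positive length")
        spans.append((float(s), float(e)))
        callable_part = iv.intersect([(s, e)], callability.intervals)
        clen = iv.total_length(callable_part)
        if clen > 0:
            rows.append((float(rate), float(s), callable_part, clen))
    spans.sort()
    for (s0, e0), (s1, _) in zip(spans[:-1], spans[1:]):
        if s1 < e0:
            raise ValueError("windows must be non-overlapping")
    if not rows:
        raise ValueError("no callable windows")
    rows.sort(key=lambda r: (r[0], r[1]))
    total = sum(r[3] for r in rows)
    low, high = [], []
    cum = 0.0
    for rate, s, part, clen in rows:
        if cum < total / 2.0:
            low.append(part)
            cum += clen
        else:
            high.append(part)
    low_arr = np.vstack(low) if low else np.empty((0, 2))
    high_arr = np.vstack(high) if high else np.empty((0, 2))
    return MaskSet(low_arr, "low-recombining"), MaskSet(high_arr, "high-recombining")


def apply_mask(variants: VariantTable, mask: MaskSet, chrom_length: float,
               callability: MaskSet | None = None):
    """Remove variants inside the mask; return (table, called_length).

    ``called_length`` is the chromosome length minus the masked length,
    intersected with the callability mask when one is given.
    """
    keep = ~mask.contains(variants.positions)
    callable_iv = iv.complement(mask.intervals, 0.0, chrom_length)
    if callability is not None:
        callable_iv = iv.intersect(callable_iv, callability.intervals)
        keep &= callability.contains(variants.positions)
    return variants.subset_sites(keep), iv.total_length(callable_iv)


# ---------------------------------------------------------------------------
# Polarization
# ---------------------------------------------------------------------------


def _allele_counts(obs) -> Counter:
    return Counter(a for a in obs if a not in (None, "", ".", "N"))


def polarize(focal_obs, outgroup1_obs, outgroup2_obs, positions=None) -> list:
    """Polarize sites using allele patterns in two outgroup species.

    Each ``*_obs`` argument is a per-site list of allele observations
    (strings; None/"."/"N" mark missing calls). ``outgroup1`` is the
    closer outgroup. Sites with more than two alleles across the three
    species are dropped. Categories:

    1. outgroup1 all missing -> focal major allele ancestral
    2. outgroup1 fixed -> outgroup1 allele ancestral
    3. outgroup1 segregating, outgroup2 all missing -> focal major ancestral
    4. both outgroups segregating -> focal major ancestral
    5. outgroup1 segregating, outgroup2 fixed -> outgroup2 allele ancestral
    """
    n = len(focal_obs)
    if len(outgroup1_obs) != n or len(outgroup2_obs) != n:
        raise ValueError("per-site observation lists must have equal length")
    if positions is None:
        positions = range(n)
    out = []
    for pos, foc, o1, o2 in zip(positions, focal_obs, outgroup1_obs, outgroup2_obs):
        fc = _allele_counts(foc)
        if len(fc) == 0:
            raise ValueError(f"no focal observations at site {pos}")
        c1 = _allele_counts(o1)
        c2 = _allele_counts(o2)
        alleles = set(fc) | set(c1) | set(c2)
        if len(alleles) > 2:
            out.append(PolarizedSite(int(pos), "", "", 0, kept=False))
            continue
        # focal major allele; exact ties fall back to first-listed allele
        ranked = fc.most_common()
        if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
            warnings.warn(f"major-allele tie at site {pos}; using first-listed allele")
            major = next(a for a in foc if a in fc)
        else:
            major = ranked[0][0]
        others = [a for a in sorted(alleles) if a != major]
        minor = others[0] if others else major

        if len(c1) == 0:
            cat, anc = 1, major
        elif len(c1) == 1:
            cat, anc = 2, next(iter(c1))
        else:  # outgroup1 segregating
            if len(c2) == 0:
                cat, anc = 3, major
            elif len(c2) >= 2:
                cat, anc = 4, major
            else:
                cat, anc = 5, next(iter(c2))
        der_pool = [a for a in sorted(alleles) if a != anc]
        der = der_pool[0] if der_pool else minor
        out.append(PolarizedSite(int(pos), anc, der, cat, kept=True))
    return out
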