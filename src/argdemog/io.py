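"""File formats: VCF, BED, multihetsep, recombination-map TSV, manifests.

Interval files are 0-based half-open (BED); VCF positions are 1-based.
Haploid samples are paired into synthetic diploids in sample order
(haplotypes 2i and 2i+1 form individual i), and VCF sample names encode
the population as ``<pop>_<index>`` so that population assignments
round-trip. The ancestral allele travels in the INFO ``AA`` field.

The multihetsep format is tab-separated ``chrom, 1-based position, number
of callable sites since the previous emitted variant (inclusive of the
current position), concatenated per-haplotype alleles``; there is no
header. A variant inside a masked region is neither emitted nor counted
as callable.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import intervals as iv
from .coalsim import VariantTable
from .masking import MaskSet
from .scenarios import (Demography, Population, RecombinationMap, SizeSegment,
                        build_demography)
from .smc import ObservationSequence

__all__ = [
    "read_vcf",
    "write_vcf",
    "read_bed",
    "write_bed",
    "write_multihetsep",
    "read_multihetsep",
    "observations_from_multihetsep",
    "read_recmap_tsv",
    "write_recmap_tsv",
    "read_hapmap_map",
    "read_demography_config",
    "write_demography_config",
    "RunManifest",
]


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def write_vcf(variants: VariantTable, path, chrom: str = "chr1"):
    """Write phased haplotypes as a VCF 4.2 text file."""
    n_hap = variants.n_haplotypes
    if n_hap % 2 != 0:
        raise ValueError("haplotype count must be even to pair into diploids")
    names = []
    pop_codes = np.asarray(variants.sample_populations)
    counters: dict = {}
    for d in range(n_hap // 2):
        pop = variants.population_names[int(pop_codes[2 * d])]
        k = counters.get(pop, 0)
        counters[pop] = k + 1
        names.append(f"{pop}_{k}")
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={chrom},length={int(variants.chrom_length)}>\n")
        fh.write('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(names) + "\n")
        anc = np.asarray(variants.ancestral)
        der = np.asarray(variants.derived)
        for i in range(variants.n_sites):
            g = variants.genotypes[i]
            gts = "\t".join(f"{g[2*d]}|{g[2*d+1]}" for d in range(n_hap // 2))
            fh.write(
                f"{chrom}\t{variants.positions[i] + 1}\t.\t{anc[i]}\t{der[i]}\t.\tPASS\t"
                f"AA={anc[i]}\tGT\t{gts}\n"
            )


def read_vcf(path, require_phased: bool = True) -> VariantTable:
    """Read biallelic SNPs from a VCF into a VariantTable.

    Multi-allelic records are skipped (a count is reported via the
    returned table's ``attrs``-like companion; see the returned object).
    Unphased genotypes raise an error naming the sample when
    ``require_phased`` is true.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    pops = []
    for s in samples:
        pops.append(s.rsplit("_", 1)[0] if "_" in s else "pop1")
    pop_names = list(dict.fromkeys(pops))
    hap_pops = np.asarray(
        [pop_names.index(p) for p in pops for _ in range(2)], dtype=np.int8
    )
    chrom_length = 0.0
    for line in vcf.raw_header.splitlines():
        if line.startswith("##contig"):
            for tok in line.strip("<>\n").split(","):
                if tok.startswith("length="):
                    chrom_length = float(tok.split("=")[1].rstrip(">"))
    positions, anc, der, rows = [], [], [], []
    n_multiallelic = 0
    for v in vcf:
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            n_multiallelic += 1
            continue
        gts = v.genotypes  # [a0, a1, phased]
        row = np.empty(2 * len(samples), dtype=np.uint8)
        for si, g in enumerate(gts):
            if require_phased and not g[2]:
                raise ValueError(f"unphased genotype for sample {samples[si]} at POS {v.POS}")
            row[2 * si] = g[0]
            row[2 * si + 1] = g[1]
        aa = v.INFO.get("AA")
        ref, alt = v.REF, v.ALT[0]
        if aa is not None and aa == alt:
            # polarize so 0 means ancestral
            row = (1 - row).astype(np.uint8)
            anc.append(alt)
            der.append(ref)
        else:
            anc.append(aa if aa is not None else ref)
            der.append(alt)
        positions.append(v.POS - 1)
        rows.append(row)
    geno = np.asarray(rows, dtype=np.uint8) if rows else np.empty((0, 2 * len(samples)), np.uint8)
    table = VariantTable(
        positions=np.asarray(positions, dtype=np.int64),
        ancestral=np.asarray(anc, dtype="<U1"),
        derived=np.asarray(der, dtype="<U1"),
        genotypes=geno,
        sample_populations=hap_pops,
        population_names=pop_names,
        chrom_length=chrom_length if chrom_length else (positions[-1] + 1 if positions else 0),
    )
    table.n_multiallelic_skipped = n_multiallelic
    return table


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------


def read_bed(path, label: str = "") -> MaskSet:
    """Read a 3+ column BED file into a normalized MaskSet."""
    rows = []
    chrom = "chr1"
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise ValueError(f"{path}: line {ln}: need at least 3 columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}: line {ln}: non-integer coordinates") from exc
            if start >= end:
                raise ValueError(f"{path}: line {ln}: start >= end")
            chrom = parts[0]
            rows.append((start, end))
    return MaskSet(iv.as_array(rows) if rows else np.empty((0, 2)), label=label, chrom=chrom)


def write_bed(mask: MaskSet, path):
    mask.to_dataframe().to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# multihetsep
# ---------------------------------------------------------------------------


def _callable_cum(mask: MaskSet, chrom_length: int) -> tuple:
    """Masked-position count helper: cum masked bp at or before 0-based pos."""
    if len(mask) == 0:
        starts = np.empty(0)
        ends = np.empty(0)
    else:
        arr = mask.intervals
        starts, ends = arr[:, 0], arr[:, 1]
    cum = np.concatenate([[0.0], np.cumsum(ends - starts)])

    def masked_upto(pos0):  # positions <= pos0 that are masked
        i = np.searchsorted(starts, pos0, side="right")
        out = cum[i]
        if i > 0 and pos0 < ends[i - 1]:
            out -= ends[i - 1] - (pos0 + 1)
        return out

    return masked_upto


def write_multihetsep(variants: VariantTable, mask: MaskSet | None, path,
                      chrom: str = "chr1", haplotypes=None):
    """Write variants as a multihetsep file, honoring a mask."""
    if mask is None:
        mask = MaskSet(np.empty((0, 2)))
    haps = np.arange(variants.n_haplotypes) if haplotypes is None else np.asarray(haplotypes)
    masked_upto = _callable_cum(mask, int(variants.chrom_length))
    keep = ~mask.contains(variants.positions)
    anc = np.asarray(variants.ancestral)
    der = np.asarray(variants.derived)
    prev_callable = 0.0
    with open(path, "w") as fh:
        for i in np.flatnonzero(keep):
            pos0 = int(variants.positions[i])
            callable_here = (pos0 + 1) - masked_upto(pos0)
            n_called = int(callable_here - prev_callable)
            prev_callable = callable_here
            alleles = "".join(
                der[i] if variants.genotypes[i, h] else anc[i] for h in haps
            )
            fh.write(f"{chrom}\t{pos0 + 1}\t{n_called}\t{alleles}\n")


def read_multihetsep(path) -> pd.DataFrame:
    """Read a multihetsep file (chrom, pos [1-based], n_called, alleles)."""
    return pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "pos", "n_called", "alleles"],
        dtype={"chrom": str, "pos": np.int64, "n_called": np.int64, "alleles": str},
    )


def observations_from_multihetsep(path, hap_a: int, hap_b: int, chrom_length: int,
                                  bin_width: int = 100) -> ObservationSequence:
    """Binned observation sequence for one haplotype pair of a multihetsep file.

    Callable sites are distributed into the bins containing the emitted
    variants' inter-variant spans; this reconstructs the same per-bin
    called counts as the VCF+mask route up to span-boundary rounding.
    """
    df = read_multihetsep(path)
    n_bins = int(np.ceil(chrom_length / bin_width))
    called = np.zeros(n_bins, dtype=np.int64)
    het = np.zeros(n_bins, dtype=np.int64)
    prev0 = -1
    for pos, n_called, alleles in zip(df["pos"], df["n_called"], df["alleles"]):
        pos0 = pos - 1
        # spread callable count uniformly over the span it covers
        span_start = max(prev0 + 1, pos0 - n_called + 1)
        span = np.arange(span_start, pos0 + 1)
        if len(span):
            add = np.bincount(span // bin_width, minlength=n_bins)[:n_bins]
            # rescale to the reported callable count
            called += (add * (n_called / max(len(span), 1))).astype(np.int64)
        if alleles[hap_a] != alleles[hap_b]:
            het[pos0 // bin_width] += 1
        prev0 = pos0
    called = np.minimum(np.maximum(called, het), bin_width)
    return ObservationSequence(called, het, bin_width, pair=(hap_a, hap_b))


# ---------------------------------------------------------------------------
# Recombination maps
# ---------------------------------------------------------------------------


def write_recmap_tsv(recmap: RecombinationMap, path, chrom: str = "chr1"):
    recmap.to_dataframe(chrom).to_csv(path, sep="\t", index=False)


def read_recmap_tsv(path) -> RecombinationMap:
    df = pd.read_csv(path, sep="\t")
    need = {"start", "end", "rate_per_bp_per_gen"}
    if not need.issubset(df.columns):
        raise ValueError(f"recombination map TSV needs columns {sorted(need)}")
    df = df.sort_values("start")
    starts = df["start"].to_numpy(dtype=float)
    ends = df["end"].to_numpy(dtype=float)
    if starts[0] != 0 or np.any(starts[1:] != ends[:-1]):
        raise ValueError("map intervals must tile the chromosome from 0")
    return RecombinationMap(
        chrom_length=float(ends[-1]),
        breakpoints=np.concatenate([starts, ends[-1:]]),
        rates=df["rate_per_bp_per_gen"].to_numpy(dtype=float),
    )


def read_hapmap_map(path, chrom_length: float | None = None) -> RecombinationMap:
    """Read a HapMap-style map (chrom, position, rate in cM/Mb, [cM]).

    The cM/Mb column applies from each position to the next;
    1 cM/Mb = 1e-8 crossovers per bp per generation.
    """
    df = pd.read_csv(path, sep=r"\s+")
    pos_col = df.columns[1]
    rate_col = df.columns[2]
    pos = df[pos_col].to_numpy(dtype=float)
    cmmb = df[rate_col].to_numpy(dtype=float)
    if np.any(np.diff(pos) <= 0):
        raise ValueError("positions must be strictly increasing")
    L = float(chrom_length) if chrom_length is not None else float(pos[-1])
    bp = [0.0]
    rates = []
    if pos[0] > 0:
        rates.append(cmmb[0] * 1e-8)
        bp.append(pos[0])
    for i in range(len(pos) - 1):
        rates.append(cmmb[i] * 1e-8)
        bp.append(pos[i + 1])
    if bp[-1] < L:
        rates.append(cmmb[-1] * 1e-8)
        bp.append(L)
    return RecombinationMap(chrom_length=L, breakpoints=np.asarray(bp), rates=np.asarray(rates))


# ---------------------------------------------------------------------------
# Demography config
# ---------------------------------------------------------------------------


def write_demography_config(demog: Demography, path):
    doc = {
        "split_time": demog.split_time,
        "ancestral_size": demog.ancestral_size,
        "mutation_rate": demog.mutation_rate,
        "populations": [
            {
                "name": p.name,
                "segments": [
                    {"t0": s.t0, "t1": s.t1, "n0": s.n0, "n1": s.n1} for s in p.segments
                ],
            }
            for p in demog.populations
        ],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_demography_config(path) -> Demography:
    doc = yaml.safe_load(Path(path).read_text())
    if "model_id" in doc:
        return build_demography(int(doc["model_id"]))
    pops = tuple(
        Population(
            p["name"],
            tuple(SizeSegment(s["t0"], s["t1"], s["n0"], s["n1"]) for s in p["segments"]),
        )
        for p in doc["populations"]
    )
    return Demography(
        populations=pops,
        split_time=float(doc["split_time"]),
        ancestral_size=float(doc["ancestral_size"]),
        mutation_rate=float(doc.get("mutation_rate", 4.6e-9)),
    )


# ---------------------------------------------------------------------------
# Run manifest
# ---------------------------------------------------------------------------


def _digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record: config, master seed, derived seeds, digests."""

    command: str
    master_seed: int
    config: dict = field(default_factory=dict)
    derived_seeds: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    tool_version: str = ""
    timestamp: str = ""

    def __post_init__(self):
        if not self.tool_version:
            from . import __version__

            self.tool_version = __version__
        if not self.timestamp:
            self.timestamp = time.strftime("%Y-%m-%dT%H:%M:%S")

    def record_output(self, name, path):
        self.outputs[name] = {"path": str(path), "sha256": _digest(path)}

    def write(self, path):
        Path(path).write_text(json.dumps(self.__dict__, indent=2, default=str))

    @classmethod
    def read(cls, path) -> "RunManifest":
        doc = json.loads(Path(path).read_text())
        return cls(**doc)
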