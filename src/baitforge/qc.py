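"""Capture-evaluation metrics from alignments and a target list.

Covers the read-level quality filters, on-/off-target base accounting,
base-by-base depth profiles around target SNPs, coverage-uniformity
fractions on the normalized per-target depth distribution, the GC-vs-depth
relation across capture regions, and cross-run SNP concordance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .formats import AlignedRead, IntervalSet, ReferenceGenome

# Read-filter rejection reasons.
N_FRACTION = "N_FRACTION"
LOW_QUALITY = "LOW_QUALITY"
ADAPTER = "ADAPTER"
DUPLICATE = "DUPLICATE"
NO_QUALITIES = "NO_QUALITIES"

DEFAULT_QC_FLANK = 300


@dataclass(frozen=True)
class TargetRegion:
    """A target SNP with its QC flank (default +/-300 bp, edge-clipped)."""

    snp_id: str
    contig: str
    pos0: int
    flank: int = DEFAULT_QC_FLANK

    def interval(self, contig_length: int) -> tuple[int, int]:
        return max(0, self.pos0 - self.flank), min(contig_length, self.pos0 + self.flank + 1)


def filter_reads(
    reads: Iterable[AlignedRead],
    max_n_frac: float = 0.10,
    lowq_frac: float = 0.40,
    lowq_cutoff: int = 10,
    adapter: str | None = None,
    dedup: bool = True,
) -> tuple[list[AlignedRead], dict[str, int]]:
    """Drop reads by N content, low-quality content, adapter, duplication.

    A read is removed iff its N fraction strictly exceeds ``max_n_frac``,
    OR the fraction of bases with Phred quality <= ``lowq_cutoff`` strictly
    exceeds ``lowq_frac``, OR it contains the adapter substring, OR (with
    ``dedup``) its duplicate flag is set. Reads without qualities are
    dropped under a distinct reason. The tally assigns each dropped read
    its first failing reason, in the order above.
    """
    kept: list[AlignedRead] = []
    tally = {N_FRACTION: 0, LOW_QUALITY: 0, ADAPTER: 0, DUPLICATE: 0, NO_QUALITIES: 0}
    for read in reads:
        n = read.length
        if n and read.sequence.count("N") / n > max_n_frac:
            tally[N_FRACTION] += 1
            continue
        if read.qualities is None:
            tally[NO_QUALITIES] += 1
            continue
        if n and float(np.mean(read.qualities <= lowq_cutoff)) > lowq_frac:
            tally[LOW_QUALITY] += 1
            continue
        if adapter and adapter in read.sequence:
            tally[ADAPTER] += 1
            continue
        if dedup and read.duplicate:
            tally[DUPLICATE] += 1
            continue
        kept.append(read)
    return kept, {k: v for k, v in tally.items() if v}


def target_interval_set(
    targets: Sequence[TargetRegion], contig_lengths: Mapping[str, int]
) -> IntervalSet:
    return IntervalSet(
        (t.contig, *t.interval(contig_lengths[t.contig])) for t in targets
    )


@dataclass
class BaseCounts:
    """Read-base accounting; aligned bases partition into on-flank and
    off-target."""

    total: int = 0
    aligned: int = 0
    unique: int = 0
    on_flank: int = 0
    off_target: int = 0

    @property
    def aligned_fraction(self) -> float:
        return self.aligned / self.total if self.total else 0.0

    @property
    def on_flank_fraction(self) -> float:
        return self.on_flank / self.total if self.total else 0.0

    @property
    def off_target_fraction(self) -> float:
        return self.off_target / self.total if self.total else 0.0

    @property
    def unique_fraction(self) -> float:
        return self.unique / self.total if self.total else 0.0


def classify_alignment_bases(
    reads: Iterable[AlignedRead],
    target_regions: IntervalSet,
    per_base: bool = False,
) -> BaseCounts:
    """Partition read bases into aligned/unique/on-flank/off-target.

    Default read-level crediting: a mapped read overlapping a target
    region by at least one base credits ALL its bases on-flank (the
    tabulation is by read class). ``per_base=True`` instead intersects
    each read with the merged target footprint base-by-base.
    """
    counts = BaseCounts()
    for read in reads:
        n = read.length
        counts.total += n
        if not read.mapped:
            continue
        counts.aligned += n
        if read.unique:
            counts.unique += n
        start, end = read.pos0, read.end0
        if per_base:
            on = _overlap_bases(target_regions, read.contig, start, end)
            counts.on_flank += on
            counts.off_target += n - on
        elif target_regions.overlaps(read.contig, start, end):
            counts.on_flank += n
        else:
            counts.off_target += n
    return counts


def _overlap_bases(regions: IntervalSet, contig: str, start: int, end: int) -> int:
    total = 0
    for c, s, e in regions:
        if c == contig and s < end and start < e:
            total += min(e, end) - max(s, start)
    return total


def depth_arrays(
    reads: Iterable[AlignedRead],
    contig_lengths: Mapping[str, int],
    exclude_duplicates: bool = True,
) -> dict[str, np.ndarray]:
    """Per-contig per-base depth from mapped reads (end-exclusive)."""
    diffs = {c: np.zeros(length + 1, dtype=np.int64) for c, length in contig_lengths.items()}
    for read in reads:
        if not read.mapped or (exclude_duplicates and read.duplicate):
            continue
        diff = diffs[read.contig]
        start = max(0, read.pos0)
        end = min(len(diff) - 1, read.end0)
        if start < end:
            diff[start] += 1
            diff[end] -= 1
    return {c: np.cumsum(d[:-1]) for c, d in diffs.items()}


@dataclass
class DepthProfile:
    """Mean depth per offset around target SNPs (offset 0 = the SNP)."""

    offsets: np.ndarray  # -flank .. +flank
    mean_depth: np.ndarray
    n_targets: np.ndarray  # targets contributing per offset

    def at(self, offset: int) -> float:
        return float(self.mean_depth[int(offset) + (len(self.offsets) - 1) // 2])


def depth_profile(
    depths: Mapping[str, np.ndarray],
    targets: Sequence[TargetRegion],
    flank: int = DEFAULT_QC_FLANK,
) -> DepthProfile:
    """Per-offset mean depth across targets; overlapping targets each
    count independently. Offsets falling outside a contig are excluded
    from that target's contribution."""
    width = 2 * flank + 1
    sums = np.zeros(width, dtype=np.float64)
    counts = np.zeros(width, dtype=np.int64)
    for t in targets:
        depth = depths[t.contig]
        lo = t.pos0 - flank
        hi = t.pos0 + flank + 1
        src_lo, src_hi = max(0, lo), min(len(depth), hi)
        if src_lo >= src_hi:
            continue
        dst_lo = src_lo - lo
        dst_hi = dst_lo + (src_hi - src_lo)
        sums[dst_lo:dst_hi] += depth[src_lo:src_hi]
        counts[dst_lo:dst_hi] += 1
    mean = np.divide(sums, counts, out=np.zeros(width), where=counts > 0)
    return DepthProfile(
        offsets=np.arange(-flank, flank + 1), mean_depth=mean, n_targets=counts
    )


def per_target_depth(
    depths: Mapping[str, np.ndarray],
    targets: Sequence[TargetRegion],
    mode: str = "snp",
) -> np.ndarray:
    """Depth per target: at the SNP base itself (default) or the region
    mean (``mode='region'``)."""
    out = np.empty(len(targets), dtype=np.float64)
    for i, t in enumerate(targets):
        depth = depths[t.contig]
        if mode == "snp":
            out[i] = depth[t.pos0]
        elif mode == "region":
            s, e = t.interval(len(depth))
            out[i] = float(depth[s:e].mean())
        else:
            raise ValueError("mode must be 'snp' or 'region'")
    return out


@dataclass
class UniformityStats:
    mean_depth: float
    fraction_ge: dict[float, float]  # threshold (x mean) -> fraction of targets
    deciles: np.ndarray  # deciles of normalized depth


def coverage_uniformity(
    target_depths: np.ndarray, thresholds: Sequence[float] = (0.4, 0.8)
) -> UniformityStats:
    """Fractions of targets at >= t x mean depth, plus the normalized
    depth deciles."""
    depths = np.asarray(target_depths, dtype=float)
    if depths.size == 0:
        raise ValueError("no target depths")
    mean = float(depths.mean())
    if mean == 0.0:
        raise ValueError("zero mean target depth")
    norm = depths / mean
    fraction_ge = {float(t): float(np.mean(norm >= t)) for t in thresholds}
    return UniformityStats(
        mean_depth=mean,
        fraction_ge=fraction_ge,
        deciles=np.percentile(norm, np.arange(0, 101, 10)),
    )


def gc_depth_table(
    targets: Sequence[TargetRegion],
    genome: ReferenceGenome,
    target_depths: np.ndarray,
    bins: Sequence[float] = (0.3, 0.5, 0.7),
) -> pd.DataFrame:
    """Mean depth per region-GC bin; GC from the +/-flank window around
    each SNP with N excluded from the denominator. Bin edges are extended
    to [0, 1] so no region overflows."""
    gcs = np.empty(len(targets))
    for i, t in enumerate(targets):
        s, e = t.interval(genome.lengths[t.contig])
        seq = genome.fetch(t.contig, s, e)
        gc = seq.count("G") + seq.count("C")
        acgt = gc + seq.count("A") + seq.count("T")
        gcs[i] = gc / acgt if acgt else np.nan
    edges = [0.0, *bins, 1.0]
    labels = [f"{lo:.0%}-{hi:.0%}" for lo, hi in zip(edges[:-1], edges[1:])]
    frame = pd.DataFrame({"gc": gcs, "depth": np.asarray(target_depths, dtype=float)})
    frame["gc_bin"] = pd.cut(frame["gc"], bins=edges, labels=labels, include_lowest=True)
    grouped = frame.groupby("gc_bin", observed=False)["depth"].agg(["count", "mean"])
    return grouped.rename(columns={"count": "n_regions", "mean": "mean_depth"}).reset_index()


@dataclass
class ConcordanceResult:
    shared: int
    only_a: int
    only_b: int
    fraction_of_a: float
    fraction_of_b: float


def snp_concordance(
    callset_a: Iterable[tuple], callset_b: Iterable[tuple]
) -> ConcordanceResult:
    """Set intersection of two callsets keyed by (contig, pos, alt)."""
    a, b = set(callset_a), set(callset_b)
    shared = len(a & b)
    return ConcordanceResult(
        shared=shared,
        only_a=len(a - b),
        only_b=len(b - a),
        fraction_of_a=shared / len(a) if a else 0.0,
        fraction_of_b=shared / len(b) if b else 0.0,
    )


@dataclass
class CaptureQCReport:
    """Aggregate capture-evaluation report for one sequencing run."""

    base_counts: BaseCounts
    read_filter_tally: dict[str, int]
    profile: DepthProfile
    target_depths: np.ndarray
    uniformity: UniformityStats
    gc_table: pd.DataFrame
    min_depth: int
    coverage_fraction: float  # targets with depth >= min_depth

    def summary(self) -> dict[str, float]:
        return {
            "total_bases": self.base_counts.total,
            "aligned_fraction": self.base_counts.aligned_fraction,
            "unique_fraction": self.base_counts.unique_fraction,
            "on_flank_fraction": self.base_counts.on_flank_fraction,
            "off_target_fraction": self.base_counts.off_target_fraction,
            "mean_target_depth": self.uniformity.mean_depth,
            "coverage_fraction": self.coverage_fraction,
            "fraction_ge_0.4x": self.uniformity.fraction_ge.get(0.4, float("nan")),
            "fraction_ge_0.8x": self.uniformity.fraction_ge.get(0.8, float("nan")),
        }


def capture_qc_report(
    reads: Sequence[AlignedRead],
    targets: Sequence[TargetRegion],
    genome: ReferenceGenome,
    min_depth: int = 4,
    flank: int = DEFAULT_QC_FLANK,
    adapter: str | None = None,
    depth_mode: str = "snp",
) -> CaptureQCReport:
    """Run the full capture QC battery on one set of alignments."""
    contig_lengths = genome.lengths
    kept, read_tally = filter_reads(list(reads), adapter=adapter)
    regions = target_interval_set(targets, contig_lengths)
    counts = classify_alignment_bases(kept, regions)
    depths = depth_arrays(kept, contig_lengths)
    profile = depth_profile(depths, targets, flank=flank)
    tdepths = per_target_depth(depths, targets, mode=depth_mode)
    uniformity = coverage_uniformity(tdepths)
    gc_table = gc_depth_table(targets, genome, tdepths)
    coverage = float(np.mean(tdepths >= min_depth))
    return CaptureQCReport(
        base_counts=counts,
        read_filter_tally=read_tally,
        profile=profile,
        target_depths=tdepths,
        uniformity=uniformity,
        gc_table=gc_table,
        min_depth=min_depth,
        coverage_fraction=coverage,
    )
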