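"""Window-based density optimization.

SNP density is evened out over consecutive 40-kb windows tiled from
coordinate 0 of each contig: each remaining SNP gets a ranking score

    score = MAF * (E - S) * (1 - |a - (E-S)/2| / ((E-S)/2))

where [S, E) is the SNP's window and ``a`` its offset within it — a
triangular weight peaking at the window center, scaled by the minor
allele frequency — and only the top-scoring SNP(s) per window are kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .screen import CandidateSNP

DEFAULT_WINDOW = 40_000


def rank_score(maf: float, a: float, S: float, E: float) -> float:
    """Triangular-weighted ranking score of a SNP at window offset ``a``."""
    if S >= E:
        raise ValueError("window start must precede window end")
    width = E - S
    if not 0 <= a < width:
        raise ValueError(f"offset a={a} outside window of width {width}")
    half = width / 2.0
    return maf * width * (1.0 - abs(a - half) / half)


@dataclass
class ScoredSNP:
    snp: CandidateSNP
    a: int  # offset within the window, bp from S
    score: float


@dataclass
class GenomicWindow:
    contig: str
    S: int
    E: int
    members: list[ScoredSNP] = field(default_factory=list)

    @property
    def width(self) -> int:
        return self.E - self.S


def assign_windows(
    snps: Iterable[CandidateSNP],
    contig_lengths: Mapping[str, int],
    window: int = DEFAULT_WINDOW,
) -> list[GenomicWindow]:
    """Tile each contig with non-overlapping windows anchored at 0 and
    assign every SNP to exactly one (index = floor(pos0 / W)).

    Terminal windows are clipped to the contig end and use their true
    width in the score. Only non-empty windows are returned.
    """
    table: dict[tuple[str, int], GenomicWindow] = {}
    for snp in snps:
        length = contig_lengths[snp.contig]
        if not 0 <= snp.pos0 < length:
            raise ValueError(f"SNP {snp.id} outside contig {snp.contig}")
        idx = snp.pos0 // window
        key = (snp.contig, idx)
        if key not in table:
            S = idx * window
            E = min(S + window, length)
            table[key] = GenomicWindow(contig=snp.contig, S=S, E=E)
        win = table[key]
        a = snp.pos0 - win.S
        win.members.append(ScoredSNP(snp=snp, a=a, score=rank_score(snp.maf, a, win.S, win.E)))
    return [table[key] for key in sorted(table)]


def thin_windows(windows: Sequence[GenomicWindow], max_per_window: int = 1) -> list[CandidateSNP]:
    """Keep the ``max_per_window`` highest-scoring SNPs per window.

    Ties break toward the SNP nearer the window center, then the lower
    coordinate, making the selection deterministic.
    """
    kept: list[CandidateSNP] = []
    for win in windows:
        half = win.width / 2.0
        ranked = sorted(
            win.members,
            key=lambda m: (-m.score, abs(m.a - half), m.snp.pos0),
        )
        kept.extend(m.snp for m in ranked[:max_per_window])
    kept.sort(key=lambda s: (s.contig, s.pos0))
    return kept


def merge_whitelist(
    kept: Sequence[CandidateSNP], whitelist: Iterable[CandidateSNP]
) -> list[CandidateSNP]:
    """Add whitelisted SNPs (exempt from thinning), de-duplicated by
    (contig, pos0); a whitelisted SNP already kept is not added twice."""
    seen = {(s.contig, s.pos0) for s in kept}
    merged = list(kept)
    for snp in whitelist:
        key = (snp.contig, snp.pos0)
        if key not in seen:
            seen.add(key)
            merged.append(snp)
    merged.sort(key=lambda s: (s.contig, s.pos0))
    return merged


@dataclass
class SpacingStats:
    distances: np.ndarray  # nearest-neighbor distance per SNP (multi-SNP contigs)
    fraction_in_band: float
    band: tuple[int, int]
    n_singleton_contigs: int
    histogram: np.ndarray
    bin_edges: np.ndarray


def spacing_stats(
    kept: Sequence[CandidateSNP],
    band: tuple[int, int] = (15_000, 70_000),
    bin_width: int = 5_000,
) -> SpacingStats:
    """Nearest-neighbor spacing distribution of the retained SNPs.

    Contigs holding a single SNP contribute no distance; they are counted
    separately and excluded from the in-band fraction.
    """
    by_contig: dict[str, list[int]] = {}
    for snp in kept:
        by_contig.setdefault(snp.contig, []).append(snp.pos0)
    distances: list[int] = []
    singletons = 0
    for positions in by_contig.values():
        positions.sort()
        if len(positions) < 2:
            singletons += 1
            continue
        arr = np.asarray(positions)
        gaps = np.diff(arr)
        left = np.concatenate(([np.iinfo(np.int64).max], gaps))
        right = np.concatenate((gaps, [np.iinfo(np.int64).max]))
        distances.extend(np.minimum(left, right).tolist())
    dist_arr = np.asarray(distances, dtype=np.int64)
    if dist_arr.size:
        lo, hi = band
        frac = float(np.mean((dist_arr >= lo) & (dist_arr <= hi)))
        edges = np.arange(0, dist_arr.max() + bin_width + 1, bin_width)
        hist, edges = np.histogram(dist_arr, bins=edges)
    else:
        frac = float("nan")
        hist, edges = np.array([]), np.array([0])
    return SpacingStats(
        distances=dist_arr,
        fraction_in_band=frac,
        band=band,
        n_singleton_contigs=singletons,
        histogram=hist,
        bin_edges=edges,
    )
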