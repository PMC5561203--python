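"""Initial SNP screens on 150-bp flanks: hairpin structure, k-mer
uniqueness against the reference, and repeat overlap.

A SNP survives only if neither flank can fold into a stem-loop with a
stem longer than 8 bp, both flanks are unique in the genome (canonical
k-mer multiplicity), and the SNP does not sit inside a repeat interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .formats import IntervalSet, ReferenceGenome, VariantRecord, reverse_complement
from .filters import compute_maf

# Screen flag codes.
HAIRPIN = "HAIRPIN"
NON_UNIQUE = "NON_UNIQUE"
REPEAT = "REPEAT"
TRUNCATED = "TRUNCATED"

SCREEN_FLAGS = (HAIRPIN, NON_UNIQUE, REPEAT, TRUNCATED)

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


@dataclass(frozen=True)
class ScreenParams:
    flank: int = 150
    min_stem: int = 9  # ">8 bp hairpin" => stems of 9+ bp fail
    min_loop: int = 3
    k: int = 30
    uniqueness_min: float = 0.95


@dataclass(frozen=True)
class HairpinHit:
    """A stem-loop: two exact reverse-complement arms within one sequence.

    ``left_start``/``right_start`` are 0-based offsets of the arm starts;
    the right arm equals the reverse complement of the left arm.
    """

    stem: int
    left_start: int
    right_start: int
    loop: int


@dataclass
class CandidateSNP:
    """A biallelic site surviving cohort filters, with flanks and flags."""

    id: str
    contig: str
    pos0: int
    ref_allele: str
    alt_allele: str
    maf: float
    flank_left: str = ""
    flank_right: str = ""
    screen_flags: set[str] = field(default_factory=set)

    @property
    def passed_screens(self) -> bool:
        return not self.screen_flags


class FlankBoundaryError(ValueError):
    """Flank would cross a contig boundary."""


def extract_flanks(
    genome: ReferenceGenome, contig: str, pos0: int, flank: int = 150
) -> tuple[str, str]:
    """Flanking sequence on either side of a SNP; the SNP base is excluded.

    left = genome[pos0-flank, pos0), right = genome[pos0+1, pos0+1+flank).
    Raises :class:`FlankBoundaryError` when either side is truncated.
    """
    length = genome.lengths[contig]
    if pos0 < 0 or pos0 >= length:
        raise ValueError(f"SNP position {pos0} outside contig {contig!r}")
    if pos0 - flank < 0 or pos0 + 1 + flank > length:
        raise FlankBoundaryError(
            f"flank of {flank} bp around {contig}:{pos0} crosses the contig edge"
        )
    left = genome.fetch(contig, pos0 - flank, pos0)
    right = genome.fetch(contig, pos0 + 1, pos0 + 1 + flank)
    return left, right


def detect_hairpin(seq: str, min_stem: int = 9, min_loop: int = 3) -> HairpinHit | None:
    """Longest stem-loop with exact reverse-complement arms, or None.

    Arms must not overlap and must be separated by at least ``min_loop``
    bases; N never pairs with anything. Runs in O(n^2) via a pairing-run
    recurrence along anti-diagonals of the complementarity matrix.
    """
    n = len(seq)
    if n < 2 * min_stem + min_loop:
        return None
    code = np.fromiter((_BASE_CODE.get(c, 4) for c in seq), dtype=np.int8, count=n)
    # pair[i, j]: base i can pair with base j (Watson-Crick, N excluded)
    pair = (code[:, None] + code[None, :]) == 3
    # run[i, j]: length of the contiguous pairing run ending at inner pair
    # (i, j), extended from the outer neighbor (i-1, j+1).
    run = np.zeros((n, n), dtype=np.int32)
    run[0] = pair[0]
    for i in range(1, n):
        shifted = np.empty(n, dtype=np.int32)
        shifted[:-1] = run[i - 1, 1:]
        shifted[-1] = 0
        run[i] = np.where(pair[i], shifted + 1, 0)
    ii, jj = np.indices((n, n))
    loop = jj - ii - 1
    valid = (run >= min_stem) & (loop >= min_loop) & (jj > ii)
    if not valid.any():
        return None
    stems = np.where(valid, run, 0)
    flat = int(np.argmax(stems))
    i, j = divmod(flat, n)
    s = int(run[i, j])
    return HairpinHit(stem=s, left_start=i - s + 1, right_start=j, loop=j - i - 1)


def has_hairpin(seq: str, min_stem: int = 9, min_loop: int = 3) -> bool:
    return detect_hairpin(seq, min_stem=min_stem, min_loop=min_loop) is not None


class KmerIndex:
    """Canonical (strand-collapsed) k-mer multiplicity index of a genome.

    k-mers containing N are skipped entirely.
    """

    def __init__(self, genome: ReferenceGenome, k: int = 30) -> None:
        if k < 2:
            raise ValueError("k must be >= 2")
        self.k = k
        counts: dict[str, int] = {}
        for seq in genome.sequences.values():
            rc = reverse_complement(seq)
            n = len(seq)
            for i in range(n - k + 1):
                kmer = seq[i : i + k]
                if "N" in kmer:
                    continue
                canon = min(kmer, rc[n - i - k : n - i])
                counts[canon] = counts.get(canon, 0) + 1
        self._counts = counts

    def multiplicity(self, kmer: str) -> int:
        if len(kmer) != self.k:
            raise ValueError(f"expected {self.k}-mer, got length {len(kmer)}")
        if "N" in kmer:
            return 0
        canon = min(kmer, reverse_complement(kmer))
        return self._counts.get(canon, 0)


def kmer_uniqueness(index: KmerIndex, seq: str) -> float | None:
    """Fraction of seq's k-mers occurring exactly once genome-wide.

    k-mers containing N are excluded from numerator and denominator;
    returns None when no k-mer is evaluable. Raises for seq shorter than k.
    """
    k = index.k
    if len(seq) < k:
        raise ValueError(f"sequence of length {len(seq)} shorter than k={k}")
    total = 0
    unique = 0
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if "N" in kmer:
            continue
        total += 1
        if index.multiplicity(kmer) == 1:
            unique += 1
    if total == 0:
        return None
    return unique / total


def repeat_overlap(snp: CandidateSNP | VariantRecord, repeats: IntervalSet) -> bool:
    """True iff the SNP base lies inside a repeat interval (point, half-open)."""
    return repeats.contains_point(snp.contig, snp.pos0)


@dataclass
class ScreenResult:
    survivors: list[CandidateSNP]
    candidates: list[CandidateSNP]  # all inputs with flags populated
    tally: dict[str, int]
    n_input: int


def _as_candidate(snp, index: int) -> CandidateSNP:
    if isinstance(snp, CandidateSNP):
        return snp
    if isinstance(snp, VariantRecord):
        try:
            maf = compute_maf(snp.genotypes)
        except ValueError:
            maf = 0.0
        return CandidateSNP(
            id=snp.id or f"snp{index}",
            contig=snp.contig,
            pos0=snp.pos0,
            ref_allele=snp.ref_allele,
            alt_allele=snp.alt_alleles[0] if snp.alt_alleles else "N",
            maf=maf,
        )
    raise TypeError(f"cannot screen object of type {type(snp).__name__}")


def screen_candidates(
    snps: Iterable[CandidateSNP | VariantRecord],
    genome: ReferenceGenome,
    repeats: IntervalSet,
    params: ScreenParams = ScreenParams(),
    kmer_index: KmerIndex | None = None,
) -> ScreenResult:
    """Apply all three screens; a SNP survives iff no flag is set.

    The tally counts every flag occurrence (a SNP may carry several).
    An existing :class:`KmerIndex` can be passed to avoid rebuilding.
    """
    if kmer_index is None:
        kmer_index = KmerIndex(genome, k=params.k)
    candidates: list[CandidateSNP] = []
    tally: dict[str, int] = {flag: 0 for flag in SCREEN_FLAGS}
    for i, snp in enumerate(snps):
        cand = _as_candidate(snp, i)
        cand.screen_flags = set()
        try:
            left, right = extract_flanks(genome, cand.contig, cand.pos0, params.flank)
            cand.flank_left, cand.flank_right = left, right
        except FlankBoundaryError:
            cand.screen_flags.add(TRUNCATED)
            candidates.append(cand)
            continue
        for flank_seq in (left, right):
            if has_hairpin(flank_seq, params.min_stem, params.min_loop):
                cand.screen_flags.add(HAIRPIN)
                break
        for flank_seq in (left, right):
            frac = kmer_uniqueness(kmer_index, flank_seq)
            if frac is None or frac < params.uniqueness_min:
                cand.screen_flags.add(NON_UNIQUE)
                break
        if repeat_overlap(cand, repeats):
            cand.screen_flags.add(REPEAT)
        candidates.append(cand)
    for cand in candidates:
        for flag in cand.screen_flags:
            tally[flag] += 1
    tally = {flag: count for flag, count in tally.items() if count}
    survivors = [c for c in candidates if c.passed_screens]
    return ScreenResult(
        survivors=survivors, candidates=candidates, tally=tally, n_input=len(candidates)
    )
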