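"""Bait enumeration, viability screening, and probe selection.

A probe is a 120-bp synthesizable oligo: a 90-bp target-specific bait
flanked by two fixed 15-bp PCR primer arms. Baits must cover their SNP
with the bait center within 50 bp of it, satisfy a 30-70% GC criterion,
and avoid stem-loops longer than 8 bp; per SNP the two (or three) baits
whose center sits closest to 20 bp from the SNP are ordered.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .formats import ReferenceGenome
from .screen import CandidateSNP, has_hairpin

ARM_A = "GAAGCGAGGATCAAC"
ARM_B = "CATTGCGTGAACCGA"

# Drop reasons.
NO_PROBE = "NO_PROBE"
ONE_PROBE = "ONE_PROBE"


@dataclass(frozen=True)
class DesignParams:
    bait_len: int = 90
    max_center_offset: int = 50
    target_offset: int = 20
    gc_range: tuple[float, float] = (0.30, 0.70)
    n_select: int = 2  # "two or three best probes"
    min_viable: int = 2
    min_stem: int = 9
    min_loop: int = 3

    def __post_init__(self) -> None:
        if self.target_offset > self.max_center_offset:
            raise ValueError("target_offset must not exceed max_center_offset")
        lo, hi = self.gc_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("gc_range must lie within [0, 1]")
        if self.n_select not in (2, 3):
            raise ValueError("n_select must be 2 or 3")


@dataclass
class ProbeCandidate:
    snp_id: str
    contig: str
    bait_start0: int
    bait_seq: str
    center_offset: int  # signed bp from bait center to the SNP position
    gc_fraction: float
    has_n: bool
    hairpin: bool
    covers_snps: tuple[str, ...] = ()
    strand: str = "+"


@dataclass
class ProbeOligo:
    probe_id: str
    snp_id: str
    contig: str
    bait_start0: int
    strand: str
    oligo_seq: str
    copies: int


def gc_fraction(seq: str) -> float:
    """(G+C) / (A+C+G+T); N bases are excluded from the denominator."""
    if not seq:
        raise ValueError("empty sequence")
    gc = seq.count("G") + seq.count("C")
    acgt = gc + seq.count("A") + seq.count("T")
    if acgt == 0:
        raise ValueError("sequence contains no A/C/G/T bases")
    return gc / acgt


def bait_center_offset(bait_start0: int, bait_len: int, snp_pos0: int) -> int:
    """Signed distance from the bait center to the SNP base."""
    return (bait_start0 + bait_len // 2) - snp_pos0


def enumerate_baits(
    genome: ReferenceGenome,
    snp: CandidateSNP,
    params: DesignParams = DesignParams(),
    all_snp_positions: dict[str, np.ndarray] | None = None,
    snp_ids_by_contig: dict[str, list[str]] | None = None,
) -> list[ProbeCandidate]:
    """All bait placements covering the SNP with |center offset| <= 50.

    One candidate per start position s with s <= pos0 < s + bait_len,
    clipped at contig edges. GC and hairpin are computed per candidate.
    ``all_snp_positions`` (sorted pos0 arrays per contig) enables the
    multi-SNP coverage annotation used by the copy-doubling rule.
    """
    length = genome.lengths[snp.contig]
    bait_len = params.bait_len
    candidates: list[ProbeCandidate] = []
    lo = max(0, snp.pos0 - bait_len + 1)
    hi = min(snp.pos0, length - bait_len)
    for start in range(lo, hi + 1):
        offset = bait_center_offset(start, bait_len, snp.pos0)
        if abs(offset) > params.max_center_offset:
            continue
        bait = genome.fetch(snp.contig, start, start + bait_len)
        has_n = "N" in bait
        try:
            gc = gc_fraction(bait)
        except ValueError:
            gc = float("nan")
            has_n = True
        covers: tuple[str, ...] = (snp.id,)
        if all_snp_positions is not None and snp.contig in all_snp_positions:
            positions = all_snp_positions[snp.contig]
            i0 = int(np.searchsorted(positions, start, side="left"))
            i1 = int(np.searchsorted(positions, start + bait_len, side="left"))
            if snp_ids_by_contig is not None:
                covers = tuple(snp_ids_by_contig[snp.contig][i] for i in range(i0, i1))
            else:
                covers = tuple(str(positions[i]) for i in range(i0, i1))
        candidates.append(
            ProbeCandidate(
                snp_id=snp.id,
                contig=snp.contig,
                bait_start0=start,
                bait_seq=bait,
                center_offset=offset,
                gc_fraction=gc,
                has_n=has_n,
                hairpin=has_hairpin(bait, params.min_stem, params.min_loop),
                covers_snps=covers,
            )
        )
    return candidates


@dataclass
class SelectionVerdict:
    selected: list[tuple[ProbeCandidate, int]]  # (candidate, copies)
    dropped_reason: str | None = None
    rescued: bool = False


def _rank_key(params: DesignParams):
    def key(c: ProbeCandidate):
        return (
            abs(abs(c.center_offset) - params.target_offset),
            abs(c.gc_fraction - 0.5),
            c.bait_start0,
        )

    return key


def select_probes(
    candidates: Sequence[ProbeCandidate], params: DesignParams = DesignParams()
) -> SelectionVerdict:
    """Pick the best baits for one SNP, applying the copy-doubling rules.

    Viable = passes GC range, placement, contains no N, and no >8 bp
    hairpin. SNPs with fewer than ``min_viable`` viable baits are dropped,
    except the rescue: when exactly two candidates pass GC/placement and
    exactly one of those is hairpin-flagged, the other is kept at two
    copies. Any selected bait covering two or more SNPs has its copy
    count doubled.
    """
    lo, hi = params.gc_range
    pool = [
        c
        for c in candidates
        if not c.has_n
        and lo <= c.gc_fraction <= hi
        and abs(c.center_offset) <= params.max_center_offset
    ]
    viable = [c for c in pool if not c.hairpin]
    rescued = False
    if len(viable) >= params.min_viable:
        chosen = sorted(viable, key=_rank_key(params))[: params.n_select]
        selected = [(c, 1) for c in chosen]
    elif len(pool) == 2 and len(viable) == 1:
        selected = [(viable[0], 2)]
        rescued = True
    elif not viable:
        return SelectionVerdict(selected=[], dropped_reason=NO_PROBE)
    else:
        return SelectionVerdict(selected=[], dropped_reason=ONE_PROBE)
    selected = [
        (c, copies * 2 if len(c.covers_snps) >= 2 else copies) for c, copies in selected
    ]
    return SelectionVerdict(selected=selected, rescued=rescued)


def build_oligo(bait: str, bait_len: int = 90) -> str:
    """Assemble the synthesizable 120-mer: primer arm A + bait + arm B."""
    if len(bait) != bait_len:
        raise ValueError(f"bait must be {bait_len} bp, got {len(bait)}")
    return ARM_A + bait + ARM_B


def split_sublibraries(oligos: Sequence[ProbeOligo], n_sublibraries: int = 2) -> list[int]:
    """Round-robin assignment of an ordered probe list into synthesis
    sub-libraries; returns one 0-based sub-library index per oligo. The
    split balances counts only — no fidelity claim beyond that."""
    if n_sublibraries < 1:
        raise ValueError("need at least one sub-library")
    return [i % n_sublibraries for i in range(len(oligos))]


@dataclass
class DesignResult:
    oligos: list[ProbeOligo]
    tally: dict[str, int]
    dropped: dict[str, str]  # snp id -> reason
    n_input: int

    @property
    def designed_snps(self) -> int:
        return len({o.snp_id for o in self.oligos})


def design_all(
    snps: Iterable[CandidateSNP],
    genome: ReferenceGenome,
    params: DesignParams = DesignParams(),
) -> DesignResult:
    """Per-SNP bait selection over a screened candidate set."""
    snps = list(snps)
    positions: dict[str, np.ndarray] = {}
    ids_by_contig: dict[str, list[str]] = {}
    for snp in sorted(snps, key=lambda s: (s.contig, s.pos0)):
        positions.setdefault(snp.contig, []).append(snp.pos0)  # type: ignore[arg-type]
        ids_by_contig.setdefault(snp.contig, []).append(snp.id)
    positions = {c: np.asarray(v) for c, v in positions.items()}

    oligos: list[ProbeOligo] = []
    dropped: dict[str, str] = {}
    tally = {"designed": 0, NO_PROBE: 0, ONE_PROBE: 0, "rescued": 0, "multi_snp_doubled": 0}
    for snp in snps:
        candidates = enumerate_baits(genome, snp, params, positions, ids_by_contig)
        verdict = select_probes(candidates, params)
        if verdict.dropped_reason is not None:
            dropped[snp.id] = verdict.dropped_reason
            tally[verdict.dropped_reason] += 1
            continue
        tally["designed"] += 1
        if verdict.rescued:
            tally["rescued"] += 1
        for rank, (cand, copies) in enumerate(verdict.selected, start=1):
            if len(cand.covers_snps) >= 2:
                tally["multi_snp_doubled"] += 1
            oligos.append(
                ProbeOligo(
                    probe_id=f"{snp.id}_p{rank}",
                    snp_id=snp.id,
                    contig=cand.contig,
                    bait_start0=cand.bait_start0,
                    strand=cand.strand,
                    oligo_seq=build_oligo(cand.bait_seq, params.bait_len),
                    copies=copies,
                )
            )
    tally = {k: v for k, v in tally.items() if v or k == "designed"}
    return DesignResult(oligos=oligos, tally=tally, dropped=dropped, n_input=len(snps))
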