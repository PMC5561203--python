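"""Readers/writers for the standard formats the pipeline touches.

All internal coordinates are 0-based half-open; the single exception is the
VCF boundary, where positions are converted to/from the format's 1-based
convention. Every other module consumes only the domain types defined here.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

# Genotype codes used throughout the package.
HOM_REF = 0
HET = 1
HOM_ALT = 2
MISSING = -1

#: INFO keys carried through as floats when present.
NUMERIC_INFO_KEYS = (
    "QD",
    "FS",
    "MQ",
    "MQRankSum",
    "ReadPosRankSum",
    "DP",
    "HaplotypeScore",
)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


class FormatError(ValueError):
    """Raised on malformed or inconsistent input files."""


@dataclass
class ReferenceGenome:
    """An in-memory reference: contig name -> uppercase A/C/G/T/N string."""

    sequences: dict[str, str]

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    def fetch(self, contig: str, start0: int, end0: int) -> str:
        """Return the sequence of a 0-based half-open interval.

        Raises ``KeyError`` for unknown contigs and ``ValueError`` for
        intervals that fall outside the contig.
        """
        seq = self.sequences[contig]
        if start0 < 0 or end0 > len(seq) or start0 > end0:
            raise ValueError(
                f"interval [{start0}, {end0}) outside contig {contig!r} "
                f"of length {len(seq)}"
            )
        return seq[start0:end0]

    def __contains__(self, contig: str) -> bool:
        return contig in self.sequences


@dataclass
class VariantRecord:
    """One VCF site with INFO metrics, genotypes and per-sample depths.

    ``genotypes`` holds one code per sample (HOM_REF/HET/HOM_ALT/MISSING);
    ``sample_depths`` holds per-sample integer depth, -1 when absent.
    Missing INFO keys are absent from ``info``, never stored as 0.
    """

    contig: str
    pos1: int
    ref_allele: str
    alt_alleles: tuple[str, ...]
    info: dict[str, float] = field(default_factory=dict)
    genotypes: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int8))
    sample_depths: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int32))
    id: str | None = None

    def __post_init__(self) -> None:
        if self.pos1 < 1:
            raise FormatError(f"VCF position must be >= 1, got {self.pos1}")
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.sample_depths = np.asarray(self.sample_depths, dtype=np.int32)
        if len(self.genotypes) != len(self.sample_depths):
            raise FormatError(
                "genotype and depth arrays differ in length "
                f"({len(self.genotypes)} vs {len(self.sample_depths)})"
            )

    @property
    def pos0(self) -> int:
        return self.pos1 - 1

    @property
    def is_biallelic_snp(self) -> bool:
        return (
            len(self.alt_alleles) == 1
            and len(self.ref_allele) == 1
            and len(self.alt_alleles[0]) == 1
        )


class IntervalSet:
    """Sorted, merged set of (contig, start0, end0) half-open intervals."""

    def __init__(self, intervals: Iterable[tuple[str, int, int]] = ()) -> None:
        by_contig: dict[str, list[tuple[int, int]]] = {}
        for contig, start, end in intervals:
            if start >= end:
                raise FormatError(f"interval start {start} >= end {end} on {contig}")
            by_contig.setdefault(contig, []).append((start, end))
        self._starts: dict[str, list[int]] = {}
        self._ends: dict[str, list[int]] = {}
        for contig, ivs in by_contig.items():
            ivs.sort()
            merged: list[list[int]] = []
            for s, e in ivs:
                if merged and s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            self._starts[contig] = [m[0] for m in merged]
            self._ends[contig] = [m[1] for m in merged]

    def __iter__(self) -> Iterator[tuple[str, int, int]]:
        for contig in self._starts:
            yield from (
                (contig, s, e)
                for s, e in zip(self._starts[contig], self._ends[contig])
            )

    def __len__(self) -> int:
        return sum(len(v) for v in self._starts.values())

    def contains_point(self, contig: str, pos0: int) -> bool:
        """True iff pos0 lies inside an interval (half-open semantics)."""
        starts = self._starts.get(contig)
        if not starts:
            return False
        i = bisect.bisect_right(starts, pos0) - 1
        return i >= 0 and pos0 < self._ends[contig][i]

    def overlaps(self, contig: str, start0: int, end0: int) -> bool:
        """True iff [start0, end0) intersects any interval."""
        starts = self._starts.get(contig)
        if not starts:
            return False
        i = bisect.bisect_right(starts, end0 - 1) - 1
        return i >= 0 and start0 < self._ends[contig][i]

    def total_length(self) -> int:
        return sum(
            e - s
            for contig in self._starts
            for s, e in zip(self._starts[contig], self._ends[contig])
        )


@dataclass
class AlignedRead:
    """SAM record subset used by capture QC."""

    name: str
    sequence: str
    qualities: np.ndarray | None  # Phred scores; None when '*'
    mapped: bool
    contig: str | None
    pos0: int | None
    mapq: int
    duplicate: bool
    unique: bool  # MAPQ at/above the uniqueness threshold

    def __post_init__(self) -> None:
        if not self.mapped and (self.contig is not None or self.pos0 is not None):
            raise FormatError("unmapped read must not carry coordinates")
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise FormatError("sequence and quality strings differ in length")

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def end0(self) -> int | None:
        return None if self.pos0 is None else self.pos0 + len(self.sequence)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> ReferenceGenome:
    """Read a FASTA file into a :class:`ReferenceGenome` (uppercased)."""
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise FormatError(f"duplicate contig name {record.id!r}")
        seq = str(record.seq).upper()
        if not seq:
            raise FormatError(f"empty sequence for contig {record.id!r}")
        sequences[record.id] = seq
    return ReferenceGenome(sequences)


def write_fasta(genome: ReferenceGenome, path: str | Path, width: int = 60) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in genome.sequences.items()
    ]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# VCF


def _vcf_header(contig_lengths: Mapping[str, int], samples: Sequence[str]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for name, length in contig_lengths.items():
        header.contigs.add(name, length=length)
    header.info.add("DP", 1, "Integer", "Total read depth")
    for key in ("QD", "FS", "MQ", "MQRankSum", "ReadPosRankSum", "HaplotypeScore"):
        header.info.add(key, 1, "Float", f"{key} site annotation")
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("DP", 1, "Integer", "Sample read depth")
    for sample in samples:
        header.add_sample(sample)
    return header


def read_vcf(path: str | Path) -> Iterator[VariantRecord]:
    """Stream VariantRecords from an uncompressed VCF.

    Multi-allelic sites are kept (downstream filters reject them);
    genotype phasing is ignored.
    """
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            info: dict[str, float] = {}
            for key in NUMERIC_INFO_KEYS:
                if key in rec.info:
                    value = rec.info[key]
                    if isinstance(value, tuple):
                        value = value[0]
                    if value is not None:
                        info[key] = float(value)
            genotypes = np.full(len(rec.samples), MISSING, dtype=np.int8)
            depths = np.full(len(rec.samples), -1, dtype=np.int32)
            for i, sample in enumerate(rec.samples.values()):
                gt = sample.get("GT")
                if gt is not None and None not in gt:
                    n_alt = sum(1 for allele in gt if allele > 0)
                    genotypes[i] = (HOM_REF, HET, HOM_ALT)[min(n_alt, 2)]
                dp = sample.get("DP")
                if dp is not None:
                    depths[i] = dp
            yield VariantRecord(
                contig=rec.contig,
                pos1=rec.pos,
                ref_allele=rec.ref,
                alt_alleles=tuple(rec.alts or ()),
                info=info,
                genotypes=genotypes,
                sample_depths=depths,
                id=rec.id,
            )


_GT_STRINGS = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}


def write_vcf(
    records: Iterable[VariantRecord],
    contig_lengths: Mapping[str, int],
    samples: Sequence[str],
    path: str | Path,
) -> None:
    """Write VariantRecords as an uncompressed VCF 4.2 file."""
    header = _vcf_header(contig_lengths, samples)
    lines = [str(header).rstrip("\n")]
    info_order = ("DP", "QD", "FS", "MQ", "MQRankSum", "ReadPosRankSum", "HaplotypeScore")
    for rec in records:
        info_parts = []
        for key in info_order:
            if key in rec.info:
                value = rec.info[key]
                if key == "DP":
                    info_parts.append(f"DP={int(value)}")
                else:
                    info_parts.append(f"{key}={value:g}")
        info_str = ";".join(info_parts) if info_parts else "."
        fields = [
            rec.contig,
            str(rec.pos1),
            rec.id or ".",
            rec.ref_allele,
            ",".join(rec.alt_alleles) if rec.alt_alleles else ".",
            ".",
            ".",
            info_str,
            "GT:DP",
        ]
        for gt, dp in zip(rec.genotypes, rec.sample_depths):
            dp_str = str(int(dp)) if dp >= 0 else "."
            fields.append(f"{_GT_STRINGS[int(gt)]}:{dp_str}")
        lines.append("\t".join(fields))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# BED


def read_bed(path: str | Path) -> IntervalSet:
    """Read a 3+ column BED (0-based half-open) into an IntervalSet."""
    intervals = []
    for line_no, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) < 3:
            raise FormatError(f"BED line {line_no}: fewer than 3 columns")
        contig, start, end = parts[0], int(parts[1]), int(parts[2])
        if start >= end:
            raise FormatError(f"BED line {line_no}: start {start} >= end {end}")
        intervals.append((contig, start, end))
    return IntervalSet(intervals)


def write_bed(intervals: Iterable[tuple[str, int, int]], path: str | Path) -> None:
    with open(path, "w") as handle:
        for contig, start, end in intervals:
            handle.write(f"{contig}\t{start}\t{end}\n")


# ---------------------------------------------------------------------------
# SAM

DEFAULT_UNIQUE_MAPQ = 30


def read_sam(path: str | Path, unique_mapq: int = DEFAULT_UNIQUE_MAPQ) -> Iterator[AlignedRead]:
    """Stream AlignedReads from a headered text SAM file.

    Flag bits 0x4 (unmapped) and 0x400 (duplicate) are honored; a read is
    flagged ``unique`` when mapped with MAPQ >= ``unique_mapq``.
    """
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for seg in sam:
            mapped = not seg.is_unmapped
            quals = seg.query_qualities
            yield AlignedRead(
                name=seg.query_name,
                sequence=seg.query_sequence or "",
                qualities=None if quals is None else np.asarray(quals, dtype=np.int16),
                mapped=mapped,
                contig=seg.reference_name if mapped else None,
                pos0=seg.reference_start if mapped else None,
                mapq=seg.mapping_quality,
                duplicate=seg.is_duplicate,
                unique=mapped and seg.mapping_quality >= unique_mapq,
            )


def write_sam(
    reads: Iterable[AlignedRead],
    contig_lengths: Mapping[str, int],
    path: str | Path,
) -> None:
    """Write AlignedReads as a headered text SAM file."""
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": name, "LN": length} for name, length in contig_lengths.items()],
        }
    )
    with pysam.AlignmentFile(str(path), "wh", header=header) as sam:
        for read in reads:
            seg = pysam.AlignedSegment(header)
            seg.query_name = read.name
            seg.query_sequence = read.sequence
            if read.qualities is not None:
                seg.query_qualities = pysam.qualitystring_to_array(
                    "".join(chr(q + 33) for q in read.qualities)
                )
            flag = 0
            if not read.mapped:
                flag |= 0x4
            if read.duplicate:
                flag |= 0x400
            seg.flag = flag
            if read.mapped:
                seg.reference_id = list(contig_lengths).index(read.contig)
                seg.reference_start = read.pos0
                seg.mapping_quality = read.mapq
                seg.cigarstring = f"{len(read.sequence)}M"
            sam.write(seg)


# ---------------------------------------------------------------------------
# Probe order

_ORDER_COLUMNS = ("probe_id", "snp_id", "contig", "bait_start0", "strand", "oligo_seq", "copies")


def write_probe_order(probes, path: str | Path, fasta_path: str | Path | None = None) -> None:
    """Write the final probe order as TSV (and optionally a FASTA of oligos).

    ``probes`` is an iterable of objects with attributes matching the TSV
    columns (see :class:`baitforge.probes.ProbeOligo`).
    """
    with open(path, "w") as handle:
        handle.write("\t".join(_ORDER_COLUMNS) + "\n")
        for p in probes:
            handle.write(
                f"{p.probe_id}\t{p.snp_id}\t{p.contig}\t{p.bait_start0}\t"
                f"{p.strand}\t{p.oligo_seq}\t{p.copies}\n"
            )
    if fasta_path is not None:
        with open(fasta_path, "w") as handle:
            for p in probes:
                handle.write(f">{p.probe_id}\n{p.oligo_seq}\n")


def read_probe_order(path: str | Path) -> list[dict]:
    """Read a probe order TSV back into a list of dicts (round-trip aid)."""
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0].split("\t") != list(_ORDER_COLUMNS):
        raise FormatError("probe order TSV missing expected header")
    rows = []
    for line in lines[1:]:
        parts = line.split("\t")
        if len(parts) != len(_ORDER_COLUMNS):
            raise FormatError("probe order TSV row with wrong column count")
        row = dict(zip(_ORDER_COLUMNS, parts))
        row["bait_start0"] = int(row["bait_start0"])
        row["copies"] = int(row["copies"])
        rows.append(row)
    return rows
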