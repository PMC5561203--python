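"""Deterministic fixture generator: genomes with planted stem-loops,
duplications and repeat annotations, cohort VCFs with controlled
MAF/missingness/depth and planted filter violations, and capture reads
concentrated around targets — every plant recorded in a truth table.

The generator verifies its plants against the package's own screens and
resamples from spare loci, so the planted fate of every emitted SNP is
exact: hairpin-fate SNPs fire the hairpin screen and nothing else,
duplicate-fate SNPs fire only the uniqueness screen, and so on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .formats import (
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    AlignedRead,
    IntervalSet,
    ReferenceGenome,
    VariantRecord,
    reverse_complement,
    write_bed,
    write_fasta,
    write_sam,
    write_vcf,
)
from .screen import (
    HAIRPIN,
    NON_UNIQUE,
    REPEAT,
    KmerIndex,
    ScreenParams,
    extract_flanks,
    has_hairpin,
    kmer_uniqueness,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# SNP position fates and INFO fates.
FATE_CLEAN = "clean"
FATE_HAIRPIN = "hairpin"
FATE_DUPLICATE = "duplicate"
FATE_REPEAT = "repeat"

INFO_PASS = "pass"
HARD_FILTER_CLAUSES = ("QD", "FS", "MQ", "MQRankSum", "ReadPosRankSum")


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-shaped defaults: a 73-animal design cohort genotyped on a
    random genome, screened at the pipeline's parameters, and 50-bp
    single-end capture reads placed by a Gaussian kernel around targets."""

    seed: int = 0
    # genome
    contig_length: int = 300_000
    contig_name: str = "chr1"
    gc_content: float = 0.5
    anchor_spacing: int = 1_000
    hairpin_stem: int = 12
    hairpin_loop: int = 4
    dup_segment: int = 321  # covers both 150-bp flanks plus the SNP base
    repeat_halfwidth: int = 50
    # SNP slot quotas
    n_clean_snps: int = 140
    n_hairpin_snps: int = 30
    n_duplicate_snps: int = 20
    n_repeat_snps: int = 10
    # cohort
    n_samples: int = 73
    maf_range: tuple[float, float] = (0.05, 0.5)
    missing_rate: float = 0.03
    mean_sample_depth: float = 6.0
    n_per_clause: int = 10
    # reads
    read_len: int = 50
    n_reads: int = 20_000
    on_target_fraction: float = 0.56
    kernel_sd: float = 75.0
    base_quality: int = 35
    dup_read_rate: float = 0.0
    n_read_rate: float = 0.0
    lowq_read_rate: float = 0.0
    multimap_rate: float = 0.0
    gc_bias: Callable[[float], float] | None = None

    def rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng([self.seed % (2**31), stage])


@dataclass(frozen=True)
class SNPSlot:
    snp_id: str
    contig: str
    pos0: int
    fate: str


@dataclass
class GenomeTruth:
    slots: list[SNPSlot]
    hairpin_loci: list[tuple[str, int]]  # (contig, stem-loop start)
    duplicated_segments: list[tuple[str, int, int]]

    def slots_by_fate(self, fate: str) -> list[SNPSlot]:
        return [s for s in self.slots if s.fate == fate]


def _random_sequence(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    draw = rng.choice(_BASES, size=length, p=probs)
    return draw.tobytes().decode("ascii")


def make_genome(
    config: SyntheticConfig, screen_params: ScreenParams = ScreenParams()
) -> tuple[ReferenceGenome, IntervalSet, GenomeTruth]:
    """Background genome with planted stem-loops, verbatim duplications,
    and annotated repeat intervals, plus verified SNP slots per fate.

    Duplication copies are written to a separate bank contig so they
    break flank uniqueness without disturbing the main contig layout.
    Each slot is verified against the actual screens; spare anchors
    absorb chance failures (e.g. an incidental hairpin in a clean flank).
    """
    rng = config.rng(1)
    seq = np.frombuffer(
        _random_sequence(rng, config.contig_length, config.gc_content).encode(),
        dtype=np.uint8,
    ).copy()
    margin = 2 * screen_params.flank + 20
    anchors = list(range(margin, config.contig_length - margin, config.anchor_spacing))
    rng.shuffle(anchors)

    # over-provision each fate to absorb verification failures
    quotas = {
        FATE_HAIRPIN: config.n_hairpin_snps,
        FATE_DUPLICATE: config.n_duplicate_snps,
        FATE_REPEAT: config.n_repeat_snps,
        FATE_CLEAN: config.n_clean_snps,
    }
    spares = {
        FATE_HAIRPIN: 6 + config.n_hairpin_snps // 4,
        FATE_DUPLICATE: 8 + config.n_duplicate_snps // 3,
        FATE_REPEAT: 6 + config.n_repeat_snps // 2,
        FATE_CLEAN: 20 + config.n_clean_snps // 4,
    }
    needed = sum(quotas.values()) + sum(q > 0 and spares[f] for f, q in quotas.items())
    if needed > len(anchors):
        raise ValueError(
            f"contig of {config.contig_length} bp supports only {len(anchors)} "
            f"slot anchors at spacing {config.anchor_spacing}; {needed} needed"
        )
    provisional: dict[str, list[int]] = {}
    cursor = 0
    for fate, quota in quotas.items():
        take = quota + (spares[fate] if quota else 0)
        provisional[fate] = anchors[cursor : cursor + take]
        cursor += take

    contig = config.contig_name
    hairpin_loci: list[tuple[str, int]] = []
    for pos in provisional[FATE_HAIRPIN]:
        arm = _random_sequence(rng, config.hairpin_stem, config.gc_content)
        loop = _random_sequence(rng, config.hairpin_loop, config.gc_content)
        plant = arm + loop + reverse_complement(arm)
        start = pos - 100  # inside the 150-bp left flank
        seq[start : start + len(plant)] = np.frombuffer(plant.encode(), dtype=np.uint8)
        hairpin_loci.append((contig, start))

    main_seq = seq.tobytes().decode("ascii")
    bank_parts: list[str] = []
    duplicated: list[tuple[str, int, int]] = []
    half = config.dup_segment // 2
    for pos in provisional[FATE_DUPLICATE]:
        s, e = pos - half, pos - half + config.dup_segment
        bank_parts.append(main_seq[s:e])
        bank_parts.append(_random_sequence(rng, 10, config.gc_content))
        duplicated.append((contig, s, e))
    sequences = {contig: main_seq}
    if bank_parts:
        sequences["chrDupBank"] = "".join(bank_parts)
    genome = ReferenceGenome(sequences)

    repeats = IntervalSet(
        (contig, pos - config.repeat_halfwidth, pos + config.repeat_halfwidth)
        for pos in provisional[FATE_REPEAT]
    )

    index = KmerIndex(genome, k=screen_params.k)

    def flanks_clean_of(pos: int, check_hairpin: bool, check_unique: bool) -> bool:
        left, right = extract_flanks(genome, contig, pos, screen_params.flank)
        if check_hairpin:
            for flank in (left, right):
                if has_hairpin(flank, screen_params.min_stem, screen_params.min_loop):
                    return False
        if check_unique:
            for flank in (left, right):
                frac = kmer_uniqueness(index, flank)
                if frac is None or frac < screen_params.uniqueness_min:
                    return False
        return True

    slots: list[SNPSlot] = []
    verifiers = {
        # each fate must fire only its own screen; verify the others
        FATE_HAIRPIN: lambda p: flanks_clean_of(p, check_hairpin=False, check_unique=True),
        FATE_DUPLICATE: lambda p: flanks_clean_of(p, check_hairpin=True, check_unique=False),
        FATE_REPEAT: lambda p: flanks_clean_of(p, check_hairpin=True, check_unique=True),
        FATE_CLEAN: lambda p: flanks_clean_of(p, check_hairpin=True, check_unique=True),
    }
    counter = 0
    for fate, quota in quotas.items():
        accepted = [p for p in provisional[fate] if verifiers[fate](p)][:quota]
        if len(accepted) < quota:
            raise RuntimeError(
                f"could only verify {len(accepted)}/{quota} {fate} slots; "
                "increase contig_length or spares"
            )
        for pos in accepted:
            slots.append(SNPSlot(snp_id=f"snp{counter:04d}", contig=contig, pos0=pos, fate=fate))
            counter += 1
    slots.sort(key=lambda s: s.pos0)
    slots = [
        SNPSlot(snp_id=f"snp{i:04d}", contig=s.contig, pos0=s.pos0, fate=s.fate)
        for i, s in enumerate(slots)
    ]
    return genome, repeats, GenomeTruth(
        slots=slots, hairpin_loci=hairpin_loci, duplicated_segments=duplicated
    )


_INFO_PASS_RANGES = {
    "QD": (15.0, 35.0),
    "FS": (0.0, 10.0),
    "MQ": (50.0, 60.0),
    "MQRankSum": (-2.0, 2.0),
    "ReadPosRankSum": (-2.0, 2.0),
}
_INFO_FAIL_RANGES = {
    "QD": (0.1, 1.9),
    "FS": (61.0, 200.0),
    "MQ": (10.0, 39.0),
    "MQRankSum": (-20.0, -13.0),
    "ReadPosRankSum": (-12.0, -8.5),
}

_ALT_OF = {"A": "G", "C": "T", "G": "A", "T": "C"}


def make_cohort_vcf(
    genome: ReferenceGenome,
    truth: GenomeTruth,
    config: SyntheticConfig,
) -> tuple[list[VariantRecord], pd.DataFrame]:
    """Cohort genotypes at the planted slots, HWE-binomial at a true MAF,
    with missingness, Poisson per-sample depths, and INFO metrics planted
    to violate one hard-filter clause on the designated clean-slot sites.

    Returns the records and a truth table (snp_id, contig, pos0, fate,
    info_fate, true_maf).
    """
    rng = config.rng(2)
    clean_ids = [s.snp_id for s in truth.slots_by_fate(FATE_CLEAN)]
    n_violating = config.n_per_clause * len(HARD_FILTER_CLAUSES)
    if n_violating > len(clean_ids):
        raise ValueError("not enough clean slots to host the hard-filter plants")
    shuffled = list(clean_ids)
    rng.shuffle(shuffled)
    info_fate = {sid: INFO_PASS for s in truth.slots for sid in [s.snp_id]}
    k = 0
    for clause in HARD_FILTER_CLAUSES:
        for _ in range(config.n_per_clause):
            info_fate[shuffled[k]] = clause
            k += 1

    records: list[VariantRecord] = []
    rows = []
    lo_maf, hi_maf = config.maf_range
    for slot in truth.slots:
        ref = genome.fetch(slot.contig, slot.pos0, slot.pos0 + 1)
        alt = _ALT_OF[ref]
        p = float(rng.uniform(lo_maf, hi_maf))
        alt_counts = rng.binomial(2, p, size=config.n_samples)
        genotypes = np.array(
            [(HOM_REF, HET, HOM_ALT)[c] for c in alt_counts], dtype=np.int8
        )
        miss = rng.random(config.n_samples) < config.missing_rate
        genotypes[miss] = MISSING
        depths = rng.poisson(config.mean_sample_depth, size=config.n_samples).astype(np.int32)
        info: dict[str, float] = {"DP": float(depths.sum())}
        fate = info_fate[slot.snp_id]
        for key in HARD_FILTER_CLAUSES:
            lo, hi = (_INFO_FAIL_RANGES if key == fate else _INFO_PASS_RANGES)[key]
            info[key] = float(np.round(rng.uniform(lo, hi), 3))
        records.append(
            VariantRecord(
                contig=slot.contig,
                pos1=slot.pos0 + 1,
                ref_allele=ref,
                alt_alleles=(alt,),
                info=info,
                genotypes=genotypes,
                sample_depths=depths,
                id=slot.snp_id,
            )
        )
        rows.append(
            {
                "snp_id": slot.snp_id,
                "contig": slot.contig,
                "pos0": slot.pos0,
                "fate": slot.fate,
                "info_fate": fate,
                "true_maf": p,
            }
        )
    return records, pd.DataFrame(rows)


def simulate_genotypes(
    true_maf: float, n_samples: int, rng: np.random.Generator
) -> np.ndarray:
    """HWE-binomial diploid genotype codes at a given alt-allele frequency."""
    alt_counts = rng.binomial(2, true_maf, size=n_samples)
    return np.array([(HOM_REF, HET, HOM_ALT)[c] for c in alt_counts], dtype=np.int8)


def make_capture_reads(
    genome: ReferenceGenome,
    targets: Sequence[tuple[str, int]],
    config: SyntheticConfig,
) -> tuple[list[AlignedRead], pd.DataFrame]:
    """Single-end reads: on-target reads placed by a Gaussian kernel
    centered on target SNPs, background reads uniform over the genome;
    duplicate/low-quality/N-rich reads planted at configured rates.

    Returns reads plus a per-read truth table (read name, origin target
    index or -1 for background, planted defect)."""
    if config.on_target_fraction > 0 and not targets:
        raise ValueError("on-target fraction set but no targets supplied")
    rng = config.rng(3)
    contigs = list(genome.sequences)
    lengths = genome.lengths
    total_len = sum(lengths.values())
    contig_probs = np.array([lengths[c] / total_len for c in contigs])
    read_len = config.read_len
    n_on = int(round(config.n_reads * config.on_target_fraction))
    reads: list[AlignedRead] = []
    rows = []
    for i in range(config.n_reads):
        if i < n_on:
            t_idx = int(rng.integers(len(targets)))
            contig, pos = targets[t_idx]
            center = rng.normal(pos, config.kernel_sd)
            start = int(round(center)) - read_len // 2
            origin = t_idx
        else:
            contig = contigs[int(rng.choice(len(contigs), p=contig_probs))]
            start = int(rng.integers(0, max(1, lengths[contig] - read_len)))
            origin = -1
        start = min(max(0, start), lengths[contig] - read_len)
        seq = genome.fetch(contig, start, start + read_len)
        quals = np.full(read_len, config.base_quality, dtype=np.int16)
        defect = "none"
        u = rng.random()
        if u < config.n_read_rate:
            defect = "n_rich"
            n_count = int(np.ceil(read_len * 0.12))
            seq = "N" * n_count + seq[n_count:]
        elif u < config.n_read_rate + config.lowq_read_rate:
            defect = "low_quality"
            quals[: int(np.ceil(read_len * 0.5))] = 2
        duplicate = bool(rng.random() < config.dup_read_rate)
        if duplicate:
            defect = "duplicate" if defect == "none" else defect
        mapq = 0 if rng.random() < config.multimap_rate else 60
        if config.gc_bias is not None:
            gc = (seq.count("G") + seq.count("C")) / read_len
            if rng.random() > config.gc_bias(gc):
                continue
        reads.append(
            AlignedRead(
                name=f"read{i:07d}",
                sequence=seq,
                qualities=quals,
                mapped=True,
                contig=contig,
                pos0=start,
                mapq=mapq,
                duplicate=duplicate,
                unique=mapq >= 30,
            )
        )
        rows.append({"read": f"read{i:07d}", "origin": origin, "defect": defect})
    return reads, pd.DataFrame(rows)


def emit_fixture(config: SyntheticConfig, out_dir: str | Path) -> dict[str, Path]:
    """Write the full fixture set (FASTA, BED, VCF, SAM, truth TSVs)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genome, repeats, truth = make_genome(config)
    records, snp_truth = make_cohort_vcf(genome, truth, config)
    targets = [(s.contig, s.pos0) for s in truth.slots_by_fate(FATE_CLEAN)]
    reads, read_truth = make_capture_reads(genome, targets, config)
    paths = {
        "genome": out / "genome.fa",
        "repeats": out / "repeats.bed",
        "vcf": out / "cohort.vcf",
        "targets": out / "targets.bed",
        "sam": out / "reads.sam",
        "snp_truth": out / "snp_truth.tsv",
        "read_truth": out / "read_truth.tsv",
    }
    write_fasta(genome, paths["genome"])
    write_bed(repeats, paths["repeats"])
    samples = [f"goat{i:03d}" for i in range(config.n_samples)]
    write_vcf(records, genome.lengths, samples, paths["vcf"])
    write_bed(((c, p, p + 1) for c, p in targets), paths["targets"])
    write_sam(reads, genome.lengths, paths["sam"])
    snp_truth.to_csv(paths["snp_truth"], sep="\t", index=False)
    read_truth.to_csv(paths["read_truth"], sep="\t", index=False)
    return paths
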