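"""Cohort SNP filtering: hard-filter expression, depth/missingness rules,
and generic MAF/HWE screens.

The hard filter mirrors GATK VariantFiltration semantics: a site fails if
ANY clause of the OR-expression triggers on a *present* INFO key; absent
keys never trigger. All comparisons are strict, so boundary values
(QD=2.0, FS=60.0, MQ=40.0, ...) pass.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .formats import HET, HOM_ALT, HOM_REF, MISSING, VariantRecord

# Machine-readable rejection reason codes, in fixed first-failure priority.
NOT_BIALLELIC = "NOT_BIALLELIC"
HARD_FILTER = "HARD_FILTER"
DEPTH_RANGE = "DEPTH_RANGE"
DEPTH_UNKNOWN = "DEPTH_UNKNOWN"
MISSINGNESS = "MISSINGNESS"
LOW_DEPTH_SAMPLES = "LOW_DEPTH_SAMPLES"
MAF = "MAF"
HWE = "HWE"

REASON_PRIORITY = (
    NOT_BIALLELIC,
    HARD_FILTER,
    DEPTH_RANGE,
    DEPTH_UNKNOWN,
    MISSINGNESS,
    LOW_DEPTH_SAMPLES,
    MAF,
    HWE,
)


@dataclass(frozen=True)
class FilterThresholds:
    """All site-filter thresholds; defaults are the chip-design values.

    ``hard_filter_clauses`` maps INFO key -> (op, threshold) where op is
    "<" or ">"; a present key failing its comparison rejects the site.
    ``missingness_mode`` controls how the missing-rate and low-depth
    clauses combine into an exclusion: "any" (either alone excludes,
    default) or "both" (both must trigger).
    """

    hard_filter_clauses: tuple[tuple[str, str, float], ...] = (
        ("QD", "<", 2.0),
        ("FS", ">", 60.0),
        ("MQ", "<", 40.0),
        ("MQRankSum", "<", -12.5),
        ("ReadPosRankSum", "<", -8.0),
    )
    site_depth_range: tuple[float, float] = (80, 1000)
    max_missing_rate: float = 0.20
    low_depth_cutoff: int = 2
    max_lowdepth_fraction: float = 0.20
    missingness_mode: str = "any"
    maf_min: float | None = None
    hwe_p_min: float | None = None

    def __post_init__(self) -> None:
        lo, hi = self.site_depth_range
        if lo > hi:
            raise ValueError("site depth range lower bound exceeds upper bound")
        if self.missingness_mode not in ("any", "both"):
            raise ValueError("missingness_mode must be 'any' or 'both'")

    def with_(self, **kwargs) -> "FilterThresholds":
        return replace(self, **kwargs)

    @classmethod
    def disabled(cls) -> "FilterThresholds":
        """Identity configuration: only the biallelic-SNP requirement remains."""
        return cls(
            hard_filter_clauses=(),
            site_depth_range=(float("-inf"), float("inf")),
            max_missing_rate=1.0,
            max_lowdepth_fraction=1.0,
        )


#: GWA-side variant hard filter (different GATK expression, same machinery).
GWA_HARD_FILTER_CLAUSES = (
    ("QD", "<", 4.0),
    ("MQ", "<", 40.0),
    ("ReadPosRankSum", "<", -8.0),
    ("FS", ">", 60.0),
    ("HaplotypeScore", ">", 13.0),
    ("MQRankSum", "<", -12.5),
)


@dataclass
class FilterVerdict:
    reasons: list[str] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not self.reasons


def apply_hard_filter(record: VariantRecord, t: FilterThresholds) -> FilterVerdict:
    """Evaluate the OR-of-clauses hard filter on present INFO keys."""
    for key, op, threshold in t.hard_filter_clauses:
        if key not in record.info:
            continue
        value = record.info[key]
        if (op == "<" and value < threshold) or (op == ">" and value > threshold):
            return FilterVerdict([HARD_FILTER])
    return FilterVerdict()


def site_depth(record: VariantRecord) -> float | None:
    """Site DP from INFO, falling back to the sum of sample depths."""
    if "DP" in record.info:
        return record.info["DP"]
    known = record.sample_depths[record.sample_depths >= 0]
    if known.size == 0:
        return None
    return float(known.sum())


def site_depth_filter(record: VariantRecord, t: FilterThresholds) -> FilterVerdict:
    """Fail when total depth is outside [lo, hi]; bounds are inclusive."""
    lo, hi = t.site_depth_range
    if lo == float("-inf") and hi == float("inf"):
        return FilterVerdict()
    dp = site_depth(record)
    if dp is None:
        return FilterVerdict([DEPTH_UNKNOWN])
    if dp < lo or dp > hi:
        return FilterVerdict([DEPTH_RANGE])
    return FilterVerdict()


def missingness_filter(record: VariantRecord, t: FilterThresholds) -> FilterVerdict:
    """Exclusion by missing-genotype rate and low-depth sample fraction.

    Each clause triggers when its fraction strictly exceeds its threshold;
    ``missingness_mode`` selects whether one trigger suffices ("any") or
    both are required ("both").
    """
    n = len(record.genotypes)
    if n == 0:
        raise ValueError("missingness filter requires at least one sample")
    missing_frac = float(np.mean(record.genotypes == MISSING))
    known_dp = record.sample_depths
    lowdepth_frac = float(np.mean((known_dp >= 0) & (known_dp < t.low_depth_cutoff)))
    miss_trigger = missing_frac > t.max_missing_rate
    low_trigger = lowdepth_frac > t.max_lowdepth_fraction
    if t.missingness_mode == "both":
        if miss_trigger and low_trigger:
            return FilterVerdict([MISSINGNESS, LOW_DEPTH_SAMPLES])
        return FilterVerdict()
    reasons = []
    if miss_trigger:
        reasons.append(MISSINGNESS)
    if low_trigger:
        reasons.append(LOW_DEPTH_SAMPLES)
    return FilterVerdict(reasons)


def compute_maf(genotypes: np.ndarray | Sequence[int]) -> float:
    """Folded minor allele frequency from diploid genotype codes.

    Missing genotypes are excluded from the denominator; the frequency is
    folded to min(f, 1-f) so the result lies in [0, 0.5].
    """
    g = np.asarray(genotypes)
    called = g[g != MISSING]
    if called.size == 0:
        raise ValueError("all genotypes missing; MAF undefined")
    alt_count = int(np.sum(called == HET)) + 2 * int(np.sum(called == HOM_ALT))
    freq = alt_count / (2 * called.size)
    return min(freq, 1.0 - freq)


def hwe_chisq(genotypes: np.ndarray | Sequence[int]) -> float:
    """1-df chi-square Hardy-Weinberg test p-value (no continuity correction).

    Expected het/hom counts come from the sample allele frequency;
    monomorphic sites return p = 1.0 by convention.
    """
    g = np.asarray(genotypes)
    called = g[g != MISSING]
    if called.size < 2:
        raise ValueError("HWE test requires at least two called genotypes")
    n_rr = int(np.sum(called == HOM_REF))
    n_ra = int(np.sum(called == HET))
    n_aa = int(np.sum(called == HOM_ALT))
    n = n_rr + n_ra + n_aa
    p = (2 * n_rr + n_ra) / (2 * n)
    q = 1.0 - p
    if p == 0.0 or q == 0.0:
        return 1.0
    expected = np.array([p * p * n, 2 * p * q * n, q * q * n])
    observed = np.array([n_rr, n_ra, n_aa], dtype=float)
    statistic = float(np.sum((observed - expected) ** 2 / expected))
    return float(stats.chi2.sf(statistic, df=1))


def site_verdict(record: VariantRecord, t: FilterThresholds) -> FilterVerdict:
    """Combined verdict over all enabled filters, reasons in priority order."""
    reasons: list[str] = []
    if not record.is_biallelic_snp:
        reasons.append(NOT_BIALLELIC)
    reasons.extend(apply_hard_filter(record, t).reasons)
    reasons.extend(site_depth_filter(record, t).reasons)
    if len(record.genotypes) > 0:
        reasons.extend(missingness_filter(record, t).reasons)
        called = record.genotypes[record.genotypes != MISSING]
        if record.is_biallelic_snp and called.size > 0:
            maf = compute_maf(record.genotypes)
            if t.maf_min is not None and maf < t.maf_min:
                reasons.append(MAF)
            if t.hwe_p_min is not None and called.size >= 2:
                if hwe_chisq(record.genotypes) < t.hwe_p_min:
                    reasons.append(HWE)
    reasons.sort(key=REASON_PRIORITY.index)
    return FilterVerdict(reasons)


@dataclass
class CohortFilterResult:
    """Survivors plus the per-reason first-failure rejection tally."""

    survivors: list[VariantRecord]
    tally: dict[str, int]
    n_input: int

    @property
    def n_rejected(self) -> int:
        return sum(self.tally.values())


def filter_cohort(
    records: Iterable[VariantRecord],
    thresholds: FilterThresholds,
) -> CohortFilterResult:
    """Reduce a cohort to biallelic SNPs passing all enabled filters.

    The tally assigns each rejected site to its highest-priority failing
    reason, so input count = survivors + sum(tally).
    """
    survivors: list[VariantRecord] = []
    tally: dict[str, int] = {reason: 0 for reason in REASON_PRIORITY}
    n_input = 0
    for record in records:
        n_input += 1
        verdict = site_verdict(record, thresholds)
        if verdict.passed:
            survivors.append(record)
        else:
            tally[verdict.reasons[0]] += 1
    tally = {reason: count for reason, count in tally.items() if count}
    return CohortFilterResult(survivors=survivors, tally=tally, n_input=n_input)
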