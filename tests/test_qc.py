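"""Read filters, on/off-target accounting, depth profiles, uniformity,
GC-depth binning, and concordance."""

import numpy as np
import pytest

from baitforge import qc
from baitforge.formats import AlignedRead, IntervalSet, ReferenceGenome
from baitforge.qc import (
    TargetRegion,
    classify_alignment_bases,
    coverage_uniformity,
    depth_arrays,
    depth_profile,
    filter_reads,
    gc_depth_table,
    per_target_depth,
    snp_concordance,
    target_interval_set,
)

from conftest import random_genome


def make_read(seq="ACGTACGTAA" * 5, quals=35, pos0=0, contig="c", mapped=True,
              dup=False, mapq=60, name="r"):
    q = None if quals is None else np.full(len(seq), quals, dtype=np.int16)
    return AlignedRead(
        name=name, sequence=seq, qualities=q, mapped=mapped,
        contig=contig if mapped else None, pos0=pos0 if mapped else None,
        mapq=mapq, duplicate=dup, unique=mapped and mapq >= 30,
    )


class TestFilterReads:
    def test_n_fraction_boundary(self):
        read_12pct = make_read("N" * 6 + "A" * 44)
        read_10pct = make_read("N" * 5 + "A" * 45)
        kept, tally = filter_reads([read_12pct, read_10pct])
        assert len(kept) == 1 and tally == {qc.N_FRACTION: 1}

    def test_low_quality_boundary(self):
        quals = np.array([10] * 20 + [35] * 30, dtype=np.int16)
        read_at = make_read("A" * 50)
        read_at.qualities = quals  # exactly 40% low: kept
        over = make_read("A" * 50)
        over.qualities = np.array([10] * 21 + [35] * 29, dtype=np.int16)
        kept, tally = filter_reads([read_at, over])
        assert len(kept) == 1 and tally == {qc.LOW_QUALITY: 1}

    def test_adapter_and_duplicate(self):
        adapter_read = make_read("AAGATCGGAAGAGC" + "A" * 36)
        dup_read = make_read(dup=True)
        kept, tally = filter_reads([adapter_read, dup_read], adapter="AGATCGGAAGAGC")
        assert kept == [] and tally == {qc.ADAPTER: 1, qc.DUPLICATE: 1}

    def test_missing_qualities_distinct_reason(self):
        kept, tally = filter_reads([make_read(quals=None)])
        assert kept == [] and tally == {qc.NO_QUALITIES: 1}

    def test_planted_tally_exact(self):
        rng = np.random.default_rng(0)
        reads, expected = [], {qc.N_FRACTION: 7, qc.LOW_QUALITY: 5, qc.DUPLICATE: 3}
        for i in range(7):
            reads.append(make_read("N" * 8 + "A" * 42, name=f"n{i}"))
        for i in range(5):
            r = make_read("A" * 50, name=f"q{i}")
            r.qualities = np.array([5] * 25 + [35] * 25, dtype=np.int16)
            reads.append(r)
        for i in range(3):
            reads.append(make_read(dup=True, name=f"d{i}"))
        for i in range(10):
            reads.append(make_read(name=f"ok{i}"))
        rng.shuffle(reads)
        kept, tally = filter_reads(reads)
        assert tally == expected and len(kept) == 10


class TestClassification:
    def test_read_inside_target_fully_on_flank(self):
        regions = IntervalSet([("c", 100, 701)])
        counts = classify_alignment_bases([make_read(pos0=300)], regions)
        assert counts.on_flank == 50 and counts.off_target == 0

    def test_unmapped_only_in_total(self):
        counts = classify_alignment_bases([make_read(mapped=False)], IntervalSet())
        assert counts.total == 50 and counts.aligned == 0

    def test_one_base_overlap_credits_whole_read(self):
        regions = IntervalSet([("c", 149, 300)])
        counts = classify_alignment_bases([make_read(pos0=100)], regions)  # [100,150)
        assert counts.on_flank == 50
        per_base = classify_alignment_bases([make_read(pos0=100)], regions, per_base=True)
        assert per_base.on_flank == 1 and per_base.off_target == 49

    def test_conservation(self):
        regions = IntervalSet([("c", 0, 200)])
        reads = [make_read(pos0=p) for p in (0, 100, 500)] + [make_read(mapped=False)]
        counts = classify_alignment_bases(reads, regions)
        assert counts.aligned == counts.on_flank + counts.off_target
        assert counts.total == counts.aligned + 50


class TestDepthProfile:
    def test_no_reads_zero_profile(self):
        depths = {"c": np.zeros(10_000, dtype=np.int64)}
        targets = [TargetRegion("t", "c", 5000)]
        profile = depth_profile(depths, targets)
        assert profile.mean_depth.sum() == 0.0
        assert len(profile.offsets) == 601

    def test_uniform_coverage_flat_profile(self):
        depths = {"c": np.full(10_000, 7, dtype=np.int64)}
        targets = [TargetRegion("t", "c", p) for p in (2000, 5000, 8000)]
        profile = depth_profile(depths, targets)
        np.testing.assert_allclose(profile.mean_depth, 7.0)

    def test_kernel_peak_at_zero(self):
        rng = np.random.default_rng(1)
        contig_len = 200_000
        targets = [TargetRegion(f"t{i}", "c", int(p))
                   for i, p in enumerate(rng.choice(np.arange(1000, 199_000), 20, replace=False))]
        reads = []
        for _ in range(20_000):
            t = targets[int(rng.integers(len(targets)))]
            start = int(round(rng.normal(t.pos0, 75))) - 25
            start = min(max(0, start), contig_len - 50)
            reads.append(make_read("A" * 50, pos0=start))
        depths = depth_arrays(reads, {"c": contig_len})
        profile = depth_profile(depths, targets)
        peak = profile.mean_depth.max()
        assert profile.at(0) >= 0.95 * peak
        assert profile.at(300) < 0.1 * peak and profile.at(-300) < 0.1 * peak

    def test_edge_target_partial_contribution(self):
        depths = {"c": np.full(1_000, 3, dtype=np.int64)}
        profile = depth_profile(depths, [TargetRegion("t", "c", 100)])
        assert profile.n_targets[0] == 0  # offset -300 off-contig
        assert profile.n_targets[-1] == 1


class TestPerTargetDepthAndUniformity:
    def test_snp_base_vs_region_mean(self):
        depth = np.zeros(1000, dtype=np.int64)
        depth[500] = 40
        depths = {"c": depth}
        targets = [TargetRegion("t", "c", 500)]
        assert per_target_depth(depths, targets, "snp")[0] == 40
        assert per_target_depth(depths, targets, "region")[0] == pytest.approx(40 / 601)

    def test_equal_depths_all_fractions_one(self):
        stats = coverage_uniformity(np.full(10, 12.0))
        assert stats.fraction_ge[0.4] == 1.0 and stats.fraction_ge[0.8] == 1.0

    def test_worked_example(self):
        stats = coverage_uniformity(np.array([0.0, 10.0, 10.0, 20.0]))
        assert stats.mean_depth == 10.0
        assert stats.fraction_ge[0.4] == 0.75
        assert stats.fraction_ge[0.8] == 0.75

    def test_fractions_non_increasing_in_threshold(self):
        rng = np.random.default_rng(2)
        depths = rng.exponential(30, size=500)
        stats = coverage_uniformity(depths, thresholds=(0.2, 0.4, 0.8, 1.2))
        values = [stats.fraction_ge[t] for t in (0.2, 0.4, 0.8, 1.2)]
        assert values == sorted(values, reverse=True)
        for t in (0.2, 0.4, 0.8, 1.2):
            assert stats.fraction_ge[t] == pytest.approx(
                float(np.mean(depths / depths.mean() >= t))
            )

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError):
            coverage_uniformity(np.zeros(5))


class TestGcDepth:
    def test_two_regions_two_bins(self):
        genome = ReferenceGenome(
            {"c": "AT" * 400 + "GC" * 400}  # GC 0 region and GC 1 region
        )
        targets = [TargetRegion("a", "c", 350), TargetRegion("b", "c", 1250)]
        table = gc_depth_table(targets, genome, np.array([10.0, 30.0]))
        low = table[table["gc_bin"] == "0%-30%"].iloc[0]
        high = table[table["gc_bin"] == "70%-100%"].iloc[0]
        assert low["mean_depth"] == 10.0 and high["mean_depth"] == 30.0

    def test_planted_gc_bias_ordering_recovered(self):
        rng = np.random.default_rng(3)
        genome = random_genome(rng, {"c": 100_000})
        targets = [TargetRegion(f"t{i}", "c", int(p))
                   for i, p in enumerate(range(1000, 99_000, 2000))]
        gcs = []
        for t in targets:
            s, e = t.interval(100_000)
            seq = genome.fetch("c", s, e)
            gcs.append((seq.count("G") + seq.count("C")) / len(seq))
        depths = np.array([100 * g + rng.normal(0, 0.5) for g in gcs])
        table = gc_depth_table(targets, genome, depths, bins=[0.48, 0.52])
        occupied = table[table["n_regions"] > 0]
        means = occupied["mean_depth"].to_numpy()
        assert (np.diff(means) > 0).all()  # higher-GC bins planted deeper

    def test_single_bin_occupied(self):
        genome = ReferenceGenome({"c": "ACGT" * 500})
        targets = [TargetRegion("a", "c", 600), TargetRegion("b", "c", 1200)]
        table = gc_depth_table(targets, genome, np.array([5.0, 15.0]))
        assert (table["n_regions"] > 0).sum() == 1


class TestConcordance:
    def test_identical_sets(self):
        a = {("c", 1, "G"), ("c", 5, "T")}
        result = snp_concordance(a, set(a))
        assert result.fraction_of_a == 1.0 and result.fraction_of_b == 1.0

    def test_disjoint_sets(self):
        result = snp_concordance({("c", 1, "G")}, {("c", 2, "T")})
        assert result.shared == 0 and result.fraction_of_a == 0.0

    def test_planted_overlap_recovered_exactly(self):
        rng = np.random.default_rng(4)
        shared = {("c", int(p), "G") for p in rng.choice(100_000, 800, replace=False)}
        only_a = {("c", int(p) + 200_000, "A") for p in rng.choice(50_000, 200, replace=False)}
        only_b = {("c", int(p) + 400_000, "T") for p in rng.choice(50_000, 200, replace=False)}
        result = snp_concordance(shared | only_a, shared | only_b)
        assert result.shared == len(shared)
        assert result.fraction_of_a == pytest.approx(len(shared) / (len(shared) + len(only_a)))


class TestTargetRegions:
    def test_edge_clipping(self):
        t = TargetRegion("t", "c", 100)
        assert t.interval(10_000) == (0, 401)
        t2 = TargetRegion("t2", "c", 9_900)
        assert t2.interval(10_000) == (9_600, 10_000)

    def test_interval_set_merges_overlapping_targets(self):
        targets = [TargetRegion("a", "c", 1000), TargetRegion("b", "c", 1200)]
        regions = target_interval_set(targets, {"c": 10_000})
        assert list(regions) == [("c", 700, 1501)]
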