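# Methods

## The design problem

A solution-hybrid-selection (SHS) SNP chip genotypes a fixed SNP panel
by capturing the fragments around each SNP with RNA baits transcribed
from a synthesized oligo library. Design quality has three axes: the
SNPs must be reliably callable in the design cohort, their local
sequence must hybridize cleanly (no self-folding baits, no ambiguous or
repetitive placements), and the panel must tile the genome at a roughly
even spacing. `baitforge` treats these as three successive filters over
a cohort callset, followed by a per-SNP bait-placement optimization and
a windowed density pass.

## Cohort filtering

Sites are evaluated with GATK `VariantFiltration` semantics: the
hard-filter expression is an OR over clauses on INFO annotations
(`QD < 2.0`, `FS > 60.0`, `MQ < 40.0`, `MQRankSum < −12.5`,
`ReadPosRankSum < −8.0` by default), each clause triggering only when
its key is present — an absent annotation never fails a site. All
comparisons are strict, so values exactly at a threshold pass. The
clause set is data, not code: the alternative expression used for
re-sequencing panels (`QD < 4.0 … HaplotypeScore > 13.0`) is shipped as
a second clause tuple, and any numeric INFO key can be filtered.

Depth bounds (site DP within [80, 1000], inclusive; the sum of
per-sample depths stands in when the site annotation is absent) and the
missingness rule complete the site filters. The missingness criterion
pairs two fractions — missing genotypes > 20%, and samples below 2×
depth > 20%. Written as an exclusion list these two clauses are most
naturally read as independent triggers, so the default mode `any`
excludes a site when either fires; the literal conjunctive reading is
preserved under `missingness_mode="both"`.

MAF is the folded alternate-allele frequency over called genotypes
(missing calls leave the denominator). The Hardy–Weinberg screen is a
1-df chi-square of observed genotype counts against p², 2pq, q² at the
sample allele frequency, without continuity correction; monomorphic
sites return p = 1 by convention. An exact test would be preferable for
very small cohorts but is not needed at the cohort sizes the filter
targets (≳ 50 diploids).

Rejected sites are tallied by their highest-priority failing reason
(biallelic → hard filter → depth → missingness → MAF → HWE), so the
funnel conserves counts: input = survivors + Σ tally.

## Flank screens

Screens operate on the 150-bp flanks on either side of the SNP (the
SNP base itself excluded); a flank truncated by a contig edge excludes
the SNP outright.

**Hairpin.** A hairpin is modeled as two exact reverse-complement arms
of ≥ 9 bp ("longer than 8 bp") separated by ≥ 3 intervening bases. N
pairs with nothing. Detection is an O(n²) dynamic program: the pairing
run length ending at each inner base pair (i, j) extends the run of its
outer neighbor (i−1, j+1), and any cell with run ≥ 9 and loop ≥ 3 is a
hit; the reported hit is the longest such stem. Mismatches, bulges and
thermodynamic folding are deliberately out of scope — the screen is a
sequence-level guard, not a folding model — and both parameters are
configurable.

**Uniqueness.** The reference is indexed by canonical
(strand-collapsed) 30-mer multiplicity; a flank's uniqueness is the
fraction of its N-free 30-mers occurring exactly once genome-wide, and
a flank passes at ≥ 0.95. This is a deterministic, self-contained
surrogate for alignment-based mappability screens; k and the threshold
are configurable. A flank with no evaluable k-mer (e.g. all N) fails
conservatively.

**Repeats.** Repeat annotation is an input BED (its production, e.g.
by RepeatMasker, is upstream of this package); a SNP is excluded when
its own base lies inside an interval, half-open semantics.

## Probe design

Each probe is `ARM_A + bait(90 bp) + ARM_B`, a 120-mer with fixed
15-bp PCR arms. Bait enumeration slides all 90 start positions covering
the SNP; every placement keeps the SNP within 45 bp of the bait center,
inside the stated 50-bp limit. A bait is viable when its GC is within
[30%, 70%] (inclusive; N-containing baits are non-viable), and it
contains no ≥ 9-bp stem hairpin.

"Best" placement is underdetermined by the stated geometry ("about
20 bp away"), so the ranking key is made total and deterministic:
primary |(|center offset|) − 20|, secondary |GC − 0.5|, tertiary
leftmost start. The top `n_select ∈ {2, 3}` viable baits are ordered at
one copy. SNPs with < 2 viable baits are dropped, with one rescue read
literally from the doubling rule: when exactly two baits pass
GC/placement and exactly one is hairpin-flagged, the other is ordered
at two copies. A selected bait covering ≥ 2 panel SNPs also has its
copy count doubled. Baits are designed on the forward strand only
(capture hybridization is strand-agnostic); copy counts only ever
increase.

## Density thinning

Windows of W = 40,000 bp tile each contig from coordinate 0,
non-overlapping; the terminal window is clipped and uses its true width
in the score. Each SNP's score is
`MAF · (E−S) · (1 − |a − (E−S)/2| / ((E−S)/2))` with `a = pos − S` —
the offset interpretation is forced by dimensional consistency (it
makes the triangular weight span exactly [0, 1]). Thinning keeps the
`max_per_window` (default 1) top-scoring SNPs per window, ties broken
toward the window center and then the lower coordinate; a uniform cap
stands in for the unstated "SNP-dense region" trigger and covers both
readings. Externally mandated SNPs enter as a whitelist exempt from
thinning, de-duplicated by position. Spacing QC reports each kept SNP's
distance to its nearest same-contig neighbor and the fraction within
[15 kb, 70 kb]; single-SNP contigs are counted separately.

## Capture QC

Reads are dropped when > 10% of bases are N, > 40% of bases have
quality ≤ 10, an adapter substring occurs, or the SAM duplicate flag is
set (reads without quality strings are dropped under a distinct
reason). Target regions are the ±300-bp windows around panel SNPs,
merged for overlap queries. Base accounting is read-level by default —
a read overlapping a target region by one base credits all its bases
on-flank, matching how capture reports tabulate megabases by read
class — with a per-base intersection mode behind a flag. "Uniquely
aligned" is MAPQ ≥ 30 (configurable); the term is conventionally left
criterion-free in capture reports, so the threshold is explicit here.
Per-target depth is the depth at the SNP base itself (region-mean mode
by flag), duplicates excluded. Uniformity is the fraction of targets at
≥ 0.4× and ≥ 0.8× of the mean per-target depth; GC bias is the mean
depth per region-GC bin (edges 30/50/70% by default, extended to [0,1]
so nothing overflows); concordance between two callsets is set
intersection on (contig, position, alt).

## Synthetic data

The generator emulates the study shape the pipeline is built for: one
random-background contig (default 300 kb, uniform base composition,
GC adjustable), a 73-sample design cohort, and 50-bp single-end capture
reads. Its plants are *verified*, not merely sampled: SNP slots are
laid on anchors ≥ 1 kb apart, each fate is planted structurally
(an exact stem-loop written into the left flank; a 321-bp segment
spanning both flanks copied verbatim into a bank contig; an annotated
repeat interval; clean background), and every slot is then checked
against the package's own screens — with spare anchors absorbing chance
failures such as an incidental hairpin arising in a random flank — so
the truth table is exact by construction, for any seed. Hard-filter
violations are planted per clause into INFO fields of clean-position
sites only, keeping the per-stage rejection tallies disjoint.
Duplications used to break flank uniqueness are deliberately *not*
written to the repeat BED (and repeat intervals carry ordinary
background sequence): conflating them would double-flag SNPs and make
the per-screen tallies ambiguous.

Genotypes are HWE-binomial at a true MAF drawn uniformly from
[0.05, 0.5]; missingness is i.i.d. (default 3%); per-sample depths are
Poisson (mean 6, so 73-sample site depth ≈ 440, inside the depth
filter's band). Capture reads are placed by a Gaussian kernel
(s.d. 75 bp) centered on their target — chosen so that expected
coverage at ±300 bp is < 1% of peak, reproducing the sharp enrichment
decay of real capture data — against a uniform background; on-target
fraction defaults to 0.56. Defects (N-rich, low-quality, duplicate,
multi-mapping reads) and a GC-bias thinning curve are planted at
configurable rates, default 0. The generator does not model sequencing
errors, indels, quality decay along the read, paired ends, or realistic
repeat families; passing tests therefore demonstrate the correctness of
the accounting and selection logic under idealized reads, not
robustness to platform artifacts.

## Numerical and scale choices

All internal coordinates are 0-based half-open; 1-based only at the
VCF boundary. Selection and thinning are fully deterministic (total
tie-break keys), so identical inputs give byte-identical probe orders.
Problem sizes in the tests and the acceptance script — a 200-SNP
planted funnel, 10,000 SNPs thinned over 10 Mb, and 100,000 reads over
a 5-Mb genome — are chosen as the smallest scales at which every
statistical check has comfortable margin (binomial noise on recovered
fractions ≤ 0.5% absolute), keeping the full battery under a minute.

One discretization note: with 50-bp reads placed by a 75-bp-s.d.
kernel, the expected depth profile around a target is the kernel
convolved with a read-length box — a near-flat plateau about one read
long centered on the SNP. The profile's exact argmax therefore wanders
within that plateau at any realistic read count, while the profile
value at offset 0 stays within a fraction of a percent of the maximum.
The unimodality checks accordingly assert the mode of the smoothed
profile within ±10 bp of the SNP, the offset-0 depth at ≥ 99% of peak,
monotone decay toward both edges, and edge depth < 10% of peak.

## Known limitations

- The hairpin model is exact-complement; G·U wobble or near-complement
  stems that fold in practice are not flagged.
- k-mer uniqueness approximates mappability; paralogs diverged beyond
  the exact-30-mer horizon are invisible to it.
- The 94 K sub-library split of a synthesized order is round-robin and
  makes no fidelity claim, the assignment rule being unspecified.
- Capture QC consumes headered SAM; BAM/CRAM should be converted
  upstream (`samtools view -h`).
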