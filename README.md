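# baitforge

Design toolkit for solution-hybrid-selection (SHS) target-enrichment SNP
chips, built for medium-density genotyping in livestock and other
non-model species. An SHS chip genotypes tens of thousands of SNPs by
capturing their surrounding genomic fragments with biotinylated RNA
baits before sequencing; the quality of the chip is decided almost
entirely at the design desk, by which SNPs are chosen and how the bait
oligos are placed.

`baitforge` implements that design pipeline end to end, plus the
sequencing-side QC used to evaluate a finished capture run:

1. **Cohort variant filtering** — reduce a joint-called cohort VCF to
   reliable biallelic SNPs with the GATK-style hard-filter expression
   `QD < 2.0 || FS > 60.0 || MQ < 40.0 || MQRankSum < −12.5 ||
   ReadPosRankSum < −8.0` (absent keys never trigger), total-depth
   bounds 80–1000, ≤ 20% missing genotypes, ≤ 20% of samples below 2×
   depth, and optional MAF/HWE screens.
2. **Flank screening** — a SNP is kept only if neither 150-bp flank can
   fold into a hairpin with a stem longer than 8 bp, both flanks are
   unique in the reference (canonical 30-mer multiplicity), and the SNP
   is outside annotated repeats.
3. **Probe design** — each probe is a 120-bp oligo: a 90-bp
   target-specific bait between two fixed 15-bp PCR primer arms
   (5′-GAAGCGAGGATCAAC-[N90]-CATTGCGTGAACCGA-3′). Baits must hold the
   SNP within 50 bp of the bait center and have 30–70% GC; per SNP the
   two (or three) hairpin-free baits whose centers sit closest to 20 bp
   from the SNP are ordered. SNPs with fewer than two viable baits are
   dropped, except that when exactly one of only two placeable baits is
   hairpin-flagged the other is ordered at double copy; baits covering
   two SNPs are also doubled.
4. **Density thinning** — chip density is evened out over consecutive
   40-kb windows using the ranking score

   `score = MAF · (E−S) · (1 − |a − (E−S)/2| / ((E−S)/2))`

   with `[S, E)` the SNP's window and `a` its offset inside it: a
   triangular weight that prefers common, centrally placed SNPs. Only
   the top-scoring SNP(s) per window are kept; nearest-neighbor spacing
   statistics report the fraction of SNPs 15–70 kb from their closest
   neighbor.
5. **Capture QC** — read filters (>10% N, >40% bases at quality ≤ 10,
   adapter, PCR duplicates), on-/off-target base accounting against
   ±300-bp target regions, base-by-base depth profiles around target
   SNPs, coverage-uniformity fractions at 0.4×/0.8× of mean depth,
   GC-vs-depth binning, and cross-platform SNP concordance.

A deterministic synthetic-data module generates genomes with planted
hairpins, duplications and repeat annotations, cohort VCFs with planted
filter violations, and kernel-placed capture reads — with exact truth
tables, so the whole pipeline is testable without any external data.

## Worked example

Run the full funnel on a seeded synthetic fixture (200 cohort SNPs with
planted defects):

```python
from baitforge.synthetic import SyntheticConfig, make_genome, make_cohort_vcf
from baitforge.filters import FilterThresholds, filter_cohort
from baitforge.screen import screen_candidates
from baitforge.probes import design_all

cfg = SyntheticConfig(seed=1)
genome, repeats, truth = make_genome(cfg)
records, _ = make_cohort_vcf(genome, truth, cfg)

filt = filter_cohort(records, FilterThresholds())
print("sites in:", filt.n_input, "| rejected:", filt.tally, "| pass:", len(filt.survivors))
scr = screen_candidates(filt.survivors, genome, repeats)
print("screen flags:", scr.tally, "| pass:", len(scr.survivors))
des = design_all(scr.survivors, genome)
print("design:", des.tally, "| oligos:", len(des.oligos))
```

prints

```
sites in: 200 | rejected: {'HARD_FILTER': 50} | pass: 150
screen flags: {'HAIRPIN': 30, 'NON_UNIQUE': 20, 'REPEAT': 10} | pass: 90
design: {'designed': 90} | oligos: 180
```

The 50 sites planted to violate one hard-filter clause each (10 per
clause) are rejected at stage one; the 30 hairpin-flank, 20
duplicated-flank and 10 in-repeat SNPs fall to the flank screens; all
90 clean SNPs receive two 120-bp probes each. The same stages are
available from the shell as `baitforge simulate | filter | screen |
design | thin | qc`, or chained with `baitforge run --config
pipeline.yaml`.

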