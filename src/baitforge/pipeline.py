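"""End-to-end chip-design pipeline: cohort filter -> flank screens ->
probe design -> window thinning, with a funnel report of survivors per
stage."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd

from . import density, formats, probes, screen
from .filters import FilterThresholds, filter_cohort


@dataclass
class PipelineConfig:
    """Per-stage parameter blocks plus input/output paths.

    Defaults are the chip-design values: hard filter 2.0/60.0/40.0/
    -12.5/-8.0, depth 80-1000, 20% missingness, 150-bp flanks, 9-bp
    stems, 90-bp baits in 120-bp oligos, 30-70% GC, 50/20-bp placement,
    40-kb windows.
    """

    fasta: str = ""
    vcf: str = ""
    repeats: str = ""
    whitelist: str | None = None
    out_dir: str = "."
    thresholds: FilterThresholds = field(default_factory=FilterThresholds)
    screen_params: screen.ScreenParams = field(default_factory=screen.ScreenParams)
    design_params: probes.DesignParams = field(default_factory=probes.DesignParams)
    window: int = density.DEFAULT_WINDOW
    max_per_window: int = 1

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "PipelineConfig":
        known = {
            "fasta", "vcf", "repeats", "whitelist", "out_dir",
            "thresholds", "screen_params", "design_params",
            "window", "max_per_window",
        }
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(data)
        if "thresholds" in kwargs:
            t = dict(kwargs["thresholds"])
            if "hard_filter_clauses" in t:
                t["hard_filter_clauses"] = tuple(tuple(c) for c in t["hard_filter_clauses"])
            if "site_depth_range" in t:
                t["site_depth_range"] = tuple(t["site_depth_range"])
            kwargs["thresholds"] = FilterThresholds(**t)
        if "screen_params" in kwargs:
            kwargs["screen_params"] = screen.ScreenParams(**kwargs["screen_params"])
        if "design_params" in kwargs:
            d = dict(kwargs["design_params"])
            if "gc_range" in d:
                d["gc_range"] = tuple(d["gc_range"])
            kwargs["design_params"] = probes.DesignParams(**d)
        return cls(**kwargs)


@dataclass
class FunnelReport:
    n_input: int
    n_post_filter: int
    n_post_screen: int
    n_designed: int
    n_kept: int
    n_final: int
    filter_tally: dict[str, int]
    screen_tally: dict[str, int]
    design_tally: dict[str, int]
    spacing_fraction_in_band: float

    def as_dict(self) -> dict[str, Any]:
        return asdict(self)


def run_pipeline(config: PipelineConfig) -> FunnelReport:
    """Run filter -> screen -> design -> thin on files and write the
    probe order, kept-SNP table and funnel report under ``out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genome = formats.read_fasta(config.fasta)
    repeats = formats.read_bed(config.repeats) if config.repeats else formats.IntervalSet()

    filt = filter_cohort(formats.read_vcf(config.vcf), config.thresholds)
    scr = screen.screen_candidates(
        filt.survivors, genome, repeats, config.screen_params
    )
    design = probes.design_all(scr.survivors, genome, config.design_params)
    designed_ids = {o.snp_id for o in design.oligos}
    designed_snps = [s for s in scr.survivors if s.id in designed_ids]

    windows = density.assign_windows(designed_snps, genome.lengths, config.window)
    kept = density.thin_windows(windows, config.max_per_window)
    if config.whitelist:
        extra = _read_whitelist(config.whitelist)
        final = density.merge_whitelist(kept, extra)
    else:
        final = kept
    spacing = density.spacing_stats(final)

    kept_ids = {s.id for s in final}
    final_oligos = [o for o in design.oligos if o.snp_id in kept_ids]
    formats.write_probe_order(final_oligos, out / "probe_order.tsv", out / "probes.fa")
    pd.DataFrame(
        [
            {"snp_id": s.id, "contig": s.contig, "pos0": s.pos0, "maf": s.maf}
            for s in final
        ]
    ).to_csv(out / "final_snps.tsv", sep="\t", index=False)

    report = FunnelReport(
        n_input=filt.n_input,
        n_post_filter=len(filt.survivors),
        n_post_screen=len(scr.survivors),
        n_designed=len(designed_snps),
        n_kept=len(kept),
        n_final=len(final),
        filter_tally=filt.tally,
        screen_tally=scr.tally,
        design_tally=design.tally,
        spacing_fraction_in_band=spacing.fraction_in_band,
    )
    (out / "funnel.json").write_text(json.dumps(report.as_dict(), indent=2) + "\n")
    return report


def _read_whitelist(path: str) -> list[screen.CandidateSNP]:
    frame = pd.read_csv(path, sep="\t")
    return [
        screen.CandidateSNP(
            id=str(row.get("snp_id", f"wl{i}")),
            contig=str(row["contig"]),
            pos0=int(row["pos0"]),
            ref_allele=str(row.get("ref", "N")),
            alt_allele=str(row.get("alt", "N")),
            maf=float(row.get("maf", 0.0)),
        )
        for i, row in frame.iterrows()
    ]
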