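"""End-to-end pipeline: simulate -> scan -> XP-EHH -> CCR -> divergence.

A single config drives every stage; all thresholds that define the
analysis (window of 9 SNPs, 0.5% empirical tails, 0.150-Mb grouping
gap, P < 0.001 haplotype significance, |D| > 0.7 divergence cut, the
five variant hard filters) are named keys with the standard analysis
values as defaults.  A config + seed pair reproduces every output.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .ccr import ConvergenceRegion, call_ccr, regions_to_frame
from .divergence import (apply_bonferroni, allelic_chisq,
                         classify_divergence, filter_variants, read_vcf,
                         restrict_to_regions, write_association_tsv)
from .geno_io import intervals_to_bed, polarize_haplotypes, write_plink_pedmap, \
    write_population_labels
from .sweep_scan import ScanConfig, scan_statistic, signals_to_frame
from .synthetic_data import (SimulationConfig, plant_sweeps,
                             simulate_variant_region, write_haplotypes_tsv,
                             write_vcf)
from .xpehh import EhhConfig, xpehh_scan, xpehh_signals

log = logging.getLogger(__name__)


@dataclass
class DivergenceConfig:
    n_variants_per_region: int = 400
    n_divergent_per_region: int = 4
    d_planted: float = 0.9
    n_a: int = 15
    n_b: int = 13
    alpha: float = 0.05
    d_cut: float = 0.7


@dataclass
class PipelineConfig:
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    scan: ScanConfig = field(default_factory=ScanConfig)
    ehh: EhhConfig = field(default_factory=EhhConfig)
    div: DivergenceConfig = field(default_factory=DivergenceConfig)
    n_sweeps: int = 5
    carrier_fraction: float = 0.9
    span_bp: int = 500_000
    out_dir: str = "sweepscan_run"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(sim=SimulationConfig(**raw.get("sim", {})),
                   scan=ScanConfig(**raw.get("scan", {})),
                   ehh=EhhConfig(**raw.get("ehh", {})),
                   div=DivergenceConfig(**raw.get("div", {})),
                   **{k: v for k, v in raw.items()
                      if k in ("n_sweeps", "carrier_fraction", "span_bp",
                               "out_dir")})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({"sim": asdict(self.sim),
                            "scan": asdict(self.scan),
                            "ehh": asdict(self.ehh),
                            "div": asdict(self.div),
                            "n_sweeps": self.n_sweeps,
                            "carrier_fraction": self.carrier_fraction,
                            "span_bp": self.span_bp,
                            "out_dir": self.out_dir}, fh, sort_keys=False)


@dataclass
class RunReport:
    seed: int = 0
    version: str = __version__
    n_markers: int = 0
    n_samples: int = 0
    n_windows: dict = field(default_factory=dict)
    n_flagged: dict = field(default_factory=dict)
    thresholds: dict = field(default_factory=dict)
    n_signals: dict = field(default_factory=dict)
    n_ccr: int = 0
    ccr_directions: dict = field(default_factory=dict)
    n_variants_raw: int = 0
    n_variants_filtered: int = 0
    n_variants_tested: int = 0
    n_bonferroni_significant: int = 0
    n_divergent: int = 0
    bonferroni_threshold: float = float("nan")
    bonferroni_log10: float = float("nan")

    def validate(self) -> None:
        for k, flg in self.n_flagged.items():
            if flg > self.n_windows.get(k, flg):
                raise ValueError(f"flagged > windows for {k}")
        if self.n_variants_tested > self.n_variants_filtered:
            raise ValueError("tested > filtered variant count")


def scan_genome(marker_map, haplotypes, genotypes,
                scan_config: ScanConfig | None = None,
                ehh_config: EhhConfig | None = None):
    """All four scans plus CCR calling, in memory.

    Returns (signals, xpehh results frame, convergence regions).
    """
    scan_config = scan_config or ScanConfig()
    ehh_config = ehh_config or EhhConfig()
    signals = []
    for stat in ("fst", "het-A", "het-B"):
        _, _, sig = scan_statistic(genotypes, marker_map, stat, scan_config)
        signals += sig
    xp = xpehh_scan(polarize_haplotypes(haplotypes), marker_map, ehh_config)
    signals += xpehh_signals(xp, ehh_config.significance_p,
                             ehh_config.group_gap_bp)
    return signals, xp, call_ccr(signals)


def run_pipeline(config: PipelineConfig) -> tuple[RunReport,
                                                  list[ConvergenceRegion]]:
    """Run every stage on a freshly simulated dataset; write all outputs
    under ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(seed=config.sim.seed)

    # --- stage 1: synthetic data ------------------------------------------
    marker_map, haps, genotypes, truth = plant_sweeps(
        config.sim, config.n_sweeps, config.carrier_fraction, config.span_bp)
    report.n_markers = len(marker_map)
    report.n_samples = genotypes.n_samples
    write_plink_pedmap(marker_map, genotypes, out / "genotypes.ped",
                       out / "genotypes.map")
    write_population_labels(genotypes, out / "populations.tsv")
    write_haplotypes_tsv(haps, marker_map, out / "haplotypes.tsv")
    truth.to_frame().to_csv(out / "truth_sweeps.tsv", sep="\t", index=False)

    # --- stage 2: frequency-based scans -----------------------------------
    signals = []
    for stat in ("fst", "het-A", "het-B"):
        track, threshold, sig = scan_statistic(genotypes, marker_map, stat,
                                               config.scan)
        name = {"fst": "FST", "het-A": "ObsHtz-A", "het-B": "ObsHtz-B"}[stat]
        track.to_frame().to_csv(out / f"track_{name}.tsv", sep="\t",
                                index=False)
        report.n_windows[name] = int((~np.isnan(track.value)).sum())
        report.n_flagged[name] = int(track.flagged.sum())
        report.thresholds[name] = threshold
        report.n_signals[name] = len(sig)
        signals += sig

    # --- stage 3: XP-EHH ---------------------------------------------------
    polarized = polarize_haplotypes(haps)
    xp = xpehh_scan(polarized, marker_map, config.ehh)
    xp.to_csv(out / "xpehh.tsv", sep="\t", index=False)
    xp_sig = xpehh_signals(xp, config.ehh.significance_p,
                           config.ehh.group_gap_bp)
    report.n_windows["XPEHH"] = len(xp)
    report.n_flagged["XPEHH"] = int((xp["p"]
                                     < config.ehh.significance_p).sum())
    report.n_signals["XPEHH"] = len(xp_sig)
    signals += xp_sig
    sig_frame = signals_to_frame(signals)
    sig_frame.to_csv(out / "signals.tsv", sep="\t", index=False)
    if len(sig_frame):
        intervals_to_bed(sig_frame, out / "signals.bed", name_col="method")

    # --- stage 4: convergence regions --------------------------------------
    regions = call_ccr(signals)
    report.n_ccr = len(regions)
    for r in regions:
        report.ccr_directions[r.direction] = \
            report.ccr_directions.get(r.direction, 0) + 1
    rframe = regions_to_frame(regions)
    rframe.to_csv(out / "ccr.tsv", sep="\t", index=False)
    if len(rframe):
        intervals_to_bed(rframe, out / "ccr.bed", name_col="id")

    # --- stage 5: divergent variants within regions ------------------------
    if regions:
        vcf_paths = []
        for i, r in enumerate(regions):
            cfg = SimulationConfig(**{**asdict(config.sim),
                                      "seed": config.sim.seed + 1000 + i})
            region = simulate_variant_region(
                r.chrom, r.start_bp, r.end_bp,
                config.div.n_variants_per_region,
                config.div.n_divergent_per_region, config.div.d_planted,
                cfg, config.div.n_a, config.div.n_b)
            path = out / f"variants_{r.id}.vcf"
            write_vcf(region, path)
            vcf_paths.append(path)
        sets = [read_vcf(p) for p in vcf_paths]
        merged = sets[0]
        if len(sets) > 1:
            import pandas as pd
            merged_table = pd.concat([s.table for s in sets],
                                     ignore_index=True)
            merged_geno = np.concatenate([s.genotypes for s in sets], axis=1)
            from .divergence import VariantSet
            merged = VariantSet(merged_table, merged_geno,
                                sets[0].sample_ids)
        report.n_variants_raw = merged.n_variants
        merged.populations = np.array(
            ["A"] * config.div.n_a + ["B"] * config.div.n_b, dtype=object)
        filtered = filter_variants(merged)
        filtered = restrict_to_regions(filtered, regions)
        report.n_variants_filtered = filtered.n_variants
        assoc = allelic_chisq(filtered)
        assoc = apply_bonferroni(assoc, config.div.alpha)
        assoc = classify_divergence(assoc, config.div.d_cut)
        report.n_variants_tested = assoc.attrs["n_tests"]
        report.n_bonferroni_significant = \
            int(assoc["bonferroni_significant"].sum())
        report.n_divergent = int(assoc["divergent"].sum())
        report.bonferroni_threshold = assoc.attrs["bonferroni_threshold"]
        report.bonferroni_log10 = assoc.attrs["bonferroni_log10"]
        write_association_tsv(assoc, out / "association.tsv")

    report.validate()
    with open(out / "report.json", "w") as fh:
        json.dump(asdict(report), fh, indent=2)
    with open(out / "report.txt", "w") as fh:
        fh.write(render_report(report, regions))
    return report, regions


def render_report(report: RunReport, regions: list[ConvergenceRegion] | None
                  = None) -> str:
    """Human-readable run summary."""
    lines = [f"sweepscan v{report.version}  (seed {report.seed})",
             f"markers: {report.n_markers}   samples: {report.n_samples}", ""]
    lines.append(f"{'method':<10}{'windows':>10}{'flagged':>10}"
                 f"{'signals':>10}{'threshold':>14}")
    for m in report.n_windows:
        thr = report.thresholds.get(m, float("nan"))
        thr_s = f"{thr:.4g}" if thr == thr else "p<0.001"
        lines.append(f"{m:<10}{report.n_windows[m]:>10}"
                     f"{report.n_flagged[m]:>10}{report.n_signals[m]:>10}"
                     f"{thr_s:>14}")
    lines.append("")
    lines.append(f"convergence candidate regions: {report.n_ccr} "
                 f"({report.ccr_directions})")
    if regions:
        lines.append(f"{'id':<8}{'chrom':<7}{'start_bp':>12}{'end_bp':>12}"
                     f"{'dir':>5}{'extreme XP-EHH':>16}")
        for r in regions:
            lines.append(f"{r.id:<8}{r.chrom:<7}{r.start_bp:>12}"
                         f"{r.end_bp:>12}{r.direction:>5}"
                         f"{r.extreme_xpehh:>16.3f}")
    lines.append("")
    if report.n_variants_raw:
        lines.append(
            f"variants: {report.n_variants_raw} raw, "
            f"{report.n_variants_filtered} after hard filters, "
            f"{report.n_variants_tested} tested")
        lines.append(
            f"Bonferroni: P < {report.bonferroni_threshold:.3g} "
            f"(= alpha/{report.n_variants_tested}); "
            f"log (1/P value) = {report.bonferroni_log10:.2f}")
        lines.append(
            f"significant: {report.n_bonferroni_significant}; "
            f"divergent |D| > 0.7: {report.n_divergent}")
    return "\n".join(lines) + "\n"
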