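"""Convergence candidate regions (CCR).

A CCR is called where at least one haplotype-based selection signal
(XP-EHH, or externally supplied hapFLK intervals) overlaps at least one
frequency-based signal (FST or observed heterozygosity).  Overlap means
one or more shared base pairs of the closed intervals; adjacency does
not merge.  Overlaps chain transitively: the connected component of the
interval-overlap graph defines the region, and its extent is the union
[min start, max end] of its members.  The region's direction comes from
the sign of the most extreme |z| XP-EHH value among its members
(positive = population A, negative = population B).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sweep_scan import SelectionSignal

log = logging.getLogger(__name__)

HAPLOTYPE_METHODS = {"XPEHH", "HAPFLK"}
FREQUENCY_METHODS = {"FST", "OBSHTZ-A", "OBSHTZ-B"}


def _chrom_key(chrom: str) -> tuple:
    """Natural chromosome ordering: numeric labels before other labels."""
    return (0, int(chrom), "") if str(chrom).isdigit() else (1, 0, str(chrom))


def _kind(method: str) -> str:
    m = method.upper()
    if m in HAPLOTYPE_METHODS:
        return "haplotype"
    if m in FREQUENCY_METHODS:
        return "frequency"
    raise ValueError(f"unknown signal method {method!r}")


@dataclass
class ConvergenceRegion:
    id: str
    chrom: str
    start_bp: int
    end_bp: int
    members: list[SelectionSignal]
    direction: str                 # "A" or "B"
    extreme_xpehh: float           # signed z of the most extreme member core
    sign_conflict: bool = False    # mixed XP-EHH signs among members

    def overlaps_interval(self, chrom: str, start_bp: int, end_bp: int) -> bool:
        return (self.chrom == chrom and self.start_bp <= end_bp
                and start_bp <= self.end_bp)


def call_ccr(signals: list[SelectionSignal]) -> list[ConvergenceRegion]:
    """Merge overlapping signals into convergence candidate regions.

    Connected components of the closed-interval overlap graph are kept
    when they contain >= 1 haplotype-based and >= 1 frequency-based
    member.  Output is ordered by (chromosome, start); ids are CCR1..n.
    Components with conflicting XP-EHH signs keep the most extreme |z|
    and are flagged.
    """
    regions: list[ConvergenceRegion] = []
    by_chrom: dict[str, list[SelectionSignal]] = {}
    for s in signals:
        _kind(s.method)   # validate early
        by_chrom.setdefault(s.chrom, []).append(s)

    components: list[list[SelectionSignal]] = []
    for chrom in sorted(by_chrom):
        group = sorted(by_chrom[chrom], key=lambda s: (s.start_bp, s.end_bp))
        # sweep line: intervals sorted by start chain while they overlap
        current: list[SelectionSignal] = []
        reach = -1
        for s in group:
            if current and s.start_bp > reach:
                components.append(current)
                current = []
            current.append(s)
            reach = max(reach, s.end_bp)
        if current:
            components.append(current)

    for comp in components:
        kinds = {_kind(s.method) for s in comp}
        if kinds != {"haplotype", "frequency"}:
            continue
        xp = [s for s in comp if s.method.upper() == "XPEHH"]
        if xp:
            peak = max(xp, key=lambda s: abs(s.peak_value))
            extreme = peak.peak_value
            conflict = len({np.sign(s.peak_value) for s in xp}) > 1
        else:   # hapFLK-only haplotype support: no direction information
            extreme, conflict = np.nan, False
        direction = ("A" if extreme > 0 else "B") if not np.isnan(extreme) \
            else "NA"
        regions.append(ConvergenceRegion(
            id="", chrom=comp[0].chrom,
            start_bp=min(s.start_bp for s in comp),
            end_bp=max(s.end_bp for s in comp),
            members=comp, direction=direction,
            extreme_xpehh=extreme, sign_conflict=conflict))
    regions.sort(key=lambda r: (_chrom_key(r.chrom), r.start_bp))
    for i, r in enumerate(regions, 1):
        r.id = f"CCR{i}"
    n_conf = sum(r.sign_conflict for r in regions)
    if n_conf:
        log.warning("%d regions carry conflicting XP-EHH signs", n_conf)
    return regions


def regions_to_frame(regions: list[ConvergenceRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"id": r.id, "chrom": r.chrom, "start_bp": r.start_bp,
          "end_bp": r.end_bp, "n_members": len(r.members),
          "methods": ",".join(sorted({m.method for m in r.members})),
          "direction": r.direction, "extreme_xpehh": r.extreme_xpehh,
          "sign_conflict": r.sign_conflict} for r in regions])


# ---------------------------------------------------------------------------
# Annotation against gene / QTL intervals
# ---------------------------------------------------------------------------

def read_annotation(path) -> pd.DataFrame:
    """Read gene/QTL intervals from BED or GFF3 into 1-based closed
    coordinates (chrom, start_bp, end_bp, name)."""
    path = str(path)
    if path.endswith((".gff", ".gff3")):
        rows = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                f = line.rstrip("\n").split("\t")
                attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
                name = attrs.get("Name") or attrs.get("gene_name") \
                    or attrs.get("ID") or "."
                rows.append((f[0], int(f[3]), int(f[4]), name, f[2]))
        return pd.DataFrame(rows, columns=["chrom", "start_bp", "end_bp",
                                           "name", "feature"])
    tab = pd.read_csv(path, sep="\t", header=None, comment="#",
                      usecols=[0, 1, 2, 3],
                      names=["chrom", "start0", "end", "name"], dtype={0: str})
    # BED is 0-based half-open
    return pd.DataFrame({"chrom": tab["chrom"].astype(str),
                         "start_bp": tab["start0"] + 1,
                         "end_bp": tab["end"], "name": tab["name"],
                         "feature": "interval"})


def annotate_regions(regions: list[ConvergenceRegion],
                     annotation: pd.DataFrame,
                     candidate_genes: list[str] | None = None,
                     ) -> pd.DataFrame:
    """Intersect regions with annotation intervals (closed, any overlap).

    Rows are (region id, annotation name, coordinates, is_candidate);
    candidate matching is case-insensitive exact symbol equality.
    Annotation records on chromosomes absent from the regions are
    skipped with a logged count.
    """
    cand = {g.strip().upper() for g in (candidate_genes or [])}
    chroms = {r.chrom for r in regions}
    skipped = int((~annotation["chrom"].astype(str).isin(chroms)).sum())
    if skipped:
        log.info("annotation: %d records on chromosomes with no region",
                 skipped)
    rows = []
    for r in regions:
        sub = annotation[(annotation["chrom"].astype(str) == r.chrom)
                         & (annotation["start_bp"] <= r.end_bp)
                         & (annotation["end_bp"] >= r.start_bp)]
        for _, a in sub.iterrows():
            rows.append({"region": r.id, "chrom": r.chrom,
                         "name": a["name"], "feature": a["feature"],
                         "start_bp": int(a["start_bp"]),
                         "end_bp": int(a["end_bp"]),
                         "is_candidate": str(a["name"]).upper() in cand})
    return pd.DataFrame(rows, columns=["region", "chrom", "name", "feature",
                                       "start_bp", "end_bp", "is_candidate"])


def read_external_signals(path) -> list[SelectionSignal]:
    """Load signals from a TSV written by this package (or an external
    hapFLK run with the same columns)."""
    tab = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return [SelectionSignal(method=row["method"], chrom=str(row["chrom"]),
                            start_bp=int(row["start_bp"]),
                            end_bp=int(row["end_bp"]),
                            n_flagged=int(row.get("n_flagged", 1)),
                            peak_value=float(row.get("peak_value", np.nan)))
            for _, row in tab.iterrows()]
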