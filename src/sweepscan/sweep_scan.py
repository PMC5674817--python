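"""Genome scans: per-SNP FST and heterozygosity, 9-SNP windows,
empirical-tail flagging, signal grouping, and LD-decay profiling.

Per-SNP Weir–Cockerham theta-hat is the full two-population
variance-component estimator (components a, b, c including the
heterozygosity correction); the Akey mean-squares form (MSP/MSG) is
available as an alternative.  Negative per-SNP estimates are retained
for window averaging — clipping would bias window means upward.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geno_io import MISSING, GenotypeMatrix, HaplotypeMatrix, MarkerMap

log = logging.getLogger(__name__)


@dataclass
class ScanConfig:
    window_size: int = 9           # SNPs per sliding window (odd)
    tail_fraction: float = 0.005   # empirical tail per statistic
    group_gap_bp: int = 150_000    # max gap joining flags into one signal
    fst_estimator: str = "weir_cockerham"   # or "akey_msp_msg"

    def __post_init__(self) -> None:
        if self.window_size < 3 or self.window_size % 2 == 0:
            raise ValueError("window_size must be odd and >= 3")
        if not 0.0 < self.tail_fraction < 0.5:
            raise ValueError("tail_fraction must lie in (0, 0.5)")


@dataclass
class SelectionSignal:
    """A method-labelled interval of grouped outlier positions."""

    method: str                    # FST | ObsHtz-A | ObsHtz-B | XPEHH | ...
    chrom: str
    start_bp: int
    end_bp: int
    n_flagged: int
    peak_value: float
    flank_start_id: str = ""
    flank_end_id: str = ""

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError("start_bp must be <= end_bp")

    def overlaps(self, other: "SelectionSignal") -> bool:
        """Closed-interval overlap: at least one shared base pair."""
        return (self.chrom == other.chrom
                and self.start_bp <= other.end_bp
                and other.start_bp <= self.end_bp)


def signals_to_frame(signals: list[SelectionSignal]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"method": s.method, "chrom": s.chrom, "start_bp": s.start_bp,
          "end_bp": s.end_bp, "n_flagged": s.n_flagged,
          "peak_value": s.peak_value, "flank_start_id": s.flank_start_id,
          "flank_end_id": s.flank_end_id} for s in signals])


# ---------------------------------------------------------------------------
# Per-SNP statistics
# ---------------------------------------------------------------------------

def _pop_counts(genotypes: GenotypeMatrix, which: str,
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(n non-missing diploids, allele-B freq, observed het fraction)."""
    dos = genotypes.dosage[genotypes.pop_mask(which)]
    called = dos != MISSING
    n = called.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(called, dos, 0).sum(axis=0) / (2.0 * n)
        h = (dos == 1).sum(axis=0) / n
    return n, p, h


def fst_weir_cockerham(genotypes: GenotypeMatrix,
                       estimator: str = "weir_cockerham") -> np.ndarray:
    """Per-SNP two-population FST (theta-hat); NaN where undefined.

    ``weir_cockerham``: theta = a / (a + b + c) from the variance
    components computed with sample sizes, allele frequencies and
    observed heterozygote fractions (r = 2 populations).  Monomorphic
    pooled sites are undefined; negative estimates are retained.

    ``akey_msp_msg``: the mean-squares form
    (MSP - MSG) / (MSP + (n_c - 1) MSG), which differs from the full
    estimator only in the heterozygosity correction.
    """
    n1, p1, h1 = _pop_counts(genotypes, "A")
    n2, p2, h2 = _pop_counts(genotypes, "B")
    valid = (n1 >= 2) & (n2 >= 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = 2.0
        nbar = (n1 + n2) / r
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        if estimator == "weir_cockerham":
            a = (nbar / nc) * (s2 - (pbar * (1 - pbar)
                                     - (r - 1.0) / r * s2
                                     - hbar / 4.0) / (nbar - 1.0))
            b = (nbar / (nbar - 1.0)) * (pbar * (1 - pbar)
                                         - (r - 1.0) / r * s2
                                         - (2.0 * nbar - 1.0)
                                         / (4.0 * nbar) * hbar)
            c = hbar / 2.0
            denom = a + b + c
            theta = np.where(denom != 0, a / denom, np.nan)
        elif estimator == "akey_msp_msg":
            msg = (n1 * p1 * (1 - p1) + n2 * p2 * (1 - p2)) / (n1 + n2 - r)
            msp = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / (r - 1.0)
            denom = msp + (nc - 1.0) * msg
            theta = np.where(denom != 0, (msp - msg) / denom, np.nan)
        else:
            raise ValueError(f"unknown estimator {estimator!r}")
    mono = (pbar == 0.0) | (pbar == 1.0)
    theta = np.where(valid & ~mono, theta, np.nan)
    n_undef = int(np.isnan(theta).sum())
    if n_undef:
        log.info("FST undefined at %d sites (monomorphic or too few samples)",
                 n_undef)
    return theta


def observed_heterozygosity(genotypes: GenotypeMatrix, which: str,
                            ) -> np.ndarray:
    """Per-SNP heterozygote fraction within one population; NaN if all
    genotypes are missing at a site."""
    _, _, h = _pop_counts(genotypes, which)
    return h


# ---------------------------------------------------------------------------
# Sliding windows and empirical tails
# ---------------------------------------------------------------------------

@dataclass
class ScanTrack:
    """Windowed statistic at central SNPs, with flag state."""

    chrom: np.ndarray
    pos_bp: np.ndarray
    marker_ids: np.ndarray
    value: np.ndarray
    flagged: np.ndarray = field(default=None)  # set by flag_tail
    n_defined: np.ndarray = field(default=None)  # defined members per window

    def to_frame(self) -> pd.DataFrame:
        d = {"chrom": self.chrom, "pos_bp": self.pos_bp,
             "marker_id": self.marker_ids, "value": self.value}
        if self.flagged is not None:
            d["flagged"] = self.flagged
        return pd.DataFrame(d)


def sliding_window_mean(values: np.ndarray, marker_map: MarkerMap,
                        window_size: int = 9) -> ScanTrack:
    """Centered moving average of per-SNP values, never spanning
    chromosomes.

    Windows containing undefined (NaN) members average the defined ones;
    chromosomes with fewer SNPs than the window yield no windows.  The
    first and last (window_size - 1)/2 markers of each chromosome are
    not central SNPs.
    """
    half = (window_size - 1) // 2
    chroms, pos, ids, out, ndef = [], [], [], [], []
    kernel = np.ones(window_size)
    for c in marker_map.chromosomes():
        idx = marker_map.chrom_slice(c)
        if len(idx) < window_size:
            continue
        v = np.asarray(values, dtype=float)[idx]
        defined = ~np.isnan(v)
        sums = np.convolve(np.where(defined, v, 0.0), kernel, mode="valid")
        counts = np.convolve(defined.astype(float), kernel, mode="valid")
        with np.errstate(invalid="ignore", divide="ignore"):
            means = np.where(counts > 0, sums / counts, np.nan)
        centre = idx[half:len(idx) - half]
        chroms.append(marker_map.chrom[centre])
        pos.append(marker_map.pos_bp[centre])
        ids.append(marker_map.ids[centre])
        out.append(means)
        ndef.append(counts.astype(int))
    if not out:
        return ScanTrack(np.array([], object), np.array([], np.int64),
                         np.array([], object), np.array([]))
    track = ScanTrack(np.concatenate(chroms), np.concatenate(pos),
                      np.concatenate(ids), np.concatenate(out))
    track.n_defined = np.concatenate(ndef)
    n_partial = int((track.n_defined < window_size).sum())
    if n_partial:
        log.info("%d windows averaged over fewer than %d defined SNPs",
                 n_partial, window_size)
    return track


def flag_tail(track: ScanTrack, tail_fraction: float = 0.005,
              side: str = "upper") -> tuple[ScanTrack, float]:
    """Flag the empirical tail of the windowed distribution.

    Nearest-rank: k = floor(tail_fraction * n_windows) windows are
    flagged; ties at the threshold value are all included, so the
    flagged count can exceed k.  Returns the track (flags set in place)
    and the threshold value.
    """
    values = track.value
    defined = ~np.isnan(values)
    n = int(defined.sum())
    k = int(np.floor(tail_fraction * n))
    flagged = np.zeros(len(values), dtype=bool)
    if k == 0:
        track.flagged = flagged
        return track, np.nan
    v = values[defined]
    if side == "upper":
        threshold = np.sort(v)[::-1][k - 1]
        flagged[defined] = values[defined] >= threshold
    elif side == "lower":
        threshold = np.sort(v)[k - 1]
        flagged[defined] = values[defined] <= threshold
    else:
        raise ValueError("side must be 'upper' or 'lower'")
    if flagged[defined].all() and n > 1:
        warnings.warn("degenerate windowed distribution: every window sits "
                      "at the threshold value; all windows flagged")
    n_extra = int(flagged.sum()) - k
    if n_extra > 0:
        log.info("tail ties: %d windows flagged beyond nearest-rank %d",
                 n_extra, k)
    track.flagged = flagged
    return track, float(threshold)


def group_signals(track: ScanTrack, method: str,
                  group_gap_bp: int = 150_000,
                  peak: str = "max") -> list[SelectionSignal]:
    """Group flagged central SNPs within ``group_gap_bp`` (inclusive)
    into selection signals.

    A signal spans the first to last member position (closed); a single
    flagged SNP gives start == end.  ``peak`` selects how the signal's
    representative value is chosen: "max", "min" or "absmax".
    """
    if track.flagged is None:
        raise ValueError("track has no flags; run flag_tail first")
    signals: list[SelectionSignal] = []
    take = {"max": np.argmax, "min": np.argmin,
            "absmax": lambda x: np.argmax(np.abs(x))}[peak]
    for c in pd.unique(track.chrom):
        on = np.flatnonzero((track.chrom == c) & track.flagged)
        if len(on) == 0:
            continue
        on = on[np.argsort(track.pos_bp[on])]
        breaks = np.flatnonzero(np.diff(track.pos_bp[on]) > group_gap_bp)
        for grp in np.split(on, breaks + 1):
            vals = track.value[grp]
            signals.append(SelectionSignal(
                method=method, chrom=c,
                start_bp=int(track.pos_bp[grp[0]]),
                end_bp=int(track.pos_bp[grp[-1]]),
                n_flagged=len(grp),
                peak_value=float(vals[take(vals)]),
                flank_start_id=str(track.marker_ids[grp[0]]),
                flank_end_id=str(track.marker_ids[grp[-1]])))
    return signals


def scan_statistic(genotypes: GenotypeMatrix, marker_map: MarkerMap,
                   statistic: str, config: ScanConfig | None = None,
                   ) -> tuple[ScanTrack, float, list[SelectionSignal]]:
    """One full scan: per-SNP stat -> windows -> tail -> signals.

    ``statistic`` is ``"fst"`` (upper tail) or ``"het-A"``/``"het-B"``
    (lower tail, per population).
    """
    config = config or ScanConfig()
    if statistic == "fst":
        per_snp = fst_weir_cockerham(genotypes, config.fst_estimator)
        side, method, peak = "upper", "FST", "max"
    elif statistic in ("het-A", "het-B"):
        which = statistic[-1]
        per_snp = observed_heterozygosity(genotypes, which)
        side, method, peak = "lower", f"ObsHtz-{which}", "min"
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    track = sliding_window_mean(per_snp, marker_map, config.window_size)
    track, threshold = flag_tail(track, config.tail_fraction, side)
    signals = group_signals(track, method, config.group_gap_bp, peak)
    return track, threshold, signals


# ---------------------------------------------------------------------------
# LD decay
# ---------------------------------------------------------------------------

DEFAULT_LD_BINS_KB = (0, 10, 20, 40, 60, 100, 200, 500, 1000)


def _pair_ld(h1: np.ndarray, h2: np.ndarray) -> tuple[float, float]:
    """r^2 and D' from two phased 0/1 columns (2x2 haplotype counts)."""
    p1, p2 = h1.mean(), h2.mean()
    if p1 in (0.0, 1.0) or p2 in (0.0, 1.0):
        return np.nan, np.nan
    p11 = (h1 & h2).mean()
    d = p11 - p1 * p2
    r2 = d * d / (p1 * (1 - p1) * p2 * (1 - p2))
    dmax = min(p1 * (1 - p2), (1 - p1) * p2) if d > 0 else \
        min(p1 * p2, (1 - p1) * (1 - p2))
    dprime = abs(d) / dmax if dmax > 0 else np.nan
    return r2, dprime


def ld_decay_profile(haplotypes: HaplotypeMatrix, marker_map: MarkerMap,
                     bins_kb: tuple = DEFAULT_LD_BINS_KB,
                     max_dist_bp: int | None = None,
                     pop: str | None = None) -> pd.DataFrame:
    """Binned mean r^2 and D' against inter-marker distance, plus the
    half-decay distance.

    Half-decay is the smallest bin midpoint where mean r^2 falls to half
    of the first bin's mean; it is attached as ``.attrs['half_decay_bp']``
    on the returned frame (NaN if never reached within the bins).
    Monomorphic columns are skipped.
    """
    rows = (haplotypes.alleles[haplotypes.pop_rows(pop)] if pop
            else haplotypes.alleles)
    edges = np.asarray(bins_kb, dtype=float) * 1000.0
    cap = max_dist_bp or int(edges[-1])
    sums_r2 = np.zeros(len(edges) - 1)
    sums_dp = np.zeros(len(edges) - 1)
    counts = np.zeros(len(edges) - 1, dtype=int)
    for c in marker_map.chromosomes():
        idx = marker_map.chrom_slice(c)
        pos = marker_map.pos_bp[idx]
        h = rows[:, idx].astype(bool)
        poly = np.flatnonzero((h.any(axis=0)) & (~h.all(axis=0)))
        for a_i, i in enumerate(poly):
            for j in poly[a_i + 1:]:
                dist = pos[j] - pos[i]
                if dist > cap:
                    break
                b = np.searchsorted(edges, dist, side="right") - 1
                if b < 0 or b >= len(counts):
                    continue
                r2, dp = _pair_ld(h[:, i], h[:, j])
                if not np.isnan(r2):
                    sums_r2[b] += r2
                    sums_dp[b] += dp
                    counts[b] += 1
    with np.errstate(invalid="ignore"):
        mean_r2 = np.where(counts > 0, sums_r2 / counts, np.nan)
        mean_dp = np.where(counts > 0, sums_dp / counts, np.nan)
    mid = (edges[:-1] + edges[1:]) / 2.0
    prof = pd.DataFrame({"bin_lo_bp": edges[:-1].astype(int),
                         "bin_hi_bp": edges[1:].astype(int),
                         "midpoint_bp": mid, "n_pairs": counts,
                         "mean_r2": mean_r2, "mean_dprime": mean_dp})
    half_decay = np.nan
    ref = next((v for v in mean_r2 if not np.isnan(v)), np.nan)
    if not np.isnan(ref):
        below = np.flatnonzero(mean_r2 <= ref / 2.0)
        if len(below):
            half_decay = float(mid[below[0]])
    prof.attrs["half_decay_bp"] = half_decay
    return prof
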