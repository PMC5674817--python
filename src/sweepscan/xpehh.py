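"""Cross-population extended haplotype homozygosity (XP-EHH).

The site statistic is the pooled-site EHH variant (EHHS/iES): at a core
marker, the probability that two chromosomes drawn from one population
are identical over the interval from the core out to a given marker,
normalized by the core-site homozygosity so the profile starts at 1.
Each population's profile is integrated over physical distance
(trapezoid rule, truncated where the profile decays below a threshold
or an inter-marker gap is too large), giving iES; the raw XP-EHH score
is ln(iES_A / iES_B), standardized genome-wide.  Positive standardized
scores indicate longer haplotype homozygosity — recent positive
selection — in population A, negative in population B.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .geno_io import HaplotypeMatrix, MarkerMap
from .sweep_scan import ScanTrack, SelectionSignal, group_signals

log = logging.getLogger(__name__)


@dataclass
class EhhConfig:
    truncation_threshold: float = 0.05  # stop integrating below this EHH
    max_gap_bp: int = 200_000           # larger gaps truncate integration
    min_pooled_maf: float = 0.05        # core eligibility
    significance_p: float = 0.001
    group_gap_bp: int = 150_000
    min_scored_cores: int = 50          # refuse standardization below this
    drop_incomplete: bool = False       # drop cores not decayed at chrom end

    def __post_init__(self) -> None:
        if not 0.0 < self.truncation_threshold < 1.0:
            raise ValueError("truncation_threshold must lie in (0, 1)")


@dataclass
class EhhProfile:
    """EHH values against distance from the core, one direction."""

    core_index: int
    direction: str                    # "left" or "right"
    distance_bp: np.ndarray
    ehh: np.ndarray
    complete: bool                    # decayed below threshold before end?


def _homozygosity(groups: np.ndarray) -> float:
    """Probability two distinct chromosomes fall in the same haplotype
    class: sum_h C(n_h,2) / C(n,2)."""
    n = len(groups)
    counts = np.bincount(groups)
    return float((counts * (counts - 1)).sum() / (n * (n - 1)))


def ehh_profile(haplotypes: np.ndarray, positions: np.ndarray,
                core_index: int, direction: str,
                config: EhhConfig | None = None) -> EhhProfile:
    """EHH profile of one population from a core marker outwards.

    ``haplotypes`` is the (n_chromosomes x n_markers) 0/1 matrix of one
    population restricted to one chromosome; ``positions`` its bp
    coordinates.  Extension stops once EHH falls below the truncation
    threshold, a gap exceeds ``max_gap_bp``, or the chromosome ends
    (the latter two leave the profile incomplete).
    """
    config = config or EhhConfig()
    n = haplotypes.shape[0]
    if n < 4:
        raise ValueError("need at least 4 chromosomes for EHH")
    step = -1 if direction == "left" else 1
    groups = haplotypes[:, core_index].astype(np.intp)
    hom0 = _homozygosity(groups)
    if hom0 == 0.0:
        # every chromosome its own class at the core (n=2 per allele max)
        return EhhProfile(core_index, direction, np.array([0.0]),
                          np.array([1.0]), True)
    dists = [0.0]
    ehhs = [1.0]
    complete = False
    j = core_index
    while True:
        jn = j + step
        if jn < 0 or jn >= haplotypes.shape[1]:
            break
        if abs(int(positions[jn]) - int(positions[j])) > config.max_gap_bp:
            break
        combined = groups * 2 + haplotypes[:, jn]
        _, groups = np.unique(combined, return_inverse=True)
        e = _homozygosity(groups) / hom0
        dists.append(abs(int(positions[jn]) - int(positions[core_index])))
        ehhs.append(e)
        j = jn
        if e < config.truncation_threshold:
            complete = True
            break
        if e == 0.0:
            complete = True
            break
    return EhhProfile(core_index, direction, np.asarray(dists, float),
                      np.asarray(ehhs, float), complete)


def _side_integral(profile: EhhProfile, threshold: float) -> float:
    """Trapezoid integral of one side, stopping at the interpolated
    crossing of the truncation threshold."""
    d, e = profile.distance_bp, profile.ehh
    total = 0.0
    for k in range(1, len(d)):
        if e[k] >= threshold:
            total += 0.5 * (e[k - 1] + e[k]) * (d[k] - d[k - 1])
        else:
            # linear interpolation of the crossing point
            frac = (e[k - 1] - threshold) / (e[k - 1] - e[k])
            x = d[k - 1] + frac * (d[k] - d[k - 1])
            total += 0.5 * (e[k - 1] + threshold) * (x - d[k - 1])
            break
    return total


def ies(left: EhhProfile, right: EhhProfile,
        config: EhhConfig | None = None) -> tuple[float, bool]:
    """Integrated site EHH: sum of the two side integrals (bp units).

    Returns (iES, complete).  ``complete`` is False when either side was
    cut by a chromosome end or an oversized gap before decaying below
    the truncation threshold.
    """
    config = config or EhhConfig()
    if left.core_index != right.core_index:
        raise ValueError("profiles do not share a core")
    t = config.truncation_threshold
    return (_side_integral(left, t) + _side_integral(right, t),
            left.complete and right.complete)


# ---------------------------------------------------------------------------
# Genome-wide scan
# ---------------------------------------------------------------------------

def xpehh_scan(haplotypes: HaplotypeMatrix, marker_map: MarkerMap,
               config: EhhConfig | None = None) -> pd.DataFrame:
    """XP-EHH at every eligible core of a polarized haplotype set.

    Cores need pooled MAF >= ``min_pooled_maf`` and a nonzero iES in
    both populations.  Raw scores ln(iES_A/iES_B) are standardized to
    z = (raw - mean)/sd over all scored cores; p-values are the
    two-sided standard-normal tail.  Fewer than ``min_scored_cores``
    scored cores is an error (standardization would be meaningless).
    """
    config = config or EhhConfig()
    pooled_freq = haplotypes.alleles.mean(axis=0)
    maf = np.minimum(pooled_freq, 1 - pooled_freq)
    eligible = maf >= config.min_pooled_maf
    if haplotypes.monomorphic is not None:
        eligible &= ~haplotypes.monomorphic

    rows_a = haplotypes.alleles[haplotypes.pop_rows("A")]
    rows_b = haplotypes.alleles[haplotypes.pop_rows("B")]
    records = []
    n_dropped = 0
    for c in marker_map.chromosomes():
        idx = marker_map.chrom_slice(c)
        pos = marker_map.pos_bp[idx]
        ha, hb = rows_a[:, idx], rows_b[:, idx]
        for local in np.flatnonzero(eligible[idx]):
            vals = {}
            ok = True
            flags = []
            for name, h in (("A", ha), ("B", hb)):
                left = ehh_profile(h, pos, local, "left", config)
                right = ehh_profile(h, pos, local, "right", config)
                v, complete = ies(left, right, config)
                flags.append(complete)
                if v <= 0.0:
                    ok = False
                    break
                vals[name] = v
            if not ok:
                n_dropped += 1
                continue
            if config.drop_incomplete and not all(flags):
                n_dropped += 1
                continue
            records.append((c, int(marker_map.pos_bp[idx[local]]),
                            str(marker_map.ids[idx[local]]),
                            vals["A"], vals["B"],
                            np.log(vals["A"] / vals["B"]),
                            all(flags)))
    if n_dropped:
        log.info("XP-EHH: %d cores dropped (zero iES or incomplete decay)",
                 n_dropped)
    out = pd.DataFrame(records, columns=["chrom", "pos_bp", "marker_id",
                                         "ies_a", "ies_b", "raw", "complete"])
    if len(out) < config.min_scored_cores:
        raise ValueError(
            f"only {len(out)} scored cores; need >= "
            f"{config.min_scored_cores} for genome-wide standardization")
    mu, sd = out["raw"].mean(), out["raw"].std(ddof=0)
    out["z"] = (out["raw"] - mu) / sd
    out["p"] = 2.0 * stats.norm.sf(np.abs(out["z"]))
    out.loc[out["p"] == 0.0, "p"] = np.nextafter(0, 1)
    out["direction"] = np.where(out["z"] > 0, "A", "B")
    return out


def xpehh_signals(results: pd.DataFrame, significance_p: float = 0.001,
                  group_gap_bp: int = 150_000) -> list[SelectionSignal]:
    """Group cores with p below the significance level into signals.

    Each signal carries its most extreme |z| as peak value; the sign of
    that peak gives the selected population (positive = A, negative = B).
    """
    track = ScanTrack(results["chrom"].to_numpy(object),
                      results["pos_bp"].to_numpy(np.int64),
                      results["marker_id"].to_numpy(object),
                      results["z"].to_numpy(float))
    track.flagged = results["p"].to_numpy(float) < significance_p
    return group_signals(track, "XPEHH", group_gap_bp, peak="absmax")
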