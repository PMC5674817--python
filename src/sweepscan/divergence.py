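"""Sequence-variant stage: hard filtering, callset intersection,
allelic chi-square breed association and divergent-frequency calls.

The association test is the basic allelic test: a Pearson chi-square
(1 df, no continuity correction) on the 2x2 table of allele counts by
population, computed from non-missing genotypes.  Monomorphic (zero
allele margin) variants are excluded from testing and from the
Bonferroni denominator.  The allele-frequency divergence is
D = freq_B - freq_A of the alternate allele (population B minus
population A); the convention is written into every output header.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from cyvcf2 import VCF
from scipy import stats

from .ccr import ConvergenceRegion

log = logging.getLogger(__name__)

D_CONVENTION = "D = alt-allele freq(popB) - freq(popA)"

#: hard-filter thresholds, strict inequalities: keep DP > 10, QUAL > 30,
#: MQ > 30, QD > 5, FS < 60
DEFAULT_FILTERS = {"DP": 10.0, "QUAL": 30.0, "MQ": 30.0, "QD": 5.0,
                   "FS": 60.0}


@dataclass
class VariantSet:
    """Bi-allelic variant records plus per-sample dosages."""

    table: pd.DataFrame        # chrom, pos_bp, ref, alt, qual, DP, MQ, QD,
                               # FS, is_indel
    genotypes: np.ndarray      # (n_samples, n_variants) alt dosage, -1 missing
    sample_ids: list[str]
    populations: np.ndarray = field(default=None)
    pop_levels: tuple[str, str] = ("A", "B")

    @property
    def n_variants(self) -> int:
        return len(self.table)

    def subset(self, mask: np.ndarray) -> "VariantSet":
        idx = np.flatnonzero(mask)
        return VariantSet(self.table.iloc[idx].reset_index(drop=True),
                          self.genotypes[:, idx], list(self.sample_ids),
                          self.populations, self.pop_levels)

    def is_sorted(self) -> bool:
        t = self.table
        for _, sub in t.groupby("chrom", sort=False):
            if not sub["pos_bp"].is_monotonic_increasing:
                return False
        return True


def read_vcf(path) -> VariantSet:
    """Read bi-allelic records from a VCF; multi-allelic sites are
    skipped with a logged count."""
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, genos = [], []
    n_multi = 0
    for v in vcf:
        if len(v.ALT) != 1:
            n_multi += 1
            continue
        rows.append({
            "chrom": v.CHROM, "pos_bp": v.POS, "ref": v.REF, "alt": v.ALT[0],
            "qual": v.QUAL if v.QUAL is not None else np.nan,
            "DP": _info(v, "DP"), "MQ": _info(v, "MQ"),
            "QD": _info(v, "QD"), "FS": _info(v, "FS"),
            "is_indel": bool(v.is_indel)})
        gt = v.gt_types  # 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        dos = np.select([gt == 0, gt == 1, gt == 3], [0, 1, 2], default=-1)
        genos.append(dos.astype(np.int8))
    if n_multi:
        log.info("skipped %d multi-allelic records", n_multi)
    table = pd.DataFrame(rows)
    geno = (np.array(genos, dtype=np.int8).T if genos
            else np.empty((len(samples), 0), np.int8))
    return VariantSet(table, geno, samples)


def _info(variant, key):
    val = variant.INFO.get(key)
    return float(val) if val is not None else np.nan


def attach_populations(variants: VariantSet, labels: pd.DataFrame) -> None:
    """Apply a (sample, pop) label table; every sample must be covered."""
    lookup = dict(zip(labels["sample"], labels["pop"]))
    missing = [s for s in variants.sample_ids if s not in lookup]
    if missing:
        raise ValueError(f"samples without a population label: {missing}")
    variants.populations = np.array(
        [lookup[s] for s in variants.sample_ids], dtype=object)
    levels = sorted(set(variants.populations))
    if len(levels) != 2:
        raise ValueError(f"expected two population levels, found {levels}")
    variants.pop_levels = (levels[0], levels[1])


# ---------------------------------------------------------------------------
# Hard filters and callset intersection
# ---------------------------------------------------------------------------

def filter_variants(variants: VariantSet,
                    thresholds: dict | None = None) -> VariantSet:
    """Keep records with DP > 10, QUAL > 30, MQ > 30, QD > 5 and FS < 60
    (strict inequalities).  A missing INFO value fails its filter."""
    th = dict(DEFAULT_FILTERS, **(thresholds or {}))
    t = variants.table
    keep = ((t["DP"] > th["DP"]) & (t["qual"] > th["QUAL"])
            & (t["MQ"] > th["MQ"]) & (t["QD"] > th["QD"])
            & (t["FS"] < th["FS"]))
    keep = keep.fillna(False).to_numpy()
    n_missing = int(t[["DP", "MQ", "QD", "FS"]].isna().any(axis=1).sum()
                    + t["qual"].isna().sum())
    if n_missing:
        log.info("hard filters: %d records with missing INFO fields failed",
                 n_missing)
    log.info("hard filters kept %d / %d variants", int(keep.sum()), len(t))
    return variants.subset(keep)


def intersect_callsets(callset1: VariantSet, callset2: VariantSet,
                       genotypes_from: int = 1) -> VariantSet:
    """Concordant variants of two callsets, matched on
    (chrom, pos, ref, alt); genotypes taken from callset1 (or 2)."""
    for i, cs in enumerate((callset1, callset2), 1):
        if not cs.is_sorted():
            raise ValueError(f"callset {i} is not coordinate-sorted")
    key1 = callset1.table[["chrom", "pos_bp", "ref", "alt"]]
    key2 = callset2.table[["chrom", "pos_bp", "ref", "alt"]]
    common = pd.merge(key1.reset_index(), key2, how="inner",
                      on=["chrom", "pos_bp", "ref", "alt"])["index"]
    mask = np.zeros(callset1.n_variants, dtype=bool)
    mask[common.to_numpy()] = True
    primary = callset1 if genotypes_from == 1 else callset2
    if genotypes_from != 1:
        key2r = key2.reset_index()
        common = pd.merge(key1, key2r, how="inner",
                          on=["chrom", "pos_bp", "ref", "alt"])["index"]
        mask = np.zeros(callset2.n_variants, dtype=bool)
        mask[common.to_numpy()] = True
    return primary.subset(mask)


def restrict_to_regions(variants: VariantSet,
                        regions: list[ConvergenceRegion]) -> VariantSet:
    """Keep variants whose position lies inside any region (closed
    intervals, boundaries inclusive)."""
    keep = np.zeros(variants.n_variants, dtype=bool)
    chrom = variants.table["chrom"].astype(str).to_numpy()
    pos = variants.table["pos_bp"].to_numpy()
    for r in regions:
        keep |= (chrom == r.chrom) & (pos >= r.start_bp) & (pos <= r.end_bp)
    return variants.subset(keep)


# ---------------------------------------------------------------------------
# Allelic chi-square association
# ---------------------------------------------------------------------------

def allele_count_table(dosage: np.ndarray, pop_mask_a: np.ndarray,
                       pop_mask_b: np.ndarray) -> np.ndarray:
    """2x2 allele-count tables (variants x [refA, altA, refB, altB])."""
    out = np.empty((dosage.shape[1], 4), dtype=np.int64)
    for k, mask in ((0, pop_mask_a), (2, pop_mask_b)):
        d = dosage[mask]
        called = d != -1
        alt = np.where(called, d, 0).sum(axis=0)
        tot = 2 * called.sum(axis=0)
        out[:, k] = tot - alt
        out[:, k + 1] = alt
    return out


def chisq_from_table(counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pearson chi-square (1 df, no continuity correction) per 2x2
    allele-count row [refA, altA, refB, altB]; NaN for zero margins."""
    counts = np.atleast_2d(counts).astype(float)
    ra, aa, rb, ab = counts.T
    n = ra + aa + rb + ab
    r1, r2 = ra + aa, rb + ab          # population margins
    c1, c2 = ra + rb, aa + ab          # allele margins
    denom = r1 * r2 * c1 * c2
    with np.errstate(invalid="ignore", divide="ignore"):
        chi2 = np.where(denom > 0, n * (ra * ab - aa * rb) ** 2 / denom,
                        np.nan)
        p = stats.chi2.sf(chi2, df=1)
    return chi2, p


def allelic_chisq(variants: VariantSet) -> pd.DataFrame:
    """Allelic association with breed identity per variant.

    Returns the variant table extended with allele counts, chi2, p,
    per-population alt frequencies and D (popB minus popA).  Variants
    with a zero allele margin (pooled-monomorphic) or an empty
    population get NaN statistics and are excluded from testing.
    """
    if variants.populations is None:
        raise ValueError("population labels not attached")
    mask_a = variants.populations == variants.pop_levels[0]
    mask_b = variants.populations == variants.pop_levels[1]
    counts = allele_count_table(variants.genotypes, mask_a, mask_b)
    chi2, p = chisq_from_table(counts)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq_a = counts[:, 1] / (counts[:, 0] + counts[:, 1])
        freq_b = counts[:, 3] / (counts[:, 2] + counts[:, 3])
    out = variants.table.copy()
    out["ref_a"], out["alt_a"] = counts[:, 0], counts[:, 1]
    out["ref_b"], out["alt_b"] = counts[:, 2], counts[:, 3]
    out["chi2"], out["p"] = chi2, p
    out["freq_a"], out["freq_b"] = freq_a, freq_b
    out["D"] = freq_b - freq_a
    n_excluded = int(np.isnan(chi2).sum())
    if n_excluded:
        log.info("association: %d monomorphic/degenerate variants excluded",
                 n_excluded)
    out.attrs["d_convention"] = D_CONVENTION
    return out


def bonferroni_threshold(n_tests: int, alpha: float = 0.05,
                         ) -> tuple[float, float]:
    """Per-test threshold alpha/n and its log scale log10(1/threshold)."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    threshold = alpha / n_tests
    return threshold, float(np.log10(1.0 / threshold))


def apply_bonferroni(assoc: pd.DataFrame, alpha: float = 0.05,
                     n_tests: int | None = None) -> pd.DataFrame:
    """Flag Bonferroni-significant variants; the denominator is the
    number of tested (non-NaN) variants unless given explicitly."""
    tested = assoc["p"].notna()
    n = n_tests if n_tests is not None else int(tested.sum())
    threshold, log_scale = bonferroni_threshold(max(n, 1), alpha)
    assoc = assoc.copy()
    assoc["bonferroni_significant"] = tested & (assoc["p"] < threshold)
    assoc.attrs["bonferroni_threshold"] = threshold
    assoc.attrs["bonferroni_log10"] = log_scale
    assoc.attrs["n_tests"] = n
    return assoc


def classify_divergence(assoc: pd.DataFrame, d_cut: float = 0.7,
                        ) -> pd.DataFrame:
    """Label variants with |D| > d_cut as divergent, annotated with the
    population carrying the higher alt-allele frequency."""
    assoc = assoc.copy()
    assoc["divergent"] = assoc["D"].abs() > d_cut
    assoc["high_in"] = np.where(assoc["D"] > 0, "B",
                                np.where(assoc["D"] < 0, "A", "none"))
    assoc.loc[~assoc["divergent"], "high_in"] = "none"
    return assoc


def write_association_tsv(assoc: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {D_CONVENTION}\n")
        if "bonferroni_threshold" in assoc.attrs:
            fh.write(f"# bonferroni_threshold={assoc.attrs['bonferroni_threshold']:.6g}"
                     f" log10_scale={assoc.attrs['bonferroni_log10']:.4f}"
                     f" n_tests={assoc.attrs['n_tests']}\n")
        assoc.to_csv(fh, sep="\t", index=False)


def manhattan_table(assoc: pd.DataFrame) -> pd.DataFrame:
    """Plot-ready table: position vs log10(1/p)."""
    tested = assoc[assoc["p"].notna()]
    return pd.DataFrame({"chrom": tested["chrom"],
                         "pos_bp": tested["pos_bp"],
                         "log10_inv_p": np.log10(1.0 / tested["p"])})
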