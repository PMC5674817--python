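"""Data model and I/O for marker maps, genotypes, haplotypes and labels.

Conventions used throughout the package:

* Coordinates are 1-based base pairs; genomic intervals are closed
  ``[start_bp, end_bp]``.  BED output converts to 0-based half-open.
* Genotypes are allele-B dosages in ``{0, 1, 2}`` with ``-1`` as the
  missing sentinel (never conflated with dosage 0).
* Haplotypes are phased 0/1 rows, two consecutive rows per sample.
* Exactly two populations, labelled ``A`` and ``B`` internally; the
  original label strings are preserved on the matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

MISSING = -1

#: chromosome labels treated as non-autosomal and dropped on read
NON_AUTOSOMES = {"0", "X", "Y", "XY", "MT", "M", "23", "24", "25", "26", "27"}


class PedMapParseError(ValueError):
    """Raised for malformed ped/map input."""


# ---------------------------------------------------------------------------
# Core containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Marker:
    id: str
    chrom: str
    pos_bp: int
    allele_a: str = "A"
    allele_b: str = "B"


@dataclass
class MarkerMap:
    """Ordered autosomal marker coordinates, grouped by chromosome.

    Markers are sorted by (chromosome, position); positions within a
    chromosome are strictly increasing and ids are unique.
    """

    chrom: np.ndarray          # str array, n_markers
    ids: np.ndarray            # str array
    pos_bp: np.ndarray         # int64, 1-based
    allele_a: np.ndarray
    allele_b: np.ndarray

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.ids = np.asarray(self.ids, dtype=object)
        self.pos_bp = np.asarray(self.pos_bp, dtype=np.int64)
        self.allele_a = np.asarray(self.allele_a, dtype=object)
        self.allele_b = np.asarray(self.allele_b, dtype=object)
        if len({len(self.chrom), len(self.ids), len(self.pos_bp)}) != 1:
            raise ValueError("MarkerMap field lengths differ")
        ids, counts = np.unique(self.ids, return_counts=True)
        if (counts > 1).any():
            raise PedMapParseError(
                f"duplicate marker id(s): {list(ids[counts > 1][:5])}")
        for c in self.chromosomes():
            pos = self.pos_bp[self.chrom == c]
            if not (np.diff(pos) > 0).all():
                raise ValueError(
                    f"positions on chromosome {c} not strictly increasing")
        if (self.pos_bp < 1).any():
            raise ValueError("positions must be >= 1 (1-based)")

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n_markers(self) -> int:
        return len(self.ids)

    def chromosomes(self) -> list[str]:
        """Chromosome labels in order of first appearance."""
        _, idx = np.unique(self.chrom, return_index=True)
        return [self.chrom[i] for i in np.sort(idx)]

    def chrom_slice(self, chrom: str) -> np.ndarray:
        return np.flatnonzero(self.chrom == chrom)

    def subset(self, indices: np.ndarray) -> "MarkerMap":
        return MarkerMap(self.chrom[indices], self.ids[indices],
                         self.pos_bp[indices], self.allele_a[indices],
                         self.allele_b[indices])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"chrom": self.chrom, "id": self.ids,
                             "pos_bp": self.pos_bp,
                             "allele_a": self.allele_a,
                             "allele_b": self.allele_b})


@dataclass
class GenotypeMatrix:
    """Diploid allele-B dosages with missingness and two population labels."""

    dosage: np.ndarray         # (n_samples, n_markers) int8, -1 missing
    sample_ids: list[str]
    populations: np.ndarray    # str array per sample, two levels
    pop_levels: tuple[str, str] = ("A", "B")   # (popA label, popB label)

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        self.populations = np.asarray(self.populations, dtype=object)
        if self.dosage.shape[0] != len(self.sample_ids):
            raise ValueError("dosage rows != sample ids")
        if len(self.populations) != len(self.sample_ids):
            raise ValueError("every sample needs a population label")

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosage.shape[1]

    def pop_mask(self, which: str) -> np.ndarray:
        """Boolean sample mask for population ``"A"`` or ``"B"``."""
        level = self.pop_levels[0] if which == "A" else self.pop_levels[1]
        return self.populations == level


@dataclass
class HaplotypeMatrix:
    """Phased binary haplotypes, two consecutive rows per sample."""

    alleles: np.ndarray        # (2*n_samples, n_markers) uint8 in {0,1}
    sample_ids: list[str]
    populations: np.ndarray    # per sample
    pop_levels: tuple[str, str] = ("A", "B")
    polarized: bool = False    # raw allele-B coding vs minor/major coding
    monomorphic: np.ndarray | None = None   # per-marker flag set on polarize

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.uint8)
        self.populations = np.asarray(self.populations, dtype=object)
        if self.alleles.shape[0] % 2:
            raise ValueError("haplotype row count must be even")
        if self.alleles.shape[0] != 2 * len(self.sample_ids):
            raise ValueError("expected two haplotype rows per sample")

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_markers(self) -> int:
        return self.alleles.shape[1]

    def pop_rows(self, which: str) -> np.ndarray:
        level = self.pop_levels[0] if which == "A" else self.pop_levels[1]
        return np.repeat(self.populations == level, 2)

    def to_genotypes(self) -> GenotypeMatrix:
        dos = (self.alleles[0::2].astype(np.int8)
               + self.alleles[1::2].astype(np.int8))
        return GenotypeMatrix(dos, list(self.sample_ids),
                              self.populations.copy(), self.pop_levels)


@dataclass
class QcReport:
    n_samples_removed: int = 0
    n_markers_call_removed: int = 0
    n_markers_maf_removed: int = 0
    removed_sample_ids: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# PLINK text ped/map
# ---------------------------------------------------------------------------

def read_plink_pedmap(ped_path, map_path) -> tuple[MarkerMap, GenotypeMatrix]:
    """Read a whitespace-delimited PLINK text ped/map pair.

    Genotypes are returned as allele-B dosages; ``0 0`` becomes missing.
    Marker order follows the map after a per-chromosome position sort;
    non-autosomal records are dropped (with a logged count).
    """
    mp = pd.read_csv(map_path, sep=r"\s+", header=None, dtype=str)
    if mp.shape[1] != 4:
        raise PedMapParseError(
            f"{map_path}: expected 4 map columns, found {mp.shape[1]}")
    mp.columns = ["chrom", "id", "cM", "pos_bp"]
    mp["pos_bp"] = mp["pos_bp"].astype(np.int64)
    auto = ~mp["chrom"].str.upper().isin(NON_AUTOSOMES)
    if (~auto).any():
        log.info("dropping %d non-autosomal markers", int((~auto).sum()))
    keep_cols = np.flatnonzero(auto.to_numpy())
    mp = mp.loc[auto].reset_index(drop=True)
    order = np.lexsort((mp["pos_bp"].to_numpy(),
                        mp["chrom"].to_numpy(dtype=object)))

    sample_ids: list[str] = []
    allele_rows: list[np.ndarray] = []
    n_total_markers = len(auto)
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * n_total_markers:
                raise PedMapParseError(
                    f"{ped_path}: line {lineno} has {len(fields)} fields, "
                    f"expected {6 + 2 * n_total_markers}")
            sample_ids.append(fields[1])
            allele_rows.append(np.array(fields[6:], dtype=object))

    n_samples = len(sample_ids)
    alleles = (np.array(allele_rows, dtype=object)
               if n_samples else np.empty((0, 2 * n_total_markers), object))
    a1 = alleles[:, 0::2][:, keep_cols][:, order] if n_samples else alleles
    a2 = alleles[:, 1::2][:, keep_cols][:, order] if n_samples else alleles
    mp = mp.iloc[order].reset_index(drop=True)

    # allele A = first allele observed per marker, allele B = the other
    n_markers = len(mp)
    dosage = np.full((n_samples, n_markers), MISSING, dtype=np.int8)
    allele_a = np.empty(n_markers, dtype=object)
    allele_b = np.empty(n_markers, dtype=object)
    for j in range(n_markers):
        col = np.concatenate([a1[:, j], a2[:, j]]) if n_samples else np.array([])
        seen = [x for x in pd.unique(col) if x != "0"]
        if len(seen) > 2:
            raise PedMapParseError(
                f"marker {mp['id'][j]}: more than two alleles {seen}")
        aa = seen[0] if seen else "A"
        bb = seen[1] if len(seen) > 1 else ("B" if not seen else aa + "'")
        allele_a[j], allele_b[j] = aa, bb
        if n_samples:
            miss = (a1[:, j] == "0") | (a2[:, j] == "0")
            dos = (a1[:, j] == bb).astype(np.int8) + (a2[:, j] == bb).astype(np.int8)
            dos[miss] = MISSING
            dosage[:, j] = dos

    marker_map = MarkerMap(mp["chrom"].to_numpy(object), mp["id"].to_numpy(object),
                           mp["pos_bp"].to_numpy(), allele_a, allele_b)
    genotypes = GenotypeMatrix(dosage, sample_ids,
                               np.array(["A"] * n_samples, dtype=object))
    return marker_map, genotypes


def write_plink_pedmap(marker_map: MarkerMap, genotypes: GenotypeMatrix,
                       ped_path, map_path) -> None:
    """Write ped/map text files (inverse of :func:`read_plink_pedmap`)."""
    with open(map_path, "w") as fh:
        for c, i, p in zip(marker_map.chrom, marker_map.ids, marker_map.pos_bp):
            fh.write(f"{c}\t{i}\t0\t{p}\n")
    aa, bb = marker_map.allele_a, marker_map.allele_b
    with open(ped_path, "w") as fh:
        for s in range(genotypes.n_samples):
            row = [genotypes.sample_ids[s], genotypes.sample_ids[s],
                   "0", "0", "0", "-9"]
            dos = genotypes.dosage[s]
            for j in range(genotypes.n_markers):
                d = dos[j]
                if d == MISSING:
                    row += ["0", "0"]
                elif d == 0:
                    row += [aa[j], aa[j]]
                elif d == 1:
                    row += [aa[j], bb[j]]
                else:
                    row += [bb[j], bb[j]]
            fh.write(" ".join(row) + "\n")


# ---------------------------------------------------------------------------
# Population labels
# ---------------------------------------------------------------------------

def read_population_labels(path, genotypes: GenotypeMatrix | None = None,
                           ) -> pd.DataFrame:
    """Read a two-column (sample id, population) TSV.

    Exactly two population levels must be present; if ``genotypes`` is
    given, every one of its samples must be labelled and the labels are
    applied in place (first level sorted lexicographically becomes popA).
    """
    tab = pd.read_csv(path, sep=r"\s+", header=None, names=["sample", "pop"],
                      dtype=str, comment="#")
    levels = sorted(tab["pop"].unique())
    if len(levels) != 2:
        raise ValueError(
            f"expected exactly two population levels, found {levels}")
    if genotypes is not None:
        lookup = dict(zip(tab["sample"], tab["pop"]))
        missing = [s for s in genotypes.sample_ids if s not in lookup]
        if missing:
            raise ValueError(f"samples without a population label: {missing}")
        genotypes.populations = np.array(
            [lookup[s] for s in genotypes.sample_ids], dtype=object)
        genotypes.pop_levels = (levels[0], levels[1])
    return tab


def write_population_labels(genotypes: GenotypeMatrix, path) -> None:
    with open(path, "w") as fh:
        for s, p in zip(genotypes.sample_ids, genotypes.populations):
            fh.write(f"{s}\t{p}\n")


# ---------------------------------------------------------------------------
# Genotype QC (PLINK order: mind -> geno -> maf)
# ---------------------------------------------------------------------------

def qc_filter(genotypes: GenotypeMatrix, marker_map: MarkerMap | None = None,
              min_sample_call: float = 0.90, min_marker_call: float = 0.90,
              min_maf: float = 0.01,
              ) -> tuple[GenotypeMatrix, MarkerMap | None, QcReport]:
    """PLINK-style QC: sample call rate, then marker call rate, then MAF.

    MAF is computed on pooled post-sample-filter genotypes.  Samples or
    markers with call rate strictly below the threshold are removed.
    """
    for t in (min_sample_call, min_marker_call, min_maf):
        if not 0.0 <= t <= 1.0:
            raise ValueError("thresholds must lie in [0, 1]")
    report = QcReport()
    dos = genotypes.dosage
    called = dos != MISSING

    sample_rate = called.mean(axis=1) if dos.shape[1] else np.ones(dos.shape[0])
    keep_s = sample_rate >= min_sample_call
    report.n_samples_removed = int((~keep_s).sum())
    report.removed_sample_ids = [
        s for s, k in zip(genotypes.sample_ids, keep_s) if not k]
    if not keep_s.any():
        raise ValueError("QC removed every sample")
    dos = dos[keep_s]
    called = called[keep_s]

    marker_rate = called.mean(axis=0)
    keep_call = marker_rate >= min_marker_call
    report.n_markers_call_removed = int((~keep_call).sum())

    with np.errstate(invalid="ignore"):
        freq_b = np.where(called, dos, 0).sum(axis=0) / (2.0 * called.sum(axis=0))
    maf = np.minimum(freq_b, 1.0 - freq_b)
    keep_maf = np.where(np.isnan(maf), False, maf >= min_maf) | (min_maf == 0)
    keep_m = keep_call & keep_maf
    report.n_markers_maf_removed = int((keep_call & ~keep_maf).sum())

    out = GenotypeMatrix(dos[:, keep_m],
                         [s for s, k in zip(genotypes.sample_ids, keep_s) if k],
                         genotypes.populations[keep_s], genotypes.pop_levels)
    out_map = marker_map.subset(np.flatnonzero(keep_m)) if marker_map else None
    return out, out_map, report


# ---------------------------------------------------------------------------
# Haplotype polarization (minor/major coding)
# ---------------------------------------------------------------------------

def polarize_haplotypes(haplotypes: HaplotypeMatrix) -> HaplotypeMatrix:
    """Recode each column so the pooled-minor allele is 1.

    Frequency is taken over both populations pooled.  A tie at exactly
    0.5 keeps allele A (the 0-coded allele) as minor, i.e. the column is
    flipped.  Monomorphic columns come out all-0 and are flagged so that
    downstream haplotype scans can exclude them as cores.
    """
    alleles = haplotypes.alleles
    freq1 = alleles.mean(axis=0)
    # tie rule: allele A (raw 0-code) is treated as minor, so ties flip on
    # the first pass; an already-polarized matrix has its ties settled and
    # flipping them again would oscillate
    if haplotypes.polarized:
        flip = freq1 > 0.5
    else:
        flip = freq1 >= 0.5
    out = np.where(flip[None, :], 1 - alleles, alleles).astype(np.uint8)
    mono = (freq1 == 0.0) | (freq1 == 1.0)
    out[:, mono] = 0
    return replace(haplotypes, alleles=out, polarized=True, monomorphic=mono)


# ---------------------------------------------------------------------------
# Interval / BED helpers
# ---------------------------------------------------------------------------

def intervals_to_bed(frame: pd.DataFrame, path,
                     name_col: str | None = None) -> None:
    """Write closed 1-based [start_bp, end_bp] intervals as BED
    (0-based half-open)."""
    with open(path, "w") as fh:
        for _, row in frame.iterrows():
            name = str(row[name_col]) if name_col else "."
            fh.write(f"{row['chrom']}\t{int(row['start_bp']) - 1}"
                     f"\t{int(row['end_bp'])}\t{name}\n")
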