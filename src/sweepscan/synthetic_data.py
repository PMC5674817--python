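"""Synthetic two-population genotype/haplotype data with planted sweeps.

The generator emulates a 50K-chip-like dataset for two breeds that have
diverged by genome-wide drift:

* allele frequencies follow the Balding–Nichols model, whose drift
  parameter F equals the expected per-SNP FST between the populations —
  this gives an analytic calibration target for parameter recovery;
* haplotypes are founder mosaics: each sample chromosome copies one of a
  small pool of founder haplotypes and switches founder with a fixed
  per-marker probability, producing linkage disequilibrium that decays
  with physical distance;
* selective sweeps are planted by copying one donor haplotype's segment
  into a chosen fraction of a population's chromosomes, which jointly
  creates elevated FST, depressed heterozygosity and extended haplotype
  homozygosity — the three signatures the scans target;
* a separate routine emits dense region-level variants (VCF) with a
  controlled number of divergent-frequency sites for the association
  stage.

All randomness flows from a single seed through named substreams, so a
config + seed pair reproduces every output byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geno_io import GenotypeMatrix, HaplotypeMatrix, MarkerMap

# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class SimulationConfig:
    """Parameters of the two-population simulator.

    Defaults are calibrated to the study system they emulate: marker
    spacing ~50 kb (50K-chip density), drift F = 0.10 per population
    (background FST in the 0.05–0.15 band), and a founder-mosaic switch
    probability giving an LD half-decay distance of roughly 50 kb.
    """

    n_per_pop: int = 60
    n_chrom: int = 5
    markers_per_chrom: int = 1000
    mean_spacing_bp: int = 50_000
    F_a: float = 0.10
    F_b: float = 0.10
    n_founders: int = 20
    switch_prob: float = 0.30
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_per_pop", "n_chrom", "markers_per_chrom",
                     "mean_spacing_bp", "n_founders"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("F_a", "F_b"):
            if not 0.0 <= getattr(self, name) < 1.0:
                raise ValueError(f"{name} must lie in [0, 1)")
        if not 0.0 < self.switch_prob <= 1.0:
            raise ValueError("switch_prob must lie in (0, 1]")

    def rng(self, stage: str) -> np.random.Generator:
        """Named substream: independent generator per pipeline stage."""
        seq = np.random.SeedSequence(self.seed, spawn_key=(_STAGES[stage],))
        return np.random.default_rng(seq)


_STAGES = {"frequencies": 0, "map": 1, "haplotypes": 2, "sweeps": 3,
           "variants": 4}


@dataclass(frozen=True)
class SweepSpec:
    """A planted sweep: donor-segment copying around a core site."""

    chrom: str
    core_pos_bp: int
    target_pop: str                # "A" or "B"
    carrier_fraction: float = 0.9
    span_bp: int = 500_000

    def __post_init__(self) -> None:
        if self.target_pop not in ("A", "B"):
            raise ValueError("target_pop must be 'A' or 'B'")
        if not 0.0 <= self.carrier_fraction <= 1.0:
            raise ValueError("carrier_fraction must lie in [0, 1]")


@dataclass
class TruthTable:
    """Planted-signal records: sweeps plus divergent variant positions."""

    sweeps: list[SweepSpec] = field(default_factory=list)
    divergent_variants: pd.DataFrame | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"chrom": s.chrom, "core_pos_bp": s.core_pos_bp,
              "target_pop": s.target_pop,
              "carrier_fraction": s.carrier_fraction,
              "span_bp": s.span_bp} for s in self.sweeps])


# ---------------------------------------------------------------------------
# Allele frequencies (Balding–Nichols drift)
# ---------------------------------------------------------------------------

def simulate_frequencies(config: SimulationConfig,
                         ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Ancestral and per-population allele frequencies.

    Ancestral frequencies are Uniform(0.05, 0.95); each population's
    frequency is Beta(p0(1-F)/F, (1-p0)(1-F)/F), so E[freq] = p0 and the
    expected between-population FST equals F.  F = 0 returns p0 exactly.
    """
    rng = config.rng("frequencies")
    n = config.n_chrom * config.markers_per_chrom
    p0 = rng.uniform(0.05, 0.95, size=n)
    freqs = []
    for F in (config.F_a, config.F_b):
        if F == 0.0:
            freqs.append(p0.copy())
        else:
            scale = (1.0 - F) / F
            freqs.append(rng.beta(p0 * scale, (1.0 - p0) * scale))
    return p0, freqs[0], freqs[1]


# ---------------------------------------------------------------------------
# Marker map and founder-mosaic haplotypes
# ---------------------------------------------------------------------------

def simulate_marker_map(config: SimulationConfig) -> MarkerMap:
    """Exponential inter-marker spacing (mean 50 kb by default)."""
    rng = config.rng("map")
    chroms, ids, pos = [], [], []
    for c in range(1, config.n_chrom + 1):
        gaps = np.maximum(
            1, rng.exponential(config.mean_spacing_bp,
                               config.markers_per_chrom).round().astype(np.int64))
        p = np.cumsum(gaps)
        # enforce strict increase after rounding
        p = np.maximum.accumulate(p + np.arange(len(p)))
        pos.append(p)
        chroms += [str(c)] * config.markers_per_chrom
        ids += [f"snp{c}_{k + 1}" for k in range(config.markers_per_chrom)]
    n = len(ids)
    return MarkerMap(np.array(chroms, dtype=object), np.array(ids, dtype=object),
                     np.concatenate(pos),
                     np.array(["A"] * n, dtype=object),
                     np.array(["B"] * n, dtype=object))


def _mosaic(rng: np.random.Generator, founders: np.ndarray, n_hap: int,
            switch_prob: np.ndarray) -> np.ndarray:
    """Sample n_hap mosaic haplotypes from a founder pool.

    ``switch_prob`` is the per-marker probability of switching founder
    between the previous marker and this one (already scaled by the
    inter-marker distance; 1.0 at each chromosome start).
    """
    n_founders, n_markers = founders.shape
    choice = rng.integers(0, n_founders, size=(n_hap, n_markers))
    switch = rng.random((n_hap, n_markers)) < switch_prob[None, :]
    switch[:, 0] = True
    # index of the most recent switch, propagated rightwards
    last = np.where(switch, np.arange(n_markers)[None, :], 0)
    last = np.maximum.accumulate(last, axis=1)
    path = np.take_along_axis(choice, last, axis=1)
    return founders[path, np.arange(n_markers)[None, :]]


def _switch_probs(marker_map: MarkerMap, switch_prob: float,
                  mean_spacing_bp: int) -> np.ndarray:
    """Distance-scaled founder-switch probability per marker.

    The switch process is a per-base-pair hazard calibrated so that a
    gap of ``mean_spacing_bp`` switches with probability ``switch_prob``:
    P(switch over gap g) = 1 - (1 - switch_prob)^(g / mean_spacing_bp).
    This makes linkage disequilibrium decay with physical distance
    rather than with marker count.  Chromosome starts always switch.
    """
    probs = np.ones(len(marker_map))
    if switch_prob >= 1.0:
        return probs
    for c in marker_map.chromosomes():
        idx = marker_map.chrom_slice(c)
        gaps = np.diff(marker_map.pos_bp[idx]).astype(float)
        probs[idx[1:]] = 1.0 - (1.0 - switch_prob) ** (gaps / mean_spacing_bp)
    return probs


def simulate_haplotypes(config: SimulationConfig,
                        freq_a: np.ndarray, freq_b: np.ndarray,
                        ) -> tuple[MarkerMap, HaplotypeMatrix]:
    """Founder-mosaic haplotypes for both populations.

    Founders are drawn per population from its Balding–Nichols
    frequencies; sample haplotypes copy founders, switching founder
    along the chromosome with a distance-scaled probability (see
    :func:`_switch_probs`), which sets the LD decay length.
    """
    marker_map = simulate_marker_map(config)
    rng = config.rng("haplotypes")
    n_markers = len(marker_map)
    probs = _switch_probs(marker_map, config.switch_prob,
                          config.mean_spacing_bp)
    haps = []
    for freq in (freq_a, freq_b):
        founders = (rng.random((config.n_founders, n_markers))
                    < freq[None, :]).astype(np.uint8)
        haps.append(_mosaic(rng, founders, 2 * config.n_per_pop, probs))
    alleles = np.vstack(haps).astype(np.uint8)
    sample_ids = ([f"A{i + 1}" for i in range(config.n_per_pop)]
                  + [f"B{i + 1}" for i in range(config.n_per_pop)])
    populations = np.array(["A"] * config.n_per_pop
                           + ["B"] * config.n_per_pop, dtype=object)
    return marker_map, HaplotypeMatrix(alleles, sample_ids, populations)


def simulate_dataset(config: SimulationConfig,
                     ) -> tuple[MarkerMap, HaplotypeMatrix, GenotypeMatrix]:
    """Frequencies + map + haplotypes + genotypes in one call."""
    _, fa, fb = simulate_frequencies(config)
    marker_map, haps = simulate_haplotypes(config, fa, fb)
    return marker_map, haps, haps.to_genotypes()


# ---------------------------------------------------------------------------
# Sweep injection
# ---------------------------------------------------------------------------

def inject_sweep(haplotypes: HaplotypeMatrix, marker_map: MarkerMap,
                 sweep: SweepSpec,
                 rng: np.random.Generator) -> HaplotypeMatrix:
    """Plant a sweep by copying a donor segment into carrier haplotypes.

    One donor is chosen among chromosomes carrying the core-site allele
    "1" (or "0" if none carry it); a ``carrier_fraction`` share of the
    target population's haplotypes then has the closed segment
    [core - span, core + span] replaced by the donor's segment.  Spans
    reaching past the chromosome are clipped.
    """
    if sweep.carrier_fraction == 0.0:
        return haplotypes
    on_chrom = marker_map.chrom_slice(sweep.chrom)
    if len(on_chrom) == 0:
        raise ValueError(f"chromosome {sweep.chrom} not in map")
    pos = marker_map.pos_bp[on_chrom]
    if not pos[0] <= sweep.core_pos_bp <= pos[-1]:
        raise ValueError("sweep core outside chromosome extent")
    core = on_chrom[np.argmin(np.abs(pos - sweep.core_pos_bp))]
    seg = on_chrom[(marker_map.pos_bp[on_chrom]
                    >= sweep.core_pos_bp - sweep.span_bp)
                   & (marker_map.pos_bp[on_chrom]
                      <= sweep.core_pos_bp + sweep.span_bp)]

    rows = np.flatnonzero(haplotypes.pop_rows(sweep.target_pop))
    alleles = haplotypes.alleles.copy()
    carrier_rows = rows[alleles[rows, core] == 1]
    if len(carrier_rows) == 0:
        carrier_rows = rows
    donor = rng.choice(carrier_rows)
    n_replace = int(round(sweep.carrier_fraction * len(rows)))
    chosen = rng.choice(rows, size=n_replace, replace=False)
    alleles[np.ix_(chosen, seg)] = alleles[donor, seg][None, :]
    out = HaplotypeMatrix(alleles, list(haplotypes.sample_ids),
                          haplotypes.populations.copy(),
                          haplotypes.pop_levels, haplotypes.polarized)
    return out


def plant_sweeps(config: SimulationConfig, n_sweeps: int = 5,
                 carrier_fraction: float = 0.9, span_bp: int = 500_000,
                 target_pops: list[str] | None = None,
                 ) -> tuple[MarkerMap, HaplotypeMatrix, GenotypeMatrix,
                            TruthTable]:
    """Simulate a dataset and plant ``n_sweeps`` sweeps, one per region.

    Cores are spread over chromosomes (round-robin) at mid-chromosome
    offsets so planted regions never overlap; target populations
    alternate A/B unless given explicitly.
    """
    _, fa, fb = simulate_frequencies(config)
    marker_map, haps = simulate_haplotypes(config, fa, fb)
    rng = config.rng("sweeps")
    chroms = marker_map.chromosomes()
    truth = TruthTable()
    for k in range(n_sweeps):
        chrom = chroms[k % len(chroms)]
        pos = marker_map.pos_bp[marker_map.chrom_slice(chrom)]
        lo, hi = pos[0] + span_bp, pos[-1] - span_bp
        # spread multiple sweeps per chromosome over thirds of its span
        n_on = n_sweeps // len(chroms) + (k % len(chroms) < n_sweeps % len(chroms))
        slot = k // len(chroms)
        core = int(lo + (hi - lo) * (slot + 0.5) / max(n_on, 1))
        target = (target_pops[k] if target_pops
                  else ("A" if k % 2 == 0 else "B"))
        spec = SweepSpec(chrom, core, target, carrier_fraction, span_bp)
        haps = inject_sweep(haps, marker_map, spec, rng)
        truth.sweeps.append(spec)
    return marker_map, haps, haps.to_genotypes(), truth


# ---------------------------------------------------------------------------
# Region-level sequence variants (association stage)
# ---------------------------------------------------------------------------

@dataclass
class SimulatedVariantRegion:
    chrom: str
    start_bp: int
    end_bp: int
    table: pd.DataFrame            # pos, ref, alt, freq_a, freq_b, divergent,
                                   # qual, DP, MQ, QD, FS, is_indel
    genotypes: np.ndarray          # (n_samples, n_variants) dosage, -1 missing
    sample_ids: list[str]
    populations: np.ndarray


def simulate_variant_region(chrom: str, start_bp: int, end_bp: int,
                            n_variants: int, n_divergent: int,
                            d_planted: float, config: SimulationConfig,
                            n_a: int = 15, n_b: int = 13,
                            fail_fraction: float = 0.05,
                            ) -> SimulatedVariantRegion:
    """Dense variants in one interval, with planted frequency divergence.

    Background variants share a common frequency across populations (the
    residual drift of the genome-wide background is intentionally absent
    so the null of the association test is exact); ``n_divergent``
    variants get |freq_A - freq_B| = ``d_planted``.  INFO fields are
    drawn so that about ``fail_fraction`` of variants fail each of the
    five hard filters (DP, QUAL, MQ, QD, FS) independently.
    """
    if not 0 <= n_divergent <= n_variants:
        raise ValueError("need 0 <= n_divergent <= n_variants")
    if abs(d_planted) > 1:
        raise ValueError("|d_planted| must be <= 1")
    rng = config.rng("variants")
    pos = np.sort(rng.choice(
        np.arange(start_bp, end_bp + 1), size=n_variants, replace=False))
    freq_a = rng.uniform(0.05, 0.95, size=n_variants)
    freq_b = freq_a.copy()
    div_idx = rng.choice(n_variants, size=n_divergent, replace=False)
    d = abs(d_planted)
    base = rng.uniform(0.0, 1.0 - d, size=n_divergent)
    hi_in_a = rng.random(n_divergent) < 0.5
    freq_a[div_idx] = np.where(hi_in_a, base + d, base)
    freq_b[div_idx] = np.where(hi_in_a, base, base + d)

    geno = np.vstack([
        rng.binomial(2, freq_a, size=(n_a, n_variants)),
        rng.binomial(2, freq_b, size=(n_b, n_variants)),
    ]).astype(np.int8)

    def passing(draw_pass, draw_fail):
        fail = rng.random(n_variants) < fail_fraction
        return np.where(fail, draw_fail(), draw_pass())

    table = pd.DataFrame({
        "chrom": chrom, "pos_bp": pos,
        "ref": rng.choice(list("ACGT"), n_variants),
        "alt": "N",   # placeholder, fixed below
        "qual": passing(lambda: rng.uniform(31, 200, n_variants),
                        lambda: rng.uniform(1, 30, n_variants)),
        "DP": passing(lambda: rng.integers(11, 120, n_variants),
                      lambda: rng.integers(1, 11, n_variants)),
        "MQ": passing(lambda: rng.uniform(31, 60, n_variants),
                      lambda: rng.uniform(5, 30, n_variants)),
        "QD": passing(lambda: rng.uniform(5.01, 35, n_variants),
                      lambda: rng.uniform(0.1, 5, n_variants)),
        "FS": passing(lambda: rng.uniform(0, 59.9, n_variants),
                      lambda: rng.uniform(60.1, 200, n_variants)),
        "is_indel": rng.random(n_variants) < 0.02,
        "freq_a": freq_a, "freq_b": freq_b,
    })
    alts = np.array(
        [rng.choice([b for b in "ACGT" if b != r]) for r in table["ref"]],
        dtype=object)
    alts[table["is_indel"].to_numpy()] = [
        r + "A" for r in table.loc[table["is_indel"], "ref"]]
    table["alt"] = alts
    table["divergent"] = False
    table.loc[div_idx, "divergent"] = True

    sample_ids = ([f"ChA{i + 1}" for i in range(n_a)]
                  + [f"MeB{i + 1}" for i in range(n_b)])
    populations = np.array(["A"] * n_a + ["B"] * n_b, dtype=object)
    return SimulatedVariantRegion(chrom, start_bp, end_bp, table, geno,
                                  sample_ids, populations)


def write_vcf(region: SimulatedVariantRegion, path) -> None:
    """Emit the region as a minimal VCF 4.2 text file with GT per sample."""
    gt_codes = {-1: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={region.chrom}>\n")
        for k, t, d in (("DP", "Integer", "Site depth"),
                        ("MQ", "Float", "Mapping quality"),
                        ("QD", "Float", "Quality by depth"),
                        ("FS", "Float", "Fisher strand (Phred)")):
            fh.write(f'##INFO=<ID={k},Number=1,Type={t},Description="{d}">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(region.sample_ids) + "\n")
        for j, row in region.table.iterrows():
            info = (f"DP={int(row['DP'])};MQ={row['MQ']:.2f};"
                    f"QD={row['QD']:.2f};FS={row['FS']:.2f}")
            gts = "\t".join(gt_codes[int(g)] for g in region.genotypes[:, j])
            fh.write(f"{row['chrom']}\t{int(row['pos_bp'])}\t.\t{row['ref']}\t"
                     f"{row['alt']}\t{row['qual']:.2f}\t.\t{info}\tGT\t{gts}\n")


def write_haplotypes_tsv(haplotypes: HaplotypeMatrix, marker_map: MarkerMap,
                         path) -> None:
    """Phased haplotypes as TSV: one row per chromosome copy."""
    with open(path, "w") as fh:
        fh.write("hap_id\tsample\tpop\t" + "\t".join(marker_map.ids) + "\n")
        for i in range(haplotypes.n_haplotypes):
            s = i // 2
            fh.write(f"{haplotypes.sample_ids[s]}.{i % 2 + 1}\t"
                     f"{haplotypes.sample_ids[s]}\t"
                     f"{haplotypes.populations[s]}\t"
                     + "\t".join(map(str, haplotypes.alleles[i])) + "\n")


def read_haplotypes_tsv(path) -> HaplotypeMatrix:
    tab = pd.read_csv(path, sep="\t")
    alleles = tab.iloc[:, 3:].to_numpy(dtype=np.uint8)
    sample_ids = list(tab["sample"][0::2])
    populations = tab["pop"][0::2].to_numpy(dtype=object)
    return HaplotypeMatrix(alleles, sample_ids, populations,
                           tuple(sorted(pd.unique(populations))))
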