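# Methods

This note documents the models, estimators and numerical choices behind
`sweepscan`, and what the synthetic benchmark does and does not show
about real data.

## Problem setting

Two populations (think of two sheep breeds selected for different
production goals) have diverged by genome-wide drift; on top of that
background, recent positive selection in one population leaves three
local signatures: elevated allele-frequency differentiation
(F<sub>ST</sub>), depressed heterozygosity in the selected population,
and unusually long stretches of haplotype homozygosity. The pipeline
scans chip-density genotypes for all three, requires convergence of a
haplotype-based and a frequency-based signal before calling a region,
and then tests dense sequence variants inside the called regions for
breed-divergent allele frequencies.

## Estimators

**Weir–Cockerham θ̂ (two populations).** With per-population sample
sizes n₁, n₂ (non-missing diploids), alt-allele frequencies p₁, p₂ and
observed heterozygote fractions h₁, h₂, the variance components are

    n̄ = (n₁+n₂)/2,  n_c = (2n̄ − (n₁²+n₂²)/(2n̄)),
    p̄ = (n₁p₁+n₂p₂)/(2n̄),  s² = Σᵢ nᵢ(pᵢ−p̄)²/n̄,  h̄ = Σᵢ nᵢhᵢ/(2n̄)
    a = (n̄/n_c)[s² − (p̄(1−p̄) − s²/2 − h̄/4)/(n̄−1)]
    b = (n̄/(n̄−1))[p̄(1−p̄) − s²/2 − h̄(2n̄−1)/(4n̄)]
    c = h̄/2,          θ̂ = a/(a+b+c).

Pooled-monomorphic sites are undefined and excluded from windows.
Negative θ̂ is retained for window averaging: clipping to zero would
bias window means upward and shift the empirical tail. The Akey-style
mean-squares form (MSP−MSG)/(MSP+(n_c−1)MSG), which drops the
heterozygosity correction, is available as `fst_estimator =
"akey_msp_msg"`; the two agree closely on balanced data and the choice
is surfaced in config rather than hidden.

**Windows and tails.** Statistics are averaged over sliding 9-SNP
windows centred on each SNP, never spanning chromosomes; windows
containing undefined per-SNP values average the defined members (the
defined count is kept for audit), and chromosomes with fewer than nine
SNPs yield no windows. Outliers are the empirical 0.5% tail by
nearest rank (k = ⌊0.005·n⌋), upper for F<sub>ST</sub>, lower for
heterozygosity; ties at the threshold are all flagged.

**XP-EHH.** The site statistic is the pooled-site EHH (the iES/EHHS
formulation): at core c and extension marker j, EHH is the probability
that two chromosomes drawn without replacement from one population are
identical over the closed marker span [c..j], normalised by the
core-site homozygosity so EHH(0) = 1. Each side is integrated over
physical distance by the trapezoid rule, stopping at the linearly
interpolated crossing of the truncation threshold (default 0.05), at
an inter-marker gap above 200 kb, or at the chromosome end (the latter
two flag the core as incomplete; a config switch can drop such cores).
iES is the sum of the two side integrals; the raw score is
ln(iES_A/iES_B), standardized to z over all scored cores, with
two-sided normal P-values and significance at P < 0.001. The per-allele
alternative (separate integrals per core allele, as in iHS) is noted
but not implemented: with the log-ratio-of-integrals definition and no
stated allele conditioning, the pooled-site form is the one the
`ies2xpehh`-style pipeline computes. Integration uses physical distance
only — no genetic map is assumed at chip density. Antisymmetry under
population swap and mean-0/sd-1 standardization are enforced by tests.

**Grouping and convergence.** Flagged/significant positions within
150 kb (inclusive) join one selection signal whose interval spans the
first to last member position — single-member signals have start = end.
Signals overlap when their closed intervals share ≥ 1 bp; adjacency
does not merge. Connected components of the overlap graph that contain
at least one haplotype-based member (XP-EHH, or external hapFLK
intervals read from TSV) and at least one frequency-based member
(F<sub>ST</sub> or heterozygosity) become convergence candidate
regions; the extent is the union [min start, max end] of members and
the direction is the sign of the most extreme |z| XP-EHH value (mixed
signs are flagged, the extreme wins). Union extent was chosen over
"haplotype interval only" because it is the reading consistent with
regions whose published span equals the widest member.

**Association stage.** Hard filters keep variants with DP > 10,
QUAL > 30, MQ > 30, QD > 5 and FS < 60, all strict; a missing INFO key
fails its filter. Two callsets intersect on (chrom, pos, ref, alt),
genotypes taken from a selectable primary. The allelic test is the
Pearson chi-square (1 df, no continuity correction) on the 2×2
allele-count table, matching PLINK's `--assoc`; zero-margin tables are
excluded from both testing and the Bonferroni denominator. The
frequency divergence is D = alt-freq(popB) − alt-freq(popA) — the sign
convention is printed in every output header because the quantity is
convention-dependent — and |D| > 0.7 (strict) marks a variant
divergent. Indels flow through all steps with their class carried so
SNP/indel counts can be reported separately.

## Coordinates and coding conventions

1-based positions, closed intervals everywhere internally; BED output
converts to 0-based half-open. Genotypes are allele-B dosages with a
distinct missing sentinel (−1), never conflated with dosage 0. Only
autosomes are processed; non-autosomal records are dropped with a
logged count. Haplotype polarization recodes each column so the
pooled-minor allele is 1; a tie at exactly 0.5 codes allele A as minor
(determinism), and an already-polarized matrix leaves ties alone so the
operation is idempotent. Monomorphic columns are flagged and excluded
as XP-EHH cores. Phased input is required only for the haplotype
stage; the frequency and association stages accept unphased genotypes.

## Synthetic data generator

The generator is the package's study system: its defaults define the
conditions under which every stochastic claim is tested.

* **Drift.** Ancestral frequencies p₀ ~ Uniform(0.05, 0.95); each
  population draws Beta(p₀(1−F)/F, (1−p₀)(1−F)/F) (Balding–Nichols),
  so F is the expected per-SNP F<sub>ST</sub> — an analytic target for
  parameter-recovery tests. Default F = 0.10 per population, placing
  background differentiation in the 0.05–0.15 band typical of diverged
  breeds.
* **Map.** Exponential inter-marker spacing, mean 50 kb (chip-like
  density), 5 chromosomes × 1,000 markers by default.
* **Haplotypes.** Each sample chromosome is a mosaic of n_founders
  (default 20) founder haplotypes drawn from the population's
  frequencies. The founder switch probability is distance-scaled:
  P(switch over gap g) = 1 − (1 − s)^(g/mean_spacing) with s = 0.30.
  A flat per-marker probability was rejected because it makes LD
  constant below the mean spacing; the distance-scaled hazard gives an
  r² profile that decays in bp, with a bin-estimated half-decay of
  ~80 kb under defaults (within a factor of two of the 50 kb
  calibration target; the sampling floor of r̄² is 1/n_haplotypes).
* **Sweeps.** A sweep is planted by copying one donor haplotype's
  segment [core − span, core + span] into a carrier fraction of the
  target population's chromosomes (default 0.9, span 500 kb). This
  directly creates all three scanned signatures with a controllable
  effect size, at the cost of not modelling the partial breakdown of
  the swept haplotype by recombination — sweep edges are sharper than
  forward simulation would give.
* **Region variants.** Background variants share one frequency across
  populations (exact null for the association test); planted divergent
  variants have |freq_A − freq_B| fixed at the requested D. Genotypes
  are binomial; INFO fields are drawn so a configurable fraction fails
  each hard filter independently. Default association sample sizes are
  15 + 13 diploids, the scale of a WGS follow-up panel.
* **Reproducibility.** All randomness flows from one seed through
  named substreams per stage; identical config + seed reproduces every
  output byte for byte.

What passing the synthetic benchmark does **not** show: power on real
chip data with ascertainment bias, realistic recombination-rate
variation, phasing error (the haplotype stage requires phased input and
the package does not phase), or the behaviour of the hard filters on
real caller annotations. The generator's null is cleaner than real
data's.

## Benchmark scales

The seeded calibrations run at 5,000 markers × 2 × 60 diploids
(scan/region stages; 10 replicates sweep + 10 neutral) and 2,000
variants × 28 samples (association null, 20 replicates). These sizes
make the whole suite run in a couple of minutes while leaving each
stage's empirical behaviour (tail fractions, recovery ≥ 4/5 sweeps,
neutral CCR counts 0–2, null Bonferroni rejections 0) well resolved.

## Known limitations

* Two populations only; no multi-population F<sub>ST</sub> or hapFLK
  computation (external hapFLK intervals are merely consumed).
* Bi-allelic variants only; multi-allelic VCF records are skipped.
* The empirical-tail rule flags a fixed fraction by construction, so
  genome-wide significance is relative, not absolute; the XP-EHH
  normal P-values assume approximate normality of the standardized
  score under neutrality.
* EHH truncation (0.05), max gap (200 kb) and the core MAF filter
  (0.05) are defaults exposed in config, not estimates.
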