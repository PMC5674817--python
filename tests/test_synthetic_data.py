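import numpy as np
import pytest

import sweepscan as ss
from sweepscan.synthetic_data import write_vcf
from sweepscan.divergence import read_vcf


class TestFrequencies:
    def test_zero_drift_returns_ancestral(self):
        cfg = ss.SimulationConfig(n_chrom=1, markers_per_chrom=500,
                                  F_a=0.0, F_b=0.0, seed=2)
        p0, fa, fb = ss.simulate_frequencies(cfg)
        np.testing.assert_array_equal(fa, p0)
        np.testing.assert_array_equal(fb, p0)

    def test_same_seed_reproducible(self):
        cfg = ss.SimulationConfig(seed=42)
        _, fa1, fb1 = ss.simulate_frequencies(cfg)
        _, fa2, fb2 = ss.simulate_frequencies(ss.SimulationConfig(seed=42))
        np.testing.assert_array_equal(fa1, fa2)
        np.testing.assert_array_equal(fb1, fb2)

    def test_drift_parameter_recovered_as_mean_fst(self):
        """Balding-Nichols drift F is the expected per-SNP FST: sampling
        many diploids binomially from the drifted frequencies recovers
        mean Weir-Cockerham theta ~= F."""
        cfg = ss.SimulationConfig(n_chrom=4, markers_per_chrom=5000,
                                  F_a=0.10, F_b=0.10, seed=9)
        rng = np.random.default_rng(9)
        _, fa, fb = ss.simulate_frequencies(cfg)
        n = 500   # diploids per population
        dos = np.vstack([rng.binomial(2, fa, size=(n, len(fa))),
                         rng.binomial(2, fb, size=(n, len(fb)))]).astype(np.int8)
        g = ss.GenotypeMatrix(dos, [f"s{i}" for i in range(2 * n)],
                              np.array(["A"] * n + ["B"] * n, dtype=object))
        theta = ss.fst_weir_cockerham(g)
        assert abs(np.nanmean(theta) - 0.10) < 0.02


class TestHaplotypes:
    def test_single_founder_uniform_population(self):
        cfg = ss.SimulationConfig(n_per_pop=10, n_chrom=1,
                                  markers_per_chrom=100, n_founders=1, seed=3)
        _, haps, _ = ss.simulate_dataset(cfg)
        a = haps.alleles[haps.pop_rows("A")]
        assert (a == a[0]).all()

    def test_switch_prob_one_gives_independence(self):
        """With a switch at every marker, adjacent-marker LD collapses
        to the finite-sample expectation E[r2] ~= 1/n_haplotypes."""
        cfg = ss.SimulationConfig(n_per_pop=100, n_chrom=1,
                                  markers_per_chrom=400, switch_prob=1.0,
                                  F_a=0.0, F_b=0.0, seed=4)
        mm, haps, _ = ss.simulate_dataset(cfg)
        prof = ss.ld_decay_profile(haps, mm, max_dist_bp=200_000, pop="A")
        near = prof[prof["n_pairs"] > 50]["mean_r2"].iloc[0]
        assert near == pytest.approx(1.0 / 200, rel=0.5)

    def test_default_r2_profile_monotone_nonincreasing(self):
        cfg = ss.SimulationConfig(n_per_pop=60, n_chrom=3,
                                  markers_per_chrom=800, seed=7)
        mm, haps, _ = ss.simulate_dataset(cfg)
        prof = ss.ld_decay_profile(haps, mm, max_dist_bp=1_000_000, pop="A")
        r2 = prof["mean_r2"].dropna().to_numpy()
        assert (np.diff(r2) <= 1e-3).all()

    def test_ld_half_decay_near_calibration_target(self):
        """Default switch probability puts the r2 half-decay distance
        within a factor of two of 50 kb."""
        cfg = ss.SimulationConfig(n_per_pop=60, n_chrom=4,
                                  markers_per_chrom=2500, seed=7)
        mm, haps, _ = ss.simulate_dataset(cfg)
        prof = ss.ld_decay_profile(haps, mm, max_dist_bp=1_000_000, pop="A")
        assert 25_000 <= prof.attrs["half_decay_bp"] <= 100_000

    def test_reproducible_byte_identical(self):
        cfg = ss.SimulationConfig(n_per_pop=8, n_chrom=1,
                                  markers_per_chrom=60, seed=5)
        mm1, h1, g1 = ss.simulate_dataset(cfg)
        mm2, h2, g2 = ss.simulate_dataset(
            ss.SimulationConfig(n_per_pop=8, n_chrom=1,
                                markers_per_chrom=60, seed=5))
        np.testing.assert_array_equal(h1.alleles, h2.alleles)
        np.testing.assert_array_equal(mm1.pos_bp, mm2.pos_bp)


class TestInjectSweep:
    def _dataset(self, seed=6):
        cfg = ss.SimulationConfig(n_per_pop=30, n_chrom=1,
                                  markers_per_chrom=400, seed=seed)
        mm, haps, _ = ss.simulate_dataset(cfg)
        return cfg, mm, haps

    def test_complete_sweep_zero_heterozygosity_at_core(self):
        cfg, mm, haps = self._dataset()
        core = int(mm.pos_bp[200])
        spec = ss.SweepSpec("1", core, "A", carrier_fraction=1.0,
                            span_bp=300_000)
        out = ss.inject_sweep(haps, mm, spec, cfg.rng("sweeps"))
        a = out.alleles[out.pop_rows("A")]
        seg = (mm.pos_bp >= core - spec.span_bp) & (mm.pos_bp <= core + spec.span_bp)
        assert (a[:, seg] == a[0, seg]).all()
        het = ss.observed_heterozygosity(out.to_genotypes(), "A")
        assert het[200] == 0.0

    def test_zero_carrier_fraction_is_identity(self):
        cfg, mm, haps = self._dataset()
        spec = ss.SweepSpec("1", int(mm.pos_bp[200]), "A",
                            carrier_fraction=0.0)
        out = ss.inject_sweep(haps, mm, spec, cfg.rng("sweeps"))
        np.testing.assert_array_equal(out.alleles, haps.alleles)

    def test_heterozygosity_decreases_in_swept_population(self):
        cfg, mm, haps = self._dataset()
        core_idx = 200
        spec = ss.SweepSpec("1", int(mm.pos_bp[core_idx]), "B",
                            carrier_fraction=0.9, span_bp=400_000)
        before = ss.observed_heterozygosity(haps.to_genotypes(), "B")
        out = ss.inject_sweep(haps, mm, spec, cfg.rng("sweeps"))
        after = ss.observed_heterozygosity(out.to_genotypes(), "B")
        seg = np.flatnonzero(
            np.abs(mm.pos_bp - spec.core_pos_bp) <= spec.span_bp)
        assert after[seg].mean() < before[seg].mean()

    def test_windowed_fst_at_core_beats_neutral_tail(self):
        """Planted sweeps (carrier fraction 0.9, span 500 kb) push the
        windowed FST at the core past the neutral genome-wide 99.5th
        percentile in at least 80% of seeded replicates."""
        from sweepscan.sweep_scan import sliding_window_mean
        hits = 0
        n_rep = 20
        for seed in range(n_rep):
            cfg = ss.SimulationConfig(n_per_pop=40, n_chrom=2,
                                      markers_per_chrom=600, seed=seed)
            mm, haps, genos = ss.simulate_dataset(cfg)
            neutral = sliding_window_mean(
                ss.fst_weir_cockerham(genos), mm)
            threshold = np.nanquantile(neutral.value, 0.995)
            core = int(mm.pos_bp[mm.chrom_slice("1")[300]])
            spec = ss.SweepSpec("1", core, "A", 0.9, 500_000)
            swept = ss.inject_sweep(haps, mm, spec, cfg.rng("sweeps"))
            track = sliding_window_mean(
                ss.fst_weir_cockerham(swept.to_genotypes()), mm)
            near = (track.chrom == "1") & (
                np.abs(track.pos_bp - core) <= 100_000)
            if near.any() and np.nanmax(track.value[near]) > threshold:
                hits += 1
        assert hits >= 0.8 * n_rep


class TestVariantRegion:
    def test_planted_fixed_difference(self):
        cfg = ss.SimulationConfig(seed=1)
        region = ss.simulate_variant_region("2", 1_000_000, 2_000_000,
                                            100, 10, 1.0, cfg)
        div = region.table[region.table["divergent"]]
        assert (np.abs(div["freq_a"] - div["freq_b"]) == 1.0).all()

    def test_no_divergence_null_calibration(self):
        """Without planted divergence the naive alpha=0.05 rejection rate
        is near nominal and Bonferroni rejections are ~0."""
        naive, bonf, tested = 0, 0, 0
        for seed in range(5):
            cfg = ss.SimulationConfig(seed=seed)
            region = ss.simulate_variant_region("1", 1, 10_000_000,
                                                2000, 0, 0.0, cfg,
                                                fail_fraction=0.0)
            from sweepscan.divergence import VariantSet, allelic_chisq, \
                apply_bonferroni
            vs = VariantSet(region.table.rename(columns={"qual": "qual"}),
                            region.genotypes, region.sample_ids,
                            region.populations, ("A", "B"))
            assoc = apply_bonferroni(allelic_chisq(vs))
            p = assoc["p"].dropna()
            naive += (p < 0.05).sum()
            bonf += assoc["bonferroni_significant"].sum()
            tested += len(p)
        assert naive / tested == pytest.approx(0.05, abs=0.02)
        assert bonf == 0

    def test_vcf_round_trip(self, tmp_path):
        cfg = ss.SimulationConfig(seed=13)
        region = ss.simulate_variant_region("3", 500, 900_000, 80, 5,
                                            0.8, cfg)
        path = tmp_path / "region.vcf"
        write_vcf(region, path)
        back = read_vcf(path)
        np.testing.assert_array_equal(back.genotypes, region.genotypes)
        np.testing.assert_array_equal(back.table["pos_bp"].to_numpy(),
                                      region.table["pos_bp"].to_numpy())
        assert back.sample_ids == region.sample_ids

    def test_bounds_validation(self):
        cfg = ss.SimulationConfig(seed=1)
        with pytest.raises(ValueError):
            ss.simulate_variant_region("1", 1, 1000, 10, 20, 0.5, cfg)
        with pytest.raises(ValueError):
            ss.simulate_variant_region("1", 1, 1000, 10, 2, 1.5, cfg)
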