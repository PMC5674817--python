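import warnings

import numpy as np
import pytest

import sweepscan as ss
from sweepscan.sweep_scan import ScanTrack, flag_tail, group_signals, \
    sliding_window_mean
from conftest import random_genotype_matrix


def wc_theta_oracle(dos_a, dos_b):
    """Scalar Weir-Cockerham theta for one SNP: direct evaluation of the
    two-population variance components a, b, c from sample sizes, allele
    frequencies and heterozygote fractions."""
    stats = []
    for dos in (dos_a, dos_b):
        dos = [d for d in dos if d != -1]
        n = len(dos)
        p = sum(dos) / (2 * n)
        h = sum(1 for d in dos if d == 1) / n
        stats.append((n, p, h))
    (n1, p1, h1), (n2, p2, h2) = stats
    r = 2
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1 ** 2 + n2 ** 2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    if pbar in (0.0, 1.0):
        return float("nan")
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2
                             - hbar / 4) / (nbar - 1))
    b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                               - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    return a / (a + b + c) if (a + b + c) != 0 else float("nan")


def make_matrix(dos_a, dos_b):
    dos = np.array(list(dos_a) + list(dos_b), dtype=np.int8)[:, None]
    return ss.GenotypeMatrix(
        dos, [f"s{i}" for i in range(len(dos))],
        np.array(["A"] * len(dos_a) + ["B"] * len(dos_b), dtype=object))


class TestWeirCockerham:
    def test_fixed_difference_is_one(self):
        g = make_matrix([2] * 10, [0] * 10)
        assert ss.fst_weir_cockerham(g)[0] == pytest.approx(1.0)

    def test_identical_samples_negative_matches_oracle(self):
        dos_a = [2, 2, 0, 0]
        dos_b = [2, 2, 0, 0]
        theta = ss.fst_weir_cockerham(make_matrix(dos_a, dos_b))[0]
        expect = wc_theta_oracle(dos_a, dos_b)
        assert theta == pytest.approx(expect, rel=1e-12)
        assert theta < 0

    def test_pooled_monomorphic_undefined(self):
        g = make_matrix([0, 0, 0], [0, 0, 0])
        assert np.isnan(ss.fst_weir_cockerham(g)[0])

    def test_matches_oracle_on_random_tables(self):
        """Vectorized theta equals the scalar variance-component oracle
        on 1000 random small genotype tables."""
        rng = np.random.default_rng(17)
        for _ in range(1000):
            na, nb = rng.integers(2, 12, size=2)
            dos_a = rng.integers(0, 3, size=na)
            dos_b = rng.integers(0, 3, size=nb)
            theta = ss.fst_weir_cockerham(make_matrix(dos_a, dos_b))[0]
            expect = wc_theta_oracle(list(dos_a), list(dos_b))
            if np.isnan(expect):
                assert np.isnan(theta)
            else:
                assert theta == pytest.approx(expect, rel=1e-10)
                assert theta <= 1.0 + 1e-12

    def test_akey_alternative_close_but_distinct(self):
        rng = np.random.default_rng(2)
        g = random_genotype_matrix(rng, n_a=20, n_b=20, n_markers=200,
                                   missing_rate=0.0)
        wc = ss.fst_weir_cockerham(g, "weir_cockerham")
        akey = ss.fst_weir_cockerham(g, "akey_msp_msg")
        ok = ~np.isnan(wc)
        assert np.corrcoef(wc[ok], akey[ok])[0, 1] > 0.98


class TestObservedHeterozygosity:
    @pytest.mark.parametrize("dos,expect", [
        ([1, 1, 1, 1], 1.0),
        ([0, 2, 0, 2], 0.0),
        ([1, 1, 1, 0, 0, 0, 2, 2, 2, 2], 0.3),
    ])
    def test_fraction(self, dos, expect):
        g = make_matrix(dos, [0, 1])
        assert ss.observed_heterozygosity(g, "A")[0] == pytest.approx(expect)

    def test_all_missing_undefined(self):
        g = make_matrix([-1, -1], [0, 1])
        assert np.isnan(ss.observed_heterozygosity(g, "A")[0])


def toy_map(n, chrom="1", spacing=10_000, start=10_000):
    pos = start + spacing * np.arange(n)
    return ss.MarkerMap(np.array([chrom] * n, dtype=object),
                        np.array([f"{chrom}_m{i}" for i in range(n)],
                                 dtype=object),
                        pos, np.array(["A"] * n, dtype=object),
                        np.array(["B"] * n, dtype=object))


class TestSlidingWindow:
    def test_constant_input(self):
        mm = toy_map(20)
        track = sliding_window_mean(np.full(20, 0.2), mm)
        assert len(track.value) == 12
        np.testing.assert_allclose(track.value, 0.2)

    def test_arithmetic_nine(self):
        mm = toy_map(9)
        track = sliding_window_mean(np.arange(1.0, 10.0), mm)
        assert len(track.value) == 1
        assert track.value[0] == pytest.approx(5.0)

    def test_short_chromosome_yields_no_windows(self):
        mm = toy_map(8)
        track = sliding_window_mean(np.arange(8.0), mm)
        assert len(track.value) == 0

    def test_undefined_members_use_defined_mean(self):
        mm = toy_map(9)
        v = np.arange(1.0, 10.0)
        v[0] = np.nan
        track = sliding_window_mean(v, mm)
        assert track.value[0] == pytest.approx(np.nanmean(v))
        assert track.n_defined[0] == 8

    def test_windows_never_span_chromosomes(self):
        mm1, mm2 = toy_map(9, "1"), toy_map(9, "2")
        mm = ss.MarkerMap(np.concatenate([mm1.chrom, mm2.chrom]),
                          np.concatenate([mm1.ids, mm2.ids]),
                          np.concatenate([mm1.pos_bp, mm2.pos_bp]),
                          np.concatenate([mm1.allele_a, mm2.allele_a]),
                          np.concatenate([mm1.allele_b, mm2.allele_b]))
        track = sliding_window_mean(np.arange(18.0), mm)
        assert list(track.chrom) == ["1", "2"]
        assert track.value[0] == pytest.approx(4.0)
        assert track.value[1] == pytest.approx(13.0)

    def test_window_mean_is_permutation_invariant(self):
        rng = np.random.default_rng(1)
        v = rng.random(9)
        mm = toy_map(9)
        base = sliding_window_mean(v, mm).value[0]
        for _ in range(5):
            perm = rng.permutation(v)
            assert sliding_window_mean(perm, mm).value[0] == \
                pytest.approx(base)


class TestFlagTail:
    def _track(self, values):
        n = len(values)
        mm = toy_map(n)
        return ScanTrack(mm.chrom, mm.pos_bp, mm.ids,
                         np.asarray(values, dtype=float))

    def test_nearest_rank_count(self):
        rng = np.random.default_rng(0)
        track = self._track(rng.permutation(1000).astype(float))
        track, thr = flag_tail(track, 0.005, "upper")
        assert track.flagged.sum() == 5
        assert thr == 995.0

    def test_paper_scale_tail_holds_236_values(self):
        """At ~47,387 windows the 0.5% upper tail holds 236 values."""
        rng = np.random.default_rng(0)
        track = self._track(rng.permutation(47_387).astype(float))
        track, _ = flag_tail(track, 0.005, "upper")
        assert track.flagged.sum() == 236

    def test_lower_tail(self):
        track = self._track(np.arange(200.0))
        track, thr = flag_tail(track, 0.005, "lower")
        assert track.flagged.sum() == 1 and track.flagged[0]

    def test_ties_all_included_and_degenerate_warns(self):
        track = self._track(np.full(100, 7.0))
        with warnings.catch_warnings(record=True) as rec:
            warnings.simplefilter("always")
            track, _ = flag_tail(track, 0.01, "upper")
        assert track.flagged.all()
        assert any("flagged" in str(w.message) for w in rec)


class TestGroupSignals:
    def _flagged_track(self, pos, flagged, values=None):
        n = len(pos)
        track = ScanTrack(np.array(["1"] * n, dtype=object),
                          np.asarray(pos, dtype=np.int64),
                          np.array([f"m{i}" for i in range(n)], dtype=object),
                          np.asarray(values if values is not None
                                     else np.ones(n), dtype=float))
        track.flagged = np.asarray(flagged, dtype=bool)
        return track

    def test_within_gap_joins(self):
        track = self._flagged_track([1_000_000, 1_100_000], [True, True])
        sig = group_signals(track, "FST")
        assert len(sig) == 1
        assert (sig[0].start_bp, sig[0].end_bp) == (1_000_000, 1_100_000)

    def test_beyond_gap_splits(self):
        track = self._flagged_track([1_000_000, 1_151_000], [True, True])
        assert len(group_signals(track, "FST")) == 2

    def test_gap_is_inclusive(self):
        track = self._flagged_track([1_000_000, 1_150_000], [True, True])
        assert len(group_signals(track, "FST")) == 1

    def test_single_snp_signal(self):
        track = self._flagged_track([5_000_000], [True])
        sig = group_signals(track, "ObsHtz-A")
        assert sig[0].start_bp == sig[0].end_bp == 5_000_000

    def test_grouping_idempotent(self):
        rng = np.random.default_rng(4)
        pos = np.sort(rng.choice(10_000_000, size=50, replace=False))
        track = self._flagged_track(pos, rng.random(50) < 0.5,
                                    rng.random(50))
        sig = sorted(group_signals(track, "FST"),
                     key=lambda s: s.start_bp)
        # consecutive signals sit further apart than the grouping gap,
        # so grouping the grouped output cannot merge anything further
        for s, t in zip(sig, sig[1:]):
            assert t.start_bp - s.end_bp > 150_000


class TestLdDecay:
    def test_duplicated_marker_pair_full_ld(self):
        rng = np.random.default_rng(3)
        col = rng.integers(0, 2, size=40).astype(np.uint8)
        alleles = np.stack([col, col], axis=1)
        haps = ss.HaplotypeMatrix(alleles, [f"s{i}" for i in range(20)],
                                  np.array(["A"] * 10 + ["B"] * 10,
                                           dtype=object))
        mm = toy_map(2, spacing=5_000)
        prof = ss.ld_decay_profile(haps, mm)
        row = prof.dropna(subset=["mean_r2"]).iloc[0]
        assert row["mean_r2"] == pytest.approx(1.0)
        assert row["mean_dprime"] == pytest.approx(1.0)

    def test_independent_markers_sampling_floor(self):
        rng = np.random.default_rng(6)
        alleles = rng.integers(0, 2, size=(200, 60)).astype(np.uint8)
        haps = ss.HaplotypeMatrix(alleles, [f"s{i}" for i in range(100)],
                                  np.array(["A"] * 50 + ["B"] * 50,
                                           dtype=object))
        mm = toy_map(60, spacing=2_000)
        prof = ss.ld_decay_profile(haps, mm)
        near = prof.dropna(subset=["mean_r2"]).iloc[0]
        assert near["mean_r2"] == pytest.approx(1.0 / 200, rel=0.5)
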