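"""Sliding-window heterozygosity and H_max peak extraction."""

import numpy as np
import pytest

from sgscan import (
    HET,
    HOM,
    MISSING,
    HProfile,
    SimConfig,
    detect_hmax_segments,
    scan_all,
    simulate_genotypes,
    window_heterozygosity,
)

from conftest import make_matrix


def brute_force_H(codes, m):
    """Independent per-window recount of H = h/(g+h)."""
    M = len(codes)
    out = np.full(M, np.nan)
    for i in range(m, M - m):
        win = codes[i - m : i + m + 1]
        h = int(np.sum(win == HET))
        g = int(np.sum(win == HOM))
        if g + h:
            out[i] = h / (g + h)
    return out


def profile(h_values, m=1):
    h = np.asarray(h_values, dtype=float)
    pos = 1000 * (1 + np.arange(len(h), dtype=np.int64))
    return HProfile("ind", "chr1", pos, h, m)


class TestWindowHeterozygosity:
    def test_all_het_window_gives_one(self):
        gm = make_matrix([[HET] * 5])
        (hp,) = window_heterozygosity(gm, "s0", m=2)
        assert hp.h_values[2] == 1.0
        assert np.isnan(hp.h_values[[0, 1, 3, 4]]).all()

    def test_missing_excluded_from_both_counts(self):
        # window of 5 with h=1, g=3, one MISSING -> H = 1/4
        gm = make_matrix([[HOM, HET, MISSING, HOM, HOM]])
        (hp,) = window_heterozygosity(gm, "s0", m=2)
        assert hp.h_values[2] == pytest.approx(0.25)

    def test_all_missing_window_undefined(self):
        gm = make_matrix([[MISSING] * 5 + [HET] * 2])
        (hp,) = window_heterozygosity(gm, "s0", m=2)
        assert np.isnan(hp.h_values[2])

    @pytest.mark.parametrize("m", [1, 5, 50])
    def test_matches_per_window_recount(self, m, rng):
        codes = rng.choice([HOM, HET, MISSING], size=(1, 501), p=[0.6, 0.3, 0.1])
        gm = make_matrix(codes)
        (hp,) = window_heterozygosity(gm, "s0", m=m)
        np.testing.assert_allclose(
            hp.h_values, brute_force_H(codes[0], m), equal_nan=True
        )

    def test_per_position_m_vector_matches_scalar(self, rng):
        codes = rng.choice([HOM, HET], size=(1, 101), p=[0.7, 0.3])
        gm = make_matrix(codes)
        (scalar,) = window_heterozygosity(gm, "s0", m=5)
        (vector,) = window_heterozygosity(gm, "s0", m=np.full(101, 5))
        np.testing.assert_allclose(scalar.h_values, vector.h_values, equal_nan=True)

    def test_short_chromosome_skipped_with_warning(self):
        gm = make_matrix([[HET] * 4])
        with pytest.warns(UserWarning, match="skipped"):
            assert window_heterozygosity(gm, "s0", m=2) == []

    def test_adjacent_window_het_count_bound(self, rng):
        # moving the window one variant swaps at most 2 genotypes, so with
        # no missing data |h(i+1) - h(i)| <= 2
        codes = rng.choice([HOM, HET], size=(1, 400), p=[0.5, 0.5])
        gm = make_matrix(codes)
        m = 10
        (hp,) = window_heterozygosity(gm, "s0", m=m)
        h_counts = hp.h_values[m:-m] * (2 * m + 1)
        assert np.all(np.abs(np.diff(h_counts)) <= 2 + 1e-9)


class TestDetectHmaxSegments:
    def test_single_unimodal_run(self):
        segs = detect_hmax_segments(
            profile([0.1, 0.2, 0.5, 0.2, 0.1]), min_rise=1, min_fall=1, min_prominence=0
        )
        assert len(segs) == 1
        seg = segs[0]
        assert (seg.start_pos, seg.peak_pos, seg.end_pos) == (1000, 3000, 5000)
        assert seg.peak_h == pytest.approx(0.5)

    def test_constant_sequence_yields_nothing(self):
        assert detect_hmax_segments(
            profile([0.3] * 8), min_rise=1, min_fall=1, min_prominence=0
        ) == []

    def test_peak_plateau_reports_first_variant(self):
        segs = detect_hmax_segments(
            profile([0.1, 0.3, 0.5, 0.5, 0.5, 0.3, 0.1]),
            min_rise=1, min_fall=1, min_prominence=0,
        )
        assert len(segs) == 1
        assert segs[0].peak_pos == 3000  # first index of the maximal plateau

    def test_min_rise_and_fall_thresholds(self):
        h = [0.1, 0.2, 0.3, 0.4, 0.3, 0.2, 0.1]
        assert len(detect_hmax_segments(profile(h), 3, 3, 0.0)) == 1
        assert detect_hmax_segments(profile(h), 4, 3, 0.0) == []
        assert detect_hmax_segments(profile(h), 3, 4, 0.0) == []
        # monotone rise with no fall is not a segment
        assert detect_hmax_segments(profile([0.1, 0.2, 0.3, 0.4]), 1, 1, 0.0) == []

    def test_prominence_filter(self):
        h = [0.30, 0.35, 0.40, 0.35, 0.30]
        assert len(detect_hmax_segments(profile(h), 1, 1, 0.10)) == 1
        assert detect_hmax_segments(profile(h), 1, 1, 0.11) == []

    def test_two_peaks_share_valley_boundary(self):
        h = [0.1, 0.4, 0.1, 0.5, 0.1]
        segs = detect_hmax_segments(profile(h), 1, 1, 0.0)
        assert len(segs) == 2
        assert segs[0].end_pos == segs[1].start_pos == 3000

    def test_undefined_values_are_skipped(self):
        h = [np.nan, 0.1, 0.2, np.nan, 0.5, 0.2, 0.1, np.nan]
        (seg,) = detect_hmax_segments(profile(h), 1, 1, 0.0)
        assert seg.peak_pos == 5000
        assert seg.start_pos == 2000

    def test_peak_h_is_segment_maximum(self, rng):
        h = rng.random(300)
        segs = detect_hmax_segments(profile(h), 1, 1, 0.0)
        assert segs, "random noise should contain unimodal runs"
        pos = 1000 * (1 + np.arange(300))
        for seg in segs:
            a = np.searchsorted(pos, seg.start_pos)
            b = np.searchsorted(pos, seg.end_pos)
            assert seg.peak_h == pytest.approx(h[a : b + 1].max())


class TestScanAll:
    def test_no_segments_gives_k_zero(self):
        gm = make_matrix(np.full((2, 7), HET, dtype=np.int8))
        sets = scan_all(gm, m=2, min_rise=1, min_fall=1, min_prominence=0.0)
        assert [cs.k for cs in sets] == [0, 0]

    def test_identical_genotypes_identical_candidates(self, rng):
        row = rng.choice([HOM, HET], size=200, p=[0.7, 0.3])
        gm = make_matrix(np.vstack([row, row]))
        a, b = scan_all(gm, m=3, min_rise=1, min_fall=1, min_prominence=0.0)
        assert a.positions == b.positions
        assert a.peak_h == b.peak_h

    def test_count_conservation_on_simulated_cohort(self):
        cfg = SimConfig(
            n_variants=3000,
            chrom_length_bp=3_000_000,
            n_carriers=8,
            maf_dist=("fixed", 0.04),
            elevation_halfwidth_bp=150_000,
            seed=11,
        )
        gm, _ = simulate_genotypes(cfg)
        sets = scan_all(gm, m=20, min_rise=2, min_fall=2, min_prominence=0.1)
        total = sum(cs.k for cs in sets)
        assert total == sum(len(cs.positions) for cs in sets)
        assert all(cs.k >= 1 for cs in sets)  # the implanted peak is always found

    def test_implanted_peak_recovered_within_window(self):
        for seed in range(5):
            cfg = SimConfig(
                n_variants=2000,
                chrom_length_bp=2_000_000,
                n_carriers=1,
                maf_dist=("fixed", 0.01),
                elevation_halfwidth_bp=200_000,
                p_het_near=1.0,
                seed=seed,
            )
            gm, truth = simulate_genotypes(cfg)
            (cs,) = scan_all(gm, m=10, min_rise=2, min_fall=2, min_prominence=0.3)
            peaks_in_window = [
                p for _, p in cs.positions
                if truth["window_start"] <= p <= truth["window_end"]
            ]
            assert peaks_in_window, f"no peak inside implanted window (seed {seed})"
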