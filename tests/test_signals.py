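import numpy as np
import pandas as pd
import pytest

from shapemotif.io import Region, SignalTrack
from shapemotif.signals import (
    MarkDistribution,
    UnscorableWordError,
    aggregate_mark_distribution,
    asymmetry_score,
    combined_score,
    intensity_score,
    kurtosis_score,
    normalize_and_smooth,
    smooth_profile,
    symmetrized_kl,
)


def constant_track(value=2.5, length=5000, name="t"):
    track = SignalTrack(name)
    track.set_chrom("chr1", 0, np.full(length, value))
    return track


def make_md(bins, bin_width=10, n_occ=1):
    bins = np.asarray(bins, dtype=float)
    md = MarkDistribution(
        word="W", track_name="t", bins=bins, bin_width=bin_width,
        halfwidth=len(bins) * bin_width // 2, n_occurrences_used=n_occ,
    )
    return md


def region_at(start, length=200, chrom="chr1", idx=0):
    return Region(id=f"r{idx}", sequence="A" * length, chrom=chrom, start=start, end=start + length)


class TestAggregation:
    def test_constant_track_fills_every_bin(self):
        track = constant_track(2.5)
        regions = [region_at(1000)]
        md = aggregate_mark_distribution([(0, 50, "+")], regions, track, K=9,
                                         halfwidth=50, bin_width=10)
        assert md.n_bins == 10
        assert np.allclose(md.bins, 25.0)

    def test_two_identical_occurrences_double_bins(self):
        track = constant_track(1.5)
        regions = [region_at(1000)]
        one = aggregate_mark_distribution([(0, 50, "+")], regions, track, 9, 50, 10)
        two = aggregate_mark_distribution([(0, 50, "+"), (0, 50, "+")], regions, track, 9, 50, 10)
        assert np.allclose(two.bins, 2 * one.bins)
        assert two.n_occurrences_used == 2

    def test_additivity_over_occurrence_sets(self):
        rng = np.random.default_rng(0)
        track = SignalTrack("t")
        track.set_chrom("chr1", 0, rng.random(6000))
        regions = [region_at(1000), region_at(3000, idx=1)]
        occ1 = [(0, 10, "+"), (0, 80, "-")]
        occ2 = [(1, 5, "+"), (1, 100, "+")]
        md1 = aggregate_mark_distribution(occ1, regions, track, 9, 200, 25)
        md2 = aggregate_mark_distribution(occ2, regions, track, 9, 200, 25)
        md12 = aggregate_mark_distribution(occ1 + occ2, regions, track, 9, 200, 25)
        assert np.allclose(md12.bins, md1.bins + md2.bins)

    def test_minus_strand_window_reversed(self):
        track = SignalTrack("t")
        values = np.zeros(4000)
        values[2100:2200] = 1.0  # asymmetric: signal right of centre 2000+...
        track.set_chrom("chr1", 0, values)
        regions = [region_at(1900)]
        # occurrence centre at 1900 + 96 + 4 = 2000
        fwd = aggregate_mark_distribution([(0, 96, "+")], regions, track, 9, 200, 25)
        rev = aggregate_mark_distribution([(0, 96, "-")], regions, track, 9, 200, 25)
        assert np.allclose(rev.bins, fwd.bins[::-1])

    def test_window_off_track_zero_filled(self):
        track = constant_track(1.0, length=100)
        regions = [region_at(0)]
        md = aggregate_mark_distribution([(0, 0, "+")], regions, track, 9, 500, 50)
        assert md.bins.sum() < 2 * 500  # most of the window is uncovered
        assert md.n_occurrences_used == 1

    def test_no_occurrences_flagged_unscorable(self):
        with pytest.raises(UnscorableWordError):
            aggregate_mark_distribution([], [region_at(0)], constant_track(), 9, 100, 10)

    def test_gaussian_peak_recovered_in_bins(self):
        # closed-form binned Gaussian oracle at 200 planted occurrences
        sigma, amp = 100.0, 5.0
        span = 300_000
        centres = np.arange(1000, span - 1000, 1500)[:200]
        x = np.arange(span, dtype=float)
        values = np.zeros(span)
        for c in centres:
            values += amp * np.exp(-((x - c) ** 2) / (2 * sigma**2))
        track = SignalTrack("g")
        track.set_chrom("chr1", 0, values)
        regions = [region_at(c - 100, idx=i) for i, c in enumerate(centres)]
        occ = [(i, 96, "+") for i in range(len(centres))]  # centre = start+96+4
        md = aggregate_mark_distribution(occ, regions, track, 9, 400, 25)
        B, w = md.n_bins, md.bin_width
        expected = np.array([
            len(centres) * amp * np.sum(np.exp(-((np.arange(-400 + b * w, -400 + (b + 1) * w)) ** 2) / (2 * sigma**2)))
            for b in range(B)
        ])
        assert np.allclose(md.bins, expected, rtol=0.02, atol=1.0)


class TestSmoothing:
    def test_uniform_profile_is_fixed_point(self):
        md = make_md(np.full(64, 3.0))
        normalize_and_smooth(md)
        assert np.allclose(md.normalized, 1 / 64)
        assert np.allclose(md.smoothed, 1 / 64, atol=1e-12)

    def test_unit_mass_conserved(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            md = make_md(rng.random(80))
            normalize_and_smooth(md)
            assert md.normalized.sum() == pytest.approx(1.0, abs=1e-9)
            assert md.smoothed.sum() == pytest.approx(1.0, abs=1e-9)
            assert np.all(md.smoothed >= 0)

    def test_single_spike_widens_but_conserves(self):
        bins = np.zeros(64)
        bins[32] = 10.0
        md = make_md(bins)
        normalize_and_smooth(md)
        assert md.smoothed.sum() == pytest.approx(1.0, abs=1e-9)
        assert (md.smoothed > 1e-6).sum() > 3  # spread beyond one bin

    def test_low_frequency_cosine_is_eigenprofile(self):
        B = 64
        x = np.arange(B)
        profile = 1.0 + 0.5 * np.cos(2 * np.pi * 2 * x / B)  # k=2, retained
        sm = smooth_profile(profile / profile.sum())
        assert np.allclose(sm, profile / profile.sum(), atol=1e-9)

    def test_high_frequency_cosine_removed(self):
        B = 64
        x = np.arange(B)
        profile = 1.0 + 0.5 * np.cos(2 * np.pi * 20 * x / B)  # k=20 > keep limit 12
        sm = smooth_profile(profile / profile.sum())
        assert np.allclose(sm, 1 / B, atol=1e-9)

    def test_all_zero_profile_uniform_fallback(self):
        md = make_md(np.zeros(16))
        with pytest.warns(UserWarning):
            normalize_and_smooth(md)
        assert np.allclose(md.smoothed, 1 / 16)


class TestIntensity:
    def test_constant_window_closed_form(self):
        track = constant_track(1.0)
        md = aggregate_mark_distribution([(0, 50, "+")], [region_at(1000)], track, 9, 100, 10)
        assert intensity_score(md) == pytest.approx(200.0)

    def test_invariant_under_occurrence_duplication(self):
        track = constant_track(3.0)
        one = aggregate_mark_distribution([(0, 50, "+")], [region_at(1000)], track, 9, 100, 10)
        four = aggregate_mark_distribution([(0, 50, "+")] * 4, [region_at(1000)], track, 9, 100, 10)
        assert intensity_score(four) == pytest.approx(intensity_score(one))

    def test_equals_bruteforce_mean_window_sum(self):
        rng = np.random.default_rng(2)
        values = rng.random(8000)
        track = SignalTrack("t")
        track.set_chrom("chr1", 0, values)
        regions = [region_at(2000)]
        occ = [(0, o, "+") for o in (3, 47, 120)]
        md = aggregate_mark_distribution(occ, regions, track, 9, 200, 25)
        brute = np.mean([
            values[2000 + o + 4 - 200 : 2000 + o + 4 + 200].sum() for o, in [(3,), (47,), (120,)]
        ])
        assert intensity_score(md) == pytest.approx(brute)


class TestKurtosis:
    def test_discrete_uniform_matches_exact_formula(self):
        B = 64
        md = make_md(np.full(B, 1.0))
        normalize_and_smooth(md)
        exact = -6 / 5 * (B**2 + 1) / (B**2 - 1)  # discrete uniform excess kurtosis
        assert kurtosis_score(md) == pytest.approx(exact, abs=1e-9)
        assert kurtosis_score(md) == pytest.approx(-1.2, abs=0.01)

    def test_binned_gaussian_near_zero(self):
        B = 80
        x = np.arange(B) - (B - 1) / 2
        md = make_md(np.exp(-(x**2) / (2 * 5.0**2)))
        md.smoothed = md.bins / md.bins.sum()
        assert abs(kurtosis_score(md)) < 0.05

    def test_two_far_spikes_give_minus_two(self):
        bins = np.zeros(64)
        bins[10] = bins[53] = 1.0
        md = make_md(bins)
        md.smoothed = bins / bins.sum()
        assert kurtosis_score(md) == pytest.approx(-2.0, abs=1e-9)

    def test_zero_variance_capped(self):
        bins = np.zeros(16)
        bins[7] = 1.0
        md = make_md(bins)
        md.smoothed = bins.copy()
        assert kurtosis_score(md) == 50.0

    def test_invariant_under_translation_and_scale(self):
        rng = np.random.default_rng(3)
        p = rng.random(40)
        p /= p.sum()
        embedded1, embedded2 = np.zeros(60), np.zeros(60)
        embedded1[2:42] = p  # same shape translated along the bin axis,
        embedded2[15:55] = p  # reported at a different bin width
        md1 = make_md(embedded1, bin_width=10)
        md1.smoothed = embedded1
        md2 = make_md(embedded2, bin_width=50)
        md2.smoothed = embedded2
        assert kurtosis_score(md1) == pytest.approx(kurtosis_score(md2), abs=1e-9)


class TestAsymmetry:
    def test_mirror_symmetric_profile_zero(self):
        p = np.array([0.1, 0.2, 0.3, 0.4, 0.4, 0.3, 0.2, 0.1])
        md = make_md(p)
        md.smoothed = p / p.sum()
        assert asymmetry_score(md) == pytest.approx(0.0, abs=1e-6)

    def test_swap_halves_invariant(self):
        rng = np.random.default_rng(4)
        p = rng.random(20)
        q = np.concatenate([p[10:][::-1], p[:10][::-1]])  # mirror the whole profile
        md1, md2 = make_md(p), make_md(q)
        md1.smoothed = p / p.sum()
        md2.smoothed = q / q.sum()
        assert asymmetry_score(md1) == pytest.approx(asymmetry_score(md2), abs=1e-9)

    def test_hand_computed_toy(self):
        # lhs=(0.8,0.2); rhs reversed = (0.2,0.8): KL terms are antisymmetric
        p = np.array([0.8, 0.2, 0.8, 0.2])  # B=4: lhs (0.8,0.2), rhs-mirrored (0.2,0.8)
        md = make_md(p)
        md.smoothed = p / p.sum()
        expect = 0.8 * np.log(0.8 / 0.2) + 0.2 * np.log(0.2 / 0.8)
        assert asymmetry_score(md) == pytest.approx(expect, abs=1e-3)

    def test_symmetrized_kl_is_symmetric_and_nonnegative(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            p, q = rng.random(12), rng.random(12)
            assert symmetrized_kl(p, q) == pytest.approx(symmetrized_kl(q, p), abs=1e-12)
            assert symmetrized_kl(p, q) >= 0
        assert symmetrized_kl(p, p) == pytest.approx(0.0, abs=1e-12)


class TestCombinedScore:
    def _table(self):
        return pd.DataFrame(
            {
                "word": ["W1", "W2", "W3"],
                "wc": [100, 90, 50],
                "lam": [10.0, 9.0, 10.0],
                "pvalue": [1e-9, 1e-9, 1e-6],
                "S_W": [10.0, 10.0, 5.0],
                "SI_t": [5.0, 5.0, 1.0],
                "SK_t": [2.0, -1.2, 0.0],
                "SA_t": [0.0, 0.5, 0.1],
            }
        )

    def test_all_beta_zero_reduces_to_sw_ranking(self):
        out = combined_score(self._table(), ["t"], 0, 0, 0)
        assert list(out["word"][:2]) == ["W1", "W2"]  # S_W ties keep stable order
        assert out["S"].tolist() == sorted(out["S"], reverse=True)
        sw_order = self._table().sort_values("S_W", ascending=False, kind="stable")["word"]
        assert list(out["word"]) == list(sw_order)

    def test_kurtosis_breaks_sw_tie(self):
        out = combined_score(self._table(), ["t"], 0.0, 0.5, 0.0)
        assert list(out["word"])[0] == "W1"  # peaked profile wins the tie

    def test_linear_combination_invariant(self):
        bI, bK, bA = 0.3, 0.5, 0.5
        out = combined_score(self._table(), ["t"], bI, bK, bA)
        recomputed = (
            bI * out["feat_I"] + bK * out["feat_K"] + bA * out["feat_A"] + out["feat_W"]
        )
        assert np.allclose(out["S"], recomputed, atol=1e-9)

    def test_no_tracks_scores_by_sw(self):
        df = self._table()[["word", "wc", "lam", "pvalue", "S_W"]]
        out = combined_score(df, [], 0.3, 0.5, 0.5)
        assert list(out["word"]) == ["W1", "W2", "W3"]
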