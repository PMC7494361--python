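"""Force-calling, peak calling, profiles and binned overlap curves."""

import numpy as np
import pandas as pd
import pytest

from meiohot import chip
from meiohot.coverage import CoverageTrack


def _track(arr, **kw):
    return CoverageTrack({"1": np.asarray(arr, dtype=float)}, **kw)


class TestForceCall:
    def test_null_ratio_gives_zero(self, flat_tracks):
        ip, ctl = flat_tracks
        wins = pd.DataFrame({"chrom": ["1"], "start": [100], "end": [600]})
        calls = chip.force_call(ip, ctl, wins)
        assert calls.enrichment.iloc[0] == pytest.approx(0.0)

    def test_zero_ip_count(self):
        ip = _track(np.r_[np.zeros(500), np.ones(500)])
        ctl = _track(np.ones(1000))
        calls = chip.force_call(ip, ctl, pd.DataFrame(
            {"chrom": ["1"], "start": [0], "end": [500]}))
        assert calls.enrichment.iloc[0] == 0.0
        assert calls.p_value.iloc[0] == 1.0

    def test_zero_input_flagged_uninformative(self):
        ip = _track(np.ones(1000))
        ctl = _track(np.r_[np.zeros(500), np.ones(500)])
        calls = chip.force_call(ip, ctl, pd.DataFrame(
            {"chrom": ["1"], "start": [0], "end": [500]}))
        assert not calls.informative.iloc[0]

    def test_enrichment_monotone_in_ip_count(self, rng):
        base = rng.poisson(2.0, 50_000).astype(float)
        ctl = _track(base)
        wins = pd.DataFrame({"chrom": ["1"], "start": [1000], "end": [2000]})
        betas, ps = [], []
        for extra in (0, 5, 10, 20):
            arr = base.copy()
            arr[1000:2000] += extra
            calls = chip.force_call(_track(arr), ctl, wins)
            betas.append(calls.enrichment.iloc[0])
            ps.append(calls.p_value.iloc[0])
        assert betas == sorted(betas)
        assert ps == sorted(ps, reverse=True)

    def test_beta_recovery_in_simulation(self, rng):
        """Windows with multiplicative enrichment 4 above Poisson background
        recover mean beta ~ 4."""
        L = 5_000_000
        arr = rng.poisson(1.0, L).astype(float)
        starts = np.arange(100_000, 110_000, 1000)
        for s in starts:
            arr[s:s + 1000] = rng.poisson(5.0, 1000)
        calls = chip.force_call(_track(arr), _track(rng.poisson(1.0, L)),
                                pd.DataFrame({"chrom": "1", "start": starts,
                                              "end": starts + 1000}))
        assert calls.enrichment.mean() == pytest.approx(4.0, rel=0.06)


class TestCallPeaks:
    def test_single_spike(self, rng):
        arr = rng.poisson(1.0, 100_000).astype(float)
        arr[50_000:50_100] += 25
        peaks = chip.call_peaks(_track(arr), _track(rng.poisson(1.0, 100_000)))
        assert len(peaks) == 1
        assert abs(peaks.peaks.center.iloc[0] - 50_050) < 150

    def test_tie_broken_leftmost(self):
        ip = np.zeros(5000)
        ip[1000] = 60.0
        ip[1100] = 60.0
        peaks = chip.call_peaks(_track(ip), _track(np.ones(5000)),
                                window_halfwidth=0)
        assert len(peaks) == 1
        assert peaks.peaks.center.iloc[0] == 1000

    def test_null_false_positives_bounded(self, rng):
        """On a pure-null megabase the peak count stays within the binomial
        expectation implied by pthresh."""
        L = 1_000_000
        peaks = chip.call_peaks(_track(rng.poisson(2.0, L)),
                                _track(rng.poisson(2.0, L)), pthresh=1e-5)
        expected = L * 1e-5
        assert len(peaks) <= expected + 4 * np.sqrt(expected) + 1

    def test_agrees_with_force_call_at_summit(self, genome_sim):
        tracks, _, _ = genome_sim
        peaks = chip.call_peaks(tracks["zcwpw1"], tracks["input"], pthresh=1e-8)
        assert len(peaks) > 0
        hw = 50
        wins = pd.DataFrame({
            "chrom": peaks.peaks.chrom,
            "start": peaks.peaks.center - hw,
            "end": peaks.peaks.center + hw + 1,
        })
        calls = chip.force_call(tracks["zcwpw1"], tracks["input"], wins)
        assert (calls.p_value < 1e-8).all()

    def test_min_separation_respected(self, genome_sim):
        tracks, _, _ = genome_sim
        peaks = chip.call_peaks(tracks["zcwpw1"], tracks["input"]).peaks
        for _, grp in peaks.groupby("chrom"):
            gaps = np.diff(np.sort(grp.center.to_numpy()))
            assert (gaps > 250).all()


class TestFilterPeaks:
    def _peakset(self, centers, inputs=None, likes=None):
        n = len(centers)
        df = pd.DataFrame({
            "chrom": ["1"] * n, "start": centers, "end": [c + 1 for c in centers],
            "center": centers,
            "input_coverage": inputs if inputs is not None else [50.0] * n,
            "likelihood": likes if likes is not None else [10.0] * n,
        })
        return chip.PeakSet(df)

    def test_hand_counted_fixture(self):
        """20 peaks with 3 constructed violations -> 17 survive (the
        top-likelihood filter is disabled for the count to stay hand-checkable)."""
        centers = [10_000 * i for i in range(1, 21)]
        inputs = [50.0] * 20
        inputs[4] = 3.0           # low input
        inputs[9] = 5.0           # boundary: <= 5 removed
        promoters = pd.DataFrame({"chrom": ["1"], "center": [20_001]})  # within 2.5kb of peak 2
        ps = chip.filter_peaks(self._peakset(centers, inputs),
                               promoter_marks=promoters, drop_top_likelihood=0,
                               input_quantile=1.0)
        assert len(ps) == 17

    def test_promoter_boundary_exclusive(self):
        promoters = pd.DataFrame({"chrom": ["1"], "center": [12_500]})
        ps = chip.filter_peaks(self._peakset([10_000]), promoter_marks=promoters,
                               drop_top_likelihood=0, input_quantile=1.0)
        assert len(ps) == 1  # exactly 2.5 kb away is retained
        ps2 = chip.filter_peaks(self._peakset([10_001]), promoter_marks=promoters,
                                drop_top_likelihood=0, input_quantile=1.0)
        assert len(ps2) == 0

    def test_top_likelihood_removed(self):
        likes = list(range(20))
        ps = chip.filter_peaks(self._peakset([10_000 * i for i in range(1, 21)],
                                             likes=likes),
                               drop_top_likelihood=5, input_quantile=1.0)
        assert len(ps) == 15
        assert ps.peaks.likelihood.max() == 14

    def test_clean_set_identity(self):
        ps = self._peakset([10_000, 50_000, 90_000])
        out = chip.filter_peaks(ps, promoter_marks=pd.DataFrame(
            {"chrom": [], "center": []}), drop_top_likelihood=0, input_quantile=1.0)
        assert len(out) == 3


class TestDedupNearby:
    def _peakset(self, centers, chrom="1"):
        return chip.PeakSet(pd.DataFrame({
            "chrom": [chrom] * len(centers), "start": centers,
            "end": [c + 1 for c in centers], "center": centers}))

    def test_pair_both_removed(self):
        out = chip.dedup_nearby(self._peakset([10_000, 13_000]))
        assert len(out) == 0

    def test_isolated_identity(self):
        out = chip.dedup_nearby(self._peakset([10_000, 20_000, 30_000]))
        assert len(out) == 3

    def test_chain_removed_transitively(self):
        out = chip.dedup_nearby(self._peakset([10_000, 13_000, 16_000]))
        assert len(out) == 0

    def test_matches_pairwise_oracle(self, rng):
        centers = np.sort(rng.choice(200_000, 50, replace=False))
        out = chip.dedup_nearby(self._peakset(list(centers)))
        keep_oracle = [c for c in centers
                       if all(abs(c - o) >= 4000 for o in centers if o != c)]
        assert out.peaks.center.tolist() == keep_oracle


class TestAggregateProfile:
    def test_flat_tracks_give_unity(self, flat_tracks, toy_regions):
        ip, ctl = flat_tracks
        prof = chip.aggregate_profile(ip, ctl, toy_regions, flank=500)
        np.testing.assert_allclose(prof.ratio, 1.0)

    def test_matches_naive_loop(self, rng, toy_regions):
        ip = _track(rng.poisson(3.0, 20_000))
        ctl = _track(rng.poisson(2.0, 20_000))
        flank = 100
        prof = chip.aggregate_profile(ip, ctl, toy_regions, flank=flank)
        # brute force
        for k, off in enumerate(range(-flank, flank + 1)):
            vals_ip, vals_ctl = [], []
            for _, r in toy_regions.iterrows():
                o = -off if r.strand == "-" else off
                p = int(r.center) + o
                vals_ip.append(ip.data["1"][p])
                vals_ctl.append(ctl.data["1"][p])
            if np.mean(vals_ctl) == 0:
                assert np.isnan(prof.ratio.iloc[k])
                continue
            exp = (np.mean(vals_ip) / ip.total) / (np.mean(vals_ctl) / ctl.total)
            assert prof.ratio.iloc[k] == pytest.approx(exp)

    def test_edge_fill_zero(self):
        ip = _track(np.ones(1000))
        ctl = _track(np.ones(1000))
        regions = pd.DataFrame({"chrom": ["1"], "center": [50], "strand": ["+"]})
        prof = chip.aggregate_profile(ip, ctl, regions, flank=200)
        off = prof.offset.to_numpy()
        assert (prof.ip_norm[off < -50] == 0).all()
        assert prof.ratio[off >= -50].notna().all()

    def test_empty_regions_error(self, flat_tracks):
        ip, ctl = flat_tracks
        with pytest.raises(ValueError):
            chip.aggregate_profile(ip, ctl, pd.DataFrame(columns=["chrom", "center"]))


class TestHeatmapMatrix:
    def test_values_within_quantiles(self, rng, toy_regions):
        ip = _track(rng.poisson(3.0, 20_000))
        ctl = _track(rng.poisson(3.0, 20_000))
        pm = chip.heatmap_matrix(ip, ctl, toy_regions, flank=500)
        assert pm.matrix.min() >= np.quantile(pm.matrix, 0.0)  # finite
        # recompute unclipped ratio and check the clip bounds are its quantiles
        pm_raw = chip.heatmap_matrix(ip, ctl, toy_regions, flank=500,
                                     quantiles=(0.0, 1.0))
        lo = np.quantile(pm_raw.matrix, 0.01)
        hi = np.quantile(pm_raw.matrix, 0.99)
        assert pm.matrix.min() >= lo - 1e-12
        assert pm.matrix.max() <= hi + 1e-12

    def test_row_order_matches_sort_oracle(self, rng):
        regions = pd.DataFrame({"chrom": ["1"] * 6,
                                "center": [2000, 5000, 8000, 11000, 14000, 17000],
                                "strand": ["+"] * 6})
        ip = _track(rng.poisson(2.0, 20_000))
        ctl = _track(rng.poisson(2.0, 20_000))
        pm = chip.heatmap_matrix(ip, ctl, regions, flank=500, order_window=200)
        means = [ip.data["1"][c - 100:c + 100].mean() for c in regions.center]
        expected = list(np.argsort(-np.array(means), kind="stable"))
        assert pm.row_order.tolist() == expected

    def test_constant_tracks_constant_matrix(self, flat_tracks, toy_regions):
        ip, ctl = flat_tracks
        pm = chip.heatmap_matrix(ip, ctl, toy_regions, flank=500)
        assert np.allclose(pm.matrix, pm.matrix[0, 0])


class TestRandomPeaks:
    SIZES = {"1": 5_000_000, "2": 5_000_000}

    def test_seed_reproducibility(self):
        a = chip.random_peaks(500, self.SIZES, seed=72346)
        b = chip.random_peaks(500, self.SIZES, seed=72346)
        pd.testing.assert_frame_equal(a.peaks, b.peaks)

    def test_min_separation(self):
        ps = chip.random_peaks(500, self.SIZES, min_sep=4000, seed=1).peaks
        for _, grp in ps.groupby("chrom"):
            assert (np.diff(np.sort(grp.center)) >= 4000).all()

    def test_overlap_matches_coverage_fraction(self):
        """Uniform placements overlap an interval set in proportion to the
        fraction of the genome it covers."""
        ps = chip.random_peaks(2000, self.SIZES, min_sep=1000, seed=9).peaks
        # features covering 7% of each chromosome
        feats = []
        for chrom, size in self.SIZES.items():
            starts = np.arange(0, size, 100_000)
            feats.append(pd.DataFrame({"chrom": chrom, "start": starts,
                                       "end": starts + 7000}))
        features = pd.concat(feats, ignore_index=True)
        from meiohot.intervals import overlaps_any
        frac = overlaps_any(ps, features).mean()
        assert frac == pytest.approx(0.07, abs=3 * np.sqrt(0.07 * 0.93 / 2000))

    def test_infeasible_density_errors(self):
        with pytest.raises(ValueError):
            chip.random_peaks(10_000, {"1": 100_000}, min_sep=4000)


class TestOverlapByEnrichment:
    def _peaks(self, rng, n=500):
        centers = np.sort(rng.choice(5_000_000, n, replace=False))
        return pd.DataFrame({"chrom": "1", "start": centers, "end": centers + 100,
                             "center": centers, "enrichment": rng.gamma(2, 2, n)})

    def test_equal_bin_sizes(self, rng):
        peaks = self._peaks(rng)
        features = pd.DataFrame({"chrom": ["1"], "start": [0], "end": [1]})
        out = chip.overlap_by_enrichment(peaks, features)
        assert out.n.max() - out.n.min() <= 1

    def test_all_overlap(self, rng):
        peaks = self._peaks(rng)
        out = chip.overlap_by_enrichment(peaks, peaks[["chrom", "start", "end"]])
        assert (out.frac_overlap == 1.0).all()

    def test_monotone_truth_recovered(self, rng):
        peaks = self._peaks(rng, n=2000)
        p_hit = 1 / (1 + np.exp(-(peaks.enrichment - 4)))
        hit = rng.random(len(peaks)) < p_hit
        features = peaks.loc[hit, ["chrom", "start", "end"]]
        out = chip.overlap_by_enrichment(peaks, features)
        from scipy.stats import spearmanr
        rho = spearmanr(out.mean_enrichment, out.smooth).statistic
        assert rho > 0.9

    def test_too_few_peaks_error(self, rng):
        with pytest.raises(ValueError):
            chip.overlap_by_enrichment(self._peaks(rng, n=10),
                                       pd.DataFrame(columns=["chrom", "start", "end"]))


class TestMarkVsBindingCurve:
    def _calls(self, rng, n, offset=0.0):
        a = rng.gamma(2, 1, n)
        b = 2 * np.log1p(a) + offset + rng.normal(0, 0.3, n)
        return (pd.DataFrame({"enrichment": a}), pd.DataFrame({"enrichment": b}))

    def test_identical_strata_identical_curves(self, rng):
        a, b = self._calls(rng, 600)
        a2 = pd.concat([a, a], ignore_index=True)
        b2 = pd.concat([b, b], ignore_index=True)
        strata = np.array(["s1"] * 600 + ["s2"] * 600)
        out = chip.mark_vs_binding_curve(a2, b2, strata)
        s1 = out[out.stratum == "s1"].drop(columns="stratum").reset_index(drop=True)
        s2 = out[out.stratum == "s2"].drop(columns="stratum").reset_index(drop=True)
        pd.testing.assert_frame_equal(s1, s2)

    def test_bin_means_match_groupby_oracle(self, rng):
        a, b = self._calls(rng, 500)
        out = chip.mark_vs_binding_curve(a, b, np.array(["all"] * 500))
        order = np.argsort(a.enrichment.to_numpy(), kind="stable")
        for bin_i, grp in out.groupby("bin"):
            lo = int(np.ceil(bin_i * 500 / 25))
            hi = int(np.ceil((bin_i + 1) * 500 / 25))
            idx = order[lo:hi]
            assert grp.mean_b.iloc[0] == pytest.approx(
                b.enrichment.to_numpy()[idx].mean())

    def test_stratum_offset_recovered(self, rng):
        delta = 1.5
        a1, b1 = self._calls(rng, 800)
        a2, b2 = self._calls(rng, 800, offset=delta)
        a = pd.concat([a1, a2], ignore_index=True)
        b = pd.concat([b1, b2], ignore_index=True)
        strata = np.array(["base"] * 800 + ["shifted"] * 800)
        out = chip.mark_vs_binding_curve(a, b, strata)
        diff = (out[out.stratum == "shifted"].mean_b.mean()
                - out[out.stratum == "base"].mean_b.mean())
        assert diff == pytest.approx(delta, abs=0.15)

    def test_empty_stratum_errors(self, rng):
        a, b = self._calls(rng, 50)
        with pytest.raises(ValueError):
            chip.mark_vs_binding_curve(a, b, np.array(["s"] * 50), n_bins=100)
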