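import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from fragsig import (
    annotate_bands,
    cluster_rt_signatures,
    detect_variable_windows,
    estimate_variability_threshold,
    merge_contiguous,
)
from fragsig.io_genomics import GenomicInterval
from fragsig.repliseq import APH, CONTROL
from fragsig.rt_variability import (
    ADVANCED,
    DELAYED,
    RTVariableRegion,
    RTWindow,
    _signature_label,
    window_means,
)

from conftest import make_profile


def profile_from_window_means(means, condition, replicate, window=100_000, per=2):
    """Profile whose window means equal ``means`` (constant within window)."""
    bin_size = window // per
    vals = np.repeat(np.asarray(means, dtype=float), per)
    return make_profile(vals, bin_size=bin_size, condition=condition, replicate=replicate)


def make_window(index, delta, flagged, chrom="chr1", window=100_000, start=None):
    start = index * window if start is None else start
    return RTWindow(
        interval=GenomicInterval(chrom, start, start + window),
        sample_means=np.array([0.0, 0.0, delta, delta]),
        n_ctrl=2,
        ctrl_mean=0.0,
        aph_mean=delta,
        delta=delta,
        masked_frac=0.0,
        flagged=flagged,
        index=index,
    )


# ---------------------------------------------------------------------------
# window means


class TestWindowMeans:
    def test_simple_means_and_trailing_drop(self):
        p = make_profile([1, 2, 3, 4, 5, 6, 7], bin_size=1000)
        ivs, means, fracs = window_means(p.track, 3000)
        assert len(ivs) == 2  # 7 bins -> 2 full windows, trailing bin dropped
        assert np.allclose(means, [2.0, 5.0])
        assert np.allclose(fracs, 0.0)
        assert (ivs[1].start, ivs[1].end) == (3000, 6000)

    def test_masked_fraction_and_nanmean(self):
        p = make_profile([1.0, np.nan, 3.0, np.nan, np.nan, np.nan], bin_size=1000)
        _, means, fracs = window_means(p.track, 3000)
        assert means[0] == pytest.approx(2.0)
        assert np.isnan(means[1])
        assert np.allclose(fracs, [1 / 3, 1.0])

    def test_window_must_tile_bins(self):
        p = make_profile([1.0, 2.0], bin_size=1000)
        with pytest.raises(ValueError, match="multiple of the bin size"):
            window_means(p.track, 2500)


# ---------------------------------------------------------------------------
# threshold calibration


class TestEstimateVariabilityThreshold:
    def test_identical_replicates_zero(self):
        vals = np.random.default_rng(1).normal(size=200)
        a = make_profile(vals, bin_size=100_000)
        b = make_profile(vals.copy(), bin_size=100_000, replicate=1)
        assert estimate_variability_threshold([a, b]) == 0.0

    def test_matches_direct_sd_oracle(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=500)
        noise = [rng.normal(0, 0.3, 500) for _ in range(3)]
        profiles = [
            make_profile(base + n, bin_size=100_000, replicate=i)
            for i, n in enumerate(noise)
        ]
        got = estimate_variability_threshold(profiles)
        diffs = np.concatenate(
            [noise[i] - noise[j] for i in range(3) for j in range(i + 1, 3)]
        )
        assert got == pytest.approx(2.0 * np.std(diffs, ddof=1))

    def test_monte_carlo_sqrt2_calibration(self):
        # two replicates with iid N(0, sigma) noise: difference SD = sqrt(2)*sigma
        rng = np.random.default_rng(3)
        sigma, n = 0.3, 20_000
        base = rng.normal(size=n)
        a = make_profile(base + rng.normal(0, sigma, n), bin_size=100_000)
        b = make_profile(base + rng.normal(0, sigma, n), bin_size=100_000, replicate=1)
        got = estimate_variability_threshold([a, b])
        assert got == pytest.approx(2 * np.sqrt(2) * sigma, rel=0.05)

    def test_needs_two_replicates(self):
        with pytest.raises(ValueError, match=">= 2"):
            estimate_variability_threshold([make_profile([1.0], bin_size=100_000)])

    def test_rejects_mixed_conditions(self):
        a = make_profile([1.0, 2.0], bin_size=100_000, condition=CONTROL)
        b = make_profile([1.0, 2.0], bin_size=100_000, condition=APH)
        with pytest.raises(ValueError, match="one condition"):
            estimate_variability_threshold([a, b])


# ---------------------------------------------------------------------------
# variable-window detection


class TestDetectVariableWindows:
    def _run(self, ctrl_means, aph_means, **kw):
        ctrl = [profile_from_window_means(m, CONTROL, i) for i, m in enumerate(ctrl_means)]
        aph = [profile_from_window_means(m, APH, i) for i, m in enumerate(aph_means)]
        return detect_variable_windows(ctrl, aph, **kw)

    def test_planted_delayed_window(self):
        zeros = [0.0] * 6
        delayed = [0.0, 0.0, 0.0, -1.2, 0.0, 0.4]
        ws = self._run([zeros, zeros], [delayed, delayed], threshold=1.0)
        assert [w.flagged for w in ws] == [False, False, False, True, False, False]
        w = ws[3]
        assert w.delta == pytest.approx(-1.2)
        assert w.direction == DELAYED
        assert ws[5].direction == ADVANCED  # direction defined even if unflagged

    def test_sign_inconsistent_pair_suppressed(self):
        zeros = [0.0] * 3
        ws = self._run([zeros, zeros], [[0.0, 2.5, 0.0], [0.0, -0.3, 0.0]], threshold=1.0)
        # |mean delta| = 1.1 >= 1 but the two stress replicates disagree in sign
        assert ws[1].delta == pytest.approx(1.1)
        assert not ws[1].flagged

    def test_any_pair_mode(self):
        zeros = [0.0] * 3
        aph = [[0.0, 1.1, 0.0], [0.0, 0.1, 0.0]]  # mean 0.6 < 1, max pair 1.1
        assert not self._run([zeros, zeros], aph, threshold=1.0)[1].flagged
        assert self._run([zeros, zeros], aph, threshold=1.0, mode="any_pair")[1].flagged

    def test_masked_window_excluded(self):
        ctrl = make_profile([0.0, 0.0, np.nan, 0.0], bin_size=50_000, condition=CONTROL)
        aph = make_profile([-2.0, -2.0, np.nan, -2.0], bin_size=50_000, condition=APH)
        ws = detect_variable_windows([ctrl], [aph], threshold=1.0, max_masked_frac=0.4)
        assert not ws[1].flagged  # half its bins masked > 0.4
        assert ws[1].masked_frac == 0.5
        assert ws[0].flagged

    def test_single_replicate_per_condition(self):
        ctrl = profile_from_window_means([0.0, 0.0], CONTROL, 0)
        aph = profile_from_window_means([0.0, -1.5], APH, 0)
        ws = detect_variable_windows([ctrl], [aph])
        assert [w.flagged for w in ws] == [False, True]

    def test_input_validation(self):
        p = profile_from_window_means([0.0], CONTROL, 0)
        with pytest.raises(ValueError, match=">= 1 replicate"):
            detect_variable_windows([], [p])
        with pytest.raises(ValueError, match="unknown mode"):
            detect_variable_windows([p], [p], mode="median")

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(4)
        ctrl_means = [rng.normal(size=40) for _ in range(2)]
        aph_means = [m + rng.normal(0, 1.0, 40) for m in ctrl_means]
        flags = {}
        for th in (0.2, 0.6, 1.0, 1.5):
            ws = self._run(ctrl_means, aph_means, threshold=th)
            flags[th] = {w.index for w in ws if w.flagged}
        assert flags[1.5] <= flags[1.0] <= flags[0.6] <= flags[0.2]

    def test_against_brute_force_oracle(self):
        # small randomized layouts vs a literal per-window reimplementation
        for trial in range(50):
            rng = np.random.default_rng(100 + trial)
            n_bins, per = 20, 2
            ctrl_vals = [rng.normal(size=n_bins) for _ in range(2)]
            aph_vals = [rng.normal(size=n_bins) for _ in range(2)]
            for v in ctrl_vals + aph_vals:
                v[rng.random(n_bins) < 0.1] = np.nan
            th = float(rng.uniform(0.2, 1.2))
            ctrl = [make_profile(v, bin_size=50_000, condition=CONTROL, replicate=i)
                    for i, v in enumerate(ctrl_vals)]
            aph = [make_profile(v, bin_size=50_000, condition=APH, replicate=i)
                   for i, v in enumerate(aph_vals)]
            ws = detect_variable_windows(ctrl, aph, 100_000, th, max_masked_frac=0.5)
            for wi in range(n_bins // per):
                seg = slice(wi * per, (wi + 1) * per)
                c_means, a_means, fracs = [], [], []
                for v in ctrl_vals:
                    c_means.append(np.nanmean(v[seg]) if not np.isnan(v[seg]).all() else np.nan)
                    fracs.append(np.isnan(v[seg]).mean())
                for v in aph_vals:
                    a_means.append(np.nanmean(v[seg]) if not np.isnan(v[seg]).all() else np.nan)
                    fracs.append(np.isnan(v[seg]).mean())
                delta = np.nanmean(a_means) - np.nanmean(c_means)
                signs = {
                    np.sign(a - c)
                    for a in a_means
                    for c in c_means
                    if not (np.isnan(a) or np.isnan(c))
                }
                sign_ok = len(signs) == 1 and 0.0 not in signs
                expect = (
                    max(fracs) <= 0.5
                    and not np.isnan(delta)
                    and abs(delta) >= th
                    and sign_ok
                )
                assert ws[wi].flagged == expect, (trial, wi)
                if not np.isnan(delta):
                    assert ws[wi].delta == pytest.approx(delta)


# ---------------------------------------------------------------------------
# merging


class TestMergeContiguous:
    def test_adjacent_same_direction_merge(self):
        ws = [
            make_window(0, -1.2, True),
            make_window(1, -1.6, True),
            make_window(2, 1.4, True),  # direction flips: new region
            make_window(3, 0.2, False),
            make_window(4, -1.1, True),
        ]
        regions = merge_contiguous(ws)
        assert len(regions) == 3
        r0 = regions[0]
        assert (r0.interval.start, r0.interval.end) == (0, 200_000)
        assert r0.direction == DELAYED
        assert r0.n_windows == 2
        assert r0.mean_delta == pytest.approx(-1.4)
        assert regions[1].direction == ADVANCED
        assert regions[2].member_windows == [4]

    def test_gap_breaks_region(self):
        # windows 0 and 2 flagged with window 1 absent from the list
        ws = [make_window(0, -1.2, True), make_window(2, -1.2, True)]
        assert len(merge_contiguous(ws)) == 2

    def test_chromosome_change_breaks_region(self):
        ws = [
            make_window(0, -1.2, True, chrom="chr1"),
            make_window(0, -1.2, True, chrom="chr2"),
        ]
        regions = merge_contiguous(ws)
        assert len(regions) == 2
        assert {r.interval.chrom for r in regions} == {"chr1", "chr2"}

    def test_empty_and_unflagged(self):
        assert merge_contiguous([]) == []
        assert merge_contiguous([make_window(0, -2.0, False)]) == []

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.booleans(), st.booleans()), min_size=0, max_size=25))
    def test_run_length_oracle_and_partition(self, pattern):
        # pattern: (flagged, delayed?) per contiguous window
        ws = [
            make_window(i, -1.5 if delayed else 1.5, flagged)
            for i, (flagged, delayed) in enumerate(pattern)
        ]
        regions = merge_contiguous(ws)
        # oracle: explicit run-length grouping over (flagged, sign)
        expected_runs = []
        run = None
        for i, (flagged, delayed) in enumerate(pattern):
            if not flagged:
                run = None
                continue
            if run is not None and run[0] == delayed:
                run[1].append(i)
            else:
                run = [delayed, [i]]
                expected_runs.append(run)
        assert [r.member_windows for r in regions] == [r[1] for r in expected_runs]
        # partition property: members are exactly the flagged windows, disjoint
        members = [i for r in regions for i in r.member_windows]
        assert sorted(members) == [i for i, (f, _) in enumerate(pattern) if f]
        assert len(set(members)) == len(members)
        for r in regions:
            assert r.interval.length == r.n_windows * 100_000


# ---------------------------------------------------------------------------
# clustering


def two_group_windows(n_per=12, seed=0):
    rng = np.random.default_rng(seed)
    ws = []
    for i in range(n_per):  # early genes delayed under stress
        c = 1.5 + rng.normal(0, 0.05)
        a = 0.2 + rng.normal(0, 0.05)
        ws.append(
            RTWindow(GenomicInterval("chr1", i * 100_000, (i + 1) * 100_000),
                     np.array([c, c, a, a]), 2, c, a, a - c, 0.0, True, i)
        )
    for i in range(n_per, 2 * n_per):  # late genes advanced under stress
        c = -1.5 + rng.normal(0, 0.05)
        a = -0.2 + rng.normal(0, 0.05)
        ws.append(
            RTWindow(GenomicInterval("chr1", i * 100_000, (i + 1) * 100_000),
                     np.array([c, c, a, a]), 2, c, a, a - c, 0.0, True, i)
        )
    return ws


class TestClusterRTSignatures:
    def test_planted_two_cluster_recovery(self):
        ws = two_group_windows()
        sigs = cluster_rt_signatures(ws, k=2, seed=0)
        assert len(sigs) == 2
        by_label = {s.label: s for s in sigs}
        assert set(by_label) == {"early-delayed", "late-advanced"}
        assert sorted(by_label["early-delayed"].member_windows) == list(range(12))
        assert sorted(by_label["late-advanced"].member_windows) == list(range(12, 24))

    def test_p_values_small_and_adjusted(self):
        sigs = cluster_rt_signatures(two_group_windows(), k=2, seed=0)
        for s in sigs:
            assert s.p_value < 1e-6  # consistent paired shift within cluster
            assert s.p_adjusted >= s.p_value

    def test_deterministic_under_seed(self):
        ws = two_group_windows()
        a = cluster_rt_signatures(ws, k=2, seed=42)
        b = cluster_rt_signatures(ws, k=2, seed=42)
        assert [s.member_windows for s in a] == [s.member_windows for s in b]

    def test_k_validation(self):
        ws = two_group_windows(n_per=2)
        with pytest.raises(ValueError, match="exceeds"):
            cluster_rt_signatures(ws, k=5)
        with pytest.raises(ValueError, match=">= 1"):
            cluster_rt_signatures(ws, k=0)

    def test_singleton_cluster_nan_p(self):
        ws = two_group_windows(n_per=1)
        sigs = cluster_rt_signatures(ws, k=2, seed=0)
        assert all(np.isnan(s.p_value) for s in sigs)


class TestSignatureLabel:
    @pytest.mark.parametrize(
        "ctrl,aph,expected",
        [
            (1.5, 0.2, "early-delayed"),
            (1.5, 0.8, "within-early-delayed"),
            (0.2, -0.2, "within-mid-delayed"),
            (-1.5, -0.2, "late-advanced"),
            (-0.2, 0.2, "within-mid-advanced"),
            (0.0, 0.8, "mid-advanced"),
        ],
    )
    def test_labels(self, ctrl, aph, expected):
        assert _signature_label(ctrl, aph) == expected


# ---------------------------------------------------------------------------
# band annotation


def region(chrom, start, end, direction, delta=-1.5):
    return RTVariableRegion(
        GenomicInterval(chrom, start, end), direction,
        (end - start) // 100_000, delta, [],
    )


class TestAnnotateBands:
    def band_table(self):
        return pd.DataFrame(
            {
                "band_id": ["b1", "b2", "b3"],
                "chrom": ["chr1", "chr1", "chr2"],
                "start": [0, 5_000_000, 0],
                "end": [5_000_000, 10_000_000, 5_000_000],
            }
        )

    def test_counts_and_straddle(self):
        regions = [
            region("chr1", 1_000_000, 1_200_000, DELAYED),
            region("chr1", 4_900_000, 5_200_000, ADVANCED, 1.0),  # straddles b1/b2
        ]
        per_band, summary = annotate_bands(regions, self.band_table(), ["b1"])
        b1 = per_band.set_index("band_id").loc["b1"]
        assert (b1["n_delayed"], b1["n_advanced"]) == (1, 1)
        b2 = per_band.set_index("band_id").loc["b2"]
        assert (b2["n_delayed"], b2["n_advanced"]) == (0, 1)
        assert summary["n_fragile_bands"] == 1
        assert summary["frac_fragile_with_delayed"] == 1.0
        assert summary["frac_both"] == 1.0
        assert summary["frac_delayed_only"] == 0.0

    def test_trisection_composition(self):
        regions = [
            region("chr1", 1_000_000, 1_200_000, DELAYED),
            region("chr1", 2_000_000, 2_200_000, DELAYED),
            region("chr2", 100_000, 200_000, DELAYED),  # not in a fragile band
        ]
        _, summary = annotate_bands(
            regions, self.band_table(), ["b1"],
            region_ctrl_rt=[1.2, -0.9, 2.0], trisection_cuts=(0.5, -0.5),
        )
        assert summary["delayed_in_fragile_trisection"] == {"early": 1, "mid": 0, "late": 1}
        assert summary["frac_delayed_in_fragile_early_or_mid"] == 0.5

    def test_unknown_fragile_band(self):
        with pytest.raises(ValueError, match="not in table"):
            annotate_bands([], self.band_table(), ["bX"])

    def test_missing_columns(self):
        with pytest.raises(ValueError, match="band table needs"):
            annotate_bands([], pd.DataFrame({"band_id": [], "chrom": []}), [])

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(55)
        bands = self.band_table()
        for _ in range(50):
            regions = []
            for _ in range(rng.integers(0, 8)):
                chrom = "chr1" if rng.random() < 0.7 else "chr2"
                start = int(rng.integers(0, 9_000_000 if chrom == "chr1" else 4_000_000))
                end = start + int(rng.integers(50_000, 2_000_000))
                regions.append(
                    region(chrom, start, end, DELAYED if rng.random() < 0.5 else ADVANCED)
                )
            per_band, _ = annotate_bands(regions, bands, ["b1", "b3"])
            for _, b in bands.iterrows():
                n_del = sum(
                    1 for r in regions
                    if r.direction == DELAYED and r.interval.chrom == b["chrom"]
                    and r.interval.start < b["end"] and b["start"] < r.interval.end
                )
                row = per_band.set_index("band_id").loc[b["band_id"]]
                assert row["n_delayed"] == n_del
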