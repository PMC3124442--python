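"""Unit and property tests for CpG density, null probes, GC strata,
smoothing and the null-distribution diagnostics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import mbdchip as mb
from mbdchip import preprocess as pp
from mbdchip.io_formats import IntensityTable
from tests.conftest import toy_design


# ---------------------------------------------------------------------------
# local_cpg_density / select_null_probes
# ---------------------------------------------------------------------------

class TestCpgDensity:
    def test_all_a_is_zero(self):
        genome = {"c": "A" * 2000}
        assert pp.local_cpg_density(genome, "c", 1000, 1000) == 0.0

    def test_three_cpgs_is_three(self):
        seq = list("A" * 2000)
        for pos in (600, 900, 1200):  # inside the window [500, 1500)
            seq[pos], seq[pos + 1] = "C", "G"
        genome = {"c": "".join(seq)}
        assert pp.local_cpg_density(genome, "c", 1000, 1000) == 3.0

    def test_unknown_chromosome(self):
        with pytest.raises(KeyError):
            pp.local_cpg_density({"c": "ACGT" * 100}, "nope", 10, 100)

    def test_truncated_window_rescales(self):
        # 2 CGs in the first 500 bp; position 0 sees only [0, 500)
        seq = "CG" + "A" * 200 + "CG" + "A" * 2000
        d = pp.local_cpg_density({"c": seq}, "c", 0, 1000)
        assert d == pytest.approx(1000.0 * 2 / 500)

    def test_agrees_with_naive_substring_count(self):
        rng = np.random.default_rng(7)
        seq = "".join(rng.choice(list("ACGT"), 10_000))
        genome = {"c": seq}
        for pos in range(0, 10_000, 487):
            lo, hi = max(0, pos - 500), min(10_000, pos + 500)
            naive = 1000.0 * sum(
                1 for i in range(lo, hi - 1) if seq[i:i + 2] == "CG"
            ) / (hi - lo)
            assert pp.local_cpg_density(genome, "c", pos, 1000) == pytest.approx(naive)


class TestNullProbes:
    def test_cpg_free_chromosome_selects_all(self):
        n = 30
        d = toy_design(n)
        genome = {"chrT": "AT" * 2000}
        nulls = pp.select_null_probes(d, genome, min_probes=1)
        assert len(nulls) == n

    def test_threshold_is_strict(self):
        # window of the single probe holds exactly 4 CGs (density 4.0) ->
        # excluded; removing one (3.0) -> included
        from mbdchip.io_formats import ProbeDesign
        d = ProbeDesign(
            probe_id=np.array(["p0"], dtype=object),
            chrom=np.array(["chrT"], dtype=object),
            start=np.array([1488], dtype=np.int64),
            length=np.array([25], dtype=np.int64),
            gc_count=np.array([12], dtype=np.int64),
        )
        mid = int(d.midpoint[0])  # 1500: the 1 kb window is never truncated
        for n_cg, expected in ((4, 0), (3, 1)):
            seq = list("A" * 3000)
            for i in range(n_cg):
                p = mid - 400 + 200 * i
                seq[p], seq[p + 1] = "C", "G"
            genome = {"chrT": "".join(seq)}
            try:
                nulls = pp.select_null_probes(d, genome, min_probes=1)
                got = len(nulls)
            except ValueError:
                got = 0
            assert got == expected, f"{n_cg} CpGs/kbp"

    def test_matches_per_probe_oracle(self, small_basic_bundle):
        b = small_basic_bundle
        nulls = pp.select_null_probes(b.design, b.genome)
        member = np.zeros(len(b.design), dtype=bool)
        member[nulls.indices] = True
        rng = np.random.default_rng(0)
        for i in rng.choice(len(b.design), 300, replace=False):
            dens = pp.local_cpg_density(
                b.genome, str(b.design.chrom[i]), int(b.design.midpoint[i]), 1000)
            assert member[i] == (dens < 4.0)

    def test_undersized_null_set_errors(self):
        d = toy_design(10)
        genome = {"chrT": "CG" * 2000}  # saturated CpG density
        with pytest.raises(ValueError, match="threshold"):
            pp.select_null_probes(d, genome, min_probes=1)


# ---------------------------------------------------------------------------
# log-ratios
# ---------------------------------------------------------------------------

def _table(design, entries):
    t = IntensityTable(design)
    for key, v in entries.items():
        t.data[key] = np.asarray(v, dtype=float)
    return t


class TestLogRatio:
    def test_hand_arithmetic(self):
        d = toy_design(1)
        t = _table(d, {
            ("s", "M", 1): [4.0], ("s", "M", 2): [6.0],
            ("s", "T", 1): [3.0], ("s", "T", 2): [3.0],
        })
        track = pp.compute_log_ratio(t, "s")
        assert track.values[0] == pytest.approx(2.0)  # mean(4,6) - mean(3,3)

    def test_replicate_null_mode_centers_at_zero(self):
        rng = np.random.default_rng(2)
        d = toy_design(4000)
        base = rng.normal(10, 0.5, 4000)
        t = _table(d, {
            ("s", "T", 1): base + rng.normal(0, 0.3, 4000),
            ("s", "T", 2): base + rng.normal(0, 0.3, 4000),
        })
        track = pp.replicate_null_log_ratio(t, "s")
        assert abs(np.median(track.values)) < 0.02

    def test_missing_replicate_errors(self):
        d = toy_design(2)
        t = _table(d, {("s", "M", 1): [1.0, np.nan], ("s", "T", 1): [1.0, 1.0]})
        with pytest.raises(Exception, match="missing"):
            pp.compute_log_ratio(t, "s")


# ---------------------------------------------------------------------------
# GC strata
# ---------------------------------------------------------------------------

class TestGcStrata:
    def _design_with_gc(self, gcs):
        d = toy_design(len(gcs))
        d.gc_count = np.asarray(gcs, dtype=np.int64)
        return d

    def test_constant_values_recover_constant(self):
        gcs = np.repeat(np.arange(8, 14), 50)
        d = self._design_with_gc(gcs)
        track = pp.SignalTrack(np.full(len(d), 0.7), pp.STAGE_LOG_RATIO)
        nulls = pp.NullProbeSet(np.arange(len(d)), 1000, 4.0)
        strata = pp.estimate_gc_baseline(track, nulls, d, min_bin_size=10)
        assert np.allclose(strata.median[8:14], 0.7)
        assert np.all(strata.scale > 0)  # degenerate MAD fell back to a positive scale

    def test_planted_gc_baseline_recovered_exactly(self):
        gcs = np.repeat(np.arange(5, 20), 40)
        d = self._design_with_gc(gcs)
        track = pp.SignalTrack(0.1 * d.gc_count.astype(float), pp.STAGE_LOG_RATIO)
        nulls = pp.NullProbeSet(np.arange(len(d)), 1000, 4.0)
        strata = pp.estimate_gc_baseline(track, nulls, d, min_bin_size=10)
        for g in range(5, 20):
            assert strata.median[g] == pytest.approx(0.1 * g, abs=1e-12)
        adjusted = pp.adjust_signal(track, strata, d)
        assert np.allclose(adjusted.values, 0.0, atol=1e-12)

    def test_sparse_bins_merged_to_size_floor(self):
        gcs = np.array([5] * 300 + [6] * 3 + [12] * 300)
        d = self._design_with_gc(gcs)
        rng = np.random.default_rng(3)
        track = pp.SignalTrack(rng.normal(0, 1, len(d)), pp.STAGE_LOG_RATIO)
        nulls = pp.NullProbeSet(np.arange(len(d)), 1000, 4.0)
        strata = pp.estimate_gc_baseline(track, nulls, d, min_bin_size=100)
        # gc 6 (3 probes) merged into its nearest neighbor, gc 5
        assert strata.effective_bin[6] == strata.effective_bin[5]
        assert strata.count[6] == 303

    def test_zero_strata_adjustment_is_identity(self):
        d = toy_design(20)
        track = pp.SignalTrack(np.arange(20.0), pp.STAGE_LOG_RATIO)
        strata = pp.GCStrata(median=np.zeros(26), scale=np.ones(26),
                             count=np.full(26, 20))
        adjusted = pp.adjust_signal(track, strata, d)
        assert np.array_equal(adjusted.values, track.values)

    def test_reestimation_on_adjusted_is_centered(self, small_basic_result):
        """Idempotence: strata re-fit on adjusted data have medians ~ 0."""
        res = small_basic_result
        d_len = len(res.adjusted)
        strata2 = res.strata_z  # estimated on the adjusted track
        pop = strata2.count > 0
        bound = 3 * strata2.scale[pop] / np.sqrt(strata2.count[pop])
        assert np.all(np.abs(strata2.median[pop]) < np.maximum(bound, 1e-9))
        assert d_len > 0

    def test_gc_trend_is_monotone_on_biased_data(self, biased_bundle, biased_result):
        """The raw log-ratio baseline rises with probe G+C content."""
        strata = biased_result.strata_raw
        gcs = np.flatnonzero(strata.count >= 200)
        m = strata.median[gcs]
        rho = np.corrcoef(gcs, m)[0, 1]
        assert rho > 0.9


# ---------------------------------------------------------------------------
# Running median
# ---------------------------------------------------------------------------

class TestRunningMedian:
    def test_even_k_rejected(self):
        d = toy_design(10)
        track = pp.SignalTrack(np.zeros(10), pp.STAGE_ADJUSTED)
        with pytest.raises(ValueError, match="odd"):
            pp.smooth_running_median(track, d, k=4)

    def test_constant_is_identity(self):
        d = toy_design(30)
        track = pp.SignalTrack(np.full(30, 1.5), pp.STAGE_ADJUSTED)
        sm = pp.smooth_running_median(track, d, k=7)
        assert np.allclose(sm.values, 1.5)

    def test_center_window_sort_and_pick(self):
        d = toy_design(7)
        track = pp.SignalTrack(np.array([0, 1, 9, 2, 3, 8, 4.0]), pp.STAGE_ADJUSTED)
        sm = pp.smooth_running_median(track, d, k=7)
        assert sm.values[3] == 3.0

    @pytest.mark.parametrize("k", [5, 7, 9])
    def test_matches_brute_force_everywhere(self, k):
        rng = np.random.default_rng(k)
        n = 10_000
        d = toy_design(n)
        v = rng.normal(0, 1, n)
        sm = pp.smooth_running_median(pp.SignalTrack(v, pp.STAGE_ADJUSTED), d, k=k)
        half = k // 2
        for i in range(0, n, 37):
            h = min(i, n - 1 - i, half)
            expected = sorted(v[i - h:i + h + 1])[h]
            assert sm.values[i] == expected

    def test_does_not_cross_chromosomes(self):
        import mbdchip.io_formats as iof
        starts = np.concatenate([np.arange(5) * 35, np.arange(5) * 35])
        d = iof.ProbeDesign(
            probe_id=np.array([f"p{i}" for i in range(10)], dtype=object),
            chrom=np.array(["c1"] * 5 + ["c2"] * 5, dtype=object),
            start=starts.astype(np.int64),
            length=np.full(10, 25, dtype=np.int64),
            gc_count=np.full(10, 10, dtype=np.int64),
        )
        v = np.array([0.0] * 5 + [100.0] * 5)
        sm = pp.smooth_running_median(pp.SignalTrack(v, pp.STAGE_ADJUSTED), d, k=5)
        assert np.allclose(sm.values[:5], 0.0)
        assert np.allclose(sm.values[5:], 100.0)

    @given(shift=st.floats(-50, 50), scale=st.floats(0.01, 20))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_shift_and_scale_equivariance(self, shift, scale):
        rng = np.random.default_rng(12)
        n = 60
        d = toy_design(n)
        v = rng.normal(0, 1, n)
        base = pp.smooth_running_median(pp.SignalTrack(v, pp.STAGE_ADJUSTED), d, k=7).values
        moved = pp.smooth_running_median(
            pp.SignalTrack(scale * v + shift, pp.STAGE_ADJUSTED), d, k=7).values
        assert np.allclose(moved, scale * base + shift, rtol=1e-9, atol=1e-9)


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------

class TestDiagnostics:
    def test_iid_noise_uncorrelated(self):
        rng = np.random.default_rng(4)
        n = 5000
        d = toy_design(n)
        track = pp.SignalTrack(rng.normal(0, 1, n), pp.STAGE_ADJUSTED)
        nulls = pp.NullProbeSet(np.arange(n), 1000, 4.0)
        r = pp.autocorrelation(track, nulls, d)
        assert abs(r) < 3 / np.sqrt(n)

    def test_ar1_coefficient_recovered(self):
        rng = np.random.default_rng(5)
        n = 20_000
        d = toy_design(n)
        v = np.empty(n)
        v[0] = rng.normal()
        eps = rng.normal(0, 1, n)
        for i in range(1, n):
            v[i] = 0.6 * v[i - 1] + eps[i]
        track = pp.SignalTrack(v, pp.STAGE_ADJUSTED)
        nulls = pp.NullProbeSet(np.arange(n), 1000, 4.0)
        assert pp.autocorrelation(track, nulls, d) == pytest.approx(0.6, abs=0.05)

    def test_zero_variance_errors(self):
        d = toy_design(200)
        track = pp.SignalTrack(np.zeros(200), pp.STAGE_ADJUSTED)
        nulls = pp.NullProbeSet(np.arange(200), 1000, 4.0)
        with pytest.raises(ValueError, match="variance"):
            pp.autocorrelation(track, nulls, d)

    def test_normal_sample_small_qq_gap(self):
        rng = np.random.default_rng(6)
        n = 10_000
        track = pp.SignalTrack(rng.normal(2, 3, n), "smoothed")
        nulls = pp.NullProbeSet(np.arange(n), 1000, 4.0)
        assert pp.normality_diagnostic(track, nulls) < 0.05

    def test_heavy_tails_large_qq_gap(self):
        rng = np.random.default_rng(6)
        n = 10_000
        track = pp.SignalTrack(rng.standard_t(2, n), "smoothed")
        nulls = pp.NullProbeSet(np.arange(n), 1000, 4.0)
        assert pp.normality_diagnostic(track, nulls) > 0.05

    def test_pipeline_null_probes_near_normal(self, small_basic_result):
        res = small_basic_result
        assert pp.normality_diagnostic(res.smoothed, res.nulls) < 0.1

    def test_smoothed_null_median_near_zero(self, small_basic_result):
        """Baseline normalization: unmethylated signal is centered at zero."""
        res = small_basic_result
        med = np.median(res.smoothed.values[res.nulls.indices])
        assert abs(med) < 0.01
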