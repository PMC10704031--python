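"""SNP-index / delta statistics, window fits, null bands, peak calling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bsamap.scan import (
    CIBand,
    MutMapScan,
    QTLSeqScan,
    call_peak_regions,
    delta_snp_index,
    index_table,
    nearest_band,
    simulate_ci,
    simulate_ci_grid,
    sliding_window_fit,
    snp_index,
)


class TestSnpIndex:
    @pytest.mark.parametrize(
        "ref,alt,expected",
        [
            (0, 34, 1.0),   # causal site in a recessive-selected pool
            (30, 0, 0.0),   # reference-congruent site
            (17, 17, 0.5),  # balanced heterozygous pool
        ],
    )
    def test_values(self, ref, alt, expected):
        assert snp_index(ref, alt) == expected

    def test_below_depth_floor_is_missing(self):
        assert np.isnan(snp_index(3, 2, min_depth=8))
        assert np.isnan(snp_index(0, 0))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            snp_index(-1, 5)

    @given(
        ref=st.integers(min_value=0, max_value=500),
        alt=st.integers(min_value=0, max_value=500),
    )
    @settings(deadline=None, max_examples=200)
    def test_bounded(self, ref, alt):
        v = snp_index(ref, alt, min_depth=1)
        assert np.isnan(v) or 0.0 <= v <= 1.0


class TestDelta:
    def test_examples(self):
        assert delta_snp_index(0.5, 0.5) == 0.0
        # recessive selection: mutant pool 1, wild-type pool 1/3
        assert delta_snp_index(1.0, 1 / 3) == pytest.approx(2 / 3)
        assert np.isnan(delta_snp_index(np.nan, 0.4))

    @given(
        a=st.floats(min_value=0, max_value=1),
        b=st.floats(min_value=0, max_value=1),
    )
    @settings(deadline=None, max_examples=200)
    def test_range(self, a, b):
        assert -1.0 <= delta_snp_index(a, b) <= 1.0


def brute_force_windows(records, window_size, step, min_sites, value_col="index"):
    """Independent oracle: literal scan of every window."""
    rows = []
    for chrom in records["chrom"].unique():
        sub = records[records["chrom"] == chrom]
        extent = int(sub["pos"].max())
        k = 0
        while k * step + 1 <= extent:
            start, end = k * step + 1, k * step + window_size
            inside = sub[(sub["pos"] >= start) & (sub["pos"] <= end)][value_col]
            vals = inside.dropna()
            mean = vals.mean() if len(vals) >= min_sites else np.nan
            rows.append((chrom, start, end, len(vals), mean))
            k += 1
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_sites", "mean"])


class TestSlidingWindow:
    def test_constant_field(self):
        rec = pd.DataFrame(
            {"chrom": "c1", "pos": np.arange(1, 1001, 10), "index": 0.7}
        )
        win = sliding_window_fit(rec, 100, 50, min_sites=1)
        ok = win["mean"].dropna()
        assert len(ok) and np.allclose(ok, 0.7)

    def test_hand_built_toy_matches_brute_force(self):
        pos = [5, 20, 40, 55, 70, 90, 120, 130, 160, 190]
        val = [0.1, 0.9, 0.5, np.nan, 1.0, 0.0, 0.3, 0.7, 0.2, 0.6]
        rec = pd.DataFrame({"chrom": "c1", "pos": pos, "index": val})
        win = sliding_window_fit(rec, 100, 50, min_sites=1)
        oracle = brute_force_windows(rec, 100, 50, 1)
        pd.testing.assert_frame_equal(
            win.reset_index(drop=True), oracle, check_dtype=False
        )

    def test_random_instances_match_brute_force(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            n = int(rng.integers(5, 80))
            rec = pd.DataFrame(
                {
                    "chrom": rng.choice(["c1", "c2"], size=n),
                    "pos": rng.integers(1, 5000, size=n),
                    "index": np.where(
                        rng.random(n) < 0.2, np.nan, rng.random(n)
                    ),
                }
            )
            rec = rec.drop_duplicates(["chrom", "pos"])
            w = int(rng.integers(100, 1000))
            s = int(rng.integers(50, w + 1))
            ms = int(rng.integers(1, 4))
            got = sliding_window_fit(rec, w, s, ms)
            exp = brute_force_windows(rec, w, s, ms)
            got = got.sort_values(["chrom", "start"]).reset_index(drop=True)
            exp = exp.sort_values(["chrom", "start"]).reset_index(drop=True)
            pd.testing.assert_frame_equal(got, exp, check_dtype=False)

    def test_empty_input(self):
        out = sliding_window_fit(pd.DataFrame(columns=["chrom", "pos", "index"]))
        assert out.empty

    def test_bad_window_step(self):
        rec = pd.DataFrame({"chrom": ["c"], "pos": [1], "index": [0.5]})
        with pytest.raises(ValueError):
            sliding_window_fit(rec, 10, 20)

    def test_peak_shape_in_mutant_pool_scan(self, scenario):
        """Window means approach 1 near the causal site, ~0.5 far away."""
        counts = scenario.counts
        rec = index_table(counts[counts["pool"] == "F2dw_pool"])
        win = sliding_window_fit(
            rec, 2_000_000, 50_000, min_sites=1,
            chrom_lengths=dict(scenario.genome.chromosomes),
        )
        causal = scenario.causal
        at_peak = win[
            (win["chrom"] == causal.chrom)
            & (win["start"] <= causal.pos)
            & (win["end"] >= causal.pos)
        ]["mean"].dropna()
        far = win[win["chrom"] != causal.chrom]["mean"].dropna()
        assert at_peak.min() > 0.9
        assert abs(far.mean() - 0.5) < 0.1


class TestCIBands:
    def test_null_delta_centred_at_zero(self):
        band = simulate_ci("qtlseq", (45, 50), depth=100, n_reps=5000, seed=1)
        lo, hi = band.bounds[0.95]
        assert lo < 0 < hi
        assert abs(lo + hi) < 0.05

    def test_nesting_and_depth_monotonicity(self):
        b20 = simulate_ci("mutmap", (28,), 20, n_reps=8000, seed=2)
        b100 = simulate_ci("mutmap", (28,), 100, n_reps=8000, seed=2)
        for b in (b20, b100):
            l95, u95 = b.bounds[0.95]
            l99, u99 = b.bounds[0.99]
            assert l99 <= l95 <= u95 <= u99
        w20 = b20.upper(0.95) - b20.lower(0.95)
        w100 = b100.upper(0.95) - b100.lower(0.95)
        assert w20 >= w100

    def test_coverage_self_consistency(self):
        """Fresh null draws fall inside the 95% band at ~0.95."""
        band = simulate_ci("qtlseq", (45, 50), 100, n_reps=10_000, seed=3)
        # fresh, independent null draws through the same generative model
        from bsamap.scan import _null_index

        rng = np.random.default_rng(4)
        stat = _null_index(rng, 45, 100, 10_000) - _null_index(rng, 50, 100, 10_000)
        lo, hi = band.bounds[0.95]
        cover = np.mean((stat >= lo) & (stat <= hi))
        se = np.sqrt(0.95 * 0.05 / 10_000)
        assert abs(cover - 0.95) <= 3 * se

    def test_unknown_design(self):
        with pytest.raises(ValueError, match="unknown design"):
            simulate_ci("other", (10,), 30, 100, seed=0)

    def test_grid_and_nearest(self):
        grid = simulate_ci_grid("mutmap", (28,), [20, 50, 100], n_reps=2000, seed=6)
        assert nearest_band(grid, 43).depth == 50
        assert nearest_band(grid, 35).depth in (20, 50)


def _band(upper95=0.8, upper99=0.9):
    return CIBand(
        "mutmap", 34, (28,), 1000,
        {0.95: (1 - upper95, upper95), 0.99: (1 - upper99, upper99)},
    )


class TestPeakCalling:
    def test_none_above(self):
        win = pd.DataFrame(
            {"chrom": "c", "start": [1, 51], "end": [100, 150], "n_sites": 5, "mean": [0.5, 0.6]}
        )
        assert call_peak_regions(win, _band(), 0.99).empty

    def test_all_above_merges_to_one(self):
        win = pd.DataFrame(
            {
                "chrom": "c",
                "start": [1, 51, 101],
                "end": [100, 150, 200],
                "n_sites": 5,
                "mean": [0.95, 0.99, 0.96],
            }
        )
        peaks = call_peak_regions(win, _band(), 0.99)
        assert len(peaks) == 1
        assert peaks.iloc[0]["start"] == 1 and peaks.iloc[0]["end"] == 200
        assert peaks.iloc[0]["peak_value"] == pytest.approx(0.99)

    def test_missing_windows_break_nothing(self):
        win = pd.DataFrame(
            {
                "chrom": "c",
                "start": [1, 201, 401],
                "end": [100, 300, 500],
                "n_sites": 5,
                "mean": [0.95, np.nan, 0.97],
            }
        )
        peaks = call_peak_regions(win, _band(), 0.99)
        assert len(peaks) == 2  # disjoint windows stay separate intervals


class TestScanModels:
    def test_mutmap_fit_recovers_causal_region(self, scenario):
        res = MutMapScan(scenario.counts, "F2dw_pool", 28).fit(
            seed=0, chrom_lengths=dict(scenario.genome.chromosomes)
        )
        peaks = res.peak_regions(0.99)
        causal = scenario.causal
        hit = peaks[
            (peaks["chrom"] == causal.chrom)
            & (peaks["start"] <= causal.pos)
            & (peaks["end"] >= causal.pos)
        ]
        assert len(hit) == 1
        assert "BSA scan" in res.summary()

    def test_qtlseq_fit_runs_and_plot_smoke(self, scenario):
        res = QTLSeqScan(scenario.counts, "SF_pool", "HL_pool", (45, 50)).fit(
            seed=0, chrom_lengths=dict(scenario.genome.chromosomes)
        )
        assert (res.records["delta"].dropna().abs() <= 1).all()
        import matplotlib

        matplotlib.use("Agg")
        ax = res.plot()
        assert ax is not None

    def test_peak_recovery_rate_across_replicates(self, genome):
        """The called interval contains the true causal position in >=95%
        of replicate simulations (100 small replicates)."""
        from bsamap.simulate import (
            MUTANT,
            causal_index,
            reference_line,
            select_pool,
            simulate_ems_line,
            simulate_f2,
            simulate_pool_counts,
        )

        hits = 0
        n_rep = 100
        for rep in range(n_rep):
            sites, sip = simulate_ems_line(genome, 300, seed=10_000 + rep)
            wt = reference_line("WT", sites)
            pop = simulate_f2(wt, sip, 200, genome, seed=20_000 + rep)
            pool = select_pool(pop, MUTANT, 28, seed=rep, name="F2dw_pool")
            counts = simulate_pool_counts(pool, pop, sites, 34, 0.0, seed=30_000 + rep)
            # window parameters matched to the ~3 sites/Mb simulated density
            scan_res = MutMapScan(counts, "F2dw_pool", 28).fit(
                window_size=4_000_000, step=1_000_000, min_sites=3,
                seed=rep, n_reps=2000, chrom_lengths=dict(genome.chromosomes),
            )
            peaks = scan_res.peak_regions(0.99)
            c = sites[causal_index(sites)]
            inside = peaks[
                (peaks["chrom"] == c.chrom)
                & (peaks["start"] <= c.pos)
                & (peaks["end"] >= c.pos)
            ]
            if len(inside) == 1:
                hits += 1
        assert hits >= 95
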