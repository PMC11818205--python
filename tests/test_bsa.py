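"""Tests of the G-statistic scan, null thresholds, projection, and consensus."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chi2_contingency

from panhap.aroh import PafRecord
from panhap.bsa import (
    GProfile,
    PeakInterval,
    consensus_interval,
    filter_snps,
    g_statistic,
    null_threshold,
    project_interval,
    run_bsa,
    select_diagnostic_snps,
    significant_intervals,
    smooth_g,
    snp_g,
)
from panhap.simulate import BulkSim, simulate_bulks


def snp_table(positions, counts):
    """counts: list of (r1, a1, r2, a2)."""
    arr = np.asarray(counts)
    return pd.DataFrame(
        {
            "CHROM": "chr1",
            "POS": positions,
            "REF": "A",
            "ALT": "T",
            "AD_bulk1_ref": arr[:, 0],
            "AD_bulk1_alt": arr[:, 1],
            "AD_bulk2_ref": arr[:, 2],
            "AD_bulk2_alt": arr[:, 3],
        }
    )


class TestGStatistic:
    def test_perfect_independence_zero(self):
        assert g_statistic(10, 10, 10, 10) == 0.0

    def test_complete_separation_closed_form(self):
        assert g_statistic(20, 0, 0, 20) == pytest.approx(80 * np.log(2), rel=1e-12)

    def test_moderate_table_hand_value(self):
        assert g_statistic(12, 8, 8, 12) == pytest.approx(1.611, abs=2e-3)

    def test_zero_iff_equal_bulk_proportions(self):
        assert g_statistic(10, 20, 20, 40) == pytest.approx(0.0, abs=1e-12)
        assert g_statistic(10, 20, 20, 30) > 0

    def test_zero_margin_scored_zero(self):
        assert g_statistic(0, 0, 10, 10) == 0.0
        assert g_statistic(10, 0, 10, 0) == 0.0

    def test_symmetry_under_bulk_and_allele_swap(self, rng):
        for _ in range(50):
            a, b, c, d = (int(x) for x in rng.integers(1, 100, 4))
            g = g_statistic(a, b, c, d)
            assert g_statistic(c, d, a, b) == pytest.approx(g, rel=1e-12)
            assert g_statistic(b, a, d, c) == pytest.approx(g, rel=1e-12)

    def test_matches_likelihood_ratio_oracle(self, rng):
        # scipy's log-likelihood-ratio contingency test is an independent path
        for _ in range(1000):
            table = rng.integers(1, 200, size=(2, 2))
            g, _, _, _ = chi2_contingency(table, correction=False, lambda_="log-likelihood")
            ours = g_statistic(table[0, 0], table[0, 1], table[1, 0], table[1, 1])
            assert ours == pytest.approx(g, abs=1e-9)

    @settings(derandomize=True, max_examples=200)
    @given(st.tuples(*[st.integers(0, 500)] * 4))
    def test_nonnegative_and_swap_symmetric(self, table):
        a, b, c, d = table
        g = g_statistic(a, b, c, d)
        assert g >= 0
        assert g_statistic(c, d, a, b) == pytest.approx(g, rel=1e-9, abs=1e-12)
        assert g_statistic(b, a, d, c) == pytest.approx(g, rel=1e-9, abs=1e-12)

    def test_vectorized_agrees_with_scalar(self, rng):
        tab = rng.integers(0, 50, size=(20, 4))
        vec = g_statistic(tab[:, 0], tab[:, 1], tab[:, 2], tab[:, 3])
        for i in range(20):
            assert vec[i] == pytest.approx(g_statistic(*map(int, tab[i])), rel=1e-12)


class TestFilterSnps:
    def test_low_depth_in_either_bulk_dropped(self):
        t = snp_table([100, 200], [(6, 6, 5, 4), (5, 5, 5, 5)])  # depths (12,9), (10,10)
        out = filter_snps(t, min_depth=10)
        assert list(out.POS) == [200]

    def test_inclusive_boundary(self):
        t = snp_table([100], [(5, 5, 5, 5)])
        assert len(filter_snps(t, min_depth=10)) == 1

    def test_empty_table(self):
        t = snp_table([], np.empty((0, 4), dtype=int))
        assert len(filter_snps(t)) == 0


class TestSmoothG:
    def test_single_snp_window_value(self):
        prof = smooth_g([1_000_000], [7.5], window=2_000_000, step=10_000, chrom_length=2_000_000)
        c = np.argmin(np.abs(prof.centers - 1_000_000))
        assert prof.g[c] == 7.5

    def test_two_snps_mean(self):
        prof = smooth_g([900_000, 1_100_000], [0.0, 10.0], window=2_000_000, step=10_000, chrom_length=2_000_000)
        c = np.argmin(np.abs(prof.centers - 1_000_000))
        assert prof.g[c] == 5.0

    def test_empty_windows_are_nan(self):
        prof = smooth_g([100_000], [1.0], window=50_000, step=10_000, chrom_length=1_000_000)
        assert np.isnan(prof.g[-1])
        assert np.isfinite(prof.g[10])

    def test_centers_on_regular_grid(self):
        prof = smooth_g([5_000], [1.0], window=10_000, step=2_500, chrom_length=20_000)
        assert np.diff(prof.centers) == pytest.approx(np.full(prof.centers.size - 1, 2_500))


class TestNullThreshold:
    def test_finite_nonnegative(self):
        table, _ = simulate_bulks(BulkSim(chrom_length=2_000_000, n_snps=100, causal_pos=None, seed=1))
        thr = null_threshold(table, n_sim=200, chrom_length=2_000_000, seed=5)
        assert np.isfinite(thr[np.isfinite(thr)]).all()
        assert (thr[np.isfinite(thr)] >= 0).all()

    def test_max_percentile_dominates(self):
        table, _ = simulate_bulks(BulkSim(chrom_length=2_000_000, n_snps=100, causal_pos=None, seed=1))
        t_max = null_threshold(table, n_sim=200, percentile=100, chrom_length=2_000_000, seed=5)
        t_995 = null_threshold(table, n_sim=200, percentile=99.5, chrom_length=2_000_000, seed=5)
        ok = np.isfinite(t_max) & np.isfinite(t_995)
        assert (t_max[ok] >= t_995[ok] - 1e-12).all()

    def test_small_n_sim_warns(self, caplog):
        table, _ = simulate_bulks(BulkSim(chrom_length=1_000_000, n_snps=50, causal_pos=None, seed=2))
        with caplog.at_level("WARNING"):
            null_threshold(table, n_sim=50, chrom_length=1_000_000, seed=1)
        assert any("n_sim" in m for m in caplog.messages)


class TestSignificantIntervals:
    def _profile(self, g, thr):
        g = np.asarray(g, dtype=float)
        return GProfile(
            chrom="chr1",
            centers=np.arange(g.size) * 10_000.0,
            g=g,
            n_snps=np.ones(g.size, dtype=int),
            window=2e6,
            step=10_000.0,
            threshold=np.full(g.size, thr),
        )

    def test_all_below_threshold_empty(self):
        assert significant_intervals(self._profile([1, 2, 1, 2], 5.0)) == []

    def test_single_run_single_interval(self):
        out = significant_intervals(self._profile([1, 9, 9, 9, 1], 5.0))
        assert len(out) == 1
        assert (out[0].start, out[0].end) == (10_000.0, 40_000.0)
        assert out[0].max_g == 9

    def test_one_step_gap_bridged(self):
        out = significant_intervals(self._profile([9, 1, 9, 1, 1, 1, 9], 5.0))
        assert len(out) == 2
        assert (out[0].start, out[0].end) == (0.0, 30_000.0)


def identity_chain(length=10_000_000, strand="+", qname="A", tname="B"):
    return [
        PafRecord(
            qname=qname, qlen=length, qstart=0, qend=length, strand=strand,
            tname=tname, tlen=length, tstart=0, tend=length,
            nmatch=length, alnlen=length, mapq=60,
        )
    ]


class TestProjection:
    def test_identity_maps_interval_unchanged(self):
        res = project_interval((2_000_000, 3_000_000), identity_chain())
        assert (res.start, res.end, res.unmapped_bp) == (2_000_000, 3_000_000, 0)

    def test_minus_strand_reverses_coordinates(self):
        res = project_interval((2_000_000, 3_000_000), identity_chain(strand="-"))
        assert (res.start, res.end) == (7_000_000, 8_000_000)

    def test_round_trip_identity(self):
        chain = identity_chain()
        fwd = project_interval((2_000_000, 3_000_000), chain, source="query")
        back = project_interval((fwd.start, fwd.end), chain, source="target")
        assert (back.start, back.end) == (2_000_000, 3_000_000)

    def test_double_inversion_returns_original(self):
        chain = identity_chain(strand="-")
        fwd = project_interval((2_000_000, 3_000_000), chain, source="query")
        back = project_interval((fwd.start, fwd.end), chain, source="target")
        assert (back.start, back.end) == (2_000_000, 3_000_000)

    def test_no_overlap_unmappable(self):
        chain = identity_chain(length=1_000_000)
        assert project_interval((2_000_000, 3_000_000), chain) is None

    def test_split_blocks_minimal_cover_and_overhang(self):
        length = 10_000_000
        blocks = [
            PafRecord("A", length, 0, 2_500_000, "+", "B", length, 0, 2_500_000, 2_500_000, 2_500_000, 60),
            PafRecord("A", length, 2_600_000, 5_000_000, "+", "B", length, 2_600_000, 5_000_000, 2_400_000, 2_400_000, 60),
        ]
        res = project_interval((2_000_000, 3_000_000), blocks)
        assert (res.start, res.end) == (2_000_000, 3_000_000)
        assert res.unmapped_bp == 100_000


def _peak(ref, start, end):
    return PeakInterval(reference=ref, chrom="chr1", start=start, end=end, max_g=10.0)


class TestConsensus:
    def test_identical_intervals_full_support(self):
        peaks = {r: _peak(r, 2e6, 3e6) for r in ("A", "B", "C")}
        chains = {r: identity_chain(qname=r, tname="A") for r in ("B", "C")}
        res = consensus_interval(peaks, chains, anchor="A")
        assert (res.start, res.end) == (2e6, 3e6)
        assert res.support == ["A", "B", "C"] and res.mode == "intersection"

    def test_staggered_intervals_intersect(self):
        peaks = {"A": _peak("A", 0, 3e6), "B": _peak("B", 1e6, 4e6), "C": _peak("C", 2e6, 5e6)}
        chains = {r: identity_chain(qname=r, tname="A") for r in ("B", "C")}
        res = consensus_interval(peaks, chains, anchor="A")
        assert (res.start, res.end) == (2e6, 3e6)

    def test_unmappable_reference_degrades_gracefully(self):
        peaks = {"A": _peak("A", 2e6, 3e6), "B": _peak("B", 2e6, 3e6), "C": _peak("C", 2e6, 3e6)}
        chains = {
            "B": identity_chain(qname="B", tname="A"),
            "C": identity_chain(length=1_000_000, qname="C", tname="A"),  # no overlap with peak
        }
        res = consensus_interval(peaks, chains, anchor="A")
        assert res.unmappable == ["C"]
        assert res.support == ["A", "B"]
        assert (res.start, res.end) == (2e6, 3e6)

    def test_order_invariance(self):
        base = {"A": _peak("A", 0, 3e6), "B": _peak("B", 1e6, 4e6), "C": _peak("C", 2e6, 5e6)}
        chains = {r: identity_chain(qname=r, tname="A") for r in ("B", "C")}
        r1 = consensus_interval(base, chains, anchor="A")
        reordered = {k: base[k] for k in ("C", "A", "B")}
        r2 = consensus_interval(reordered, chains, anchor="A")
        assert (r1.start, r1.end, r1.support) == (r2.start, r2.end, r2.support)


class TestDiagnosticSnps:
    def test_pass_fail_reasons(self):
        t = snp_table(
            [100, 200, 300],
            [
                (0, 30, 15, 15),  # freq (1.0, 0.5), depths (30, 30) -> pass
                (12, 18, 15, 15),  # bulk1 freq 0.6 vs expected 1.0 -> frequency
                (0, 8, 15, 15),  # bulk1 depth 8 -> depth
            ],
        )
        out = select_diagnostic_snps(t, (0, 1000), expected_freqs=(1.0, 0.5), min_depth=10, tol=0.1)
        by_pos = out.set_index("POS")
        assert bool(by_pos.loc[100, "passed"]) and by_pos.loc[100, "reason"] == ""
        assert not by_pos.loc[200, "passed"] and by_pos.loc[200, "reason"] == "frequency"
        assert not by_pos.loc[300, "passed"] and by_pos.loc[300, "reason"] == "depth"

    def test_ranked_by_depth(self):
        t = snp_table([100, 200], [(0, 40, 20, 20), (0, 12, 6, 6)])
        out = select_diagnostic_snps(t, (0, 1000))
        assert list(out.POS) == [100, 200]


class TestEndToEnd:
    def test_planted_locus_top_interval_contains_causal(self):
        cfg = BulkSim(chrom_length=20_000_000, n_snps=800, causal_pos=10_000_000, mean_depth=40, seed=7)
        table, _ = simulate_bulks(cfg)
        profile, intervals = run_bsa(
            table, n_sim=300, n_plants=cfg.n_plants, chrom_length=cfg.chrom_length, seed=11
        )
        assert intervals, "planted locus should produce a significant interval"
        top = intervals[0]
        assert top.start <= 10_000_000 <= top.end
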