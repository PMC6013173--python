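"""Integration layer: BoE computation, TSS collapse, windows, counting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from boearch.integration import (
    architecture_size,
    build_count_matrix,
    collapse_redundant,
    compute_boe,
    exclude_covariates,
    filter_peaks_by_qs,
    promoter_window,
)
from boearch.types import PeakRecord, TssRecord


class TestComputeBoe:
    def test_all_off_row(self):
        expr = pd.DataFrame([[0.0, 0.0, 0.0]], index=["t1"])
        r = compute_boe(expr)
        assert r.successes[0] == 0 and r.trials == 3 and r.boe[0] == 0.0

    def test_cutoff_is_strict(self):
        expr = pd.DataFrame([[10.0, 10.1]], index=["t1"])
        r = compute_boe(expr, tpm_cutoff=10.0)
        assert r.successes[0] == 1 and r.boe[0] == 0.5

    def test_matches_per_cell_brute_force(self, rng):
        expr = pd.DataFrame(rng.exponential(8.0, size=(100, 50)),
                            index=[f"t{i}" for i in range(100)])
        r = compute_boe(expr, tpm_cutoff=10.0)
        for i in range(100):
            brute = sum(1 for v in expr.iloc[i] if v > 10.0)
            assert r.successes[i] == brute

    def test_monotone_in_cutoff(self, rng):
        expr = pd.DataFrame(rng.exponential(10.0, size=(50, 30)))
        low = compute_boe(expr, tpm_cutoff=5.0)
        high = compute_boe(expr, tpm_cutoff=15.0)
        assert (high.successes <= low.successes).all()

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            compute_boe(pd.DataFrame())


class TestCollapseRedundant:
    def test_shared_tss_keeps_smallest_id(self):
        recs = [TssRecord("NM_2", "chr1", "+", 100),
                TssRecord("NM_1", "chr1", "+", 100)]
        out = collapse_redundant(recs)
        assert [r.transcript_id for r in out] == ["NM_1"]

    def test_distinct_tsses_identity(self):
        recs = [TssRecord(f"NM_{i}", "chr1", "+", 100 * i) for i in range(1, 5)]
        assert set(r.transcript_id for r in collapse_redundant(recs)) == {
            "NM_1", "NM_2", "NM_3", "NM_4"}

    def test_matches_brute_force_group_by(self, rng):
        recs = [
            TssRecord(f"NM_{i:04d}", f"chr{rng.integers(1, 4)}",
                      "+-"[rng.integers(2)], int(rng.integers(0, 50)) * 100)
            for i in range(1000)
        ]
        out = collapse_redundant(recs)
        groups = {}
        for r in recs:
            groups.setdefault((r.chrom, r.strand, r.tss), []).append(
                r.transcript_id)
        expected = {min(ids) for ids in groups.values()}
        assert {r.transcript_id for r in out} == expected
        # strand matters: same position on opposite strands is two promoters
        assert len(out) == len(groups)


class TestPromoterWindow:
    def test_centred_window(self):
        w = promoter_window(TssRecord("t", "chr1", "+", 10_000), 500)
        assert (w.start, w.end) == (9_500, 10_500)

    def test_clipped_at_chromosome_start(self):
        w = promoter_window(TssRecord("t", "chr1", "-", 200), 500)
        assert (w.start, w.end) == (0, 700)

    def test_strand_does_not_change_window(self):
        plus = promoter_window(TssRecord("a", "chr1", "+", 5000))
        minus = promoter_window(TssRecord("b", "chr1", "-", 5000))
        assert (plus.start, plus.end) == (minus.start, minus.end)

    @settings(derandomize=True, max_examples=50)
    @given(tss=st.integers(min_value=0, max_value=10**8),
           w=st.integers(min_value=1, max_value=10_000))
    def test_width_property(self, tss, w):
        win = promoter_window(TssRecord("t", "chr1", "+", tss), w)
        if tss >= w:
            assert len(win) == 2 * w
        else:
            assert win.start == 0 and win.end == tss + w


class TestQsFilter:
    def test_strictness_at_the_cutoff(self):
        keep = PeakRecord("chr1", 0, 10, "A", 501)
        drop = PeakRecord("chr1", 0, 10, "A", 500)
        assert filter_peaks_by_qs([keep, drop]) == [keep]

    def test_empty_input(self):
        assert filter_peaks_by_qs([]) == []

    def test_matches_brute_force_scan(self, rng):
        peaks = [PeakRecord("chr1", i, i + 10, "A", int(q))
                 for i, q in enumerate(rng.integers(0, 1001, size=500))]
        out = filter_peaks_by_qs(peaks, 500)
        assert len(out) == sum(1 for p in peaks if p.qs > 500)
        assert out == [p for p in peaks if p.qs > 500]  # order preserved


def _window(chrom, start, end):
    from boearch.types import GenomicInterval

    return GenomicInterval(chrom, start, end)


class TestCountMatrix:
    def test_multiset_counting(self):
        peaks = [PeakRecord("chr1", 990, 1010, "Egr1", 900),
                 PeakRecord("chr1", 1100, 1150, "Egr1", 800),
                 PeakRecord("chr1", 900, 920, "SUZ12", 700)]
        P = build_count_matrix(peaks, [_window("chr1", 500, 1500)], ["t1"])
        assert P.loc["t1", "Egr1"] == 2 and P.loc["t1", "SUZ12"] == 1

    def test_empty_architecture_row(self):
        peaks = [PeakRecord("chr1", 5000, 5100, "A", 900)]
        P = build_count_matrix(peaks, [_window("chr1", 0, 1000)], ["t1"])
        assert P.loc["t1"].sum() == 0

    def test_overlapping_windows_both_count(self):
        peaks = [PeakRecord("chr1", 995, 1005, "A", 900)]
        windows = [_window("chr1", 500, 1500), _window("chr1", 900, 1900)]
        P = build_count_matrix(peaks, windows, ["t1", "t2"])
        assert P["A"].tolist() == [1, 1]

    def test_midpoint_rule_at_boundary(self):
        # midpoint floor((start+end)/2) must lie inside the half-open window
        inside = PeakRecord("chr1", 995, 1004, "A", 900)  # mid 999
        outside = PeakRecord("chr1", 996, 1005, "B", 900)  # mid 1000
        P = build_count_matrix([inside, outside],
                               [_window("chr1", 0, 1000)], ["t1"])
        assert P.loc["t1", "A"] == 1 and P.loc["t1", "B"] == 0

    def test_unknown_chromosome_ignored(self, caplog):
        peaks = [PeakRecord("chrUn", 0, 100, "A", 900),
                 PeakRecord("chr1", 10, 30, "A", 900)]
        P = build_count_matrix(peaks, [_window("chr1", 0, 1000)], ["t1"])
        assert P.loc["t1", "A"] == 1

    def test_matches_brute_force_overlap_count(self, rng):
        tfs = ["A", "B", "C"]
        peaks = [PeakRecord("chr1", int(s), int(s) + int(l), tfs[int(t)], 900)
                 for s, l, t in zip(rng.integers(0, 5000, 300),
                                    rng.integers(10, 300, 300),
                                    rng.integers(0, 3, 300))]
        windows = [_window("chr1", int(s), int(s) + 1000)
                   for s in rng.integers(0, 4500, 40)]
        names = [f"t{i}" for i in range(40)]
        P = build_count_matrix(peaks, windows, names)
        for i, w in enumerate(windows):
            for tf in tfs:
                brute = sum(1 for p in peaks
                            if p.tf_label == tf
                            and w.start <= (p.start + p.end) // 2 < w.end)
                assert P.iloc[i][tf] == brute

    def test_permutation_invariance_in_peak_order(self, rng):
        peaks = [PeakRecord("chr1", int(s), int(s) + 50, "AB"[int(t)], 900)
                 for s, t in zip(rng.integers(0, 3000, 100),
                                 rng.integers(0, 2, 100))]
        windows = [_window("chr1", 0, 1000), _window("chr1", 800, 1800)]
        P1 = build_count_matrix(peaks, windows, ["a", "b"])
        shuffled = list(peaks)
        rng.shuffle(shuffled)
        P2 = build_count_matrix(shuffled, windows, ["a", "b"])
        pd.testing.assert_frame_equal(P1, P2)


class TestArchitectureSize:
    def test_raw_and_unique_by_definition(self):
        P = pd.DataFrame({"Egr1": [2], "SUZ12": [1], "X": [0]}, index=["t"])
        assert architecture_size(P, "raw").iloc[0] == 3
        assert architecture_size(P, "unique").iloc[0] == 2

    def test_all_zero_row(self):
        P = pd.DataFrame({"A": [0], "B": [0]}, index=["t"])
        for mode in ("raw", "unique"):
            assert architecture_size(P, mode).iloc[0] == 0

    def test_pol2_exclusion(self):
        P = pd.DataFrame({"Pol2": [5], "A": [2]}, index=["t"])
        s = architecture_size(P, "raw", exclude_pol2=True, pol2_labels=["Pol2"])
        assert s.iloc[0] == 2
        with pytest.raises(ValueError):
            architecture_size(P, "raw", exclude_pol2=True, pol2_labels=["nope"])

    def test_size_correlates_with_boe_under_activating_truth(self, linear_truth):
        from boearch.correlation import spearman_rho

        size = architecture_size(linear_truth.count_matrix, "raw")
        boe = linear_truth.response.boe
        # mostly activating planted effects: strong positive rank correlation
        assert spearman_rho(size.to_numpy(), boe) > 0.4


class TestExcludeCovariates:
    def test_column_count_drops(self):
        P = pd.DataFrame(np.zeros((3, 148), dtype=int),
                         columns=[f"TF{i}" for i in range(148)])
        out = exclude_covariates(P, [f"TF{i}" for i in range(4)])
        assert out.shape[1] == 144

    def test_empty_list_identity_and_round_trip(self):
        P = pd.DataFrame({"A": [1], "B": [2]})
        pd.testing.assert_frame_equal(exclude_covariates(P, []), P)
        out = exclude_covariates(P, ["A"])
        restored = pd.concat([P[["A"]], out], axis=1)[P.columns]
        pd.testing.assert_frame_equal(restored, P)

    def test_unknown_label(self):
        with pytest.raises(ValueError):
            exclude_covariates(pd.DataFrame({"A": [1]}), ["B"])
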