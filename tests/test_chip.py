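"""ChIP operations: enrichment testing, merging, counting, normalization,
and PWM scanning, each against an independent oracle or frozen hand value."""
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from p53sig.chip import (
    bh_fdr,
    build_pwm_from_consensus,
    call_significant_peaks,
    count_fragments,
    merge_regions,
    normalize_top30,
    poisson_tail,
    scan_pwm,
    annotate_motifs,
)
from p53sig.types import GenomicInterval, PeakCall


def mk_peak(ip, ctrl, ip_lib=1000, ctrl_lib=1000, start=0, sample="CHIP_LA2_tam"):
    return PeakCall(
        interval=GenomicInterval("c1", start, start + 100),
        sample_id=sample,
        ip_count=ip,
        control_count=ctrl,
        ip_libsize=ip_lib,
        control_libsize=ctrl_lib,
    )


class TestPoissonTail:
    def test_whole_support(self):
        assert poisson_tail(0, 0.5) == 1.0
        assert poisson_tail(0, 1000.0) == 1.0

    def test_frozen_partial_sums(self):
        # 1 - e^-1 (1 + 1 + 1/2) and 1 - e^-2
        assert poisson_tail(3, 1.0) == pytest.approx(0.080301397, abs=1e-8)
        assert poisson_tail(1, 2.0) == pytest.approx(0.864664717, abs=1e-8)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            poisson_tail(1, 0.0)
        with pytest.raises(ValueError):
            poisson_tail(-1, 1.0)

    def test_large_lambda_stable(self):
        p = poisson_tail(1200, 1000.0)
        assert 0 < p < 1 and not math.isnan(p)


def textbook_bh(pvals):
    """Independent step-up implementation: sort, scale, cumulative min."""
    p = np.asarray(pvals, float)
    n = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


class TestBhFdr:
    def test_single_p_identity(self):
        assert bh_fdr([0.05]) == [0.05]

    def test_hand_step_up(self):
        assert bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=50))
    def test_matches_textbook_and_never_decreases(self, pvals):
        q = np.array(bh_fdr(pvals))
        assert np.allclose(q, textbook_bh(pvals), atol=1e-12)
        assert np.all(q >= np.asarray(pvals) - 1e-12)

    def test_permutation_equivariant(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=20)
        perm = rng.permutation(20)
        assert np.allclose(np.array(bh_fdr(p))[perm], bh_fdr(p[perm]))


class TestCallSignificantPeaks:
    def test_all_zero_ip_not_significant(self):
        peaks = [mk_peak(0, c) for c in (0, 1, 5)]
        called = call_significant_peaks(peaks)
        assert not any(p.significant for p in called)

    def test_strong_peak_significant(self):
        peaks = call_significant_peaks([mk_peak(200, 2)])
        assert peaks[0].enrichment == pytest.approx(200 / 3)
        assert peaks[0].significant

    def test_fold_filter_binds(self):
        # enrichment 49/10 = 4.9 < 5 despite a vanishing q-value
        peaks = call_significant_peaks([mk_peak(49, 9)])
        assert peaks[0].qvalue < 1e-6
        assert peaks[0].enrichment == pytest.approx(4.9)
        assert not peaks[0].significant

    def test_libsize_scaling(self):
        # pooled control at twice the depth halves the control rate
        peaks = call_significant_peaks([mk_peak(30, 9, ip_lib=1000, ctrl_lib=2000)])
        assert peaks[0].enrichment == pytest.approx(6.0)

    def test_monotone_in_ip_count(self):
        flags = [
            call_significant_peaks([mk_peak(ip, 4)])[0].significant
            for ip in range(0, 120, 5)
        ]
        assert flags == sorted(flags)  # once significant, stays significant

    def test_empty_input(self):
        assert call_significant_peaks([]) == []


def brute_force_covered(intervals, span=400):
    """Base-marking oracle: the exact set of covered bases per chromosome."""
    covered = {}
    for iv in intervals:
        arr = covered.setdefault(iv.chrom, np.zeros(span, bool))
        arr[iv.start : iv.end] = True
    return covered


def assert_matches_base_marking(merged, intervals, span=400):
    """Merged output covers exactly the base-marked union, is disjoint and
    sorted, and splits only at junctions no input interval spans (touching
    intervals do not merge)."""
    oracle = brute_force_covered(intervals, span)
    got = {}
    for r in merged:
        arr = got.setdefault(r.interval.chrom, np.zeros(span, bool))
        assert not arr[r.interval.start : r.interval.end].any()  # disjoint
        arr[r.interval.start : r.interval.end] = True
    assert set(got) == set(oracle)
    for chrom in oracle:
        assert np.array_equal(got[chrom], oracle[chrom])
    regions = [(r.interval.chrom, r.interval.start, r.interval.end) for r in merged]
    assert regions == sorted(regions)
    for (c1, _s1, e1), (c2, s2, _e2) in zip(regions, regions[1:]):
        if c1 == c2 and e1 == s2:  # touching split: no input spans it
            assert not any(
                iv.chrom == c1 and iv.start < e1 and s2 < iv.end for iv in intervals
            )


class TestMergeRegions:
    def test_overlap_merges(self):
        merged = merge_regions([GenomicInterval("c1", 1, 10), GenomicInterval("c1", 5, 20)])
        assert [(r.interval.start, r.interval.end) for r in merged] == [(1, 20)]
        assert merged[0].region_id == "c1:1-20"

    def test_adjacent_stay_separate(self):
        merged = merge_regions([GenomicInterval("c1", 1, 10), GenomicInterval("c1", 10, 20)])
        assert len(merged) == 2

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        ivs = [
            GenomicInterval("c1", int(s), int(s) + int(l))
            for s, l in zip(rng.integers(0, 300, 200), rng.integers(1, 40, 200))
        ]
        once = merge_regions(ivs)
        twice = merge_regions([r.interval for r in once])
        assert [r.region_id for r in once] == [r.region_id for r in twice]

    def test_matches_base_marking_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            ivs = [
                GenomicInterval(f"c{int(c)}", int(s), int(s) + int(l))
                for c, s, l in zip(
                    rng.integers(1, 3, 200),
                    rng.integers(0, 350, 200),
                    rng.integers(1, 30, 200),
                )
            ]
            assert_matches_base_marking(merge_regions(ivs), ivs)


class TestCountFragments:
    def test_no_fragments_all_zero(self):
        regions = merge_regions([GenomicInterval("c1", 0, 10)])
        assert count_fragments([], regions).tolist() == [0]

    def test_double_overlap_counts_both(self):
        regions = merge_regions(
            [GenomicInterval("c1", 0, 10), GenomicInterval("c1", 12, 20)]
        )
        counts = count_fragments([GenomicInterval("c1", 5, 15)], regions)
        assert counts.tolist() == [1, 1]

    def test_unknown_chromosome_rejected(self):
        regions = merge_regions([GenomicInterval("c1", 0, 10)])
        with pytest.raises(ValueError, match="unknown chromosome"):
            count_fragments([GenomicInterval("c9", 0, 5)], regions)

    def test_matches_quadratic_oracle(self):
        rng = np.random.default_rng(3)
        base = [
            GenomicInterval("c1", int(s), int(s) + 20)
            for s in rng.choice(np.arange(0, 5000, 40), 50, replace=False)
        ]
        regions = merge_regions(base)
        frags = [
            GenomicInterval("c1", int(s), int(s) + int(l))
            for s, l in zip(rng.integers(0, 5000, 1000), rng.integers(1, 60, 1000))
        ]
        got = count_fragments(frags, regions)
        expected = [
            sum(1 for f in frags if f.overlaps(r.interval)) for r in regions
        ]
        assert got.tolist() == expected


class TestNormalizeTop30:
    def test_hand_example(self):
        raw = pd.DataFrame(
            {"A": [100, 50, 10, 40], "B": [200, 100, 20, 80]},
            index=["r1", "r2", "r3", "r4"],
        )
        norm = normalize_top30(raw)
        # shared top-30% set {r1, r2}: S_A=150, S_B=300, mean 225
        assert norm.at["r3", "A"] == pytest.approx(15.0)
        assert norm.at["r3", "B"] == pytest.approx(15.0)

    def test_scale_invariance_per_condition(self):
        rng = np.random.default_rng(5)
        raw = pd.DataFrame(
            rng.integers(1, 500, size=(30, 3)),
            index=[f"r{i:02d}" for i in range(30)],
            columns=["A", "B", "C"],
        )
        scaled = raw.copy()
        scaled["B"] = raw["B"] * 7
        a = normalize_top30(raw)
        b = normalize_top30(scaled)
        ratio = (b / a).to_numpy()
        assert np.allclose(ratio, ratio[0, 0])  # single global constant

    def test_all_equal_counts(self):
        raw = pd.DataFrame(
            {"A": [5] * 10, "B": [5] * 10}, index=[f"r{i}" for i in range(10)]
        )
        norm = normalize_top30(raw)
        assert np.allclose(norm.to_numpy(), norm.iat[0, 0])

    def test_too_few_regions(self):
        raw = pd.DataFrame({"A": [1, 2], "B": [2, 1]}, index=["r1", "r2"])
        with pytest.raises(ValueError):
            normalize_top30(raw)


class TestPwm:
    def test_fixed_base_row(self):
        pwm = build_pwm_from_consensus("A", pseudocount=0.0)
        assert pwm.probs[0].tolist() == [1.0, 0.0, 0.0, 0.0]

    def test_degenerate_row(self):
        pwm = build_pwm_from_consensus("R", pseudocount=0.0)
        assert pwm.probs[0].tolist() == [0.5, 0.0, 0.5, 0.0]

    def test_rows_normalized(self):
        pwm = build_pwm_from_consensus()
        assert pwm.length == 20
        assert np.allclose(pwm.probs.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(pwm.probs > 0)

    def test_invalid_code(self):
        with pytest.raises(ValueError, match="IUPAC"):
            build_pwm_from_consensus("AXG")

    def test_threshold_is_worst_single_mismatch(self):
        pwm = build_pwm_from_consensus()
        lods = np.log2(pwm.probs / pwm.background)
        expected = lods.max(axis=1).sum() - (lods.max(axis=1) - lods.min(axis=1)).max()
        assert pwm.score_threshold == pytest.approx(expected)


def brute_scores(seq, pwm):
    """Per-offset log2-odds scores on both strands, plain Python."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    out = []
    L = pwm.length
    for off in range(len(seq) - L + 1):
        window = seq[off : off + L]
        rc = "".join(comp[b] for b in reversed(window))
        scores = {}
        for strand, word in (("+", window), ("-", rc)):
            s = 0.0
            for j, b in enumerate(word):
                if b == "N":
                    continue
                s += math.log2(pwm.probs[j, idx[b]] / pwm.background[idx[b]])
            scores[strand] = s
        out.append((off, scores["+"], scores["-"]))
    return out


class TestScanPwm:
    def test_poly_a_no_hits(self):
        pwm = build_pwm_from_consensus()
        assert scan_pwm("A" * 100, pwm) == []

    def test_embedded_consensus_recovered(self):
        rng = np.random.default_rng(42)
        pwm = build_pwm_from_consensus()
        word = "GGACATGTCCGGACATGTCC"
        for _ in range(5):
            bg = "".join(rng.choice(list("ACGT"), 60))
            seq = bg[:17] + word + bg[37:]
            hits = scan_pwm(seq, pwm)
            offsets = {h[0] for h in hits}
            assert offsets == {17}
            assert any(s == "+" for _, s, _ in hits)

    def test_matches_brute_force_everywhere(self):
        rng = np.random.default_rng(9)
        pwm = build_pwm_from_consensus()
        seq = "".join(rng.choice(list("ACGTN"), 200, p=[0.24, 0.24, 0.24, 0.24, 0.04]))
        hits = scan_pwm(seq, pwm, threshold_bits=-1e9)
        by_key = {(off, strand): score for off, strand, score in hits}
        for off, fwd, rev in brute_scores(seq, pwm):
            assert by_key[(off, "+")] == pytest.approx(fwd, abs=1e-9)
            assert by_key[(off, "-")] == pytest.approx(rev, abs=1e-9)

    def test_short_sequence(self):
        pwm = build_pwm_from_consensus()
        assert scan_pwm("ACGT", pwm) == []


class TestAnnotateMotifs:
    GENOME = {"c1": "A" * 40 + "GGACATGTCCGGACATGTCC" + "A" * 40}

    def test_motif_region_flagged(self):
        pwm = build_pwm_from_consensus()
        regions = merge_regions([GenomicInterval("c1", 30, 70)])
        annotate_motifs(regions, self.GENOME, pwm)
        assert regions[0].has_motif
        assert regions[0].motif_score > pwm.score_threshold - 1e-9

    def test_background_region_unflagged(self):
        pwm = build_pwm_from_consensus()
        regions = merge_regions([GenomicInterval("c1", 0, 30)])
        annotate_motifs(regions, self.GENOME, pwm)
        assert regions[0].has_motif is False
        assert regions[0].motif_score is None

    def test_straddling_motif_not_counted(self):
        # only 10 of the 20 motif bases fall inside the region
        pwm = build_pwm_from_consensus()
        regions = merge_regions([GenomicInterval("c1", 0, 50)])
        annotate_motifs(regions, self.GENOME, pwm)
        assert regions[0].has_motif is False

    def test_out_of_bounds_region(self):
        pwm = build_pwm_from_consensus()
        regions = merge_regions([GenomicInterval("c1", 50, 500)])
        with pytest.raises(ValueError, match="bounds"):
            annotate_motifs(regions, self.GENOME, pwm)
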