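"""Six-criterion DMR caller: seeding, filters, the 2x2 test, annotation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from rrbsmeth.dmr import (DMR, CandidateRegion, annotate_dmrs,
                          apply_count_and_coverage_filters,
                          apply_length_filter, call_dmrs, pearson_chi2_2x2,
                          seed_candidate_regions)
from rrbsmeth.dmr import test_region as score_region
from rrbsmeth.formats import GenomicFeature
from conftest import make_sites, overlaps


def make_calls(rows):
    """Calls frame from (chrom, pos, n_meth, n_total, is_methylated) rows."""
    frame = make_sites([(c, p, "+", "CG", m, t) for c, p, m, t, _ in rows])
    frame["level"] = frame["n_meth"] / frame["n_total"].clip(lower=1)
    frame["p_value"] = 0.0
    frame["q_value"] = 0.0
    frame["is_methylated"] = [bool(r[4]) for r in rows]
    return frame


def make_region(pos, meth_a, total_a, meth_b, total_b,
                ismeth_a=None, ismeth_b=None):
    pos = np.asarray(pos)
    meth_a, total_a = np.asarray(meth_a), np.asarray(total_a)
    meth_b, total_b = np.asarray(meth_b), np.asarray(total_b)
    if ismeth_a is None:
        ismeth_a = meth_a > 0
    if ismeth_b is None:
        ismeth_b = meth_b > 0
    return CandidateRegion(chrom="c", start=int(pos[0]), end=int(pos[-1]) + 1,
                           context="CG", pos=pos, meth_a=meth_a,
                           total_a=total_a, meth_b=meth_b, total_b=total_b,
                           ismeth_a=np.asarray(ismeth_a),
                           ismeth_b=np.asarray(ismeth_b))


class TestSeeding:
    def test_gap_rule_splits_and_merges(self):
        calls = make_calls([("c", 100, 20, 25, True), ("c", 250, 20, 25, True),
                            ("c", 600, 20, 25, True)])
        regions = seed_candidate_regions(calls, calls, "CG", max_gap=200)
        spans = [(r.start, r.end) for r in regions]
        assert spans == [(100, 251), (600, 601)]

    def test_gap_of_exactly_max_gap_splits(self):
        calls = make_calls([("c", 0, 20, 25, True), ("c", 200, 20, 25, True)])
        regions = seed_candidate_regions(calls, calls, "CG", max_gap=200)
        assert [(r.start, r.end) for r in regions] == [(0, 1), (200, 201)]

    def test_single_site_forms_singleton(self):
        calls = make_calls([("c", 42, 20, 25, True)])
        (region,) = seed_candidate_regions(calls, calls, "CG")
        assert (region.start, region.end, region.n_sites) == (42, 43, 1)

    def test_union_of_either_samples_methylated_sites(self):
        a = make_calls([("c", 10, 20, 25, True), ("c", 60, 0, 25, False)])
        b = make_calls([("c", 10, 0, 25, False), ("c", 60, 20, 25, True)])
        (region,) = seed_candidate_regions(a, b, "CG")
        assert region.n_sites == 2

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(st.lists(st.integers(0, 5000), min_size=1, max_size=60,
                    unique=True))
    def test_partition_matches_naive_scan(self, positions):
        positions = sorted(positions)
        calls = make_calls([("c", p, 20, 25, True) for p in positions])
        regions = seed_candidate_regions(calls, calls, "CG", max_gap=200)
        # oracle: linear scan splitting wherever the gap reaches 200
        expected, run = [], [positions[0]]
        for prev, cur in zip(positions, positions[1:]):
            if cur - prev >= 200:
                expected.append((run[0], run[-1] + 1))
                run = []
            run.append(cur)
        expected.append((run[0], run[-1] + 1))
        assert [(r.start, r.end) for r in regions] == expected


class TestCountCoverageFilter:
    def test_six_qualified_sites_pass(self):
        region = make_region(range(6), [5] * 6, [12] * 6, [0] * 6, [12] * 6)
        assert apply_count_and_coverage_filters(region)

    def test_five_methylated_in_both_samples_fail(self):
        region = make_region(range(5), [5] * 5, [12] * 5, [5] * 5, [12] * 5)
        assert not apply_count_and_coverage_filters(region)

    def test_one_member_at_coverage_ten_fails(self):
        region = make_region(range(6), [5] * 6, [12] * 5 + [10],
                             [0] * 6, [12] * 6)
        assert not apply_count_and_coverage_filters(region)

    def test_weakly_methylated_member_does_not_count(self):
        # six called-methylated members but one has only 4 methylated reads:
        # five qualify, the bound is strict, the region fails
        region = make_region(range(6), [5] * 5 + [4], [12] * 6,
                             [0] * 6, [12] * 6,
                             ismeth_a=[True] * 6, ismeth_b=[False] * 6)
        assert not apply_count_and_coverage_filters(region)


class TestLengthFilter:
    @pytest.mark.parametrize("length,ok", [(40, True), (39, False),
                                           (10_000, True), (10_001, False)])
    def test_inclusive_bounds(self, length, ok):
        region = make_region([0, length - 1], [20] * 2, [25] * 2,
                             [20] * 2, [25] * 2)
        assert apply_length_filter(region) is ok


class TestRegionTest:
    def test_worked_2x2_example(self):
        region = make_region([0, 10], [20, 10], [50, 50], [3, 2], [50, 50])
        chi2, p, fold, direction = score_region(region)
        # hand oracle: n(ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d))
        expected = 200 * (30 * 95 - 70 * 5) ** 2 / (100 * 100 * 35 * 165)
        assert chi2 == pytest.approx(expected, rel=1e-12)
        assert chi2 == pytest.approx(21.645, abs=1e-3)
        assert p == pytest.approx(3.3e-6, rel=0.02)
        assert fold == pytest.approx(6.0)
        assert direction == "hypo"

    def test_identical_tables_are_null(self):
        region = make_region([0, 10], [15, 15], [30, 30], [15, 15], [30, 30])
        chi2, p, fold, _ = score_region(region)
        assert (chi2, p, fold) == (0.0, 1.0, 1.0)

    def test_fold_exactly_two_is_not_above_threshold(self):
        region = make_region([0, 10], [20, 20], [50, 50], [10, 10], [50, 50])
        _, _, fold, _ = score_region(region)
        assert fold == pytest.approx(2.0)
        assert not fold > 2.0

    def test_zero_mean_in_one_sample_gives_infinite_fold(self):
        region = make_region([0, 10], [20, 20], [50, 50], [0, 0], [50, 50])
        _, _, fold, direction = score_region(region)
        assert np.isinf(fold) and direction == "hypo"

    def test_no_reads_in_one_sample_rejected(self):
        region = make_region([0, 10], [20, 20], [50, 50], [0, 0], [0, 0])
        with pytest.raises(ValueError, match="no reads"):
            score_region(region)

    def test_chi2_matches_contingency_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(1000):
            a, b, c, d = rng.integers(0, 200, size=4)
            if (a + b) == 0 or (c + d) == 0:
                continue
            chi2, p = pearson_chi2_2x2(int(a), int(b), int(c), int(d))
            if (a + c) == 0 or (b + d) == 0:
                assert (chi2, p) == (0.0, 1.0)
                continue
            ref_chi2, ref_p, _, _ = stats.chi2_contingency(
                [[a, b], [c, d]], correction=False)
            assert chi2 == pytest.approx(ref_chi2, rel=1e-9, abs=1e-9)
            assert p == pytest.approx(ref_p, rel=1e-9, abs=1e-12)

    def test_fold_monotone_in_added_methylated_reads(self):
        folds = []
        for extra in range(0, 30, 3):
            region = make_region([0, 10], [40, 40], [50, 50],
                                 [5 + extra, 5], [50 + extra, 50])
            folds.append(score_region(region)[2])
        assert all(f1 >= f2 - 1e-12 for f1, f2 in zip(folds, folds[1:]))


class TestCallDmrs:
    def test_identical_samples_yield_nothing(self):
        calls = make_calls([("c", p, 20, 25, True) for p in range(0, 500, 20)])
        assert call_dmrs(calls, calls) == []

    def test_planted_demethylated_block_is_recovered(self):
        # 10 CG sites over 450 bp: 0.8 in control, 0.1 in treatment
        pos = list(range(1000, 1450, 50))
        a = make_calls([("c", p, 24, 30, True) for p in pos])
        b = make_calls([("c", p, 3, 30, True) for p in pos])
        (dmr,) = call_dmrs(a, b, contexts=("CG",))
        assert (dmr.start, dmr.end, dmr.direction) == (1000, 1401, "hypo")
        assert dmr.fold_change == pytest.approx(8.0)

    def test_short_block_fails_length_criterion(self):
        pos = [1000, 1003, 1006, 1009, 1012, 1015, 1018]  # 19 bp span
        a = make_calls([("c", p, 24, 30, True) for p in pos])
        b = make_calls([("c", p, 3, 30, True) for p in pos])
        assert call_dmrs(a, b, contexts=("CG",)) == []

    def test_same_context_dmrs_never_overlap(self, calls_pair):
        calls_a, calls_b = calls_pair
        dmrs = call_dmrs(calls_a, calls_b, contexts=("CG",))
        assert dmrs, "standard scenario should produce CG DMRs"
        by_chrom = {}
        for d in dmrs:
            by_chrom.setdefault(d.chrom, []).append(d)
        for group in by_chrom.values():
            group.sort(key=lambda d: d.start)
            for left, right in zip(group, group[1:]):
                assert left.end <= right.start


class TestAnnotate:
    @staticmethod
    def _dmr(start, end):
        return DMR(chrom="c", start=start, end=end, context="CG", n_sites=6,
                   meth_a=60, unmeth_a=20, meth_b=10, unmeth_b=70,
                   mean_level_a=0.75, mean_level_b=0.125, fold_change=6.0,
                   chi2=30.0, p_value=1e-6, direction="hypo")

    def test_relations_by_position_and_strand(self):
        plus = GenomicFeature(id="g1", chrom="c", start=10_000, end=14_000,
                              strand="+", kind="gene")
        minus = GenomicFeature(id="g2", chrom="c", start=30_000, end=34_000,
                               strand="-", kind="gene")
        te = GenomicFeature(id="t1", chrom="c", start=50_000, end=52_000,
                            strand="+", kind="TE")
        dmrs = [self._dmr(8_400, 8_600),    # 1.5 kb 5' of plus gene
                self._dmr(50_500, 50_700),  # inside the TE body
                self._dmr(34_500, 34_700),  # 3' side of minus gene = its up2k
                self._dmr(70_000, 70_200)]  # 2.1 kb away from everything
        annotate_dmrs(dmrs, [plus, minus, te])
        assert dmrs[0].linked_features == [("g1", "up2k")]
        assert dmrs[1].linked_features == [("t1", "body")]
        assert dmrs[2].linked_features == [("g2", "up2k")]
        assert dmrs[3].linked_features == []

    def test_dmr_may_link_many_features(self):
        near = [GenomicFeature(id=f"g{i}", chrom="c", start=s, end=s + 1000,
                               strand="+", kind="gene")
                for i, s in enumerate((10_000, 12_000))]
        dmr = self._dmr(11_200, 11_400)
        annotate_dmrs([dmr], near)
        assert {fid for fid, _ in dmr.linked_features} == {"g0", "g1"}
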