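"""The walk statistic: site classification, descent, and exact P-values."""

from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from paraconv.io import project_onto_paralog_columns
from paraconv.walk import (
    StepSeries,
    binomial_coverage_pvalue,
    build_triplet_walk,
    classify_site,
    collapse_magnitudes,
    combine_quadruplet,
    infer_direction,
    max_descent_pvalue,
    maximum_descent,
)

from conftest import make_alignment


def brute_force_descent_pvalue(m: int, n: int, k: int) -> float:
    """Oracle: enumerate all C(m+n, n) orderings of unit steps."""
    if k == 0:
        return 1.0
    total = m + n
    count = hits = 0
    for downs in combinations(range(total), n):
        ds = set(downs)
        h = mx = dd = 0
        for t in range(total):
            h += -1 if t in ds else 1
            mx = max(mx, h)
            dd = max(dd, mx - h)
        count += 1
        hits += dd >= k
    return hits / count


def make_walk(pattern: str, total_columns: int | None = None) -> StepSeries:
    """Walk from a string of 'U'/'D' (unit) letters."""
    signs = np.array([1 if c == "U" else -1 for c in pattern])
    cols = np.arange(len(pattern))
    return StepSeries(cols, signs, np.ones(len(pattern), dtype=int),
                      total_columns or len(pattern))


class TestClassifySite:
    def test_paralog_match_is_down(self):
        # primary == paralog != ortholog: the conversion-like pattern
        assert classify_site("A", "A", "C") == "down"

    def test_ortholog_match_is_up(self):
        assert classify_site("A", "C", "A") == "up"

    @pytest.mark.parametrize("triple", [("A", "A", "A"), ("A", "C", "G"), ("A", "C", "C")])
    def test_neutral(self, triple):
        assert classify_site(*triple) == "neutral"

    def test_ambiguity_rejected(self):
        with pytest.raises(ValueError):
            classify_site("A", "N", "A")
        with pytest.raises(ValueError):
            classify_site("-", "A", "A")


class TestTripletWalk:
    def test_identical_triple_no_steps(self):
        paralog = make_alignment("ACGTACGTAC", "ACGTACGTAC")
        proj = np.frombuffer(b"ACGTACGTAC", dtype=np.uint8).copy()
        walk = build_triplet_walk(paralog, proj, 1)
        assert (walk.m, walk.n) == (0, 0)

    def test_single_paralog_match_site(self):
        # primary == paralog != ortholog at one column: one down step
        paralog = make_alignment("ACGTACGTAC", "ACGTACGTAC")
        proj = np.frombuffer(b"ACGTTCGTAC", dtype=np.uint8).copy()
        walk = build_triplet_walk(paralog, proj, 1)
        assert (walk.m, walk.n) == (0, 1)
        assert walk.columns.tolist() == [4]

    def test_uncovered_projection_empty_walk(self):
        paralog = make_alignment("ACGT", "ACGT")
        walk = build_triplet_walk(paralog, np.zeros(4, dtype=np.uint8), 1)
        assert len(walk) == 0

    def test_gap_and_ambiguity_columns_skipped(self):
        paralog = make_alignment("AC-TN", "ACGTN", start2=0)
        proj = np.frombuffer(b"CCGTN", dtype=np.uint8).copy()
        walk = build_triplet_walk(paralog, proj, 1)
        # col 0: primary A, paralog A, ortholog C -> down; cols 2 (gap), 4 (N) skipped
        assert walk.columns.tolist() == [0]
        assert walk.n == 1

    def test_full_pipeline_projection(self, sim_with_conversion):
        sim = sim_with_conversion
        paralog = [a for a in sim.paralog_alignments
                   if a.interval1.species == "S1"][0]
        found = sim.orthology.best_alignment(paralog.interval1, "S2")
        assert found is not None
        proj = project_onto_paralog_columns(paralog, found[0], 1, found[1])
        walk = build_triplet_walk(paralog, proj, 1)
        # plenty of informative sites on a 3 kb alignment
        assert walk.m + walk.n > 100
        # cumulative score final value = m - n
        assert int((walk.signs * walk.magnitudes).sum()) == walk.m - walk.n


class TestCombineQuadruplet:
    def test_both_down_single_magnitude2(self):
        w1 = make_walk("D", 10)
        w2 = make_walk("D", 10)
        combined = combine_quadruplet(w1, w2)
        assert combined.magnitudes.tolist() == [2]
        assert combined.n == 2

    def test_single_walk_column_kept_as_unit(self):
        w1 = make_walk("U", 10)
        w2 = StepSeries(np.array([5]), np.array([1]), np.array([1]), 10)
        combined = combine_quadruplet(w1, w2)
        assert combined.columns.tolist() == [0, 5]
        assert combined.magnitudes.tolist() == [1, 1]

    def test_empty_second_walk_is_identity(self):
        w1 = make_walk("UDUD", 10)
        w2 = StepSeries(np.array([]), np.array([]), np.array([]), 10)
        combined = combine_quadruplet(w1, w2)
        assert combined.columns.tolist() == w1.columns.tolist()
        assert combined.signs.tolist() == w1.signs.tolist()

    def test_conflicting_signs_raise(self):
        w1 = make_walk("U", 10)
        w2 = make_walk("D", 10)
        with pytest.raises(ValueError, match="up in one"):
            combine_quadruplet(w1, w2)

    def test_self_combine_doubles_counts(self):
        w = make_walk("UUDUD", 20)
        doubled = combine_quadruplet(w, w)
        assert doubled.m == 2 * w.m
        assert doubled.n == 2 * w.n
        assert (doubled.magnitudes == 2).all()

    def test_collapse_restores_unit_magnitudes(self):
        w = make_walk("UUD", 10)
        collapsed = collapse_magnitudes(combine_quadruplet(w, w))
        assert (collapsed.magnitudes == 1).all()
        assert collapsed.m == w.m and collapsed.n == w.n


class TestMaximumDescent:
    def test_uudd(self):
        # heights 0,1,2,1,0: k=2 spanning the two down steps
        d = maximum_descent(make_walk("UUDD"))
        assert d.k == 2
        assert (d.start_col, d.end_col) == (2, 3)

    def test_monotone_up_no_descent(self):
        d = maximum_descent(make_walk("UUUUU"))
        assert d.k == 0 and d.empty

    def test_single_down(self):
        d = maximum_descent(make_walk("D"))
        assert d.k == 1
        assert (d.start_col, d.end_col) == (0, 0)

    def test_empty_walk(self):
        d = maximum_descent(StepSeries(np.array([]), np.array([]), np.array([]), 5))
        assert d.k == 0

    def test_descent_starts_at_last_peak(self):
        # max reattained before the real descent: interval excludes the noise
        d = maximum_descent(make_walk("UDUDDD"))
        # heights 0,1,0,1,0,-1,-2; peak at step 4 (col 3), descent cols 4..5...
        assert d.k == 3
        assert (d.start_col, d.end_col) == (3, 5)

    def test_k_equals_brute_force_definition(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            pattern = "".join(rng.choice(["U", "D"], size=30))
            walk = make_walk(pattern)
            heights = np.concatenate(([0], np.cumsum(walk.signs)))
            brute = max(
                heights[i] - heights[j]
                for i in range(len(heights))
                for j in range(i, len(heights))
            )
            assert maximum_descent(walk).k == brute


class TestMaxDescentPvalue:
    def test_no_downs_no_descent(self):
        assert max_descent_pvalue(5, 0, 1) == 0.0

    def test_k_zero_always_one(self):
        assert max_descent_pvalue(3, 4, 0) == 1.0

    def test_forced_full_descent(self):
        assert max_descent_pvalue(0, 4, 4) == 1.0

    def test_two_two_two(self):
        # 3 of the 6 orderings of UUDD reach descent 2
        assert max_descent_pvalue(2, 2, 2) == pytest.approx(0.5)

    def test_negative_arguments_rejected(self):
        with pytest.raises(ValueError):
            max_descent_pvalue(-1, 2, 1)

    @pytest.mark.parametrize("m,n", [(3, 3), (5, 2), (2, 5), (0, 6), (6, 1), (4, 4)])
    def test_matches_enumeration_oracle(self, m, n):
        for k in range(0, n + 2):
            assert max_descent_pvalue(m, n, k) == pytest.approx(
                brute_force_descent_pvalue(m, n, k), abs=1e-12
            )

    @given(
        st.integers(min_value=0, max_value=60),
        st.integers(min_value=0, max_value=60),
    )
    @settings(max_examples=40, deadline=None)
    def test_monotone_nonincreasing_in_k(self, m, n):
        values = [max_descent_pvalue(m, n, k) for k in range(n + 2)]
        assert all(0.0 <= v <= 1.0 for v in values)
        assert all(a >= b - 1e-12 for a, b in zip(values, values[1:]))

    def test_large_counts_run_fast_and_sane(self):
        p_small_k = max_descent_pvalue(1200, 800, 10)
        p_large_k = max_descent_pvalue(1200, 800, 120)
        assert p_small_k > 0.9
        assert p_large_k < 1e-6


class TestBinomialCoveragePvalue:
    def test_three_one(self):
        p_value, p = binomial_coverage_pvalue(3, 1)
        assert p == pytest.approx(0.25)
        assert p_value == pytest.approx(1 - 0.75**4)

    def test_no_downs_tail_is_one(self):
        p_value, p = binomial_coverage_pvalue(7, 0)
        assert p == 0.0
        assert p_value == 1.0

    def test_all_downs(self):
        p_value, p = binomial_coverage_pvalue(0, 5)
        assert p == pytest.approx(0.5)
        assert p_value == pytest.approx(0.5**5)

    def test_zero_sites_rejected(self):
        with pytest.raises(ValueError):
            binomial_coverage_pvalue(0, 0)

    @given(st.integers(0, 80), st.integers(0, 80))
    @settings(max_examples=60, deadline=None)
    def test_matches_direct_pmf_sum(self, m, n):
        if m + n == 0:
            return
        p_value, p = binomial_coverage_pvalue(m, n)
        total = m + n
        direct = sum(
            float(stats.binom.pmf(i, total, p)) for i in range(n, total + 1)
        )
        assert p_value == pytest.approx(direct, abs=1e-12)


class TestInferDirection:
    def _walk_with_downs(self, n_down: int, n_up: int, total: int = 40):
        pattern = "D" * n_down + "U" * n_up
        return make_walk(pattern, total)

    def test_asymmetric_proportions_call_direction(self):
        from paraconv.walk import MaxDescent

        # triplet 1 all paralog-match (recipient-like), triplet 2 mixed
        w1 = self._walk_with_downs(20, 0)
        w2 = self._walk_with_downs(9, 11)
        shared = MaxDescent(1, 0, 39)
        direction, p = infer_direction(w1, w2, shared)
        assert direction == "row2->row1"  # row1 is the recipient
        assert p is not None and p < 0.05

    def test_identical_proportions_unknown(self):
        from paraconv.walk import MaxDescent

        w1 = self._walk_with_downs(5, 5)
        w2 = self._walk_with_downs(5, 5)
        direction, _ = infer_direction(w1, w2, MaxDescent(1, 0, 39))
        assert direction == "unknown"

    def test_empty_triplet_in_interval_unknown(self):
        from paraconv.walk import MaxDescent

        w1 = self._walk_with_downs(10, 0)
        w2 = StepSeries(np.array([]), np.array([]), np.array([]), 40)
        direction, p = infer_direction(w1, w2, MaxDescent(1, 0, 39))
        assert direction == "unknown"
        assert p is None


class TestWalkInvariants:
    @given(st.lists(st.sampled_from(["U", "D"]), min_size=1, max_size=80))
    @settings(max_examples=60, deadline=None)
    def test_final_value_and_descent_bounds(self, letters):
        walk = make_walk("".join(letters))
        heights = np.cumsum(walk.signs * walk.magnitudes)
        assert heights[-1] == walk.m - walk.n
        descent = maximum_descent(walk)
        assert 0 <= descent.k <= walk.n
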