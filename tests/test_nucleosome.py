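"""Fragment filtering, interval counting, density and the statistics stack."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from iesflow.annotations import IesAnnotation
from iesflow.nucleosome import (
    BoxSummary,
    FragmentRecord,
    box_summary,
    compare_groups,
    compute_density,
    count_over_intervals,
    downsample_libraries,
    filter_fragments,
    holm_bonferroni,
    mann_whitney_u,
)


def frag(start, end, scaffold="sc"):
    return FragmentRecord(scaffold=scaffold, start=start, end=end)


class TestFilter:
    @pytest.mark.parametrize(
        "length,kept",
        [(124, False), (125, True), (150, True), (175, True), (176, False)],
    )
    def test_inclusive_mononucleosome_window(self, length, kept):
        out = filter_fragments([frag(0, length)])
        assert (len(out) == 1) is kept

    def test_partition_conserves_fragments(self, rng):
        frags = [frag(0, int(l)) for l in rng.integers(60, 260, size=10)]
        kept = filter_fragments(frags)
        discarded = [f for f in frags if f not in kept]
        assert len(kept) + len(discarded) == 10
        assert all(125 <= f.length <= 175 for f in kept)
        assert all(f.length < 125 or f.length > 175 for f in discarded)

    def test_inverted_bounds_rejected(self):
        with pytest.raises(ValueError):
            filter_fragments([], min_len=200, max_len=100)


class TestDownsample:
    def _libs(self):
        return {
            "a": [frag(i, i + 150) for i in range(100)],
            "b": [frag(i, i + 150) for i in range(80)],
        }

    def test_equalized_to_minimum(self):
        out = downsample_libraries(self._libs(), seed=1)
        assert {k: len(v) for k, v in out.items()} == {"a": 80, "b": 80}

    def test_deterministic(self):
        o1 = downsample_libraries(self._libs(), seed=7)
        o2 = downsample_libraries(self._libs(), seed=7)
        assert o1 == o2

    def test_sampling_without_replacement(self):
        out = downsample_libraries(self._libs(), seed=3)
        assert len(set(out["a"])) == 80

    def test_empty_library_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            downsample_libraries({"a": [frag(0, 150)], "b": []})


ANNS = [
    IesAnnotation("ies1", "sc", 100, 200, 0),
    IesAnnotation("ies2", "sc", 200, 300, 0),
    IesAnnotation("ies3", "sc", 500, 560, 0),
]


class TestCounting:
    def test_fragment_inside_counts_in_both_modes(self):
        f = [frag(120, 180)]
        assert count_over_intervals(f, ANNS, "any-overlap")["ies1"] == 1
        assert count_over_intervals(f, ANNS, "midpoint")["ies1"] == 1

    def test_straddling_fragment_mode_semantics(self):
        f = [frag(150, 250)]
        any_counts = count_over_intervals(f, ANNS, "any-overlap")
        assert any_counts["ies1"] == 1 and any_counts["ies2"] == 1
        mid_counts = count_over_intervals(f, ANNS, "midpoint")
        assert sum(mid_counts.values()) == 1
        assert mid_counts["ies1"] == 1  # midpoint tie resolves to lower coordinate

    def test_scaffold_mismatch_rejected(self):
        with pytest.raises(ValueError, match="not in annotation"):
            count_over_intervals([frag(0, 150, scaffold="other")], ANNS)

    def test_matches_quadratic_oracle(self, rng):
        frags = [
            frag(int(s), int(s) + int(l))
            for s, l in zip(rng.integers(0, 600, 20), rng.integers(30, 200, 20))
        ]
        counts = count_over_intervals(frags, ANNS, "any-overlap")
        oracle = {a.ies_id: 0 for a in ANNS}
        for f in frags:
            for a in ANNS:
                if f.start < a.end_mic and f.end > a.start_mic:
                    oracle[a.ies_id] += 1
        assert counts == oracle
        mid = count_over_intervals(frags, ANNS, "midpoint")
        oracle_mid = {a.ies_id: 0 for a in ANNS}
        for f in frags:
            for a in ANNS:
                if a.start_mic <= f.midpoint < a.end_mic:
                    oracle_mid[a.ies_id] += 1
        assert mid == oracle_mid


class TestDensity:
    def test_balanced_counts_give_unit_density(self):
        (rec,) = compute_density({"a": 10}, {"a": 10}, 1000, 1000)
        assert rec.density == pytest.approx(1.0)

    def test_zero_input_is_undefined(self):
        (rec,) = compute_density({"a": 10}, {"a": 0}, 1000, 1000)
        assert rec.density is None and not rec.defined

    def test_scale_invariance(self, rng):
        m = {f"i{k}": int(v) for k, v in enumerate(rng.integers(1, 50, 20))}
        g = {f"i{k}": int(v) for k, v in enumerate(rng.integers(1, 50, 20))}
        d1 = compute_density(m, g, 1000, 2000)
        d3 = compute_density(
            {k: 3 * v for k, v in m.items()}, {k: 3 * v for k, v in g.items()}, 3000, 6000
        )
        for r1, r3 in zip(d1, d3):
            assert r1.density == pytest.approx(r3.density)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            compute_density({"a": -1}, {"a": 1}, 10, 10)


def exact_two_sided_p(x, y):
    """Enumeration oracle: permutation distribution of U over all pooled
    label assignments (valid without ties)."""
    pooled = sorted(x + y)
    nx = len(x)
    u_obs = sum(1 for xi in x for yi in y if xi > yi)
    us = []
    for combo in itertools.combinations(range(len(pooled)), nx):
        xs = [pooled[i] for i in combo]
        ys = [pooled[i] for i in range(len(pooled)) if i not in combo]
        us.append(sum(1 for xi in xs for yi in ys if xi > yi))
    us = np.array(us)
    mean = nx * (len(pooled) - nx) / 2
    dev = abs(u_obs - mean)
    return float(np.mean(np.abs(us - mean) >= dev - 1e-12))


class TestMannWhitney:
    def test_separated_samples_exact_p(self):
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)
        assert p == pytest.approx(exact_two_sided_p([1, 2, 3], [4, 5, 6]))

    @pytest.mark.parametrize(
        "x,y",
        [([1, 5, 9, 11], [2, 3, 4]), ([1, 2, 7], [3, 8, 9, 10]), ([4, 6], [1, 2, 3, 5])],
    )
    def test_small_samples_match_enumeration(self, x, y):
        _, p = mann_whitney_u(x, y)
        assert p == pytest.approx(exact_two_sided_p(x, y))

    def test_identical_samples_not_significant(self):
        _, p = mann_whitney_u([1, 2, 2, 3, 3, 3, 4] * 3, [1, 2, 2, 3, 3, 3, 4] * 3)
        assert p >= 0.99

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestHolm:
    def test_single_p_unchanged(self):
        assert holm_bonferroni([0.02]) == pytest.approx([0.02])

    def test_hand_computed_stepdown(self):
        assert holm_bonferroni([0.01, 0.04, 0.03]) == pytest.approx([0.03, 0.06, 0.06])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            holm_bonferroni([0.5, 1.5])

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=20))
    @settings(max_examples=200, deadline=None)
    def test_adjusted_dominates_raw(self, ps):
        adj = holm_bonferroni(ps)
        assert np.all(adj >= np.asarray(ps) - 1e-12)
        assert np.all(adj <= 1.0 + 1e-12)


class TestCompareGroups:
    def test_family_is_all_requested_pairs(self, rng):
        groups = {
            "a": rng.normal(0, 1, 50),
            "b": rng.normal(0, 1, 50),
            "c": rng.normal(2, 1, 50),
        }
        results = compare_groups(groups)
        assert len(results) == 3
        raw = [r.p_raw for r in results]
        assert [r.p_adj for r in results] == pytest.approx(holm_bonferroni(raw))
        for r in results:
            assert r.p_adj >= r.p_raw


class TestBoxSummary:
    def test_constant_vector(self):
        s = box_summary([2.0] * 10)
        assert s.median == s.q1 == s.q3 == 2.0
        assert s.outliers.size == 0

    def test_extreme_point_is_outlier(self):
        s = box_summary(list(range(1, 101)) + [1000])
        assert 1000 in s.outliers
        assert s.whisker_hi <= 100

    def test_conservation_of_points(self, rng):
        v = rng.normal(size=200)
        s = box_summary(v)
        inside = v[(v >= s.whisker_lo) & (v <= s.whisker_hi)]
        assert inside.size + s.outliers.size == v.size

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            box_summary([])
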