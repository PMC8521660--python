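import itertools

import numpy as np
import pytest
from scipy.stats import multivariate_hypergeom

from phyllocom.overlap import (
    OverlapCurve,
    ReadPool,
    incremental_overlap,
    pool_reads,
    reachable_asv_set,
    reachable_read_fraction,
    restrict_to_top_fraction,
)
from phyllocom.tables import CountTable


def pool(**counts):
    return ReadPool(tuple(counts), np.array(list(counts.values()), dtype=np.int64))


def enumerate_expected_overlap(pool_a, pool_b, depth) -> float:
    """Exhaustive oracle: expectation of |detA & detB| / |detA| over all
    without-replacement subsample outcomes of both pools."""
    ids = sorted(set(pool_a.asv_ids) | set(pool_b.asv_ids))
    a = pool_a.series().reindex(ids, fill_value=0).to_numpy()
    b = pool_b.series().reindex(ids, fill_value=0).to_numpy()

    def outcomes(colors, n):
        support = [range(0, c + 1) for c in colors]
        for combo in itertools.product(*support):
            if sum(combo) == n:
                yield (
                    np.array(combo),
                    multivariate_hypergeom.pmf(list(combo), colors.tolist(), n),
                )

    total = 0.0
    for xa, pa in outcomes(a, depth):
        det_a = xa > 0
        if det_a.sum() == 0:
            continue
        for xb, pb in outcomes(b, depth):
            shared = (det_a & (xb > 0)).sum()
            total += pa * pb * shared / det_a.sum()
    return total


class TestPoolReads:
    def test_group_sums(self):
        table = CountTable.from_arrays(
            ["s1", "s2"], ["t1", "t2", "t3"], np.array([[1, 2, 0], [0, 3, 0]])
        )
        p = pool_reads(table, ["s1", "s2"])
        assert p.pooled_counts.tolist() == [1, 5, 0]
        assert p.total_reads == 6

    def test_singleton_group_and_conservation(self, tiny_table):
        single = pool_reads(tiny_table, ["s2"])
        assert single.pooled_counts.tolist() == list(tiny_table.row("s2"))
        a = pool_reads(tiny_table, ["s1"])
        b = pool_reads(tiny_table, ["s2", "s3"])
        assert a.total_reads + b.total_reads == int(tiny_table.counts.sum())

    def test_unknown_sample_or_empty_group_rejected(self, tiny_table):
        with pytest.raises(KeyError):
            pool_reads(tiny_table, ["nope"])
        with pytest.raises(ValueError):
            pool_reads(tiny_table, [])


class TestIncrementalOverlap:
    def test_identical_pools_give_one_at_every_depth(self):
        p = pool(t1=300, t2=200, t3=100)
        curve = incremental_overlap(p, p, step=100, replicates=3, seed=0)
        assert all(v == 1.0 for v in curve.proportions)
        assert curve.depths[0] == 600 and curve.depths[-1] == 100

    def test_disjoint_pools_give_zero_at_every_depth(self):
        a = pool(t1=200, t2=100)
        b = pool(t3=150, t4=150)
        curve = incremental_overlap(a, b, step=100, replicates=3, seed=0)
        assert all(v == 0.0 for v in curve.proportions)

    def test_full_depth_draw_of_smaller_pool_is_exhaustive(self):
        # A detects only t1; at depth 100 the whole of B is drawn, so t1 is
        # necessarily detected in B as well
        a = pool(t1=100)
        b = pool(t1=50, t2=50)
        curve = incremental_overlap(a, b, step=100, replicates=5, seed=1)
        assert curve.proportions[0] == 1.0

    def test_expected_curve_matches_exhaustive_enumeration(self):
        a = pool(t1=4, t2=3)
        b = pool(t1=2, t2=2, t3=3)
        reps = 3000
        curve = incremental_overlap(a, b, step=2, replicates=reps, seed=5)
        for depth, mean, sd in zip(curve.depths, curve.proportions, curve.sds):
            expected = enumerate_expected_overlap(a, b, depth)
            se = sd / np.sqrt(reps)
            assert abs(mean - expected) <= max(3 * se, 1e-9), (
                f"depth {depth}: {mean} vs exact {expected}"
            )

    def test_step_larger_than_pool_rejected(self):
        with pytest.raises(ValueError, match="step"):
            incremental_overlap(pool(t1=50), pool(t1=50), step=100)

    def test_enlarging_pool_b_support_never_hurts_overlap(self):
        # monotone-under-nesting, checked in expectation by simulation
        a = pool(t1=200, t2=200, t3=200)
        b_small = pool(t1=300, t4=300)
        b_big = pool(t1=300, t2=300, t4=300)
        c_small = incremental_overlap(a, b_small, step=100, replicates=40, seed=2)
        c_big = incremental_overlap(a, b_big, step=100, replicates=40, seed=2)
        assert c_big.converged() >= c_small.converged() - 0.02


class TestTopFraction:
    def test_rank_and_ceil_by_hand(self):
        p = pool(t1=50, t2=30, t3=15, t4=5)
        top, share = restrict_to_top_fraction(p, 0.5)
        assert top.detected() == {"t1", "t2"}
        assert share == pytest.approx(0.8)

    def test_fraction_one_is_identity(self):
        p = pool(t1=5, t2=3)
        top, share = restrict_to_top_fraction(p, 1.0)
        assert top.pooled_counts.tolist() == [5, 3] and share == 1.0

    def test_tie_at_cutoff_keeps_smaller_id(self):
        p = pool(t1=50, t2=20, t3=20, t4=5)
        top, _ = restrict_to_top_fraction(p, 0.5)
        assert top.detected() == {"t1", "t2"}

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            restrict_to_top_fraction(pool(t1=0), 0.5)


class TestReachable:
    def test_threshold_defines_membership(self):
        table = CountTable.from_arrays(
            ["g1", "g2", "g3"],
            ["a", "b"],
            np.array([[0, 2], [4, 2], [0, 2]]),
        )
        assert reachable_asv_set(table, 3) == {"a"}
        assert reachable_asv_set(table, 1) == {"a", "b"}

    def test_empty_table_rejected(self):
        table = CountTable.from_arrays([], ["a"], np.zeros((0, 1), int))
        with pytest.raises(ValueError, match="empty"):
            reachable_asv_set(table, 3)

    def test_read_fraction_cases(self):
        row = {"a": 542, "b": 542}
        assert reachable_read_fraction(row, {"a"}) == pytest.approx(0.5)
        assert reachable_read_fraction(row, set()) == 0.0
        assert reachable_read_fraction(row, {"a", "b", "c"}) == 1.0
        with pytest.raises(ValueError):
            reachable_read_fraction({"a": 0}, {"a"})


class TestCurveValidation:
    def test_depths_must_descend_by_step(self):
        with pytest.raises(ValueError, match="descend"):
            OverlapCurve((300, 100), (0.5, 0.5), (0, 0), step=100, replicates_per_depth=1)

    def test_converged_is_mean_over_deepest_window(self):
        curve = OverlapCurve(
            (500, 400, 300, 200, 100),
            (0.5, 0.4, 0.3, 0.2, 0.1),
            (0,) * 5,
            step=100,
            replicates_per_depth=1,
        )
        assert curve.converged(2) == pytest.approx(0.45)
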