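import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from phyllocom.clustering import clades, linkage_complete
from phyllocom.drivers import (
    identify_drivers,
    random_removal_null,
    removal_test,
    screen_iteration,
    single_feature_clades,
    single_feature_distance_matrix,
    single_taxon_cluster_test,
)
from phyllocom.preprocess import RarefactionPlan
from phyllocom.tables import CountTable


class TestSingleTaxonTest:
    def test_flower_exclusive_taxon_reproduces_the_clade(self):
        profile = pd.Series(
            {"f1": 10.0, "f2": 12.0, "f3": 11.0, "r1": 0.0, "r2": 0.0, "r3": 0.0}
        )
        assert single_taxon_cluster_test(profile, {"f1", "f2", "f3"})

    def test_constant_positive_taxon_fails_for_non_prefix_target(self):
        # all distances zero: the lexicographic caterpillar only yields
        # prefixes, and the flower samples are not one
        profile = pd.Series({"a1": 3.0, "f1": 3.0, "f2": 3.0, "z1": 3.0})
        assert not single_taxon_cluster_test(profile, {"f1", "f2"})

    def test_detected_in_one_flower_only_fails(self):
        profile = pd.Series({"f1": 9.0, "f2": 0.0, "f3": 0.0, "r1": 0.0})
        assert not single_taxon_cluster_test(profile, {"f1", "f2", "f3"})

    def test_absent_taxon_returns_false_with_warning(self, caplog):
        profile = pd.Series({"f1": 0.0, "f2": 0.0, "r1": 0.0})
        with caplog.at_level("WARNING"):
            assert not single_taxon_cluster_test(profile, {"f1", "f2"})
        assert "absent" in caplog.text

    def test_max_extra_relaxation_admits_near_matches(self):
        profile = pd.Series(
            {"f1": 10.0, "f2": 11.0, "x1": 9.5, "r1": 0.0, "r2": 0.0}
        )
        target = {"f1", "f2"}
        assert not single_taxon_cluster_test(profile, target, max_extra=0)
        assert single_taxon_cluster_test(profile, target, max_extra=1)

    def test_invalid_target_sets_rejected(self):
        profile = pd.Series({"a": 1.0, "b": 2.0})
        with pytest.raises(ValueError):
            single_taxon_cluster_test(profile, {"a"})
        with pytest.raises(ValueError):
            single_taxon_cluster_test(profile, {"a", "b"})


class TestClosedFormCladeSet:
    @given(st.data())
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_matches_generic_linkage_on_random_profiles(self, data):
        n = data.draw(st.integers(2, 8))
        values = data.draw(
            st.lists(st.integers(0, 4), min_size=n, max_size=n)
        )
        ids = [f"s{chr(97 + i)}" for i in range(n)]
        fast = single_feature_clades(np.array(values, float), ids)
        tree = linkage_complete(
            single_feature_distance_matrix(np.array(values, float), ids)
        )
        assert fast == clades(tree)

    def test_vectorised_screen_equals_per_taxon_closed_form(self):
        rng = np.random.default_rng(12)
        for _ in range(40):
            n, p = int(rng.integers(4, 9)), int(rng.integers(2, 12))
            counts = rng.integers(0, 5, size=(n, p))
            ids = [f"s{chr(97 + i)}" for i in range(n)]
            table = CountTable.from_arrays(ids, [f"a{j}" for j in range(p)], counts)
            size = int(rng.integers(2, n))
            target = set(rng.choice(ids, size=size, replace=False))
            got = screen_iteration(table, target)
            want = np.array(
                [
                    counts[:, j].max() > 0
                    and frozenset(target)
                    in single_feature_clades(counts[:, j].astype(float), ids)
                    for j in range(p)
                ]
            )
            assert (got == want).all()


def planted_table(n_flowers=4, n_others=8, n_drivers=3, n_noise=20, seed=0):
    """Flowers carry high counts of driver ASVs; noise ASVs are unstructured."""
    rng = np.random.default_rng(seed)
    n = n_flowers + n_others
    flowers = [f"flw{i}" for i in range(n_flowers)]
    others = [f"oth{i}" for i in range(n_others)]
    ids = flowers + others
    counts = rng.integers(0, 6, size=(n, n_noise))
    drivers = rng.integers(400, 600, size=(n_flowers, n_drivers))
    driver_block = np.vstack(
        [drivers, rng.integers(0, 3, size=(n_others, n_drivers))]
    )
    # background block keeps totals deep; its within-sample spread is wide
    # (log-uniform x8) so compositional dilution of the flower samples does
    # not by itself separate the groups on any single background taxon
    bg = np.exp(rng.uniform(np.log(50), np.log(400), size=(n, 10))).astype(int)
    table = CountTable.from_arrays(
        ids,
        [f"drv{k}" for k in range(n_drivers)]
        + [f"nse{k}" for k in range(n_noise)]
        + [f"bg{k}" for k in range(10)],
        np.hstack([driver_block, counts, bg]),
    )
    return table, flowers, [f"drv{k}" for k in range(n_drivers)]


class TestIdentifyDrivers:
    def test_planted_drivers_recovered_exactly(self):
        table, flowers, drivers = planted_table()
        plan = RarefactionPlan(depth=900, n_iterations=10, base_seed=4)
        result = identify_drivers(table, flowers, plan)
        assert set(result.candidates) == set(drivers)
        assert result.n_iterations == 10
        assert all(result.per_asv_recovery[d] == 10 for d in drivers)

    def test_all_iterations_rule_is_strict(self):
        table, flowers, drivers = planted_table()
        plan = RarefactionPlan(depth=900, n_iterations=8, base_seed=4)
        result = identify_drivers(table, flowers, plan)
        for asv, rec in result.per_asv_recovery.items():
            assert (asv in result.candidates) == (rec == 8)

    def test_candidates_shrink_with_more_iterations(self):
        # same seed stream: recovery can only fail more often with more
        # iterations, so candidate sets are nested
        table, flowers, _ = planted_table(seed=3)
        few = identify_drivers(
            table, flowers, RarefactionPlan(depth=900, n_iterations=3, base_seed=9)
        )
        many = identify_drivers(
            table, flowers, RarefactionPlan(depth=900, n_iterations=12, base_seed=9)
        )
        assert set(many.candidates) <= set(few.candidates)

    def test_single_iteration_equals_reference_screen(self):
        table, flowers, _ = planted_table(seed=5)
        plan = RarefactionPlan(depth=900, n_iterations=1, base_seed=2)
        result = identify_drivers(table, flowers, plan)
        assert set(result.candidates) == {
            a for a, r in result.per_asv_recovery.items() if r == 1
        }


class TestRemovalTests:
    def test_removing_drivers_breaks_the_clade(self):
        table, flowers, drivers = planted_table()
        plan = RarefactionPlan(depth=900, n_iterations=10, base_seed=1)
        breaks, frac = removal_test(table, drivers, flowers, plan)
        assert breaks and frac <= 0.5

    def test_removing_irrelevant_taxa_keeps_the_clade(self):
        table, flowers, _ = planted_table()
        plan = RarefactionPlan(depth=900, n_iterations=10, base_seed=1)
        breaks, frac = removal_test(
            table, ["nse0", "nse1", "nse2"], flowers, plan
        )
        assert not breaks and frac > 0.5

    def test_leaving_one_strong_driver_keeps_the_clade(self):
        table, flowers, drivers = planted_table()
        plan = RarefactionPlan(depth=900, n_iterations=10, base_seed=1)
        breaks, frac = removal_test(table, drivers[:-1], flowers, plan)
        assert not breaks and frac > 0.5

    def test_random_removal_null_retains_clade(self):
        table, flowers, drivers = planted_table()
        plan = RarefactionPlan(depth=900, n_iterations=10, base_seed=1)
        frac = random_removal_null(
            table,
            k=len(drivers),
            excluded=drivers,
            n_draws=20,
            target_set=flowers,
            plan=plan,
            seed=8,
        )
        assert frac >= 0.9

    def test_null_guards(self):
        table, flowers, drivers = planted_table()
        plan = RarefactionPlan(depth=900, n_iterations=2, base_seed=1)
        with pytest.raises(ValueError, match="k must be"):
            random_removal_null(
                table, 0, drivers, 5, flowers, plan
            )
        with pytest.raises(ValueError, match="non-empty"):
            removal_test(table, [], flowers, plan)
        with pytest.raises(ValueError, match="every ASV"):
            removal_test(table, list(table.asv_ids), flowers, plan)
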