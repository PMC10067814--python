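"""Attribution: per-bin comparison, neighbor filter, Monte-Carlo region
test and environment sharing."""

import itertools

import numpy as np
import pandas as pd
import pytest

from chancexpr import stats as cstats
from chancexpr.attribution import (
    attribution_by_bin,
    group_difference_check,
    neighbor_filter,
    region_chance_test,
    shared_fraction,
)


def bin_series(values_by_label):
    order = cstats.bin_order()
    return pd.Series([values_by_label.get(b, 0.0) for b in order], index=order)


class TestAttributionByBin:
    def test_barcodes_cover_windows_everywhere(self):
        w = bin_series({"0.1-0.2": 0.05, "0.2-0.3": 0.02, cstats.NONSIG_BIN: 0.93})
        b = bin_series({"0.1-0.2": 0.08, "0.2-0.3": 0.05, cstats.NONSIG_BIN: 0.87})
        _, total = attribution_by_bin(w, b)
        assert total == 0.0

    def test_excess_window_mass_is_unattributable(self):
        w = bin_series({"0.5-0.6": 0.04, cstats.NONSIG_BIN: 0.96})
        b = bin_series({"0.5-0.6": 0.01, cstats.NONSIG_BIN: 0.99})
        df, total = attribution_by_bin(w, b)
        assert total == pytest.approx(0.03)
        row = df[df["bin"] == "0.5-0.6"].iloc[0]
        assert row["attributable_fraction"] == pytest.approx(0.25)

    def test_nonsig_bin_always_attributable(self):
        w = bin_series({cstats.NONSIG_BIN: 1.0})
        b = bin_series({"0.1-0.2": 1.0})
        df, total = attribution_by_bin(w, b)
        assert total == 0.0
        assert df[df["bin"] == cstats.NONSIG_BIN]["attributable_fraction"].iloc[0] == 1.0

    def test_mismatched_grids_rejected(self):
        w = bin_series({})
        b = w.iloc[:-1]
        with pytest.raises(ValueError, match="different cutoff grids"):
            attribution_by_bin(w, b)

    def test_same_distribution_gives_near_zero(self, rng):
        # both populations draw REL estimate vectors from one process
        def batch(n, k, seed):
            r = np.random.default_rng(seed)
            true = np.exp(r.normal(-2.0, 1.0, size=n))
            return true[:, None] * (1 + r.normal(0, 0.1, size=(n, k)))

        gw = cstats.cutoff_grid_tests(batch(3000, 3, 1))
        gb = cstats.cutoff_grid_tests(batch(3000, 8, 2))
        _, total = attribution_by_bin(cstats.bin_fractions(gw), cstats.bin_fractions(gb))
        assert total <= 0.05


class TestNeighborFilter:
    def test_exchangeable_input_stops_immediately(self, rng):
        pool = rng.lognormal(0, 1, 2000)
        sel = rng.choice(pool, size=400, replace=False)
        state = neighbor_filter(sel, pool, n_resamples=300, seed=1)
        assert state.removed_groups <= 1
        assert state.trace["frac_me2_ge_me1"].iloc[-1] > 0.05
        assert len(state.retained_index) >= 400 - 400 // 50 - 1

    def test_planted_readthrough_removed_before_stopping(self, rng):
        pool = rng.lognormal(0, 1, 3000)
        background = rng.choice(pool, size=280, replace=False)
        planted = np.quantile(pool, 0.999) * (1 + rng.random(120))
        sel = np.concatenate([background, planted])
        state = neighbor_filter(sel, pool, n_resamples=300, seed=2)
        assert state.removed_groups >= 1
        assert state.retained_index.size > 0
        # the retained set's neighbor level is no longer unusually high
        assert state.trace["frac_me2_ge_me1"].iloc[-1] > 0.05
        # ME1 can only decrease as the top groups are stripped
        assert (np.diff(state.trace["me1"]) <= 1e-12).all()

    def test_groups_of_size_one_when_input_small(self, rng):
        pool = rng.lognormal(0, 1, 100)
        sel = pool[:10]
        state = neighbor_filter(sel, pool, n_groups=50, n_resamples=100, seed=3)
        assert state.trace["n_remaining"].iloc[0] == 10

    def test_resampled_fraction_matches_exhaustive_enumeration(self, rng):
        # tiny pool: compare the Monte-Carlo fraction(ME2 >= ME1) with
        # enumeration over all same-size subsets
        pool = np.round(rng.lognormal(0, 1, 10), 3)
        sel = rng.choice(pool, size=4, replace=False)
        me1 = np.median(sel)
        k = len(sel)
        exact = np.mean(
            [np.median(c) >= me1 for c in itertools.combinations(pool, k)]
        )
        state = neighbor_filter(sel, pool, n_groups=k, n_resamples=4000, seed=4)
        got = state.trace["frac_me2_ge_me1"].iloc[0]
        se = np.sqrt(exact * (1 - exact) / 4000)
        assert abs(got - exact) <= 3 * se + 1e-9

    def test_empty_selection_rejected(self):
        with pytest.raises(ValueError, match="no windows"):
            neighbor_filter([], [1.0, 2.0])


def rel_frame(rels_by_unit):
    rows = [
        (rid, direction, rel)
        for (rid, direction), rels in rels_by_unit.items()
        for rel in rels
    ]
    return pd.DataFrame(rows, columns=["region_id", "direction", "rel"])


class TestRegionChanceTest:
    def test_observation_above_library_maximum(self):
        res = region_chance_test(
            rel_frame({("r", "+"): [2.0]}), {"r": 2}, [0.1, 0.5], n_reps=1000, seed=0
        )
        assert res["p"].iloc[0] == 0.0

    def test_observation_below_library_minimum(self):
        res = region_chance_test(
            rel_frame({("r", "+"): [0.01]}), {"r": 2}, [0.1, 0.5], n_reps=1000, seed=0
        )
        assert res["p"].iloc[0] == 1.0

    def test_two_value_library_matches_exact_probability(self):
        # library {0.1, 0.5}, N=2, E_obs=0.3: P(max > 0.3) = 1 - 0.5^2 = 0.75
        n_reps = 10_000
        res = region_chance_test(
            rel_frame({("r", "+"): [0.3]}), {"r": 2}, [0.1, 0.5],
            n_reps=n_reps, seed=5,
        )
        se = np.sqrt(0.75 * 0.25 / n_reps)
        assert abs(res["p"].iloc[0] - 0.75) <= 3 * se

    def test_matches_enumeration_oracle_small_libraries(self, rng):
        n_reps = 10_000
        for trial in range(8):
            lib = np.round(rng.choice([0.05, 0.2, 0.4, 0.7, 1.1], size=5, replace=True), 3)
            N = int(rng.integers(1, 4))
            e_obs = float(rng.choice([0.1, 0.3, 0.6, 0.9]))
            # exact: P(all N draws <= e_obs) via the empirical CDF
            exact = 1.0 - np.mean(lib <= e_obs) ** N
            res = region_chance_test(
                rel_frame({("r", "+"): [e_obs]}), {"r": N}, lib,
                n_reps=n_reps, seed=100 + trial,
            )
            se = np.sqrt(max(exact * (1 - exact), 1e-12) / n_reps)
            assert abs(res["p"].iloc[0] - exact) <= 3 * se + 1e-9

    def test_p95_summary_supported(self):
        rels = list(np.linspace(0, 1, 21))
        res = region_chance_test(
            rel_frame({("r", "+"): rels}), {"r": 1}, [0.5], summary="p95",
            n_reps=100, seed=0,
        )
        assert res["e_obs"].iloc[0] == pytest.approx(np.percentile(rels, 95))

    def test_empty_library_rejected(self):
        with pytest.raises(ValueError, match="empty promoter"):
            region_chance_test(rel_frame({("r", "+"): [0.1]}), {"r": 1}, [])

    def test_units_are_region_by_direction(self):
        res = region_chance_test(
            rel_frame({("r", "+"): [0.1], ("r", "-"): [0.2]}),
            {"r": 1}, [0.05, 0.5], n_reps=500, seed=1,
        )
        assert len(res) == 2 and set(res["direction"]) == {"+", "-"}


def exceed_grid(index, exceed_by_cutoff):
    df = pd.DataFrame(index=index)
    for c in cstats.DEFAULT_CUTOFFS:
        df[f"exceeds_{c:.1f}"] = [i in exceed_by_cutoff.get(c, set()) for i in index]
    return df


class TestSharedFraction:
    def test_superset_gives_full_sharing(self):
        idx = list("abcd")
        ga = exceed_grid(idx, {0.1: {"a", "b"}})
        gb = exceed_grid(idx, {0.1: {"a", "b", "c"}})
        sf = shared_fraction(ga, gb)
        assert sf.loc[sf["cutoff"] == 0.1, "shared_a_to_b"].iloc[0] == 1.0

    def test_disjoint_sets_share_nothing(self):
        idx = list("abcd")
        ga = exceed_grid(idx, {0.1: {"a"}})
        gb = exceed_grid(idx, {0.1: {"b"}})
        sf = shared_fraction(ga, gb)
        assert sf.loc[sf["cutoff"] == 0.1, "shared_a_to_b"].iloc[0] == 0.0

    def test_empty_denominator_is_undefined(self):
        idx = list("ab")
        sf = shared_fraction(exceed_grid(idx, {}), exceed_grid(idx, {}))
        assert sf["shared_a_to_b"].isna().all()

    def test_different_universes_rejected(self):
        with pytest.raises(ValueError, match="universes"):
            shared_fraction(exceed_grid(list("ab"), {}), exceed_grid(list("ac"), {}))


class TestGroupDifference:
    def test_identical_groups_not_significant(self):
        res = group_difference_check([1, 2, 3], [1, 2, 3])
        assert res["p"] >= 0.5

    def test_smaller_first_group_large_p(self):
        # testing first > second with {1,2,3} vs {4,5,6}
        res = group_difference_check([1, 2, 3], [4, 5, 6])
        assert res["p"] >= 19 / 20

    def test_planted_difference_detected(self, rng):
        hi = rng.lognormal(1.0, 0.3, 40)
        lo = rng.lognormal(0.0, 0.3, 40)
        assert group_difference_check(hi, lo)["p"] < 0.01

    def test_empty_group_reported(self):
        res = group_difference_check([], [1.0])
        assert res["p"] is None and res["reason"] == "empty group"
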