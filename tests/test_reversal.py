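from itertools import product

import numpy as np
import pandas as pd
import pytest

import revaging as rv
from revaging.preprocess import split_periods
from revaging.reversal import (
    PATTERNS,
    PermutationResult,
    TrendSignEngine,
    classify_patterns,
    consistent_direction_genes,
    consistent_pattern_genes,
    pattern_counts,
    permutation_test_consistency,
    permute_ages,
    random_geneset_consistency_test,
)
from revaging.trajectories import age_expression_trends


def _table(directions, rhos=None):
    genes = pd.Index([f"g{i}" for i in range(len(directions))])
    if rhos is None:
        rhos = [{"up": 0.5, "down": -0.5, "flat": 0.0}[d] for d in directions]
    return pd.DataFrame({"rho": rhos, "direction": directions}, index=genes)


class TestClassification:
    def test_sign_pair_enumeration(self):
        dev = _table(["up", "down", "up", "down", "flat", "up"])
        aging = _table(["down", "up", "up", "down", "up", "flat"])
        patterns = classify_patterns(dev, aging)
        assert list(patterns) == [
            "up-down", "down-up", "up-up", "down-down", "excluded", "excluded",
        ]

    def test_counts_partition_the_gene_universe(self, small_study):
        datasets, _ = small_study
        engine = TrendSignEngine(datasets)
        table = engine.reversal_table()
        for name in table.columns:
            counts = pattern_counts(table[name])
            assert counts.sum() == len(table)

    def test_engine_signs_match_trend_tables(self, small_study):
        datasets, _ = small_study
        engine = TrendSignEngine(datasets)
        table = engine.reversal_table()
        ds = datasets[0]
        dev, aging = split_periods(ds)
        expected = classify_patterns(
            age_expression_trends(dev), age_expression_trends(aging)
        )
        assert (table[ds.name] == expected).all()


class TestConsistency:
    def test_single_table_returns_all_of_direction(self):
        t = _table(["up", "up", "down", "flat"])
        assert list(consistent_direction_genes([t], "up")) == ["g0", "g1"]

    def test_unanimity_required(self):
        t1 = _table(["up", "up", "up"])
        t2 = _table(["up", "down", "up"])
        assert list(consistent_direction_genes([t1, t2], "up")) == ["g0", "g2"]

    def test_pattern_consistency_and_exclusion(self):
        rt = pd.DataFrame(
            {"d1": ["up-down", "up-down", "up-up"],
             "d2": ["up-down", "excluded", "up-up"]},
            index=["g0", "g1", "g2"],
        )
        assert list(consistent_pattern_genes(rt, "up-down")) == ["g0"]
        assert list(consistent_pattern_genes(rt, "up-up")) == ["g2"]

    def test_matches_exhaustive_enumeration_over_sign_assignments(self):
        # 2 datasets x 10 genes: every per-dataset direction combination
        rng = np.random.default_rng(0)
        choices = ["up", "down", "flat"]
        for _ in range(20):
            d1 = _table(rng.choice(choices, 10))
            d2 = _table(rng.choice(choices, 10))
            got = set(consistent_direction_genes([d1, d2], "up"))
            brute = {
                g for g in d1.index
                if d1.loc[g, "direction"] == "up" and d2.loc[g, "direction"] == "up"
            }
            assert got == brute


class TestPermuteAges:
    def _study(self):
        cfg = rv.SimulationConfig(
            n_sources=2, regions_per_source=2, n_individuals_dev=5,
            n_individuals_aging=5, n_genes=20, seed=3,
        )
        return rv.generate_age_series(cfg)[0]

    def test_same_individual_same_age_across_regions(self):
        datasets = self._study()
        permuted = permute_ages(datasets, seed=1)
        a, b = permuted[0], permuted[1]  # two regions of source1
        merged = a.meta.set_index("individual_id")["age_days"]
        for ind, age in b.meta.set_index("individual_id")["age_days"].items():
            assert merged[ind] == age

    def test_age_multiset_preserved_within_source_and_period(self):
        datasets = self._study()
        permuted = permute_ages(datasets, seed=2)
        for before, after in zip(datasets, permuted):
            cut = 20 * 365.25
            for mask in (before.ages_days < cut, before.ages_days >= cut):
                assert sorted(before.ages_days[mask]) == sorted(
                    after.ages_days[mask.to_numpy()]
                )

    def test_period_membership_is_preserved(self):
        datasets = self._study()
        permuted = permute_ages(datasets, seed=3)
        cut = 20 * 365.25
        for before, after in zip(datasets, permuted):
            np.testing.assert_array_equal(
                before.ages_days.to_numpy() < cut, after.ages_days.to_numpy() < cut
            )

    def test_expression_untouched(self):
        datasets = self._study()
        permuted = permute_ages(datasets, seed=4)
        for before, after in zip(datasets, permuted):
            pd.testing.assert_frame_equal(before.expr, after.expr)

    def test_inconsistent_individual_ages_rejected(self):
        datasets = self._study()
        bad = datasets[1].meta.copy()
        bad["age_days"] = bad["age_days"] + 1.0
        broken = rv.AgeSeriesDataset(
            expr=datasets[1].expr, meta=bad, name=datasets[1].name
        )
        with pytest.raises(ValueError, match="inconsistent ages"):
            permute_ages([datasets[0], broken], seed=0)


class TestPermutationTest:
    def test_p_formula_and_reproducibility(self, null_study):
        datasets, _ = null_study
        r1 = permutation_test_consistency(datasets, "up-down", 50, seed=5)
        r2 = permutation_test_consistency(datasets, "up-down", 50, seed=5)
        assert r1.p == r2.p
        np.testing.assert_array_equal(r1.null, r2.null)
        assert r1.p >= 1 / 51
        assert r1.p == (1 + np.sum(r1.null >= r1.observed)) / 51

    def test_constant_statistic_gives_p_one(self, null_study):
        datasets, _ = null_study
        res = permutation_test_consistency(
            datasets, lambda dev, aging: 1.0, 20, seed=0
        )
        assert res.p == 1.0
        assert res.fdr == 1.0

    def test_planted_updown_signal_is_significant(self, small_study):
        datasets, truth = small_study
        res = permutation_test_consistency(datasets, "up-down", 99, seed=6)
        assert res.p <= 0.05
        assert res.observed > res.expected

    def test_planted_genes_recovered_in_consistent_set(self, small_study):
        datasets, truth = small_study
        engine = TrendSignEngine(datasets)
        got = set(consistent_pattern_genes(engine.reversal_table(), "up-down"))
        planted = set(truth.genes_with_pattern("up-down"))
        assert len(got & planted) / len(planted) >= 0.8

    def test_null_consistency_count_matches_binomial_oracle(self):
        # k independent datasets: expected count = n_genes * 2 * (1/2)^k
        for k in (2, 3, 4):
            cfg = rv.SimulationConfig(
                n_sources=k, regions_per_source=1, n_individuals_dev=10,
                n_individuals_aging=10, n_genes=2000,
                fraction_updown=0, fraction_downup=0,
                fraction_monotonic_up=0, fraction_monotonic_down=0,
                seed=100 + k,
            )
            datasets, _ = rv.generate_age_series(cfg)
            tables = []
            for ds in datasets:
                dev, _aging = split_periods(ds)
                tables.append(age_expression_trends(dev))
            count = sum(
                len(consistent_direction_genes(tables, d)) for d in ("up", "down")
            )
            expect = cfg.n_genes * 2 * 0.5**k
            se = np.sqrt(cfg.n_genes * 2 * 0.5**k * (1 - 2 * 0.5**k))
            assert abs(count - expect) <= 3 * se

    def test_null_reversal_fraction_is_half(self, null_study):
        datasets, _ = null_study
        engine = TrendSignEngine(datasets)
        col = engine.reversal_table().iloc[:, 0]
        classifiable = col[col != "excluded"]
        frac = classifiable.isin(["up-down", "down-up"]).mean()
        se = 0.5 / np.sqrt(len(classifiable))
        assert abs(frac - 0.5) <= 3 * se


class TestRandomGenesetTest:
    def test_whole_universe_gives_p_one(self):
        t = _table(["up", "up", "down", "down"])
        res = random_geneset_consistency_test(t.index, t, "up", n_draws=50, seed=0)
        assert res.p == 1.0

    def test_all_up_set_in_strong_simulation_is_significant(self, small_study):
        datasets, truth = small_study
        dev, _ = split_periods(datasets[0])
        tt = age_expression_trends(dev)
        planted = truth.genes_with_pattern("up-down")
        res = random_geneset_consistency_test(planted, tt, "up",
                                              n_draws=500, seed=1)
        assert res.p <= 2 / 501

    def test_singleton_null_proportion_is_bernoulli(self):
        t = _table(["up"] * 50 + ["down"] * 50)
        res = random_geneset_consistency_test(
            ["g0"], t, "up", n_draws=2000, seed=2, as_proportion=True
        )
        assert res.expected == pytest.approx(0.5, abs=0.05)

    def test_empty_intersection_is_an_error(self):
        t = _table(["up", "down"])
        with pytest.raises(ValueError):
            random_geneset_consistency_test(["zz"], t, "up", n_draws=10)


class TestPermutationResult:
    def test_summary_and_randomized_p_bounds(self):
        res = PermutationResult(3.0, np.array([1.0, 2.0, 3.0, 4.0]), 4, seed=9)
        assert res.p == (1 + 2) / 5
        assert res.expected == 2.5
        s = res.summary()
        assert s["observed"] == 3.0 and s["n_permutations"] == 4
        rp = res.randomized_p(0)
        assert 1 / 5 < rp < 3 / 5  # between the discrete bounds given one tie
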