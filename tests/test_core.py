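"""Ranking, consistency scoring, the binomial model, block expansion, null."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from pairdiff import (
    AveragedPair,
    binomial_reproducibility_p,
    build_pair,
    consistency_score,
    pd_identify,
    permutation_null_experiment,
    rank_by_abs_difference,
    simulate_datasets,
    SimulationConfig,
    topn_consistency_curve,
)
from pairdiff.core import DEFAULT_CURVE_DEPTHS, permutation_null_from_pairs
from conftest import make_dataset


def pair_from_d(d: dict, n1=2, n2=2, label="pair") -> AveragedPair:
    """Build an AveragedPair with the requested signed differences."""
    idx = pd.Index(list(d), name="gene_id")
    base = pd.Series(1000.0, index=idx)
    return AveragedPair(base, base + pd.Series(d), n1, n2, label)


class TestRanking:
    def test_descending_absolute_difference(self):
        rp = rank_by_abs_difference(pair_from_d({"g1": 5.0, "g2": -7.0, "g3": 1.0}))
        assert list(rp.order) == ["g2", "g1", "g3"]
        assert rp.signs.tolist() == [-1, 1, 1]

    def test_ties_break_lexicographically(self):
        rp = rank_by_abs_difference(pair_from_d({"b": -3.0, "a": 3.0}))
        assert list(rp.order) == ["a", "b"]

    def test_zero_difference_genes_are_excluded(self):
        rp = rank_by_abs_difference(pair_from_d({"a": 2.0, "z": 0.0}))
        assert list(rp.order) == ["a"]

    def test_matches_independent_sort_oracle(self, rng):
        genes = [f"g{i:04d}" for i in range(1000)]
        d = dict(zip(genes, rng.normal(0, 50, 1000)))
        rp = rank_by_abs_difference(pair_from_d(d))
        oracle = sorted(genes, key=lambda g: (-abs(d[g]), g))
        assert list(rp.order) == oracle


class TestConsistencyScore:
    def test_published_worked_example(self):
        # 4744 shared genes of which 4736 agree in direction -> 99.83%
        n = 4744
        a = pd.Series(1, index=pd.Index([f"g{i}" for i in range(n)]))
        b = a.copy()
        b.iloc[: n - 4736] = -1
        r = consistency_score(a, b)
        assert (r.k, r.s) == (4744, 4736)
        assert round(100 * r.score, 2) == 99.83
        assert r.p < 2.2e-16

    def test_identical_and_flipped_lists(self):
        a = pd.Series([1, -1, 1], index=pd.Index(["x", "y", "z"]))
        assert consistency_score(a, a).score == 1.0
        assert consistency_score(a, -a).score == 0.0

    def test_symmetry_in_arguments(self, rng):
        a = pd.Series(rng.choice([-1, 1], 50), index=pd.Index([f"g{i}" for i in range(50)]))
        b = pd.Series(rng.choice([-1, 1], 40), index=pd.Index([f"g{i}" for i in range(10, 50)]))
        rab, rba = consistency_score(a, b), consistency_score(b, a)
        assert (rab.k, rab.s, rab.score, rab.p) == (rba.k, rba.s, rba.score, rba.p)

    def test_empty_overlap_flagged_with_p_one(self):
        a = pd.Series([1], index=pd.Index(["x"]))
        b = pd.Series([1], index=pd.Index(["y"]))
        r = consistency_score(a, b)
        assert r.empty and r.p == 1.0 and math.isnan(r.score)

    def test_duplicated_gene_rejected(self):
        a = pd.Series([1, 1], index=pd.Index(["x", "x"]))
        with pytest.raises(ValueError, match="duplicated"):
            consistency_score(a, pd.Series([1], index=pd.Index(["x"])))


class TestBinomialTail:
    def test_zero_successes_gives_one(self):
        assert binomial_reproducibility_p(0, 17) == 1.0

    def test_single_outcome_tail(self):
        assert binomial_reproducibility_p(10, 10) == pytest.approx(2**-10, rel=1e-12)

    def test_eight_of_ten(self):
        assert binomial_reproducibility_p(8, 10) == pytest.approx(56 / 1024, rel=1e-12)

    def test_far_tail_is_stable_and_tiny(self):
        p = binomial_reproducibility_p(918, 1000)
        assert 0.0 < p < 2.2e-16

    @given(k=st.integers(1, 20), data=st.data())
    def test_agrees_with_exhaustive_summation(self, k, data):
        s = data.draw(st.integers(0, k))
        expected = sum(math.comb(k, i) for i in range(s, k + 1)) / 2**k
        assert binomial_reproducibility_p(s, k) == pytest.approx(expected, rel=1e-12)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            binomial_reproducibility_p(5, 4)
        with pytest.raises(ValueError):
            binomial_reproducibility_p(1, 0)
        with pytest.raises(ValueError):
            binomial_reproducibility_p(1, 2, p_e=1.0)


class TestTopNCurve:
    def test_identical_pairs_score_one_at_every_depth(self, rng):
        d = dict(zip([f"g{i:05d}" for i in range(6000)], rng.normal(0, 100, 6000)))
        rp = rank_by_abs_difference(pair_from_d(d))
        results = topn_consistency_curve(rp, rp)
        assert [r.n for r in results] == list(DEFAULT_CURVE_DEPTHS)
        assert all(r.score == 1.0 for r in results)

    def test_depth_beyond_universe_is_an_error(self, rng):
        d = dict(zip(["a", "b", "c"], [3.0, -2.0, 1.0]))
        rp = rank_by_abs_difference(pair_from_d(d))
        with pytest.raises(ValueError, match="exceeds"):
            topn_consistency_curve(rp, rp, ns=(5,))

    def test_independent_pairs_score_near_half(self, rng):
        # 300 repetitions of two unrelated difference profiles: the mean
        # top-n consistency converges to the chance level p_e = 0.5
        genes = [f"g{i:04d}" for i in range(2000)]
        scores = []
        for _ in range(300):
            ra = rank_by_abs_difference(pair_from_d(dict(zip(genes, rng.normal(0, 10, 2000)))))
            rb = rank_by_abs_difference(pair_from_d(dict(zip(genes, rng.normal(0, 10, 2000)))))
            scores.append(topn_consistency_curve(ra, rb, ns=(500,))[0].score)
        mean, se = np.mean(scores), np.std(scores, ddof=1) / np.sqrt(len(scores))
        assert abs(mean - 0.5) < 3 * se + 1e-9


class TestPdIdentify:
    def test_identical_strong_pairs_report_every_gene(self, rng):
        d = dict(zip([f"g{i}" for i in range(10)], (rng.normal(0, 1000, 10) + 2000)))
        a, b = pair_from_d(d, label="A"), pair_from_d(d, label="B")
        res = pd_identify([a, b], step=2)
        assert set(res.de_genes) == set(d)
        assert (res.genes["direction"] == 1).all()
        assert res.comparisons[0].n_star == 10

    def test_null_pairs_yield_empty_set(self, rng):
        genes = [f"g{i:05d}" for i in range(10000)]
        empty = 0
        for _ in range(20):
            a = pair_from_d(dict(zip(genes, rng.normal(0, 10, 10000))), label="A")
            b = pair_from_d(dict(zip(genes, rng.normal(0, 10, 10000))), label="B")
            empty += len(pd_identify([a, b])) == 0
        assert empty == 20

    def test_raising_threshold_never_enlarges_the_de_set(self):
        datasets, _ = simulate_datasets(SimulationConfig(n_genes=2000, n_de=300), seed=5)
        prs = [build_pair(d, source_label=f"d{i}") for i, d in enumerate(datasets)]
        previous = None
        for threshold in (0.80, 0.90, 0.95, 0.99):
            res = pd_identify(prs, threshold=threshold)
            n_stars = [c.n_star for c in res.comparisons]
            if previous is not None:
                assert all(n <= p for n, p in zip(n_stars, previous[0]))
                assert set(res.de_genes) <= previous[1]
            previous = (n_stars, set(res.de_genes))

    def test_result_invariant_to_pair_order(self):
        datasets, _ = simulate_datasets(SimulationConfig(n_genes=3000, n_de=150), seed=9)
        prs = [build_pair(d, source_label=f"d{i}") for i, d in enumerate(datasets)]
        res_fwd = pd_identify(prs)
        res_rev = pd_identify(prs[::-1])
        assert list(res_fwd.de_genes) == list(res_rev.de_genes)
        assert (res_fwd.genes["direction"] == res_rev.genes["direction"]).all()

    def test_directions_match_sign_of_d_in_every_supporting_pair(self):
        datasets, _ = simulate_datasets(SimulationConfig(n_genes=2000, n_de=300), seed=3)
        prs = [build_pair(d, source_label=f"d{i}") for i, d in enumerate(datasets)]
        res = pd_identify(prs)
        assert len(res) > 0
        for i, pair in enumerate(prs):
            for comp in res.comparisons:
                if f"d{i}" in comp.label.split("|"):
                    signs = np.sign(pair.d.loc[comp.genes.index].to_numpy())
                    np.testing.assert_array_equal(signs, comp.genes.to_numpy())

    def test_conflicting_directions_across_comparisons_are_dropped(self):
        genes = [f"g{i}" for i in range(10)]
        strong = dict(zip(genes, [1000.0 - 50 * i for i in range(10)]))
        flipped = dict(strong, g0=-strong["g0"])
        # comparisons (A,B) and (C,D) each pass in one block; g0 is up in the
        # first and down in the second, so it must be dropped
        pairs = [
            pair_from_d(strong, label="A"),
            pair_from_d(strong, label="B"),
            pair_from_d(flipped, label="C"),
            pair_from_d(flipped, label="D"),
        ]
        res = pd_identify(pairs, step=10)
        assert res.dropped_conflicts == ["g0"]
        assert set(res.de_genes) == set(genes) - {"g0"}

    def test_intersection_combination_requires_all_comparisons(self):
        datasets, _ = simulate_datasets(SimulationConfig(n_genes=2000, n_de=300), seed=13)
        prs = [build_pair(d, source_label=f"d{i}") for i, d in enumerate(datasets)]
        union = pd_identify(prs, combine="union")
        inter = pd_identify(prs, combine="intersection")
        assert set(inter.de_genes) <= set(union.de_genes)
        assert (inter.genes["n_support"] == len(inter.comparisons)).all()

    def test_refinement_extends_depth_at_single_gene_resolution(self, rng):
        # 30 consistent genes then an inconsistent tail: the coarse grid stops
        # at 20; refinement walks to 31, the deepest depth where 30/31 still
        # clears the 95% threshold, and the one inconsistent gene is excluded
        # from the reported set
        consistent = {f"a{i:02d}": 1000.0 - i for i in range(30)}
        tail_a = {f"z{i:02d}": (10.0 - 0.1 * i) for i in range(30)}
        tail_b = {g: -v for g, v in tail_a.items()}
        a = pair_from_d({**consistent, **tail_a}, label="A")
        b = pair_from_d({**consistent, **tail_b}, label="B")
        coarse = pd_identify([a, b], step=20, refine=False)
        fine = pd_identify([a, b], step=20, refine=True)
        assert coarse.comparisons[0].n_star == 20
        assert fine.comparisons[0].n_star == 31
        assert fine.comparisons[0].final.s == 30
        assert set(fine.de_genes) == set(consistent)

    def test_requires_two_pairs_and_positive_step(self):
        p = pair_from_d({"a": 1.0})
        with pytest.raises(ValueError, match="two"):
            pd_identify([p])
        with pytest.raises(ValueError, match="step"):
            pd_identify([p, p], step=0)


class TestPermutationNull:
    def test_seeded_run_is_reproducible(self, rng):
        ds = make_dataset(rng.lognormal(6, 1.5, (500, 20)))
        a = permutation_null_experiment(ds, n_top=50, reps=30, seed=4)
        b = permutation_null_experiment(ds, n_top=50, reps=30, seed=4)
        assert a.mean == b.mean and a.sd == b.sd

    def test_exchangeable_data_centres_on_half(self):
        cfg = SimulationConfig(n_datasets=1, n_normal=30, n_cancer=30,
                               n_genes=4000, n_de=0, seed=21)
        (ds,), _ = simulate_datasets(cfg)
        summary = permutation_null_experiment(ds, n_top=400, reps=300, seed=8)
        se = summary.sd / np.sqrt(summary.reps)
        assert abs(summary.mean - 0.5) < 3 * se + 1e-9

    def test_true_labels_used_as_both_lists_give_score_one(self, rng):
        # degenerate identity: a pair compared against itself is fully consistent
        ds = make_dataset(rng.lognormal(6, 1, (200, 10)))
        rp = rank_by_abs_difference(build_pair(ds))
        assert consistency_score(rp.top(50), rp.top(50)).score == 1.0

    def test_vectorised_experiment_agrees_with_pair_pipeline(self):
        cfg = SimulationConfig(n_datasets=1, n_normal=20, n_cancer=20,
                               n_genes=2000, n_de=0, seed=31)
        (ds,), _ = simulate_datasets(cfg)
        fast = permutation_null_experiment(ds, n_top=200, reps=400, seed=17)
        slow = np.array([
            permutation_null_from_pairs(ds, 200, seed=1000 + i).score
            for i in range(60)
        ])
        se = np.sqrt(fast.sd**2 / fast.reps + slow.var(ddof=1) / len(slow))
        assert abs(fast.mean - slow.mean()) < 4 * se + 1e-9
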