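"""Performance measures, aggregation, Wilcoxon comparison, grid search."""

import math

import numpy as np
import pytest

from loco.evaluation import (GridSpec, SetMetrics, aggregate, cross_validate,
                             decoy_metrics, evaluate_decoy_set,
                             evaluate_with_scorer, metrics_from_scores,
                             metrics_table, native_metrics, parameter_grid,
                             wilcoxon_compare)
from loco.potential import LoCoParams
from loco.scoring import omega_set_scores
from loco.synthetic import ideal_helix, make_decoys

from oracles import bf_decoy_metrics, bf_native_metrics, exact_signed_rank_tail


class TestNativeMetrics:
    def test_native_strictly_best(self):
        scores = [1.0, 2.0, 3.0, 4.0]
        rmsds = [0.0, 2.0, 4.0, 6.0]
        rank_nat, rmsd_best, z_nat, cc_nat, fe_nat = native_metrics(scores, rmsds)
        assert rank_nat == 1
        assert rmsd_best == 0.0
        assert z_nat > 0  # better than the mean gives positive Z

    def test_fraction_enrichment_with_k_of_two(self):
        # 20 structures; the 2 lowest-RMSD are also the 2 best-scoring
        rng = np.random.default_rng(0)
        scores = np.arange(20, dtype=float)
        rmsds = np.concatenate([[0.0, 0.5], rng.uniform(2, 9, 18)])
        *_, fe_nat = native_metrics(scores, rmsds)
        assert fe_nat == 100.0

    def test_degenerate_variance_flags_nan(self):
        rank_nat, _, z_nat, cc_nat, _ = native_metrics(
            [1.0, 1.0, 1.0], [0.0, 2.0, 3.0])
        assert math.isnan(z_nat)
        assert math.isnan(cc_nat)
        assert rank_nat == 1  # min rank under total tie


class TestBruteForceEquivalence:
    def test_all_thirteen_measures_match_exhaustive_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            n = int(rng.integers(3, 13))
            scores = np.round(rng.normal(0, 5, n), 3)
            rmsds = np.round(rng.uniform(0, 10, n), 3)
            got = native_metrics(scores, rmsds)
            expected = bf_native_metrics(scores.tolist(), rmsds.tolist())
            np.testing.assert_allclose(got, expected, atol=1e-12, equal_nan=True)
            got_d = decoy_metrics(scores, rmsds)
            expected_d = bf_decoy_metrics(scores.tolist(), rmsds.tolist())
            np.testing.assert_allclose(got_d, expected_d, atol=1e-12,
                                       equal_nan=True)

    def test_rank_invariants(self):
        rng = np.random.default_rng(43)
        for _ in range(100):
            n = int(rng.integers(3, 30))
            scores = rng.normal(0, 5, n)
            rmsds = rng.uniform(0, 10, n)
            r_b1, r_b10, *_, lp1, lp10 = decoy_metrics(scores, rmsds)
            assert r_b10 <= r_b1
            assert lp1 <= 0 and lp10 <= 0

    def test_rank_measures_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(44)
        scores = rng.normal(0, 5, 25)
        rmsds = rng.uniform(0, 10, 25)
        a = decoy_metrics(scores, rmsds)
        b = decoy_metrics(np.exp(scores / 3.0), rmsds)  # strictly monotone
        for k in (0, 1, 2, 5, 6, 7):  # ranks, rmsd_decoy, fe, log-p
            assert a[k] == pytest.approx(b[k], abs=1e-12)


class TestAggregate:
    def test_single_set_is_identity(self):
        m = SetMetrics(rank_nat=3, rmsd_decoy=2.5)
        agg, counts = aggregate([m])
        assert agg.rank_nat == 3
        assert agg.rmsd_decoy == 2.5
        assert counts["rank_nat"] == 1

    def test_mean_and_pairwise_nan_exclusion(self):
        a = SetMetrics(rmsd_decoy=3.0, z_nat=1.0)
        b = SetMetrics(rmsd_decoy=4.0, z_nat=math.nan)
        agg, counts = aggregate([a, b])
        assert agg.rmsd_decoy == pytest.approx(3.5)
        assert agg.z_nat == pytest.approx(1.0)
        assert counts["z_nat"] == 1
        with pytest.raises(ValueError):
            aggregate([])

    def test_field_wise_mean_matches_direct_recomputation(self):
        rng = np.random.default_rng(45)
        ms = [SetMetrics(**{f: float(rng.normal()) for f in
                            SetMetrics().as_dict()}) for _ in range(20)]
        agg, _ = aggregate(ms)
        for f, v in agg.as_dict().items():
            assert v == pytest.approx(np.mean([getattr(m, f) for m in ms]))


class TestWilcoxon:
    def test_identical_samples_are_degenerate(self):
        p, degenerate = wilcoxon_compare([1, 2, 3], [1, 2, 3])
        assert p == 1.0 and degenerate

    def test_strict_dominance_has_exact_tail(self):
        b = np.array([10.0, 20, 30, 40, 50, 60, 70, 80])
        a = b - np.arange(1.0, 9.0)  # distinct |differences|, all negative
        p, degenerate = wilcoxon_compare(a, b)
        assert not degenerate
        assert p == pytest.approx(2.0 ** -8, rel=1e-9)
        assert p == pytest.approx(exact_signed_rank_tail((a - b).tolist()),
                                  rel=1e-9)

    def test_exact_tail_matches_enumeration_for_mixed_signs(self):
        rng = np.random.default_rng(46)
        for _ in range(5):
            d = rng.normal(0, 3, 10)
            d = np.where(np.abs(d) < 0.1, 0.5, d)  # keep away from zero
            d += rng.uniform(0, 1e-6, 10)  # break |d| ties
            b = rng.normal(50, 10, 10)
            p, _ = wilcoxon_compare(b + d, b)
            assert p == pytest.approx(exact_signed_rank_tail(d.tolist()),
                                      rel=1e-9)

    def test_null_rejection_rate_is_nominal(self):
        rng = np.random.default_rng(47)
        rejections = 0
        n_rep = 500
        for _ in range(n_rep):
            a = rng.normal(0, 1, 20)
            b = rng.normal(0, 1, 20)
            p, _ = wilcoxon_compare(a, b)
            rejections += p < 0.05
        assert abs(rejections / n_rep - 0.05) < 0.025

    def test_unpaired_mode_accepts_unequal_lengths(self):
        p, _ = wilcoxon_compare([1, 2, 3], [10, 11, 12, 13], paired=False)
        assert p < 0.1
        with pytest.raises(ValueError):
            wilcoxon_compare([1, 2], [1, 2, 3], paired=True)


class TestParameterGrid:
    def test_full_search_space_has_84_versions(self):
        grid = parameter_grid(GridSpec())
        assert len(grid) == 84
        assert len(set(grid)) == 84
        # cutoff-major deterministic order
        assert grid[0] == LoCoParams(cutoff=8.0, exclude_neighbors=1,
                                     penalty_mult=1.0)
        assert grid[-1] == LoCoParams(cutoff=20.0, exclude_neighbors=4,
                                      penalty_mult=3.0)

    def test_cardinality_is_product_of_list_lengths(self):
        spec = GridSpec(cutoffs=(10.0, 14.0), exclusions=(1, 2, 3),
                        penalty_mults=(2.0,))
        assert len(parameter_grid(spec)) == 6
        single = GridSpec(cutoffs=(14.0,), exclusions=(1,), penalty_mults=(3.0,))
        assert len(parameter_grid(single)) == 1


class TestCrossValidate:
    def _sets(self, n):
        helix = ideal_helix(12, id="n")
        return [make_decoys(helix, n=3, sigma=8.0, seed=k, name=f"set{k}")
                for k in range(n)]

    def test_single_version_grid_always_wins(self):
        grid = [LoCoParams()]
        rmsd = np.random.default_rng(1).uniform(1, 5, (1, 10))
        best, report = cross_validate(grid, self._sets(10), [], folds=5,
                                      repeats=2, seed=3, rmsd_matrix=rmsd)
        assert best == grid[0]
        assert report["winner_version"] == 0

    def test_deterministic_given_seed(self):
        grid = [LoCoParams(cutoff=c) for c in (10.0, 12.0, 14.0)]
        rng = np.random.default_rng(2)
        rmsd = rng.uniform(1, 5, (3, 12))
        sets = self._sets(12)
        r1 = cross_validate(grid, sets, [], folds=4, repeats=3, seed=9,
                            rmsd_matrix=rmsd)
        r2 = cross_validate(grid, sets, [], folds=4, repeats=3, seed=9,
                            rmsd_matrix=rmsd)
        assert r1[0] == r2[0]
        assert r1[1] == r2[1]

    def test_planted_dominant_version_is_selected_in_every_repeat(self):
        grid = [LoCoParams(cutoff=c) for c in (10.0, 12.0, 14.0)]
        rng = np.random.default_rng(4)
        rmsd = rng.uniform(3, 6, (3, 15))
        rmsd[1] = rng.uniform(0.5, 1.0, 15)  # version 1 dominates every set
        best, report = cross_validate(grid, self._sets(15), [], folds=5,
                                      repeats=4, seed=11, rmsd_matrix=rmsd)
        assert best == grid[1]
        assert all(rep["winner_version"] == 1 for rep in report["repeats"])
        for rep in report["repeats"]:
            assert all(f["selected_version"] == 1 for f in rep["folds"])

    def test_fold_sizes_differ_by_at_most_one(self):
        grid = [LoCoParams()]
        rmsd = np.ones((1, 13))
        _, report = cross_validate(grid, self._sets(13), [], folds=5,
                                   repeats=1, seed=0, rmsd_matrix=rmsd)
        sizes = sorted(len(f["held_out_sets"]) for f in
                       report["repeats"][0]["folds"])
        assert sizes == [2, 2, 3, 3, 3]

    def test_full_pipeline_on_tiny_grid(self, helix_corpus):
        helix = ideal_helix(15, id="n")
        sets = [make_decoys(helix, n=4, sigma=10.0, seed=k, name=f"s{k}")
                for k in range(4)]
        grid = [LoCoParams(cutoff=10.0), LoCoParams(cutoff=14.0)]
        best, report = cross_validate(grid, sets, helix_corpus[:20],
                                      folds=2, repeats=2, seed=5)
        assert best in grid
        assert report["n_versions"] == 2


class TestEvaluateDrivers:
    def test_evaluate_decoy_set_produces_finite_metrics(self, helix_db):
        helix = ideal_helix(20, id="native")
        dset = make_decoys(helix, n=12, sigma=15.0, seed=3)
        m = evaluate_decoy_set(helix_db, dset)
        assert m.rank_nat >= 1
        assert m.r_b10 <= m.r_b1
        assert m.log_p_b1 <= 0
        assert 0 <= m.fe_nat <= 100

    def test_omega_scorer_plugs_into_evaluation(self, helix20):
        dset = make_decoys(helix20, n=8, sigma=5.0, seed=4, omega_sigma=6.0)
        m = evaluate_with_scorer(omega_set_scores, dset, ascending=False)
        assert m.rank_nat >= 1

    def test_metrics_table_has_per_set_and_aggregate_rows(self, helix_db):
        helix = ideal_helix(15, id="native")
        per_set = {}
        for k in range(3):
            dset = make_decoys(helix, n=6, sigma=12.0, seed=k)
            per_set[f"set{k}"] = evaluate_decoy_set(helix_db, dset)
        df = metrics_table(per_set)
        assert list(df.index) == ["set0", "set1", "set2", "aggregate"]
        assert df.loc["aggregate", "rmsd_decoy"] == pytest.approx(
            df.loc[["set0", "set1", "set2"], "rmsd_decoy"].mean())
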