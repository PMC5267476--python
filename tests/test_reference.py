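"""cis-SNP selection, capped-LASSO fitting, CV scoring, reference building."""

import numpy as np
import pytest

from epistruct import simulate_cohort, subset_samples
from epistruct.data import GenotypeData, MethylationData, SiteAnnotation
from epistruct.reference import (
    BuilderParams,
    build_reference,
    cv_score,
    fit_cpg_model,
    make_folds,
    select_cis_snps,
)

from oracles import cd_lasso, lasso_objective, nearest_w_snps


def S(sid, chrom, pos):
    return SiteAnnotation(sid, chrom, pos)


class TestSelectCisSnps:
    def test_nearest_on_same_chromosome_only(self):
        cpg = S("cg", "1", 1000)
        snps = [S("a", "1", 900), S("b", "1", 1150), S("c", "2", 1001)]
        assert select_cis_snps(cpg, snps, 2) == ["a", "b"]

    def test_equidistant_tie_goes_to_lower_position(self):
        cpg = S("cg", "1", 1000)
        snps = [S("hi", "1", 1100), S("lo", "1", 900)]
        assert select_cis_snps(cpg, snps, 1) == ["lo"]

    def test_returns_fewer_when_chromosome_is_sparse(self):
        cpg = S("cg", "1", 10)
        snps = [S("a", "1", 5), S("b", "2", 10)]
        assert select_cis_snps(cpg, snps, 5) == ["a"]

    def test_no_same_chromosome_snp_gives_empty_list(self):
        assert select_cis_snps(S("cg", "3", 10), [S("a", "1", 5)], 2) == []

    @pytest.mark.parametrize("w", [1, 3, 7, 50])
    def test_matches_sort_all_then_truncate_oracle(self, w, rng):
        snps = [
            S(f"s{i}", str(rng.integers(1, 3)), int(rng.integers(1, 500)))
            for i in range(40)
        ]
        cpg = S("cg", "1", int(rng.integers(1, 500)))
        assert select_cis_snps(cpg, snps, w) == nearest_w_snps(cpg, snps, w)


class TestFitCpgModel:
    def test_perfect_single_predictor_recovered(self, rng):
        X = rng.standard_normal((60, 6))
        X = (X - X.mean(0)) / X.std(0)
        y = X[:, 3].copy()
        fit = fit_cpg_model(y, X, p=2)
        support = set(np.flatnonzero(fit.coef))
        assert support == {3}
        pred = fit.intercept + X @ fit.coef
        assert np.corrcoef(pred, y)[0, 1] ** 2 > 0.999

    def test_active_set_never_exceeds_p(self, rng):
        for p in (1, 3, 5):
            X = rng.standard_normal((40, 12))
            y = X @ rng.standard_normal(12) + rng.standard_normal(40)
            fit = fit_cpg_model(y, X, p=p)
            assert np.count_nonzero(fit.coef) <= p

    def test_empty_design_rejected(self):
        with pytest.raises(ValueError):
            fit_cpg_model(np.ones(5), np.empty((5, 0)), p=1)

    def test_p_below_one_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_cpg_model(rng.standard_normal(5), rng.standard_normal((5, 2)), p=0)

    def test_constant_response_gives_null_model(self, rng):
        X = rng.standard_normal((10, 3))
        fit = fit_cpg_model(np.full(10, 0.7), X, p=2)
        assert fit.intercept == pytest.approx(0.7)
        np.testing.assert_array_equal(fit.coef, 0.0)

    @pytest.mark.parametrize("seed", range(8))
    def test_objective_matches_coordinate_descent_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n, m = 20, 5
        X = rng.standard_normal((n, m))
        X = (X - X.mean(0)) / X.std(0)
        y = X @ rng.standard_normal(m) * 0.5 + rng.standard_normal(n)
        fit = fit_cpg_model(y, X, p=3)
        yc = y - y.mean()
        beta_oracle = cd_lasso(X, yc, fit.alpha)
        obj_impl = lasso_objective(X, yc, fit.coef, fit.alpha)
        obj_oracle = lasso_objective(X, yc, beta_oracle, fit.alpha)
        assert obj_impl == pytest.approx(obj_oracle, abs=1e-8)


class TestCvScore:
    def test_noiseless_signal_scores_near_one(self, rng):
        n = 100
        X = rng.standard_normal((n, 8))
        y = 2.0 * X[:, 1] - 1.5 * X[:, 4]
        params = BuilderParams(w=8, p=4, k_folds=10, fold_seed=0)
        score, fold_r2 = cv_score(y, X, params)
        assert score >= 0.99
        assert len(fold_r2) == 10

    def test_pure_noise_scores_low(self, rng):
        n = 300
        X = rng.standard_normal((n, 20))
        y = rng.standard_normal(n)
        score, _ = cv_score(y, X, BuilderParams(w=20, p=5, fold_seed=1))
        assert score < 0.1

    def test_degenerate_fold_contributes_zero(self):
        # all-zero predictors give constant predictions in every fold
        n = 40
        X = np.zeros((n, 3))
        y = np.random.default_rng(0).standard_normal(n)
        score, fold_r2 = cv_score(y, X, BuilderParams(w=3, p=1, k_folds=4, fold_seed=0))
        assert score == 0.0
        assert all(r == 0.0 for r in fold_r2)

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(ValueError, match="at least"):
            cv_score(
                rng.standard_normal(15),
                rng.standard_normal((15, 2)),
                BuilderParams(k_folds=10),
            )

    def test_score_is_median_of_fold_r2(self, rng):
        X = rng.standard_normal((80, 5))
        y = X[:, 0] + rng.standard_normal(80)
        score, fold_r2 = cv_score(y, X, BuilderParams(w=5, p=3, k_folds=4, fold_seed=2))
        assert score == pytest.approx(np.median(fold_r2))


class TestMakeFolds:
    def test_partition_covers_all_samples_once(self):
        folds = make_folds(23, 5, seed=0)
        joined = np.concatenate(folds)
        assert sorted(joined) == list(range(23))

    def test_seed_determines_partition(self):
        a = make_folds(30, 5, seed=1)
        b = make_folds(30, 5, seed=1)
        c = make_folds(30, 5, seed=2)
        assert all(np.array_equal(x, y) for x, y in zip(a, b))
        assert any(not np.array_equal(x, y) for x, y in zip(a, c))


class TestBuildReference:
    @pytest.fixture(scope="class")
    def planted(self):
        geno, meth, _, truth = simulate_cohort(
            n_samples=300, n_snps=200, n_cpgs=40, seed=5,
            frac_genetic=0.5, frac_cellular=0.0, rho2_genetic=0.8,
        )
        return geno, meth, truth

    def test_recovers_planted_genetic_cpgs(self, planted):
        geno, meth, truth = planted
        ref, scores = build_reference(geno, meth, BuilderParams(fold_seed=5))
        assert set(ref.cpg_ids) == set(truth.cpg_ids_of_kind("genetic"))
        assert len(scores) == meth.n_cpgs

    def test_threshold_zero_keeps_every_windowed_cpg(self, planted):
        geno, meth, _ = planted
        ref, scores = build_reference(
            geno, meth, BuilderParams(score_threshold=0.0, fold_seed=5)
        )
        n_windowed = int((scores["n_cis_snps"] > 0).sum())
        # strict inequality: only exact-zero scores are excluded at threshold 0
        assert len(ref) == int((scores["score"] > 0).sum())
        assert len(ref) <= n_windowed

    def test_threshold_one_gives_empty_list_with_warning(self, planted):
        geno, meth, _ = planted
        with pytest.warns(UserWarning, match="empty"):
            ref, _ = build_reference(
                geno, meth, BuilderParams(score_threshold=1.0, fold_seed=5)
            )
        assert len(ref) == 0

    def test_raising_threshold_never_adds_cpgs(self, planted):
        geno, meth, _ = planted
        lo, _ = build_reference(
            geno, meth, BuilderParams(score_threshold=0.3, fold_seed=5)
        )
        hi, _ = build_reference(
            geno, meth, BuilderParams(score_threshold=0.6, fold_seed=5)
        )
        assert set(hi.cpg_ids) <= set(lo.cpg_ids)

    def test_same_fold_seed_is_bit_identical(self, planted):
        geno, meth, _ = planted
        r1, s1 = build_reference(geno, meth, BuilderParams(fold_seed=9))
        r2, s2 = build_reference(geno, meth, BuilderParams(fold_seed=9))
        assert r1.entries == r2.entries
        assert s1.equals(s2)

    def test_sample_alignment_by_id_not_order(self, planted):
        geno, meth, truth = planted
        perm = np.random.default_rng(0).permutation(geno.n_samples)
        shuffled = subset_samples(geno, list(perm))
        ref_a, _ = build_reference(geno, meth, BuilderParams(fold_seed=5))
        ref_b, _ = build_reference(shuffled, meth, BuilderParams(fold_seed=5))
        assert ref_a.entries == ref_b.entries

    def test_disjoint_sample_sets_rejected(self, planted):
        geno, meth, _ = planted
        bad = GenotypeData(
            [f"x{i}" for i in range(geno.n_samples)], geno.snps, geno.dosages
        )
        with pytest.raises(ValueError, match="sample sets disagree"):
            build_reference(bad, meth, BuilderParams())

    def test_unimputed_genotypes_rejected(self, planted):
        geno, meth, _ = planted
        D = geno.dosages.copy()
        D[0, 0] = np.nan
        bad = GenotypeData(list(geno.sample_ids), list(geno.snps), D)
        with pytest.raises(ValueError, match="imputed"):
            build_reference(bad, meth, BuilderParams())

    def test_cpgs_without_cis_window_skipped_not_scored(self):
        geno = GenotypeData(
            [f"s{i}" for i in range(30)],
            [S("snp0", "1", 100)],
            np.random.default_rng(1).integers(0, 3, (30, 1)).astype(float),
        )
        meth = MethylationData(
            [f"s{i}" for i in range(30)],
            [S("cgA", "1", 90), S("cgB", "2", 90)],  # cgB has no chr2 SNP
            np.random.default_rng(2).uniform(0.2, 0.8, (30, 2)),
        )
        ref, scores = build_reference(
            geno, meth, BuilderParams(w=1, p=1, k_folds=5, fold_seed=0)
        )
        row = scores.set_index("cpg_id")
        assert np.isnan(row.loc["cgB", "score"])
        assert row.loc["cgB", "n_cis_snps"] == 0
        assert not np.isnan(row.loc["cgA", "score"])


class TestFoldSeedSensitivity:
    @pytest.mark.parametrize("rho2", [0.0, 0.5, 0.9])
    def test_score_varies_little_across_fold_seeds(self, rho2):
        from epistruct import simulate_genotypes, simulate_methylation
        from epistruct.reference import select_cis_snps as cis

        geno, truth = simulate_genotypes(500, 120, seed=60)
        meth, truth = simulate_methylation(
            geno, truth, 3, frac_genetic=1.0, frac_cellular=0.0,
            rho2_genetic=rho2, seed=61,
        )
        snp_idx = {s: j for j, s in enumerate(geno.snp_ids)}
        for j, cpg in enumerate(meth.cpgs):
            window = cis(cpg, geno.snps, 50)
            X = geno.dosages[:, [snp_idx[s] for s in window]]
            scores = [
                cv_score(meth.values[:, j], X, BuilderParams(fold_seed=fs))[0]
                for fs in range(5)
            ]
            assert np.std(scores) < 0.05


class TestBuilderParams:
    @pytest.mark.parametrize(
        "kwargs", [dict(p=0), dict(p=60, w=50), dict(k_folds=1),
                   dict(score_threshold=1.5)]
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            BuilderParams(**kwargs)
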