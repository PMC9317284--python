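"""Genotype QC, REML mixed model, stepwise selection, marginal R2, bootstrap."""

import numpy as np
import pandas as pd
import pytest

from hefam.pedigree import CovarianceStructure, covariance_structure
from hefam.pqtl import (
    bca_block_bootstrap,
    hwe_exact_test,
    ld_prune,
    maf_filter,
    marginal_r2,
    reml_fit,
    select_candidates,
    stepwise_select,
    univariate_scan,
)
from hefam.simulate import (
    GenotypeTable,
    SimulationConfig,
    add_singletons,
    gene_drop,
    simulate_pedigree,
    simulate_phenotype,
)


def make_gt(dosages, positions=None, chrom="1"):
    dosages = np.asarray(dosages, dtype=float)
    m = dosages.shape[1]
    snps = pd.DataFrame({
        "snp_id": [f"s{j}" for j in range(m)],
        "chromosome": chrom,
        "position": positions if positions is not None else 1000 * (np.arange(m) + 1),
        "effect_allele": "A",
        "reference_allele": "G",
    })
    ids = [f"i{k}" for k in range(dosages.shape[0])]
    return GenotypeTable(ids=ids, snps=snps, dosages=dosages)


def singleton_structure(n):
    return CovarianceStructure(
        ids=[f"i{k}" for k in range(n)], A=np.eye(n), H=np.eye(n),
        family_incidence={f"i{k}": f"f{k}" for k in range(n)})


class TestMAFFilter:
    def test_monomorphic_removed(self):
        gt = make_gt(np.zeros((20, 1)))
        assert maf_filter(gt).n_snps == 0

    def test_threshold_is_strict_less_than(self):
        # 100 individuals, 10 heterozygotes: MAF exactly 0.05 -> retained
        d = np.zeros((100, 1))
        d[:10, 0] = 1.0
        assert maf_filter(make_gt(d), 0.05).n_snps == 1
        d[9, 0] = 0.0  # 9 hets -> MAF 0.045 -> removed
        assert maf_filter(make_gt(d), 0.05).n_snps == 0

    def test_reorients_to_minor_allele(self):
        d = np.full((10, 1), 2.0)
        d[:3, 0] = 1.0  # effect-allele freq 0.85
        out = maf_filter(make_gt(d), 0.05)
        assert out.snps.loc[0, "effect_allele"] == "G"
        assert out.maf()[0] == pytest.approx(0.15)
        assert np.all(out.dosages[:, 0] == 2.0 - d[:, 0])


def hwe_enumeration_oracle(n0, n1, n2):
    """Full enumeration over heterozygote counts with the same allele counts."""
    from math import comb
    n = n0 + n1 + n2
    rare = min(2 * n0 + n1, 2 * n2 + n1)
    probs = {}
    for h in range(rare % 2, min(rare, 2 * n - rare) + 1, 2):
        hr = (rare - h) // 2
        hc = n - h - hr
        # multinomial count of genotype configurations x 2^h
        probs[h] = comb(n, hr) * comb(n - hr, h) * 2 ** h
    tot = sum(probs.values())
    p_obs = probs[n1]
    return sum(v for v in probs.values() if v <= p_obs * (1 + 1e-12)) / tot


class TestHWE:
    @pytest.mark.parametrize("counts", [(25, 50, 25), (50, 0, 50), (3, 14, 83), (10, 20, 5)])
    def test_matches_enumeration_oracle(self, counts):
        n0, n1, n2 = counts
        d = np.concatenate([np.zeros(n0), np.ones(n1), np.full(n2, 2.0)])
        assert hwe_exact_test(d) == pytest.approx(hwe_enumeration_oracle(*counts), rel=1e-10)

    def test_perfect_proportions_high_p(self):
        d = np.concatenate([np.zeros(25), np.ones(50), np.full(25, 2.0)])
        assert hwe_exact_test(d) >= 0.5

    def test_het_deficit_extreme(self):
        d = np.concatenate([np.zeros(50), np.full(50, 2.0)])
        assert hwe_exact_test(d) < 1e-4

    def test_monomorphic_p_one(self):
        assert hwe_exact_test(np.zeros(60)) == 1.0


class TestLDPrune:
    def test_duplicate_columns_one_survives(self):
        rng = np.random.default_rng(0)
        col = rng.integers(0, 3, 80).astype(float)
        gt = make_gt(np.column_stack([col, col, rng.integers(0, 3, 80)]))
        out = ld_prune(gt)
        assert out.n_snps == 2

    def test_independent_snps_not_pruned(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            d = rng.binomial(2, 0.3, size=(155, 30)).astype(float)
            gt = make_gt(d)
            assert ld_prune(gt, r2_max=0.2).n_snps >= 28  # r2 ~ 1/n, rare excursions

    def test_three_way_ld_single_survivor(self):
        rng = np.random.default_rng(3)
        base = rng.binomial(2, 0.4, 200).astype(float)
        noisy = lambda: np.clip(base + (rng.random(200) < 0.05), 0, 2)
        gt = make_gt(np.column_stack([base, noisy(), noisy()]))
        out = ld_prune(gt, r2_max=0.2)
        assert out.n_snps == 1

    def test_unsorted_raises(self):
        gt = make_gt(np.zeros((10, 2)), positions=[2000, 1000])
        with pytest.raises(ValueError, match="sorted"):
            ld_prune(gt)


class TestREML:
    def test_identity_covariance_equals_ols(self):
        rng = np.random.default_rng(5)
        n = 60
        st = singleton_structure(n)
        x = rng.standard_normal(n)
        y = 1.0 + 0.5 * x + rng.standard_normal(n)
        fit = reml_fit(y, pd.DataFrame({"x": x}), st)
        X = np.column_stack([np.ones(n), x])
        beta_ols = np.linalg.solve(X.T @ X, X.T @ y)
        assert np.allclose(fit.beta, beta_ols, atol=1e-6)
        # individual components are aliased when A = H = I; the total is the
        # REML residual variance
        rss = float(y @ y - (X @ beta_ols) @ y)
        total = fit.sigma2_G + fit.sigma2_C + fit.sigma2_I
        assert total == pytest.approx(rss / (n - 2), rel=1e-4)

    def test_matches_grid_search_oracle(self):
        """Two-component REML vs brute-force grid on the heritability ratio."""
        cfg = SimulationConfig(n_families=8, family_sizes=(10, 16), h2_true=0.5,
                               c2_true=0.0, beta_sex=0.0, beta_ms=0.0, seed=41)
        ped = simulate_pedigree(cfg)
        st = covariance_structure(ped)
        rng = np.random.default_rng(42)
        y = simulate_phenotype(ped, st, cfg, rng=rng)
        fit = reml_fit(y, pd.DataFrame(index=range(st.n)), st, use_household=False)

        def neg_restricted_ll(sG, sI):
            n = st.n
            V = sG * st.A + sI * np.eye(n)
            X = np.ones((n, 1))
            Vi = np.linalg.inv(V)
            XtViX = X.T @ Vi @ X
            beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
            r = y - X @ beta
            s, ld = np.linalg.slogdet(V)
            s2, ld2 = np.linalg.slogdet(XtViX)
            return 0.5 * (ld + ld2 + r @ Vi @ r)

        tot = fit.sigma2_G + fit.sigma2_I
        ratios = np.arange(0.001, 1.0, 0.001)
        vals = [neg_restricted_ll(g * tot, (1 - g) * tot) for g in ratios]
        g_star = ratios[int(np.argmin(vals))]
        assert abs(fit.sigma2_G - g_star * tot) < max(1e-3, tot * 1.5e-3)

    def test_planted_effect_recovered(self):
        cfg = SimulationConfig(n_families=10, family_sizes=(8, 16), h2_true=0.3,
                               c2_true=0.1, beta_sex=0.0, beta_ms=0.0,
                               n_snps=1, seed=51, snp_effects=[(0, 0.5)])
        ped = simulate_pedigree(cfg)
        st = covariance_structure(ped)
        gt = gene_drop(ped, [0.3], seed=52)
        y = simulate_phenotype(ped, st, cfg, gt, rng=np.random.default_rng(53))
        fit = reml_fit(y, pd.DataFrame({"snp": gt.dosages[:, 0]}), st, snp_cols=["snp"])
        b, se, p = fit.coef("snp")
        assert abs(b - 0.5) < 3 * se


class TestScanSelection:
    def _small_scan(self, seed=61, beta=0.0):
        cfg = SimulationConfig(n_families=6, family_sizes=(8, 14), h2_true=0.3,
                               c2_true=0.0, beta_sex=0.1, beta_ms=0.0,
                               n_snps=12, seed=seed)
        if beta:
            cfg.snp_effects = [(0, beta)]
        ped = simulate_pedigree(cfg)
        ped = add_singletons(ped, 40, seed=seed + 1)
        st = covariance_structure(ped)
        rng = np.random.default_rng(seed + 2)
        mafs = rng.uniform(0.2, 0.5, cfg.n_snps)
        gt = gene_drop(ped, mafs, seed=seed + 3)
        y = simulate_phenotype(ped, st, cfg, gt, rng=np.random.default_rng(seed + 4))
        tab = ped.table.set_index("individual_id").loc[st.ids]
        cov = pd.DataFrame({"sex": (tab["sex"] == "female").to_numpy(float)})
        return y, gt, st, cov

    def test_scan_relabeling_invariance(self):
        y, gt, st, cov = self._small_scan()
        scan1 = univariate_scan(y, gt, st, cov)
        perm = np.random.default_rng(0).permutation(st.n)
        ids2 = [st.ids[k] for k in perm]
        st2 = st.subset(ids2)
        gt2 = gt.subset_individuals(ids2)
        scan2 = univariate_scan(y[perm], gt2, st2, cov.iloc[perm].reset_index(drop=True))
        assert np.allclose(scan1["beta"], scan2["beta"], atol=1e-6)
        assert np.allclose(scan1["p_value"], scan2["p_value"], atol=1e-6)

    def test_allele_flip_equivariance(self):
        y, gt, st, cov = self._small_scan()
        flipped = GenotypeTable(gt.ids, gt.snps.copy(), 2.0 - gt.dosages)
        s1 = univariate_scan(y, gt, st, cov)
        s2 = univariate_scan(y, flipped, st, cov)
        assert np.allclose(s1["beta"], -s2["beta"], atol=1e-6)
        assert np.allclose(s1["p_value"], s2["p_value"], atol=1e-8)

    def test_select_candidates_k_larger_than_panel(self):
        y, gt, st, cov = self._small_scan()
        scan = univariate_scan(y, gt, st, cov)
        assert len(select_candidates(scan, k=100)) == gt.n_snps

    def test_select_candidates_deterministic_tiebreak(self):
        scan = pd.DataFrame({
            "snp_id": ["a", "b", "c"], "chromosome": "1",
            "position": [100, 200, 300],
            "maf": 0.3, "effect_allele": "A",
            "beta": [0.5, 0.8, 0.2], "se": [0.1, 0.1, 0.1],
            "p_value": [0.01, 0.01, 0.5],
        })
        assert select_candidates(scan, k=2) == ["b", "a"]

    def test_stepwise_finds_planted_and_resolves_duplicates(self):
        y, gt, st, cov = self._small_scan(seed=71, beta=0.6)
        # duplicate the causal SNP: collinear pair, exactly one may enter
        d = np.column_stack([gt.dosages, gt.dosages[:, 0]])
        snps = pd.concat([gt.snps, gt.snps.iloc[[0]].assign(snp_id="dup", position=999_999)],
                         ignore_index=True)
        gt2 = GenotypeTable(gt.ids, snps, d)
        scan = univariate_scan(y, gt2, st, cov)
        cands = select_candidates(scan, k=13)
        chosen = stepwise_select(y, gt2, cands, st, cov, alpha=1e-4)
        assert len([s for s in chosen if s in ("snp1", "dup")]) <= 1
        assert len(chosen) >= 1

    def test_stepwise_null_rarely_selects(self):
        picked = 0
        for seed in (81, 91, 101):
            y, gt, st, cov = self._small_scan(seed=seed)
            scan = univariate_scan(y, gt, st, cov)
            cands = select_candidates(scan, k=12)
            picked += len(stepwise_select(y, gt, cands, st, cov, alpha=1e-4))
        assert picked == 0


class TestMarginalR2:
    def test_empty_and_zero_effects(self):
        from hefam.pqtl import LMMFit
        fit = LMMFit(beta=np.array([0.0]), se=np.array([1.0]), names=["intercept"],
                     sigma2_G=0.3, sigma2_C=0.1, sigma2_I=0.6, loglik=0.0,
                     converged=True, sigma2_F=0.0, sigma2_SNPs=0.0)
        assert marginal_r2(fit) == 0.0

    def test_affine_trait_invariance(self):
        rng = np.random.default_rng(8)
        n = 80
        st = singleton_structure(n)
        x = rng.binomial(2, 0.4, n).astype(float)
        y = 0.6 * x + rng.standard_normal(n)
        f1 = reml_fit(y, pd.DataFrame({"snp": x}), st, snp_cols=["snp"])
        f2 = reml_fit(5.0 * y + 2.0, pd.DataFrame({"snp": x}), st, snp_cols=["snp"])
        assert marginal_r2(f1) == pytest.approx(marginal_r2(f2), abs=1e-6)

    def test_denominator_conventions(self):
        from hefam.pqtl import LMMFit
        fit = LMMFit(beta=np.zeros(1), se=np.ones(1), names=["intercept"],
                     sigma2_G=0.2, sigma2_C=0.0, sigma2_I=0.4, loglik=0.0,
                     converged=True, sigma2_F=0.0, sigma2_SNPs=0.4)
        assert marginal_r2(fit) == pytest.approx(0.4)
        assert marginal_r2(fit, include_snp_variance_in_denominator=False) == \
            pytest.approx(0.4 / 0.6)


class TestEndToEndPipeline:
    def test_scan_select_r2_ci_recovers_planted_architecture(self):
        """Full scan -> top-k -> stepwise -> R2 -> BCA path on a 155-control
        analog with three strong planted SNPs (18% of variance each): the
        planted set is recovered in >= 90% of replicates and the BCA interval
        usually contains the true explained fraction."""
        from hefam.pqtl import explained_variance
        from hefam.simulate import planted_snp_study
        reps = 20
        recovered = 0
        covered = 0
        truth = 0.54 / (1.0 + 0.2 ** 2 * 0.25)
        for r in range(reps):
            ped, st, gt, y, cov, planted = planted_snp_study(
                total_explained=0.54, n_planted=3, n_null_snps=37,
                seed=40_000 + 11 * r)
            res = explained_variance(y, gt, st, cov, topk=20, alpha=1e-4,
                                     B=150, seed=r)
            if set(planted) <= set(res["selected"]):
                recovered += 1
            lo, hi = res["ci"]
            covered += (lo <= truth <= hi)
        assert recovered >= int(0.9 * reps)
        assert covered >= int(0.75 * reps)


class TestBCABootstrap:
    def test_constant_statistic_degenerate(self):
        fams = [np.array([k]) for k in range(10)]
        lo, hi = bca_block_bootstrap(lambda b: 0.7, fams, B=50, seed=1)
        assert lo == hi == 0.7

    def test_same_seed_identical(self):
        rng = np.random.default_rng(2)
        data = rng.standard_normal(40)
        fams = [np.array([2 * k, 2 * k + 1]) for k in range(20)]
        stat = lambda blocks: float(np.clip(np.mean([data[b].mean() for b in blocks]) + 0.5, 0, 1))
        ci1 = bca_block_bootstrap(stat, fams, B=200, seed=7)
        ci2 = bca_block_bootstrap(stat, fams, B=200, seed=7)
        assert ci1 == ci2

    def test_symmetric_statistic_close_to_percentile(self):
        rng = np.random.default_rng(3)
        data = rng.standard_normal(400)
        fams = [np.array([4 * k + j for j in range(4)]) for k in range(100)]
        stat = lambda blocks: float(np.mean([data[b].mean() for b in blocks]) + 0.5)
        lo, hi = bca_block_bootstrap(stat, fams, B=3000, seed=11)
        # percentile oracle with the same resampling scheme
        r2 = np.random.default_rng(11)
        boot = [stat([fams[i] for i in r2.integers(100, size=100)]) for _ in range(3000)]
        plo, phi = np.quantile(boot, [0.025, 0.975])
        assert abs(lo - plo) < 0.015 and abs(hi - phi) < 0.015
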