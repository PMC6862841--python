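import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr, ttest_ind

from canopyselect.selection import combine_categories
from canopyselect.trials import (
    AdjustedMeans,
    TrialModelSpec,
    adjusted_means,
    compare_categories,
    fit_trial_model,
    significance_stars,
    top_rank_attribution,
    welch_t,
    yield_given_r8,
)


def simulate_pyt(
    rng,
    n_g=100,
    n_loc=2,
    n_rep=2,
    block_size=10,
    comps=dict(g=1.0, loc=0.5, rep=0.2, blk=0.1, gxl=0.3, e=1.0),
    mu=10.0,
    r8_slope=0.0,
):
    """Balanced alpha-lattice-style multi-location trial with known truth."""
    genos = [f"g{i:03d}" for i in range(n_g)]
    g = rng.normal(0, np.sqrt(comps["g"]), n_g)
    r8 = 100 + rng.normal(0, 3, n_g)
    rows = []
    for loc in range(n_loc):
        e_loc = rng.normal(0, np.sqrt(comps["loc"]))
        gxl = rng.normal(0, np.sqrt(comps["gxl"]), n_g)
        for rep in range(n_rep):
            e_rep = rng.normal(0, np.sqrt(comps["rep"]))
            order = rng.permutation(n_g)
            e_blk = rng.normal(0, np.sqrt(comps["blk"]), n_g // block_size)
            for k, gi in enumerate(order):
                b = k // block_size
                rows.append(
                    {
                        "line_id": genos[gi],
                        "location": f"L{loc}",
                        "rep": rep,
                        "block": b,
                        "r8_dap": r8[gi],
                        "yield_kg_ha": mu + g[gi] + r8_slope * (r8[gi] - 100)
                        + e_loc + e_rep + e_blk[b] + gxl[gi]
                        + rng.normal(0, np.sqrt(comps["e"])),
                    }
                )
    truth = pd.Series(g, index=genos)
    return pd.DataFrame(rows), truth


class TestReml:
    def test_recovers_genetic_and_residual_variance(self):
        rng = np.random.default_rng(0)
        est_g, est_e = [], []
        for _ in range(8):
            df, _ = simulate_pyt(rng)
            fit = fit_trial_model(df, TrialModelSpec())
            est_g.append(fit.varcomps["genotype"])
            est_e.append(fit.varcomps["sigma_e2"])
        assert np.mean(est_g) == pytest.approx(1.0, rel=0.15)
        assert np.mean(est_e) == pytest.approx(1.0, rel=0.15)

    def test_balanced_one_way_matches_anova(self):
        rng = np.random.default_rng(1)
        n_g, r = 30, 4
        genos = np.repeat([f"g{i}" for i in range(n_g)], r)
        y = 10 + np.repeat(rng.normal(0, 2, n_g), r) + rng.normal(0, 1, n_g * r)
        df = pd.DataFrame(
            {"line_id": genos, "location": "L0", "rep": np.tile(range(r), n_g),
             "block": 0, "yield_kg_ha": y}
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_trial_model(df, TrialModelSpec())
        ybar = df.groupby("line_id")["yield_kg_ha"].mean()
        msb = r * ybar.var(ddof=1)
        mse = (
            (df["yield_kg_ha"] - ybar.loc[df["line_id"]].to_numpy()) ** 2
        ).sum() / (n_g * (r - 1))
        assert fit.varcomps["genotype"] == pytest.approx((msb - mse) / r,
                                                         abs=1e-6)
        assert fit.varcomps["sigma_e2"] == pytest.approx(mse, abs=1e-6)

    def test_no_genetic_signal_collapses_sigma_g(self):
        rng = np.random.default_rng(2)
        df, _ = simulate_pyt(rng, comps=dict(g=0.0, loc=0.5, rep=0.2, blk=0.1,
                                             gxl=0.0, e=1.0))
        fit = fit_trial_model(df, TrialModelSpec())
        assert fit.varcomps["genotype"] < 0.05 * fit.varcomps["sigma_e2"]

    def test_optimum_beats_random_admissible_points(self):
        from canopyselect.trials import _design, _profiled_reml

        rng = np.random.default_rng(3)
        df, _ = simulate_pyt(rng, n_g=40, block_size=8)
        spec = TrialModelSpec()
        fit = fit_trial_model(df, spec)
        z, _, x, _, _ = _design(df, spec)
        y = df["yield_kg_ha"].to_numpy()
        y_s = y / y.std()
        zz = [z[k] @ z[k].T for k in z]
        gammas = np.array(
            [fit.varcomps[k] / fit.varcomps["sigma_e2"] for k in z]
        )
        at_opt = _profiled_reml(np.log(np.maximum(gammas, 1e-8)), zz, x, y_s)[0]
        for _ in range(20):
            trial_pt = rng.uniform(-6, 2, len(zz))
            assert at_opt <= _profiled_reml(trial_pt, zz, x, y_s)[0] + 1e-6

    def test_singular_fixed_design_is_error(self):
        df = pd.DataFrame(
            {"line_id": ["a", "b"], "location": "L0", "rep": 0, "block": 0,
             "yield_kg_ha": [1.0, 2.0], "r8_dap": [3.0, 3.0]}
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            with pytest.raises(ValueError, match="singular|constant"):
                fit_trial_model(
                    df, TrialModelSpec(genotype_effect="fixed",
                                       covariates=("r8_dap",))
                )


class TestAdjustedMeans:
    def test_degenerate_single_genotype(self):
        rng = np.random.default_rng(4)
        y = 10 + rng.normal(0, 1, 8)
        df = pd.DataFrame(
            {"line_id": "g0", "location": "L0", "rep": range(8), "block": 0,
             "yield_kg_ha": y}
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_trial_model(df, TrialModelSpec())
        am = adjusted_means(fit)
        assert am.series()["g0"] == pytest.approx(y.mean(), rel=1e-6)

    def test_shift_equivariance(self):
        rng = np.random.default_rng(5)
        df, _ = simulate_pyt(rng, n_g=30, block_size=6)
        fit = fit_trial_model(df, TrialModelSpec())
        df2 = df.assign(yield_kg_ha=df["yield_kg_ha"] + 100.0)
        fit2 = fit_trial_model(df2, TrialModelSpec())
        a = adjusted_means(fit).series().sort_index()
        b = adjusted_means(fit2).series().sort_index()
        np.testing.assert_allclose(b - a, 100.0, atol=1e-4)

    def test_random_genotype_means_are_shrunken(self):
        rng = np.random.default_rng(6)
        df, _ = simulate_pyt(rng, n_g=60, block_size=12)
        # unbalance: drop a third of the plots
        df = df.sample(frac=0.67, random_state=1)
        fit = fit_trial_model(df, TrialModelSpec())
        adj = adjusted_means(fit).series()
        raw = df.groupby("line_id")["yield_kg_ha"].mean()
        assert adj.var() <= raw.var()

    def test_fixed_and_random_fits_rank_alike(self):
        rng = np.random.default_rng(7)
        df, _ = simulate_pyt(
            rng, comps=dict(g=4.0, loc=0.5, rep=0.2, blk=0.1, gxl=0.1, e=0.5)
        )
        rand = adjusted_means(fit_trial_model(df, TrialModelSpec())).series()
        fixed = adjusted_means(
            fit_trial_model(df, TrialModelSpec(genotype_effect="fixed"))
        ).series()
        rho = spearmanr(rand.sort_index(), fixed.sort_index()).statistic
        assert rho > 0.95


class TestR8Covariate:
    def test_slope_recovery(self):
        rng = np.random.default_rng(8)
        df, _ = simulate_pyt(rng, r8_slope=5.0)
        _, fit = yield_given_r8(df)
        assert fit.fixed_effects["r8_dap"] == pytest.approx(5.0, rel=0.10)

    def test_pure_maturity_signal_flattens_means(self):
        rng = np.random.default_rng(9)
        df, _ = simulate_pyt(
            rng, comps=dict(g=0.0, loc=0.0, rep=0.0, blk=0.0, gxl=0.0, e=0.01),
            r8_slope=5.0,
        )
        means, _ = yield_given_r8(df)
        assert means.table["adjusted"].std() < 0.5  # vs ~15 without adjustment

    def test_null_covariate_preserves_ranking(self):
        rng = np.random.default_rng(10)
        df, _ = simulate_pyt(rng, r8_slope=0.0)
        plain = adjusted_means(fit_trial_model(df, TrialModelSpec())).series()
        adj, _ = yield_given_r8(df)
        r = np.corrcoef(plain.sort_index(), adj.series().sort_index())[0, 1]
        assert r > 0.98


class TestCategoryComparison:
    def test_welch_matches_scipy_oracle(self, rng):
        a = rng.normal(0, 1, 23)
        b = rng.normal(0.4, 2, 31)
        t, df, p = welch_t(a, b)
        ref = ttest_ind(a, b, equal_var=False)
        assert t == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_identical_samples(self):
        t, _, p = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == 1.0
        assert significance_stars(p) == "ns"

    def test_star_thresholds(self):
        assert significance_stars(0.00005) == "****"
        assert significance_stars(0.0005) == "***"
        assert significance_stars(0.005) == "**"
        assert significance_stars(0.05) == "*"
        assert significance_stars(0.06) == "ns"

    def test_power_at_two_sd_separation(self, rng):
        hits = 0
        for _ in range(100):
            a = rng.normal(0, 1, 50)
            b = rng.normal(2, 1, 50)
            hits += welch_t(a, b)[2] < 0.001
        assert hits >= 95

    def test_compare_categories_table(self, rng):
        lines = [f"l{i:03d}" for i in range(60)]
        vals = pd.DataFrame(
            {"line_id": lines, "adjusted": rng.normal(10, 1, 60), "se": 0.1}
        )
        means = AdjustedMeans("yield", vals)
        membership = combine_categories(
            {"Yield": lines[:20], "ACC": lines[15:35], "Yield|ACC": lines[30:50]}
        )
        comp = compare_categories(means, membership)
        assert len(comp.table) == 3  # all unordered pairs
        assert set(comp.category_means) == {"Yield", "ACC", "Yield|ACC"}
        assert ((comp.table["p"] >= 0) & (comp.table["p"] <= 1)).all()


class TestTopRankAttribution:
    def test_known_toy_fixture(self):
        means = AdjustedMeans(
            "yield",
            pd.DataFrame(
                {"line_id": ["a", "b", "c", "d"],
                 "adjusted": [4.0, 3.0, 2.0, 1.0], "se": 0.1}
            ),
        )
        membership = combine_categories(
            {"Yield": ["a", "c"], "ACC": ["b"], "Yield|ACC": ["b", "a"]}
        )
        table, summary = top_rank_attribution(means, membership, k=3)
        assert list(table["line_id"]) == ["a", "b", "c"]
        assert table.loc[0, "categories"] == "Yield+Yield|ACC"
        assert summary == {"acc_informed": 2, "yield_alone": 1, "other": 0}

    def test_triple_selection_shows_all_labels(self):
        means = AdjustedMeans(
            "yield",
            pd.DataFrame({"line_id": ["a"], "adjusted": [1.0], "se": 0.1}),
        )
        membership = combine_categories(
            {"Yield": ["a"], "ACC": ["a"], "Yield|ACC": ["a"]}
        )
        table, _ = top_rank_attribution(means, membership, k=1)
        assert table.loc[0, "categories"] == "ACC+Yield+Yield|ACC"

    def test_summary_partitions_k(self, rng):
        lines = [f"l{i:02d}" for i in range(30)]
        means = AdjustedMeans(
            "yield",
            pd.DataFrame(
                {"line_id": lines, "adjusted": rng.normal(0, 1, 30), "se": 0.1}
            ),
        )
        membership = combine_categories(
            {"Yield": lines[:8], "ACC": lines[5:12], "Yield|ACC": lines[10:18]}
        )
        _, summary = top_rank_attribution(means, membership, k=10)
        assert sum(summary.values()) == 10


class TestSelectionExperimentEndToEnd:
    def test_equal_h2_perfect_corr_gives_no_category_difference(self):
        # when ACC and yield have identical h2 and genetic correlation 1 the
        # three categories pick interchangeable lines (the covariate slope of
        # the animal model converges to the environmental slope, leaving
        # Yield|ACC BLUPs ~ Yield BLUPs), so no category pair differs
        # significantly in the follow-up trial
        from canopyselect.gblup import (
            AnimalModelSpec,
            ChainConfig,
            fit_trait_with_covariate,
            gibbs_animal_model,
            precompute_animal_design,
        )
        from canopyselect.pedigree import build_a_matrix
        from canopyselect.selection import select_top
        from canopyselect.synth import (
            GeneticArchitecture,
            augmented_layout,
            simulate_breeding_values,
            simulate_pedigree,
            simulate_trial,
            terminal_lines,
        )

        arch = GeneticArchitecture(
            ("yield", "acc"), [0.3, 0.3], [[1.0, 1.0], [1.0, 1.0]],
            [10.0, 0.1], [100.0, 0.5],
        )
        ped = simulate_pedigree(12, 400, 2, seed=31)
        amat = build_a_matrix(ped)
        lay = augmented_layout(terminal_lines(ped), ("P0000", "P0001"), seed=31)
        gen = np.random.default_rng(32)
        clean = 0
        n_experiments = 10
        design = None
        for rep in range(n_experiments):
            truth = simulate_breeding_values(ped, arch, seed=100 + rep,
                                             amatrix=amat)
            pheno = simulate_trial(lay, truth, arch, 0.0, seed=200 + rep)
            lines = sorted(set(pheno["line_id"]))
            a_sub = amat.loc(lines)
            if design is None:
                design = precompute_animal_design(a_sub, pheno)
            chain = ChainConfig(n_iter=2000, burn_in=500, thin=2, seed=rep)
            blups = {
                "Yield": gibbs_animal_model(
                    pheno, a_sub, AnimalModelSpec("yield", chain=chain),
                    design=design,
                ).blups,
                "ACC": gibbs_animal_model(
                    pheno, a_sub, AnimalModelSpec("acc", chain=chain),
                    design=design,
                ).blups,
                "Yield|ACC": fit_trait_with_covariate(
                    pheno, a_sub, None, "yield", "acc", chain=chain,
                    design=design,
                ).blups,
            }
            selected = {c: select_top(s, 0.09) for c, s in blups.items()}
            union = sorted(set().union(*selected.values()))
            rows = []
            gmap = truth.breeding_values["yield"]
            for loc in range(2):
                for r in range(2):
                    for k, lid in enumerate(union):
                        rows.append(
                            {"line_id": lid, "location": f"L{loc}", "rep": r,
                             "block": k // 10,
                             "yield_kg_ha": 100 + gmap[lid]
                             + gen.normal(0, np.sqrt(0.7) * 10)}
                        )
            fit = fit_trial_model(pd.DataFrame(rows), TrialModelSpec())
            comp = compare_categories(
                adjusted_means(fit), combine_categories(selected)
            )
            clean += (comp.table["p"] > 0.05).all()
        assert clean >= 0.9 * n_experiments
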