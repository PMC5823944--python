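import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from scnome import profiles as P
from scnome.profiles import _bernoulli_negll
from scnome.simulate import (
    simulate_ndr_expression,
    simulate_profile_cells,
)


class TestPseudobulkProfile:
    def test_window_count_arithmetic(self):
        rates = {"c": pd.DataFrame({"pos": [1], "rate": [0.5]})}
        prof = P.pseudobulk_profile(rates, 400, window=50, step=25)
        assert len(prof.starts) == 15

    def test_constant_rate_gives_flat_profile(self):
        rng = np.random.default_rng(0)
        rates = {
            f"c{i}": pd.DataFrame(
                {"pos": np.sort(rng.choice(500, 60, replace=False)) + 1, "rate": 0.7}
            )
            for i in range(5)
        }
        prof = P.pseudobulk_profile(rates, 500, window=50, step=10)
        covered = ~np.isnan(prof.mean)
        assert np.allclose(prof.mean[covered], 0.7)
        assert np.allclose(prof.sd[covered], 0.0)

    def test_window_larger_than_region_errors(self):
        with pytest.raises(ValueError, match="window"):
            P.pseudobulk_profile({}, 40, window=50, step=10)

    def test_uncovered_windows_are_missing(self):
        rates = {"c": pd.DataFrame({"pos": [10, 20], "rate": [0.5, 0.5]})}
        prof = P.pseudobulk_profile(rates, 1000, window=50, step=50)
        assert np.isnan(prof.mean[-1])

    def test_nucleosome_array_periodicity(self):
        """Simulated 190 bp repeat yields 180-200 bp peak spacing."""
        from scnome.context import partition_report
        from scnome.quant import site_rate
        from scnome.simulate import SimConfig, simulate_cells

        cfg = SimConfig(
            seed=2, n_cells=50, genome_length=60_000, n_genes=4, coverage_prob=0.3
        )
        sim = simulate_cells(cfg)
        lo, hi = 11_000, 22_000   # intergenic span
        rates = {}
        for cell, sites in sim.sites_by_cell.items():
            gpc = partition_report(sites, sim.genome)[1]
            sub = gpc[(gpc["pos"] >= lo) & (gpc["pos"] <= hi)]
            tot = (sub["n_meth"] + sub["n_unmeth"]).to_numpy()
            r, _ = site_rate(sub["n_meth"].to_numpy(), tot, 1, 1)
            rates[cell] = pd.DataFrame({"pos": sub["pos"] - lo + 1, "rate": r})
        prof = P.pseudobulk_profile(rates, hi - lo + 1, window=50, step=10)
        spacing = P.peak_spacing(prof)
        assert 180 <= spacing <= 200


class TestStratifyGenes:
    @pytest.mark.parametrize(
        "x, expected",
        [(1.9, "Low"), (2.0, "Medium"), (4.0, "Medium"), (6.0, "Medium"), (7.0, "High")],
    )
    def test_thresholds(self, x, expected):
        out = P.stratify_genes_by_expression(pd.Series({"g": x}))
        assert out["g"] == expected


class TestSelectProfiledGenes:
    def test_inclusive_boundaries(self):
        # 10 sites in exactly 40% of 10 cells -> kept
        counts = pd.DataFrame(
            [[10] * 4 + [0] * 6, [9] * 10],
            index=["borderline", "shallow"],
        )
        kept = P.select_profiled_genes(counts, min_cell_frac=0.4, min_sites=10)
        assert "borderline" in kept and "shallow" not in kept

    def test_zero_fraction_keeps_everything(self):
        counts = pd.DataFrame([[0, 0], [1, 1]], index=["a", "b"])
        assert len(P.select_profiled_genes(counts, min_cell_frac=0.0)) == 2


class TestBPRFit:
    def test_saturated_accessible_window(self):
        x = np.linspace(-1, 1, 50)
        fit = P.fit_bpr_profile(x, np.full(50, 3), np.full(50, 3))
        assert fit.predict(x, P.BasisSet()).min() >= 0.95

    def test_symmetric_data_symmetric_curve(self):
        x = np.concatenate([-np.linspace(0.1, 1, 20), np.linspace(0.1, 1, 20)])
        m = np.concatenate([np.arange(20) % 2, np.arange(20) % 2])
        n = np.ones(40, dtype=int) * 2
        m = np.minimum(m + 1, n)
        fit = P.fit_bpr_profile(x, m, n)
        grid = np.linspace(-1, 1, 101)
        curve = fit.predict(grid, P.BasisSet())
        assert np.allclose(curve, curve[::-1], atol=1e-6)

    def test_generative_recovery(self):
        """Fitted curve tracks the true curve to RMSE < 0.1 at 200 sites."""
        rng = np.random.default_rng(4)
        basis = P.BasisSet()
        w_true = rng.normal(0, 1, basis.M + 1)
        x = np.sort(rng.uniform(-1, 1, 200))
        p = basis.mean(basis.design(x) @ w_true)
        n = np.full(200, 5)
        m = rng.binomial(n, p)
        fit = P.fit_bpr_profile(x, m, n)
        grid = np.linspace(-1, 1, 201)
        rmse = np.sqrt(
            np.mean((fit.predict(grid, basis) - basis.mean(basis.design(grid) @ w_true)) ** 2)
        )
        assert rmse < 0.1

    def test_concave_objective_optimizer_agreement(self):
        """Newton solution and an independent L-BFGS run agree in the curve."""
        rng = np.random.default_rng(9)
        basis = P.BasisSet()
        grid = np.linspace(-1, 1, 101)
        for _ in range(20):
            x = np.sort(rng.uniform(-1, 1, 25))
            n = 1 + rng.poisson(1.5, 25)
            m = rng.binomial(n, 0.1 + 0.8 * np.exp(-0.5 * (x / 0.3) ** 2))
            fit = P.fit_bpr_profile(x, m, n)
            res = optimize.minimize(
                _bernoulli_negll,
                np.zeros(basis.M + 1),
                args=(basis.design(x), m.astype(float), n.astype(float), 0.01, "probit"),
                jac=True,
                method="L-BFGS-B",
                options={"maxiter": 500, "ftol": 1e-14},
            )
            other = basis.mean(basis.design(grid) @ res.x)
            assert np.abs(fit.predict(grid, basis) - other).max() < 1e-4


class TestClusterProfiles:
    def test_homogeneous_cells_choose_one_cluster(self):
        data, _ = simulate_profile_cells(n_cells=40, true_k=1, seed=5)
        res = P.cluster_profiles(data, (1, 2, 3, 4), seed=5)
        assert res.k == 1

    def test_two_separated_groups_recovered(self):
        hits, accs = 0, []
        for seed in range(5):
            data, labels = simulate_profile_cells(n_cells=40, true_k=2, seed=seed)
            res = P.cluster_profiles(data, (1, 2, 3, 4), seed=seed)
            if res.k == 2:
                hits += 1
                a = (res.assignments == labels).mean()
                accs.append(max(a, 1 - a))
        assert hits >= 4
        assert np.mean(accs) >= 0.9

    def test_bic_defined_for_every_attempted_k(self):
        data, _ = simulate_profile_cells(n_cells=20, true_k=2, seed=2)
        res = P.cluster_profiles(data, (1, 2, 3), seed=2)
        assert set(res.bic) == {1, 2, 3}
        assert all(np.isfinite(v) for v in res.bic.values())

    def test_k1_equals_pooled_fit(self):
        """The K=1 mixture log-likelihood equals the pooled single fit."""
        data, _ = simulate_profile_cells(n_cells=10, true_k=1, seed=3)
        res = P.cluster_profiles(data, (1,), seed=3)
        x = np.concatenate([d[0] for d in data])
        m = np.concatenate([d[1] for d in data])
        n = np.concatenate([d[2] for d in data])
        pooled = P.fit_bpr_profile(x, m, n)
        assert res.loglik == pytest.approx(pooled.loglik, abs=1e-4)

    def test_too_few_cells_rejected(self):
        data, _ = simulate_profile_cells(n_cells=2, true_k=1, seed=1)
        with pytest.raises(ValueError):
            P.cluster_profiles(data[:1])


class TestHeterogeneityReport:
    def _mixtures(self, ks):
        return {
            f"g{i}": P.MixtureResult(
                gene_id=f"g{i}", k=k, bic={}, assignments=np.zeros(2, int),
                cluster_weights=np.zeros((k, 10)), mixing=np.ones(k) / k, loglik=0.0,
            )
            for i, k in enumerate(ks)
        }

    def test_expression_decreases_with_k(self):
        """Homogeneous (K=1) genes simulated with higher expression."""
        rng = np.random.default_rng(0)
        ks = [1] * 30 + [2] * 30 + [3] * 30
        expr = pd.Series(
            np.concatenate(
                [rng.normal(7, 1, 30), rng.normal(4, 1, 30), rng.normal(2, 1, 30)]
            ),
            index=[f"g{i}" for i in range(90)],
        )
        rep = P.heterogeneity_report(self._mixtures(ks), expr)
        med = rep.set_index("k")["median_expression"]
        assert med[1] > med[2] > med[3]

    def test_marks_columns_optional(self):
        rep = P.heterogeneity_report(
            self._mixtures([1, 1]), pd.Series({"g0": 1.0, "g1": 2.0})
        )
        assert not any(c.startswith("frac_") for c in rep.columns)
        marks = pd.Series({"g0": "bivalent", "g1": "active"})
        rep2 = P.heterogeneity_report(
            self._mixtures([1, 1]), pd.Series({"g0": 1.0, "g1": 2.0}), marks
        )
        assert "frac_bivalent" in rep2.columns

    def test_single_k_single_row(self):
        rep = P.heterogeneity_report(
            self._mixtures([2, 2]), pd.Series({"g0": 1.0, "g1": 2.0})
        )
        assert len(rep) == 1


class TestPredictExpression:
    def test_noiseless_linear_function_is_recovered(self):
        rng = np.random.default_rng(1)
        genes = [f"g{i}" for i in range(60)]
        X = pd.DataFrame(rng.normal(0, 1, (60, 5)), index=genes)
        beta = rng.normal(0, 1, 5)
        expr = pd.DataFrame({"cell": X.to_numpy() @ beta + 3.0}, index=genes)
        out = P.predict_expression({"cell": X}, expr, folds=10, seed=0)
        assert out.loc["cell", "cv_r"] >= 0.99

    def test_permuted_expression_has_no_signal(self):
        rng = np.random.default_rng(2)
        rs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            genes = [f"g{i}" for i in range(80)]
            X = pd.DataFrame(rng.normal(0, 1, (80, 4)), index=genes)
            y = X.to_numpy() @ np.ones(4)
            expr = pd.DataFrame({"c": rng.permutation(y)}, index=genes)
            out = P.predict_expression({"c": X}, expr, folds=5, seed=seed)
            rs.append(out.loc["c", "cv_r"])
        assert abs(np.median(rs)) < 0.1

    def test_profiles_beat_rates_when_shape_carries_signal(self):
        """NDR-depth-coded expression favours profile features."""
        wins = 0
        for seed in range(5):
            data, expr, _ = simulate_ndr_expression(
                n_genes=40, n_cells=8, seed=seed
            )
            basis = P.BasisSet()
            prof_f, rate_f = {}, {}
            for cell in expr.columns:
                Pw, Rw = {}, {}
                for g in expr.index:
                    x, m, n = data[(g, cell)]
                    Pw[g] = P.fit_bpr_profile(x, m, n, basis=basis).weights
                    Rw[g] = [m.sum() / n.sum()]
                prof_f[cell] = pd.DataFrame.from_dict(Pw, orient="index")
                rate_f[cell] = pd.DataFrame.from_dict(Rw, orient="index")
            rp = P.predict_expression(prof_f, expr, folds=5, seed=seed)
            rr = P.predict_expression(rate_f, expr, folds=5, seed=seed)
            wins += rp["cv_r"].mean() > rr["cv_r"].mean()
        assert wins >= 4

    def test_fewer_genes_than_features_rejected(self):
        X = pd.DataFrame(np.eye(4), index=list("abcd"))
        expr = pd.DataFrame({"c": [1.0, 2, 3, 4]}, index=list("abcd"))
        with pytest.raises(ValueError, match="fewer genes"):
            P.predict_expression({"c": X}, expr)


class TestFisherEnrichment:
    def test_hypergeometric_oracle(self):
        universe = [f"g{i}" for i in range(1000)]
        query = universe[:50]
        gene_set = universe[:10] + universe[50:140]  # 10 in-query, 90 outside
        out = P.fisher_enrichment(query, universe, {"s": gene_set})
        assert out["odds_ratio"].iloc[0] == pytest.approx(
            (10 * 860) / (40 * 90), abs=1e-9
        )
        p_oracle = stats.fisher_exact([[10, 40], [90, 860]])[1]
        assert out["p"].iloc[0] == pytest.approx(p_oracle, rel=1e-9)

    def test_disjoint_set(self):
        universe = [f"g{i}" for i in range(1000)]
        out = P.fisher_enrichment(
            universe[:50], universe, {"s": universe[990:]}
        )
        assert out["odds_ratio"].iloc[0] == 0.0
        assert out["p"].iloc[0] > 0.5

    def test_query_equals_universe(self):
        universe = [f"g{i}" for i in range(100)]
        out = P.fisher_enrichment(universe, universe, {"s": universe[:30]})
        assert out["p"].iloc[0] == pytest.approx(1.0)

    def test_empty_query_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            P.fisher_enrichment([], ["g1"], {"s": ["g1"]})
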