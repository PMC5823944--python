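import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from scnome import coupling as K
from scnome.simulate import simulate_cellwise_coupling, simulate_coupled_loci
from scnome.types import RateMatrix


def oracle_weighted_pearson(x, y, w):
    """Brute-force weighted moments, written independently."""
    w = np.asarray(w, float)
    w = w / w.sum()
    mx = float(np.sum(w * x))
    my = float(np.sum(w * y))
    cov = float(np.sum(w * (np.asarray(x) - mx) * (np.asarray(y) - my)))
    vx = float(np.sum(w * (np.asarray(x) - mx) ** 2))
    vy = float(np.sum(w * (np.asarray(y) - my) ** 2))
    return cov / np.sqrt(vx * vy)


finite_floats = st.floats(-50, 50, allow_nan=False)


class TestWeightedPearson:
    def test_perfect_correlation(self):
        assert K.weighted_pearson([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)
        assert K.weighted_pearson([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_matches_brute_force_oracle(self):
        x, y, w = [0, 1, 2], [0, 1, 1], [1, 1, 2]
        assert K.weighted_pearson(x, y, w) == pytest.approx(
            oracle_weighted_pearson(x, y, w), abs=1e-12
        )

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(
        data=st.lists(
            st.tuples(finite_floats, finite_floats, st.floats(0.1, 10)),
            min_size=3,
            max_size=30,
        ),
        a=st.floats(0.1, 5),
        b=finite_floats,
    )
    def test_symmetry_and_affine_invariance(self, data, a, b):
        x, y, w = (np.array(v, float) for v in zip(*data))
        r = K.weighted_pearson(x, y, w)
        if not np.isfinite(r):
            return
        assert K.weighted_pearson(y, x, w) == pytest.approx(r, abs=1e-9)
        assert K.weighted_pearson(a * x + b, y, w) == pytest.approx(r, abs=1e-6)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        data=st.lists(
            st.tuples(finite_floats, finite_floats), min_size=3, max_size=30
        )
    )
    def test_equal_weights_reduce_to_plain_pearson(self, data):
        x, y = (np.array(v, float) for v in zip(*data))
        if np.var(x) == 0 or np.var(y) == 0:
            return
        r = K.weighted_pearson(x, y, np.full(x.size, 3.7))
        assert r == pytest.approx(stats.pearsonr(x, y).statistic, abs=1e-12)

    def test_zero_variance_is_flagged_nan(self):
        assert np.isnan(K.weighted_pearson([1, 1, 1], [1, 2, 3]))


class TestPearsonTTest:
    def test_null_r(self):
        t, p = K.pearson_t_test(0.0, 20)
        assert t == 0.0 and p == 1.0

    def test_boundary_r(self):
        t, p = K.pearson_t_test(1.0, 10)
        assert np.isinf(t) and p == 0.0

    def test_t_distribution_oracle(self):
        t, p = K.pearson_t_test(0.5, 20)
        t_expected = 0.5 * np.sqrt(18 / 0.75)
        assert t == pytest.approx(t_expected, abs=1e-9)
        assert p == pytest.approx(2 * stats.t.sf(t_expected, 18), abs=1e-12)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            K.pearson_t_test(0.5, 2)


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert K.bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_hand_step_up(self):
        q = K.bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, 0.04)

    def test_capped_at_one(self):
        assert K.bh_adjust([0.5, 0.9, 0.99]).max() <= 1.0

    def test_nan_excluded(self):
        q = K.bh_adjust([0.01, np.nan, 0.04])
        assert np.isnan(q[1]) and np.isfinite(q[0])

    def test_order_invariance(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0, 1, 50)
        perm = rng.permutation(50)
        q = K.bh_adjust(p)
        q_perm = K.bh_adjust(p[perm])
        assert np.allclose(q[perm], q_perm)

    def test_grouped_adjustment_is_per_group(self):
        p = np.array([0.01, 0.04, 0.01, 0.04])
        g = np.array(["a", "a", "b", "b"])
        q = K.bh_adjust(p, g)
        assert np.allclose(q, K.bh_adjust(p[:2]).tolist() * 2)


class TestAcrossCellsScan:
    def test_recovers_coupled_loci_with_fdr_control(self):
        """Met-expr coupling at r=-0.8 in 20/100 loci, 40 cells, 10 seeds."""
        powers, fdps = [], []
        for seed in range(10):
            met, expr, feats, coupled = simulate_coupled_loci(
                40, 100, 20, -0.8, "expr", seed=seed
            )
            res = K.across_cells_scan(met, expr, feats)
            sig = set(res.loc[res["significant"], "unit_id"])
            truth = set(feats.loc[coupled, "feature_id"])
            powers.append(len(sig & truth) / len(truth))
            fdps.append(len(sig - truth) / max(len(sig), 1))
        assert np.mean(powers) >= 0.8
        assert np.mean(fdps) <= 0.2

    def test_locus_under_min_cells_absent(self):
        met, expr, feats, _ = simulate_coupled_loci(40, 30, 5, -0.8, "expr", seed=1)
        # restrict one locus to 19 observed cells
        fid = met.features[0]
        obs_cells = met.rates.columns[met.rates.loc[fid].notna()][19:]
        met.rates.loc[fid, obs_cells] = np.nan
        met.n_sites.loc[fid, obs_cells] = np.nan
        met.se.loc[fid, obs_cells] = np.nan
        res = K.across_cells_scan(met, expr, feats)
        assert fid not in set(res["unit_id"])

    def test_sign_convention(self):
        """Negative latent coupling comes out as negative correlations."""
        met, expr, feats, coupled = simulate_coupled_loci(
            40, 60, 30, -0.8, "expr", seed=3
        )
        res = K.across_cells_scan(met, expr, feats)
        hits = res[res["significant"]]
        assert (hits["r"] < 0).mean() > 0.9

    def test_met_acc_partner(self):
        met, acc, feats, coupled = simulate_coupled_loci(
            40, 60, 30, -0.8, "acc", seed=4
        )
        res = K.across_cells_scan(met, acc, feats)
        assert res["layer_pair"].iloc[0] == "met-acc"
        assert (res.loc[res["significant"], "r"] < 0).any()

    def test_disjoint_cells_error(self):
        met, expr, feats, _ = simulate_coupled_loci(20, 10, 0, -0.8, "expr", seed=5)
        expr.columns = [f"other_{c}" for c in expr.columns]
        with pytest.raises(ValueError, match="share no cells"):
            K.across_cells_scan(met, expr, feats)


class TestAcrossGenesScan:
    def test_null_layers_centred_at_zero(self):
        medians = []
        for seed in range(10):
            met, acc, feats = simulate_cellwise_coupling(
                np.zeros(30), n_loci=60, seed=seed
            )
            percell, _ = K.across_genes_scan(met, acc, feats)
            medians.append(percell["r"].median())
        assert abs(np.median(medians)) < 0.05

    def test_global_negative_coupling_detected(self):
        """Latent rho=-0.5 for every cell gives negative per-cell r,
        within 0.15 of the latent-rate oracle."""
        met, acc, feats, (lm, la) = simulate_cellwise_coupling(
            np.full(40, -0.5), n_loci=80, seed=11, return_latent=True
        )
        percell, _ = K.across_genes_scan(met, acc, feats)
        assert percell["r"].median() < 0
        oracle = np.median(
            [np.corrcoef(lm[:, i], la[:, i])[0, 1] for i in range(40)]
        )
        assert abs(percell["r"].median() - oracle) < 0.15

    def test_pseudobulk_is_definitional(self):
        met, acc, feats = simulate_cellwise_coupling(
            np.full(25, -0.4), n_loci=40, seed=7
        )
        _, bulk = K.across_genes_scan(met, acc, feats)
        a = met.rates.where(met.n_sites >= 3)
        b = acc.rates.where(acc.n_sites >= 3)
        am, bm = a.mean(axis=1), b.mean(axis=1)
        w = met.n_sites.sum(axis=1)
        obs = am.notna() & bm.notna() & (w > 0)
        expected = K.weighted_pearson(
            am[obs].to_numpy(), bm[obs].to_numpy(), w[obs].to_numpy()
        )
        assert bulk["r"].iloc[0] == pytest.approx(expected, abs=1e-12)

    def test_cell_below_min_loci_omitted(self):
        met, acc, feats = simulate_cellwise_coupling(
            np.zeros(20), n_loci=40, seed=9
        )
        cell = met.cells[0]
        keep = met.rates.index[:5]
        met.rates.loc[~met.rates.index.isin(keep), cell] = np.nan
        res, _ = K.across_genes_scan(met, acc, feats)
        assert cell not in set(res["unit_id"])
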