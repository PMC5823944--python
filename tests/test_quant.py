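import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from scnome import quant as Q
from scnome.types import FEATURE_COLUMNS, QCThresholds


def _sites(n_meth, n_unmeth):
    return pd.DataFrame({"n_meth": n_meth, "n_unmeth": n_unmeth})


class TestEstimatePrior:
    def test_flat_method_always_uniform(self):
        sites = _sites([1] * 20, [1] * 20)
        assert Q.estimate_prior(sites, method="flat") == (1.0, 1.0)

    def test_degenerate_all_extreme_falls_back(self):
        """Equal numbers of all-0 and all-1 proportions hit maximal variance."""
        sites = _sites([0] * 10 + [5] * 10, [5] * 10 + [0] * 10)
        with pytest.warns(UserWarning, match="degenerate"):
            assert Q.estimate_prior(sites) == (1.0, 1.0)

    def test_recovers_beta_hyperparameters(self):
        rng = np.random.default_rng(0)
        r = rng.beta(5, 5, 10_000)
        n = np.full(10_000, 50)
        m = rng.binomial(n, r)
        a, b = Q.estimate_prior(_sites(m, n - m))
        assert abs(a - 5) / 5 < 0.2 and abs(b - 5) / 5 < 0.2

    def test_too_few_sites_rejected(self):
        with pytest.raises(ValueError, match="10"):
            Q.estimate_prior(_sites([1] * 5, [1] * 5))


class TestSiteRate:
    @pytest.mark.parametrize(
        "m, n, a, b, expected",
        [
            (5, 10, 1, 1, 0.5),            # flat prior: MAP = MLE
            (3, 4, 2, 2, 4.0 / 6.0),
            (0, 3, 1, 1, 0.0),
        ],
    )
    def test_map_closed_forms(self, m, n, a, b, expected):
        rate, _ = Q.site_rate(m, n, a, b)
        assert rate == pytest.approx(expected, abs=1e-12)

    def test_posterior_sd_of_zero_observed(self):
        # Beta(1, 4): sd = sqrt(4 / (25 * 6))
        _, se = Q.site_rate(0, 3, 1, 1)
        assert se == pytest.approx(np.sqrt(4 / (25 * 6)), abs=1e-12)

    def test_zero_total_is_missing_not_error(self):
        rate, se = Q.site_rate(0, 0, 1, 1)
        assert np.isnan(rate) and np.isnan(se)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(
        m=st.integers(0, 50),
        extra=st.integers(0, 50),
        a=st.floats(1.0, 20.0),
        b=st.floats(1.0, 20.0),
    )
    def test_map_interpolates_between_prior_mode_and_mle(self, m, extra, a, b):
        """The MAP always lies between the prior mode and the raw proportion."""
        n = m + extra
        if n == 0:
            return
        rate, _ = Q.site_rate(m, n, a, b)
        mle = m / n
        if a + b > 2:
            prior_mode = (a - 1) / (a + b - 2)
            lo, hi = sorted([mle, prior_mode])
            assert lo - 1e-12 <= rate <= hi + 1e-12
        else:
            assert rate == pytest.approx(mle, abs=1e-12)

    def test_se_shrinks_with_depth(self):
        depths = [2, 10, 50, 200]
        ses = [Q.site_rate(d // 2, d, 2, 2)[1] for d in depths]
        assert all(s1 > s2 for s1, s2 in zip(ses, ses[1:]))


class TestFeatureRate:
    def test_single_site_passthrough(self):
        assert Q.feature_rate([0.3], [0.05]) == (0.3, 0.05, 1)

    def test_equal_se_symmetric_mean(self):
        rate, _, n = Q.feature_rate([0.2, 0.8], [0.1, 0.1])
        assert rate == pytest.approx(0.5) and n == 2

    def test_inverse_variance_weighting_hand_example(self):
        rate, _, _ = Q.feature_rate([0.0, 0.0, 0.9], [0.1, 0.1, 0.2])
        assert rate == pytest.approx(0.1, abs=1e-12)

    def test_equal_se_equals_plain_mean(self):
        rng = np.random.default_rng(3)
        r = rng.uniform(0, 1, 20)
        rate, _, _ = Q.feature_rate(r, np.full(20, 0.07))
        assert rate == pytest.approx(r.mean(), abs=1e-12)


class TestAggregateAcrossCells:
    def test_identical_cells_have_zero_between_cell_sd(self):
        mean, sd, n = Q.aggregate_across_cells([0.4] * 5, [0.05] * 5)
        assert mean == pytest.approx(0.4) and sd == pytest.approx(0.0)

    def test_two_cell_symmetry(self):
        mean, _, _ = Q.aggregate_across_cells([0.0, 1.0], [0.1, 0.1])
        assert mean == pytest.approx(0.5)

    def test_recovers_between_cell_sd(self):
        rng = np.random.default_rng(5)
        truth = rng.normal(0.5, 0.2, 200)
        obs = truth + rng.normal(0, 0.05, 200)
        _, sd, _ = Q.aggregate_across_cells(obs, np.full(200, 0.05))
        assert 0.17 <= sd <= 0.23

    def test_single_cell_flagged(self):
        mean, sd, n = Q.aggregate_across_cells([0.3], [0.1])
        assert mean == pytest.approx(0.3) and np.isnan(sd) and n == 1


class TestRateMatrix:
    @staticmethod
    def _features():
        return pd.DataFrame(
            [
                ("chr1", 1, 100, "+", "fA", "promoter", None),
                ("chr1", 50, 150, "+", "fB", "promoter", None),
                ("chr1", 300, 400, "+", "fC", "promoter", None),
            ],
            columns=FEATURE_COLUMNS,
        )

    @staticmethod
    def _cell(positions, m=2, u=1):
        return pd.DataFrame(
            {
                "chrom": "chr1",
                "pos": positions,
                "strand": "+",
                "n_meth": m,
                "n_unmeth": u,
                "context": "CpG",
                "trinucleotide": "ACG",
            }
        )

    def test_missingness_matches_interval_overlap_oracle(self):
        cells = {
            "c1": self._cell([10, 60, 120]),
            "c2": self._cell([350]),
            "c3": self._cell([160, 250]),   # covers no feature
        }
        rm = Q.rate_matrix(cells, self._features(), prior="flat")
        oracle = pd.DataFrame(False, index=["fA", "fB", "fC"], columns=cells)
        for cell, df in cells.items():
            for _, f in self._features().iterrows():
                hit = ((df["pos"] >= f["start"]) & (df["pos"] <= f["end"])).any()
                oracle.loc[f["feature_id"], cell] = bool(hit)
        pd.testing.assert_frame_equal(rm.mask, oracle)

    def test_boundary_positions_are_inclusive(self):
        cells = {"c": self._cell([1, 100])}
        rm = Q.rate_matrix(cells, self._features(), prior="flat")
        assert rm.n_sites.loc["fA", "c"] == 2

    def test_min_sites_threshold(self):
        cells = {"c": self._cell([10, 60])}
        rm = Q.rate_matrix(cells, self._features(), prior="flat", min_sites=2)
        assert rm.mask.loc["fA", "c"] and not rm.mask.loc["fB", "c"]


class TestQCFilter:
    def test_es_preset_failures(self, qc_fixture):
        res = Q.qc_filter(qc_fixture, "es")
        assert not res.loc["cell_15", "pass_rna"]      # 200k reads < 300k
        assert "low_mapped_reads" in res.loc["cell_15", "fail_reasons"]
        assert not res.loc["cell_16", "pass_rna"]      # 16% mito > 15%
        assert not res.loc["cell_18", "pass_bs"]       # 8% mapping efficiency
        assert not res.loc["cell_20", "pass_bs"]       # 4M GpC sites < 5M
        assert res["pass"].sum() == 14

    def test_eb_preset_relaxes_depth(self, qc_fixture):
        res = Q.qc_filter(qc_fixture, "eb")
        assert res.loc["cell_15", "pass_rna"]          # 200k > 100k EB floor
        assert res.loc["cell_20", "pass_bs"]           # no GpC threshold in EB

    def test_all_thresholds_disabled_passes_everyone(self, qc_fixture):
        res = Q.qc_filter(qc_fixture, QCThresholds())
        assert res["pass"].all()

    def test_missing_statistic_names_cell_and_field(self, qc_fixture):
        broken = qc_fixture.copy()
        broken.loc["cell_03", "mito_frac"] = np.nan
        with pytest.raises(ValueError, match="cell_03.*mito_frac"):
            Q.qc_filter(broken, "es")

    def test_deterministic_output(self, qc_fixture):
        a = Q.qc_filter(qc_fixture, "es")
        b = Q.qc_filter(qc_fixture, "es")
        pd.testing.assert_frame_equal(a, b)


class TestNormalizeExpression:
    def test_scale_invariance_between_proportional_cells(self):
        rng = np.random.default_rng(0)
        base = rng.poisson(5, 2000) + 1
        counts = pd.DataFrame({"a": base, "b": 2 * base})
        norm = Q.normalize_expression(counts)
        assert np.allclose(norm["a"], norm["b"])

    def test_single_cell_is_pure_log_transform(self):
        counts = pd.DataFrame({"only": np.arange(1, 30)})
        norm = Q.normalize_expression(counts)
        assert np.allclose(norm["only"], np.log2(counts["only"] + 1))

    def test_size_factors_have_mean_one(self):
        rng = np.random.default_rng(1)
        counts = pd.DataFrame(rng.poisson(5, (500, 8)) + 1)
        assert Q.size_factors(counts).mean() == pytest.approx(1.0)

    def test_depth_differences_removed(self):
        rng = np.random.default_rng(2)
        means = rng.gamma(2, 3, 2000)
        shallow = rng.poisson(means)
        deep = rng.poisson(4 * means)
        counts = pd.DataFrame({"x1": shallow, "x4": deep})
        norm = Q.normalize_expression(counts)
        expressed = (counts > 0).all(axis=1)
        # the systematic (mean) log-fold-change must vanish; per-gene
        # Poisson noise remains
        lfc = (norm.loc[expressed, "x4"] - norm.loc[expressed, "x1"]).mean()
        assert abs(lfc) < 0.05

    def test_all_zero_cell_rejected(self):
        counts = pd.DataFrame({"ok": [1, 2], "dead": [0, 0]})
        with pytest.raises(ValueError, match="dead"):
            Q.normalize_expression(counts)
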