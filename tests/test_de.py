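"""NB GLM fitting, Wald tests, BH adjustment, DEG calling, pattern clusters."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import optimize, special, stats

from masldstage import (
    DEGThresholds,
    adjust_bh,
    build_design,
    call_severity_degs,
    cluster_deg_patterns,
    fit_gene_model,
    two_group_mouse_degs,
    wald_test,
)

LN2 = np.log(2.0)


def _design_nas(nas):
    X = np.column_stack([np.ones(len(nas)), np.asarray(nas, float)])
    return X, ["intercept", "nas"]


def _mle_oracle(y, X, offset):
    """Independent joint MLE via a generic optimizer (natural-log betas)."""
    def negll(theta):
        beta, logphi = theta[:-1], theta[-1]
        phi = np.exp(logphi)
        mu = np.exp(np.clip(X @ beta + offset, -30, 30))
        inv = 1.0 / phi
        return -np.sum(special.gammaln(y + inv) - special.gammaln(inv)
                       - special.gammaln(y + 1)
                       + y * np.log(phi * mu / (1 + phi * mu))
                       - inv * np.log1p(phi * mu))
    start = np.zeros(X.shape[1] + 1)
    start[0] = np.log(np.mean(y) + 0.5)
    start[-1] = np.log(0.1)
    res = optimize.minimize(negll, start, method="Nelder-Mead",
                            options={"xatol": 1e-8, "fatol": 1e-8,
                                     "maxiter": 20000})
    return res.x[:-1]


class TestGeneFit:
    def test_constant_gene_has_zero_slopes(self):
        nas = np.array([0, 1, 2, 3, 4, 5, 6, 7.0])
        X, names = _design_nas(nas)
        fit = fit_gene_model(np.full(8, 12), X, names, np.ones(8))
        assert abs(fit.beta_log2["nas"]) < 1e-6
        assert abs(fit.beta_log2["intercept"] - np.log2(12)) < 1e-6

    def test_all_zero_gene_yields_missing_fit(self):
        nas = np.arange(8.0)
        X, names = _design_nas(nas)
        assert fit_gene_model(np.zeros(8), X, names, np.ones(8)) is None

    def test_coefficient_scale_doubling_per_unit(self):
        # noiseless doubling per NAS unit => beta exactly 1.0 log2/unit
        nas = np.repeat([0, 1, 2, 3.0], 5)
        y = 100 * 2.0 ** nas
        X, names = _design_nas(nas)
        fit = fit_gene_model(y, X, names, np.ones(len(y)))
        assert abs(fit.beta_log2["nas"] - 1.0) < 1e-4

    def test_matches_generic_optimizer_mle(self, rng):
        # 10 simulated genes: IRLS + profile dispersion vs joint MLE oracle
        n = 60
        nas = rng.integers(0, 9, n).astype(float)
        X, names = _design_nas(nas)
        sf = np.ones(n)
        for _ in range(10):
            beta_true = rng.uniform(-0.3, 0.3)
            mu = 2.0 ** (5.0 + beta_true * nas)
            y = rng.negative_binomial(1 / 0.1, 1 / (1 + 0.1 * mu))
            if not y.any():
                continue
            fit = fit_gene_model(y.astype(float), X, names, sf)
            oracle = _mle_oracle(y.astype(float), X, np.log(sf))
            assert abs(fit.beta_log2["nas"] - oracle[1] / LN2) < 0.02

    def test_offset_absorbs_size_factors(self, rng):
        # at fixed dispersion 0 the Poisson score equations make doubling
        # counts and size factors together an exact invariance
        from masldstage.de import _irls
        n = 40
        nas = rng.integers(0, 9, n).astype(float)
        X, _ = _design_nas(nas)
        mu = 2.0 ** (6.0 + 0.2 * nas)
        y = rng.poisson(mu).astype(float)
        beta1, _, _ = _irls(y, X, np.zeros(n), phi=0.0)
        beta2, _, _ = _irls(y * 2, X, np.log(np.full(n, 2.0)), phi=0.0)
        assert abs(beta1[1] - beta2[1]) < 1e-8


class TestWald:
    def test_zero_beta_gives_p_one(self):
        from masldstage.de import GeneFit
        fit = GeneFit(beta_log2={"nas": 0.0}, se_log2={"nas": 0.3},
                      phi=0.1, converged=True, loglik=0.0)
        z, p = wald_test(fit, "nas")
        assert z == 0.0 and p == 1.0

    def test_normal_quantile_identity(self):
        from masldstage.de import GeneFit
        fit = GeneFit(beta_log2={"nas": 1.959964}, se_log2={"nas": 1.0},
                      phi=0.1, converged=True, loglik=0.0)
        _, p = wald_test(fit, "nas")
        assert abs(p - 0.05) < 1e-6

    def test_zero_se_flagged_missing(self):
        from masldstage.de import GeneFit
        fit = GeneFit(beta_log2={"nas": 0.5}, se_log2={"nas": 0.0},
                      phi=0.1, converged=True, loglik=0.0)
        z, p = wald_test(fit, "nas")
        assert np.isnan(z) and np.isnan(p)


class TestBH:
    def test_single_p_is_identity(self):
        assert adjust_bh(np.array([0.03]))[0] == pytest.approx(0.03)

    def test_hand_step_up_example(self):
        out = adjust_bh(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_missing_stays_missing(self):
        out = adjust_bh(np.array([0.01, np.nan, 0.5]))
        assert np.isnan(out[1])
        # m counts only observed p-values
        assert out[0] == pytest.approx(0.02)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_bh(np.array([0.5, 1.2]))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 10_000), st.integers(1, 40))
    def test_matches_sort_and_cummin_oracle(self, seed, m):
        rs = np.random.default_rng(seed)
        p = rs.uniform(size=m)
        out = adjust_bh(p)
        # brute-force step-up oracle
        order = np.argsort(p)
        scaled = p[order] * m / (np.arange(m) + 1)
        oracle_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
        oracle = np.empty(m)
        oracle[order] = np.minimum(oracle_sorted, 1.0)
        assert np.allclose(out, oracle, atol=1e-12)

    def test_invariant_under_permutation(self, rng):
        p = rng.uniform(size=30)
        perm = rng.permutation(30)
        out = adjust_bh(p)
        out_perm = adjust_bh(p[perm])
        assert np.allclose(out[perm], out_perm)


class TestDEGCalling:
    def _table(self, rows):
        return pd.DataFrame(rows).set_index("gene_id")

    def test_positive_nas_effect_called_up(self):
        table = self._table([dict(gene_id="g", beta_nas=0.15, padj_nas=0.01,
                                  beta_fib=0.0, padj_fib=1.0)])
        assert call_severity_degs(table)["deg_call"].iloc[0] == "up"

    def test_insignificant_effect_not_called(self):
        table = self._table([dict(gene_id="g", beta_nas=0.15, padj_nas=0.5,
                                  beta_fib=0.05, padj_fib=0.5)])
        assert call_severity_degs(table)["deg_call"].iloc[0] == "none"

    def test_six_gene_exhaustive_rule_evaluation(self):
        # manual enumeration of the threshold rule branches
        rows = [
            dict(gene_id="a", beta_nas=0.05, padj_nas=0.01, beta_fib=0.05,
                 padj_fib=0.01),                                  # below LFC
            dict(gene_id="b", beta_nas=0.15, padj_nas=0.01, beta_fib=0.0,
                 padj_fib=1.0),                                   # up via NAS
            dict(gene_id="c", beta_nas=-0.3, padj_nas=0.01, beta_fib=0.0,
                 padj_fib=1.0),                                   # down via NAS
            dict(gene_id="d", beta_nas=0.0, padj_nas=1.0, beta_fib=0.3,
                 padj_fib=0.01),                                  # up via fib
            dict(gene_id="e", beta_nas=0.3, padj_nas=0.2, beta_fib=-0.3,
                 padj_fib=0.2),                                   # not significant
            dict(gene_id="f", beta_nas=0.3, padj_nas=0.01, beta_fib=-0.3,
                 padj_fib=0.01),                                  # ambiguous
        ]
        out = call_severity_degs(self._table(rows))
        assert list(out["deg_call"]) == ["none", "up", "down", "up", "none",
                                         "none"]
        assert out["ambiguous"].tolist() == [False, False, False, False,
                                             False, True]

    def test_threshold_is_strict(self):
        table = self._table([dict(gene_id="g", beta_nas=0.1, padj_nas=0.001,
                                  beta_fib=0.2, padj_fib=0.001)])
        assert call_severity_degs(table)["deg_call"].iloc[0] == "none"

    def test_call_monotone_in_effect_size(self, rng):
        # raising |beta| at fixed padj never turns a call into none
        for _ in range(20):
            beta = rng.uniform(0, 0.5)
            padj = rng.uniform(0, 1)
            base = self._table([dict(gene_id="g", beta_nas=beta,
                                     padj_nas=padj, beta_fib=0.0,
                                     padj_fib=1.0)])
            bigger = self._table([dict(gene_id="g", beta_nas=beta + 0.2,
                                       padj_nas=padj, beta_fib=0.0,
                                       padj_fib=1.0)])
            call0 = call_severity_degs(base)["deg_call"].iloc[0]
            call1 = call_severity_degs(bigger)["deg_call"].iloc[0]
            if call0 == "up":
                assert call1 == "up"


class TestPatternClustering:
    def _samples(self, nas):
        return pd.DataFrame({
            "sample_id": [f"s{i}" for i in range(len(nas))],
            "batch": "b1", "sex": "M", "species": "human",
            "nas": np.asarray(nas, float),
            "fibrosis": np.clip(np.rint(np.asarray(nas) / 2), 0, 4),
            "group": "g",
        }).set_index("sample_id", drop=False)

    def _patterned_expr(self, rng, n_per=8):
        nas = np.repeat(np.arange(9), 6).astype(float)
        samples = self._samples(nas)
        down = np.vstack([-1.0 * nas + rng.normal(0, 0.05, nas.size)
                          for _ in range(n_per)])
        up = np.vstack([1.0 * nas + rng.normal(0, 0.05, nas.size)
                        for _ in range(n_per)])
        updown = np.vstack([
            (np.minimum(nas, 5) - np.maximum(nas - 5, 0))
            + rng.normal(0, 0.05, nas.size) for _ in range(n_per)])
        expr = pd.DataFrame(
            np.vstack([down, up, updown]),
            index=[f"g{i}" for i in range(3 * n_per)],
            columns=samples.index)
        labels = np.repeat([0, 1, 2], n_per)
        return expr, samples, labels

    def test_recovers_three_planted_patterns(self, rng):
        expr, samples, truth = self._patterned_expr(rng)
        found = cluster_deg_patterns(expr, samples, k=3).to_numpy()
        # purity 1.0 up to label permutation
        for t in np.unique(truth):
            members = found[truth == t]
            assert len(np.unique(members)) == 1
        assert len(np.unique(found)) == 3

    def test_single_cluster(self, rng):
        expr, samples, _ = self._patterned_expr(rng, n_per=2)
        found = cluster_deg_patterns(expr, samples, k=1)
        assert (found == 0).all()

    def test_duplicated_genes_co_cluster(self, rng):
        expr, samples, _ = self._patterned_expr(rng, n_per=4)
        dup = expr.copy()
        dup.loc["g0_copy"] = expr.loc["g0"]
        found = cluster_deg_patterns(dup, samples, k=3)
        assert found["g0_copy"] == found["g0"]

    def test_fewer_genes_than_clusters_fails(self, rng):
        expr, samples, _ = self._patterned_expr(rng, n_per=4)
        with pytest.raises(ValueError):
            cluster_deg_patterns(expr.iloc[:2], samples, k=3)


class TestTwoGroup:
    def _dataset(self, rng, lfc=2.0, n_per=6, n_genes=30):
        mu0 = 200.0
        group = np.array(["ctrl"] * n_per + ["diet"] * n_per)
        counts = np.empty((n_genes, 2 * n_per), dtype=int)
        phi = 0.05
        for g in range(n_genes):
            m = np.where((group == "diet") & (g == 0), mu0 * 2 ** lfc, mu0)
            counts[g] = rng.negative_binomial(1 / phi, 1 / (1 + phi * m))
        frame = pd.DataFrame(counts, index=[f"g{i}" for i in range(n_genes)],
                             columns=[f"s{j}" for j in range(2 * n_per)])
        samples = pd.DataFrame({
            "sample_id": frame.columns, "batch": "b", "sex": "M",
            "species": "mouse", "nas": np.nan, "fibrosis": np.nan,
            "group": group,
        }).set_index("sample_id", drop=False)
        return frame, samples

    def test_planted_fourfold_gene_called_up(self, rng):
        counts, samples = self._dataset(rng, lfc=2.0)
        table = two_group_mouse_degs(counts, samples)
        assert table.loc["g0", "deg_call"] == "up"
        assert abs(table.loc["g0", "lfc"] - 2.0) < 0.6

    def test_null_genes_rarely_called(self, rng):
        counts, samples = self._dataset(rng, lfc=0.0, n_genes=80)
        table = two_group_mouse_degs(counts, samples)
        assert (table["deg_call"] != "none").sum() <= 2

    def test_single_group_fails(self, rng):
        counts, samples = self._dataset(rng)
        samples["group"] = "ctrl"
        with pytest.raises(ValueError, match="two groups"):
            two_group_mouse_degs(counts, samples)

    def test_undersized_group_fails(self, rng):
        counts, samples = self._dataset(rng)
        samples.iloc[:-1, samples.columns.get_loc("group")] = "ctrl"
        with pytest.raises(ValueError, match="fewer than 2"):
            two_group_mouse_degs(counts, samples)


def test_design_matrix_rejects_aliased_covariates(toy_samples):
    samples = toy_samples.copy()
    samples["sex"] = samples["batch"]      # sex aliased with batch
    with pytest.raises(ValueError, match="aliased"):
        build_design(samples)


def test_design_matrix_columns(toy_samples):
    X, names = build_design(toy_samples)
    assert names == ["intercept", "batch[b2]", "sex[M]", "nas", "fibrosis"]
    assert X.shape == (len(toy_samples), 5)
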