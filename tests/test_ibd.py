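"""Mantel tests and beta-regression IBD model tests."""

from itertools import permutations as iter_permutations

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from polypopgen.distances import DistanceMatrix
from polypopgen.ibd import (
    cluster_indicator_matrix,
    fit_beta_regression,
    him_ssm_protocol,
    mantel,
    rescale_to_unit,
)


def _dm(v, labels=None, kind="generic"):
    v = np.asarray(v, float)
    labels = labels or [f"x{i}" for i in range(len(v))]
    return DistanceMatrix(labels, v, kind)


def _random_dm(rng, n, labels=None):
    v = rng.random((n, n))
    v = (v + v.T) / 2
    np.fill_diagonal(v, 0)
    return _dm(v, labels)


class TestMantel:
    def test_self_correlation_is_one(self, rng):
        a = _random_dm(rng, 8)
        res = mantel(a, a, permutations=99, seed=1)
        assert res.r == pytest.approx(1.0)
        assert res.p <= 0.05

    def test_affine_invariance(self, rng):
        a = _random_dm(rng, 8)
        b = _random_dm(rng, 8)
        r1 = mantel(a, b, permutations=9, seed=0).r
        b2 = _dm(2.5 * b.values + _offdiag_shift(b.values, 3.0))
        r2 = mantel(a, b2, permutations=9, seed=0).r
        assert r1 == pytest.approx(r2)

    def test_exact_p_against_full_enumeration(self, rng):
        """Standard-scheme p equals exhaustive enumeration over all n! label
        permutations for n=5 (asymptotically, using every permutation once)."""
        n = 5
        a = _random_dm(rng, n)
        b = _random_dm(rng, n)
        iu = np.triu_indices(n, 1)
        vb = b.values[iu]
        r_obs = np.corrcoef(a.values[iu], vb)[0, 1]
        count = 0
        total = 0
        for perm in iter_permutations(range(n)):
            pa = a.values[np.ix_(perm, perm)][iu]
            if np.corrcoef(pa, vb)[0, 1] >= r_obs - 1e-12:
                count += 1
            total += 1
        exact_p = count / total
        res = mantel(a, b, permutations=4999, seed=11)
        assert res.p == pytest.approx(exact_p, abs=0.03)

    def test_constant_matrix_error(self):
        a = _dm(np.zeros((4, 4)))
        b = _dm(1 - np.eye(4))
        with pytest.raises(ValueError):
            mantel(a, b, permutations=9)

    def test_stratified_reduces_to_standard_with_one_stratum(self, rng):
        a = _random_dm(rng, 7)
        b = _random_dm(rng, 7)
        strata = {l: "s" for l in a.labels}
        r1 = mantel(a, b, "standard", 199, seed=4)
        r2 = mantel(a, b, "stratified", 199, strata=strata, seed=4)
        assert r1.r == pytest.approx(r2.r)
        assert r1.p == pytest.approx(r2.p)

    def test_partial_removes_confound(self, rng):
        """a and b both driven by c only: partial r|c is near zero."""
        n = 15
        c = _random_dm(rng, n)
        noise_a = 0.05 * _random_dm(rng, n).values
        noise_b = 0.05 * _random_dm(rng, n).values
        a = _dm(c.values + noise_a)
        b = _dm(c.values + noise_b)
        full = mantel(a, b, "standard", 99, seed=0)
        part = mantel(a, b, "partial", 99, covariate=c, seed=0)
        assert full.r > 0.9
        assert abs(part.r) < 0.35


def _offdiag_shift(v, c):
    out = np.full_like(v, c)
    np.fill_diagonal(out, 0)
    return out


class TestHimSsmProtocol:
    @staticmethod
    def _layout(rng, n_clusters=3, per=3):
        labels = [f"C{c}P{p}" for c in range(n_clusters) for p in range(per)]
        clusters = {l: l.split("P")[0] for l in labels}
        coords = {}
        for c in range(n_clusters):
            cx, cy = 10.0 * c, 5.0 * (c % 2)
            for p in range(per):
                coords[f"C{c}P{p}"] = (cx + rng.normal(scale=0.7), cy + rng.normal(scale=0.7))
        n = len(labels)
        geo = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                xi, yi = coords[labels[i]]
                xj, yj = coords[labels[j]]
                geo[i, j] = geo[j, i] = np.hypot(xi - xj, yi - yj)
        return labels, clusters, _dm(geo, labels, "geographic")

    def test_pure_hierarchical_pattern(self, rng):
        labels, clusters, geo = self._layout(rng)
        n = len(labels)
        gen = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                base = 0.8 if clusters[labels[i]] != clusters[labels[j]] else 0.1
                gen[i, j] = gen[j, i] = base + rng.normal(scale=0.02)
        gen = np.abs(gen)
        table = him_ssm_protocol(_dm(gen, labels, "nei"), geo, clusters, permutations=499, seed=2)
        stratified = table[table.adjustment.str.startswith("stratified")].iloc[0]
        cluster_test = table[table.matrix_b == "clusters"].iloc[0]
        assert stratified.p > 0.05  # no within-cluster IBD
        assert cluster_test.p <= 0.05  # cluster effect net of geography

    def test_pure_stepping_stone_pattern(self, rng):
        labels, clusters, geo = self._layout(rng)
        g = geo.values / geo.values.max()
        noise = 0.03 * _random_dm(rng, len(labels)).values
        gen = np.abs(0.05 + 0.6 * g + noise)
        np.fill_diagonal(gen, 0)
        table = him_ssm_protocol(_dm(gen, labels, "nei"), geo, clusters, permutations=499, seed=3)
        partial_geo = table[
            (table.matrix_b == "geographic") & table.adjustment.str.startswith("partial")
        ].iloc[0]
        assert partial_geo.p <= 0.05
        assert partial_geo.r > 0.5

    def test_single_cluster_degenerates_to_two_tests(self, rng):
        labels, _, geo = self._layout(rng, n_clusters=1, per=6)
        gen = _random_dm(rng, 6, labels)
        clusters = {l: "only" for l in labels}
        table = him_ssm_protocol(gen, geo, clusters, permutations=99, seed=0)
        assert len(table) == 2  # partial tests impossible without >=2 clusters
        std = table.iloc[0]
        strat = table.iloc[1]
        assert std.r == pytest.approx(strat.r)


class TestBetaRegression:
    def test_parameter_recovery(self, rng):
        n = 500
        x = rng.uniform(0, 1, n)
        beta = np.array([-1.0, 0.5])
        phi = 30.0
        mu = expit(beta[0] + beta[1] * x)
        y = rng.beta(mu * phi, (1 - mu) * phi)
        y = np.clip(y, 1e-6, 1 - 1e-6)
        fit = fit_beta_regression(y, pd.DataFrame({"x": x}))
        assert fit.coefficients["const"] == pytest.approx(beta[0], abs=3 * fit.std_errors["const"])
        assert fit.coefficients["x"] == pytest.approx(beta[1], abs=3 * fit.std_errors["x"])
        assert fit.precision == pytest.approx(phi, rel=0.35)
        assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * 3)

    def test_constant_model_symmetric_response(self, rng):
        y = np.concatenate([0.5 - rng.uniform(0.05, 0.3, 100), 0.5 + rng.uniform(0.05, 0.3, 100)])
        fit = fit_beta_regression(y, pd.DataFrame(index=range(200)))
        assert abs(fit.coefficients["const"]) < 0.1

    def test_response_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            fit_beta_regression(np.array([0.2, 1.2, 0.5, 0.4, 0.3]), pd.DataFrame({"x": np.arange(5)}))

    def test_noise_covariate_rarely_helps_much(self, rng):
        improved = 0
        for t in range(20):
            x = rng.uniform(0, 1, 60)
            mu = expit(-0.5 + 1.0 * x)
            y = np.clip(rng.beta(mu * 20, (1 - mu) * 20), 1e-6, 1 - 1e-6)
            f0 = fit_beta_regression(y, pd.DataFrame({"x": x}))
            f1 = fit_beta_regression(y, pd.DataFrame({"x": x, "z": rng.uniform(0, 1, 60)}))
            if f1.aic < f0.aic - 2:
                improved += 1
        assert improved <= 4  # adding noise should rarely beat by >2 AIC

    def test_rescale_to_unit(self):
        y, rec = rescale_to_unit(np.array([0.0, 1.0, 2.0, 5.0]))
        assert (y > 0).all() and (y < 1).all()
        assert rec["min"] == 0.0 and rec["max"] == 5.0

    def test_gradient_near_zero_at_optimum(self, rng):
        from statsmodels.othermod.betareg import BetaModel

        x = rng.uniform(0, 1, 120)
        mu = expit(0.3 - 0.8 * x)
        y = np.clip(rng.beta(mu * 15, (1 - mu) * 15), 1e-6, 1 - 1e-6)
        X = pd.DataFrame({"x": x})
        fit = fit_beta_regression(y, X)
        Xd = X.copy()
        Xd.insert(0, "const", 1.0)
        model = BetaModel(y, Xd)
        params = np.concatenate([fit.coefficients.values, [np.log(fit.precision)]])
        grad = model.score(params)
        assert np.linalg.norm(grad) / len(y) < 1e-3


class TestClusterIndicator:
    def test_definition(self):
        m = cluster_indicator_matrix(["a", "b", "c"], {"a": "X", "b": "X", "c": "Y"})
        assert m.values[0, 1] == 0
        assert m.values[0, 2] == 1
        assert np.allclose(m.values, m.values.T)
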