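"""Correlation, soft-threshold, TOM and module-detection numerics."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import linalg

from lncmodnet import (
    WGCNA,
    bicor,
    bicor_matrix,
    detect_modules,
    merge_close_modules,
    module_eigengenes,
    module_membership,
    pick_soft_threshold,
    scale_free_fit,
    tom_similarity,
)


def _bicor_oracle(x, y):
    """Step-by-step evaluation of the biweight midcorrelation formula."""
    def transform(v):
        v = np.asarray(v, float)
        med = np.median(v)
        mad = np.median(np.abs(v - med))
        u = (v - med) / (9 * mad)
        w = np.where(np.abs(u) < 1, (1 - u**2) ** 2, 0.0)
        return (v - med) * w

    xt, yt = transform(x), transform(y)
    return float(np.dot(xt, yt) / np.sqrt((xt**2).sum() * (yt**2).sum()))


class TestBicor:
    def test_self_correlation_is_one(self):
        assert bicor([1, 2, 3, 4, 5], [1, 2, 3, 4, 5]) == pytest.approx(1.0)

    def test_exact_anticorrelation(self):
        assert bicor([1, 2, 3, 4, 5], [5, 4, 3, 2, 1]) == pytest.approx(-1.0)

    def test_outlier_case_matches_oracle_and_differs_from_pearson(self):
        x, y = [1, 2, 3, 4, 100], [1, 2, 3, 4, 5]
        got = bicor(x, y)
        assert got == pytest.approx(_bicor_oracle(x, y), abs=1e-12)
        assert abs(got - np.corrcoef(x, y)[0, 1]) > 0.05

    @pytest.mark.parametrize("a,b", [(2.0, 3.0), (0.5, -10.0)])
    def test_affine_invariance_and_antisymmetry(self, a, b):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=20), rng.normal(size=20)
        base = bicor(x, y)
        assert bicor(a * x + b, y) == pytest.approx(base, abs=1e-12)
        assert bicor(-a * x + b, y) == pytest.approx(-base, abs=1e-12)

    def test_constant_vector_raises_and_zero_mad_falls_back(self):
        with pytest.raises(ValueError):
            bicor([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        # zero MAD but non-constant on both sides: Pearson fallback exactly
        x = [0.0, 0.0, 0.0, 0.0, 10.0]
        y = [0.0, 0.0, 0.0, 2.0, 0.0]
        assert bicor(x, y) == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-12)

    def test_matrix_equals_pairwise_loop(self):
        rng = np.random.default_rng(3)
        expr = pd.DataFrame(rng.normal(size=(8, 15)))
        mat = bicor_matrix(expr)
        for i in range(8):
            for j in range(i + 1, 8):
                assert mat.iloc[i, j] == pytest.approx(
                    bicor(expr.iloc[i], expr.iloc[j]), abs=1e-12
                )


class TestScaleFreeFit:
    def test_power_law_sample_scores_high(self):
        rng = np.random.default_rng(0)
        # exact discrete power law p(k) ~ k^-2 on 1..50
        ks = np.arange(1, 51)
        p = ks**-2.0
        k = rng.choice(ks, size=5000, p=p / p.sum()).astype(float)
        assert scale_free_fit(k) > 0.9

    def test_all_equal_returns_zero_with_warning(self):
        with pytest.warns(UserWarning):
            assert scale_free_fit(np.full(50, 3.0)) == 0.0

    def test_increasing_distribution_scores_negative(self):
        rng = np.random.default_rng(1)
        ks = np.arange(1, 51)
        p = ks**2.0
        k = rng.choice(ks, size=5000, p=p / p.sum()).astype(float)
        assert scale_free_fit(k) < 0


class TestPickSoftThreshold:
    def test_returns_lowest_qualifying_power(self, default_run):
        table = default_run.wgcna.fit_table_
        beta = default_run.wgcna.power_
        if table["qualified"].iloc[0]:
            qualifying = table[table["fit"] >= 0.8]["power"]
            assert beta == qualifying.min()

    def test_fit_table_matches_bruteforce_double_loop(self):
        rng = np.random.default_rng(5)
        expr = pd.DataFrame(rng.normal(size=(30, 24)))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _beta, table = pick_soft_threshold(expr, powers=[2, 5])
        r = bicor_matrix(expr).to_numpy()
        for _, row in table.iterrows():
            k = np.array(
                [
                    sum(
                        abs(r[i, j]) ** row["power"]
                        for j in range(30)
                        if j != i
                    )
                    for i in range(30)
                ]
            )
            assert row["fit"] == pytest.approx(scale_free_fit(k), abs=1e-12)
            assert row["mean_k"] == pytest.approx(k.mean(), abs=1e-9)

    def test_too_few_genes_raises(self):
        with pytest.raises(ValueError):
            pick_soft_threshold(pd.DataFrame(np.ones((1, 10))))


def _tom_oracle(a):
    """Cubic-time triple loop TOM."""
    a = a.copy()
    np.fill_diagonal(a, 0.0)
    n = a.shape[0]
    t = np.eye(n)
    k = a.sum(axis=1)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
            t[i, j] = (l + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return t


class TestTOM:
    def test_empty_network(self):
        t = tom_similarity(np.zeros((4, 4)))
        assert np.allclose(t, np.eye(4))

    def test_fully_connected_triangle(self):
        a = np.ones((3, 3))
        t = tom_similarity(a)
        assert np.allclose(t, 1.0)  # (1 + 1) / (2 + 1 - 1)

    def test_matches_triple_loop_oracle(self):
        rng = np.random.default_rng(2)
        a = rng.uniform(size=(20, 20))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 1.0)
        assert np.allclose(tom_similarity(a), _tom_oracle(a), atol=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_bounded_in_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.uniform(size=(15, 15)) ** 2
        a = (a + a.T) / 2
        t = tom_similarity(a)
        assert t.min() >= 0 and t.max() <= 1 + 1e-12

    def test_rejects_asymmetric(self):
        a = np.zeros((3, 3))
        a[0, 1] = 0.5
        with pytest.raises(ValueError):
            tom_similarity(a)


def _block_dissim(rng, sizes, within=0.2, between=0.95, jitter=0.02):
    n = sum(sizes)
    d = np.full((n, n), between)
    start = 0
    for s in sizes:
        d[start : start + s, start : start + s] = within
        start += s
    d += rng.uniform(-jitter, jitter, size=(n, n))
    d = np.clip((d + d.T) / 2, 0, 1)
    np.fill_diagonal(d, 0.0)
    genes = [f"g{i:03d}" for i in range(n)]
    return pd.DataFrame(d, index=genes, columns=genes)


class TestDetectModules:
    def test_two_planted_blocks_recovered_exactly(self):
        from sklearn.metrics import adjusted_rand_score

        d = _block_dissim(np.random.default_rng(0), [50, 50])
        labels = detect_modules(d)
        truth = [1] * 50 + [2] * 50
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_block_below_min_size_unassigned(self):
        d = _block_dissim(np.random.default_rng(1), [50, 20])
        labels = detect_modules(d, min_module_size=30)
        assert set(labels.iloc[50:]) == {0}
        assert set(labels.iloc[:50]) == {1}

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(2)
        d = _block_dissim(rng, [40, 35])
        labels = detect_modules(d)
        perm = rng.permutation(d.shape[0])
        dp = d.iloc[perm, perm]
        labels_p = detect_modules(dp)
        pd.testing.assert_series_equal(labels_p.sort_index(), labels.sort_index())


class TestEigengenes:
    def test_rank_one_module(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=24)
        expr = pd.DataFrame([v * 3 + 1, v * 0.5 - 2, v], index=list("abc"))
        labels = pd.Series(1, index=expr.index)
        eig, pve = module_eigengenes(expr, labels)
        standardized = (v - v.mean()) / v.std(ddof=1)
        assert np.allclose(np.abs(eig.loc[1]), np.abs(standardized), atol=1e-9)
        assert pve.loc[1] == pytest.approx(1.0)

    def test_orientation_gives_nonnegative_mean_kme(self, default_run):
        modules = default_run.wgcna.modules_
        for m in modules.module_ids:
            own = modules.kme.loc[modules.genes_in(m), m]
            assert own.mean() >= 0

    def test_matches_direct_eigendecomposition(self):
        rng = np.random.default_rng(4)
        expr = pd.DataFrame(rng.normal(size=(5, 24)))
        labels = pd.Series(1, index=expr.index)
        eig, pve = module_eigengenes(expr, labels)
        z = ((expr.T - expr.T.mean()) / expr.T.std(ddof=1)).T.to_numpy()
        cov = z @ z.T
        w, v = linalg.eigh(cov)
        assert pve.loc[1] == pytest.approx(w[-1] / w.sum(), abs=1e-10)
        scores = z.T @ v[:, -1]
        assert abs(np.corrcoef(scores, eig.loc[1])[0, 1]) == pytest.approx(1.0)

    def test_unit_variance(self, default_run):
        eig = default_run.wgcna.eigengenes_
        assert np.allclose(eig.std(axis=1, ddof=1), 1.0, atol=1e-9)


class TestMerge:
    def _expr_two_modules(self, shared=True, seed=0):
        rng = np.random.default_rng(seed)
        u1 = rng.normal(size=24)
        u2 = u1 if shared else rng.normal(size=24)
        rows = [u1 * rng.uniform(0.8, 1.2) + rng.normal(0, 0.1, 24) for _ in range(10)]
        rows += [u2 * rng.uniform(0.8, 1.2) + rng.normal(0, 0.1, 24) for _ in range(10)]
        expr = pd.DataFrame(rows, index=[f"g{i}" for i in range(20)])
        labels = pd.Series([1] * 10 + [2] * 10, index=expr.index)
        return expr, labels

    def test_same_latent_factor_merged(self):
        expr, labels = self._expr_two_modules(shared=True)
        merged = merge_close_modules(expr, labels)
        assert len(merged.module_ids) == 1

    def test_orthogonal_factors_not_merged(self):
        expr, labels = self._expr_two_modules(shared=False, seed=1)
        merged = merge_close_modules(expr, labels)
        assert len(merged.module_ids) == 2

    def test_idempotent_at_fixed_height(self):
        expr, labels = self._expr_two_modules(shared=False, seed=2)
        once = merge_close_modules(expr, labels)
        twice = merge_close_modules(expr, once.labels)
        pd.testing.assert_series_equal(once.labels, twice.labels)


class TestModuleMembership:
    def test_gene_equal_to_eigengene_has_unit_kme(self):
        rng = np.random.default_rng(0)
        e = rng.normal(size=24)
        expr = pd.DataFrame([e, e * 2 + 1], index=["a", "b"])
        eig = pd.DataFrame([e / e.std(ddof=1)], index=[1], columns=expr.columns)
        kme = module_membership(expr, eig)
        assert kme.loc["a", 1] == pytest.approx(1.0, abs=1e-9)

    def test_independent_noise_gene_near_zero(self):
        rng = np.random.default_rng(42)
        e = rng.normal(size=24)
        noise = rng.normal(size=24)
        expr = pd.DataFrame([e, noise], index=["sig", "null"])
        eig = pd.DataFrame([e], index=[1], columns=expr.columns)
        kme = module_membership(expr, eig)
        assert abs(kme.loc["null", 1]) < 0.3

    def test_constant_gene_gets_zero_with_warning(self):
        rng = np.random.default_rng(1)
        e = rng.normal(size=24)
        expr = pd.DataFrame([e, np.zeros(24)], index=["sig", "flat"])
        eig = pd.DataFrame([e], index=[1], columns=expr.columns)
        with pytest.warns(UserWarning):
            kme = module_membership(expr, eig)
        assert kme.loc["flat", 1] == 0.0


class TestWGCNAEstimator:
    def test_sklearn_params_round_trip(self):
        model = WGCNA(min_module_size=40)
        assert model.get_params()["min_module_size"] == 40
        model.set_params(merge_height=0.3)
        assert model.merge_height == 0.3

    def test_adjacency_monotone_in_power(self, default_run):
        r = default_run.wgcna.correlation_.to_numpy()
        off = np.abs(r[np.triu_indices_from(r, 1)])
        off = off[off < 1]
        assert np.all(off**7 <= off**6 + 1e-15)

    def test_fixed_power_skips_selection(self, default_run):
        model = WGCNA(power=7).fit(default_run.norm.iloc[:80])
        assert model.power_ == 7 and model.fit_table_.empty
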