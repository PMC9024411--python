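"""Filtering, TMM, log-CPM and the simplified DE test against oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lncmodnet import (
    SimulationConfig,
    bh_adjust,
    differential_expression,
    filter_low_expression,
    log_cpm,
    simulate_dataset,
    tmm_factors,
)
from lncmodnet.preprocess import TMMNormalizer


def _toy_counts(design, rows):
    return pd.DataFrame(
        rows, index=[f"g{i}" for i in range(len(rows))], columns=design.samples
    )


class TestFilter:
    def test_kept_iff_cpm_reaches_one_in_at_least_four_samples(self, design):
        # filler keeps every library near 1e6 so CPM ~ count
        rows = np.vstack(
            [
                np.full(24, 999_998),
                np.r_[np.full(4, 2), np.zeros(20)],  # CPM ~2 in exactly 4 samples
                np.r_[np.full(3, 2), np.zeros(21)],  # only 3 qualifying samples
                np.full(24, 0),  # all zero
            ]
        ).astype(int)
        counts = _toy_counts(design, rows)
        kept = filter_low_expression(counts, design)
        assert list(kept.index) == ["g0", "g1"]
        # brute-force CPM evaluation agrees with the rule
        cpm = counts / counts.sum(axis=0) * 1e6
        expected = counts.index[(cpm >= 1).sum(axis=1) >= 4]
        assert list(kept.index) == list(expected)

    def test_all_zero_gene_removed_and_filter_idempotent(self, design):
        counts, _ = simulate_dataset(SimulationConfig(seed=1), design)
        counts.iloc[5] = 0
        kept = filter_low_expression(counts, design)
        assert counts.index[5] not in kept.index
        pd.testing.assert_frame_equal(filter_low_expression(kept, design), kept)

    def test_degenerate_all_filtered_raises(self, design):
        counts = _toy_counts(design, np.ones((2, 24), dtype=int))
        counts.iloc[:] = 0
        counts.iloc[0, 0] = 5
        with pytest.raises(ValueError):
            filter_low_expression(counts, design)


def _tmm_oracle(counts: np.ndarray, j: int, ref: int, trim_m=0.3, trim_a=0.05):
    """Brute-force doubly-trimmed precision-weighted mean of M-values."""
    lib = counts.sum(axis=0)
    obs, refc = counts[:, j].astype(float), counts[:, ref].astype(float)
    keep = (obs > 0) & (refc > 0)
    obs, refc = obs[keep], refc[keep]
    m = np.log2((obs / lib[j]) / (refc / lib[ref]))
    a = 0.5 * np.log2(obs / lib[j] * refc / lib[ref])
    w = (lib[j] - obs) / (lib[j] * obs) + (lib[ref] - refc) / (lib[ref] * refc)
    if np.max(np.abs(m)) < 1e-6:
        return 1.0
    n = len(m)
    lo_m, hi_m = np.floor(n * trim_m) + 1, n - np.floor(n * trim_m)
    lo_a, hi_a = np.floor(n * trim_a) + 1, n - np.floor(n * trim_a)
    rm, ra = stats.rankdata(m), stats.rankdata(a)
    sel = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    return 2.0 ** (np.sum(m[sel] / w[sel]) / np.sum(1.0 / w[sel]))


class TestTMM:
    def test_scaled_sample_gets_unit_factor(self, design):
        rng = np.random.default_rng(0)
        a = rng.poisson(100, size=200)
        counts = pd.DataFrame({"A": a, "B": 2 * a})
        f = tmm_factors(counts)
        assert np.allclose(f, 1.0, atol=1e-9)

    def test_identical_samples_unit_factors(self):
        a = np.random.default_rng(1).poisson(50, size=100)
        counts = pd.DataFrame({s: a for s in "ABCD"})
        assert np.allclose(tmm_factors(counts), 1.0)

    def test_geometric_mean_one(self, design):
        counts, _ = simulate_dataset(SimulationConfig(seed=2), design)
        f = tmm_factors(counts)
        assert np.isclose(np.exp(np.log(f).mean()), 1.0, atol=1e-12)

    def test_spiked_sample_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(7)
        base = rng.poisson(200, size=500)
        spiked = base.copy()
        spiked[:25] = spiked[:25] * 20  # strongly DE block
        counts = pd.DataFrame(
            {"A": base, "B": rng.poisson(spiked), "C": rng.poisson(base)}
        )
        f = tmm_factors(counts)
        x = counts.to_numpy(float)
        # reference chosen as in the implementation: upper-quartile rule
        lib = x.sum(axis=0)
        uq = np.array([np.quantile(x[:, j] / lib[j] * 1e6, 0.75) for j in range(3)])
        ref = int(np.argmin(np.abs(uq - uq.mean())))
        raw = np.array([_tmm_oracle(x, j, ref) for j in range(3)])
        expected = raw / np.exp(np.mean(np.log(raw)))
        assert np.allclose(f.to_numpy(), expected, rtol=1e-10)

    def test_matches_edger_on_small_matrix(self, tmp_path):
        """Cross-check against the reference R implementation."""
        import shutil
        import subprocess

        if shutil.which("Rscript") is None:
            pytest.skip("Rscript unavailable")
        rng = np.random.default_rng(11)
        counts = pd.DataFrame(
            rng.poisson(rng.uniform(20, 400, size=(120, 1)), size=(120, 4)),
            columns=list("ABCD"),
        )
        counts.iloc[:10, 0] *= 8
        path = tmp_path / "counts.tsv"
        counts.to_csv(path, sep="\t")
        script = tmp_path / "tmm.R"
        script.write_text(
            "suppressMessages(library(edgeR));"
            f"x <- as.matrix(read.delim('{path}', row.names=1));"
            "cat(calcNormFactors(x, method='TMM'), sep='\\n')"
        )
        out = subprocess.run(
            ["Rscript", "--vanilla", str(script)], capture_output=True, text=True
        )
        assert out.returncode == 0, out.stderr
        expected = np.array([float(v) for v in out.stdout.split()])
        ours = tmm_factors(counts).to_numpy()
        assert np.allclose(ours, expected, atol=1e-6), (ours, expected)


class TestLogCpm:
    def test_all_zero_equal_libraries_constant(self):
        counts = pd.DataFrame(np.zeros((5, 3), dtype=int), columns=list("ABC"))
        counts.loc["lib"] = 1000  # equal library sizes
        vals = log_cpm(counts).drop(index="lib")
        assert vals.nunique().eq(1).all() and vals.iloc[0].nunique() == 1

    def test_monotone_in_count(self):
        counts = pd.DataFrame({"A": [10, 20], "B": [10, 20]})
        doubled = counts.copy()
        doubled.iloc[0, 0] = 20
        assert (
            log_cpm(doubled, pd.Series(1.0, index=counts.columns)).iloc[0, 0]
            > log_cpm(counts, pd.Series(1.0, index=counts.columns)).iloc[0, 0]
        )

    def test_worked_cell(self):
        counts = pd.DataFrame({"A": [7, 93]})
        factors = pd.Series({"A": 1.25})
        got = log_cpm(counts, factors).iloc[0, 0]
        assert np.isclose(got, np.log2((7 + 0.5) / (100 * 1.25 + 1.0) * 1e6))

    def test_transformer_round(self, design):
        counts, _ = simulate_dataset(SimulationConfig(seed=3), design)
        norm = TMMNormalizer().fit(counts).transform(counts)
        assert norm.shape == counts.shape and np.isfinite(norm.to_numpy()).all()


def _bh_oracle(p):
    """Quadratic-time step-up: q_i = min over p_j >= p_i of m*p_j/rank_j."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    ranks = np.empty(m, int)
    ranks[order] = np.arange(1, m + 1)
    q = np.empty(m)
    for i in range(m):
        candidates = [
            min(1.0, m * p[j] / ranks[j]) for j in range(m) if p[j] >= p[i]
        ]
        q[i] = min(candidates)
    return q


class TestBH:
    def test_single_and_all_ones(self):
        assert bh_adjust([0.37]) == pytest.approx([0.37])
        assert bh_adjust([1.0, 1.0, 1.0]) == pytest.approx([1, 1, 1])

    def test_worked_stepup(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_rejects_invalid(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_bruteforce_and_statsmodels(self, seed):
        from statsmodels.stats.multitest import multipletests

        p = np.random.default_rng(seed).uniform(size=150)
        q = bh_adjust(p)
        assert np.allclose(q, _bh_oracle(p), atol=1e-12)
        assert np.allclose(q, multipletests(p, method="fdr_bh")[1], atol=1e-12)


class TestDifferentialExpression:
    def test_identical_groups_null(self, design):
        rng = np.random.default_rng(0)
        norm = pd.DataFrame(
            np.tile(rng.normal(5, 1, size=(50, 1)), (1, 24)),
            columns=design.samples,
        )
        de = differential_expression(norm, design, "DMSO_LAM")
        assert np.allclose(de["log2fc"], 0.0)
        assert (de["p"] == 1.0).all() and not de["significant"].any()

    def test_planted_responsive_genes_flagged(self, design):
        # large shift relative to the latent + residual within-group spread
        from lncmodnet.simulate import ResponsiveEffect

        cfg = SimulationConfig(
            seed=5,
            noise_sd=0.3,
            baseline_log_sd=0.3,  # keep down-shifted counts out of the
            # Poisson-noise floor so the premise (small noise) holds
            responsive_modules={
                1: ResponsiveEffect.coherent(
                    ("DMSO_LAM", "DMSO_QUE", "H2O_LIT", "H2O_VAL"), 12.0
                )
            },
        )
        counts, truth = simulate_dataset(cfg, design)
        norm = TMMNormalizer().fit_transform(counts)
        de = differential_expression(norm, design, "DMSO_LAM").set_index("gene_id")
        responsive = truth.module_genes(1)  # module 1 shifts in every contrast
        assert de.loc[responsive, "significant"].mean() >= 0.9
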