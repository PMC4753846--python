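"""Differential expression: filtering, weights, block correlation, GLS,
moderation, and FDR control machinery."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rootzone import de
from rootzone import simulate as sim


def brute_force_bh(p):
    """Literal Benjamini-Hochberg step-up with explicit monotonicity loop."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        q[i] = running
    return q


@pytest.fixture(scope="module")
def design():
    return sim.generate_design(4, 4, seed=0)


def _expr(logged, design, weights=None):
    cols = list(design["sample_id"])
    idx = [f"g{i}" for i in range(logged.shape[0])]
    if weights is None:
        weights = np.ones_like(logged)
    return de.ExpressionMatrix(
        logged=pd.DataFrame(logged, index=idx, columns=cols),
        weights=pd.DataFrame(weights, index=idx, columns=cols),
    )


def _cells(design):
    return np.array([
        sim.cell_index(t, c)
        for t, c in zip(design["tissue"], design["treatment"])
    ])


class TestFilterLowCounts:
    def test_worked_example(self, design):
        cells = _cells(design)
        y = np.zeros((3, 32), int)
        y[0] = 10                     # everywhere: kept
        y[1, cells == 3] = 7          # one full group: kept
        y[2] = 4                      # never reaches 5: dropped
        counts = pd.DataFrame(
            y, index=["a", "b", "c"], columns=design["sample_id"]
        )
        kept = de.filter_low_counts(counts, design, min_count=5)
        assert list(kept) == ["a", "b"]

    def test_brute_force_on_random_counts(self, design):
        rng = np.random.default_rng(3)
        cells = _cells(design)
        y = rng.poisson(4, size=(200, 32))
        counts = pd.DataFrame(
            y, index=[f"g{i}" for i in range(200)],
            columns=design["sample_id"],
        )
        kept = set(de.filter_low_counts(counts, design, min_count=5))
        for i in range(200):
            expect = any(
                all(y[i, j] >= 5 for j in range(32) if cells[j] == k)
                for k in range(8)
            )
            assert (f"g{i}" in kept) == expect

    def test_negative_min_count_rejected(self, design):
        counts = pd.DataFrame(
            np.ones((1, 32), int), index=["g"], columns=design["sample_id"]
        )
        with pytest.raises(ValueError, match=">= 0"):
            de.filter_low_counts(counts, design, min_count=-1)


class TestTransformAndWeight:
    def test_weights_positive_and_finite(self, design):
        rng = np.random.default_rng(4)
        counts = pd.DataFrame(
            rng.negative_binomial(5, 0.01, size=(300, 32)),
            index=[f"g{i}" for i in range(300)], columns=design["sample_id"],
        )
        expr = de.transform_and_weight(counts, design)
        w = expr.weights.to_numpy()
        assert np.all(np.isfinite(w)) and np.all(w > 0)

    def test_low_counts_downweighted(self, design):
        """NB counts: weight increases with expression (variance of log falls)."""
        rng = np.random.default_rng(5)
        mu = np.geomspace(2, 2000, 300)
        phi = 0.05
        y = sim._nb_draw(
            rng, np.repeat(mu[:, None], 32, axis=1).ravel(),
            np.full(300 * 32, phi),
        ).reshape(300, 32)
        counts = pd.DataFrame(
            y, index=[f"g{i}" for i in range(300)], columns=design["sample_id"]
        )
        expr = de.transform_and_weight(
            counts, design, effective_library_sizes=np.full(32, 1e6)
        )
        w = expr.weights.to_numpy().mean(axis=1)
        # strongly positive rank correlation between abundance and weight
        assert stats.spearmanr(mu, w).statistic > 0.8

    def test_cpm_scaling_shifts_logged_values(self, design):
        counts = pd.DataFrame(
            np.full((20, 32), 100), index=[f"g{i}" for i in range(20)],
            columns=design["sample_id"],
        )
        raw = de.transform_and_weight(counts, design, cpm_scale=False)
        cpm = de.transform_and_weight(
            counts, design, effective_library_sizes=np.full(32, 1e6 - 1)
        )
        shift = cpm.logged.to_numpy() - raw.logged.to_numpy()
        np.testing.assert_allclose(shift, 0.0, atol=1e-9)  # 100/1e6*1e6 = 100

    def test_too_few_genes_rejected(self, design):
        counts = pd.DataFrame(
            np.ones((5, 32), int), index=[f"g{i}" for i in range(5)],
            columns=design["sample_id"],
        )
        with pytest.raises(ValueError, match=">= 10"):
            de.transform_and_weight(counts, design)


class TestBlockCorrelation:
    @staticmethod
    def _simulate_logged(design, rho, n_genes, seed):
        rng = np.random.default_rng(seed)
        cells = _cells(design)
        lanes = pd.get_dummies(design["lane"]).to_numpy(float)
        sigma_u2 = rho
        sigma_e2 = 1.0 - rho
        mu = rng.normal(8.0, 1.0, size=(n_genes, 8))
        u = rng.normal(0.0, np.sqrt(sigma_u2), size=(n_genes, lanes.shape[1]))
        eps = rng.normal(0.0, np.sqrt(sigma_e2), size=(n_genes, len(design)))
        return mu[:, cells] + u @ lanes.T + eps

    def test_recovers_planted_correlation(self, design):
        logged = self._simulate_logged(design, rho=0.5, n_genes=2000, seed=6)
        rho_hat = de.estimate_block_correlation(_expr(logged, design), design)
        assert abs(rho_hat - 0.5) < 0.1

    def test_zero_when_no_lane_effects(self, design):
        logged = self._simulate_logged(design, rho=0.0, n_genes=2000, seed=7)
        rho_hat = de.estimate_block_correlation(_expr(logged, design), design)
        assert abs(rho_hat) < 0.05

    def test_invariant_to_lane_relabelling(self, design):
        logged = self._simulate_logged(design, rho=0.3, n_genes=500, seed=8)
        expr = _expr(logged, design)
        relabelled = design.copy()
        mapping = {
            lane: f"L{i}" for i, lane in enumerate(
                reversed(sorted(design["lane"].unique()))
            )
        }
        relabelled["lane"] = relabelled["lane"].map(mapping)
        a = de.estimate_block_correlation(expr, design)
        b = de.estimate_block_correlation(expr, relabelled)
        assert np.isclose(a, b, atol=1e-10)

    def test_single_lane_warns_and_returns_zero(self):
        single = sim.generate_design(1, 8, seed=0)
        rng = np.random.default_rng(9)
        logged = rng.normal(8, 1, size=(50, 8))
        with pytest.warns(UserWarning, match="single lane"):
            rho = de.estimate_block_correlation(_expr(logged, single), single)
        assert rho == 0.0


class TestFitContrasts:
    def test_noise_free_recovery(self, design):
        cells = _cells(design)
        means = np.array([[5, 7, 4, 4, 6, 3, 8, 8.5]], float)
        logged = means[:, cells]
        fits = de.fit_contrasts(_expr(logged, design), design)
        np.testing.assert_allclose(fits.log2fc[0], [2.0, 0.0, -3.0, 0.5],
                                   atol=1e-10)
        assert fits.sigma2[0] < 1e-20

    def test_reduces_to_ols_group_means(self, design):
        rng = np.random.default_rng(10)
        logged = rng.normal(8, 1, size=(30, 32))
        cells = _cells(design)
        fits = de.fit_contrasts(_expr(logged, design), design, rho=0.0)
        for g in range(30):
            gm = np.array([logged[g, cells == k].mean() for k in range(8)])
            expect = np.array([
                gm[sim.cell_index(t, "deficit")] - gm[sim.cell_index(t, "control")]
                for t in sim.TISSUES
            ])
            np.testing.assert_allclose(fits.log2fc[g], expect, atol=1e-10)
        # unscaled sd of a difference of two 4-replicate means
        np.testing.assert_allclose(
            fits.stdev_unscaled, np.sqrt(0.5), atol=1e-10
        )
        assert fits.df_residual == 24.0

    def test_estimates_unbiased_under_correlation(self, design):
        logged = TestBlockCorrelation._simulate_logged(
            design, rho=0.4, n_genes=3000, seed=11
        )
        # plant a +1 deficit effect in Mz for every gene
        cells = _cells(design)
        logged[:, cells == sim.cell_index("Mz", "deficit")] += 1.0
        fits = de.fit_contrasts(_expr(logged, design), design, rho=0.4)
        assert abs(fits.log2fc[:, 0].mean() - 1.0) < 0.05
        assert abs(fits.log2fc[:, 1:].mean()) < 0.05


class TestModeration:
    def _random_fits(self, design, n_genes=500, seed=12):
        rng = np.random.default_rng(seed)
        # heterogeneous true variances so the inverse-chi-square prior is
        # informative (finite d0)
        sd = np.exp(rng.normal(0.0, 0.5, size=n_genes))
        logged = rng.normal(8, 1, size=(n_genes, 32)) * sd[:, None]
        return de.fit_contrasts(_expr(logged, design), design)

    def test_prior_df_zero_is_classical_t(self, design):
        fits = self._random_fits(design)
        res = de.moderate_and_test(fits, prior_df=0.0)
        t_manual = fits.log2fc / (
            fits.stdev_unscaled * np.sqrt(fits.sigma2)[:, None]
        )
        got = res.pivot(
            index="gene_id", columns="tissue", values="moderated_stat"
        ).loc[fits.gene_ids, list(sim.TISSUES)].to_numpy()
        np.testing.assert_allclose(got, t_manual, atol=1e-10)
        assert res.attrs["df_total"] == fits.df_residual
        p_manual = 2 * stats.t.sf(np.abs(t_manual), fits.df_residual)
        got_p = res.pivot(
            index="gene_id", columns="tissue", values="p_value"
        ).loc[fits.gene_ids, list(sim.TISSUES)].to_numpy()
        np.testing.assert_allclose(got_p, p_manual, atol=1e-12)

    def test_prior_df_inf_uses_prior_variance(self, design):
        fits = self._random_fits(design)
        res = de.moderate_and_test(fits, prior_df=np.inf, prior_var=2.0)
        t_manual = fits.log2fc / (fits.stdev_unscaled * np.sqrt(2.0))
        got = res.pivot(
            index="gene_id", columns="tissue", values="moderated_stat"
        ).loc[fits.gene_ids, list(sim.TISSUES)].to_numpy()
        np.testing.assert_allclose(got, t_manual, atol=1e-10)
        assert np.isinf(res.attrs["df_total"])

    def test_moderated_between_limits(self, design):
        fits = self._random_fits(design)
        res = de.moderate_and_test(fits)
        d0 = res.attrs["prior_df"]
        assert 0 < d0 < np.inf
        post = (d0 * res.attrs["prior_var"] + fits.df_residual * fits.sigma2) \
            / (d0 + fits.df_residual)
        lo = np.minimum(fits.sigma2, res.attrs["prior_var"])
        hi = np.maximum(fits.sigma2, res.attrs["prior_var"])
        assert np.all(post >= lo - 1e-12) and np.all(post <= hi + 1e-12)

    def test_too_few_genes_for_prior(self, design):
        fits = self._random_fits(design, n_genes=20, seed=13)
        with pytest.raises(ValueError, match=">= 100"):
            de.moderate_and_test(fits)


class TestAdjustFdr:
    def test_worked_example(self):
        p = np.array([0.01, 0.02, 0.03, 0.04])
        # q_i = min over j>=i of p_j * m / j
        np.testing.assert_allclose(de.adjust_fdr(p), [0.04, 0.04, 0.04, 0.04])

    def test_single_and_empty(self):
        np.testing.assert_allclose(de.adjust_fdr(np.array([0.2])), [0.2])
        assert de.adjust_fdr(np.array([])).size == 0

    def test_against_brute_force(self):
        rng = np.random.default_rng(14)
        for _ in range(20):
            m = rng.integers(1, 400)
            p = rng.uniform(size=m) ** rng.uniform(0.5, 3)
            np.testing.assert_allclose(
                de.adjust_fdr(p), brute_force_bh(p), atol=1e-12
            )

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="\\[0, 1\\]"):
            de.adjust_fdr(np.array([0.5, 1.2]))


class TestSelectResponsive:
    def _results(self):
        rows = []
        table = {
            # gene: {tissue: (log2fc, q)}
            "up_all": {t: (2.0, 0.001) for t in sim.TISSUES},
            "mz_only": {"Mz": (1.5, 0.002)},
            "mixed": {"Mz": (1.5, 0.001), "St": (-1.5, 0.001)},
            "weak": {"Mz": (0.5, 0.001)},       # fails lfc cut
            "not_sig": {"Ez": (3.0, 0.5)},      # fails fdr cut
        }
        for gene, hits in table.items():
            for t in sim.TISSUES:
                lfc, q = hits.get(t, (0.0, 1.0))
                rows.append((gene, t, lfc, q))
        return pd.DataFrame(
            rows, columns=["gene_id", "tissue", "log2fc", "q_value"]
        )

    def test_worked_example(self):
        sel = de.select_responsive(self._results(), fdr_cut=0.01, lfc_cut=1.0)
        assert sel["per_tissue"]["Mz"] == {"up_all", "mz_only", "mixed"}
        assert sel["per_tissue"]["Ez"] == {"up_all"}
        assert sel["up_down"]["St"] == (1, 1)
        assert sel["n_any"] == 3
        assert sel["n_multi_tissue"] == 2      # up_all, mixed
        assert sel["n_all_tissues"] == 1       # up_all
        assert sel["n_direction_consistent"] == 1  # up_all only
        assert sel["direction_consistency"] == pytest.approx(0.5)
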