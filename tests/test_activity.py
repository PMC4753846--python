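"""Empirical-Bayes estimation, Laplace posteriors, and threshold calibration."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from rootzone import activity as act
from rootzone import simulate as sim


def quadrature_posterior_tail(y, offsets, hyper, phi, cell, threshold):
    """Exact 1-D posterior tail P(beta > T) for one cell by dense quadrature.

    Valid for fits without random effects: the per-cell posteriors factorize.
    """
    m0, v0 = hyper.beta_mean[cell], hyper.beta_var[cell]
    grid = np.linspace(m0 - 30 * np.sqrt(v0), m0 + 30 * np.sqrt(v0), 40_001)
    r = 1.0 / phi
    ll = act._nb_loglik(
        y[None, :], offsets[None, :] + grid[:, None], r
    ).sum(axis=1)
    ll -= 0.5 * (grid - m0) ** 2 / v0
    w = np.exp(ll - ll.max())
    return np.trapezoid(w[grid > threshold], grid[grid > threshold]) / np.trapezoid(w, grid)


class TestHyperparameters:
    def test_invalid_variances_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            act.Hyperparameters(np.zeros(8), np.zeros(8), 0.0, 1.0)
        with pytest.raises(ValueError, match="positive"):
            act.Hyperparameters(
                np.zeros(8), np.ones(8), 0.0, 1.0, lane_precision_rate=0.0
            )

    def test_too_few_genes_rejected(self, experiment):
        with pytest.raises(ValueError, match=">= 500"):
            act.estimate_hyperparameters(
                experiment["matrix"].counts.iloc[:100],
                experiment["design"],
                experiment["offsets"].offsets.iloc[:100],
            )

    def test_recovery_is_plausible(self, hyper, experiment):
        """On the shared 800-gene experiment the pooled estimates sit near
        the generating values (tight recovery is checked at 5,000 genes in
        the acceptance suite)."""
        cfg = experiment["config"]
        assert np.all(np.abs(hyper.beta_mean - cfg.beta_mean) < 0.5)
        assert np.all(hyper.beta_var > 0.5 * cfg.beta_var)
        assert np.all(hyper.beta_var < 2.0 * cfg.beta_var)
        assert abs(hyper.log_disp_mean - cfg.log_disp_mean) < 0.5


class TestPosteriors:
    def _small_posterior_inputs(self, rng, n_samples=8):
        design = sim.generate_design(1, n_samples, seed=0)
        gd_cells = np.array([
            sim.cell_index(t, c)
            for t, c in zip(design["tissue"], design["treatment"])
        ])
        return design, gd_cells

    def test_matches_dense_quadrature(self, default_hyper):
        """Skew-normal Laplace summaries reproduce exact 1-D posterior tails
        at the same plug-in dispersion."""
        rng = np.random.default_rng(17)
        design, cells = self._small_posterior_inputs(rng)
        gd = act._build_design(design, random_effects=False)
        threshold = np.log(2.0)
        worst = 0.0
        for _ in range(25):
            beta = rng.normal(np.log(15.0), 1.5, 8)
            phi = float(np.exp(rng.normal(np.log(0.1), 0.5)))
            mu = np.exp(beta[cells])
            y = sim._nb_draw(rng, mu, np.full(len(cells), phi)).astype(float)
            mean, sd, skew, ok = act._laplace_gene(
                y, np.zeros(len(cells)), gd, default_hyper, phi
            )
            assert ok
            p = act._sn_tail(threshold, mean, sd, skew)
            for k in range(8):
                exact = quadrature_posterior_tail(
                    y[cells == k], np.zeros((cells == k).sum()),
                    default_hyper, phi, k, threshold,
                )
                worst = max(worst, abs(p[k] - exact))
        assert worst <= 0.02

    def test_tighter_prior_shrinks_posterior(self, default_hyper):
        design, cells = self._small_posterior_inputs(np.random.default_rng(0))
        counts = pd.DataFrame(
            np.full((1, 8), 40), index=["g"], columns=design["sample_id"]
        )
        offsets = pd.DataFrame(
            np.zeros((1, 8)), index=["g"], columns=design["sample_id"]
        )
        tight = act.Hyperparameters(
            beta_mean=np.zeros(8), beta_var=np.full(8, 1e-4),
            log_disp_mean=default_hyper.log_disp_mean,
            log_disp_var=default_hyper.log_disp_var,
        )
        post_tight = act.fit_posteriors(
            counts, design, offsets, tight,
            random_effects=False, sample_adjustment=False,
        )
        post_wide = act.fit_posteriors(
            counts, design, offsets, default_hyper,
            random_effects=False, sample_adjustment=False,
        )
        # a near-degenerate prior at 0 pins the posterior near 0
        assert np.all(np.abs(post_tight["posterior_mean"]) < 0.05)
        assert np.all(post_wide["posterior_mean"] > 3.0)

    def test_directional_probabilities(self, experiment, hyper):
        """All-zero genes get small p_exceed, abundant genes get large."""
        mat, design = experiment["matrix"], experiment["design"]
        counts = mat.counts.iloc[:40]
        offsets = experiment["offsets"].offsets.iloc[:40]
        zero = counts.copy()
        zero.iloc[0] = 0
        big = counts.copy()
        big.iloc[1] = 5000
        for frame in (zero, big):
            post = act.fit_posteriors(frame, design, offsets, hyper)
            p = act.p_exceed(post, np.log(2.0))
            by_gene = p.groupby(post["gene_id"]).agg(["min", "max"])
            if frame is zero:
                assert by_gene.loc[counts.index[0], "max"] < 0.1
            else:
                assert by_gene.loc[counts.index[1], "min"] > 0.95

    def test_p_exceed_monotone_in_threshold(self, experiment, hyper):
        mat, design = experiment["matrix"], experiment["design"]
        post = act.fit_posteriors(
            mat.counts.iloc[:30], design,
            experiment["offsets"].offsets.iloc[:30], hyper,
        )
        thresholds = np.linspace(-3.0, 5.0, 33)
        probs = np.column_stack([act.p_exceed(post, t) for t in thresholds])
        assert np.all(np.diff(probs, axis=1) <= 1e-12)

    def test_calls_strictly_above_half(self):
        """p_exceed exactly 0.5 must NOT be called active."""
        post = pd.DataFrame(
            {
                "gene_id": ["g"] * 8,
                "cell": list(sim.CELL_LABELS),
                "posterior_mean": [1.0] * 8,
                "posterior_sd": [0.3] * 8,
            }
        )
        calls = act.call_activity(post, threshold=1.0)
        p = calls.attrs["probabilities"]
        assert np.allclose(p.to_numpy(), 0.5)
        assert not calls.to_numpy().any()

    def test_gene_order_invariance(self, experiment, hyper):
        mat, design = experiment["matrix"], experiment["design"]
        counts = mat.counts.iloc[:25]
        offsets = experiment["offsets"].offsets.iloc[:25]
        post = act.fit_posteriors(counts, design, offsets, hyper)
        post_r = act.fit_posteriors(
            counts.iloc[::-1], design, offsets.iloc[::-1], hyper
        )
        a = post.set_index(["gene_id", "cell"]).sort_index()
        b = post_r.set_index(["gene_id", "cell"]).sort_index()
        pd.testing.assert_frame_equal(a, b)


class TestSkewNormalTail:
    def test_zero_skew_is_normal(self):
        from scipy.stats import norm

        assert np.isclose(
            act._sn_tail(1.0, 0.5, 2.0, 0.0), norm.sf(1.0, 0.5, 2.0)
        )

    def test_moment_inversion_roundtrip(self):
        from scipy.stats import skewnorm

        mean, sd, skew = 1.2, 0.8, -0.5
        g = skew
        c = np.sign(g) * (2 * abs(g) / (4 - np.pi)) ** (1 / 3)
        db = c / np.sqrt(1 + c * c)
        delta = db / np.sqrt(2 / np.pi)
        alpha = delta / np.sqrt(1 - delta**2)
        omega = sd / np.sqrt(1 - db * db)
        xi = mean - omega * db
        m, v, s = skewnorm.stats(alpha, loc=xi, scale=omega, moments="mvs")
        assert np.isclose(m, mean) and np.isclose(np.sqrt(v), sd)
        assert np.isclose(s, skew)


class TestCalibration:
    def test_boundary_inverts_calibration(self, default_hyper):
        t = act.calibrate_threshold(default_hyper, target_rpm=2.0)
        rpm = act.boundary_rpm(default_hyper, t)
        assert np.isclose(rpm, 2.0, rtol=1e-6)

    def test_threshold_monotone_in_target(self, default_hyper):
        ts = [
            act.calibrate_threshold(default_hyper, target_rpm=rpm)
            for rpm in (0.5, 1.0, 2.0, 5.0, 10.0)
        ]
        assert all(a < b for a, b in zip(ts, ts[1:]))

    def test_gene_term_raises_count_boundary(self, default_hyper):
        t = act.calibrate_threshold(default_hyper)
        c0 = act.boundary_count(default_hyper, t, gene_term=0.0)
        c_long = act.boundary_count(default_hyper, t, gene_term=1.0)
        assert c_long > c0

    def test_invalid_target_rejected(self, default_hyper):
        with pytest.raises(ValueError, match="positive"):
            act.calibrate_threshold(default_hyper, target_rpm=0.0)


class TestEndToEndCalling:
    def test_sensitivity_and_specificity(self, experiment, hyper):
        """Calls on the shared experiment track the planted truth."""
        mat, design, params = (
            experiment["matrix"], experiment["design"], experiment["params"]
        )
        post = act.fit_posteriors(
            mat.counts, design, experiment["offsets"].offsets, hyper
        )
        t = act.calibrate_threshold(hyper, target_rpm=2.0)
        calls = act.call_activity(post, t).loc[mat.counts.index]
        pred = calls.to_numpy()
        truth = params.truly_active
        sens = pred[truth].mean()
        spec = (~pred[~truth]).mean()
        assert sens > 0.9
        assert spec > 0.9
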