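"""Hierarchical empirical-Bayes negative-binomial activity calling.

Per gene the read counts follow a negative binomial GLMM: conditional on lane
and replicate random effects, log mean count = normalization offset + fixed
effect of the tissue x treatment cell + lane effect + replicate effect.
Across genes the 8 fixed effects are draws from a diagonal-covariance normal,
log NB dispersion from a normal, and the random-effect precisions from gamma
distributions.  The population parameters are estimated by pooling per-gene
maximum-likelihood fits (empirical Bayes); each gene's posterior over its
fixed effects is then approximated by a nested Laplace scheme: a Newton
mode/curvature search over fixed and random effects jointly (NB dispersion
and random-effect precisions plugged in at their empirical-Bayes estimates),
followed by one-dimensional numerical integration of each fixed effect's
conditional posterior, summarized as a moment-matched skew-normal.

A gene is called *active* in a cell when the posterior probability that its
fixed effect exceeds a threshold T is strictly greater than 0.5; T itself is
calibrated so that an average-length, average-GC gene sits on the call
boundary at a chosen expected reads-per-million (default 2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import gammaln, ndtr
from scipy.stats import skewnorm

from rootzone.normalization import NormalizationOffsets
from rootzone.simulate import CELL_LABELS, CELLS, cell_index

logger = logging.getLogger(__name__)

_BETA_BOUND = 14.0  # |log RPM| beyond which a per-gene MLE is unidentified


@dataclass
class Hyperparameters:
    """Population parameters of the hierarchical model."""

    beta_mean: np.ndarray  # (8,)
    beta_var: np.ndarray  # (8,)
    log_disp_mean: float
    log_disp_var: float
    replicate_precision_shape: float = 2.0
    replicate_precision_rate: float = 0.04
    lane_precision_shape: float = 0.01
    lane_precision_rate: float = 0.01
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.beta_mean = np.asarray(self.beta_mean, float)
        self.beta_var = np.asarray(self.beta_var, float)
        if np.any(self.beta_var <= 0) or self.log_disp_var <= 0:
            raise ValueError("hyper-variances must be positive")
        for name in (
            "replicate_precision_shape",
            "replicate_precision_rate",
            "lane_precision_shape",
            "lane_precision_rate",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


# ---------------------------------------------------------------------------
# negative binomial log likelihood (plug-in dispersion), natural-log link
# ---------------------------------------------------------------------------

def _nb_loglik(y: np.ndarray, eta: np.ndarray, r: float | np.ndarray) -> np.ndarray:
    """Elementwise NB log likelihood at log-mean eta with size r = 1/phi."""
    mu = np.exp(eta)
    return (
        gammaln(y + r) - gammaln(r) - gammaln(y + 1.0)
        + r * np.log(r / (r + mu))
        + y * (eta - np.log(r + mu))
    )


def _nb_score_weight(y, eta, r):
    """First derivative and negative second derivative of the NB log lik."""
    mu = np.exp(eta)
    score = y - (y + r) * mu / (r + mu)
    weight = (y + r) * r * mu / (r + mu) ** 2
    return score, weight


# ---------------------------------------------------------------------------
# vectorized per-gene maximum likelihood (cell means + dispersion)
# ---------------------------------------------------------------------------

def _fit_cell_betas(
    y: np.ndarray, offsets: np.ndarray, cells: np.ndarray, r: np.ndarray,
    n_iter: int = 60,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene, per-cell ML fixed effects by vectorized Newton iterations.

    Returns (beta_hat, info) each of shape (G, 8); info is the observed Fisher
    information of each estimate (sum of IRLS weights).
    """
    n_genes = y.shape[0]
    beta = np.empty((n_genes, 8))
    info = np.empty((n_genes, 8))
    r_col = r[:, None]
    for k in range(8):
        sel = cells == k
        yk, ok = y[:, sel], offsets[:, sel]
        b = np.log((yk.sum(axis=1) + 0.5) / np.exp(ok).sum(axis=1))
        for _ in range(n_iter):
            eta = np.clip(ok + b[:, None], -30.0, 30.0)
            score, weight = _nb_score_weight(yk, eta, r_col)
            step = score.sum(axis=1) / np.maximum(weight.sum(axis=1), 1e-12)
            step = np.clip(step, -3.0, 3.0)
            b = np.clip(b + step, -_BETA_BOUND - 1, _BETA_BOUND + 1)
            if np.max(np.abs(step)) < 1e-10:
                break
        beta[:, k] = b
        eta = np.clip(ok + b[:, None], -30.0, 30.0)
        _, weight = _nb_score_weight(yk, eta, r_col)
        info[:, k] = weight.sum(axis=1)
    return beta, info


_LOG_PHI_GRID = np.linspace(-7.0, 3.0, 51)


def _dispersion_profile(
    y: np.ndarray, offsets: np.ndarray, cells: np.ndarray, beta: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Adjusted-profile-likelihood dispersion estimates, vectorized over genes.

    Profiles the NB log likelihood over a log-dispersion grid at fixed cell
    means, with a Cox-Reid adjustment (-0.5 * sum_k log info_k, exact for the
    diagonal cell-means design), then refines the maximum by quadratic
    interpolation.  Returns (log_phi_hat, sampling_var).
    """
    n_genes = y.shape[0]
    eta = np.clip(offsets + beta[:, cells], -30.0, 30.0)
    apl = np.empty((n_genes, len(_LOG_PHI_GRID)))
    for j, lp in enumerate(_LOG_PHI_GRID):
        r = np.exp(-lp)
        ll = _nb_loglik(y, eta, r).sum(axis=1)
        _, w = _nb_score_weight(y, eta, r)
        adj = np.zeros(n_genes)
        for k in range(8):
            adj += np.log(np.maximum(w[:, cells == k].sum(axis=1), 1e-300))
        apl[:, j] = ll - 0.5 * adj
    j_star = np.argmax(apl, axis=1)
    j_star = np.clip(j_star, 1, len(_LOG_PHI_GRID) - 2)
    rows = np.arange(n_genes)
    f0, f1, f2 = apl[rows, j_star - 1], apl[rows, j_star], apl[rows, j_star + 1]
    h = _LOG_PHI_GRID[1] - _LOG_PHI_GRID[0]
    denom = f0 - 2 * f1 + f2
    shift = np.where(denom < -1e-12, 0.5 * (f0 - f2) / denom, 0.0)
    shift = np.clip(shift, -1.0, 1.0)
    log_phi = _LOG_PHI_GRID[j_star] + shift * h
    curv = np.where(denom < -1e-12, -denom / h**2, 1e-6)
    return log_phi, 1.0 / np.maximum(curv, 1e-6)


def sample_residual_adjustment(
    y: np.ndarray,
    offsets: np.ndarray,
    cells: np.ndarray,
    n_iter: int = 2,
) -> np.ndarray:
    """Empirical point estimates of shared per-sample effects (centred).

    The lane and replicate effects of the model are shared across genes, as
    are residual errors of the TMM sample factors; the median across
    well-expressed genes of the per-sample log-count residual (after removing
    offsets and fitted cell means) estimates their sum.  Adding the returned
    per-sample term to the offsets approximates profiling those effects out
    of the per-gene likelihoods.
    """
    adj = np.zeros(y.shape[1])
    expressed = y.mean(axis=1) >= 5
    if expressed.sum() < 20:
        expressed = np.ones(len(y), dtype=bool)
    r = np.full(int(expressed.sum()), 10.0)
    for _ in range(n_iter):
        beta, _ = _fit_cell_betas(y[expressed], offsets[expressed] + adj, cells, r)
        resid = np.log(y[expressed] + 0.5) - (
            offsets[expressed] + adj + beta[:, cells]
        )
        step = np.median(resid, axis=0)
        adj = adj + step - step.mean()
    return adj


def _sample_effect_variances(
    y: np.ndarray,
    offsets: np.ndarray,
    beta: np.ndarray,
    cells: np.ndarray,
    design: pd.DataFrame,
) -> tuple[float, float]:
    """Method-of-moments lane / replicate effect variances.

    Uses per-sample means (across well-expressed genes) of the log-count
    residual after removing offsets and fitted cell means, decomposed on lane
    and replicate factors by least squares.
    """
    fitted = offsets + beta[:, cells]
    expressed = (y.mean(axis=1) >= 5) & np.all(np.abs(beta) < _BETA_BOUND, axis=1)
    if expressed.sum() < 20:
        expressed = y.mean(axis=1) >= 1
    resid = np.log(y[expressed] + 0.5) - fitted[expressed]
    m = resid.mean(axis=0)
    lanes = pd.get_dummies(design["lane"]).to_numpy(float)
    reps = pd.get_dummies(design["replicate"]).to_numpy(float)
    x = np.column_stack([np.ones(len(m)), lanes[:, :-1], reps[:, :-1]])
    coef, *_ = np.linalg.lstsq(x, m, rcond=None)
    n_lane = lanes.shape[1]
    lane_eff = np.append(coef[1:n_lane], 0.0)
    rep_eff = np.append(coef[n_lane:], 0.0)
    var_u = float(np.var(lane_eff - lane_eff.mean()))
    var_v = float(np.var(rep_eff - rep_eff.mean()))
    return max(var_u, 1e-4), max(var_v, 1e-4)


def estimate_hyperparameters(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    offsets: pd.DataFrame,
    min_genes: int = 500,
) -> Hyperparameters:
    """Empirical-Bayes pooling of per-gene ML fits into population parameters.

    Per-gene fixed effects and log-dispersions are estimated by maximum
    (adjusted profile) likelihood, then pooled by method of moments with a
    sampling-variance correction.  Cells whose estimate sits at the
    identifiability bound (e.g. all-zero counts) are dropped from the moment
    pool; the lane- and replicate-precision gamma priors are matched (with
    shape 2) to the realized lane- and replicate-effect variances, so their
    prior means equal the empirical precisions.
    """
    if len(counts) < min_genes:
        raise ValueError(
            f"hyperparameter estimation needs >= {min_genes} genes, "
            f"got {len(counts)}"
        )
    y = counts.to_numpy(float)
    o = offsets.loc[counts.index, counts.columns].to_numpy(float)
    cells = np.array(
        [cell_index(t, c) for t, c in zip(design["tissue"], design["treatment"])]
    )
    o = o + sample_residual_adjustment(y, o, cells)

    r = np.full(len(counts), 10.0)  # phi = 0.1 starting value
    beta = info = None
    for _ in range(3):
        beta, info = _fit_cell_betas(y, o, cells, r)
        log_phi, phi_var = _dispersion_profile(y, o, cells, beta)
        r = np.exp(-log_phi)

    usable = np.abs(beta) < _BETA_BOUND
    n_dropped = int((~usable).any(axis=1).sum())
    if n_dropped:
        logger.info("dropped %d gene/cell fits at the identifiability bound",
                    n_dropped)
    beta_m = np.empty(8)
    beta_v = np.empty(8)
    for k in range(8):
        ok = usable[:, k]
        bk = beta[ok, k]
        beta_m[k] = bk.mean()
        sampling = np.mean(1.0 / np.maximum(info[ok, k], 1e-8))
        beta_v[k] = max(np.var(bk) - sampling, 1e-6)

    # pool log-dispersions over genes whose dispersion is well identified;
    # winsorize the sampling-variance correction against profile outliers
    informative = np.isfinite(log_phi) & (phi_var <= 2.0)
    if informative.sum() < 50:
        informative = np.isfinite(log_phi)
    lp = log_phi[informative]
    pv = np.minimum(
        phi_var[informative], np.quantile(phi_var[informative], 0.9)
    )
    ld_mean = float(lp.mean())
    ld_var = float(max(np.var(lp) - pv.mean(), 1e-6))

    var_u, var_v = _sample_effect_variances(y, o, beta, cells, design)
    return Hyperparameters(
        beta_mean=beta_m,
        beta_var=beta_v,
        log_disp_mean=ld_mean,
        log_disp_var=ld_var,
        replicate_precision_shape=2.0,
        replicate_precision_rate=2.0 * var_v,
        lane_precision_shape=2.0,
        lane_precision_rate=2.0 * var_u,
        n_dropped=n_dropped,
    )


# ---------------------------------------------------------------------------
# per-gene posterior via Laplace approximation
# ---------------------------------------------------------------------------

@dataclass
class _GeneDesign:
    """Precomputed per-experiment design pieces shared by every gene."""

    x: np.ndarray  # (n_samples, 8 + L + R)
    cells: np.ndarray
    n_lanes: int
    n_reps: int


def _build_design(design: pd.DataFrame, random_effects: bool = True) -> _GeneDesign:
    n = len(design)
    cells = np.array(
        [cell_index(t, c) for t, c in zip(design["tissue"], design["treatment"])]
    )
    blocks = [np.eye(8)[cells]]
    n_lanes = n_reps = 0
    if random_effects:
        lanes = pd.get_dummies(design["lane"]).to_numpy(float)
        reps = pd.get_dummies(design["replicate"]).to_numpy(float)
        n_lanes, n_reps = lanes.shape[1], reps.shape[1]
        blocks += [lanes, reps]
    return _GeneDesign(
        x=np.column_stack(blocks), cells=cells, n_lanes=n_lanes, n_reps=n_reps
    )


def _laplace_gene(
    y: np.ndarray,
    offsets: np.ndarray,
    gd: _GeneDesign,
    hyper: Hyperparameters,
    phi: float,
    max_iter: int = 100,
    tol: float = 1e-9,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Marginal posterior summaries (mean, sd, skewness) of the 8 fixed
    effects for one gene.

    Nested Laplace scheme: damped Newton ascent over the joint of fixed
    effects, lane effects and replicate effects, with the random-effect
    precisions plugged in at their empirical-Bayes gamma-prior means (a joint
    mode over effects *and* precisions is degenerate — the precision can
    collapse to let the random effects absorb the likelihood).  Each fixed
    effect's marginal is then refined by one-dimensional numerical
    integration of its conditional posterior at the joint mode (capturing the
    skewness the Gaussian approximation misses at low counts), with the
    variance inflated by the marginal/conditional curvature ratio from the
    joint Hessian to retain the uncertainty of the integrated-out random
    effects.
    """
    r = 1.0 / phi
    x = gd.x
    p = x.shape[1]
    theta = np.zeros(p)
    theta[:8] = np.clip(
        np.log((np.bincount(gd.cells, weights=y, minlength=8) + 0.5)
               / np.bincount(gd.cells, weights=np.exp(offsets), minlength=8)),
        -_BETA_BOUND, _BETA_BOUND,
    )
    tau_u = min(max(hyper.lane_precision_shape / hyper.lane_precision_rate,
                    1e-4), 1e8)
    tau_v = min(max(hyper.replicate_precision_shape
                    / hyper.replicate_precision_rate, 1e-4), 1e8)

    prior_mean = np.zeros(p)
    prior_mean[:8] = hyper.beta_mean
    prec = np.empty(p)
    prec[:8] = 1.0 / hyper.beta_var
    prec[8:8 + gd.n_lanes] = tau_u
    prec[8 + gd.n_lanes:] = tau_v

    def log_post(th: np.ndarray) -> float:
        eta = np.clip(offsets + x @ th, -30.0, 30.0)
        lp = _nb_loglik(y, eta, r).sum()
        lp -= 0.5 * np.sum(prec * (th - prior_mean) ** 2)
        return float(lp)

    converged = False
    h = None
    for _ in range(max_iter):
        eta = np.clip(offsets + x @ theta, -30.0, 30.0)
        score, weight = _nb_score_weight(y, eta, r)
        grad = x.T @ score - prec * (theta - prior_mean)
        h = (x.T * weight) @ x
        h[np.diag_indices_from(h)] += prec
        step = np.linalg.solve(h, grad)
        norm = np.linalg.norm(step)
        if norm > 4.0:
            step *= 4.0 / norm
        # backtracking line search on the log posterior
        f0 = log_post(theta)
        alpha = 1.0
        for _ in range(25):
            cand = theta + alpha * step
            if log_post(cand) >= f0 - 1e-12:
                break
            alpha *= 0.5
        theta = theta + alpha * step
        if np.linalg.norm(alpha * step) < tol:
            converged = True
            break

    cov = np.linalg.inv(h)
    sd_marg = np.sqrt(np.clip(np.diag(cov)[:8], 1e-12, None))
    sd_cond = 1.0 / np.sqrt(np.clip(np.diag(h)[:8], 1e-12, None))

    # 1-D refinement of each cell's marginal at the joint mode
    eta_all = offsets + x @ theta
    mean = np.empty(8)
    sd = np.empty(8)
    skew = np.empty(8)
    z_grid = np.linspace(-8.0, 8.0, 321)
    for k in range(8):
        sel = gd.cells == k
        eta_other = eta_all[sel] - theta[k]
        grid = theta[k] + z_grid * sd_marg[k]
        ll = _nb_loglik(
            y[sel][None, :], eta_other[None, :] + grid[:, None], r
        ).sum(axis=1)
        ll -= 0.5 * prec[k] * (grid - prior_mean[k]) ** 2
        w = np.exp(ll - ll.max())
        z0 = np.trapezoid(w, grid)
        m1 = np.trapezoid(w * grid, grid) / z0
        v1 = max(np.trapezoid(w * (grid - m1) ** 2, grid) / z0, 1e-24)
        m3 = np.trapezoid(w * (grid - m1) ** 3, grid) / z0
        mean[k] = m1
        sd[k] = np.sqrt(v1) * (sd_marg[k] / sd_cond[k])
        skew[k] = m3 / v1**1.5
    return mean, sd, skew, converged


def fit_posteriors(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    offsets: pd.DataFrame,
    hyper: Hyperparameters,
    random_effects: bool = True,
    sample_adjustment: bool = True,
) -> pd.DataFrame:
    """Posterior summaries for every gene x cell.

    Returns a long-format frame with columns gene_id, cell, posterior_mean,
    posterior_sd, converged.  Dispersions are plugged in at their per-gene
    empirical-Bayes posterior modes (normal shrinkage of the adjusted-profile
    ML estimate toward the population mean); shared per-sample effects are
    absorbed into the offsets first (see :func:`sample_residual_adjustment`).
    """
    y = counts.to_numpy(float)
    o = offsets.loc[counts.index, counts.columns].to_numpy(float)
    gd = _build_design(design, random_effects=random_effects)
    if sample_adjustment:
        o = o + sample_residual_adjustment(y, o, gd.cells)

    r0 = np.full(len(counts), np.exp(-hyper.log_disp_mean))
    beta0, _ = _fit_cell_betas(y, o, gd.cells, r0)
    log_phi_ml, phi_var = _dispersion_profile(y, o, gd.cells, beta0)
    w = 1.0 / np.maximum(phi_var, 1e-6)
    w0 = 1.0 / hyper.log_disp_var
    log_phi = (w * log_phi_ml + w0 * hyper.log_disp_mean) / (w + w0)
    phi = np.exp(np.clip(log_phi, -8.0, 4.0))

    records = []
    for i, gene in enumerate(counts.index):
        mean, sd, skew, ok = _laplace_gene(y[i], o[i], gd, hyper, float(phi[i]))
        if not ok:
            # one jittered restart, then flag with the prior as fallback
            mean2, sd2, skew2, ok = _laplace_gene(
                y[i], o[i] + 1e-6, gd, hyper, float(phi[i])
            )
            if ok:
                mean, sd, skew = mean2, sd2, skew2
            else:
                logger.warning("posterior fit did not converge for %s", gene)
                mean, sd = hyper.beta_mean.copy(), np.sqrt(hyper.beta_var)
                skew = np.zeros(8)
        for k in range(8):
            records.append(
                (gene, CELL_LABELS[k], mean[k], sd[k], skew[k], ok)
            )
    return pd.DataFrame(
        records,
        columns=["gene_id", "cell", "posterior_mean", "posterior_sd",
                 "posterior_skew", "converged"],
    )


#: largest |skewness| a skew-normal can represent; estimates are clipped.
_SKEW_MAX = 0.995

_SN_B = np.sqrt(2.0 / np.pi)


def _sn_tail(
    threshold: float,
    mean: np.ndarray | float,
    sd: np.ndarray | float,
    skew: np.ndarray | float = 0.0,
) -> np.ndarray | float:
    """Upper-tail probability of the moment-matched skew-normal summary.

    The (mean, sd, skewness) triple is mapped to skew-normal
    (shape, location, scale) by exact moment inversion; zero skewness reduces
    to the normal tail.
    """
    g = np.clip(np.asarray(skew, float), -_SKEW_MAX, _SKEW_MAX)
    c = np.sign(g) * (2.0 * np.abs(g) / (4.0 - np.pi)) ** (1.0 / 3.0)
    db = c / np.sqrt(1.0 + c * c)  # delta * sqrt(2/pi)
    delta = db / _SN_B
    alpha = delta / np.sqrt(np.clip(1.0 - delta * delta, 1e-12, None))
    omega = np.asarray(sd, float) / np.sqrt(1.0 - db * db)
    xi = np.asarray(mean, float) - omega * db
    out = skewnorm.sf(threshold, alpha, loc=xi, scale=omega)
    return float(out) if np.isscalar(mean) else out


def p_exceed(posteriors: pd.DataFrame, threshold: float) -> pd.Series:
    """P(fixed effect > T) under the skew-normal posterior summary.

    Frames without a ``posterior_skew`` column fall back to the plain normal
    approximation.
    """
    mean = posteriors["posterior_mean"].to_numpy()
    sd = posteriors["posterior_sd"].to_numpy()
    if "posterior_skew" in posteriors.columns:
        skew = posteriors["posterior_skew"].to_numpy()
    else:
        skew = np.zeros_like(mean)
    return pd.Series(
        _sn_tail(threshold, mean, sd, skew),
        index=posteriors.index, name="p_exceed",
    )


def call_activity(posteriors: pd.DataFrame, threshold: float) -> pd.DataFrame:
    """Boolean activity calls (p_exceed strictly > 0.5) as genes x 8 cells."""
    post = posteriors.copy()
    post["p_exceed"] = p_exceed(posteriors, threshold)
    post["active"] = post["p_exceed"] > 0.5
    calls = post.pivot(index="gene_id", columns="cell", values="active")
    calls = calls[list(CELL_LABELS)]
    calls.attrs["threshold"] = threshold
    probs = post.pivot(index="gene_id", columns="cell", values="p_exceed")
    calls.attrs["probabilities"] = probs[list(CELL_LABELS)]
    return calls


# ---------------------------------------------------------------------------
# threshold calibration against expected reads per million
# ---------------------------------------------------------------------------

def _pseudo_gene_posterior(
    expected_count: float,
    hyper: Hyperparameters,
    library_size: float,
    n_replicates: int,
    gene_term: float = 0.0,
) -> tuple[float, float, float]:
    """Posterior (mean, sd, skewness) of the fixed effect for an average
    pseudo-gene observed at exactly its expected count in one cell's
    replicates."""
    y = np.full(n_replicates, expected_count)
    offsets = np.full(n_replicates, np.log(library_size / 1e6) + gene_term)
    phi = float(np.exp(hyper.log_disp_mean))
    r = 1.0 / phi
    m0 = float(hyper.beta_mean.mean())
    v0 = float(hyper.beta_var.mean())
    b = np.log((y.sum() + 0.5) / np.exp(offsets).sum())
    for _ in range(200):
        eta = np.clip(offsets + b, -30.0, 30.0)
        score, weight = _nb_score_weight(y, eta, r)
        grad = score.sum() - (b - m0) / v0
        curv = weight.sum() + 1.0 / v0
        step = np.clip(grad / curv, -2.0, 2.0)
        b += step
        if abs(step) < 1e-12:
            break
    eta = np.clip(offsets + b, -30.0, 30.0)
    _, weight = _nb_score_weight(y, eta, r)
    sd_mode = 1.0 / np.sqrt(weight.sum() + 1.0 / v0)
    # same 1-D marginal refinement as the per-gene fits
    grid = b + np.linspace(-8.0, 8.0, 321) * sd_mode
    ll = _nb_loglik(y[None, :], offsets[None, :] + grid[:, None], r).sum(axis=1)
    ll -= 0.5 * (grid - m0) ** 2 / v0
    w = np.exp(ll - ll.max())
    z0 = np.trapezoid(w, grid)
    m1 = np.trapezoid(w * grid, grid) / z0
    v1 = max(np.trapezoid(w * (grid - m1) ** 2, grid) / z0, 1e-24)
    m3 = np.trapezoid(w * (grid - m1) ** 3, grid) / z0
    return float(m1), float(np.sqrt(v1)), float(m3 / v1**1.5)


def calibrate_threshold(
    hyper: Hyperparameters,
    target_rpm: float = 2.0,
    library_size: float = 1_000_000.0,
    n_replicates: int = 4,
) -> float:
    """Find T such that an average gene at ``target_rpm`` expected reads per
    million sits exactly on the activity-call boundary (p_exceed = 0.5)."""
    if target_rpm <= 0:
        raise ValueError("target_rpm must be positive")
    mean, sd, skew = _pseudo_gene_posterior(
        target_rpm * library_size / 1e6, hyper, library_size, n_replicates
    )

    def crossing(t: float) -> float:
        return _sn_tail(t, mean, sd, skew) - 0.5

    lo, hi = mean - 10 * sd, mean + 10 * sd
    if crossing(lo) * crossing(hi) > 0:
        raise ValueError(
            f"no calibration root in bracket [{lo:.3f}, {hi:.3f}]"
        )
    return float(brentq(crossing, lo, hi, xtol=1e-10))


def boundary_rpm(
    hyper: Hyperparameters,
    threshold: float,
    library_size: float = 1_000_000.0,
    n_replicates: int = 4,
    gene_term: float = 0.0,
) -> float:
    """Expected reads-per-million at which a gene crosses the call boundary.

    Inverts the calibration: root-finds the RPM whose pseudo-gene posterior
    gives p_exceed(threshold) = 0.5.  ``gene_term`` shifts the offset for a
    non-average gene (larger smoother term -> higher count boundary).
    """
    def crossing(log_rpm: float) -> float:
        mean, sd, skew = _pseudo_gene_posterior(
            np.exp(log_rpm) * library_size / 1e6,
            hyper, library_size, n_replicates, gene_term=gene_term,
        )
        return _sn_tail(threshold, mean, sd, skew) - 0.5

    lo, hi = np.log(1e-4), np.log(1e5)
    if crossing(lo) * crossing(hi) > 0:
        raise ValueError("no boundary root in the RPM search bracket")
    return float(np.exp(brentq(crossing, lo, hi, xtol=1e-10)))


def boundary_count(
    hyper: Hyperparameters,
    threshold: float,
    gene_term: float = 0.0,
    library_size: float = 1_000_000.0,
    n_replicates: int = 4,
) -> float:
    """Expected-count call boundary for a gene with a given smoother term."""
    rpm = boundary_rpm(
        hyper, threshold, library_size, n_replicates, gene_term=gene_term
    )
    return rpm * library_size / 1e6
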