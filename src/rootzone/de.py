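"""Precision-weighted differential expression under the incomplete-block design.

The workflow mirrors the voom / duplicate-correlation / moderated-t chain of
the microarray-style linear-modelling tradition, re-implemented for this
design: counts are filtered (>= ``min_count`` reads in every replicate of at
least one tissue x treatment group), log2-transformed with a 0.5 offset on a
counts-per-million scale, given inverse-variance observation weights from a
fitted mean-variance trend, and fitted per gene by generalized least squares
with a cell-means tissue x treatment model and a shared within-lane
correlation (the random-lane-effect block structure, recovering interblock
information).  Residual variances are shrunk toward a scaled-inverse-chi-square
prior fitted across genes, the four water deficit - control contrasts are
tested with moderated t statistics, and p-values are Benjamini-Hochberg
adjusted within each contrast.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

from rootzone.simulate import TISSUES, cell_index


def _groups(design: pd.DataFrame) -> np.ndarray:
    return np.array(
        [cell_index(t, c) for t, c in zip(design["tissue"], design["treatment"])]
    )


def filter_low_counts(
    counts: pd.DataFrame, design: pd.DataFrame, min_count: int = 5
) -> pd.Index:
    """Genes with >= min_count reads in every replicate of >= 1 tissue x
    treatment group."""
    if min_count < 0:
        raise ValueError("min_count must be >= 0")
    y = counts.to_numpy()
    cells = _groups(design)
    keep = np.zeros(len(counts), dtype=bool)
    for k in range(8):
        keep |= (y[:, cells == k] >= min_count).all(axis=1)
    return counts.index[keep]


@dataclass
class ExpressionMatrix:
    """log2 expression with per-observation precision weights."""

    logged: pd.DataFrame
    weights: pd.DataFrame

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.logged.to_numpy())):
            raise ValueError("logged expression contains non-finite values")
        w = self.weights.to_numpy()
        if not (np.all(np.isfinite(w)) and np.all(w > 0)):
            raise ValueError("weights must be finite and positive")


def _cell_mean_fit(logged: np.ndarray, cells: np.ndarray):
    """Group means, fitted values and residual sd for every gene (OLS)."""
    n_genes, n_samples = logged.shape
    means = np.empty((n_genes, 8))
    fitted = np.empty_like(logged)
    for k in range(8):
        sel = cells == k
        means[:, k] = logged[:, sel].mean(axis=1)
        fitted[:, sel] = means[:, k][:, None]
    resid = logged - fitted
    df = n_samples - 8
    sd = np.sqrt((resid**2).sum(axis=1) / df)
    return means, fitted, sd


def transform_and_weight(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    effective_library_sizes: np.ndarray | None = None,
    span: float = 0.4,
    cpm_scale: bool = True,
) -> ExpressionMatrix:
    """log2(count + 0.5) transform plus mean-variance trend weights.

    ``effective_library_sizes`` (e.g. TMM-adjusted totals) scale the counts to
    per-million units before logging; per-gene cell-means fits give residual
    standard deviations, a lowess trend of sqrt(sd) on fitted log-expression
    is interpolated at every fitted value, and each observation's weight is
    the inverse fourth power of the predicted sqrt(sd) (inverse variance).
    """
    if len(counts) < 10:
        raise ValueError("mean-variance trend needs >= 10 genes")
    y = counts.to_numpy(float)
    if effective_library_sizes is None:
        effective_library_sizes = y.sum(axis=0)
    lib = np.asarray(effective_library_sizes, float)
    if cpm_scale:
        logged = np.log2((y + 0.5) / (lib + 1.0)[None, :] * 1e6)
    else:
        logged = np.log2(y + 0.5)
    cells = _groups(design)
    _, fitted, sd = _cell_mean_fit(logged, cells)

    x = fitted.mean(axis=1)  # average fitted log-expression per gene
    sqrt_sd = np.sqrt(sd)
    # degenerate inputs (e.g. zero residual variance throughout) make the
    # lowess internals divide by zero harmlessly; the result is clipped below
    with np.errstate(invalid="ignore", divide="ignore"):
        trend = lowess(sqrt_sd, x, frac=span, return_sorted=True)
    tx = trend[:, 0]
    ty = np.where(np.isfinite(trend[:, 1]), trend[:, 1], 0.0)
    ty = np.maximum(ty, 1e-3)
    pred = np.interp(fitted, tx, ty)
    weights = pred**-4.0
    return ExpressionMatrix(
        logged=pd.DataFrame(logged, index=counts.index, columns=counts.columns),
        weights=pd.DataFrame(weights, index=counts.index, columns=counts.columns),
    )


# ---------------------------------------------------------------------------
# shared within-lane correlation (interblock structure)
# ---------------------------------------------------------------------------

def estimate_block_correlation(
    expr: ExpressionMatrix, design: pd.DataFrame
) -> float:
    """Consensus within-lane correlation across genes.

    Per gene the lane-effect variance is estimated by method of moments from
    the estimable lane deviations of a fixed cell-means + lane model (sum of
    squared lane deviations minus their sampling variance), the residual
    variance from that model's residual mean square; per-gene correlations
    sigma_lane^2 / (sigma_lane^2 + sigma_e^2) are combined on the Fisher-z
    scale.
    """
    lanes = pd.get_dummies(design["lane"]).to_numpy(float)
    n_lanes = lanes.shape[1]
    if n_lanes < 2:
        import warnings

        warnings.warn("single lane: block correlation set to 0")
        return 0.0
    cells = _groups(design)
    x = np.column_stack([np.eye(8)[cells], lanes])
    n, p = x.shape
    xtx_pinv = np.linalg.pinv(x.T @ x)
    rank = np.linalg.matrix_rank(x)
    df = n - rank
    # contrast matrix extracting lane deviations from the mean lane effect
    c = np.zeros((n_lanes, p))
    c[:, 8:] = np.eye(n_lanes) - 1.0 / n_lanes
    a = c @ xtx_pinv @ x.T  # lane deviations = a @ y
    hat = x @ xtx_pinv @ x.T
    q = np.eye(n) - hat  # residual projector

    y = expr.logged.to_numpy().T  # (samples, genes)
    lane_dev = a @ y  # (n_lanes, genes)
    rss = np.einsum("sg,st,tg->g", y, q, y)
    sigma2_e = rss / df
    sampling = np.trace(c @ xtx_pinv @ c.T)
    sigma2_u = (np.sum(lane_dev**2, axis=0) - sampling * sigma2_e) / (n_lanes - 1)
    rho_g = sigma2_u / (np.abs(sigma2_u) + sigma2_e)
    rho_g = np.clip(rho_g, -0.95, 0.99)
    return float(np.tanh(np.mean(np.arctanh(rho_g))))


# ---------------------------------------------------------------------------
# per-gene weighted GLS with the lane-block correlation
# ---------------------------------------------------------------------------

@dataclass
class GeneFits:
    """Per-gene x contrast estimates before moderation."""

    gene_ids: list[str]
    log2fc: np.ndarray  # (genes, 4) deficit - control per tissue
    stdev_unscaled: np.ndarray  # (genes, 4)
    sigma2: np.ndarray  # (genes,) residual variances
    df_residual: float
    rho: float


def fit_contrasts(
    expr: ExpressionMatrix, design: pd.DataFrame, rho: float = 0.0
) -> GeneFits:
    """Weighted GLS of the tissue x treatment cell-means model per gene."""
    cells = _groups(design)
    x = np.eye(8)[cells]
    n = len(design)
    lanes = pd.get_dummies(design["lane"]).to_numpy(float)
    r_mat = (1 - rho) * np.eye(n) + rho * (lanes @ lanes.T)
    l_chol = np.linalg.cholesky(r_mat)

    contrasts = np.zeros((4, 8))
    for t, tissue in enumerate(TISSUES):
        contrasts[t, cell_index(tissue, "deficit")] = 1.0
        contrasts[t, cell_index(tissue, "control")] = -1.0

    logged = expr.logged.to_numpy()
    weights = expr.weights.to_numpy()
    n_genes = logged.shape[0]
    log2fc = np.empty((n_genes, 4))
    sdu = np.empty((n_genes, 4))
    sigma2 = np.empty(n_genes)
    df = n - 8
    from scipy.linalg import solve_triangular

    for g in range(n_genes):
        sw = np.sqrt(weights[g])
        xs = solve_triangular(l_chol, x * sw[:, None], lower=True)
        ys = solve_triangular(l_chol, logged[g] * sw, lower=True)
        xtx = xs.T @ xs
        if np.linalg.matrix_rank(xtx) < 8:
            from rootzone.simulate import CELLS

            missing = [
                f"{t}_{c}" for k, (t, c) in enumerate(CELLS)
                if np.all(cells != k)
            ]
            raise ValueError(f"rank-deficient design; aliased cell(s): {missing}")
        xtx_inv = np.linalg.inv(xtx)
        coef = xtx_inv @ xs.T @ ys
        resid = ys - xs @ coef
        sigma2[g] = resid @ resid / df
        log2fc[g] = contrasts @ coef
        sdu[g] = np.sqrt(np.einsum("ij,jk,ik->i", contrasts, xtx_inv, contrasts))
    return GeneFits(
        gene_ids=list(expr.logged.index),
        log2fc=log2fc,
        stdev_unscaled=sdu,
        sigma2=sigma2,
        df_residual=float(df),
        rho=rho,
    )


# ---------------------------------------------------------------------------
# variance moderation (scaled inverse-chi-square prior across genes)
# ---------------------------------------------------------------------------

def _trigamma_inverse(x: float) -> float:
    if x <= 0:
        return np.inf
    y = 0.5 + 1.0 / x
    for _ in range(100):
        tri = polygamma(1, y)
        dif = tri * (1 - tri / x) / polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def estimate_variance_prior(
    sigma2: np.ndarray, df: float
) -> tuple[float, float]:
    """Fit (d0, s0^2) of the scaled inverse-chi-square variance prior by
    matching moments of log variances."""
    s2 = sigma2[np.isfinite(sigma2) & (sigma2 > 0)]
    z = np.log(s2)
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    evar = np.var(z, ddof=1) - polygamma(1, df / 2.0)
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_2 = float(np.exp(np.mean(e) + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0_2 = float(np.exp(np.mean(e)))
    return d0, s0_2


def moderate_and_test(
    fits: GeneFits,
    prior_df: float | None = None,
    prior_var: float | None = None,
    min_genes: int = 100,
) -> pd.DataFrame:
    """Moderated t statistics, p- and BH q-values per gene x tissue contrast.

    ``prior_df`` forces d0 (0 disables moderation, inf gives complete
    shrinkage to the prior variance); by default (d0, s0^2) are estimated
    across genes.
    """
    n_genes = len(fits.gene_ids)
    if prior_df is None and n_genes < min_genes:
        raise ValueError(f"variance-prior estimation needs >= {min_genes} genes")
    dg = fits.df_residual
    finite = np.isfinite(fits.sigma2)
    n_bad = int((~finite).sum())
    if n_bad:
        import logging

        logging.getLogger(__name__).info(
            "dropping %d genes with non-finite variances", n_bad
        )
    if prior_df is None:
        d0, s0_2 = estimate_variance_prior(fits.sigma2[finite], dg)
    else:
        d0 = prior_df
        s0_2 = prior_var if prior_var is not None else (
            estimate_variance_prior(fits.sigma2[finite], dg)[1]
        )

    if np.isinf(d0):
        post_var = np.full(n_genes, s0_2)
        df_total = np.inf
    elif d0 == 0:
        post_var = fits.sigma2
        df_total = dg
    else:
        post_var = (d0 * s0_2 + dg * fits.sigma2) / (d0 + dg)
        df_total = d0 + dg

    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = fits.log2fc / (fits.stdev_unscaled * np.sqrt(post_var)[:, None])
    if np.isinf(df_total):
        pvals = 2.0 * stats.norm.sf(np.abs(tstat))
    else:
        pvals = 2.0 * stats.t.sf(np.abs(tstat), df_total)

    rows = []
    for t, tissue in enumerate(TISSUES):
        q = adjust_fdr(pvals[finite, t])
        qcol = np.full(n_genes, np.nan)
        qcol[finite] = q
        for g, gene in enumerate(fits.gene_ids):
            rows.append(
                (
                    gene, tissue, fits.log2fc[g, t], tstat[g, t],
                    pvals[g, t], qcol[g],
                )
            )
    frame = pd.DataFrame(
        rows,
        columns=["gene_id", "tissue", "log2fc", "moderated_stat",
                 "p_value", "q_value"],
    )
    frame.attrs["prior_df"] = d0
    frame.attrs["prior_var"] = s0_2
    frame.attrs["df_total"] = df_total
    return frame


def adjust_fdr(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (shared by all modules)."""
    p = np.asarray(p_values, float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def select_responsive(
    results: pd.DataFrame, fdr_cut: float = 0.01, lfc_cut: float = 1.0
) -> dict:
    """Water-deficit-responsive gene sets and their cross-tissue structure."""
    res = results.copy()
    res["passes"] = (res["q_value"] < fdr_cut) & (
        res["log2fc"].abs() >= lfc_cut
    )
    per_tissue = {
        tissue: set(res.loc[(res["tissue"] == tissue) & res["passes"], "gene_id"])
        for tissue in TISSUES
    }
    up_down = {
        tissue: (
            int((res["passes"] & (res["tissue"] == tissue)
                 & (res["log2fc"] > 0)).sum()),
            int((res["passes"] & (res["tissue"] == tissue)
                 & (res["log2fc"] < 0)).sum()),
        )
        for tissue in TISSUES
    }
    hits = res[res["passes"]]
    count_by_gene = hits.groupby("gene_id")["tissue"].nunique()
    multi = set(count_by_gene[count_by_gene >= 2].index)
    all_four = set(count_by_gene[count_by_gene == 4].index)
    consistent = 0
    for gene in multi:
        signs = np.sign(hits.loc[hits["gene_id"] == gene, "log2fc"])
        if len(set(signs)) == 1:
            consistent += 1
    return {
        "results": res,
        "per_tissue": per_tissue,
        "up_down": up_down,
        "n_multi_tissue": len(multi),
        "n_direction_consistent": consistent,
        "direction_consistency": consistent / len(multi) if multi else np.nan,
        "n_all_tissues": len(all_four),
        "n_any": int(count_by_gene.size),
    }
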