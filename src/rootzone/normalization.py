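"""Normalization offsets: TMM scaling plus a covariate smoother.

The activity model conditions on a per-gene, per-sample natural-log offset

    offset[g, s] = log(TMM_s * N_s / 1e6) + smooth(gc_g, log len_g)

where ``N_s`` is the number of mapped reads in sample ``s``, ``TMM_s`` the
trimmed-mean-of-M-values scaling factor, and ``smooth`` a local-linear
surface fitted to the log mean raw count as a function of GC fraction and log
gene length (centred across genes, so the per-sample term carries the whole
library scale and the fixed effects live on a log reads-per-million scale for
a gene of average length and GC).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


def tmm_factors(
    counts: pd.DataFrame | np.ndarray,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
    reference: int | None = None,
) -> np.ndarray:
    """Trimmed-mean-of-M-values scaling factors (reference factor = 1).

    For each sample against the reference, genes with a zero count in either
    sample are excluded, M (log2 expression ratio) and A (average log2
    expression) are computed on library-size-scaled counts, the upper and
    lower ``trim_m`` / ``trim_a`` quantiles of M and A are trimmed, and the
    factor is 2 to the precision-weighted mean of the surviving M values.

    The reference defaults to the sample whose 75th-percentile count fraction
    is closest to the across-sample mean of that quantity.
    """
    y = np.asarray(counts, dtype=float)
    if y.ndim != 2 or y.shape[1] < 2:
        raise ValueError("TMM needs a genes x samples matrix with >= 2 samples")
    lib = y.sum(axis=0)
    zero = lib == 0
    if zero.any():
        names = (
            list(counts.columns) if isinstance(counts, pd.DataFrame)
            else list(range(y.shape[1]))
        )
        bad = [str(names[i]) for i in np.nonzero(zero)[0]]
        raise ValueError(f"sample(s) with all-zero counts: {', '.join(bad)}")
    if reference is None:
        q75 = np.array(
            [np.quantile(y[:, s][y[:, s] > 0], 0.75) for s in range(y.shape[1])]
        ) / lib
        reference = int(np.argmin(np.abs(q75 - q75.mean())))

    factors = np.ones(y.shape[1])
    yr, nr = y[:, reference], lib[reference]
    for s in range(y.shape[1]):
        if s == reference:
            continue
        ys, ns = y[:, s], lib[s]
        keep = (ys > 0) & (yr > 0)
        ps, pr = ys[keep] / ns, yr[keep] / nr
        m = np.log2(ps / pr)
        a = 0.5 * np.log2(ps * pr)
        lo_m, hi_m = np.quantile(m, [trim_m, 1 - trim_m])
        lo_a, hi_a = np.quantile(a, [trim_a, 1 - trim_a])
        kept = (m >= lo_m) & (m <= hi_m) & (a >= lo_a) & (a <= hi_a)
        if not kept.any():  # degenerate tiny matrix: fall back to untrimmed
            kept = np.ones_like(kept, dtype=bool)
        w = 1.0 / (
            (ns - ys[keep][kept]) / (ns * ys[keep][kept])
            + (nr - yr[keep][kept]) / (nr * yr[keep][kept])
        )
        factors[s] = 2 ** (np.sum(w * m[kept]) / np.sum(w))
    return factors


@dataclass
class SmootherFit:
    """A fitted 2-D local-linear surface over (gc_fraction, log length).

    Tri-cube kernel over the ``span`` nearest neighbours in standardized
    covariate space; ``fitted`` holds the surface evaluated at the training
    genes, centred to mean zero.
    """

    gc: np.ndarray
    log_length: np.ndarray
    response: np.ndarray
    span: float
    fitted: np.ndarray  # centred fitted values at training genes
    centre: float  # mean raw fitted value removed from `fitted`
    _scale: np.ndarray = None  # type: ignore[assignment]

    def predict(self, gc: np.ndarray, length_bp: np.ndarray) -> np.ndarray:
        """Evaluate the centred surface at new (gc, length) points."""
        return self._raw_predict(np.asarray(gc, float),
                                 np.log(np.asarray(length_bp, float))) - self.centre

    def _raw_predict(self, gc: np.ndarray, log_length: np.ndarray) -> np.ndarray:
        gc = np.atleast_1d(gc)
        log_length = np.atleast_1d(log_length)
        x_train = np.column_stack([self.gc, self.log_length]) / self._scale
        x_new = np.column_stack([gc, log_length]) / self._scale
        k = max(int(np.ceil(self.span * len(self.response))), 4)
        out = np.empty(len(x_new))
        for i, point in enumerate(x_new):
            d = np.sqrt(((x_train - point) ** 2).sum(axis=1))
            idx = np.argpartition(d, min(k, len(d) - 1))[:k]
            dmax = d[idx].max()
            if dmax == 0:
                out[i] = self.response[idx].mean()
                continue
            w = (1 - (d[idx] / dmax) ** 3) ** 3
            w = np.maximum(w, 1e-9)
            x = np.column_stack(
                [np.ones(len(idx)), x_train[idx] - point]
            )
            xtw = x.T * w
            try:
                coef = np.linalg.solve(xtw @ x, xtw @ self.response[idx])
                out[i] = coef[0]
            except np.linalg.LinAlgError:
                out[i] = np.average(self.response[idx], weights=w)
        return out


def fit_covariate_smoother(
    counts: pd.DataFrame,
    covariates: pd.DataFrame,
    span: float = 0.5,
) -> SmootherFit:
    """Fit the log-mean-count ~ (GC, log length) local-linear surface."""
    if len(counts) < 50:
        raise ValueError("covariate smoother needs >= 50 genes")
    cov = covariates.loc[counts.index]
    gc = cov["gc_fraction"].to_numpy(float)
    log_length = np.log(cov["length_bp"].to_numpy(float))
    if np.ptp(gc) == 0 or np.ptp(log_length) == 0:
        raise ValueError("constant covariate: smoother fit is degenerate")
    response = np.log(counts.to_numpy(float).mean(axis=1) + 0.5)
    scale = np.array([max(gc.std(), 1e-9), max(log_length.std(), 1e-9)])
    fit = SmootherFit(
        gc=gc,
        log_length=log_length,
        response=response,
        span=span,
        fitted=np.empty(0),
        centre=0.0,
        _scale=scale,
    )
    raw = fit._raw_predict(gc, log_length)
    fit.centre = float(raw.mean())
    fit.fitted = raw - fit.centre
    return fit


@dataclass
class NormalizationOffsets:
    """Composed natural-log offsets plus their ingredients."""

    offsets: pd.DataFrame  # genes x samples
    tmm: pd.Series  # per-sample factors
    smoother_fit: SmootherFit
    library_sizes: pd.Series

    def average_sample_term(self, library_size: float | None = None) -> float:
        """Per-sample offset term for average library conditions.

        With an explicit ``library_size`` the term is log(size / 1e6) at the
        mean TMM factor; otherwise the across-sample mean of the fitted terms.
        """
        if library_size is not None:
            return float(np.log(library_size / 1e6))
        return float(
            np.log(
                self.tmm.to_numpy() * self.library_sizes.to_numpy() / 1e6
            ).mean()
        )


def compose_offsets(
    factors: np.ndarray | pd.Series,
    smoother_fit: SmootherFit,
    library_sizes: np.ndarray | pd.Series,
    gene_ids: list[str] | None = None,
    sample_ids: list[str] | None = None,
) -> NormalizationOffsets:
    """Combine TMM factors, library sizes and the smoother into offsets."""
    factors = np.asarray(factors, float)
    lib = np.asarray(library_sizes, float)
    if factors.shape != lib.shape:
        raise ValueError("tmm factors and library sizes differ in length")
    gene_term = smoother_fit.fitted
    sample_term = np.log(factors * lib / 1e6)
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(len(gene_term))]
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(len(sample_term))]
    offsets = pd.DataFrame(
        gene_term[:, None] + sample_term[None, :],
        index=gene_ids,
        columns=sample_ids,
    )
    return NormalizationOffsets(
        offsets=offsets,
        tmm=pd.Series(factors, index=sample_ids),
        smoother_fit=smoother_fit,
        library_sizes=pd.Series(lib, index=sample_ids),
    )


def normalize(counts: pd.DataFrame, covariates: pd.DataFrame,
              trim_m: float = 0.30, trim_a: float = 0.05,
              span: float = 0.5,
              library_sizes: np.ndarray | None = None) -> NormalizationOffsets:
    """One-call convenience: TMM + smoother + composition.

    ``library_sizes`` (total mapped reads per sample) defaults to the column
    sums; pass the true mapped totals when the matrix covers only a subset of
    the transcriptome.
    """
    factors = tmm_factors(counts, trim_m=trim_m, trim_a=trim_a)
    fit = fit_covariate_smoother(counts, covariates, span=span)
    lib = (
        counts.to_numpy(float).sum(axis=0)
        if library_sizes is None else np.asarray(library_sizes, float)
    )
    return compose_offsets(
        factors, fit, lib,
        gene_ids=list(counts.index), sample_ids=list(counts.columns),
    )
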