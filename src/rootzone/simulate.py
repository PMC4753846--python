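"""Synthetic count experiments with the structure the activity model assumes.

Counts for gene ``g`` in sample ``s`` are negative binomial with

    log mu[g, s] = log(L_s / 1e6) + f(gc_g, log len_g)
                   + beta[g, cell(s)] + u[lane(s)] + v[rep(s)]

where ``L_s`` is the nominal library size, ``f`` a smooth length/GC bias,
``beta`` the tissue x treatment fixed effect (log reads-per-million scale for
a gene of average length and GC), and ``u``/``v`` lane and replicate effects
drawn once per lane / replicate from normals whose precisions are themselves
gamma draws.  Per-gene log-dispersions are normal across genes.  Ground truth
(activity of each of the 8 cells, planted per-tissue treatment effects) is
recorded so every downstream stage can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

TISSUES: tuple[str, ...] = ("Mz", "Ez", "Co", "St")
TREATMENTS: tuple[str, ...] = ("control", "deficit")
#: The 8 tissue x treatment cells, tissue-major (control before deficit).
CELLS: tuple[tuple[str, str], ...] = tuple(
    (t, c) for t in TISSUES for c in TREATMENTS
)
CELL_LABELS: tuple[str, ...] = tuple(f"{t}_{c}" for t, c in CELLS)


def cell_index(tissue: str, treatment: str) -> int:
    """Column index of a tissue x treatment cell in 8-vector parameters."""
    return CELLS.index((tissue, treatment))


@dataclass(frozen=True)
class SimulationConfig:
    """Generator settings; defaults emulate a desk-scale root-tissue study.

    ``beta_mean``/``beta_var`` give the diagonal-normal population of the 8
    fixed effects on the log reads-per-million scale; ``log_disp_*`` the
    normal population of log NB dispersions; the ``*_precision_*`` pairs the
    gamma distributions of the random-effect precisions.  ``fraction_inactive``
    genes have a randomly chosen subset of cells forced to ``inactive_beta``;
    ``fraction_de`` genes carry planted per-tissue treatment effects of size
    ``de_log2fc`` (random sign).
    """

    n_genes: int = 1000
    n_replicates: int = 4
    libraries_per_lane: int = 4
    beta_mean: np.ndarray = field(
        default_factory=lambda: np.full(8, np.log(15.0))
    )
    beta_var: np.ndarray = field(default_factory=lambda: np.full(8, 2.25))
    log_disp_mean: float = float(np.log(0.1))
    log_disp_var: float = 0.25
    replicate_precision_shape: float = 10.0
    replicate_precision_rate: float = 0.2
    lane_precision_shape: float = 50.0
    lane_precision_rate: float = 0.5
    mean_library_size: float = 1_000_000.0
    library_size_log_sd: float = 0.15
    fraction_inactive: float = 0.3
    fraction_de: float = 0.1
    de_log2fc: float = 2.0
    inactive_beta: float = float(np.log(0.05))
    #: log-RPM above which a cell counts as truly active at generation time.
    activity_threshold: float = float(np.log(2.0))
    # length/GC bias of expected counts (log scale, centred covariates)
    length_log_slope: float = 1.0
    gc_linear: float = 0.0
    gc_quadratic: float = -2.0
    mean_log_length: float = float(np.log(2000.0))
    sd_log_length: float = 0.6
    gc_beta_a: float = 20.0
    gc_beta_b: float = 16.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "beta_mean", np.asarray(self.beta_mean, float))
        object.__setattr__(self, "beta_var", np.asarray(self.beta_var, float))
        if self.beta_mean.shape != (8,) or self.beta_var.shape != (8,):
            raise ValueError("beta_mean and beta_var must be length-8 vectors")
        if np.any(self.beta_var < 0) or self.log_disp_var < 0:
            raise ValueError("variances must be non-negative")
        for name in (
            "replicate_precision_shape",
            "replicate_precision_rate",
            "lane_precision_shape",
            "lane_precision_rate",
            "mean_library_size",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("fraction_inactive", "fraction_de"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass
class GeneParams:
    """Per-gene ground truth drawn by :func:`draw_gene_params`."""

    gene_ids: list[str]
    beta: np.ndarray  # (n_genes, 8)
    log_dispersion: np.ndarray  # (n_genes,)
    length_bp: np.ndarray  # (n_genes,) int
    gc_fraction: np.ndarray  # (n_genes,)
    truly_active: np.ndarray  # (n_genes, 8) bool
    planted_log2fc: np.ndarray  # (n_genes, 4)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)


@dataclass
class CountMatrix:
    """Integer read counts (genes x samples) with per-gene covariates.

    When produced by :func:`simulate_counts`, ``true_offsets`` holds the
    generation-time normalization offsets (log library scaling + length/GC
    effect, natural-log scale) and ``realized`` the drawn lane/replicate
    effects and precisions, for estimator-recovery checks.
    """

    counts: pd.DataFrame
    gene_covariates: pd.DataFrame  # columns length_bp, gc_fraction
    true_offsets: pd.DataFrame | None = None
    realized: dict | None = None

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)


def generate_design(
    n_replicates: int = 4, libraries_per_lane: int = 4, seed: int = 0
) -> pd.DataFrame:
    """Assign all 8 x n_replicates libraries to incomplete blocks (lanes).

    Uses a deterministic cyclic construction: within each replicate the 8
    tissue x treatment combinations are rotated by a seed-derived offset plus
    the replicate index before being chunked into lanes, so no lane holds two
    replicates of the same combination when the lane size allows it.
    """
    total = 8 * n_replicates
    if n_replicates < 1 or libraries_per_lane < 1:
        raise ValueError("n_replicates and libraries_per_lane must be >= 1")
    if total % libraries_per_lane != 0:
        raise ValueError(
            f"{total} libraries are not divisible into lanes of "
            f"{libraries_per_lane}"
        )
    base_offset = int(np.random.default_rng(seed).integers(0, 8))
    rows = []
    for rep in range(1, n_replicates + 1):
        shift = (base_offset + rep - 1) % 8
        combos = [CELLS[(i + shift) % 8] for i in range(8)]
        for tissue, treatment in combos:
            rows.append(
                {
                    "sample_id": f"{tissue}_{treatment}_r{rep}",
                    "tissue": tissue,
                    "treatment": treatment,
                    "replicate": rep,
                }
            )
    design = pd.DataFrame(rows)
    design["lane"] = [
        f"L{1 + i // libraries_per_lane}" for i in range(total)
    ]
    return design[["sample_id", "tissue", "treatment", "replicate", "lane"]]


def draw_gene_params(config: SimulationConfig) -> GeneParams:
    """Draw per-gene fixed effects, dispersions, covariates and ground truth."""
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    beta = rng.normal(
        config.beta_mean, np.sqrt(config.beta_var), size=(n, 8)
    )
    log_disp = rng.normal(
        config.log_disp_mean, np.sqrt(config.log_disp_var), size=n
    )
    length_bp = np.maximum(
        np.round(
            np.exp(rng.normal(config.mean_log_length, config.sd_log_length, n))
        ).astype(int),
        200,
    )
    gc = rng.beta(config.gc_beta_a, config.gc_beta_b, size=n)

    planted = np.zeros((n, 4))
    n_de = int(round(config.fraction_de * n))
    if n_de:
        de_genes = rng.choice(n, size=n_de, replace=False)
        # one affected tissue per DE gene, random direction
        tissue_idx = rng.integers(0, 4, size=n_de)
        sign = rng.choice([-1.0, 1.0], size=n_de)
        planted[de_genes, tissue_idx] = sign * config.de_log2fc
        for g, t, s in zip(de_genes, tissue_idx, sign):
            beta[g, 2 * t + 1] = beta[g, 2 * t] + s * config.de_log2fc * np.log(2)

    n_inactive = int(round(config.fraction_inactive * n))
    if n_inactive:
        off_genes = rng.choice(n, size=n_inactive, replace=False)
        for g in off_genes:
            # force a random non-empty subset of cells far below threshold
            mask = rng.random(8) < 0.75
            if not mask.any():
                mask[rng.integers(0, 8)] = True
            beta[g, mask] = config.inactive_beta
            planted[g, :] = 0.0

    truly_active = beta > config.activity_threshold
    gene_ids = [f"gene_{i:05d}" for i in range(n)]
    return GeneParams(
        gene_ids=gene_ids,
        beta=beta,
        log_dispersion=log_disp,
        length_bp=length_bp,
        gc_fraction=gc,
        truly_active=truly_active,
        planted_log2fc=planted,
    )


def _covariate_effect(params: GeneParams, config: SimulationConfig) -> np.ndarray:
    loglen = np.log(params.length_bp)
    gc_centre = config.gc_beta_a / (config.gc_beta_a + config.gc_beta_b)
    gcd = params.gc_fraction - gc_centre
    return (
        config.length_log_slope * (loglen - config.mean_log_length)
        + config.gc_linear * gcd
        + config.gc_quadratic * gcd**2
    )


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Gamma-Poisson draw: var = mu + phi * mu^2 (Poisson when phi ~ 0)."""
    mu = np.asarray(mu, float)
    phi = np.broadcast_to(np.asarray(phi, float), mu.shape)
    out = np.zeros(mu.shape, dtype=np.int64)
    pois = phi < 1e-10
    if pois.any():
        out[pois] = rng.poisson(mu[pois])
    od = ~pois & (mu > 0)
    if od.any():
        r = 1.0 / phi[od]
        lam = rng.gamma(shape=r, scale=mu[od] / r)
        out[od] = rng.poisson(lam)
    return out


def simulate_counts(
    params: GeneParams,
    design: pd.DataFrame,
    config: SimulationConfig,
    seed: int | None = None,
) -> CountMatrix:
    """Simulate the NB count matrix for a drawn gene population and design."""
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    n_samples = len(design)
    lanes = list(dict.fromkeys(design["lane"]))
    reps = sorted(design["replicate"].unique())

    tau_lane = rng.gamma(
        config.lane_precision_shape, 1.0 / config.lane_precision_rate
    )
    tau_rep = rng.gamma(
        config.replicate_precision_shape, 1.0 / config.replicate_precision_rate
    )
    u = rng.normal(0.0, 1.0 / np.sqrt(tau_lane), size=len(lanes))
    v = rng.normal(0.0, 1.0 / np.sqrt(tau_rep), size=len(reps))
    lane_of = {lane: i for i, lane in enumerate(lanes)}
    rep_of = {rep: i for i, rep in enumerate(reps)}

    lib = np.exp(
        rng.normal(
            np.log(config.mean_library_size), config.library_size_log_sd, n_samples
        )
    )
    cov_eff = _covariate_effect(params, config)
    cells = np.array(
        [cell_index(t, c) for t, c in zip(design["tissue"], design["treatment"])]
    )
    sample_log_off = (
        np.log(lib / 1e6)
        + u[[lane_of[l] for l in design["lane"]]]
        + v[[rep_of[r] for r in design["replicate"]]]
    )
    # (genes, samples)
    log_mu = cov_eff[:, None] + params.beta[:, cells] + sample_log_off[None, :]
    phi = np.exp(params.log_dispersion)[:, None]
    counts = _nb_draw(rng, np.exp(log_mu), phi)

    counts_df = pd.DataFrame(
        counts, index=params.gene_ids, columns=list(design["sample_id"])
    )
    covariates = pd.DataFrame(
        {
            "length_bp": params.length_bp,
            "gc_fraction": params.gc_fraction,
        },
        index=params.gene_ids,
    )
    true_offsets = pd.DataFrame(
        cov_eff[:, None] + np.log(lib / 1e6)[None, :],
        index=params.gene_ids,
        columns=list(design["sample_id"]),
    )
    realized = {
        "lane_effects": dict(zip(lanes, u)),
        "replicate_effects": dict(zip(reps, v)),
        "lane_precision": tau_lane,
        "replicate_precision": tau_rep,
        "library_sizes": dict(zip(design["sample_id"], lib)),
    }
    return CountMatrix(
        counts=counts_df,
        gene_covariates=covariates,
        true_offsets=true_offsets,
        realized=realized,
    )


def ground_truth_frame(params: GeneParams) -> pd.DataFrame:
    """Per-gene truth table: 8 activity booleans + 4 planted log2 fold changes."""
    data: dict[str, np.ndarray] = {}
    for k, label in enumerate(CELL_LABELS):
        data[f"active_{label}"] = params.truly_active[:, k]
    for t, tissue in enumerate(TISSUES):
        data[f"log2fc_{tissue}"] = params.planted_log2fc[:, t]
    return pd.DataFrame(data, index=pd.Index(params.gene_ids, name="gene_id"))


def write_fixture(
    matrix: CountMatrix,
    design: pd.DataFrame,
    params: GeneParams,
    path: str | Path,
) -> dict[str, Path]:
    """Write counts/design/covariate/truth TSVs that round-trip via rootzone.io."""
    from rootzone import io as rio

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": path / "counts.tsv",
        "design": path / "design.tsv",
        "covariates": path / "covariates.tsv",
        "truth": path / "truth.tsv",
    }
    rio.write_table(matrix.counts.rename_axis("gene_id"), paths["counts"], "counts")
    rio.write_table(design.set_index("sample_id"), paths["design"], "design")
    rio.write_table(
        matrix.gene_covariates.rename_axis("gene_id"),
        paths["covariates"],
        "covariates",
    )
    rio.write_table(ground_truth_frame(params), paths["truth"], "truth")
    return paths
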