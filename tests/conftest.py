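"""Shared fixtures: one mid-sized simulated experiment reused across modules."""

from __future__ import annotations

import numpy as np
import pytest

from rootzone import activity as act
from rootzone import normalization as norm
from rootzone import simulate as sim


@pytest.fixture(scope="session")
def experiment():
    """An 800-gene simulated experiment with its normalization offsets."""
    cfg = sim.SimulationConfig(n_genes=800, seed=3)
    design = sim.generate_design(
        cfg.n_replicates, cfg.libraries_per_lane, seed=cfg.seed
    )
    params = sim.draw_gene_params(cfg)
    mat = sim.simulate_counts(params, design, cfg)
    lib = np.array(
        [mat.realized["library_sizes"][s] for s in mat.counts.columns]
    )
    offsets = norm.normalize(mat.counts, mat.gene_covariates, library_sizes=lib)
    return {
        "config": cfg,
        "design": design,
        "params": params,
        "matrix": mat,
        "library_sizes": lib,
        "offsets": offsets,
    }


@pytest.fixture(scope="session")
def hyper(experiment):
    """Estimated hyperparameters of the shared experiment."""
    return act.estimate_hyperparameters(
        experiment["matrix"].counts,
        experiment["design"],
        experiment["offsets"].offsets,
    )


@pytest.fixture()
def default_hyper():
    """Population parameters matching the generator's defaults."""
    return act.Hyperparameters(
        beta_mean=np.full(8, np.log(15.0)),
        beta_var=np.full(8, 2.25),
        log_disp_mean=float(np.log(0.1)),
        log_disp_var=0.25,
    )
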