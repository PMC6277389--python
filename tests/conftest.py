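"""Shared fixtures: a default-scale screening run (computed once per session)
and a small fast scenario for unit-level checks."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pytest

from bamscope import (
    ScenarioConfig,
    compute_tscore_bam,
    consensus_cluster,
    cut_clusters,
    fit_pca,
    hypergeom_overrep,
    make_default_template,
    select_k,
    simulate_bam_library,
)
from bamscope.phenoprint import project_library


@dataclass
class Run:
    """Materialised pipeline state shared across tests."""

    cfg: ScenarioConfig
    library: object
    truth: object
    table: pd.DataFrame
    maps: dict
    template: object
    model: object
    pp_train: pd.DataFrame
    pp_test: pd.DataFrame
    consensus: object
    k: int
    assignment: object
    association: object


def _materialise(cfg: ScenarioConfig, consensus_seed: int, n_iterations: int) -> Run:
    library, truth, table = simulate_bam_library(cfg)
    maps = {d: compute_tscore_bam(s) for d, s in library.bams.items()}
    template = make_default_template(cfg.grid_h, cfg.grid_w)
    train = [d for d, m in truth.membership.items() if m == "training"]
    test = [d for d, m in truth.membership.items() if m == "test"]
    n_comp = min(20, len(train) - 1)
    model = fit_pca(np.stack([maps[d] for d in train]), template.mask, n_comp)
    cols = [f"pc{i + 1}" for i in range(model.n_components)]
    pp_train = pd.DataFrame(
        project_library(np.stack([maps[d] for d in train]), model), index=train, columns=cols
    )
    pp_test = pd.DataFrame(
        project_library(np.stack([maps[d] for d in test]), model), index=test, columns=cols
    )
    k_hi = min(15, len(train) - 1)
    result = consensus_cluster(
        pp_train.to_numpy(), train, range(2, k_hi + 1), n_iterations=n_iterations, seed=consensus_seed
    )
    k = select_k(result)
    assignment = cut_clusters(result, k, tscore_maps=maps)
    association = hypergeom_overrep(assignment, table, phenoprints=pp_train)
    return Run(
        cfg=cfg,
        library=library,
        truth=truth,
        table=table,
        maps=maps,
        template=template,
        model=model,
        pp_train=pp_train,
        pp_test=pp_test,
        consensus=result,
        k=k,
        assignment=assignment,
        association=association,
    )


@pytest.fixture(scope="session")
def default_run() -> Run:
    """The default study-scale scenario (179 training / 121 test drugs,
    5 replicates, default noise), clustered with 250 consensus resamples."""
    return _materialise(ScenarioConfig(seed=1), consensus_seed=11, n_iterations=250)


@pytest.fixture(scope="session")
def small_run() -> Run:
    """A reduced scenario (fast) with the same statistical structure."""
    cfg = ScenarioConfig(
        n_train_drugs=48,
        n_test_drugs=24,
        n_clusters=4,
        grid_h=24,
        grid_w=16,
        seed=7,
    )
    return _materialise(cfg, consensus_seed=5, n_iterations=120)
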