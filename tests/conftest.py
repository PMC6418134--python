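"""Shared fixtures: small deterministic studies built from the generator."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from gcna import CohortStudy, ExpressionMatrix, SimulationConfig, generate_cohort

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


def make_study(
    values: np.ndarray,
    genes: list[str],
    event: np.ndarray | None = None,
    time: np.ndarray | None = None,
    node: np.ndarray | None = None,
    cohort: str = "test",
) -> CohortStudy:
    """Build a CohortStudy directly from arrays (genes x samples)."""
    n = values.shape[1]
    samples = [f"{cohort}_S{i:03d}" for i in range(n)]
    expr = ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples), cohort=cohort)
    rng = np.random.default_rng(0)
    clinical = pd.DataFrame(
        {
            "recurrence_event": event if event is not None else rng.binomial(1, 0.4, n).astype(float),
            "followup_time": time if time is not None else rng.exponential(8.0, n) + 0.01,
            "node_status": node if node is not None else rng.binomial(1, 0.2, n).astype(float),
            "cohort": cohort,
        },
        index=pd.Index(samples, name="sample_id"),
    )
    return CohortStudy(expr, clinical, [cohort])


def signal_config(
    rng_seed: int,
    n_samples: int = 2000,
    n_genes: int = 40,
    gene_log_hr: dict | None = None,
    block_rho: float = 0.95,
    with_block: bool = True,
) -> SimulationConfig:
    """Small single-cohort config: optional planted block, custom effects."""
    return SimulationConfig(
        rng_seed=rng_seed,
        n_cohorts=1,
        n_samples=n_samples,
        n_genes=n_genes,
        seed_gene_ids=("LST1", "IGHM", "CAND01", "CAND02"),
        seed_coupled_ids=("LST1", "IGHM") if with_block else (),
        block_gene_ids=("IGHA1", "IGHD", "IGHG1", "IGHG3", "IGLC2", "IGLJ3") if with_block else (),
        gene_log_hr=gene_log_hr,
        block_rho=block_rho,
        cohort_shift=((0.0, 1.0),),
        n_missing_events=0,
    )


@pytest.fixture(scope="session")
def block_study() -> CohortStudy:
    """One cohort, n=2000, planted block at Spearman 0.95, per-gene HR 0.85."""
    return generate_cohort(signal_config(rng_seed=11), 0)


@pytest.fixture(scope="session")
def null_study() -> CohortStudy:
    """One cohort with no planted structure and no survival effects."""
    cfg = signal_config(rng_seed=13, n_samples=1000, n_genes=30,
                        gene_log_hr={}, with_block=False)
    return generate_cohort(cfg, 0)
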