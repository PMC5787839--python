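"""Shared fixtures: one small fully simulated study reused across tests."""

import numpy as np
import pandas as pd
import pytest

from bsmeth import core
from bsmeth.simulate import SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def study():
    """Small two-condition study with planted CG DMRs and coupled expression."""
    cfg = SimulationConfig(
        seed=7,
        chrom_lengths=[80_000, 80_000],
        gene_count=30,
        te_fraction=0.30,
        n_dmrs=4,
        spike_in_length=20_000,
    )
    cfg.expression.couple_promoter_hyper = True
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def pooled(study):
    """Replicate-pooled count tables per condition."""
    reps = range(1, study.config.replicates_per_condition + 1)
    return {
        cond: core.pool_replicates([study.counts[(cond, r)] for r in reps])
        for cond in ("control", "case")
    }


@pytest.fixture(scope="session")
def site_tables(study, pooled):
    """Site-methylation tables per condition (nonconversion-corrected)."""
    r, _ = core.estimate_nonconversion(pooled["control"], "lambda")
    return {
        cond: core.compute_site_methylation(tab, r=r, min_coverage=4)
        for cond, tab in pooled.items()
    } | {"r": r}


@pytest.fixture(scope="session")
def main_lengths(study):
    """Chromosome lengths excluding the spike-in."""
    return {
        name: length
        for name, length in study.genome.lengths.items()
        if name != study.genome.spike_in_chrom
    }
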