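import numpy as np
import pandas as pd
import pytest

from oxbstools.config import SimConfig
from oxbstools.io import assemble_matrix
from oxbstools import mlml, pooling
from oxbstools.simulate import simulate_dataset

# The frozen simulation seed for all study-scale checks.
STUDY_SEED = 1

# Smoothing span for the synthetic-scale DMR analyses: matched to the smallest
# injected DMR (10 CpGs at ~100 bp spacing), chosen by the matched-filter
# principle and a pilot bandwidth sweep on separate seeds.
DMR_SMOOTH = dict(h_bp=500.0, min_cpgs_smooth=21)


@pytest.fixture(scope="session")
def small_dataset():
    """A light simulated study reused by module-level tests."""
    cfg = SimConfig(n_chrom=2, cpgs_per_chrom=2000, seed=7,
                    n_dmrs_5mc=4, n_dmrs_5hmc=4)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_matrix(small_dataset):
    ds = small_dataset
    return assemble_matrix(ds.sheet, ds.reports)


@pytest.fixture(scope="session")
def study_dataset():
    """The study-scale simulation: 3v3 animals, 1 chromosome x 20,000 CpGs,
    8X coverage, bases 58.7% / 4.4%, 20 injected DMRs per methylation type."""
    cfg = SimConfig(n_chrom=1, cpgs_per_chrom=20_000, seed=STUDY_SEED,
                    n_dmrs_5mc=20, n_dmrs_5hmc=20)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def null_dataset():
    """Same study conditions with zero injected DMRs."""
    cfg = SimConfig(n_chrom=1, cpgs_per_chrom=20_000, seed=STUDY_SEED,
                    n_dmrs_5mc=0, n_dmrs_5hmc=0)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def corr_dataset():
    """A wider genome (more genes) for the methylation-expression
    correlation analysis, where the observation unit is the gene/element."""
    cfg = SimConfig(n_chrom=4, cpgs_per_chrom=10_000, seed=STUDY_SEED,
                    n_dmrs_5mc=0, n_dmrs_5hmc=0)
    ds = simulate_dataset(cfg)
    matrix = assemble_matrix(ds.sheet, ds.reports)
    pooled, _ = pooling.run_pooling(matrix, ds.sheet)
    return {"ds": ds, "est_pooled": mlml.estimate_all(pooled, ds.sheet)}


@pytest.fixture(scope="session")
def study_pipeline(study_dataset):
    """Matrix, pooled matrix and estimates for the study-scale simulation."""
    ds = study_dataset
    matrix = assemble_matrix(ds.sheet, ds.reports)
    pooled, report = pooling.run_pooling(matrix, ds.sheet)
    est_pooled = mlml.estimate_all(pooled, ds.sheet)
    est_raw = mlml.estimate_all(matrix, ds.sheet)
    return {"ds": ds, "matrix": matrix, "pooled": pooled,
            "report": report, "est_pooled": est_pooled, "est_raw": est_raw}


@pytest.fixture(scope="session")
def null_pipeline(null_dataset):
    ds = null_dataset
    matrix = assemble_matrix(ds.sheet, ds.reports)
    pooled, _ = pooling.run_pooling(matrix, ds.sheet)
    return {"ds": ds, "matrix": matrix, "pooled": pooled,
            "est_pooled": mlml.estimate_all(pooled, ds.sheet),
            "est_raw": mlml.estimate_all(matrix, ds.sheet)}
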