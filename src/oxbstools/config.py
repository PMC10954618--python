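"""Configuration objects for the simulator and the end-to-end pipeline.

Every tunable of the analysis lives here with its default, so that a run can
be reproduced from the frozen config copy the pipeline writes next to its
outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Tuple

import yaml


class ConfigError(ValueError):
    """Raised when a configuration field fails validation."""


def _check(cond: bool, fieldname: str, message: str) -> None:
    if not cond:
        raise ConfigError(f"{fieldname}: {message}")


@dataclass
class SimConfig:
    """Parameters of the synthetic paired BS/OxBS study.

    The defaults emulate the structure of the whole-genome data the pipeline
    is designed for: two groups of 3 animals, one BS and one OxBS library per
    animal at ~8X mean CpG coverage, genome-wide mean 5mC near 58.7% and 5hmC
    near 4.4%, block-structured background methylation, and injected
    inter-group DMRs at the calling thresholds (10% for 5mC, 1% for 5hmC).
    """

    n_chrom: int = 1
    cpgs_per_chrom: int = 20_000
    mean_coverage: float = 8.0          # reads per CpG dyad per library
    group_sizes: Tuple[int, int] = (3, 3)
    base_5mc: float = 0.587
    base_5hmc: float = 0.044
    n_dmrs_5mc: int = 20
    n_dmrs_5hmc: int = 20
    dmr_size_cpgs: Tuple[int, int] = (10, 30)
    dmr_effect_5mc: float = 0.10
    dmr_effect_5hmc: float = 0.01
    bs_conversion_error: float = 0.0    # unmethylated C read as methylated in BS
    oxbs_oxidation_failure: float = 0.0  # fraction of 5hmC read as methylated in OxBS
    seed: int = 0

    # genome geometry
    cpg_gap_bp: Tuple[int, int] = (50, 150)
    gene_body_bp: Tuple[int, int] = (20_000, 40_000)
    intergenic_bp: Tuple[int, int] = (8_000, 16_000)
    promoter_bp: int = 2_000
    random_element_bp: Tuple[int, int] = (300, 1_500)

    # background methylation structure: piecewise-constant blocks with
    # Beta-distributed block means around the base rates
    block_cpgs: Tuple[int, int] = (50, 200)
    block_conc_5mc: float = 120.0
    block_conc_5hmc: float = 300.0

    # expression model
    expr_coupling: float = 1.0          # log-scale slope on standardised intronic 5hmC
    expr_dispersion: float = 0.1        # NB dispersion (var = mu + a*mu^2)
    expr_baseline_mean: float = 500.0
    libsize_factor_range: Tuple[float, float] = (0.6, 1.6)

    def validate(self) -> "SimConfig":
        _check(self.n_chrom >= 0, "n_chrom", "must be >= 0")
        _check(self.cpgs_per_chrom >= 0, "cpgs_per_chrom", "must be >= 0")
        _check(self.mean_coverage > 0, "mean_coverage", "must be > 0")
        _check(len(self.group_sizes) == 2 and all(g >= 1 for g in self.group_sizes),
               "group_sizes", "needs two counts, both >= 1")
        for name in ("base_5mc", "base_5hmc", "dmr_effect_5mc", "dmr_effect_5hmc",
                     "bs_conversion_error", "oxbs_oxidation_failure"):
            v = getattr(self, name)
            _check(0.0 <= v <= 1.0, name, "must be a proportion in [0, 1]")
        _check(self.base_5mc + self.base_5hmc <= 1.0, "base_5mc",
               "base_5mc + base_5hmc must not exceed 1")
        _check(self.n_dmrs_5mc >= 0, "n_dmrs_5mc", "must be >= 0")
        _check(self.n_dmrs_5hmc >= 0, "n_dmrs_5hmc", "must be >= 0")
        lo, hi = self.dmr_size_cpgs
        _check(lo >= 3, "dmr_size_cpgs", "minimum DMR size must be >= 3 CpGs")
        _check(lo <= hi, "dmr_size_cpgs", "range must be (min, max) with min <= max")
        _check(self.cpg_gap_bp[0] >= 2, "cpg_gap_bp", "CpG gaps must be >= 2 bp")
        _check(self.block_cpgs[0] >= 1 and self.block_cpgs[0] <= self.block_cpgs[1],
               "block_cpgs", "range must be (min, max) with 1 <= min <= max")
        _check(self.expr_dispersion >= 0, "expr_dispersion", "must be >= 0")
        _check(int(self.seed) == self.seed, "seed", "must be an integer")
        return self


@dataclass
class RunConfig:
    """Stage parameters and paths for the end-to-end pipeline run."""

    # inputs
    sample_sheet: Optional[str] = None
    elements: Optional[str] = None
    genes: Optional[str] = None
    counts: Optional[str] = None
    output_dir: str = "oxbstools_run"

    # pooling stage
    window_size: int = 30
    step: int = 2
    min_pooled_coverage: float = 100.0
    outlier_pct: float = 99.9
    min_per_group: int = 1
    combined_mode: str = "per-animal-pair"   # or "all-libraries"

    # DMR stage
    dmr_min_reads: int = 2
    dmr_strict_prefilter: bool = False
    h_bp: float = 1000.0
    min_cpgs_smooth: int = 70
    var_floor_quantile: float = 0.75
    max_tcap: float = 50.0
    cutoff_quantiles: Tuple[float, float] = (0.025, 0.975)
    min_dmr_cpgs: int = 3
    min_diff_5mc: float = 0.10
    min_diff_5hmc: float = 0.01

    # enrichment / correlation
    classic_jaccard: bool = False
    unique_query_overlaps: bool = False

    seed: int = 0

    def validate(self) -> "RunConfig":
        _check(self.window_size >= 1, "window_size", "must be >= 1")
        _check(self.step >= 1, "step", "must be >= 1")
        _check(self.step <= self.window_size, "step",
               "step must not exceed window_size")
        _check(0 < self.outlier_pct <= 100, "outlier_pct", "must be in (0, 100]")
        _check(self.min_pooled_coverage >= 0, "min_pooled_coverage", "must be >= 0")
        _check(self.min_per_group >= 0, "min_per_group", "must be >= 0")
        _check(self.combined_mode in ("per-animal-pair", "all-libraries"),
               "combined_mode", "must be 'per-animal-pair' or 'all-libraries'")
        lo, hi = self.cutoff_quantiles
        _check(0 < lo < hi < 1, "cutoff_quantiles", "need 0 < low < high < 1")
        _check(self.min_dmr_cpgs >= 1, "min_dmr_cpgs", "must be >= 1")
        _check(self.h_bp > 0, "h_bp", "must be > 0")
        _check(self.min_cpgs_smooth >= 1, "min_cpgs_smooth", "must be >= 1")
        _check(0 < self.var_floor_quantile < 1, "var_floor_quantile",
               "must be in (0, 1)")
        return self


def _from_mapping(cls, data: dict, source: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = sorted(set(data) - known)
    if unknown:
        raise ConfigError(f"{source}: unknown keys {unknown}")
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name in data:
            v = data[f.name]
            if isinstance(v, list):
                v = tuple(v)
            kwargs[f.name] = v
    return cls(**kwargs).validate()


def load_sim_config(path) -> SimConfig:
    """Load a SimConfig from a YAML mapping; unknown keys are rejected."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    return _from_mapping(SimConfig, data, str(path))


def load_run_config(path) -> RunConfig:
    """Load a RunConfig from a YAML mapping; unknown keys are rejected."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    return _from_mapping(RunConfig, data, str(path))


def dump_config(cfg, path) -> None:
    """Write the resolved config back out, freezing the run's parameters."""
    data = dataclasses.asdict(cfg)
    for k, v in data.items():
        if isinstance(v, tuple):
            data[k] = list(v)
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))
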