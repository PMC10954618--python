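"""End-to-end orchestration with a fixed stage order and a run manifest.

Stage order: assemble -> normalize -> outlier-filter -> unite -> window ->
pool -> estimate (pooled and per-CpG) -> per-type DMR calling (prefilter ->
smooth -> tstat -> dmrFind -> filter -> rank) -> annotate/enrich ->
correlate. Every stage's record counts and every output file digest are
recorded in ``manifest.json`` so filtering decisions are auditable;
intermediate tables are always written, enabling stage-level inspection.

Genome-summary figures are computed two ways on purpose: the
report-subtraction percentages come from the raw, unpooled counts (the
alignment-report analogue), the MLML means from the pooled estimates.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd

from . import annotate, dmr, expression, mlml, pooling
from .config import RunConfig, dump_config
from .io import (read_elements, read_genes, read_sample_sheet, assemble_matrix,
                 write_bed)

logger = logging.getLogger(__name__)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write(df: pd.DataFrame, path: Path, manifest: dict, **kw) -> None:
    df.to_csv(path, sep="\t", index=kw.pop("index", False), **kw)
    manifest["digests"][path.name] = _digest(path)


def run_all(config: RunConfig, sheet: Optional[pd.DataFrame] = None) -> dict:
    """Execute the pipeline per ``config``; returns the run manifest."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": {}, "digests": {},
                      "config": dataclasses.asdict(config)}
    stages = manifest["stages"]
    dump_config(config, out / "config.resolved.yaml")

    try:
        if sheet is None:
            if config.sample_sheet is None:
                raise ValueError("run_all needs a sample sheet")
            sheet = read_sample_sheet(config.sample_sheet)
        matrix = assemble_matrix(sheet)
        stages["assemble"] = {"in": int(len(sheet)), "out": int(len(matrix))}
        _write(matrix, out / "matrix_raw.tsv", manifest)

        pooled, report = pooling.run_pooling(
            matrix, sheet, config.window_size, config.step,
            config.min_pooled_coverage, config.outlier_pct,
            config.min_per_group, config.combined_mode)
        stages["pooling"] = report
        _write(pooled, out / "pooled.tsv", manifest)

        est_pooled = mlml.estimate_all(pooled, sheet)
        _write(est_pooled, out / "estimates_pooled.tsv", manifest)
        est_raw = mlml.estimate_all(matrix, sheet)
        _write(est_raw, out / "estimates_unpooled.tsv", manifest)
        stages["estimate"] = {"pooled_sites": int(len(est_pooled)),
                              "unpooled_sites": int(len(est_raw))}

        summary = mlml.genome_summary(matrix, sheet, estimates=est_pooled)
        (out / "summary.json").write_text(
            json.dumps(dataclasses.asdict(summary), indent=2, sort_keys=True))
        manifest["digests"]["summary.json"] = _digest(out / "summary.json")

        dmr_results: Dict[str, pd.DataFrame] = {}
        for mtype, min_diff in (("5mC", config.min_diff_5mc),
                                ("5hmC", config.min_diff_5hmc)):
            res = dmr.call_dmrs(
                est_raw, sheet, mtype, min_reads=config.dmr_min_reads,
                strict_prefilter=config.dmr_strict_prefilter,
                h_bp=config.h_bp, min_cpgs_smooth=config.min_cpgs_smooth,
                var_floor_quantile=config.var_floor_quantile,
                max_cap=config.max_tcap,
                cutoff_quantiles=config.cutoff_quantiles,
                min_dmr_cpgs=config.min_dmr_cpgs, min_diff=min_diff)
            tag = mtype.lower()
            stages[f"dmr_{tag}"] = {
                "in": int(len(est_raw)),
                "prefilter_removed": int(res.n_prefiltered),
                "candidates": int(len(res.candidates)),
                "filtered": int(len(res.dmrs)),
            }
            _write(res.dmrs, out / f"dmrs_{tag}.tsv", manifest)
            write_bed(res.dmrs, out / f"dmrs_{tag}.bed",
                      name_col="rank", score_col="area_stat")
            manifest["digests"][f"dmrs_{tag}.bed"] = _digest(
                out / f"dmrs_{tag}.bed")
            dmr_results[mtype] = res.dmrs

        if config.elements:
            elements = read_elements(config.elements)
            genes = read_genes(config.genes) if config.genes else None
            if elements["gene_id"].isna().any() and genes is not None:
                na = elements["gene_id"].isna()
                elements.loc[na, "gene_id"] = annotate.closest_gene(
                    elements.loc[na], genes).to_numpy()
            enr = pd.concat([
                annotate.enrichment_table(
                    dmr_results[mtype], elements, mtype,
                    classic=config.classic_jaccard,
                    unique_queries=config.unique_query_overlaps)
                for mtype in dmr_results], ignore_index=True)
            _write(enr, out / "enrichment.tsv", manifest)
            stages["enrichment"] = {"elements": int(len(elements)),
                                    "rows": int(len(enr))}

            animals = sorted(set(sheet["animal"]))
            value_cols = [f"{a}.{v}" for a in animals for v in ("p_m", "p_h")]
            elem_meth = annotate.element_mean_methylation(
                est_pooled, elements, value_cols)
            _write(elem_meth, out / "element_methylation.tsv", manifest)

            if config.counts:
                counts = pd.read_csv(config.counts, sep="\t", index_col=0)
                factors = expression.tmm_factors(counts)
                normed = expression.normalize_expression(counts, factors)
                groups = dict(sheet[["animal", "group"]]
                              .drop_duplicates().itertuples(index=False))
                corr = expression.correlate_elements(elem_meth, normed, groups)
                _write(corr, out / "correlation.tsv", manifest)
                mat = expression.correlation_matrix(corr)
                (out / "correlation_heatmap.txt").write_text(
                    expression.render_heatmap(mat) + "\n")
                manifest["digests"]["correlation_heatmap.txt"] = _digest(
                    out / "correlation_heatmap.txt")
                stages["correlate"] = {
                    "genes": int(len(counts)),
                    "cells": int(len(corr)),
                    "tmm_factors": {k: float(v) for k, v in factors.items()},
                }
    except Exception as exc:
        stage = list(stages)[-1] if stages else "setup"
        raise RuntimeError(f"pipeline aborted after stage '{stage}': {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True))
    return manifest
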