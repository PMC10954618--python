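"""Synthetic paired BS/OxBS study generator with known ground truth.

The generator emulates the structure the pipeline assumes: two groups of
animals, each contributing one BS and one OxBS library at low (~8X) mean CpG
coverage; background methylation organised in piecewise-constant blocks of
50-200 CpGs whose means are Beta-distributed around the genome-wide base
rates (58.7% 5mC, 4.4% 5hmC); non-overlapping injected DMRs shifting exactly
one methylation type in the case group; classed functional elements laid
over non-overlapping genes; and a gene expression matrix whose expected
counts increase monotonically with the group-truth mean intronic 5hmC
(negative binomial counts, unequal library sizes to exercise TMM).

Measurement model: per CpG dyad and library, coverage ~ Poisson(mean);
coverage splits binomially between the two strands; each strand's methylated
count is Binomial with success probability p_m + p_h (BS) or p_m (OxBS),
plus the optional error terms. What it does NOT model: read-level artifacts,
PCR duplicates, CpH contexts, inter-animal biological variability of the
truth (animals within a group share the group truth, so within-group
variance is purely sampling noise).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from . import annotate
from .config import SimConfig
from .io import (ELEMENT_CLASSES, REPORT_COLUMNS, write_cytosine_report,
                 write_elements, write_sample_sheet)

logger = logging.getLogger(__name__)


@dataclass
class SimTruth:
    """Ground truth: per-CpG per-group triples, injected DMRs, expression model."""
    sites: pd.DataFrame          # chrom, pos, {group}.p_m / .p_h per group
    injected_dmrs: pd.DataFrame  # chrom, idx_start/idx_end (CpG indices within
                                 # chrom), start/end (bp, 0-based half-open),
                                 # methylation_type, direction, effect
    expression_model: dict


@dataclass
class SimulatedDataset:
    config: SimConfig
    cpg_map: pd.DataFrame
    elements: pd.DataFrame
    genes: pd.DataFrame
    truth: SimTruth
    sheet: pd.DataFrame
    reports: Dict[str, pd.DataFrame]
    counts: pd.DataFrame


def _rngs(config: SimConfig) -> Dict[str, np.random.Generator]:
    children = np.random.SeedSequence(int(config.seed)).spawn(4)
    names = ("genome", "truth", "reads", "expression")
    return {n: np.random.default_rng(s) for n, s in zip(names, children)}


# ---------------------------------------------------------------------------
# genome and elements
# ---------------------------------------------------------------------------

def generate_genome(config: SimConfig,
                    rng: Optional[np.random.Generator] = None
                    ) -> Tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """CpG coordinates, classed elements and gene intervals.

    Returns (cpg_map, elements, genes). CpG positions are strictly
    increasing 1-based + strand C coordinates; elements and genes are
    0-based half-open with every element assigned its closest gene.
    """
    config.validate()
    if rng is None:
        rng = _rngs(config)["genome"]
    cpg_rows, gene_rows, elem_rows = [], [], []
    for c in range(config.n_chrom):
        chrom = f"chr{c + 1}"
        gaps = rng.integers(config.cpg_gap_bp[0], config.cpg_gap_bp[1] + 1,
                            size=config.cpgs_per_chrom)
        pos = 1000 + np.cumsum(gaps)
        cpg_rows.append(pd.DataFrame({"chrom": chrom, "pos": pos}))
        chrom_len = int(pos[-1]) + 2000 if len(pos) else 4000

        cursor = 500
        k = 0
        while True:
            gap = int(rng.integers(*config.intergenic_bp))
            body = int(rng.integers(*config.gene_body_bp))
            start = cursor + gap
            end = start + body
            if end + 500 > chrom_len:
                break
            gene_id = f"{chrom}_g{k:03d}"
            gene_rows.append({"chrom": chrom, "start": start, "end": end,
                              "gene_id": gene_id})
            e1 = start + max(200, int(0.15 * body))
            i_end = e1 + int(0.60 * body)
            elem_rows += [
                {"chrom": chrom, "start": max(0, start - config.promoter_bp),
                 "end": start, "element_class": "promoter", "gene_id": gene_id},
                {"chrom": chrom, "start": start, "end": e1,
                 "element_class": "exon", "gene_id": gene_id},
                {"chrom": chrom, "start": e1, "end": i_end,
                 "element_class": "intron", "gene_id": gene_id},
                {"chrom": chrom, "start": i_end, "end": end,
                 "element_class": "exon", "gene_id": gene_id},
                {"chrom": chrom, "start": start + int(0.05 * body), "end": e1,
                 "element_class": "CDS", "gene_id": gene_id},
                {"chrom": chrom, "start": i_end,
                 "end": i_end + max(100, int(0.10 * body)),
                 "element_class": "CDS", "gene_id": gene_id},
            ]
            cursor = end
            k += 1
        n_genes = k
        for cls in ("enhancer", "CTCF", "TF_binding", "open_chromatin"):
            for _ in range(max(4, n_genes // 2)):
                length = int(rng.integers(*config.random_element_bp))
                start = int(rng.integers(0, max(1, chrom_len - length)))
                elem_rows.append({"chrom": chrom, "start": start,
                                  "end": start + length, "element_class": cls,
                                  "gene_id": None})
    cpg_map = (pd.concat(cpg_rows, ignore_index=True) if cpg_rows
               else pd.DataFrame(columns=["chrom", "pos"]))
    genes = pd.DataFrame(gene_rows, columns=["chrom", "start", "end", "gene_id"])
    elements = pd.DataFrame(
        elem_rows, columns=["chrom", "start", "end", "element_class", "gene_id"])
    if len(elements):
        unassigned = elements["gene_id"].isna()
        if unassigned.any() and len(genes):
            elements.loc[unassigned, "gene_id"] = annotate.closest_gene(
                elements.loc[unassigned], genes).to_numpy()
        elements["element_id"] = [
            f"{r.element_class}_{i:05d}" for i, r in
            enumerate(elements.itertuples(index=False))]
        elements = elements[["chrom", "start", "end", "element_class",
                             "gene_id", "element_id"]]
    missing = set(ELEMENT_CLASSES) - set(elements.get("element_class", []))
    if missing and len(cpg_map):
        logger.warning("element classes not represented: %s", sorted(missing))
    return cpg_map, elements, genes


# ---------------------------------------------------------------------------
# truth
# ---------------------------------------------------------------------------

def _beta_params(mean: float, conc: float) -> Tuple[float, float]:
    return mean * conc, (1.0 - mean) * conc


def generate_truth(config: SimConfig, cpg_map: pd.DataFrame,
                   rng: Optional[np.random.Generator] = None) -> SimTruth:
    """Block-structured background truth plus injected DMRs.

    Background 5mC/5hmC levels are constant within blocks of 50-200 CpGs
    with Beta-distributed block means around the base rates; both groups
    share the background. Each injected DMR shifts exactly one methylation
    type in the case group by exactly the configured effect; DMRs never
    overlap each other.
    """
    config.validate()
    if len(cpg_map) == 0:
        raise ValueError("cpg_map is empty")
    if rng is None:
        rng = _rngs(config)["truth"]
    a_m, b_m = _beta_params(config.base_5mc, config.block_conc_5mc)
    a_h, b_h = _beta_params(config.base_5hmc, config.block_conc_5hmc)

    site_pieces, dmr_rows = [], []
    n_m_left, n_h_left = config.n_dmrs_5mc, config.n_dmrs_5hmc
    chrom_sizes = cpg_map.groupby("chrom", sort=True).size()
    total = int(chrom_sizes.sum())
    for chrom, sub in cpg_map.groupby("chrom", sort=True):
        n = len(sub)
        p_m = np.empty(n)
        p_h = np.empty(n)
        i = 0
        while i < n:
            blk = int(rng.integers(config.block_cpgs[0],
                                   config.block_cpgs[1] + 1))
            bm = rng.beta(a_m, b_m)
            bh = rng.beta(a_h, b_h)
            bh = min(bh, 0.98 - bm)  # keep p_m + p_h off the simplex edge
            p_m[i:i + blk] = bm
            p_h[i:i + blk] = bh
            i += blk
        case_m, case_h = p_m.copy(), p_h.copy()

        share = n / total
        n_dmr_m = min(n_m_left, int(round(config.n_dmrs_5mc * share)))
        n_dmr_h = min(n_h_left, int(round(config.n_dmrs_5hmc * share)))
        if chrom == chrom_sizes.index[-1]:
            n_dmr_m, n_dmr_h = n_m_left, n_h_left
        occupied = np.zeros(n, dtype=bool)
        margin = min(50, n // 10)
        specs = ([("5mC", config.dmr_effect_5mc)] * n_dmr_m
                 + [("5hmC", config.dmr_effect_5hmc)] * n_dmr_h)
        for j, (mtype, effect) in enumerate(specs):
            placed = False
            for _ in range(2000):
                size = int(rng.integers(config.dmr_size_cpgs[0],
                                        config.dmr_size_cpgs[1] + 1))
                if n - margin - size <= margin:
                    break
                s = int(rng.integers(margin, n - margin - size))
                e = s + size  # half-open in CpG index
                if occupied[max(0, s - 5):e + 5].any():
                    continue
                direction = 1 if j % 2 == 0 else -1
                base = case_m[s:e] if mtype == "5mC" else case_h[s:e]
                other = case_h[s:e] if mtype == "5mC" else case_m[s:e]
                for direction in (direction, -direction):
                    shifted = base + direction * effect
                    if (shifted.min() >= 0.005
                            and (shifted + other).max() <= 0.995):
                        break
                else:
                    continue
                if mtype == "5mC":
                    case_m[s:e] = base + direction * effect
                else:
                    case_h[s:e] = base + direction * effect
                occupied[s:e] = True
                pos = sub["pos"].to_numpy()
                dmr_rows.append({"chrom": chrom, "idx_start": s,
                                 "idx_end": e - 1,
                                 "start": int(pos[s]) - 1,
                                 "end": int(pos[e - 1]),
                                 "n_cpg": size, "methylation_type": mtype,
                                 "direction": direction, "effect": effect})
                placed = True
                break
            if not placed:
                raise ValueError(
                    f"could not place a {mtype} DMR on {chrom} without overlap")
        n_m_left -= n_dmr_m
        n_h_left -= n_dmr_h
        site_pieces.append(pd.DataFrame({
            "chrom": chrom, "pos": sub["pos"].to_numpy(),
            "control.p_m": p_m, "control.p_h": p_h,
            "case.p_m": case_m, "case.p_h": case_h}))
    sites = pd.concat(site_pieces, ignore_index=True)
    injected = pd.DataFrame(dmr_rows, columns=[
        "chrom", "idx_start", "idx_end", "start", "end", "n_cpg",
        "methylation_type", "direction", "effect"])
    model = {
        "coupling": config.expr_coupling,
        "dispersion": config.expr_dispersion,
        "hmc_scale": float(np.sqrt(config.base_5hmc * (1 - config.base_5hmc)
                                   / (config.block_conc_5hmc + 1))),
    }
    return SimTruth(sites=sites, injected_dmrs=injected,
                    expression_model=model)


# ---------------------------------------------------------------------------
# sequencing reads
# ---------------------------------------------------------------------------

def make_sample_sheet(config: SimConfig) -> pd.DataFrame:
    rows = []
    labels = (("WT", "control"), ("KO", "case"))
    for (prefix, group), size in zip(labels, config.group_sizes):
        for i in range(1, size + 1):
            animal = f"{prefix}{i}"
            for treatment in ("BS", "OxBS"):
                rows.append({"sample_id": f"{animal}_{treatment}",
                             "animal": animal, "group": group,
                             "treatment": treatment, "path": ""})
    return pd.DataFrame(rows)


def simulate_reads(truth: SimTruth, config: SimConfig,
                   rng: Optional[np.random.Generator] = None
                   ) -> Tuple[pd.DataFrame, Dict[str, pd.DataFrame]]:
    """Per-sample Bismark-style cytosine report tables (both strands).

    Returns (sample sheet, {sample_id: calls}). BS reads score methylated
    with probability p_m + p_h (+ conversion error on the unmethylated
    fraction); OxBS with probability p_m (+ oxidation-failure leakage of
    p_h).
    """
    config.validate()
    if rng is None:
        rng = _rngs(config)["reads"]
    sheet = make_sample_sheet(config)
    n = len(truth.sites)
    chrom = truth.sites["chrom"].to_numpy()
    pos = truth.sites["pos"].to_numpy(np.int64)
    reports: Dict[str, pd.DataFrame] = {}
    for row in sheet.itertuples(index=False):
        p_m = truth.sites[f"{row.group}.p_m"].to_numpy()
        p_h = truth.sites[f"{row.group}.p_h"].to_numpy()
        if row.treatment == "BS":
            q = p_m + p_h + config.bs_conversion_error * (1.0 - p_m - p_h)
        else:
            q = p_m + config.oxbs_oxidation_failure * p_h
        q = np.clip(q, 0.0, 1.0)
        cov = rng.poisson(config.mean_coverage, size=n)
        cov_plus = rng.binomial(cov, 0.5)
        cov_minus = cov - cov_plus
        meth_plus = rng.binomial(cov_plus, q)
        meth_minus = rng.binomial(cov_minus, q)
        calls = pd.DataFrame({
            "chrom": np.repeat(chrom, 2),
            "pos": np.column_stack([pos, pos + 1]).ravel(),
            "strand": np.tile(["+", "-"], n),
            "meth_count": np.column_stack([meth_plus, meth_minus]).ravel(),
            "unmeth_count": np.column_stack(
                [cov_plus - meth_plus, cov_minus - meth_minus]).ravel(),
            "context": "CpG",
            "trinucleotide": np.tile(["CGG", "CGA"], n),
        })[REPORT_COLUMNS]
        reports[row.sample_id] = calls
    return sheet, reports


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def simulate_expression(truth: SimTruth, elements: pd.DataFrame,
                        config: SimConfig,
                        rng: Optional[np.random.Generator] = None
                        ) -> pd.DataFrame:
    """Gene x animal raw count matrix coupled to intronic 5hmC.

    Expected counts are baseline_g * exp(coupling * z) where z is the
    group-truth mean 5hmC over the gene's intron CpGs, standardised by the
    block-level 5hmC spread; counts are negative binomial (Gamma-Poisson)
    and per-animal library-size factors differ. Genes whose introns contain
    no CpG are excluded with a log message.
    """
    config.validate()
    if rng is None:
        rng = _rngs(config)["expression"]
    sheet = make_sample_sheet(config)
    animals = sheet[["animal", "group"]].drop_duplicates()
    introns = elements.loc[elements["element_class"] == "intron"]
    means = annotate.element_mean_methylation(
        truth.sites, introns, ["control.p_h", "case.p_h"])
    means = means.groupby("gene_id", as_index=True)[
        ["control.p_h", "case.p_h"]].mean()
    covered = means.dropna()
    dropped = sorted(set(means.index) - set(covered.index))
    if dropped:
        logger.info("simulate_expression: %d genes without intronic CpGs "
                    "excluded: %s", len(dropped), dropped[:5])
    genes = covered.index.to_numpy()
    scale = truth.expression_model["hmc_scale"]
    coupling = truth.expression_model["coupling"]
    disp = truth.expression_model["dispersion"]
    baseline = rng.lognormal(mean=np.log(config.expr_baseline_mean),
                             sigma=1.0, size=len(genes))
    lib = rng.uniform(*config.libsize_factor_range, size=len(animals))
    counts = {}
    for (animal, group), lf in zip(animals.itertuples(index=False), lib):
        z = (covered[f"{group}.p_h"].to_numpy() - config.base_5hmc) / scale
        mu = baseline * np.exp(coupling * 0.5 * z) * lf
        if disp > 0:
            lam = rng.gamma(shape=1.0 / disp, scale=mu * disp)
        else:
            lam = mu
        counts[animal] = rng.poisson(lam)
    out = pd.DataFrame(counts, index=pd.Index(genes, name="gene_id"))
    return out


# ---------------------------------------------------------------------------
# orchestration and file output
# ---------------------------------------------------------------------------

def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Run the whole generator with stage-separated deterministic RNG streams."""
    config.validate()
    rngs = _rngs(config)
    cpg_map, elements, genes = generate_genome(config, rngs["genome"])
    truth = generate_truth(config, cpg_map, rngs["truth"])
    sheet, reports = simulate_reads(truth, config, rngs["reads"])
    counts = simulate_expression(truth, elements, config, rngs["expression"])
    return SimulatedDataset(config=config, cpg_map=cpg_map, elements=elements,
                            genes=genes, truth=truth, sheet=sheet,
                            reports=reports, counts=counts)


def write_dataset(ds: SimulatedDataset, outdir) -> Dict[str, str]:
    """Write the simulated study to a directory; returns the file manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: Dict[str, str] = {}
    sheet = ds.sheet.copy()
    for i, row in enumerate(sheet.itertuples(index=False)):
        fname = f"{row.sample_id}.CpG_report.txt"
        write_cytosine_report(ds.reports[row.sample_id], outdir / fname)
        sheet.loc[sheet.index[i], "path"] = str(outdir / fname)
        manifest[row.sample_id] = fname
    write_sample_sheet(sheet, outdir / "samples.tsv")
    write_elements(ds.elements, outdir / "elements.tsv")
    ds.genes.to_csv(outdir / "genes.tsv", sep="\t", index=False)
    ds.counts.to_csv(outdir / "counts.tsv", sep="\t")
    ds.truth.sites.to_csv(outdir / "truth_sites.tsv", sep="\t", index=False)
    ds.truth.injected_dmrs.to_csv(outdir / "truth_dmrs.tsv", sep="\t",
                                  index=False)
    manifest.update({"samples": "samples.tsv", "elements": "elements.tsv",
                     "genes": "genes.tsv", "counts": "counts.tsv",
                     "truth_sites": "truth_sites.tsv",
                     "truth_dmrs": "truth_dmrs.tsv"})
    meta = {"config": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in vars(ds.config).items()},
            "files": manifest,
            "expression_model": ds.truth.expression_model}
    (outdir / "manifest.json").write_text(json.dumps(meta, indent=2,
                                                     sort_keys=True))
    return manifest
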