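"""Constrained maximum-likelihood estimation of (5mC, 5hmC, unmethylated).

Model
-----
BS converts unmethylated C but protects both 5mC and 5hmC, so a BS library
reads "methylated" with probability p_m + p_h. OxBS first oxidizes 5hmC so
only 5mC is protected: the OxBS methylated probability is p_m. With
methylated counts m_bs ~ Binomial(n_bs, p_m + p_h) and
m_ox ~ Binomial(n_ox, p_m), the MLE of (p_m, p_h, p_u) constrained to the
simplex has a closed form for this two-assay design:

* interior: p_m = m_ox/n_ox, p_h = m_bs/n_bs - m_ox/n_ox, p_u = 1 - m_bs/n_bs
  whenever the BS fraction is at least the OxBS fraction;
* boundary (p_h = 0) otherwise: p_m = (m_bs + m_ox)/(n_bs + n_ox), which is
  the unconstrained maximizer of the product likelihood with a common
  success probability.

The binomial log-likelihood is evaluated with real-valued "counts", so the
fractional counts produced by window pooling are accepted; the closed forms
are unchanged, and scaling both assays' counts by a common factor leaves the
estimate invariant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .io import library_key, matrix_libraries

logger = logging.getLogger(__name__)


def mlml_estimate(bs_meth, bs_total, ox_meth, ox_total):
    """Closed-form constrained MLE of (p_m, p_h, p_u) from paired counts.

    Accepts scalars or arrays (fractional counts allowed). Entries with a
    non-positive total in either assay are returned as NaN triples — one
    assay alone cannot separate 5mC from 5hmC.
    """
    bs_meth = np.asarray(bs_meth, float)
    bs_total = np.asarray(bs_total, float)
    ox_meth = np.asarray(ox_meth, float)
    ox_total = np.asarray(ox_total, float)
    scalar = bs_meth.ndim == 0
    bs_meth, bs_total, ox_meth, ox_total = np.atleast_1d(
        bs_meth, bs_total, ox_meth, ox_total)

    ok = (bs_total > 0) & (ox_total > 0)
    if np.any((bs_meth > bs_total + 1e-9) | (ox_meth > ox_total + 1e-9)):
        raise ValueError("methylated count exceeds total")

    with np.errstate(invalid="ignore", divide="ignore"):
        bs_f = np.where(ok, bs_meth / np.where(bs_total > 0, bs_total, 1.0), np.nan)
        ox_f = np.where(ok, ox_meth / np.where(ox_total > 0, ox_total, 1.0), np.nan)
        pooled = (bs_meth + ox_meth) / np.where(ok, bs_total + ox_total, 1.0)

    interior = bs_f >= ox_f
    p_m = np.where(interior, ox_f, pooled)
    p_h = np.where(interior, bs_f - ox_f, 0.0)
    p_u = 1.0 - p_m - p_h
    # guard float round-off at the simplex edges
    p_m = np.clip(p_m, 0.0, 1.0)
    p_h = np.clip(p_h, 0.0, 1.0)
    p_u = np.clip(p_u, 0.0, 1.0)
    s = p_m + p_h + p_u
    with np.errstate(invalid="ignore"):
        p_m, p_h, p_u = p_m / s, p_h / s, p_u / s
    bad = ~ok
    for arr in (p_m, p_h, p_u):
        arr[bad] = np.nan
    if scalar:
        return float(p_m[0]), float(p_h[0]), float(p_u[0])
    return p_m, p_h, p_u


def estimate_all(matrix: pd.DataFrame, sheet: pd.DataFrame) -> pd.DataFrame:
    """Per-(site, animal) MLML triples plus per-group mean triples.

    ``matrix`` may be the raw assembled matrix (integer counts) or the pooled
    matrix (real counts, NaN where a channel did not survive pooling). The
    output carries, per animal, ``{animal}.p_m/.p_h/.p_u`` and
    ``{animal}.cov`` (the smaller of the two channel totals, the per-animal
    evidence floor), and per group ``{group}.mean_p_m/.mean_p_h`` and
    ``{group}.n_animals``.
    """
    out = {"chrom": matrix["chrom"].to_numpy(), "pos": matrix["pos"].to_numpy()}
    animal_group = dict(zip(sheet["animal"], sheet["group"]))
    animals = sorted(animal_group)
    for animal in animals:
        bs = library_key(animal, "BS")
        ox = library_key(animal, "OxBS")
        bs_t = matrix[f"{bs}.total"].to_numpy(float)
        ox_t = matrix[f"{ox}.total"].to_numpy(float)
        bs_t = np.nan_to_num(bs_t, nan=0.0)
        ox_t = np.nan_to_num(ox_t, nan=0.0)
        bs_m = np.nan_to_num(matrix[f"{bs}.meth"].to_numpy(float), nan=0.0)
        ox_m = np.nan_to_num(matrix[f"{ox}.meth"].to_numpy(float), nan=0.0)
        p_m, p_h, p_u = mlml_estimate(bs_m, bs_t, ox_m, ox_t)
        out[f"{animal}.p_m"] = p_m
        out[f"{animal}.p_h"] = p_h
        out[f"{animal}.p_u"] = p_u
        out[f"{animal}.cov"] = np.minimum(bs_t, ox_t)
    est = pd.DataFrame(out)
    for group in sorted(set(animal_group.values())):
        members = [a for a in animals if animal_group[a] == group]
        pm = est[[f"{a}.p_m" for a in members]].to_numpy()
        ph = est[[f"{a}.p_h" for a in members]].to_numpy()
        n_avail = np.sum(~np.isnan(pm), axis=1)
        with np.errstate(invalid="ignore"):
            est[f"{group}.mean_p_m"] = np.nanmean(pm, axis=1)
            est[f"{group}.mean_p_h"] = np.nanmean(ph, axis=1)
        est[f"{group}.n_animals"] = n_avail
    return est


@dataclass
class GenomeSummary:
    """Genome-wide methylation percentages on the percent scale."""
    pct_5mc_report: float
    pct_5hmc_report: float
    per_library_pct: Dict[str, float]
    pct_5mc_mlml: Optional[float] = None
    pct_5hmc_mlml: Optional[float] = None


def genome_summary(matrix: pd.DataFrame, sheet: pd.DataFrame,
                   estimates: Optional[pd.DataFrame] = None) -> GenomeSummary:
    """Whole-genome 5mC/5hmC percentages by two methods.

    Report subtraction mirrors per-library alignment-report aggregates over
    the raw counts: a library's percentage is 100 * sum(meth) / sum(total)
    over all CpGs; 5mC is the mean over OxBS libraries and 5hmC is the mean
    over BS libraries minus the mean over OxBS libraries. If ``estimates``
    are supplied (per-animal MLML triples), their per-site means provide the
    ``mlml_mean`` figures alongside.
    """
    libs = matrix_libraries(matrix)
    if not any(t == "BS" for _, t in libs) or not any(t == "OxBS" for _, t in libs):
        raise ValueError("genome_summary needs at least one BS and one OxBS library")
    per_lib = {}
    for animal, treatment in libs:
        stem = library_key(animal, treatment)
        meth = np.nansum(matrix[f"{stem}.meth"].to_numpy(float))
        total = np.nansum(matrix[f"{stem}.total"].to_numpy(float))
        per_lib[stem] = 100.0 * meth / total if total > 0 else np.nan
    bs_mean = float(np.mean([v for k, v in per_lib.items() if k.endswith(".BS")]))
    ox_mean = float(np.mean([v for k, v in per_lib.items() if k.endswith(".OxBS")]))
    pct_5hmc = bs_mean - ox_mean
    if pct_5hmc < 0:
        logger.warning("report-subtraction 5hmC percentage is negative (%.3f); "
                       "reported as-is", pct_5hmc)
    summary = GenomeSummary(pct_5mc_report=ox_mean, pct_5hmc_report=pct_5hmc,
                            per_library_pct=per_lib)
    if estimates is not None:
        animals = sorted(set(sheet["animal"]))
        pm = estimates[[f"{a}.p_m" for a in animals]].to_numpy()
        ph = estimates[[f"{a}.p_h" for a in animals]].to_numpy()
        summary.pct_5mc_mlml = float(np.nanmean(pm) * 100.0)
        summary.pct_5hmc_mlml = float(np.nanmean(ph) * 100.0)
    return summary
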