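"""Smoothing-based differential methylation region (DMR) calling.

The procedure follows the BSmooth family of methods: per-sample methylation
levels are smoothed along the genome with a coverage-weighted local linear
(tricube kernel) fit, a per-CpG two-group t-like statistic with a floored,
locally smoothed pooled standard deviation is computed, maximal runs of CpGs
beyond empirical quantile cutoffs of the t distribution form candidate
regions, and candidates are filtered by CpG count and mean methylation
difference (10 percentage points for 5mC, 1 for 5hmC) and ranked by the
``areaStat`` score, the sum of the member CpGs' t-statistics.

Smoothing bandwidth is a genuine tuning knob: the effective window should
not exceed the span of the smallest regions of interest, otherwise their
smoothed mean difference is attenuated below the filter threshold. The
defaults (h_bp=1000, min_cpgs=70) suit broad, kilobase-scale regions;
callers hunting small regions should shrink both.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DIFF_THRESHOLDS = {"5mC": 0.10, "5hmC": 0.01}


# ---------------------------------------------------------------------------
# prefilter
# ---------------------------------------------------------------------------

def prefilter(coverage: np.ndarray, groups: Sequence[str], min_reads: int = 2,
              strict: bool = False) -> np.ndarray:
    """Boolean keep-mask over sites from a (sites x samples) coverage array.

    Default reading: a site is removed only when no sample in either group
    reaches ``min_reads``. With ``strict=True`` every group must contain at
    least one sample reaching ``min_reads``.
    """
    coverage = np.asarray(coverage, float)
    if min_reads <= 0:
        return np.ones(coverage.shape[0], dtype=bool)
    groups = np.asarray(groups)
    reach = np.nan_to_num(coverage, nan=0.0) >= min_reads
    if strict:
        keep = np.ones(coverage.shape[0], dtype=bool)
        for g in np.unique(groups):
            keep &= reach[:, groups == g].any(axis=1)
        return keep
    return reach.any(axis=1)


# ---------------------------------------------------------------------------
# smoothing
# ---------------------------------------------------------------------------

def _smooth_chrom(pos: np.ndarray, values: np.ndarray, weights: np.ndarray,
                  h_bp: float, min_cpgs: int) -> np.ndarray:
    """Coverage-weighted tricube local-linear smoother for one chromosome.

    ``values`` and ``weights`` are (n x s); NaN values get zero weight. The
    window at each CpG is the larger of +-h_bp and the span of the
    ``min_cpgs`` nearest CpGs (symmetric in count, shifted at chromosome
    ends).
    """
    n, s = values.shape
    y = np.nan_to_num(values, nan=0.0)
    w_cov = np.where(np.isnan(values), 0.0, np.nan_to_num(weights, nan=0.0))
    out = np.empty_like(y)
    m = min(min_cpgs, n)
    half = m // 2
    lo_h = np.searchsorted(pos, pos - h_bp, side="left")
    hi_h = np.searchsorted(pos, pos + h_bp, side="right")
    for i in range(n):
        lo_c = min(max(0, i - half), n - m)
        hi_c = lo_c + m
        lo = min(lo_h[i], lo_c)
        hi = max(hi_h[i], hi_c)
        d = np.abs(pos[lo:hi] - pos[i]).astype(float)
        h = max(h_bp, d.max() if d.size else h_bp) + 1e-9
        kern = (1.0 - (d / h) ** 3) ** 3
        w = w_cov[lo:hi] * kern[:, None]
        yy = y[lo:hi]
        s0 = w.sum(axis=0)
        dx = (pos[lo:hi] - pos[i]).astype(float)[:, None]
        s1 = (w * dx).sum(axis=0)
        s2 = (w * dx * dx).sum(axis=0)
        t0 = (w * yy).sum(axis=0)
        t1 = (w * yy * dx).sum(axis=0)
        det = s0 * s2 - s1 * s1
        with np.errstate(invalid="ignore", divide="ignore"):
            fit = np.where(np.abs(det) > 1e-12 * np.maximum(s0 * s2, 1e-300),
                           (s2 * t0 - s1 * t1) / det,
                           np.where(s0 > 0, t0 / np.maximum(s0, 1e-300), np.nan))
        out[i] = fit
    return np.clip(out, 0.0, 1.0)


def smooth(sites: pd.DataFrame, value_cols: Sequence[str],
           weight_cols: Sequence[str], h_bp: float = 1000.0,
           min_cpgs: int = 70) -> pd.DataFrame:
    """Smooth per-sample methylation tracks along each chromosome.

    ``sites`` must be sorted by (chrom, pos). Returns a DataFrame with
    chrom, pos and one smoothed column per entry of ``value_cols``.
    Chromosomes with fewer than ``min_cpgs`` sites fall back to the same
    local fit over all their sites (a plain weighted fit), with a warning.
    """
    pieces = []
    for chrom, sub in sites.groupby("chrom", sort=True):
        pos = sub["pos"].to_numpy(np.int64)
        if len(pos) < min_cpgs:
            logger.warning("smooth: chromosome %s has %d < %d CpGs; using a "
                           "whole-chromosome fit", chrom, len(pos), min_cpgs)
        vals = sub[list(value_cols)].to_numpy(float)
        wts = sub[list(weight_cols)].to_numpy(float)
        sm = _smooth_chrom(pos, vals, wts, h_bp, min_cpgs)
        piece = pd.DataFrame({"chrom": chrom, "pos": pos})
        for j, c in enumerate(value_cols):
            piece[c] = sm[:, j]
        pieces.append(piece)
    return pd.concat(pieces, ignore_index=True)


# ---------------------------------------------------------------------------
# t statistics
# ---------------------------------------------------------------------------

def _rolling_mean(x: np.ndarray, window: int) -> np.ndarray:
    return (pd.Series(x).rolling(window, center=True, min_periods=1)
            .mean().to_numpy())


def tstat(smoothed: pd.DataFrame, control_cols: Sequence[str],
          case_cols: Sequence[str], var_floor_quantile: float = 0.75,
          max_cap: float = 50.0, sd_window: int = 101) -> pd.DataFrame:
    """Per-CpG t-like statistic for case - control smoothed methylation.

    The pooled within-group standard deviation is locally smoothed along
    each chromosome (running mean of the pooled variance over ``sd_window``
    CpGs) and floored at its genome-wide ``var_floor_quantile`` quantile; t
    is capped at +-``max_cap`` to guard zero-variance degeneracies and is
    exactly 0 wherever the group means are equal.
    """
    n1, n2 = len(control_cols), len(case_cols)
    if n1 < 2 or n2 < 2:
        raise ValueError("tstat needs >= 2 samples per group for a variance; "
                         "use mean_diff-only calling otherwise")
    x1 = smoothed[list(control_cols)].to_numpy(float)
    x2 = smoothed[list(case_cols)].to_numpy(float)
    m1 = x1.mean(axis=1)
    m2 = x2.mean(axis=1)
    diff = m2 - m1
    ss = (((x1 - m1[:, None]) ** 2).sum(axis=1)
          + ((x2 - m2[:, None]) ** 2).sum(axis=1))
    var = ss / (n1 + n2 - 2)
    sd_sm = np.empty_like(var)
    chroms = smoothed["chrom"].to_numpy()
    for chrom in pd.unique(chroms):
        sel = chroms == chrom
        sd_sm[sel] = np.sqrt(np.maximum(_rolling_mean(var[sel], sd_window), 0.0))
    floor = float(np.nanquantile(sd_sm, var_floor_quantile))
    sd_used = np.maximum(sd_sm, floor)
    scale = np.sqrt(1.0 / n1 + 1.0 / n2)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(diff == 0.0, 0.0,
                     diff / np.where(sd_used > 0, sd_used * scale, np.inf))
    t = np.where((diff != 0.0) & (sd_used == 0.0),
                 np.sign(diff) * max_cap, t)
    t = np.clip(t, -max_cap, max_cap)
    return pd.DataFrame({"chrom": chroms, "pos": smoothed["pos"].to_numpy(),
                         "t": t, "mean_control": m1, "mean_case": m2,
                         "diff": diff, "sd": sd_used})


# ---------------------------------------------------------------------------
# region finding, filtering, ranking
# ---------------------------------------------------------------------------

def _runs(mask: np.ndarray) -> List[Tuple[int, int]]:
    """Maximal runs of True as inclusive (start, end) index pairs."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    ends = np.concatenate([idx[breaks], [idx[-1]]])
    return list(zip(starts.tolist(), ends.tolist()))


def dmr_find(tstats: pd.DataFrame,
             cutoff_quantiles: Tuple[float, float] = (0.025, 0.975),
             cutoff: Optional[Tuple[float, float]] = None) -> pd.DataFrame:
    """Candidate DMRs: maximal same-side runs of t beyond the cutoffs.

    Cutoffs default to empirical quantiles of the genome-wide t distribution;
    absolute cutoffs may be passed instead. Boundaries are the genomic
    positions of the first/last member CpG (emitted 0-based half-open);
    ``mean_diff`` is the mean smoothed case - control difference over member
    CpGs and ``area_stat`` their summed t. Runs are never merged across a
    sub-threshold CpG or across chromosomes.
    """
    t_all = tstats["t"].to_numpy(float)
    if cutoff is None:
        lo_cut = float(np.quantile(t_all, cutoff_quantiles[0]))
        hi_cut = float(np.quantile(t_all, cutoff_quantiles[1]))
    else:
        lo_cut, hi_cut = cutoff
    rows = []
    for chrom, sub in tstats.groupby("chrom", sort=True):
        t = sub["t"].to_numpy(float)
        d = sub["diff"].to_numpy(float)
        pos = sub["pos"].to_numpy(np.int64)
        for side, mask in (("+", t > hi_cut), ("-", t < lo_cut)):
            for s, e in _runs(mask):
                members = slice(s, e + 1)
                rows.append({
                    "chrom": chrom,
                    "start": int(pos[s]) - 1,
                    "end": int(pos[e]),
                    "n_cpg": e - s + 1,
                    "mean_diff": float(d[members].mean()),
                    "area_stat": float(t[members].sum()),
                    "direction": 1 if side == "+" else -1,
                    "idx_start": int(s),
                    "idx_end": int(e),
                })
    cands = pd.DataFrame(rows, columns=["chrom", "start", "end", "n_cpg",
                                        "mean_diff", "area_stat", "direction",
                                        "idx_start", "idx_end"])
    return cands.sort_values(["chrom", "start"], ignore_index=True)


def filter_dmrs(candidates: pd.DataFrame, methylation_type: str,
                min_cpgs: int = 3, min_diff: Optional[float] = None
                ) -> pd.DataFrame:
    """Keep candidates with >= ``min_cpgs`` CpGs and |mean_diff| >= the
    type's threshold (0.10 for 5mC, 0.01 for 5hmC unless overridden)."""
    if min_diff is None:
        if methylation_type not in DIFF_THRESHOLDS:
            raise ValueError(f"unknown methylation type: {methylation_type}")
        min_diff = DIFF_THRESHOLDS[methylation_type]
    keep = ((candidates["n_cpg"] >= min_cpgs)
            & (candidates["mean_diff"].abs() >= min_diff))
    out = candidates.loc[keep].reset_index(drop=True)
    out.insert(len(out.columns), "methylation_type",
               [methylation_type] * len(out))
    return out


def rank_dmrs(dmrs: pd.DataFrame) -> pd.DataFrame:
    """Order by |area_stat| descending (ties: chrom, start); adds ``rank``."""
    out = dmrs.copy()
    out["_abs"] = out["area_stat"].abs()
    out = out.sort_values(["_abs", "chrom", "start"],
                          ascending=[False, True, True], kind="mergesort",
                          ignore_index=True).drop(columns="_abs")
    out["rank"] = np.arange(1, len(out) + 1)
    return out


# ---------------------------------------------------------------------------
# end-to-end caller
# ---------------------------------------------------------------------------

@dataclass
class DmrResult:
    dmrs: pd.DataFrame
    candidates: pd.DataFrame
    tstats: pd.DataFrame
    n_prefiltered: int


def call_dmrs(estimates: pd.DataFrame, sheet: pd.DataFrame,
              methylation_type: str, min_reads: int = 2,
              strict_prefilter: bool = False, h_bp: float = 1000.0,
              min_cpgs_smooth: int = 70, var_floor_quantile: float = 0.75,
              max_cap: float = 50.0,
              cutoff_quantiles: Tuple[float, float] = (0.025, 0.975),
              min_dmr_cpgs: int = 3, min_diff: Optional[float] = None
              ) -> DmrResult:
    """Call ranked DMRs of one methylation type from per-animal estimates.

    ``estimates`` is the table produced by :func:`oxbstools.mlml.estimate_all`
    (per-animal ``p_m``/``p_h`` plus ``cov`` columns); the 5mC track uses
    ``p_m`` and the 5hmC track ``p_h``. Groups must be exactly control and
    case, each with >= 2 animals.
    """
    track = {"5mC": "p_m", "5hmC": "p_h"}.get(methylation_type)
    if track is None:
        raise ValueError(f"unknown methylation type: {methylation_type}")
    animal_group = dict(zip(sheet["animal"], sheet["group"]))
    groups = sorted(set(animal_group.values()))
    if len(groups) != 2:
        raise ValueError("DMR calling needs exactly two groups")
    if "control" in groups:
        control = "control"
        case = [g for g in groups if g != "control"][0]
    else:  # alphabetical fallback
        control, case = groups
    control_animals = sorted(a for a, g in animal_group.items() if g == control)
    case_animals = sorted(a for a, g in animal_group.items() if g == case)

    animals = control_animals + case_animals
    cov = estimates[[f"{a}.cov" for a in animals]].to_numpy(float)
    labels = [control] * len(control_animals) + [case] * len(case_animals)
    keep = prefilter(cov, labels, min_reads, strict_prefilter)
    n_removed = int((~keep).sum())
    logger.info("prefilter: removed %d / %d sites", n_removed, len(estimates))
    sites = estimates.loc[keep].reset_index(drop=True)

    value_cols = [f"{a}.{track}" for a in animals]
    weight_cols = [f"{a}.cov" for a in animals]
    smoothed = smooth(sites, value_cols, weight_cols, h_bp, min_cpgs_smooth)
    ts = tstat(smoothed,
               [f"{a}.{track}" for a in control_animals],
               [f"{a}.{track}" for a in case_animals],
               var_floor_quantile, max_cap)
    candidates = dmr_find(ts, cutoff_quantiles)
    dmrs = rank_dmrs(filter_dmrs(candidates, methylation_type, min_dmr_cpgs,
                                 min_diff))
    return DmrResult(dmrs=dmrs, candidates=candidates, tstats=ts,
                     n_prefiltered=n_removed)
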