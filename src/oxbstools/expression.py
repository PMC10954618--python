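"""TMM normalization and element-level methylation-expression correlation.

TMM (trimmed mean of M-values) rescales library sizes so that most genes
show no expression change between samples: for each sample against a
reference, gene-wise log-ratios (M) and log-abundances (A) are computed on
library-size-scaled counts, both tails of M and A are trimmed, and the
scaling factor is 2 to the precision-weighted mean of the surviving
M-values. Factors are recentred to geometric mean 1, so a sample's
effective library size is libsize x factor.

Correlation: per sample and per functional element class, the Spearman rank
correlation between element mean methylation and the normalized expression
of the element's closest gene; cells of the output matrix are the average
coefficient across samples (per group and combined). Spearman is rank-based,
so no log transform of expression is needed.
"""

from __future__ import annotations

import logging
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


def tmm_factors(counts: pd.DataFrame, trim_m: float = 0.30,
                trim_a: float = 0.05) -> pd.Series:
    """TMM scaling factors (geometric mean 1) for a gene x sample matrix."""
    mat = counts.to_numpy(float)
    if (mat < 0).any():
        raise ValueError("counts must be non-negative")
    libsize = mat.sum(axis=0)
    if (libsize == 0).any():
        bad = counts.columns[np.flatnonzero(libsize == 0)[0]]
        raise ValueError(f"sample {bad} has all-zero counts")
    # reference: upper-quartile/libsize ratio closest to the mean ratio
    uq = np.quantile(mat, 0.75, axis=0) / libsize
    ref = int(np.argmin(np.abs(uq - uq.mean())))
    factors = np.ones(mat.shape[1])
    yr, nr = mat[:, ref], libsize[ref]
    for s in range(mat.shape[1]):
        if s == ref:
            continue
        ys, ns = mat[:, s], libsize[s]
        keep = (ys > 0) & (yr > 0)
        if not keep.any():
            continue
        y1, y2 = ys[keep], yr[keep]
        m = np.log2((y1 / ns) / (y2 / nr))
        a = 0.5 * np.log2((y1 / ns) * (y2 / nr))
        if np.max(np.abs(m)) < 1e-6:
            continue
        # asymptotic variance of M (delta method) for precision weighting
        v = (ns - y1) / (ns * y1) + (nr - y2) / (nr * y2)
        n = len(m)
        lo_m = np.floor(n * trim_m) + 1
        hi_m = n + 1 - lo_m
        lo_a = np.floor(n * trim_a) + 1
        hi_a = n + 1 - lo_a
        rm = stats.rankdata(m)
        ra = stats.rankdata(a)
        sel = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
        if not sel.any():
            continue
        f = np.sum(m[sel] / v[sel]) / np.sum(1.0 / v[sel])
        if np.isfinite(f):
            factors[s] = 2.0 ** f
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


def normalize_expression(counts: pd.DataFrame,
                         factors: Optional[pd.Series] = None) -> pd.DataFrame:
    """Counts per million of effective library size (libsize x TMM factor).

    Scaling within a sample is monotone, so gene ranking is preserved.
    """
    if factors is None:
        factors = tmm_factors(counts)
    eff = counts.sum(axis=0) * factors
    return counts / eff * 1e6


def correlate_elements(element_means: pd.DataFrame, expression: pd.DataFrame,
                       sample_groups: Dict[str, str],
                       value_types: Dict[str, str] = None,
                       min_pairs: int = 3) -> pd.DataFrame:
    """Spearman correlation of element methylation vs closest-gene expression.

    ``element_means`` has one row per element with ``element_class``,
    ``gene_id`` and per-sample methylation columns named
    ``{sample}.{value}`` (e.g. ``WT1.p_h``); ``value_types`` maps the value
    suffix to a methylation-type label (default p_m -> 5mC, p_h -> 5hmC).
    ``expression`` is a normalized gene x sample table whose columns cover
    the same sample ids. Returns a long table with one row per (class,
    methylation type, sample) holding rho and n_pairs, plus mean-rho rows
    per group and combined (sample == "mean:<group>" / "mean:combined").
    Cells with fewer than ``min_pairs`` complete pairs or zero rank variance
    are reported missing (NaN).
    """
    if value_types is None:
        value_types = {"p_m": "5mC", "p_h": "5hmC"}
    samples = [s for s in expression.columns if s in sample_groups]
    if not samples:
        raise ValueError("no shared samples between expression and groups")
    assigned = element_means.dropna(subset=["gene_id"])
    assigned = assigned.loc[assigned["gene_id"].isin(expression.index)]
    rows = []
    for cls, sub in assigned.groupby("element_class"):
        genes = sub["gene_id"].to_numpy()
        for suffix, mtype in value_types.items():
            per_sample = {}
            for s in samples:
                col = f"{s}.{suffix}"
                if col not in sub.columns:
                    continue
                meth = sub[col].to_numpy(float)
                expr = expression.loc[genes, s].to_numpy(float)
                ok = ~np.isnan(meth) & ~np.isnan(expr)
                rho = np.nan
                if ok.sum() >= min_pairs:
                    if (np.unique(meth[ok]).size > 1
                            and np.unique(expr[ok]).size > 1):
                        rho = stats.spearmanr(meth[ok], expr[ok]).statistic
                per_sample[s] = (rho, int(ok.sum()))
                rows.append({"element_class": cls, "methylation_type": mtype,
                             "sample": s, "rho": rho, "n_pairs": int(ok.sum())})
            by_group: Dict[str, list] = {}
            for s, (rho, n) in per_sample.items():
                by_group.setdefault(sample_groups[s], []).append((rho, n))
            by_group["combined"] = [v for vs in
                                    [vals for g, vals in by_group.items()
                                     if g != "combined"] for v in vs]
            for g, vals in by_group.items():
                rhos = [r for r, _ in vals if not np.isnan(r)]
                rows.append({"element_class": cls, "methylation_type": mtype,
                             "sample": f"mean:{g}",
                             "rho": float(np.mean(rhos)) if rhos else np.nan,
                             "n_pairs": int(sum(n for _, n in vals))})
    return pd.DataFrame(rows)


def correlation_matrix(long_table: pd.DataFrame, layout: str = "mean:combined"
                       ) -> pd.DataFrame:
    """Pivot the long correlation table into a class x type matrix."""
    sub = long_table.loc[long_table["sample"] == layout]
    return sub.pivot(index="element_class", columns="methylation_type",
                     values="rho")


def render_heatmap(matrix: pd.DataFrame) -> str:
    """Plain-text rendering of the class x type correlation matrix."""
    lines = [f"{'element_class':<16}" + "".join(f"{c:>10}" for c in matrix.columns)]
    for cls, row in matrix.iterrows():
        cells = "".join(f"{v:>10.3f}" if np.isfinite(v) else f"{'NA':>10}"
                        for v in row)
        lines.append(f"{cls:<16}" + cells)
    return "\n".join(lines)
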