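"""Coverage-boosting CpG pooling.

Low-coverage (~8X) BS/OxBS libraries cannot resolve a ~4% 5hmC signal at
single-CpG resolution, which would need >100X depth. The pooling procedure
trades a little spatial resolution for depth:

1. median coverage normalization across libraries,
2. removal of CpGs above a high-coverage outlier percentile,
3. a ``unite`` filter dropping CpGs with no coverage in some stratum,
4. sliding windows of 30 consecutive retained CpGs, step 2 (so every interior
   CpG sits in 15 windows), keeping only windows reaching 100X combined
   coverage,
5. dividing each window's pooled counts by its CpG count, assigning the
   quotient to every member CpG, and averaging the multiple assignments each
   CpG receives.

Pooled counts are carried as reals; rounding after division by 30 would
destroy the small 5hmC signal.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .io import library_key, matrix_libraries

logger = logging.getLogger(__name__)


def nearest_rank_percentile(values: np.ndarray, pct: float) -> float:
    """Nearest-rank percentile: the ceil(pct/100 * n)-th order statistic."""
    v = np.sort(np.asarray(values))
    if v.size == 0:
        raise ValueError("percentile of empty vector")
    k = max(1, math.ceil(pct / 100.0 * v.size))
    return float(v[k - 1])


def _count_cols(matrix: pd.DataFrame) -> Tuple[List[str], List[str]]:
    meth = [c for c in matrix.columns if c.endswith(".meth")]
    total = [c.rsplit(".", 1)[0] + ".total" for c in meth]
    return meth, total


def normalize_coverage(matrix: pd.DataFrame) -> Tuple[pd.DataFrame, Dict[str, float]]:
    """Scale every library to the median of the libraries' median coverages.

    The factor ``median(medians) / median(this library's coverage over covered
    sites)`` multiplies both methylated and total counts, so per-site
    proportions are untouched. Scaled values are kept as reals.
    """
    meth_cols, total_cols = _count_cols(matrix)
    medians = {}
    for tc in total_cols:
        cov = matrix[tc].to_numpy(float)
        covered = cov[cov > 0]
        if covered.size == 0:
            raise ValueError(f"library {tc.rsplit('.', 1)[0]} has no covered sites")
        medians[tc] = float(np.median(covered))
    target = float(np.median(list(medians.values())))
    out = matrix.copy()
    factors = {}
    for mc, tc in zip(meth_cols, total_cols):
        f = target / medians[tc]
        factors[tc.rsplit(".", 1)[0]] = f
        out[mc] = out[mc].astype(float) * f
        out[tc] = out[tc].astype(float) * f
        logger.info("normalize_coverage: %s median %.3f factor %.4f",
                    tc, medians[tc], f)
    return out, factors


def remove_outliers(matrix: pd.DataFrame, pct: float = 99.9
                    ) -> Tuple[pd.DataFrame, int]:
    """Drop CpGs whose coverage strictly exceeds a library's high percentile.

    The threshold is the nearest-rank ``pct`` percentile of that library's
    coverage over its covered sites; a site is removed entirely if any
    library exceeds its own threshold there.
    """
    if not 0 < pct <= 100:
        raise ValueError("pct must be in (0, 100]")
    _, total_cols = _count_cols(matrix)
    drop = np.zeros(len(matrix), dtype=bool)
    for tc in total_cols:
        cov = matrix[tc].to_numpy(float)
        covered = cov[cov > 0]
        if covered.size == 0:
            continue
        thr = nearest_rank_percentile(covered, pct)
        drop |= cov > thr
    n_removed = int(drop.sum())
    logger.info("remove_outliers: removed %d sites above the %.4g%% percentile",
                n_removed, pct)
    return matrix.loc[~drop].reset_index(drop=True), n_removed


def unite(matrix: pd.DataFrame, sheet: pd.DataFrame, min_per_group: int = 1
          ) -> pd.DataFrame:
    """Keep sites covered in at least ``min_per_group`` libraries of every
    (group x treatment) stratum.

    Applied to the counts as they stand; positivity of coverage is invariant
    under the positive scaling of the normalization step, so the result
    matches filtering on raw counts. Idempotent.
    """
    if min_per_group <= 0:
        return matrix
    keep = np.ones(len(matrix), dtype=bool)
    for (_, _), sub in sheet.groupby(["group", "treatment"]):
        cols = [library_key(a, t) + ".total"
                for a, t in zip(sub["animal"], sub["treatment"])]
        n_covered = (matrix[cols].to_numpy(float) > 0).sum(axis=1)
        keep &= n_covered >= min_per_group
    logger.info("unite: retained %d / %d sites (min_per_group=%d)",
                int(keep.sum()), len(matrix), min_per_group)
    return matrix.loc[keep].reset_index(drop=True)


@dataclass
class Windows:
    """Sliding windows over the ordered retained CpGs of each chromosome.

    ``start``/``end`` are inclusive 0-based indices into that chromosome's
    retained-CpG order.
    """
    chrom: List[str] = field(default_factory=list)
    start: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    end: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    window_size: int = 30
    step: int = 2

    def __len__(self) -> int:
        return len(self.chrom)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"chrom": self.chrom, "start_idx": self.start,
                             "end_idx": self.end})


def build_windows(target_cpgs: pd.DataFrame, window_size: int = 30,
                  step: int = 2) -> Windows:
    """Enumerate windows of ``window_size`` consecutive target-CpGs, sliding
    by ``step``, per chromosome. Tail fragments shorter than ``window_size``
    are not emitted; windows never straddle chromosomes.
    """
    if window_size < 1 or step < 1:
        raise ValueError("window_size and step must be >= 1")
    if window_size % step != 0:
        logger.warning("window_size %d is not a multiple of step %d; "
                       "per-CpG window multiplicity will vary", window_size, step)
    chroms: List[str] = []
    starts: List[np.ndarray] = []
    for chrom, sub in target_cpgs.groupby("chrom", sort=True):
        n = len(sub)
        if n < window_size:
            logger.warning("build_windows: chromosome %s has %d < %d CpGs; "
                           "no windows", chrom, n, window_size)
            continue
        s = np.arange(0, n - window_size + 1, step, dtype=int)
        chroms.extend([chrom] * len(s))
        starts.append(s)
    if not starts:
        return Windows(window_size=window_size, step=step)
    start = np.concatenate(starts)
    return Windows(chrom=chroms, start=start, end=start + window_size - 1,
                   window_size=window_size, step=step)


def _animal_pairs(matrix: pd.DataFrame) -> Dict[str, Dict[str, str]]:
    """animal -> {'BS': column stem, 'OxBS': column stem}."""
    pairs: Dict[str, Dict[str, str]] = {}
    for animal, treatment in matrix_libraries(matrix):
        pairs.setdefault(animal, {})[treatment] = library_key(animal, treatment)
    return pairs


def pool(matrix: pd.DataFrame, windows: Windows,
         min_pooled_coverage: float = 100.0,
         combined_mode: str = "per-animal-pair") -> pd.DataFrame:
    """Window-pool counts and average the per-CpG window assignments.

    Per window and library, pooled counts are the sums over member CpGs. A
    window survives, in ``per-animal-pair`` mode, for an animal whose BS and
    OxBS libraries both reach ``min_pooled_coverage`` summed coverage in it;
    in ``all-libraries`` mode it survives for every animal once the sum over
    all libraries reaches the threshold. Each surviving window assigns
    (pooled_total / n_cpgs, pooled_meth / n_cpgs) to every member CpG and a
    CpG's final value is the mean over the surviving windows containing it.
    CpGs in no surviving window for an animal are NaN for that animal; CpGs
    with no surviving window for any animal are dropped.
    """
    if combined_mode not in ("per-animal-pair", "all-libraries"):
        raise ValueError(f"unknown combined_mode: {combined_mode}")
    pairs = _animal_pairs(matrix)
    size = windows.window_size

    out_cols: Dict[str, np.ndarray] = {}
    n = len(matrix)
    for animal, tr in pairs.items():
        for treatment in ("BS", "OxBS"):
            stem = tr[treatment]
            out_cols[f"{stem}.meth"] = np.full(n, np.nan)
            out_cols[f"{stem}.total"] = np.full(n, np.nan)

    win_df = windows.to_frame()
    offset = 0
    for chrom, sub in matrix.groupby("chrom", sort=True):
        m = len(sub)
        wsub = win_df[win_df["chrom"] == chrom]
        if wsub.empty:
            offset += m
            continue
        w_start = wsub["start_idx"].to_numpy()
        # per-library window sums via cumulative sums
        sums: Dict[str, Dict[str, np.ndarray]] = {}
        for animal, tr in pairs.items():
            sums[animal] = {}
            for treatment in ("BS", "OxBS"):
                stem = tr[treatment]
                for kind in ("meth", "total"):
                    col = sub[f"{stem}.{kind}"].to_numpy(float)
                    cs = np.concatenate([[0.0], np.cumsum(col)])
                    sums[animal][f"{treatment}.{kind}"] = (
                        cs[w_start + size] - cs[w_start])
        if combined_mode == "all-libraries":
            grand = np.zeros(len(w_start))
            for animal in pairs:
                grand += sums[animal]["BS.total"] + sums[animal]["OxBS.total"]
            survive_all = grand >= min_pooled_coverage
        for animal, tr in pairs.items():
            if combined_mode == "per-animal-pair":
                survive = ((sums[animal]["BS.total"] >= min_pooled_coverage)
                           & (sums[animal]["OxBS.total"] >= min_pooled_coverage))
            else:
                survive = survive_all
            if not survive.any():
                continue
            s_idx = w_start[survive]
            cnt = np.zeros(m + 1)
            np.add.at(cnt, s_idx, 1.0)
            np.add.at(cnt, s_idx + size, -1.0)
            cnt = np.cumsum(cnt[:-1])
            for treatment in ("BS", "OxBS"):
                stem = tr[treatment]
                for kind in ("meth", "total"):
                    val = sums[animal][f"{treatment}.{kind}"][survive] / size
                    acc = np.zeros(m + 1)
                    np.add.at(acc, s_idx, val)
                    np.add.at(acc, s_idx + size, -val)
                    acc = np.cumsum(acc[:-1])
                    with np.errstate(invalid="ignore", divide="ignore"):
                        final = np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan)
                    out_cols[f"{stem}.{kind}"][offset:offset + m] = final
        offset += m

    pooled = pd.DataFrame({"chrom": matrix["chrom"].to_numpy(),
                           "pos": matrix["pos"].to_numpy(), **out_cols})
    total_cols = [c for c in pooled.columns if c.endswith(".total")]
    any_kept = pooled[total_cols].notna().any(axis=1)
    n_dropped = int((~any_kept).sum())
    if n_dropped:
        logger.info("pool: %d CpGs in no surviving window were dropped", n_dropped)
    return pooled.loc[any_kept].reset_index(drop=True)


def run_pooling(matrix: pd.DataFrame, sheet: pd.DataFrame,
                window_size: int = 30, step: int = 2,
                min_pooled_coverage: float = 100.0, outlier_pct: float = 99.9,
                min_per_group: int = 1,
                combined_mode: str = "per-animal-pair"):
    """The fixed pooling pipeline: normalize -> remove_outliers -> unite ->
    build_windows -> pool. Returns (pooled, report dict)."""
    report = {"input_sites": len(matrix)}
    normalized, factors = normalize_coverage(matrix)
    report["normalization_factors"] = factors
    filtered, n_out = remove_outliers(normalized, outlier_pct)
    report["outliers_removed"] = n_out
    united = unite(filtered, sheet, min_per_group)
    report["united_sites"] = len(united)
    windows = build_windows(united, window_size, step)
    report["windows"] = len(windows)
    pooled = pool(united, windows, min_pooled_coverage, combined_mode)
    report["pooled_sites"] = len(pooled)
    return pooled, report
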