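"""Overlap of CpGs/DMRs with classed functional elements.

All intervals are 0-based half-open. A CpG at 1-based position p is treated
as the width-1 interval [p-1, p), so CpG-element and DMR-element overlap
share one geometry kernel.

The enrichment score follows the intersection-over-union style metric used
for ranking element classes by DMR occupancy: the number of overlapping
(query, element) pairs divided by (number of DMRs + number of elements).
The classical set-theoretic Jaccard denominator (which subtracts the
intersection) is available behind a flag.
"""

from __future__ import annotations

import logging
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)


def overlap_pairs(queries: pd.DataFrame, elements: pd.DataFrame) -> pd.DataFrame:
    """All (query, element) index pairs whose intervals share >= 1 base.

    Inputs need ``chrom``/``start``/``end`` columns (0-based half-open).
    Returns a DataFrame with ``query_idx`` and ``element_idx`` referring to
    the positional indices of the two inputs. A query may pair with many
    elements and vice versa; half-open adjacency does not overlap.
    """
    for name, df in (("query", queries), ("element", elements)):
        bad = df["start"] >= df["end"]
        if bad.any():
            rec = df.loc[bad].iloc[0]
            raise ValueError(f"malformed {name} interval "
                             f"{rec['chrom']}:{rec['start']}-{rec['end']}")
    trees: Dict[str, IntervalTree] = {}
    for chrom, sub in elements.groupby("chrom"):
        trees[chrom] = IntervalTree.from_tuples(
            zip(sub["start"], sub["end"], sub.index))
    q_idx, e_idx = [], []
    for chrom, sub in queries.groupby("chrom"):
        tree = trees.get(chrom)
        if tree is None:
            continue
        for qi, s, e in zip(sub.index, sub["start"], sub["end"]):
            for hit in tree.overlap(s, e):
                q_idx.append(qi)
                e_idx.append(hit.data)
    out = pd.DataFrame({"query_idx": np.asarray(q_idx, dtype=int),
                        "element_idx": np.asarray(e_idx, dtype=int)})
    return out.sort_values(["query_idx", "element_idx"], ignore_index=True)


def jaccard_enrichment(dmrs: pd.DataFrame, elements: pd.DataFrame,
                       element_class: str, classic: bool = False,
                       unique_queries: bool = False) -> Optional[dict]:
    """Enrichment of DMRs in one element class.

    score = n_overlap / (n_dmr + n_elem), with n_overlap the number of
    overlapping (DMR, element) pairs (or of distinct overlapping DMRs when
    ``unique_queries``). ``classic`` switches the denominator to
    n_dmr + n_elem - n_overlap. Returns None when both sets are empty.
    """
    elems = elements.loc[elements["element_class"] == element_class]
    n_dmr, n_elem = len(dmrs), len(elems)
    if n_dmr + n_elem == 0:
        logger.warning("jaccard_enrichment: no DMRs or %s elements",
                       element_class)
        return None
    pairs = overlap_pairs(dmrs.reset_index(drop=True),
                          elems.reset_index(drop=True))
    n_overlap = pairs["query_idx"].nunique() if unique_queries else len(pairs)
    denom = n_dmr + n_elem - (n_overlap if classic else 0)
    return {"element_class": element_class, "n_overlap": int(n_overlap),
            "n_dmr": n_dmr, "n_elem": n_elem,
            "score": n_overlap / denom if denom > 0 else np.nan}


def enrichment_table(dmrs: pd.DataFrame, elements: pd.DataFrame,
                     methylation_type: str, classes: Sequence[str] = None,
                     classic: bool = False,
                     unique_queries: bool = False) -> pd.DataFrame:
    if classes is None:
        classes = sorted(elements["element_class"].unique())
    rows = []
    for cls in classes:
        score = jaccard_enrichment(dmrs, elements, cls, classic, unique_queries)
        if score is not None:
            score["methylation_type"] = methylation_type
            rows.append(score)
    return pd.DataFrame(rows)


def cpgs_as_intervals(estimates: pd.DataFrame) -> pd.DataFrame:
    """View 1-based CpG positions as width-1 half-open intervals."""
    return pd.DataFrame({"chrom": estimates["chrom"].to_numpy(),
                         "start": estimates["pos"].to_numpy(np.int64) - 1,
                         "end": estimates["pos"].to_numpy(np.int64)})


def element_mean_methylation(estimates: pd.DataFrame, elements: pd.DataFrame,
                             value_cols: Sequence[str]) -> pd.DataFrame:
    """Unweighted mean of per-CpG values over the CpGs inside each element.

    Returns one row per element of ``elements`` (positional order preserved,
    with its ``element_id``/``element_class``/``gene_id``), the number of
    contributing CpGs, and the mean of each requested column; elements
    containing no estimated CpG are NaN.
    """
    elems = elements.reset_index(drop=True)
    pairs = overlap_pairs(cpgs_as_intervals(estimates), elems)
    out = elems[["element_id", "element_class", "gene_id"]].copy()
    agg = pd.DataFrame(
        {c: estimates[c].to_numpy(float)[pairs["query_idx"]] for c in value_cols})
    agg["element_idx"] = pairs["element_idx"].to_numpy()
    grouped = agg.groupby("element_idx").mean()
    counts = agg.groupby("element_idx").size()
    out["n_cpg"] = counts.reindex(range(len(elems))).fillna(0).astype(int).to_numpy()
    for c in value_cols:
        out[c] = grouped[c].reindex(range(len(elems))).to_numpy()
    return out


def closest_gene(elements: pd.DataFrame, genes: pd.DataFrame) -> pd.Series:
    """Assign each element the gene minimizing interval distance.

    Overlap counts as distance 0. Ties are broken by the smaller distance
    between the element start and the gene start, then by lexicographic gene
    id. Elements on chromosomes without genes are left unassigned (None).
    """
    result = np.full(len(elements), None, dtype=object)
    elems = elements.reset_index(drop=True)
    for chrom, sub in elems.groupby("chrom"):
        g = genes.loc[genes["chrom"] == chrom]
        if g.empty:
            logger.warning("closest_gene: no genes on %s; %d elements "
                           "unassigned", chrom, len(sub))
            continue
        gs = g["start"].to_numpy(float)
        ge = g["end"].to_numpy(float)
        gid = g["gene_id"].to_numpy(object)
        order = np.argsort(gid, kind="mergesort")
        for i in sub.index:
            es, ee = elems.at[i, "start"], elems.at[i, "end"]
            dist = np.maximum(0, np.maximum(gs - ee, es - ge))
            start_dist = np.abs(es - gs)
            # lexicographic tie-break via stable sort on gene id order
            best = min(order, key=lambda j: (dist[j], start_dist[j]))
            result[i] = gid[best]
    return pd.Series(result, index=elements.index, name="gene_id")
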