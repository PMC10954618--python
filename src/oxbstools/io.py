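"""Readers and writers for the file dialects the pipeline touches.

Conventions
-----------
* Bismark CpG cytosine reports: 7-column TSV, no header, 1-based positions
  (chrom, pos, strand, meth_count, unmeth_count, context, trinucleotide).
* BED-like interval files: 0-based half-open.
* Internal CpG sites are keyed to the 1-based position of the + strand C of
  the CpG dyad; the two strands of a dyad are collapsed into one site.
* A per-library count matrix is a DataFrame with columns ``chrom``, ``pos``
  and, for every library, ``{animal}.{treatment}.meth`` and
  ``{animal}.{treatment}.total`` (treatment is ``BS`` or ``OxBS``).
"""

from __future__ import annotations

import logging
from functools import reduce
from pathlib import Path
from typing import Iterable, List, Tuple

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

REPORT_COLUMNS = ["chrom", "pos", "strand", "meth_count", "unmeth_count",
                  "context", "trinucleotide"]
TREATMENTS = ("BS", "OxBS")
GROUPS = ("control", "case")


class ParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# cytosine reports
# ---------------------------------------------------------------------------

def read_cytosine_report(path, keep_context: str = "CpG") -> pd.DataFrame:
    """Parse a Bismark-style cytosine report.

    Non-CpG contexts are dropped (their number is logged). Malformed rows
    raise :class:`ParseError` naming the 1-based line number.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", header=None, names=REPORT_COLUMNS,
                         dtype={"chrom": str, "context": str,
                                "trinucleotide": str, "strand": str},
                         comment=None)
    except pd.errors.EmptyDataError:
        logger.warning("%s: empty cytosine report", path)
        return pd.DataFrame(columns=REPORT_COLUMNS)

    if df.shape[1] != len(REPORT_COLUMNS):
        raise ParseError(f"{path}: expected 7 tab-separated columns")

    for col in ("pos", "meth_count", "unmeth_count"):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() | (converted != converted.astype("float64").round())
        if bad.any():
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 1
            raise ParseError(f"{path}: line {line}: non-integer value in '{col}'")
        df[col] = converted.astype(np.int64)

    neg = (df["meth_count"] < 0) | (df["unmeth_count"] < 0) | (df["pos"] < 1)
    if neg.any():
        line = int(np.flatnonzero(neg.to_numpy())[0]) + 1
        raise ParseError(f"{path}: line {line}: negative count or position")

    bad_strand = ~df["strand"].isin(["+", "-"])
    if bad_strand.any():
        line = int(np.flatnonzero(bad_strand.to_numpy())[0]) + 1
        raise ParseError(f"{path}: line {line}: strand must be '+' or '-'")

    if keep_context is not None:
        keep = df["context"] == keep_context
        n_dropped = int((~keep).sum())
        if n_dropped:
            logger.info("%s: dropped %d non-%s rows", path, n_dropped, keep_context)
        df = df.loc[keep].reset_index(drop=True)
    return df


def write_cytosine_report(calls: pd.DataFrame, path) -> None:
    calls.to_csv(path, sep="\t", header=False, index=False,
                 columns=REPORT_COLUMNS)


def collapse_strands(calls: pd.DataFrame) -> pd.DataFrame:
    """Collapse the CpG dyad onto the + strand cytosine.

    A - strand call at position p+1 is merged (counts summed) into the
    + strand site at p; an orphan - strand call is re-anchored to its own
    position minus one. Returns a sorted, unique (chrom, pos, meth, total)
    table.
    """
    if calls.empty:
        return pd.DataFrame(columns=["chrom", "pos", "meth", "total"])
    pos = calls["pos"].to_numpy(np.int64)
    anchored = np.where(calls["strand"].to_numpy() == "-", pos - 1, pos)
    df = pd.DataFrame({
        "chrom": calls["chrom"].to_numpy(),
        "pos": anchored,
        "meth": calls["meth_count"].to_numpy(np.int64),
        "total": (calls["meth_count"] + calls["unmeth_count"]).to_numpy(np.int64),
    })
    out = (df.groupby(["chrom", "pos"], as_index=False, sort=True)[["meth", "total"]]
             .sum())
    return out


# ---------------------------------------------------------------------------
# sample sheets
# ---------------------------------------------------------------------------

SHEET_COLUMNS = ["sample_id", "animal", "group", "treatment", "path"]


def validate_sample_sheet(sheet: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SHEET_COLUMNS if c not in sheet.columns]
    if missing:
        raise ParseError(f"sample sheet is missing columns {missing}")
    if sheet["sample_id"].duplicated().any():
        dup = sheet.loc[sheet["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ParseError(f"duplicate sample id: {dup}")
    bad = ~sheet["treatment"].isin(TREATMENTS)
    if bad.any():
        raise ParseError(f"unknown treatment: {sheet.loc[bad, 'treatment'].iloc[0]}")
    for animal, sub in sheet.groupby("animal"):
        tr = sorted(sub["treatment"])
        if tr != sorted(TREATMENTS):
            raise ParseError(
                f"animal {animal} must contribute exactly one BS and one OxBS "
                f"library (got {tr})")
        if sub["group"].nunique() != 1:
            raise ParseError(f"animal {animal} assigned to multiple groups")
    if sheet["group"].nunique() < 1:
        raise ParseError("sample sheet has no groups")
    return sheet


def read_sample_sheet(path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t", dtype=str)
    return validate_sample_sheet(sheet)


def write_sample_sheet(sheet: pd.DataFrame, path) -> None:
    sheet.to_csv(path, sep="\t", index=False, columns=SHEET_COLUMNS)


# ---------------------------------------------------------------------------
# count matrix
# ---------------------------------------------------------------------------

def library_key(animal: str, treatment: str) -> str:
    return f"{animal}.{treatment}"


def matrix_libraries(matrix: pd.DataFrame) -> List[Tuple[str, str]]:
    """Return the (animal, treatment) pairs present in a count matrix."""
    libs = []
    for col in matrix.columns:
        if col.endswith(".total"):
            animal, treatment, _ = col.split(".")
            libs.append((animal, treatment))
    return libs


def assemble_matrix(sheet: pd.DataFrame, calls_by_sample=None) -> pd.DataFrame:
    """Outer-join strand-collapsed per-sample counts into one site matrix.

    ``calls_by_sample`` may supply already-parsed cytosine call tables keyed
    by sample id; otherwise each sample's ``path`` is read from disk. Sites
    missing in a sample get 0/0 counts.
    """
    validate_sample_sheet(sheet)
    pieces = []
    for row in sheet.itertuples(index=False):
        if calls_by_sample is not None and row.sample_id in calls_by_sample:
            calls = calls_by_sample[row.sample_id]
        else:
            calls = read_cytosine_report(row.path)
        sites = collapse_strands(calls)
        key = library_key(row.animal, row.treatment)
        sites = sites.rename(columns={"meth": f"{key}.meth",
                                      "total": f"{key}.total"})
        pieces.append(sites)
    if not pieces:
        raise ParseError("sample sheet is empty")
    matrix = reduce(
        lambda a, b: pd.merge(a, b, on=["chrom", "pos"], how="outer"), pieces)
    count_cols = [c for c in matrix.columns if c not in ("chrom", "pos")]
    matrix[count_cols] = matrix[count_cols].fillna(0.0)
    matrix = matrix.sort_values(["chrom", "pos"], kind="mergesort",
                                ignore_index=True)
    if matrix.duplicated(["chrom", "pos"]).any():
        raise ParseError("duplicate (chrom, pos) after assembly")
    return matrix


# ---------------------------------------------------------------------------
# BED-like intervals
# ---------------------------------------------------------------------------

ELEMENT_COLUMNS = ["chrom", "start", "end", "element_class", "gene_id",
                   "element_id"]
ELEMENT_CLASSES = ("exon", "intron", "CDS", "promoter", "enhancer", "CTCF",
                   "TF_binding", "open_chromatin")


def read_elements(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "gene_id": str,
                                            "element_id": str})
    missing = [c for c in ELEMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: element table missing columns {missing}")
    bad = df["start"] >= df["end"]
    if bad.any():
        rec = df.loc[bad].iloc[0]
        raise ParseError(f"{path}: malformed interval "
                         f"{rec['chrom']}:{rec['start']}-{rec['end']}")
    return df


def write_elements(elements: pd.DataFrame, path) -> None:
    elements.to_csv(path, sep="\t", index=False)


def read_genes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "gene_id": str})
    for c in ("chrom", "start", "end", "gene_id"):
        if c not in df.columns:
            raise ParseError(f"{path}: gene table missing column '{c}'")
    return df


def write_bed(intervals: pd.DataFrame, path, name_col: str = None,
              score_col: str = None) -> None:
    """Write chrom/start/end (+ optional name and score) as BED."""
    cols = {"chrom": intervals["chrom"], "start": intervals["start"],
            "end": intervals["end"]}
    if name_col is not None:
        cols["name"] = intervals[name_col]
    if score_col is not None:
        cols["score"] = intervals[score_col]
    pd.DataFrame(cols).to_csv(path, sep="\t", header=False, index=False)
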