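"""Read-to-gene assignment and per-group tail-length summaries.

Reads are assigned to genes by maximal same-strand overlap of the read's
reference span with the gene span (bed-style, not exon-aware). Reads
overlapping no same-strand gene are left unassigned; exact overlap ties are
dropped so per-gene distributions stay disjoint. Summaries report mean,
median, quartiles (linear interpolation), Pearson's second skewness
coefficient 3*(mean - median)/s, and the number of observations per gene or
splice isoform.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)


def read_bed12(path: str | Path) -> pd.DataFrame:
    """Parse gene intervals from a BED(12) file (0-based half-open)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}:{lineno}: expected >= 6 BED columns, got {len(fields)}")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            rows.append(
                {"chrom": fields[0], "start": start, "end": end,
                 "gene_id": fields[3], "strand": fields[5]}
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene_id", "strand"])


def read_gtf_genes(path: str | Path) -> pd.DataFrame:
    """Parse gene spans from a GTF file (converted to 0-based half-open).

    Uses ``gene`` features when present, otherwise the union of each
    gene_id's exons.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GTF columns")
            chrom, _, feature, start, end, _, strand, _, attrs = fields[:9]
            gene_id = None
            for attr in attrs.split(";"):
                attr = attr.strip()
                if attr.startswith("gene_id"):
                    gene_id = attr.split(None, 1)[1].strip('"')
                    break
            if gene_id is None:
                raise ValueError(f"{path}:{lineno}: missing gene_id attribute")
            rows.append(
                {"chrom": chrom, "start": int(start) - 1, "end": int(end),
                 "gene_id": gene_id, "strand": strand, "feature": feature}
            )
    df = pd.DataFrame(rows)
    if (df.feature == "gene").any():
        df = df[df.feature == "gene"]
        return df.drop(columns="feature").reset_index(drop=True)
    agg = df.groupby(["gene_id", "chrom", "strand"], sort=False).agg(
        start=("start", "min"), end=("end", "max")
    ).reset_index()
    return agg[["chrom", "start", "end", "gene_id", "strand"]]


def read_annotation(path: str | Path) -> pd.DataFrame:
    path = str(path)
    if path.endswith((".gtf", ".gff")):
        return read_gtf_genes(path)
    return read_bed12(path)


def _build_trees(annotation: pd.DataFrame) -> dict[tuple[str, str], IntervalTree]:
    trees: dict[tuple[str, str], IntervalTree] = {}
    for row in annotation.itertuples(index=False):
        trees.setdefault((row.chrom, row.strand), IntervalTree()).addi(
            row.start, row.end, row.gene_id
        )
    return trees


def assign_to_genes(tails: pd.DataFrame, annotation: pd.DataFrame) -> pd.DataFrame:
    """Assign each read to the same-strand gene with maximal span overlap.

    Adds a ``gene_id`` column; unassigned reads (no overlap, or an exact
    overlap tie between genes) get NA.
    """
    trees = _build_trees(annotation)
    gene_ids: list[object] = []
    for row in tails.itertuples(index=False):
        tree = trees.get((row.reference_name, row.strand))
        best_gene, best_ov, tie = None, 0, False
        if tree is not None:
            for iv in tree.overlap(row.ref_start, row.ref_end):
                ov = min(iv.end, row.ref_end) - max(iv.begin, row.ref_start)
                if ov > best_ov:
                    best_gene, best_ov, tie = iv.data, ov, False
                elif ov == best_ov and best_gene is not None:
                    tie = True
        gene_ids.append(pd.NA if tie or best_gene is None else best_gene)
    out = tails.copy()
    out["gene_id"] = gene_ids
    return out


def pearson_skew(lengths) -> float:
    """Pearson's second skewness coefficient 3*(mean - median)/s.

    s is the sample standard deviation (n-1 denominator). Returns NaN when
    n < 2 or s = 0 (undefined).
    """
    x = np.asarray(lengths, dtype=float)
    if x.size < 2:
        return float("nan")
    s = x.std(ddof=1)
    if s == 0:
        return float("nan")
    return float(3.0 * (x.mean() - np.median(x)) / s)


def summarize_group(lengths, group_id: str = "", condition: str = "") -> dict:
    """Tail-length summary for one gene or isoform under one condition."""
    x = np.asarray(lengths, dtype=float)
    if x.size == 0:
        raise ValueError("cannot summarize an empty group")
    q25, med, q75 = np.percentile(x, [25, 50, 75])
    return {
        "group_id": group_id,
        "condition": condition,
        "n_reads": int(x.size),
        "mean": float(x.mean()),
        "median": float(med),
        "q25": float(q25),
        "q75": float(q75),
        "pearson_skew": pearson_skew(x),
    }


def summarize_by_gene(assigned: pd.DataFrame) -> pd.DataFrame:
    """Per-(gene, sample) tail summaries over passing, assigned reads."""
    df = assigned[assigned.is_tail & assigned.gene_id.notna()]
    rows = [
        summarize_group(sub.clip_length.to_numpy(), group_id=gene, condition=sample)
        for (gene, sample), sub in df.groupby(["gene_id", "sample"], sort=True)
    ]
    columns = ["group_id", "condition", "n_reads", "mean", "median", "q25", "q75", "pearson_skew"]
    return pd.DataFrame(rows, columns=columns)


def summarize_by_isoform(
    assigned: pd.DataFrame, isoform_assignments: pd.DataFrame
) -> pd.DataFrame:
    """Per-(isoform, sample) summaries with the intron-retention flag.

    ``isoform_assignments`` columns: read_id, isoform_id, intron_retained
    (optionally gene_id). Reads absent from the table are skipped; a
    read_id mapped to more than one isoform is an error.
    """
    dup = isoform_assignments[isoform_assignments.read_id.duplicated(keep=False)]
    conflicts = dup.groupby("read_id").isoform_id.nunique()
    offenders = conflicts[conflicts > 1].index.tolist()
    if offenders:
        raise ValueError(f"conflicting isoform assignments for reads: {offenders}")
    iso = isoform_assignments.drop_duplicates("read_id")
    df = assigned[assigned.is_tail].merge(
        iso[["read_id", "isoform_id", "intron_retained"]], on="read_id", how="inner"
    )
    if df.empty:
        logger.warning("no reads matched the isoform assignment table")
        return pd.DataFrame(
            columns=["group_id", "condition", "n_reads", "mean", "median",
                     "q25", "q75", "pearson_skew", "is_intron_retained"]
        )
    rows = []
    for (iso_id, sample, ir), sub in df.groupby(
        ["isoform_id", "sample", "intron_retained"], sort=True
    ):
        rec = summarize_group(sub.clip_length.to_numpy(), group_id=iso_id, condition=sample)
        rec["is_intron_retained"] = bool(ir)
        rows.append(rec)
    return pd.DataFrame(rows)
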