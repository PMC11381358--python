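"""Differential tail-length testing between two conditions.

Per gene (or isoform), the two conditions' tail-length distributions are
compared with a two-sided Mann–Whitney U test (tie-corrected normal
approximation with continuity correction; group sizes passing the read
filter are large enough for the approximation). P-values are adjusted with
the Benjamini–Hochberg step-up procedure and calls are made at FDR < 0.05.
Replicates are pooled per condition before testing.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

DEFAULT_MIN_READS = 100
DEFAULT_FDR = 0.05


def mann_whitney_u(a, b, method: str = "asymptotic") -> tuple[float, float]:
    """Two-sided Mann–Whitney U test; returns (U for sample a, p-value).

    The asymptotic p uses the tie correction and continuity correction.
    When every value in both samples is identical the test is degenerate:
    U = n_a*n_b/2 and p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return a.size * b.size / 2.0, 1.0
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must be in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def compare_conditions(
    tails_a: pd.DataFrame,
    tails_b: pd.DataFrame,
    min_reads: int = DEFAULT_MIN_READS,
    fdr: float = DEFAULT_FDR,
    group_col: str = "gene_id",
    value_col: str = "clip_length",
    label_a: str = "A",
    label_b: str = "B",
) -> pd.DataFrame:
    """Test every group with >= min_reads passing reads in each condition.

    Input tables carry group assignments (``group_col``) and per-read tail
    lengths (``value_col``); only ``is_tail`` rows with a non-null group are
    used. Direction is the sign of median_a - median_b for significant
    groups.
    """
    def _usable(df: pd.DataFrame) -> pd.DataFrame:
        df = df[df[group_col].notna()]
        if "is_tail" in df.columns:
            df = df[df.is_tail]
        return df

    a = _usable(tails_a)
    b = _usable(tails_b)
    groups_a = {g: sub[value_col].to_numpy(float) for g, sub in a.groupby(group_col)}
    groups_b = {g: sub[value_col].to_numpy(float) for g, sub in b.groupby(group_col)}
    testable = sorted(
        g for g in set(groups_a) & set(groups_b)
        if groups_a[g].size >= min_reads and groups_b[g].size >= min_reads
    )
    columns = ["group_id", "n_a", "n_b", "median_a", "median_b",
               "u_stat", "p_value", "q_value", "direction", "significant"]
    if not testable:
        logger.warning("no groups pass the %d-read filter in both conditions", min_reads)
        return pd.DataFrame(columns=columns)

    rows = []
    for g in testable:
        xa, xb = groups_a[g], groups_b[g]
        u, p = mann_whitney_u(xa, xb)
        rows.append(
            {"group_id": g, "n_a": xa.size, "n_b": xb.size,
             "median_a": float(np.median(xa)), "median_b": float(np.median(xb)),
             "u_stat": u, "p_value": p}
        )
    out = pd.DataFrame(rows, columns=columns[:7])
    out["q_value"] = bh_adjust(out.p_value.to_numpy())
    out["significant"] = out.q_value < fdr
    diff = out.median_a - out.median_b
    out["direction"] = np.select(
        [out.significant & (diff > 0), out.significant & (diff < 0)],
        [f"longer_in_{label_a}", f"longer_in_{label_b}"],
        default="none",
    )
    return out[columns].sort_values("q_value", kind="stable").reset_index(drop=True)
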