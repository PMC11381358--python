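"""Positional nucleotide composition of called poly(A) tails.

Tails are stacked either at the cleavage site (position 0 = first tail base
after the cleavage site, counting toward 3′) or at the 3′ end (position 0 =
terminal base, counting toward 5′) and per-position base counts are
accumulated. T in the stored DNA-space sequences is reported as U, since
tails are RNA. Condition differences are assessed per position with a
Welch two-sample t-test on per-read binary non-A indicators among the
tails covering that position; no correction is applied across positions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

ANCHORS = ("cleavage_site", "three_prime_end")
DEFAULT_MAX_POS = {"cleavage_site": 400, "three_prime_end": 50}

_BASE_ORDER = ("A", "C", "G", "U")


def _oriented(seq: str, anchor: str) -> str:
    # cleavage_site: walk 5'->3'; three_prime_end: walk 3'->5'
    return seq if anchor == "cleavage_site" else seq[::-1]


def build_profile(
    tails: pd.DataFrame,
    anchor: str = "three_prime_end",
    max_pos: int | None = None,
    condition: str = "",
) -> pd.DataFrame:
    """Per-position base counts over passing tails.

    Returns a long-format table: condition, anchor, position, base, count,
    coverage, fraction. N bases are excluded from both counts and coverage.
    """
    if anchor not in ANCHORS:
        raise ValueError(f"anchor must be one of {ANCHORS}, got {anchor!r}")
    if max_pos is None:
        max_pos = DEFAULT_MAX_POS[anchor]
    counts = np.zeros((max_pos, 4), dtype=np.int64)
    df = tails[tails.is_tail] if "is_tail" in tails.columns else tails
    idx = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}
    for seq in df.tail_seq:
        for p, base in enumerate(_oriented(seq, anchor)[:max_pos]):
            j = idx.get(base)
            if j is not None:
                counts[p, j] += 1
    coverage = counts.sum(axis=1)
    rows = []
    for p in range(max_pos):
        for j, base in enumerate(_BASE_ORDER):
            rows.append(
                {"condition": condition, "anchor": anchor, "position": p,
                 "base": base, "count": int(counts[p, j]),
                 "coverage": int(coverage[p]),
                 "fraction": counts[p, j] / coverage[p] if coverage[p] else np.nan}
            )
    return pd.DataFrame(rows)


def _nonA_indicators(tails: pd.DataFrame, anchor: str, max_pos: int) -> list[list[int]]:
    """Per position, the binary non-A indicator of every tail covering it."""
    cover: list[list[int]] = [[] for _ in range(max_pos)]
    df = tails[tails.is_tail] if "is_tail" in tails.columns else tails
    for seq in df.tail_seq:
        for p, base in enumerate(_oriented(seq, anchor)[:max_pos]):
            if base == "N":
                continue
            cover[p].append(0 if base == "A" else 1)
    return cover


def positionwise_test(
    tails_a: pd.DataFrame,
    tails_b: pd.DataFrame,
    anchor: str = "three_prime_end",
    max_pos: int | None = None,
) -> pd.DataFrame:
    """Welch t-test on non-A indicators at each position; two-sided p per position.

    Positions with coverage < 2 in either condition get NaN. A position where
    both conditions are constant with equal means (e.g. all-A on both sides)
    is also undefined (no variance to test against).
    """
    if anchor not in ANCHORS:
        raise ValueError(f"anchor must be one of {ANCHORS}, got {anchor!r}")
    if max_pos is None:
        max_pos = DEFAULT_MAX_POS[anchor]
    if (tails_a.is_tail.sum() if "is_tail" in tails_a.columns else len(tails_a)) == 0 or \
       (tails_b.is_tail.sum() if "is_tail" in tails_b.columns else len(tails_b)) == 0:
        raise ValueError("both conditions must contain passing tails")
    cov_a = _nonA_indicators(tails_a, anchor, max_pos)
    cov_b = _nonA_indicators(tails_b, anchor, max_pos)
    rows = []
    for p in range(max_pos):
        xa = np.asarray(cov_a[p], dtype=float)
        xb = np.asarray(cov_b[p], dtype=float)
        if xa.size < 2 or xb.size < 2:
            pval, tstat = np.nan, np.nan
        elif xa.var() == 0 and xb.var() == 0:
            # no within-group variance: identical rates are trivially equal,
            # different constant rates admit no t statistic
            tstat, pval = (0.0, 1.0) if xa.mean() == xb.mean() else (np.nan, np.nan)
        else:
            res = stats.ttest_ind(xa, xb, equal_var=False)
            tstat, pval = float(res.statistic), float(res.pvalue)
        rows.append(
            {"position": p, "n_a": xa.size, "n_b": xb.size,
             "rate_a": xa.mean() if xa.size else np.nan,
             "rate_b": xb.mean() if xb.size else np.nan,
             "t_stat": tstat, "p_value": pval}
        )
    return pd.DataFrame(rows)
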