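"""Metabolic-labeling (nucleotide-recoding) RNA turnover kinetics.

During a pulse of 4-thiouridine, newly synthesized RNA incorporates s4U;
chemical recoding converts it so that new reads carry T→C mismatches
against the reference. Per read we count reference-T sites passing the
quality/end/SNP filters (n_T) and how many of those read as C (n_TC). A
gene's reads are then a two-component binomial mixture: a fraction θ of
reads are "new" with per-T conversion rate p_new, the rest "old" with the
background rate p_old. θ is estimated by EM, and under first-order
turnover over a labeling window of t hours,

    k_deg = -ln(1 - θ) / t          (1/h)
    k_syn = k_deg * steady-state expression level.

Mutation-calling filters: a T site contributes only if its base quality is
at least 40, it lies at least 5 nt from both read ends, and it is not in
the SNP mask. On minus-strand genes the transcript-space T→C event is a
genomic A→G, handled via the annotation strand.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats
from scipy.special import logsumexp

from .tailcall import AlignedRead

logger = logging.getLogger(__name__)

DEFAULT_MIN_QUAL = 40
DEFAULT_END_TRIM = 5
DEFAULT_T_LABEL = 2.0
THETA_CLAMP = 1.0 - 1e-6

_CONSUME_QUERY = {0, 1, 4, 7, 8}  # M I S = X
_CONSUME_REF = {0, 2, 3, 7, 8}  # M D N = X


@dataclasses.dataclass
class MutationCounts:
    read_id: str
    gene_id: str
    n_T: int
    n_TC: int
    sample: str = ""


@dataclasses.dataclass
class MixtureParams:
    theta: float
    p_new: float
    p_old: float
    log_likelihood: float
    n_iter: int
    ll_trajectory: list[float] = dataclasses.field(default_factory=list)


def load_snp_mask(path: str | Path) -> dict[str, IntervalTree]:
    """Load a BED file of masked positions into per-chromosome trees."""
    trees: dict[str, IntervalTree] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            chrom, start, end = line.split("\t")[:3]
            trees.setdefault(chrom, IntervalTree()).addi(int(start), int(end))
    return trees


def _aligned_pairs(read: AlignedRead) -> Iterable[tuple[int, int]]:
    """(query_pos, ref_pos) for aligned (match/mismatch) columns, from CIGAR."""
    q, r = 0, read.ref_start
    for op, length in read.cigar:
        if op in (0, 7, 8):  # aligned columns
            for k in range(length):
                yield q + k, r + k
            q += length
            r += length
        elif op in _CONSUME_QUERY:
            q += length
        elif op in _CONSUME_REF:
            r += length


def call_mutations(
    read: AlignedRead,
    reference: dict[str, str] | None = None,
    snp_mask: dict[str, IntervalTree] | None = None,
    min_qual: int = DEFAULT_MIN_QUAL,
    end_trim: int = DEFAULT_END_TRIM,
    gene_strand: str = "+",
    gene_id: str = "",
) -> MutationCounts:
    """Count filtered reference-T sites and T→C conversions in one read.

    The reference base at each aligned column comes from ``reference``
    (chromosome → sequence) or, if absent, from the read's MD-tag-resolved
    pairs captured at parse time. A column counts toward n_T when its
    transcript-space reference base is T (genomic A for minus-strand
    genes), its base quality is >= ``min_qual``, it lies >= ``end_trim`` nt
    from both read ends, and it is not masked; it additionally counts
    toward n_TC when the read base is the transcript-space C (genomic G on
    the minus strand).
    """
    if read.base_qualities is None:
        raise ValueError(f"read {read.read_id}: base qualities required for mutation calling")
    if reference is not None:
        pairs = (
            (q, r, reference[read.reference_name][r]) for q, r in _aligned_pairs(read)
        )
    elif read.ref_pairs is not None:
        pairs = iter(read.ref_pairs)
    else:
        raise ValueError(
            f"read {read.read_id}: need a reference sequence or MD-tag pairs"
        )
    if gene_strand == "+":
        ref_t, mut_base = "T", "C"
    else:
        ref_t, mut_base = "A", "G"
    mask = snp_mask.get(read.reference_name) if snp_mask else None
    qlen = len(read.sequence)
    n_t = n_tc = 0
    for qpos, rpos, refbase in pairs:
        if refbase.upper() != ref_t:
            continue
        if qpos < end_trim or qpos >= qlen - end_trim:
            continue
        if read.base_qualities[qpos] < min_qual:
            continue
        if mask is not None and mask.overlaps(rpos):
            continue
        n_t += 1
        if read.sequence[qpos] == mut_base:
            n_tc += 1
    return MutationCounts(read.read_id, gene_id, n_t, n_tc, sample=read.sample)


def _mixture_ll(n_t, n_tc, theta, p_new, p_old) -> float:
    la = np.log(theta + 1e-300) + stats.binom.logpmf(n_tc, n_t, p_new)
    lb = np.log(1 - theta + 1e-300) + stats.binom.logpmf(n_tc, n_t, p_old)
    return float(logsumexp(np.stack([la, lb]), axis=0).sum())


def fit_binomial_mixture(
    counts: pd.DataFrame | Sequence[MutationCounts],
    fix_p_old: float | None = None,
    min_reads: int = 20,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> MixtureParams:
    """EM fit of the two-binomial mixture of per-read T→C counts.

    Maximizes sum_i log[ θ·Bin(n_TC|n_T, p_new) + (1−θ)·Bin(n_TC|n_T, p_old) ]
    over θ, p_new and (unless fixed) p_old. The log-likelihood is monotone
    non-decreasing across iterations; convergence when the increase drops
    below ``tol`` or after ``max_iter`` iterations.
    """
    if not isinstance(counts, pd.DataFrame):
        counts = pd.DataFrame([dataclasses.asdict(c) for c in counts])
    df = counts[counts.n_T >= 1]
    if len(df) < min_reads:
        raise ValueError(f"need >= {min_reads} reads with n_T >= 1, got {len(df)}")
    n_t = df.n_T.to_numpy(dtype=float)
    n_tc = df.n_TC.to_numpy(dtype=float)

    rates = n_tc / n_t
    p_old = fix_p_old if fix_p_old is not None else max(np.quantile(rates, 0.25), 1e-5)
    p_new = max(np.quantile(rates, 0.9), p_old * 5, 1e-3)
    p_new = min(p_new, 0.5)
    theta = 0.5

    ll_prev = -np.inf
    traj: list[float] = []
    it = 0
    for it in range(1, max_iter + 1):
        la = np.log(theta + 1e-300) + stats.binom.logpmf(n_tc, n_t, p_new)
        lb = np.log(1 - theta + 1e-300) + stats.binom.logpmf(n_tc, n_t, p_old)
        norm = np.logaddexp(la, lb)
        gamma = np.exp(la - norm)  # responsibility of the "new" component
        ll = float(norm.sum())
        traj.append(ll)

        theta = float(np.clip(gamma.mean(), 1e-9, 1 - 1e-9))
        denom_new = float((gamma * n_t).sum())
        if denom_new > 0:
            p_new = float(np.clip((gamma * n_tc).sum() / denom_new, 1e-9, 1.0))
        if fix_p_old is None:
            denom_old = float(((1 - gamma) * n_t).sum())
            if denom_old > 0:
                p_old = float(np.clip(((1 - gamma) * n_tc).sum() / denom_old, 0.0, 1.0))
        if p_new < p_old:  # keep the labeled component the high-rate one
            p_new, p_old = p_old, p_new
            theta = 1.0 - theta
        if ll - ll_prev < tol and it > 1:
            break
        ll_prev = ll

    if p_new - p_old < 1e-7:
        # components collapsed: the mixture is unidentifiable and there is
        # no evidence of a distinct labeled population
        theta = 0.0
    ll_final = _mixture_ll(n_t, n_tc, theta, p_new, p_old)
    return MixtureParams(theta=theta, p_new=p_new, p_old=p_old,
                         log_likelihood=ll_final, n_iter=it, ll_trajectory=traj)


def kdeg_from_theta(theta: float, t_label: float = DEFAULT_T_LABEL) -> float:
    """First-order degradation rate constant from fraction-new.

    k_deg = -ln(1-θ)/t; θ is clamped just below 1 to keep the rate finite.
    """
    if not 0 <= theta <= 1:
        raise ValueError("theta must be in [0, 1]")
    if t_label <= 0:
        raise ValueError("t_label must be > 0")
    if theta > THETA_CLAMP:
        logger.info("theta %.6f clamped to %.6f before log", theta, THETA_CLAMP)
        theta = THETA_CLAMP
    return float(-np.log1p(-theta) / t_label)


def ksyn_from_kdeg(k_deg: float, expression_level: float) -> float:
    """Synthesis rate under steady state: k_syn = k_deg * level."""
    if k_deg < 0 or expression_level < 0:
        raise ValueError("k_deg and expression_level must be >= 0")
    return k_deg * expression_level


def fit_gene_kinetics(
    mutation_table: pd.DataFrame,
    t_label: float = DEFAULT_T_LABEL,
    fix_p_old: float | None = None,
    expression: pd.Series | dict | None = None,
    min_reads: int = 20,
) -> pd.DataFrame:
    """Per-gene θ → k_deg (→ k_syn when expression levels are supplied)."""
    rows = []
    for gene, sub in mutation_table.groupby("gene_id", sort=True):
        try:
            fit = fit_binomial_mixture(sub, fix_p_old=fix_p_old, min_reads=min_reads)
        except ValueError:
            continue
        k_deg = kdeg_from_theta(fit.theta, t_label)
        level = np.nan if expression is None else float(expression.get(gene, np.nan))
        rows.append(
            {"gene_id": gene, "n_reads": len(sub), "theta": fit.theta,
             "p_new": fit.p_new, "p_old": fit.p_old, "k_deg": k_deg,
             "expression_level": level,
             "k_syn": ksyn_from_kdeg(k_deg, level) if np.isfinite(level) else np.nan}
        )
    return pd.DataFrame(
        rows, columns=["gene_id", "n_reads", "theta", "p_new", "p_old",
                       "k_deg", "expression_level", "k_syn"]
    )


def estimate_background_rate(control_table: pd.DataFrame) -> float:
    """Pooled T→C rate from an unlabeled control (no-s4U) sample."""
    tot_t = control_table.n_T.sum()
    if tot_t == 0:
        raise ValueError("control table has no T sites")
    return float(control_table.n_TC.sum() / tot_t)


def compare_kinetics(
    kin_a: pd.DataFrame,
    kin_b: pd.DataFrame,
    tails_a: pd.Series | dict | None = None,
    tails_b: pd.Series | dict | None = None,
    bin_width: float = 50.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene log2 fold changes between conditions and their correlations.

    Returns (fold-change table, correlation summary). Genes with zero or
    non-finite rates in either condition are excluded (count logged). When
    per-gene median tails are supplied, the Δtail vs Δk_deg correlation and
    per-tail-bin k_deg summaries are included.
    """
    merged = kin_a.merge(kin_b, on="gene_id", suffixes=("_a", "_b"))
    n_in = len(merged)
    ok = (merged.k_deg_a > 0) & (merged.k_deg_b > 0)
    merged = merged[ok].copy()
    if n_in - len(merged):
        logger.info("excluded %d genes with zero/undefined rates", n_in - len(merged))
    merged["log2fc_kdeg"] = np.log2(merged.k_deg_a / merged.k_deg_b)
    with np.errstate(divide="ignore", invalid="ignore"):
        merged["log2fc_ksyn"] = np.log2(merged.k_syn_a / merged.k_syn_b)

    cors = []

    def _pearson(x, y, name):
        m = np.isfinite(x) & np.isfinite(y)
        if m.sum() < 3 or np.std(x[m]) == 0 or np.std(y[m]) == 0:
            cors.append({"pair": name, "n": int(m.sum()), "r": np.nan, "p_value": np.nan})
            return
        r, p = stats.pearsonr(x[m], y[m])
        cors.append({"pair": name, "n": int(m.sum()), "r": float(r), "p_value": float(p)})

    _pearson(merged.log2fc_kdeg.to_numpy(), merged.log2fc_ksyn.to_numpy(),
             "log2fc_kdeg_vs_log2fc_ksyn")

    if tails_a is not None and tails_b is not None:
        ta = pd.Series(tails_a)
        tb = pd.Series(tails_b)
        merged["median_tail_a"] = merged.gene_id.map(ta)
        merged["median_tail_b"] = merged.gene_id.map(tb)
        with np.errstate(divide="ignore", invalid="ignore"):
            merged["log2fc_tail"] = np.log2(merged.median_tail_a / merged.median_tail_b)
        _pearson(merged.log2fc_tail.to_numpy(), merged.log2fc_kdeg.to_numpy(),
                 "log2fc_tail_vs_log2fc_kdeg")
        merged["tail_bin"] = (merged.median_tail_a // bin_width) * bin_width

    return merged, pd.DataFrame(cors)


def kdeg_by_tail_bin(fc_table: pd.DataFrame, which: str = "k_deg_a") -> pd.DataFrame:
    """Median k_deg per median-tail-length bin (requires compare_kinetics output)."""
    if "tail_bin" not in fc_table.columns:
        raise ValueError("fold-change table lacks tail bins; pass tails to compare_kinetics")
    g = fc_table.groupby("tail_bin")[which]
    return g.agg(["count", "median", "mean"]).reset_index()
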