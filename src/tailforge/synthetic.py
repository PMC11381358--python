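"""Ground-truth simulators for every pipeline stage.

The generator produces a small single-chromosome genome with non-overlapping
single-exon genes on both strands, long reads whose poly(A) tails are known
exactly, metabolic-labeling (nucleotide-recoding) mutation tables with known
fraction-new, and equilibrium binding curves with known K_d — so each
downstream stage can be tested against recorded truth without external data.

Conventions
-----------
All genomic coordinates are 0-based half-open. BED output is written as-is;
GTF output is converted to 1-based closed. Tail lengths are drawn from a
negative binomial parameterized by its *median* and a dispersion (size)
parameter, an overdispersed family resembling observed per-gene tail-length
spreads. Non-A substitutions are confined to the terminal ``nonA_window``
positions of each tail, emulating the 3′-end-anchored non-A signal seen in
cellular tails.

Every function takes an explicit ``seed``; there is no global random state,
and identical seeds give byte-identical file output.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import pysam
from scipy import optimize, stats

_BASES = np.array(list("ACGT"))
_COMP = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclasses.dataclass
class SyntheticTruth:
    """Simulation parameters for one gene under one condition.

    Downstream stages must recover these values: the tail caller the
    per-read tail lengths, the summary/differential stages
    ``true_median_tail`` and the condition effect, the kinetics stage
    ``theta_true``.
    """

    gene_id: str
    condition: str
    true_median_tail: float
    tail_dispersion: float = 10.0
    nonA_rate_3prime: float = 0.0
    theta_true: float = 0.0
    p_new: float = 0.05
    p_old: float = 0.002
    reads_per_gene: int = 100

    def __post_init__(self) -> None:
        if not 0.0 <= self.theta_true <= 1.0:
            raise ValueError(f"theta_true must be in [0,1], got {self.theta_true}")
        if not 0.0 <= self.p_old < self.p_new <= 1.0:
            raise ValueError(
                f"need 0 <= p_old < p_new <= 1, got p_old={self.p_old}, p_new={self.p_new}"
            )
        if self.true_median_tail < 0:
            raise ValueError("true_median_tail must be >= 0")
        if self.reads_per_gene < 0:
            raise ValueError("reads_per_gene must be >= 0")


def nbinom_params_for_median(median: float, dispersion: float) -> tuple[float, float]:
    """Return scipy ``(n, p)`` for a negative binomial with the given median.

    ``dispersion`` is the NB size parameter r (variance = mu + mu^2/r).
    The mean mu is solved so that P(X <= median) = 0.5, putting the
    distribution's median at the requested integer value.
    """
    if median <= 0:
        raise ValueError("median must be positive")
    r = float(dispersion)
    m = float(np.floor(median))

    def cdf_gap(mu: float) -> float:
        return stats.nbinom.cdf(m, r, r / (r + mu)) - 0.5

    mu = optimize.brentq(cdf_gap, 1e-6, max(10.0 * m, 100.0))
    return r, r / (r + mu)


def generate_reference(
    n_genes: int,
    gene_length_range: tuple[int, int] = (500, 2000),
    intergenic_gap: int = 200,
    seed: int = 0,
    chrom: str = "synth1",
) -> tuple[dict[str, str], pd.DataFrame, pd.DataFrame]:
    """Generate a genome, a gene annotation, and an (initially empty) truth table.

    Genes are laid left to right with ``intergenic_gap`` nt between them,
    strands assigned at random, so no two genes overlap by construction.

    Returns
    -------
    genome : dict mapping chromosome name to sequence
    annotation : DataFrame with columns chrom, start, end, gene_id, strand
        (0-based half-open)
    truth : DataFrame skeleton with one row per gene (gene_id, strand,
        start, end, length) to be joined with per-condition parameters
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    lo, hi = gene_length_range
    if lo > hi:
        raise ValueError(f"invalid gene_length_range: min {lo} > max {hi}")
    if lo < 200:
        raise ValueError("gene lengths must be >= 200 nt")

    rng = np.random.default_rng(seed)
    lengths = rng.integers(lo, hi + 1, size=n_genes)
    strands = rng.choice(["+", "-"], size=n_genes)

    rows = []
    pieces = []
    pos = intergenic_gap
    for i in range(n_genes):
        gap = rng.choice(["A", "C", "G", "T"], size=intergenic_gap)
        body = rng.choice(["A", "C", "G", "T"], size=int(lengths[i]))
        pieces.append("".join(gap))
        pieces.append("".join(body))
        rows.append(
            {
                "chrom": chrom,
                "start": pos,
                "end": pos + int(lengths[i]),
                "gene_id": f"gene{i:04d}",
                "strand": str(strands[i]),
            }
        )
        pos += intergenic_gap + int(lengths[i])
    pieces.append("".join(rng.choice(["A", "C", "G", "T"], size=intergenic_gap)))
    # first block of sequence precedes gene 0: shift assembled genome
    genome_seq = "".join(pieces)
    genome = {chrom: genome_seq}

    annotation = pd.DataFrame(rows)
    truth = annotation.assign(length=annotation.end - annotation.start)
    return genome, annotation, truth


def simulate_tailed_reads(
    truth: Sequence[SyntheticTruth],
    annotation: pd.DataFrame,
    genome: dict[str, str],
    seed: int = 0,
    tail_model: str = "nbinom",
    nonA_window: int = 10,
    min_body: int = 100,
) -> pd.DataFrame:
    """Simulate long reads: a 3′ gene-body fragment plus a known poly(A) tail.

    Each read covers the 3′-most ``body_len`` nt of its gene (body length
    uniform on [min_body, gene length]) followed by a tail of negative
    binomial length. Within the terminal ``nonA_window`` tail positions each
    base is replaced by a random non-A base with probability
    ``nonA_rate_3prime``.

    Returns a per-read truth table with columns: read_id, gene_id, condition,
    chrom, strand, body_start, body_end (reference span, 0-based half-open),
    body_len, tail_len, tail_seq (transcript 5′→3′, A-rich).
    """
    if tail_model != "nbinom":
        raise ValueError(f"unknown tail_model: {tail_model!r}")
    rng = np.random.default_rng(seed)
    ann = annotation.set_index("gene_id")
    records = []
    for t in truth:
        gene = ann.loc[t.gene_id]
        glen = int(gene.end - gene.start)
        if t.reads_per_gene == 0:
            continue
        n, p = nbinom_params_for_median(t.true_median_tail, t.tail_dispersion)
        tail_lens = stats.nbinom.rvs(n, p, size=t.reads_per_gene, random_state=rng)
        body_lens = rng.integers(min(min_body, glen), glen + 1, size=t.reads_per_gene)
        for j in range(t.reads_per_gene):
            tail_len = int(tail_lens[j])
            tail = np.full(tail_len, "A")
            w = min(nonA_window, tail_len)
            if w > 0 and t.nonA_rate_3prime > 0:
                hit = rng.random(w) < t.nonA_rate_3prime
                subs = rng.choice(["C", "G", "T"], size=int(hit.sum()))
                tail[tail_len - w :][hit] = subs
            body_len = int(body_lens[j])
            if gene.strand == "+":
                body_start, body_end = int(gene.end) - body_len, int(gene.end)
            else:
                body_start, body_end = int(gene.start), int(gene.start) + body_len
            records.append(
                {
                    "read_id": f"{t.gene_id}_{t.condition}_{j:05d}",
                    "gene_id": t.gene_id,
                    "condition": t.condition,
                    "chrom": gene.chrom,
                    "strand": gene.strand,
                    "body_start": body_start,
                    "body_end": body_end,
                    "body_len": body_len,
                    "tail_len": tail_len,
                    "tail_seq": "".join(tail),
                }
            )
    columns = [
        "read_id", "gene_id", "condition", "chrom", "strand",
        "body_start", "body_end", "body_len", "tail_len", "tail_seq",
    ]
    return pd.DataFrame(records, columns=columns)


def write_alignments(
    reads: pd.DataFrame,
    genome: dict[str, str],
    path: str | Path,
) -> None:
    """Write simulated reads as a SAM file with the tail as a terminal soft clip.

    Plus-strand genes: gene-body bases as ``<body>M`` followed by the tail as
    a trailing ``<tail>S`` soft clip, sequence stored forward. Minus-strand
    genes: the stored sequence is the reverse complement of the transcript,
    the flag has the reverse bit set, and the tail appears as a *leading*
    soft clip whose stored bases are the reverse complement of the tail
    (mostly T).
    """
    path = str(path)
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": name, "LN": len(seq)} for name, seq in genome.items()],
    }
    ref_ids = {name: i for i, name in enumerate(genome)}
    with pysam.AlignmentFile(path, "wh", header=header) as out:
        for row in reads.itertuples(index=False):
            body = genome[row.chrom][row.body_start : row.body_end]
            a = pysam.AlignedSegment()
            a.query_name = row.read_id
            a.reference_id = ref_ids[row.chrom]
            a.reference_start = row.body_start
            a.mapping_quality = 60
            if row.strand == "+":
                transcript = body + row.tail_seq
                a.flag = 0
                a.query_sequence = transcript
                a.cigarstring = (
                    f"{row.body_len}M{row.tail_len}S" if row.tail_len else f"{row.body_len}M"
                )
            else:
                transcript = reverse_complement(body) + row.tail_seq
                a.flag = 16
                a.query_sequence = reverse_complement(transcript)
                a.cigarstring = (
                    f"{row.tail_len}S{row.body_len}M" if row.tail_len else f"{row.body_len}M"
                )
            a.query_qualities = pysam.qualitystring_to_array("I" * len(transcript))
            out.write(a)


def simulate_timelapse(
    truth: Sequence[SyntheticTruth],
    reads_per_gene: int | None = None,
    read_T_content: float = 40.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate per-read T→C mutation counts under a two-binomial mixture.

    With probability ``theta_true`` a read is newly synthesized (labeled) and
    its T→C count is Binomial(n_T, p_new); otherwise Binomial(n_T, p_old).
    n_T is Poisson around ``read_T_content`` (floored at 1). The hidden
    new/old label is retained as ``is_new``.
    """
    rng = np.random.default_rng(seed)
    frames = []
    for t in truth:
        n_reads = t.reads_per_gene if reads_per_gene is None else reads_per_gene
        if n_reads == 0:
            continue
        n_T = np.maximum(rng.poisson(read_T_content, size=n_reads), 1)
        is_new = rng.random(n_reads) < t.theta_true
        rate = np.where(is_new, t.p_new, t.p_old)
        n_TC = rng.binomial(n_T, rate)
        frames.append(
            pd.DataFrame(
                {
                    "read_id": [f"{t.gene_id}_{t.condition}_tl{j:05d}" for j in range(n_reads)],
                    "gene_id": t.gene_id,
                    "sample": t.condition,
                    "n_T": n_T,
                    "n_TC": n_TC,
                    "is_new": is_new,
                }
            )
        )
    columns = ["read_id", "gene_id", "sample", "n_T", "n_TC", "is_new"]
    if not frames:
        return pd.DataFrame(columns=columns)
    return pd.concat(frames, ignore_index=True)


# default concentration design: two-fold series from 4 uM down to 62.5 nM
DEFAULT_CONCENTRATIONS_NM = [4000.0, 2000.0, 1000.0, 500.0, 250.0, 125.0, 62.5]


def simulate_binding(
    kd: float,
    f_max: float,
    concentrations: Sequence[float] = DEFAULT_CONCENTRATIONS_NM,
    noise_sd: float = 0.0,
    n_replicates: int = 1,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate fraction-bound observations on a hyperbolic binding curve.

    fraction = f_max * c / (c + kd) + Gaussian noise, clipped to [0, 1].
    Concentrations are in nM.
    """
    if kd <= 0:
        raise ValueError("kd must be > 0")
    if not 0 < f_max <= 1:
        raise ValueError("f_max must be in (0, 1]")
    rng = np.random.default_rng(seed)
    c = np.tile(np.asarray(concentrations, dtype=float), n_replicates)
    frac = f_max * c / (c + kd)
    if noise_sd > 0:
        frac = frac + rng.normal(0.0, noise_sd, size=c.size)
    frac = np.clip(frac, 0.0, 1.0)
    return pd.DataFrame({"protein_conc_nM": c, "fraction_bound": frac})


def write_fasta(genome: dict[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_bed12(annotation: pd.DataFrame, path: str | Path) -> None:
    """Write the annotation as BED12 with a single block per gene."""
    with open(path, "w") as fh:
        for row in annotation.itertuples(index=False):
            size = row.end - row.start
            fh.write(
                f"{row.chrom}\t{row.start}\t{row.end}\t{row.gene_id}\t0\t{row.strand}"
                f"\t{row.start}\t{row.end}\t0\t1\t{size},\t0,\n"
            )


def write_gtf(annotation: pd.DataFrame, path: str | Path) -> None:
    """Write gene records as GTF (1-based closed coordinates)."""
    with open(path, "w") as fh:
        for row in annotation.itertuples(index=False):
            attrs = f'gene_id "{row.gene_id}";'
            fh.write(
                f"{row.chrom}\ttailforge\tgene\t{row.start + 1}\t{row.end}\t.\t"
                f"{row.strand}\t.\t{attrs}\n"
            )
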