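"""Poly(A) tail calling from terminal soft clips of long-read alignments.

After splice-aware mapping of full-length cDNA reads, the non-templated
poly(A) tail survives as a terminal soft clip in the CIGAR. The caller
extracts the transcript-3′ clip (trailing clip for forward alignments,
leading clip reverse-complemented for reverse alignments), computes its
adenine fraction, and accepts it as a tail when the clip is at least
``min_len`` nt and at least ``min_frac_a`` adenine (default 85%,
inclusive). The reported tail length is the full clip length, non-A bases
included — non-A nucleotides are part of real tails.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterator

import pandas as pd
import pysam

from .synthetic import reverse_complement

DEFAULT_MIN_FRAC_A = 0.85
DEFAULT_MIN_LEN = 5

_SOFT_CLIP = 4  # CIGAR op code S


@dataclasses.dataclass
class AlignedRead:
    """One primary, mapped long read."""

    read_id: str
    reference_name: str
    ref_start: int
    ref_end: int
    is_reverse: bool
    cigar: list[tuple[int, int]]  # (op, length) pysam codes
    sequence: str  # SAM orientation
    base_qualities: list[int] | None = None
    sample: str = ""
    ref_pairs: list[tuple[int, int, str]] | None = None  # (qpos, rpos, refbase)


@dataclasses.dataclass
class TailCall:
    read_id: str
    clip_length: int
    tail_seq: str  # transcript 5'->3'
    frac_A: float
    is_tail: bool
    sample: str = ""


def read_alignments(
    path: str | Path,
    region: str | None = None,
    sample: str = "",
    with_reference_bases: bool = False,
) -> Iterator[AlignedRead]:
    """Stream primary mapped records from a SAM/BAM file.

    Secondary, supplementary and unmapped records are skipped. With
    ``with_reference_bases`` the per-base reference alignment is resolved
    from the MD tag (required in that case) and attached as ``ref_pairs``.
    """
    mode = "rb" if str(path).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(path), mode) as fh:
        records = fh.fetch(region=region) if region else fh
        for rec in records:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            pairs = None
            if with_reference_bases:
                if not rec.has_tag("MD"):
                    raise ValueError(
                        f"read {rec.query_name}: MD tag required to resolve reference bases"
                    )
                pairs = [
                    (q, r, b)
                    for q, r, b in rec.get_aligned_pairs(matches_only=True, with_seq=True)
                ]
            yield AlignedRead(
                read_id=rec.query_name,
                reference_name=rec.reference_name,
                ref_start=rec.reference_start,
                ref_end=rec.reference_end,
                is_reverse=rec.is_reverse,
                cigar=list(rec.cigartuples or []),
                sequence=rec.query_sequence or "",
                base_qualities=list(rec.query_qualities) if rec.query_qualities is not None else None,
                sample=sample,
                ref_pairs=pairs,
            )


def extract_candidate_tail(read: AlignedRead) -> str:
    """Return the transcript-3′ terminal soft clip in transcript orientation.

    Forward alignment: the trailing soft clip as stored. Reverse alignment:
    the leading soft clip, reverse-complemented. Empty string when the read
    has no such clip.
    """
    if not read.cigar:
        return ""
    if read.is_reverse:
        op, length = read.cigar[0]
        if op != _SOFT_CLIP:
            return ""
        return reverse_complement(read.sequence[:length])
    op, length = read.cigar[-1]
    if op != _SOFT_CLIP:
        return ""
    return read.sequence[len(read.sequence) - length :]


def call_tail(
    clip: str,
    min_frac_a: float = DEFAULT_MIN_FRAC_A,
    min_len: int = DEFAULT_MIN_LEN,
    read_id: str = "",
    sample: str = "",
) -> TailCall:
    """Apply the adenine-content rule to a candidate clip.

    frac_A is computed over the full clip; the call passes when the clip is
    at least ``min_len`` nt and frac_A >= ``min_frac_a`` (inclusive
    boundary, so 17/20 = 0.85 passes at the default threshold).
    """
    if not 0 < min_frac_a <= 1:
        raise ValueError("min_frac_a must be in (0, 1]")
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    n = len(clip)
    frac_a = clip.count("A") / n if n else 0.0
    return TailCall(
        read_id=read_id,
        clip_length=n,
        tail_seq=clip,
        frac_A=frac_a,
        is_tail=n >= min_len and frac_a >= min_frac_a,
        sample=sample,
    )


def tail_table(
    alignments: Iterator[AlignedRead] | list[AlignedRead],
    min_frac_a: float = DEFAULT_MIN_FRAC_A,
    min_len: int = DEFAULT_MIN_LEN,
) -> pd.DataFrame:
    """Call tails for a stream of alignments; one row per input read.

    Rows with ``is_tail`` False are retained (flagged) so callers can audit
    the rejection rate; downstream statistics use only passing rows. The
    reference span and strand are carried along for gene assignment.
    """
    rows = []
    for read in alignments:
        clip = extract_candidate_tail(read)
        call = call_tail(clip, min_frac_a, min_len, read_id=read.read_id, sample=read.sample)
        rows.append(
            {
                "read_id": read.read_id,
                "sample": read.sample,
                "reference_name": read.reference_name,
                "ref_start": read.ref_start,
                "ref_end": read.ref_end,
                "strand": "-" if read.is_reverse else "+",
                "clip_length": call.clip_length,
                "frac_A": call.frac_A,
                "is_tail": call.is_tail,
                "tail_seq": call.tail_seq,
            }
        )
    columns = [
        "read_id", "sample", "reference_name", "ref_start", "ref_end",
        "strand", "clip_length", "frac_A", "is_tail", "tail_seq",
    ]
    return pd.DataFrame(rows, columns=columns)


def write_tail_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_tail_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"tail_seq": str}, keep_default_na=False,
                     na_values=[""])
    df["tail_seq"] = df["tail_seq"].fillna("")
    df["is_tail"] = df["is_tail"].astype(bool)
    return df
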