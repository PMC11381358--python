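import numpy as np
import pandas as pd
import pytest

from tailforge import synthetic


@pytest.fixture(scope="session")
def small_world():
    """A 12-gene genome with annotation, shared by read-level tests."""
    genome, annotation, _ = synthetic.generate_reference(
        12, gene_length_range=(600, 1500), seed=7
    )
    return genome, annotation


@pytest.fixture(scope="session")
def simulated_run(small_world, tmp_path_factory):
    """Two-condition simulated reads written as SAM, with per-read truth."""
    genome, annotation = small_world
    outdir = tmp_path_factory.mktemp("sim")
    frames = {}
    for i, (cond, med) in enumerate([("ctrl", 100.0), ("mut", 120.0)]):
        truth = [
            synthetic.SyntheticTruth(
                gene_id=g, condition=cond, true_median_tail=med,
                nonA_rate_3prime=0.05, reads_per_gene=60,
            )
            for g in annotation.gene_id
        ]
        reads = synthetic.simulate_tailed_reads(truth, annotation, genome, seed=11 + i)
        path = outdir / f"{cond}.sam"
        synthetic.write_alignments(reads, genome, path)
        frames[cond] = {"reads": reads, "sam": path}
    return genome, annotation, frames


def make_sam(path, records, refs=(("chr1", 10_000),)):
    """Write a minimal SAM file from raw record tuples.

    Each record: (qname, flag, rname, pos1, cigar, seq, qual, tags) with
    1-based pos and qual as a string (or None for '*').
    """
    lines = ["@HD\tVN:1.6\tSO:unsorted"]
    for name, length in refs:
        lines.append(f"@SQ\tSN:{name}\tLN:{length}")
    for qname, flag, rname, pos, cigar, seq, qual, tags in records:
        fields = [qname, str(flag), rname, str(pos), "60", cigar, "*", "0", "0",
                  seq, qual if qual is not None else "*"]
        fields.extend(tags)
        lines.append("\t".join(fields))
    path.write_text("\n".join(lines) + "\n")
    return path
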