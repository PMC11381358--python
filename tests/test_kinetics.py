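"""Mutation calling filters, mixture EM, and kinetic conversions."""

import numpy as np
import pandas as pd
import pytest
from intervaltree import IntervalTree

from tailforge import kinetics, synthetic, tailcall
from tailforge.kinetics import (call_mutations, compare_kinetics,
                                fit_binomial_mixture, kdeg_from_theta,
                                ksyn_from_kdeg)

from conftest import make_sam

REF = ("ACGTTTGCATTAGCTTACGATTTGCAGTAC" * 4)[:100]  # T-rich reference


def _sam_read(tmp_path, seq, qual, pos1=1, cigar=None, md=True):
    cigar = cigar or f"{len(seq)}M"
    tags = []
    if md:
        ref = REF[pos1 - 1 : pos1 - 1 + len(seq)]
        md_str, run = "", 0
        for r, q in zip(ref, seq):
            if r == q:
                run += 1
            else:
                md_str += f"{run}{r}"
                run = 0
        md_str += str(run)
        tags.append(f"MD:Z:{md_str}")
    sam = make_sam(tmp_path / "k.sam",
                   [("r1", 0, "chr1", pos1, cigar, seq, qual, tags)],
                   refs=(("chr1", len(REF)),))
    return next(tailcall.read_alignments(sam, with_reference_bases=md))


def brute_count(seq, qual_scores, ref, start, snp_positions=(),
                min_qual=40, end_trim=5, strand="+"):
    """Independent per-base recount for simple all-M alignments."""
    ref_t = "T" if strand == "+" else "A"
    mut = "C" if strand == "+" else "G"
    n_t = n_tc = 0
    for i, base in enumerate(seq):
        rpos = start + i
        if ref[rpos] != ref_t:
            continue
        if i < end_trim or i >= len(seq) - end_trim:
            continue
        if qual_scores[i] < min_qual:
            continue
        if rpos in snp_positions:
            continue
        n_t += 1
        if base == mut:
            n_tc += 1
    return n_t, n_tc


class TestCallMutations:
    def test_perfect_match_counts_eligible_T_only(self, tmp_path):
        seq = REF[:30]
        read = _sam_read(tmp_path, seq, "I" * 30)  # qual 40
        mc = call_mutations(read, reference={"chr1": REF})
        expect = brute_count(seq, [40] * 30, REF, 0)
        assert (mc.n_T, mc.n_TC) == expect and mc.n_TC == 0

    def test_end_trim_excludes_terminal_conversion(self, tmp_path):
        seq = list(REF[:30])
        assert REF[2] == "G" or True
        # put a T->C at read position 2 (inside the 5-nt trim zone)
        tpos = REF[:30].index("T")
        assert tpos < 5
        seq[tpos] = "C"
        read = _sam_read(tmp_path, "".join(seq), "I" * 30)
        mc = call_mutations(read, reference={"chr1": REF})
        assert mc.n_TC == 0

    def test_quality_threshold_is_exclusive_below_40(self, tmp_path):
        seq = list(REF[:30])
        tpos = [i for i in range(30) if REF[i] == "T" and 5 <= i < 25][0]
        seq[tpos] = "C"
        for qchar, counted in [("H", False), ("I", True)]:  # qual 39 vs 40
            qual = ["I"] * 30
            qual[tpos] = qchar
            read = _sam_read(tmp_path, "".join(seq), "".join(qual))
            mc = call_mutations(read, reference={"chr1": REF})
            assert (mc.n_TC == 1) is counted

    def test_snp_mask_excludes_site_entirely(self, tmp_path):
        seq = list(REF[:30])
        tpos = [i for i in range(30) if REF[i] == "T" and 5 <= i < 25][0]
        seq[tpos] = "C"
        read = _sam_read(tmp_path, "".join(seq), "I" * 30)
        mask = {"chr1": IntervalTree()}
        mask["chr1"].addi(tpos, tpos + 1)
        masked = call_mutations(read, reference={"chr1": REF}, snp_mask=mask)
        open_ = call_mutations(read, reference={"chr1": REF})
        assert open_.n_TC == 1 and masked.n_TC == 0
        assert masked.n_T == open_.n_T - 1

    def test_minus_strand_gene_counts_A_to_G(self, tmp_path):
        apos = [i for i in range(30) if REF[i] == "A" and 5 <= i < 25][0]
        seq = list(REF[:30])
        seq[apos] = "G"
        read = _sam_read(tmp_path, "".join(seq), "I" * 30)
        plus = call_mutations(read, reference={"chr1": REF}, gene_strand="+")
        minus = call_mutations(read, reference={"chr1": REF}, gene_strand="-")
        assert minus.n_TC == 1
        assert plus.n_TC == 0  # an A>G is not a T>C in plus-strand space

    def test_md_tag_path_matches_reference_path(self, tmp_path):
        seq = list(REF[:40])
        for i in (7, 19):
            if REF[i] == "T":
                seq[i] = "C"
        seq = "".join(seq)
        read_md = _sam_read(tmp_path, seq, "I" * 40, md=True)
        via_md = call_mutations(read_md, reference=None)
        via_ref = call_mutations(read_md, reference={"chr1": REF})
        assert (via_md.n_T, via_md.n_TC) == (via_ref.n_T, via_ref.n_TC)
        assert (via_md.n_T, via_md.n_TC) == brute_count(seq, [40] * 40, REF, 0)

    def test_agrees_with_brute_force_on_random_reads(self, tmp_path):
        rng = np.random.default_rng(4)
        for trial in range(10):
            start = int(rng.integers(0, 50))
            length = int(rng.integers(20, 50))
            seq = list(REF[start:start + length])
            quals = rng.choice([35, 39, 40, 41], size=length)
            for i in range(length):
                if seq[i] == "T" and rng.random() < 0.2:
                    seq[i] = "C"
            seq = "".join(seq)
            read = tailcall.AlignedRead(
                read_id=f"t{trial}", reference_name="chr1", ref_start=start,
                ref_end=start + length, is_reverse=False,
                cigar=[(0, length)], sequence=seq,
                base_qualities=quals.tolist())
            mc = call_mutations(read, reference={"chr1": REF})
            assert (mc.n_T, mc.n_TC) == brute_count(seq, quals, REF, start)

    def test_missing_qualities_rejected(self):
        read = tailcall.AlignedRead("r", "chr1", 0, 10, False, [(0, 10)],
                                    REF[:10], base_qualities=None)
        with pytest.raises(ValueError, match="qualities"):
            call_mutations(read, reference={"chr1": REF})

    def test_missing_reference_and_md_rejected(self):
        read = tailcall.AlignedRead("r", "chr1", 0, 10, False, [(0, 10)],
                                    REF[:10], base_qualities=[40] * 10)
        with pytest.raises(ValueError, match="reference"):
            call_mutations(read, reference=None)


class TestMixtureEM:
    def _simulate(self, theta, n=5000, seed=0):
        t = [synthetic.SyntheticTruth(
            gene_id="g", condition="A", true_median_tail=100,
            theta_true=theta, p_new=0.05, p_old=0.002, reads_per_gene=n)]
        return synthetic.simulate_timelapse(t, seed=seed)

    def test_mutation_free_reads_give_theta_zero(self):
        df = pd.DataFrame({"n_T": [40] * 100, "n_TC": [0] * 100})
        fit = fit_binomial_mixture(df, fix_p_old=0.0)
        assert fit.theta < 0.01

    @pytest.mark.parametrize("theta", [0.1, 0.3, 0.5, 0.8])
    def test_theta_recovered_within_tolerance(self, theta):
        fit = fit_binomial_mixture(self._simulate(theta, seed=10))
        assert abs(fit.theta - theta) < 0.03

    def test_boundary_theta_one_recovered(self):
        fit = fit_binomial_mixture(self._simulate(1.0, seed=11), fix_p_old=0.002)
        assert fit.theta >= 0.97

    def test_log_likelihood_monotone(self):
        fit = fit_binomial_mixture(self._simulate(0.3, seed=12))
        assert np.all(np.diff(fit.ll_trajectory) >= -1e-7)
        assert 0 <= fit.p_old <= fit.p_new <= 1
        assert 0 <= fit.theta <= 1

    def test_insufficient_reads_rejected(self):
        df = pd.DataFrame({"n_T": [40] * 5, "n_TC": [1] * 5})
        with pytest.raises(ValueError, match="20 reads"):
            fit_binomial_mixture(df)


class TestKineticConversions:
    @pytest.mark.parametrize("theta,t,expect", [
        (0.0, 2.0, 0.0),
        (0.5, 2.0, np.log(2) / 2),
        (0.99, 2.0, -np.log(0.01) / 2),
    ])
    def test_kdeg_closed_form(self, theta, t, expect):
        assert kdeg_from_theta(theta, t) == pytest.approx(expect)

    def test_kdeg_strictly_increasing_in_theta(self):
        thetas = np.linspace(0, 0.999, 50)
        k = [kdeg_from_theta(t) for t in thetas]
        assert np.all(np.diff(k) > 0)

    def test_theta_one_clamped_finite(self):
        assert np.isfinite(kdeg_from_theta(1.0))

    def test_ksyn_identity(self):
        assert ksyn_from_kdeg(0.0, 100.0) == 0.0
        assert ksyn_from_kdeg(0.2, 100.0) == pytest.approx(20.0)
        with pytest.raises(ValueError):
            ksyn_from_kdeg(-0.1, 1.0)


def _kin(rng, n_genes, kdeg=None):
    kdeg = kdeg if kdeg is not None else rng.lognormal(-3, 0.5, n_genes)
    level = rng.lognormal(3, 1, n_genes)
    return pd.DataFrame({
        "gene_id": [f"g{i}" for i in range(n_genes)],
        "theta": 1 - np.exp(-kdeg * 2), "k_deg": kdeg,
        "expression_level": level, "k_syn": kdeg * level})


class TestCompareKinetics:
    def test_identical_conditions_give_zero_fold_changes(self):
        rng = np.random.default_rng(8)
        kin = _kin(rng, 50)
        fc, cors = compare_kinetics(kin, kin.copy())
        assert np.allclose(fc.log2fc_kdeg, 0)
        assert np.isnan(cors.r.iloc[0])  # zero variance: undefined

    def test_coupled_rates_show_strong_correlation(self):
        rng = np.random.default_rng(9)
        base = rng.lognormal(-3, 0.5, 500)
        shift = rng.normal(0, 0.5, 500)
        a = _kin(rng, 500, kdeg=base * 2 ** shift)
        b = _kin(rng, 500, kdeg=base)
        # couple synthesis changes to degradation changes with small noise
        a["k_syn"] = b.k_syn.to_numpy() * 2 ** (shift + rng.normal(0, 0.1, 500))
        fc, cors = compare_kinetics(a, b)
        r = cors.set_index("pair").r["log2fc_kdeg_vs_log2fc_ksyn"]
        assert r > 0.9

    def test_uncoupled_tails_show_no_correlation(self):
        rng = np.random.default_rng(10)
        a = _kin(rng, 2000)
        b = _kin(rng, 2000)
        tails_a = pd.Series(rng.lognormal(np.log(100), 0.3, 2000),
                            index=a.gene_id)
        tails_b = pd.Series(rng.lognormal(np.log(100), 0.3, 2000),
                            index=b.gene_id)
        fc, cors = compare_kinetics(a, b, tails_a, tails_b)
        r = cors.set_index("pair").r["log2fc_tail_vs_log2fc_kdeg"]
        assert abs(r) < 0.1

    def test_tail_bins_use_configured_width(self):
        rng = np.random.default_rng(11)
        a = _kin(rng, 200)
        b = _kin(rng, 200)
        tails = pd.Series(rng.uniform(10, 250, 200), index=a.gene_id)
        fc, _ = compare_kinetics(a, b, tails, tails, bin_width=50)
        binned = kinetics.kdeg_by_tail_bin(fc)
        assert set(binned.tail_bin) <= {0.0, 50.0, 100.0, 150.0, 200.0}
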