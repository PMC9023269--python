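"""Outcome classification, per-sample profiles and the substitution window."""

import numpy as np
import pytest

from amplicas.align import IndelCall, align_semiglobal, extract_variants, normalize_indel
from amplicas.classify import (
    OutcomeRecord,
    classify_read,
    classify_sample,
    deletion_size_spectrum,
    profile_sample,
    substitution_rate,
)
from amplicas.refmodel import tis_template
from amplicas.simulate import OutcomeMix, simulate_short_reads


def _call(kind, ref, pos, length=1, seq=""):
    return normalize_indel(ref, IndelCall(kind, pos, length, seq, (pos, pos + 1)))


class TestClassifyRead:
    def test_templated_insertion_at_cut(self, toy_site):
        ref = toy_site.working_seq
        ins = _call("insertion", ref, toy_site.cut_pos, 1, tis_template(toy_site, 1))
        rec = classify_read([ins], toy_site)
        assert rec.klass == "insertion" and rec.is_TIS

    def test_non_templated_insertion(self, toy_site):
        ref = toy_site.working_seq
        # template is 'T'; 'G' is one of the three non-templated bases
        rec = classify_read([_call("insertion", ref, toy_site.cut_pos, 1, "G")], toy_site)
        assert rec.klass == "insertion" and rec.is_TIS is False

    def test_one_bp_deletion(self, toy_site):
        ref = toy_site.working_seq
        rec = classify_read([_call("deletion", ref, toy_site.cut_pos - 1, 1)], toy_site)
        assert rec.klass == "del_1bp" and rec.del_size == 1

    def test_mixed_precedence(self, toy_site):
        ref = toy_site.working_seq
        cut = toy_site.cut_pos
        rec = classify_read(
            [_call("deletion", ref, cut - 1, 1), _call("insertion", ref, cut + 3, 1, "A")],
            toy_site,
        )
        assert rec.klass == "mixed"

    def test_distal_variant_is_not_editing(self, toy_site):
        ref = toy_site.working_seq
        rec = classify_read([_call("deletion", ref, 1, 1)], toy_site)  # 26 nt from cut
        assert rec.klass == "unedited"

    def test_substitution_only(self, toy_site):
        ref = toy_site.working_seq
        rec = classify_read([_call("substitution", ref, toy_site.cut_pos, 1, "A")], toy_site)
        assert rec.klass == "substitution_only"

    def test_tis_exhaustive_over_all_insertions(self, toy_site):
        """Exactly 1 of 4^k possible k-bp insertions at the cut is templated."""
        ref = toy_site.working_seq
        cut = toy_site.cut_pos
        from itertools import product

        for k in (1, 2, 3):
            n_tis = 0
            for bases in product("ACGT", repeat=k):
                read = ref[:cut] + "".join(bases) + ref[cut:]
                aln = align_semiglobal(read, ref)
                rec = classify_read(extract_variants(aln, ref, read), toy_site)
                assert rec.klass == "insertion" and rec.ins_size == k
                n_tis += bool(rec.is_TIS)
            assert n_tis == 1

    def test_tis_invariant_to_indel_placement(self, sim_site):
        """A templated insertion stays TIS wherever the aligner placed it."""
        ref = sim_site.working_seq
        cut = sim_site.cut_pos
        template = tis_template(sim_site, 1)
        raw_left = IndelCall("insertion", cut, 1, template, (cut, cut + 1))
        left = normalize_indel(ref, raw_left)
        # right-most equivalent placement, with the rotated sequence
        hi = left.equivalence_interval[1] - 1
        seq = template
        pos = left.ref_start
        while pos < hi:
            seq = seq[1:] + ref[pos]
            pos += 1
        right = IndelCall("insertion", hi, 1, seq, (hi, hi + 1))
        for call in (left, normalize_indel(ref, right)):
            assert classify_read([call], sim_site).is_TIS


class TestProfileSample:
    def test_percentages_arithmetic(self):
        records = (
            [OutcomeRecord(f"d{i}", "del_1bp", del_size=1) for i in range(4)]
            + [OutcomeRecord(f"D{i}", "del_gt1bp", del_size=5) for i in range(3)]
            + [
                OutcomeRecord("i0", "insertion", ins_size=1, ins_seq="T", is_TIS=True),
                OutcomeRecord("i1", "insertion", ins_size=1, ins_seq="T", is_TIS=True),
                OutcomeRecord("i2", "insertion", ins_size=1, ins_seq="G", is_TIS=False),
            ]
        )
        p = profile_sample(records, n_reads_total=10)
        assert p.pct_del_1bp == 40 and p.pct_del_gt1bp == 30 and p.pct_insertion == 30
        assert p.pct_TIS_1bp_of_insertions == pytest.approx(66.67, abs=0.01)
        assert p.indel_rate == 100.0

    def test_class_percentages_sum_to_100(self, sim_site):
        reads, _ = simulate_short_reads(sim_site, OutcomeMix(seed=3), n=400)
        records, _ = classify_sample(reads, sim_site)
        p = profile_sample(records, len(reads))
        total = p.pct_del_1bp + p.pct_del_gt1bp + p.pct_insertion + p.pct_mixed
        assert total == pytest.approx(100.0, abs=0.01)

    def test_all_unedited_percentages_missing(self):
        records = [OutcomeRecord(f"r{i}", "unedited") for i in range(5)]
        p = profile_sample(records, 5)
        assert p.indel_rate == 0 and p.pct_del_1bp is None
        assert p.pct_TIS_1bp_of_insertions is None

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="empty sample"):
            profile_sample([], 0)

    def test_histogram_totals_match_class_tallies(self, sim_site):
        reads, _ = simulate_short_reads(sim_site, OutcomeMix(seed=11), n=300)
        records, _ = classify_sample(reads, sim_site)
        p = profile_sample(records, len(reads))
        n_del = sum(1 for r in records if r.klass in ("del_1bp", "del_gt1bp"))
        assert sum(p.size_histogram.values()) == n_del


class TestSubstitutionRate:
    def test_error_free_reads_zero(self, sim_site):
        reads, _ = simulate_short_reads(sim_site, OutcomeMix(error_rate=0.0, seed=5), n=100)
        _, aligned = classify_sample(reads, sim_site)
        assert substitution_rate(aligned, sim_site) == 0.0

    def test_one_planted_mismatch_each_is_100(self, sim_site):
        ref = sim_site.working_seq
        cut = sim_site.cut_pos
        reads = []
        for i, off in enumerate(range(-20, 20, 5)):
            pos = cut + off
            base = "A" if ref[pos] != "A" else "C"
            reads.append((f"r{i}", ref[:pos] + base + ref[pos + 1 :]))
        _, aligned = classify_sample(reads, sim_site)
        assert substitution_rate(aligned, sim_site) == 100.0

    def test_window_uncovered_raises(self, sim_site):
        ref = sim_site.working_seq
        reads = [("r0", ref[:40])]  # nowhere near the cut
        _, aligned = classify_sample(reads, sim_site)
        with pytest.raises(ValueError, match="window uncovered"):
            substitution_rate(aligned, sim_site)

    def test_binomial_expectation_recovered(self, sim_site):
        """At per-base error e over the 40-nt window the expected read-level
        rate is 100*(1-(1-e)^40); e=0.005, n=2000 keeps this fast yet tight."""
        e, n = 0.005, 2000
        mix = OutcomeMix(
            p_unedited=1.0, p_del1=0, p_mmej=0, p_tis=0, p_ins_random=0, error_rate=e, seed=9
        )
        reads, _ = simulate_short_reads(sim_site, mix, n=n)
        _, aligned = classify_sample(reads, sim_site)
        rate = substitution_rate(aligned, sim_site)
        expected = 100 * (1 - (1 - e) ** 40)
        se = 100 * np.sqrt(expected / 100 * (1 - expected / 100) / n)
        assert abs(rate - expected) <= 3 * se


class TestDeletionSpectrum:
    def test_planted_peaks(self, sim_site):
        """The default MMEJ pairs put peaks at 8 and 11 nt."""
        mix = OutcomeMix(
            p_unedited=0, p_del1=0, p_mmej=1.0, p_tis=0, p_ins_random=0,
            error_rate=0.0, seed=2,
        )
        reads, truths = simulate_short_reads(sim_site, mix, n=200)
        records, _ = classify_sample(reads, sim_site)
        hist = deletion_size_spectrum(records)
        assert set(hist) == {8, 11}
        assert hist[8] == sum(1 for t in truths if t.true_del_size == 8)

    def test_all_one_bp(self):
        records = [OutcomeRecord(f"r{i}", "del_1bp", del_size=1) for i in range(5)]
        assert deletion_size_spectrum(records) == {1: 5}

    def test_empty(self):
        assert deletion_size_spectrum([]) == {}

    def test_overflow_bin(self):
        records = [OutcomeRecord("r", "del_gt1bp", del_size=45)]
        assert deletion_size_spectrum(records) == {"gt30": 1}


def test_pct_tis_monotone_in_simulated_tis_fraction(sim_site):
    """Raising the simulator's TIS fraction raises the profiled TIS percentage
    monotonically (rank correlation 1 across settings)."""
    pcts = []
    for p_tis in (0.05, 0.15, 0.30, 0.50, 0.70):
        rest = 1.0 - p_tis - 0.10
        mix = OutcomeMix(
            p_unedited=0.10, p_del1=rest / 3, p_mmej=rest / 3, p_tis=p_tis,
            p_ins_random=rest / 3, error_rate=0.0, seed=17,
        )
        reads, _ = simulate_short_reads(sim_site, mix, n=1200)
        records, _ = classify_sample(reads, sim_site)
        prof = profile_sample(records, len(reads))
        pcts.append(prof.pct_TIS_1bp_of_insertions)
    assert pcts == sorted(pcts) and len(set(pcts)) == len(pcts)
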