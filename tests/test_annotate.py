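"""Annotation stages: merging, QC, germline calls, CDR3, isotype, SHM."""

import numpy as np
import pytest

from abrep import annotate as ann
from abrep.model import GermlineGene, SequenceRecord, revcomp, translate
from abrep.numbering import cdr3_labels
from abrep.sim import j_anchor_offset


def _rec(nt, quals=None, read_id="r"):
    return SequenceRecord(read_id=read_id, nt=nt, quals=quals)


class TestMergeReadPair:
    def test_constructed_overlap(self):
        r1 = _rec("ACGTACGTACGT")
        # mate covers the last 8 bases of r1 plus 4 novel 3' bases
        r2 = _rec(revcomp("ACGTACGT" + "GGGG"))
        merged, reason = ann.merge_read_pair(r1, r2, min_overlap=8)
        assert reason == "merged"
        assert merged.nt == "ACGTACGTACGT" + "GGGG"
        assert len(merged.nt) == 16

    def test_identical_reads_merge_to_themselves(self):
        r1 = _rec("ACGTTGCAACGTTGCA")
        r2 = _rec(revcomp(r1.nt))
        merged, _ = ann.merge_read_pair(r1, r2, min_overlap=8)
        assert merged.nt == r1.nt

    def test_disagreement_resolved_by_higher_phred(self):
        r1 = _rec("ACGTACGTAC", quals=[40] * 9 + [10])
        mate = "ACGTACGTAT"  # disagrees at the last base, higher quality
        r2 = SequenceRecord("m", revcomp(mate), quals=[30] * 10)
        merged, _ = ann.merge_read_pair(r1, r2, min_overlap=10)
        assert merged.nt == mate
        assert merged.quals[-1] == 30 - 10

    def test_random_unrelated_reads_rejected(self):
        rng = np.random.default_rng(0)
        bases = np.array(list("ACGT"))
        for _ in range(20):
            a = "".join(rng.choice(bases, 50))
            b = "".join(rng.choice(bases, 50))
            merged, reason = ann.merge_read_pair(_rec(a), _rec(b), min_overlap=10)
            # oracle: exhaustive scan; best overlap by matches - mismatches,
            # accepted only if its identity reaches 0.8
            brc = revcomp(b)
            scored = [
                (2 * sum(x == y for x, y in zip(a[-o:], brc[:o])) - o, o)
                for o in range(10, 51)
            ]
            _, best_o = max(scored, key=lambda t: (t[0], t[1]))
            best = sum(x == y for x, y in zip(a[-best_o:], brc[:best_o])) / best_o
            if best < 0.8:
                assert merged is None and reason == "overlap_identity_below_0.8"
            else:
                assert merged is not None

    def test_too_short_reads_rejected_with_reason(self):
        merged, reason = ann.merge_read_pair(_rec("ACGT"), _rec("ACGT"),
                                             min_overlap=10)
        assert merged is None and reason == "too_short_for_overlap"


class TestExpectedErrors:
    def test_closed_forms(self):
        assert ann.expected_errors([20] * 100) == pytest.approx(1.0)
        assert ann.expected_errors([10] * 10) == pytest.approx(1.0)

    def test_mixed_equals_brute_force_sum(self):
        rng = np.random.default_rng(1)
        quals = list(rng.integers(2, 41, size=200))
        brute = sum(10 ** (-q / 10) for q in quals)
        assert ann.expected_errors(quals) == pytest.approx(brute)

    def test_negative_quality_rejected(self):
        with pytest.raises(ValueError):
            ann.expected_errors([30, -1])


class TestQCFilter:
    def test_length_boundary(self):
        short = _rec("A" * 299, quals=[40] * 299)
        ok = _rec("A" * 300, quals=[40] * 300)
        kept, rejected = ann.qc_filter([short, ok])
        assert kept == [ok]
        assert rejected[0][1] == "length_below_minimum"

    def test_expected_error_boundary(self):
        # 2,100 bases at Q20 -> EE = 21 > 20
        noisy = _rec("A" * 2100, quals=[20] * 2100)
        clean = _rec("A" * 2100, quals=[40] * 2100)
        kept, rejected = ann.qc_filter([noisy, clean])
        assert kept == [clean]
        assert rejected[0][1] == "expected_errors_above_maximum"


class TestAssignVDJ:
    def test_identity_case(self, toy_germline):
        v = next(g for g in toy_germline if g.allele_name == "IGHV-T1*01")
        j = next(g for g in toy_germline if g.allele_name == "IGHJ-T1*01")
        rec = _rec(v.ungapped_nt + j.ungapped_nt)
        vdj = ann.assign_vdj(rec, toy_germline, chain="heavy")
        assert vdj.v_call == "IGHV-T1*01" and vdj.j_call == "IGHJ-T1*01"
        assert vdj.v_alignment.identity == 1.0
        assert vdj.v_alignment.mismatch_positions == []

    def test_substitutions_keep_call_and_are_located(self, toy_germline):
        v = next(g for g in toy_germline if g.allele_name == "IGHV-T2*01")
        j = next(g for g in toy_germline if g.allele_name == "IGHJ-T1*01")
        nt = list(v.ungapped_nt)
        for pos in (10, 100, 200):
            nt[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[nt[pos]]
        rec = _rec("".join(nt) + j.ungapped_nt)
        vdj = ann.assign_vdj(rec, toy_germline, chain="heavy")
        assert vdj.v_call == "IGHV-T2*01"
        assert sorted(p for p, _ in vdj.v_alignment.mismatch_positions) == [10, 100, 200]

    def test_scrambled_sequence_unassignable(self, toy_germline):
        rng = np.random.default_rng(3)
        rec = _rec("".join(rng.choice(list("ACGT"), 350)))
        vdj = ann.assign_vdj(rec, toy_germline)
        assert not vdj.assignable

    def test_noise_free_simulation_full_recovery(self, toy_germline, noise_free_sim):
        _, truth = noise_free_sim
        for cell in truth.cells:
            if not cell.productive:
                continue
            rec = _rec(cell.transcript_nt, read_id=cell.cell_id)
            vdj = ann.assign_vdj(rec, toy_germline, chain="heavy")
            assert vdj.v_call == cell.v_call
            assert vdj.j_call == cell.j_call


class TestExtractCDR3:
    def _custom_j(self):
        # anchor W at offset 0: WGQG stem plus a tail
        return GermlineGene("IGHJ-X*01", "J", "heavy",
                            "TGGGGCCAAGGAACCCTGGTCACCGTCTCC")

    def test_constructed_junction(self, toy_germline):
        v = next(g for g in toy_germline if g.segment_kind == "V"
                 and g.chain == "heavy")
        j = self._custom_j()
        nt = v.ungapped_nt + "GCGAGAGACTAC" + j.ungapped_nt
        vdj = ann.assign_vdj(_rec(nt), [v, j], chain="heavy")
        cdr3_nt, cdr3_aa = ann.extract_cdr3(nt, v, vdj.v_alignment, j,
                                            vdj.j_alignment)
        assert cdr3_nt == "GCGAGAGACTAC"
        assert cdr3_aa == "ARDY"

    def test_mutated_cys_anchor_gives_absent(self, toy_germline):
        v = next(g for g in toy_germline if g.segment_kind == "V"
                 and g.chain == "heavy")
        j = self._custom_j()
        nt = v.ungapped_nt + "GCGAGAGACTAC" + j.ungapped_nt
        # TGT (Cys104, last V codon) -> CGT (Arg)
        pos = len(v.ungapped_nt) - 3
        nt = nt[:pos] + "CGT" + nt[pos + 3:]
        vdj = ann.assign_vdj(_rec(nt), [v, j], chain="heavy")
        assert ann.extract_cdr3(nt, v, vdj.v_alignment, j,
                                vdj.j_alignment) == (None, None)

    def test_out_of_frame_junction_gives_absent(self, toy_germline):
        v = next(g for g in toy_germline if g.segment_kind == "V"
                 and g.chain == "heavy")
        j = self._custom_j()
        nt = v.ungapped_nt + "GCGAGAGACTA" + j.ungapped_nt  # 11 nt junction
        vdj = ann.assign_vdj(_rec(nt), [v, j], chain="heavy")
        assert ann.extract_cdr3(nt, v, vdj.v_alignment, j,
                                vdj.j_alignment) == (None, None)

    def test_simulated_cells_recover_truth_cdr3(self, toy_germline, noise_free_sim):
        _, truth = noise_free_sim
        germline = {g.allele_name: g for g in toy_germline}
        for cell in truth.cells:
            if not cell.productive:
                continue
            rec = _rec(cell.transcript_nt, read_id=cell.cell_id)
            vdj = ann.assign_vdj(rec, toy_germline, chain="heavy")
            cdr3_nt, cdr3_aa = ann.extract_cdr3(
                rec.nt, germline[vdj.v_call], vdj.v_alignment,
                germline[vdj.j_call], vdj.j_alignment)
            assert cdr3_nt == cell.cdr3_nt
            assert cdr3_aa == cell.cdr3_aa


class TestAssignIsotype:
    def test_exact_ch1_match(self, toy_germline):
        igg = next(g for g in toy_germline if g.allele_name == "IGHG1*01")
        assert ann.assign_isotype(igg.ungapped_nt[:40], toy_germline) == "IgG"

    def test_no_tail_unknown(self, toy_germline):
        assert ann.assign_isotype("", toy_germline) == "unknown"

    def test_two_mismatches_still_called(self, toy_germline):
        igm = next(g for g in toy_germline if g.allele_name == "IGHM*01")
        nt = list(igm.ungapped_nt)
        nt[5] = {"A": "C", "C": "A", "G": "T", "T": "G"}[nt[5]]
        nt[30] = {"A": "C", "C": "A", "G": "T", "T": "G"}[nt[30]]
        assert ann.assign_isotype("".join(nt), toy_germline) == "IgM"

    def test_random_tail_unknown(self, toy_germline):
        rng = np.random.default_rng(8)
        tail = "".join(rng.choice(list("ACGT"), 60))
        assert ann.assign_isotype(tail, toy_germline) == "unknown"


class TestProductiveness:
    def test_clean_transcript_productive(self, toy_germline, noise_free_sim):
        _, truth = noise_free_sim
        cell = next(c for c in truth.cells if c.productive)
        t = ann.annotate_record(_rec(cell.transcript_nt), toy_germline,
                                chain="heavy")
        assert t.productive

    def test_single_deletion_in_fr3_nonproductive(self, toy_germline, noise_free_sim):
        _, truth = noise_free_sim
        cell = next(c for c in truth.cells if c.productive)
        nt = cell.transcript_nt[:240] + cell.transcript_nt[241:]  # FR3 deletion
        t = ann.annotate_record(_rec(nt), toy_germline, chain="heavy")
        assert t is None or not t.productive

    def test_stop_codon_in_cdr2_nonproductive(self, toy_germline, noise_free_sim):
        _, truth = noise_free_sim
        cell = next(c for c in truth.cells if c.productive)
        # IMGT 57 is inside CDR2 and present in the toy V (codon start 3*56
        # in gapped coords; the toy genes gap 60-61, which lie downstream)
        v = next(g for g in toy_germline if g.allele_name == cell.v_call)
        span = v.ungapped_index_of_imgt(57)
        nt = (cell.transcript_nt[:span[0]] + "TAA"
              + cell.transcript_nt[span[1]:])
        t = ann.annotate_record(_rec(nt), toy_germline, chain="heavy")
        assert t is None or not t.productive


class TestComputeSHM:
    def test_identical_to_germline_is_zero(self, toy_germline):
        v = next(g for g in toy_germline if g.segment_kind == "V")
        j = next(g for g in toy_germline if g.segment_kind == "J"
                 and g.chain == v.chain)
        rec = _rec(v.ungapped_nt + j.ungapped_nt)
        vdj = ann.assign_vdj(rec, toy_germline, chain=v.chain)
        pct, subs = ann.compute_shm(vdj.v_alignment, v, rec.nt)
        assert pct == 0.0 and subs == []

    def test_six_mismatches_arithmetic(self, toy_germline):
        v = next(g for g in toy_germline if g.allele_name == "IGHV-T1*01")
        j = next(g for g in toy_germline if g.allele_name == "IGHJ-T1*01")
        nt = list(v.ungapped_nt)
        for pos in (12, 45, 90, 150, 210, 270):
            nt[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[nt[pos]]
        rec = _rec("".join(nt) + j.ungapped_nt)
        vdj = ann.assign_vdj(rec, toy_germline, chain="heavy")
        pct, _ = ann.compute_shm(vdj.v_alignment, v, rec.nt)
        cols = vdj.v_alignment.n_columns
        assert pct == pytest.approx(100.0 * 6 / cols)

    def test_shm_equals_truth_mutation_count(self, toy_germline, shm_sim):
        reads, truth = shm_sim
        germline = {g.allele_name: g for g in toy_germline}
        checked = 0
        for r in reads:
            cell = truth.cell(truth.reads[r.read_id].cell_id)
            if not cell.productive:
                continue
            vdj = ann.assign_vdj(r, toy_germline, chain="heavy")
            if vdj.v_call != cell.v_call:
                continue
            v = germline[vdj.v_call]
            pct, _ = ann.compute_shm(vdj.v_alignment, v, r.nt)
            # count truth mutations inside the aligned V span (transcript
            # coordinates equal germline V coordinates upstream of the
            # junction); terminal mismatches clipped by local alignment
            # are outside that span by construction
            r0, r1_ = vdj.v_alignment.reference_span
            truth_v_muts = sum(1 for pos, _o, _n in cell.shm_positions
                               if r0 <= pos < r1_)
            expected = 100.0 * truth_v_muts / vdj.v_alignment.n_columns
            if len(vdj.v_alignment.blocks) == 1:
                # gapless alignment: mismatches are exactly the mutations
                assert pct == pytest.approx(expected)
                checked += 1
            else:
                # clustered adjacent mutations can admit an equal-scoring
                # gapped explanation with fewer mismatches
                assert pct <= expected + 1e-9
        assert checked >= 25


class TestNumbering:
    def test_identity_numbering_matches_germline(self, toy_germline):
        v = next(g for g in toy_germline if g.segment_kind == "V")
        j = next(g for g in toy_germline if g.segment_kind == "J"
                 and g.chain == v.chain)
        rec = _rec(v.ungapped_nt + j.ungapped_nt)
        vdj = ann.assign_vdj(rec, toy_germline, chain=v.chain)
        numbering = ann.number_positions(rec.nt, v, vdj.v_alignment, "IMGT")
        germ = ann._germline_residues(v)
        assert {k: v_ for k, v_ in numbering.items() if float(k) <= 104} == germ

    def test_cdr3_13mer_has_no_insertion_codes(self):
        labels = cdr3_labels(13)
        assert labels == [str(p) for p in range(105, 118)]

    def test_cdr3_symmetric_fill_short_and_long(self):
        assert cdr3_labels(4) == ["105", "106", "116", "117"]
        assert cdr3_labels(5) == ["105", "106", "107", "116", "117"]
        assert "111.1" in cdr3_labels(14)

    def test_kabat_lookup_through_table(self, toy_germline):
        v = next(g for g in toy_germline if g.segment_kind == "V"
                 and g.chain == "heavy")
        j = next(g for g in toy_germline if g.segment_kind == "J"
                 and g.chain == "heavy")
        rec = _rec(v.ungapped_nt + j.ungapped_nt)
        vdj = ann.assign_vdj(rec, toy_germline, chain="heavy")
        kabat = ann.number_positions(rec.nt, v, vdj.v_alignment, "Kabat")
        from abrep.numbering import scheme_table
        table = scheme_table(v.gene_name, "Kabat")
        inverse = {sl: il for il, sl in table.items()}
        imgt = ann.number_positions(rec.nt, v, vdj.v_alignment, "IMGT")
        assert kabat["52"] == imgt[inverse["52"]]

    def test_unsupported_scheme_rejected(self, toy_germline):
        v = next(g for g in toy_germline if g.segment_kind == "V")
        rec = _rec(v.ungapped_nt)
        vdj = ann.assign_vdj(rec, [v], chain=v.chain)
        with pytest.raises(ValueError, match="scheme"):
            ann.number_positions(rec.nt, v, vdj.v_alignment, "Martin")
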