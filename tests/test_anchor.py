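import numpy as np
import pytest

from ssrkit.anchor import (AnchorQuery, anchor_loci, builtin_align,
                           extract_flanks, reciprocal_unique_pairs)
from ssrkit.io import AlignmentHit, SequenceRecord
from ssrkit.miner import SSRLocus, find_perfect_ssrs
from ssrkit.io import GenomicInterval


def make_locus(seq_id, start, end, motif="AT"):
    return SSRLocus(interval=GenomicInterval(seq_id, start, end),
                    motif=motif, canonical_family="AT",
                    repeat_count=(end - start + 1) // len(motif),
                    ssr_class="I")


def random_genome(rng, length, seq_id="c1"):
    return SequenceRecord(seq_id,
                          "".join(rng.choice(list("ACGT"), size=length)))


class TestExtractFlanks:
    def test_window_arithmetic(self):
        rng = np.random.default_rng(0)
        rec = random_genome(rng, 2000)
        genome = {rec.id: rec}
        locus = make_locus("c1", 1000, 1019)
        q = extract_flanks(locus, genome, 250)
        assert q.window_start == 750
        assert q.window_end == 1269
        assert len(q.window_seq) == 520
        assert q.window_seq[q.mask_start - 1 : q.mask_end] == "N" * 20
        assert q.window_seq[: q.mask_start - 1] == rec.seq[749:999]

    def test_left_flank_clamped(self):
        rng = np.random.default_rng(1)
        rec = random_genome(rng, 2000)
        locus = make_locus("c1", 100, 119)
        q = extract_flanks(locus, {rec.id: rec}, 250)
        assert q.window_start == 1 and q.mask_start == 100

    def test_mask_suppresses_ssr_redetection(self):
        rng = np.random.default_rng(2)
        left = "".join(rng.choice(list("ACGT"), size=300))
        right = "".join(rng.choice(list("ACGT"), size=300))
        rec = SequenceRecord("c1", left + "AT" * 10 + right)
        locus = find_perfect_ssrs(rec)[0]
        q = extract_flanks(locus, {rec.id: rec}, 250)
        window_rec = SequenceRecord("w", q.window_seq)
        for call in find_perfect_ssrs(window_rec):
            assert not (call.interval.start <= q.mask_end
                        and call.interval.end >= q.mask_start)

    def test_unknown_sequence_rejected(self):
        with pytest.raises(ValueError):
            extract_flanks(make_locus("nope", 500, 519), {}, 250)


class TestBuiltinAlign:
    def _query(self, seq, qid="A|c1:1-10"):
        locus = make_locus("c1", 1, 10)
        return AnchorQuery(query_id=qid, genome="A", locus=locus,
                           window_seq=seq, window_start=1, mask_start=1,
                           mask_end=1)

    def test_verbatim_copy_single_hit(self):
        rng = np.random.default_rng(3)
        insert = "".join(rng.choice(list("ACGT"), size=600))
        subject = random_genome(rng, 500, "s1")
        subject = SequenceRecord("s1", subject.seq + insert
                                 + random_genome(rng, 500, "x").seq)
        hits = builtin_align([self._query(insert)], {"s1": subject})
        plus = [h for h in hits if h.s_start <= h.s_end]
        assert len(plus) == 1
        (hit,) = plus
        assert hit.percent_identity == 100.0
        assert hit.align_length == 600
        assert hit.evalue == 0.0  # surrogate underflows for a full window
        assert (hit.s_start, hit.s_end) == (501, 1100)

    def test_absent_query_no_hits(self):
        rng = np.random.default_rng(4)
        subject = random_genome(rng, 1000, "s1")
        query = "".join(np.random.default_rng(99).choice(list("ACGT"),
                                                         size=200))
        hits = builtin_align([self._query(query)], {"s1": subject})
        assert hits == []

    def test_planted_duplication_preserves_ambiguity(self):
        rng = np.random.default_rng(5)
        insert = "".join(rng.choice(list("ACGT"), size=150))
        spacer = "".join(rng.choice(list("ACGT"), size=400))
        subject = SequenceRecord("s1", spacer + insert + spacer[::-1]
                                 + insert + spacer)
        hits = builtin_align([self._query(insert)], {"s1": subject})
        plus = [h for h in hits if h.s_start <= h.s_end]
        assert len(plus) == 2

    def test_minus_strand_hit_reported_inverted(self):
        from ssrkit.miner import reverse_complement
        rng = np.random.default_rng(6)
        insert = "".join(rng.choice(list("ACGT"), size=120))
        pad = "".join(rng.choice(list("ACGT"), size=300))
        subject = SequenceRecord("s1",
                                 pad + reverse_complement(insert) + pad[:250])
        hits = builtin_align([self._query(insert)], {"s1": subject})
        minus = [h for h in hits if h.s_start > h.s_end]
        assert minus and minus[0].align_length == 120


def make_hit(qid, sid, evalue, s_start=1, s_end=500):
    return AlignmentHit(query_id=qid, subject_id=sid, percent_identity=100.0,
                        align_length=abs(s_end - s_start) + 1, mismatches=0,
                        gap_opens=0, q_start=1, q_end=500, s_start=s_start,
                        s_end=s_end, evalue=evalue, bit_score=900.0)


def make_query(qid, genome, seq_id, start, end):
    locus = make_locus(seq_id, start, end)
    return AnchorQuery(query_id=qid, genome=genome, locus=locus,
                       window_seq="N" * 520, window_start=max(1, start - 250),
                       mask_start=251, mask_end=270)


class TestReciprocalUniquePairs:
    def setup_method(self):
        self.qa = [make_query("A|a1:1000-1019", "A", "a1", 1000, 1019)]
        self.qb = [make_query("B|b1:2000-2019", "B", "b1", 2000, 2019),
                   make_query("B|b1:9000-9019", "B", "b1", 9000, 9019)]

    def test_mutual_single_hits_pair(self):
        ab = [make_hit("A|a1:1000-1019", "b1", 0.0, 1750, 2269)]
        ba = [make_hit("B|b1:2000-2019", "a1", 0.0, 750, 1269)]
        pairs = reciprocal_unique_pairs(ab, ba, self.qa, self.qb)
        assert len(pairs) == 1 and pairs[0].reciprocal
        assert pairs[0].locus_a.interval.start == 1000
        assert pairs[0].locus_b.interval.start == 2000

    def test_two_passing_targets_excluded(self):
        ab = [make_hit("A|a1:1000-1019", "b1", 0.0, 1750, 2269),
              make_hit("A|a1:1000-1019", "b1", 1e-60, 8750, 9269)]
        ba = [make_hit("B|b1:2000-2019", "a1", 0.0, 750, 1269)]
        assert reciprocal_unique_pairs(ab, ba, self.qa, self.qb) == []

    def test_split_flank_hits_on_same_window_still_unique(self):
        ab = [make_hit("A|a1:1000-1019", "b1", 1e-80, 1750, 1999),
              make_hit("A|a1:1000-1019", "b1", 1e-80, 2020, 2269)]
        ba = [make_hit("B|b1:2000-2019", "a1", 0.0, 750, 1269)]
        pairs = reciprocal_unique_pairs(ab, ba, self.qa, self.qb)
        assert len(pairs) == 1

    def test_reverse_direction_above_threshold_excluded(self):
        ab = [make_hit("A|a1:1000-1019", "b1", 1e-60, 1750, 2269)]
        ba = [make_hit("B|b1:2000-2019", "a1", 1e-30, 750, 1269)]
        assert reciprocal_unique_pairs(ab, ba, self.qa, self.qb,
                                       evalue_max=1e-40) == []

    def test_unknown_query_id_rejected(self):
        ab = [make_hit("A|ghost:1-20", "b1", 0.0)]
        with pytest.raises(ValueError):
            reciprocal_unique_pairs(ab, [], self.qa, self.qb)

    def test_tightening_threshold_never_adds_pairs(self):
        ab = [make_hit("A|a1:1000-1019", "b1", 1e-50, 1750, 2269)]
        ba = [make_hit("B|b1:2000-2019", "a1", 1e-45, 750, 1269)]
        loose = reciprocal_unique_pairs(ab, ba, self.qa, self.qb, 1e-40)
        tight = reciprocal_unique_pairs(ab, ba, self.qa, self.qb, 1e-60)
        assert len(tight) <= len(loose)


class TestEndToEnd:
    def test_symmetry_and_injectivity(self, sim_pair):
        ga = {r.id: r for r in sim_pair.records_a}
        gb = {r.id: r for r in sim_pair.records_b}
        sa = [s for r in sim_pair.records_a for s in find_perfect_ssrs(r)]
        sb = [s for r in sim_pair.records_b for s in find_perfect_ssrs(r)]
        fwd = anchor_loci(sa, ga, sb, gb)
        rev = anchor_loci(sb, gb, sa, ga)
        fwd_set = {(p.locus_a.locus_id, p.locus_b.locus_id) for p in fwd}
        rev_set = {(p.locus_b.locus_id, p.locus_a.locus_id) for p in rev}
        assert fwd_set == rev_set
        assert len({a for a, _ in fwd_set}) == len(fwd_set)
        assert len({b for _, b in fwd_set}) == len(fwd_set)

    def test_all_planted_orthologs_recovered(self, sim_pair):
        ga = {r.id: r for r in sim_pair.records_a}
        gb = {r.id: r for r in sim_pair.records_b}
        sa = [s for r in sim_pair.records_a for s in find_perfect_ssrs(r)]
        sb = [s for r in sim_pair.records_b for s in find_perfect_ssrs(r)]
        pairs = anchor_loci(sa, ga, sb, gb)
        assert len(pairs) == len(sim_pair.truth)
        truth = sim_pair.truth.set_index("locus_id")
        for p in pairs:
            row = truth.loc[p.locus_a.locus_id]
            assert p.locus_b.interval.start == row.start_b
            assert p.locus_b.interval.end == row.end_b
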