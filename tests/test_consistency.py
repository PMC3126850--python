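import numpy as np
import pytest

from spinkit.align import batch_align, find_hsps
from spinkit.consistency import (consistency_report, eci_score, ici_score,
                                 select_nonoverlapping_hsps)
from spinkit.records import HSP, Assembly, LayoutEntry, SequenceRecord

from conftest import random_dna


def make_hsp(qstart, qend, score, pid=100.0, qid="q", sid="s", length=None):
    length = length if length is not None else qend - qstart
    return HSP(qid, sid, pid, length, score, 1e-20,
               qstart, qend, qstart, qstart + length)


class TestOverlapResolution:
    def test_disjoint_hsps_all_kept(self):
        hsps = [make_hsp(0, 100, 90), make_hsp(120, 200, 70)]
        assert len(select_nonoverlapping_hsps(hsps)) == 2

    def test_greedy_keeps_only_the_higher_scoring_overlap(self):
        a = make_hsp(0, 100, 50)
        b = make_hsp(50, 150, 60)
        kept = select_nonoverlapping_hsps([a, b])
        assert kept == [b]

    def test_mixed_pairs_rejected(self):
        with pytest.raises(ValueError, match="pairs"):
            select_nonoverlapping_hsps([make_hsp(0, 10, 5, qid="q1"),
                                        make_hsp(0, 10, 5, qid="q2")])

    def test_result_always_pairwise_disjoint(self, rng):
        """Brute-force interval-overlap check over 500 random HSP sets."""
        for _ in range(500):
            n = int(rng.integers(1, 12))
            hsps = []
            for _ in range(n):
                start = int(rng.integers(0, 300))
                length = int(rng.integers(10, 120))
                hsps.append(make_hsp(start, start + length,
                                     int(rng.integers(1, 100))))
            kept = select_nonoverlapping_hsps(hsps)
            for i, a in enumerate(kept):
                for b in kept[i + 1:]:
                    assert a.qend <= b.qstart or b.qend <= a.qstart


class TestIciScore:
    def test_full_length_perfect_mapping_scores_100(self):
        assert ici_score(100, [make_hsp(0, 100, 100, pid=100.0)]) == 100.0

    def test_no_hsps_scores_zero(self):
        assert ici_score(100, []) == 0.0

    def test_sum_formula_on_two_disjoint_hsps(self):
        # 100 * (120*0.95 + 60*0.90) / 200 = 84.0
        hsps = [make_hsp(0, 120, 110, pid=95.0),
                make_hsp(130, 190, 50, pid=90.0)]
        assert ici_score(200, hsps) == pytest.approx(84.0)

    def test_nonpositive_read_length_rejected(self):
        with pytest.raises(ValueError):
            ici_score(0, [])

    def test_score_clamped_at_100_under_gap_inflation(self):
        # alignment length > read span through gap columns
        h = HSP("q", "s", 100.0, 110, 100, 1e-30, 0, 100, 0, 110)
        assert ici_score(100, [h]) == 100.0

    def test_always_within_bounds(self, rng):
        for _ in range(200):
            read_len = int(rng.integers(50, 400))
            hsps = []
            for _ in range(int(rng.integers(0, 5))):
                start = int(rng.integers(0, read_len - 10))
                end = int(rng.integers(start + 10, read_len + 1))
                hsps.append(make_hsp(start, end, int(rng.integers(1, 200)),
                                     pid=float(rng.uniform(0, 100))))
            assert 0.0 <= ici_score(read_len, hsps) <= 100.0


class TestEciScore:
    def test_identical_copy_scores_100(self, rng):
        seq = random_dna(rng, 500)
        a, b = SequenceRecord("c1", seq), SequenceRecord("c2", seq)
        hsps = find_hsps(a, b)
        assert eci_score(500, hsps) == 100.0

    def test_no_hsps_scores_zero(self):
        assert eci_score(500, []) == 0.0

    def test_partial_overlap_formula(self):
        # 100 * 250 * 0.8 / 500 = 40.0
        hsps = [make_hsp(0, 250, 150, pid=80.0, qid="c1", sid="c2")]
        assert eci_score(500, hsps) == pytest.approx(40.0)

    def test_self_pair_rejected(self):
        with pytest.raises(ValueError, match="self"):
            eci_score(100, [make_hsp(0, 50, 40, qid="c1", sid="c1")])


def align_assembly(assembly, reads):
    laid = {e.read_id for e in assembly.layout}
    assembled = [r for r in reads if r.id in laid]
    read_hsps = batch_align(assembled, assembly.contigs,
                            mode="reads_to_contigs", layout=assembly)
    contig_hsps = batch_align(assembly.contigs, assembly.contigs,
                              mode="all_vs_all")
    lengths = {r.id: len(r.sequence) for r in assembled}
    return read_hsps, contig_hsps, lengths


class TestConsistencyReport:
    def test_error_free_truth_assembly_has_perfect_ici(self):
        from spinkit.simulate import (ReadSimParams, TranscriptomeModel,
                                      build_truth_assembly,
                                      generate_transcriptome, simulate_reads)

        transcripts, truth = generate_transcriptome(
            TranscriptomeModel(n_families=6, seed=11, spidroin_fraction=0.0,
                               paralogs_per_family=1.0))
        reads, truth = simulate_reads(
            transcripts, ReadSimParams(mean_coverage=6, substitution_rate=0.0,
                                       homopolymer_indel_rate=0.0, seed=12))
        assembly = build_truth_assembly(transcripts, reads, truth)
        read_hsps, contig_hsps, lengths = align_assembly(assembly, reads)
        rep = consistency_report(assembly, read_hsps, contig_hsps,
                                 read_lengths=lengths)
        assert rep.average_ici == pytest.approx(100.0)
        assert rep.no_hit_reads == []

    def test_duplicated_contigs_are_flagged_as_one_unordered_pair(self, rng):
        seq = random_dna(rng, 400)
        other = random_dna(rng, 400)
        contigs = [SequenceRecord("dupA", seq), SequenceRecord("dupB", seq),
                   SequenceRecord("other", other)]
        layout = [LayoutEntry(c.id, f"{c.id}_r{i}", "+", 0)
                  for c in contigs for i in range(2)]
        reads = [SequenceRecord(e.read_id,
                                dict((c.id, c.sequence) for c in contigs)[e.contig_id])
                 for e in layout]
        assembly = Assembly(contigs=contigs, layout=layout)
        read_hsps, contig_hsps, lengths = align_assembly(assembly, reads)
        rep = consistency_report(assembly, read_hsps, contig_hsps,
                                 flag_threshold=75.0, read_lengths=lengths)
        assert [(a, b) for a, b, _ in rep.flagged_pairs] == [("dupA", "dupB")]
        assert rep.flagged_pairs[0][2] == pytest.approx(100.0)

    def test_planted_foreign_read_lands_in_no_hit_list(self, rng):
        seq = random_dna(rng, 400)
        contigs = [SequenceRecord("c1", seq)]
        layout = [LayoutEntry("c1", "good", "+", 0),
                  LayoutEntry("c1", "alien", "+", 0)]
        reads = [SequenceRecord("good", seq[:150]),
                 SequenceRecord("alien", random_dna(rng, 150))]
        assembly = Assembly(contigs=contigs, layout=layout)
        read_hsps, contig_hsps, lengths = align_assembly(assembly, reads)
        rep = consistency_report(assembly, read_hsps, contig_hsps,
                                 read_lengths=lengths)
        assert rep.no_hit_reads == ["alien"]
        ici = {s.query_id: s.score for s in rep.per_read_ici}
        assert ici["alien"] == 0.0
        assert ici["good"] == pytest.approx(100.0)

    def test_hsp_for_unassembled_read_rejected(self):
        assembly = Assembly(contigs=[], layout=[])
        with pytest.raises(ValueError, match="ghost"):
            consistency_report(assembly, [make_hsp(0, 50, 40, qid="ghost")], [])

    def test_flag_set_invariant_to_contig_order(self, rng):
        seq = random_dna(rng, 300)
        contigs = [SequenceRecord("x", seq), SequenceRecord("y", seq),
                   SequenceRecord("z", random_dna(rng, 300))]
        layout = [LayoutEntry(c.id, f"{c.id}_r{i}", "+", 0)
                  for c in contigs for i in range(2)]
        reads = [SequenceRecord(e.read_id, next(c.sequence for c in contigs
                                                if c.id == e.contig_id)[:120])
                 for e in layout]
        flags = []
        for order in ([0, 1, 2], [2, 1, 0], [1, 2, 0]):
            asm = Assembly(contigs=[contigs[i] for i in order],
                           layout=layout, singlets=[])
            rh, ch, lens = align_assembly(asm, reads)
            rep = consistency_report(asm, rh, ch, read_lengths=lens)
            flags.append({(a, b) for a, b, _ in rep.flagged_pairs})
        assert flags[0] == flags[1] == flags[2] == {("x", "y")}

    def test_mean_ici_strictly_decreases_with_substitution_rate(self):
        """Mean ICI over a simulated assembly drops as the read error rate
        rises (smaller cohort than the headline check, same shape)."""
        from spinkit.simulate import (ReadSimParams, TranscriptomeModel,
                                      build_truth_assembly,
                                      generate_transcriptome, simulate_reads)

        transcripts, _ = generate_transcriptome(
            TranscriptomeModel(n_families=8, seed=21, spidroin_fraction=0.0,
                               paralogs_per_family=1.0))
        means = []
        for rate in (0.0, 0.03, 0.10):
            reads, truth = simulate_reads(
                transcripts, ReadSimParams(mean_coverage=5,
                                           substitution_rate=rate,
                                           homopolymer_indel_rate=0.0, seed=22))
            assembly = build_truth_assembly(transcripts, reads, truth)
            rh, ch, lens = align_assembly(assembly, reads)
            rep = consistency_report(assembly, rh, ch, read_lengths=lens)
            means.append(rep.average_ici)
        assert means[0] > means[1] > means[2]
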