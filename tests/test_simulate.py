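import numpy as np
import pytest

from spinkit.io import read_sequences, write_sequences
from spinkit.simulate import (ReadSimParams, TranscriptomeModel,
                              build_truth_assembly, generate_transcriptome,
                              kog_annotations_from_truth, simulate_reads,
                              write_fixture_bundle)


class TestGenerateTranscriptome:
    def test_zero_spidroin_fraction_flags_nothing(self):
        _, truth = generate_transcriptome(
            TranscriptomeModel(n_families=10, seed=1, spidroin_fraction=0.0))
        assert not any(t.is_spidroin for t in truth.transcripts.values())

    def test_expansion_spec_sets_exact_copy_numbers(self):
        model = TranscriptomeModel(n_families=8, seed=2,
                                   kog_expansion_spec=[(3, 10, 1)])
        _, truth = generate_transcriptome(model)
        assert truth.families[3] == (10, 1)
        in_a = sum(1 for t in truth.transcripts.values()
                   if t.family == 3 and t.dataset == "A")
        in_b = sum(1 for t in truth.transcripts.values()
                   if t.family == 3 and t.dataset == "B")
        assert (in_a, in_b) == (10, 1)

    def test_same_seed_gives_identical_fasta_bytes(self, tmp_path):
        model = TranscriptomeModel(n_families=6, seed=3, spidroin_fraction=0.3)
        for name in ("one", "two"):
            transcripts, _ = generate_transcriptome(model)
            write_sequences(transcripts, tmp_path / f"{name}.fasta")
        assert (tmp_path / "one.fasta").read_bytes() == \
               (tmp_path / "two.fasta").read_bytes()

    def test_zero_families_rejected(self):
        with pytest.raises(ValueError):
            TranscriptomeModel(n_families=0)

    def test_unspecified_families_are_balanced(self):
        _, truth = generate_transcriptome(
            TranscriptomeModel(n_families=15, seed=4, paralogs_per_family=3.0))
        for a, b in truth.families.values():
            assert a == b >= 1

    def test_within_family_identity_decreases_with_mutation_rate(self):
        """Mean pairwise identity between paralogs drops monotonically over
        five substitution rates (fixed seed)."""
        def family_identity(rate):
            model = TranscriptomeModel(n_families=5, seed=5,
                                       paralogs_per_family=3.0,
                                       per_duplication_substitution_rate=rate,
                                       spidroin_fraction=0.0)
            transcripts, truth = generate_transcriptome(model)
            by_family = {}
            for t in transcripts:
                by_family.setdefault(truth.transcripts[t.id].family, []).append(
                    t.sequence)
            idents = []
            for seqs in by_family.values():
                for i in range(len(seqs)):
                    for j in range(i + 1, len(seqs)):
                        a, b = seqs[i], seqs[j]
                        idents.append(np.mean([x == y for x, y in zip(a, b)]))
            return float(np.mean(idents)) if idents else 1.0

        vals = [family_identity(r) for r in (0.0, 0.01, 0.03, 0.06, 0.12)]
        assert all(x > y for x, y in zip(vals, vals[1:]))


class TestSimulateReads:
    def test_zero_antisense_prob_gives_all_plus_strands(self):
        transcripts, _ = generate_transcriptome(
            TranscriptomeModel(n_families=5, seed=6))
        _, truth = simulate_reads(transcripts,
                                  ReadSimParams(mean_coverage=5, seed=7))
        assert all(rt.strand == "+" for rt in truth.reads.values())

    def test_error_free_plus_reads_are_exact_substrings(self):
        transcripts, _ = generate_transcriptome(
            TranscriptomeModel(n_families=5, seed=8, spidroin_fraction=0.0))
        by_id = {t.id: t.sequence for t in transcripts}
        reads, truth = simulate_reads(
            transcripts, ReadSimParams(mean_coverage=5, substitution_rate=0.0,
                                       homopolymer_indel_rate=0.0, seed=9))
        for r in reads:
            rt = truth.reads[r.id]
            assert r.sequence == by_id[rt.transcript_id][rt.start:rt.start + len(r.sequence)]
            assert rt.n_errors == 0

    def test_antisense_fraction_within_binomial_bound(self):
        transcripts, _ = generate_transcriptome(
            TranscriptomeModel(n_families=30, seed=10, spidroin_fraction=0.0))
        p = 0.3
        n_target = 10_000
        coverage = n_target / len(transcripts)
        _, truth = simulate_reads(transcripts,
                                  ReadSimParams(mean_coverage=coverage,
                                                antisense_prob=p, seed=11))
        n = len(truth.reads)
        frac = sum(rt.strand == "-" for rt in truth.reads.values()) / n
        assert abs(frac - p) <= 3 * (p * (1 - p) / n) ** 0.5

    def test_empty_transcript_list_rejected(self):
        with pytest.raises(ValueError):
            simulate_reads([], ReadSimParams())

    def test_truth_covers_every_read(self):
        transcripts, _ = generate_transcriptome(
            TranscriptomeModel(n_families=6, seed=12))
        reads, truth = simulate_reads(
            transcripts, ReadSimParams(mean_coverage=4,
                                       contaminant_fraction=0.05, seed=13))
        assert {r.id for r in reads} == set(truth.reads)


class TestBuildTruthAssembly:
    def test_read_conservation_and_contig_membership(self, small_bundle):
        transcripts, reads, truth, assembly = small_bundle
        assert len(assembly.layout) + len(assembly.singlets) == len(reads)
        for entry in assembly.layout:
            rt = truth.reads[entry.read_id]
            assert entry.contig_id == f"ctg_{rt.transcript_id}"
            assert entry.strand == rt.strand
            assert entry.offset == rt.start

    def test_transcripts_with_single_read_become_singlets(self):
        transcripts, _ = generate_transcriptome(
            TranscriptomeModel(n_families=10, seed=14, paralogs_per_family=1.0))
        reads, truth = simulate_reads(transcripts,
                                      ReadSimParams(mean_coverage=1.2, seed=15))
        assembly = build_truth_assembly(transcripts, reads, truth)
        per_transcript = {}
        for r in reads:
            tid = truth.reads[r.id].transcript_id
            per_transcript[tid] = per_transcript.get(tid, 0) + 1
        n_single = sum(1 for v in per_transcript.values() if v == 1)
        n_multi = sum(1 for v in per_transcript.values() if v >= 2)
        assert len(assembly.singlets) == n_single
        assert len(assembly.contigs) == n_multi

    def test_contig_consensus_is_the_transcript(self, small_bundle):
        transcripts, reads, truth, assembly = small_bundle
        by_id = {t.id: t.sequence for t in transcripts}
        for contig in assembly.contigs:
            assert contig.sequence == by_id[contig.id.removeprefix("ctg_")]


class TestFixtureBundle:
    def test_bundle_roundtrips_through_disk(self, small_bundle, tmp_path):
        transcripts, reads, truth, assembly = small_bundle
        write_fixture_bundle(tmp_path, transcripts, reads, assembly, truth,
                             TranscriptomeModel(), ReadSimParams())
        back_reads = read_sequences(tmp_path / "reads.fastq", "fastq")
        assert [r.id for r in back_reads] == [r.id for r in reads]
        assert (tmp_path / "params.yaml").exists()
        lines = (tmp_path / "truth_reads.tsv").read_text().splitlines()
        assert len(lines) == len(reads) + 1

    def test_truth_annotations_split_by_dataset(self):
        _, truth = generate_transcriptome(
            TranscriptomeModel(n_families=5, seed=16, paralogs_per_family=2.0))
        ann_a = kog_annotations_from_truth(truth, "A")
        ann_b = kog_annotations_from_truth(truth, "B")
        n_a = sum(1 for t in truth.transcripts.values() if t.dataset == "A")
        n_b = sum(1 for t in truth.transcripts.values() if t.dataset == "B")
        assert (len(ann_a), len(ann_b)) == (n_a, n_b)
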