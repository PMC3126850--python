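"""Synthetic spinning-gland transcriptomes and 454-style reads with ground truth.

The generator emulates the statistical structure the downstream analyses
assume: paralog gene families with controlled copy-number expansion between
two datasets, spidroin-like transcripts built from the silk repeat-motif
grammar, ~250 nt pyrosequencing reads with substitution and
homopolymer-indel errors, a tunable antisense read probability,
low-complexity contaminant reads, and deliberately short reads.  Every
read and transcript is tracked in truth tables, so parameter-recovery and
planted-truth tests need no external data.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import yaml
from Bio.Seq import Seq

from .io import write_layout, write_sequences
from .comparative import KOGAnnotation
from .records import Assembly, LayoutEntry, SequenceRecord, reverse_complement

KOG_CATEGORIES = "JAKLBDYVTMNZWUOCGEFHIPQRS"

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# reverse codon table (standard code), built once
_CODONS_FOR: dict[str, list[str]] = {}
for _b1 in "TCAG":
    for _b2 in "TCAG":
        for _b3 in "TCAG":
            _codon = _b1 + _b2 + _b3
            _aa = str(Seq(_codon).translate())
            if _aa != "*":
                _CODONS_FOR.setdefault(_aa, []).append(_codon)


@dataclass
class TranscriptomeModel:
    """Two-dataset paralog-family transcriptome parameters.

    Paralog counts per family are geometric with the given mean and are
    shared between datasets A and B unless overridden by
    ``kog_expansion_spec`` entries (family_index, copies_in_A, copies_in_B),
    so unspecified families have a copy ratio of exactly 1 and planted
    expansions are unambiguous.
    """

    n_families: int = 40
    paralogs_per_family: float = 2.0
    per_duplication_substitution_rate: float = 0.02
    transcript_length_median: int = 800
    transcript_length_sigma: float = 0.35
    spidroin_fraction: float = 0.05
    kog_expansion_spec: list[tuple[int, int, int]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_families < 1:
            raise ValueError("need at least one gene family")
        if not (0.0 <= self.spidroin_fraction <= 1.0):
            raise ValueError("spidroin_fraction must be a probability")
        if not (0.0 <= self.per_duplication_substitution_rate <= 1.0):
            raise ValueError("substitution rate must be a probability")
        if self.paralogs_per_family < 1.0:
            raise ValueError("mean paralog count must be >= 1")


@dataclass
class ReadSimParams:
    """454-style read simulation parameters.

    Defaults reflect GS-FLX-era titration runs: ~250 nt mean read length,
    ~1% substitutions and homopolymer-length miscalls as the characteristic
    error mode.  ``antisense_prob`` draws a read from the reverse
    complement and marks its truth strand '-'.
    """

    mean_coverage: float = 10.0
    read_length_mean: float = 250.0
    read_length_sd: float = 50.0
    substitution_rate: float = 0.01
    homopolymer_indel_rate: float = 0.01
    antisense_prob: float = 0.0
    contaminant_fraction: float = 0.0
    short_fraction: float = 0.0
    phred_mean: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("substitution_rate", "homopolymer_indel_rate",
                     "antisense_prob", "contaminant_fraction", "short_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be a probability, got {v}")
        if self.mean_coverage <= 0:
            raise ValueError("mean_coverage must be positive")


@dataclass
class TranscriptTruth:
    family: int
    dataset: str  # 'A' or 'B'
    kog_id: str
    kog_category: str
    is_spidroin: bool


@dataclass
class ReadTruth:
    transcript_id: str | None  # None for contaminant reads
    strand: str
    start: int  # leftmost position on the transcript
    n_errors: int


@dataclass
class TruthTables:
    """Complete ground truth: every transcript and read appears exactly once."""

    transcripts: dict[str, TranscriptTruth] = field(default_factory=dict)
    families: dict[int, tuple[int, int]] = field(default_factory=dict)
    reads: dict[str, ReadTruth] = field(default_factory=dict)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode()


def _spidroin_peptide(rng: np.random.Generator, n_repeat_aa: int) -> str:
    """Repeat region from the orbicularian motif grammar."""
    parts: list[str] = []
    total = 0
    ggx_x = "AQYLS"
    gpg_x = "GQY"
    while total < n_repeat_aa:
        kind = rng.integers(0, 4)
        if kind == 0:
            unit = "A" * int(rng.integers(4, 9))
        elif kind == 1:
            unit = "GA" * int(rng.integers(3, 7))
        elif kind == 2:
            unit = "".join("GG" + ggx_x[rng.integers(0, len(ggx_x))]
                           for _ in range(int(rng.integers(2, 5))))
        else:
            unit = "".join("GPG" + "".join(gpg_x[rng.integers(0, len(gpg_x))]
                                           for _ in range(int(rng.integers(1, 3))))
                           for _ in range(int(rng.integers(2, 4))))
        parts.append(unit)
        total += len(unit)
    return "".join(parts)[:n_repeat_aa]


def _reverse_translate(rng: np.random.Generator, peptide: str) -> str:
    return "".join(
        _CODONS_FOR[aa][rng.integers(0, len(_CODONS_FOR[aa]))] for aa in peptide
    )


def _mutate(rng: np.random.Generator, sequence: str, rate: float) -> str:
    if rate <= 0:
        return sequence
    arr = np.frombuffer(sequence.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(arr.size) < rate)[0]
    for i in hits:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = choices[rng.integers(0, len(choices))]
    return arr.tobytes().decode()


def generate_transcriptome(model: TranscriptomeModel,
                           ) -> tuple[list[SequenceRecord], TruthTables]:
    """Two-dataset paralog transcriptome with per-transcript ground truth.

    Each family starts from one base transcript; paralog copies are
    mutated at the per-duplication substitution rate.  Spidroin families
    concatenate motif-grammar repeat units plus a 100-aa non-repetitive
    C-terminal coding block.  Deterministic under ``model.seed``.
    """
    rng = np.random.default_rng(model.seed)
    expansion = {f: (a, b) for f, a, b in model.kog_expansion_spec}
    transcripts: list[SequenceRecord] = []
    truth = TruthTables()

    for fam in range(model.n_families):
        is_spidroin = bool(rng.random() < model.spidroin_fraction)
        if is_spidroin:
            n_repeat = int(rng.integers(150, 300))
            peptide = _spidroin_peptide(rng, n_repeat)
            cterm = "".join(
                "ACDEFGHIKLMNPQRSTVWY"[rng.integers(0, 20)] for _ in range(100)
            )
            base = "ATG" + _reverse_translate(rng, peptide + cterm) + "TAA"
        else:
            length = int(np.exp(rng.normal(np.log(model.transcript_length_median),
                                           model.transcript_length_sigma)))
            base = _random_seq(rng, max(length, 150))
        kog_id = f"KOG{fam:04d}"
        category = KOG_CATEGORIES[fam % len(KOG_CATEGORIES)]
        if fam in expansion:
            copies_a, copies_b = expansion[fam]
        else:
            copies_a = int(rng.geometric(1.0 / model.paralogs_per_family))
            copies_b = copies_a
        truth.families[fam] = (copies_a, copies_b)
        for dataset, n_copies in (("A", copies_a), ("B", copies_b)):
            for c in range(n_copies):
                tid = f"F{fam:03d}_{dataset}_c{c:02d}"
                seq = _mutate(rng, base, model.per_duplication_substitution_rate)
                transcripts.append(SequenceRecord(tid, seq))
                truth.transcripts[tid] = TranscriptTruth(
                    fam, dataset, kog_id, category, is_spidroin)
    if not transcripts:
        raise ValueError("model produced no transcripts")
    return transcripts, truth


def _apply_homopolymer_indels(rng: np.random.Generator, seq: str,
                              rate: float) -> tuple[str, int]:
    """Lengthen or shorten homopolymer runs >= 3 by one base at the given rate."""
    if rate <= 0:
        return seq, 0
    out: list[str] = []
    n_err = 0
    i = 0
    n = len(seq)
    while i < n:
        j = i
        while j < n and seq[j] == seq[i]:
            j += 1
        run = seq[i:j]
        if j - i >= 3 and rng.random() < rate:
            n_err += 1
            if rng.random() < 0.5:
                run = run + seq[i]
            else:
                run = run[:-1]
        out.append(run)
        i = j
    return "".join(out), n_err


def simulate_reads(transcripts: list[SequenceRecord], params: ReadSimParams,
                   truth: TruthTables | None = None,
                   ) -> tuple[list[SequenceRecord], TruthTables]:
    """454-style reads drawn uniformly along transcripts, with ground truth.

    Read counts per transcript are Poisson(mean_coverage); lengths are
    normal, truncated at 40 nt and at the transcript length.  Antisense
    reads are reverse-complemented with truth strand '-'.  Substitutions
    are i.i.d. per base; homopolymer runs >= 3 gain or lose one base at the
    homopolymer-indel rate.  Contaminants are pure homopolymer or dimer
    repeats; short reads are forced below 70 nt.  Truth rows are appended
    to ``truth`` when given, else to a fresh table.
    """
    if not transcripts:
        raise ValueError("simulate_reads requires at least one transcript")
    rng = np.random.default_rng(params.seed)
    truth = truth if truth is not None else TruthTables()
    reads: list[SequenceRecord] = []
    counter = 0

    for tr in transcripts:
        n_reads = int(rng.poisson(params.mean_coverage))
        for _ in range(n_reads):
            if params.short_fraction > 0 and rng.random() < params.short_fraction:
                length = int(rng.integers(40, 70))
            else:
                length = int(round(rng.normal(params.read_length_mean,
                                              params.read_length_sd)))
                length = max(length, 40)
            length = min(length, len(tr.sequence))
            start = int(rng.integers(0, len(tr.sequence) - length + 1))
            fragment = tr.sequence[start:start + length]
            n_err = 0
            mutated = _mutate(rng, fragment, params.substitution_rate)
            n_err += sum(1 for a, b in zip(fragment, mutated) if a != b)
            mutated, indels = _apply_homopolymer_indels(
                rng, mutated, params.homopolymer_indel_rate)
            n_err += indels
            strand = "+"
            if params.antisense_prob > 0 and rng.random() < params.antisense_prob:
                strand = "-"
                mutated = reverse_complement(mutated)
            rid = f"r{counter:06d}"
            counter += 1
            reads.append(SequenceRecord(
                rid, mutated, qualities=[params.phred_mean] * len(mutated)))
            truth.reads[rid] = ReadTruth(tr.id, strand, start, n_err)

    if params.contaminant_fraction > 0:
        n_real = len(reads)
        f = params.contaminant_fraction
        n_cont = int(round(f / (1.0 - f) * n_real)) if f < 1.0 else n_real
        for _ in range(n_cont):
            unit = (_random_seq(rng, 1) if rng.random() < 0.5
                    else _random_seq(rng, 2))
            length = max(int(round(rng.normal(params.read_length_mean,
                                              params.read_length_sd))), 40)
            seq = (unit * (length // len(unit) + 1))[:length]
            rid = f"r{counter:06d}"
            counter += 1
            reads.append(SequenceRecord(
                rid, seq, qualities=[params.phred_mean] * len(seq)))
            truth.reads[rid] = ReadTruth(None, "+", 0, 0)
    return reads, truth


def build_truth_assembly(transcripts: list[SequenceRecord],
                         reads: list[SequenceRecord],
                         truth: TruthTables) -> Assembly:
    """Idealized assembly from the truth tables.

    Each transcript with >= 2 reads becomes one contig whose consensus is
    the transcript sequence; layout strands and offsets are the truth
    values.  A transcript with exactly one read contributes that read as a
    singlet.  Contaminant reads (no truth transcript) join neither.
    """
    for r in reads:
        if r.id not in truth.reads:
            raise ValueError(f"read {r.id!r} missing from truth tables")
    by_transcript: dict[str, list[SequenceRecord]] = {}
    for r in reads:
        tid = truth.reads[r.id].transcript_id
        if tid is not None:
            by_transcript.setdefault(tid, []).append(r)

    contigs: list[SequenceRecord] = []
    layout: list[LayoutEntry] = []
    singlets: list[SequenceRecord] = []
    for tr in transcripts:
        assigned = by_transcript.get(tr.id, [])
        if len(assigned) >= 2:
            cid = f"ctg_{tr.id}"
            contigs.append(SequenceRecord(cid, tr.sequence))
            for r in assigned:
                rt = truth.reads[r.id]
                layout.append(LayoutEntry(cid, r.id, rt.strand, rt.start))
        elif len(assigned) == 1:
            singlets.append(assigned[0])
    return Assembly(contigs=contigs, layout=layout, singlets=singlets)


def kog_annotations_from_truth(truth: TruthTables, dataset: str,
                               ) -> list[KOGAnnotation]:
    """Perfect per-transcript KOG annotations for one dataset, from truth."""
    out = []
    for tid, info in sorted(truth.transcripts.items()):
        if info.dataset == dataset:
            out.append(KOGAnnotation(tid, info.kog_id, info.kog_category,
                                     1e-50, 1.0))
    return out


def write_fixture_bundle(outdir: str | os.PathLike,
                         transcripts: list[SequenceRecord],
                         reads: list[SequenceRecord],
                         assembly: Assembly,
                         truth: TruthTables,
                         model: TranscriptomeModel | None = None,
                         params: ReadSimParams | None = None) -> None:
    """Write the on-disk fixture bundle (FASTA/FASTQ/TSV plus a config echo)."""
    outdir = str(outdir)
    os.makedirs(outdir, exist_ok=True)
    write_sequences(transcripts, os.path.join(outdir, "transcripts.fasta"))
    write_sequences(reads, os.path.join(outdir, "reads.fastq"), "fastq")
    write_sequences(assembly.contigs, os.path.join(outdir, "contigs.fasta"))
    write_sequences(assembly.singlets, os.path.join(outdir, "singlets.fasta"))
    write_layout(assembly.layout, os.path.join(outdir, "layout.tsv"))
    with open(os.path.join(outdir, "truth_reads.tsv"), "w") as fh:
        fh.write("read_id\ttranscript_id\tstrand\tstart\tn_errors\n")
        for rid, rt in sorted(truth.reads.items()):
            fh.write(f"{rid}\t{rt.transcript_id or '-'}\t{rt.strand}\t"
                     f"{rt.start}\t{rt.n_errors}\n")
    with open(os.path.join(outdir, "truth_transcripts.tsv"), "w") as fh:
        fh.write("transcript_id\tfamily\tdataset\tkog_id\tkog_category\tis_spidroin\n")
        for tid, tt in sorted(truth.transcripts.items()):
            fh.write(f"{tid}\t{tt.family}\t{tt.dataset}\t{tt.kog_id}\t"
                     f"{tt.kog_category}\t{int(tt.is_spidroin)}\n")
    with open(os.path.join(outdir, "truth_families.tsv"), "w") as fh:
        fh.write("family\tcopies_a\tcopies_b\n")
        for fam, (a, b) in sorted(truth.families.items()):
            fh.write(f"{fam}\t{a}\t{b}\n")
    config: dict = {}
    if model is not None:
        config["transcriptome"] = {
            k: v for k, v in vars(model).items() if not k.startswith("_")
        }
    if params is not None:
        config["reads"] = {
            k: v for k, v in vars(params).items() if not k.startswith("_")
        }
    with open(os.path.join(outdir, "params.yaml"), "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
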