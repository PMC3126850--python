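"""Core value types shared across the toolkit.

Coordinates are 0-based half-open everywhere in memory; on-disk dialects
(BLAST tabular, ACE) keep their native 1-based inclusive conventions and are
converted at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field


NUCLEOTIDES = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(sequence: str) -> str:
    """Reverse complement of a nucleotide string (N self-pairs)."""
    return sequence.translate(_COMPLEMENT)[::-1]


@dataclass
class SequenceRecord:
    """One read, transcript or contig consensus.

    Parameters
    ----------
    id : str
        Unique token within a file or record set.
    sequence : str
        Uppercase nucleotide (``ACGTN``) or amino-acid string; never empty.
    description : str
        Free text after the id on the FASTA/FASTQ header line.
    qualities : list of int, optional
        Per-base Phred scores; when present, same length as ``sequence``.
    """

    id: str
    sequence: str
    description: str = ""
    qualities: list[int] | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record id must be non-empty")
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: sequence must be non-empty")
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise ValueError(
                f"record {self.id!r}: {len(self.qualities)} quality values for "
                f"{len(self.sequence)} bases"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class LayoutEntry:
    """Placement of one read on one contig consensus."""

    contig_id: str
    read_id: str
    strand: str  # '+' or '-'
    offset: int  # 0-based start of the read on the consensus

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(
                f"layout entry {self.contig_id}/{self.read_id}: "
                f"strand must be '+' or '-', got {self.strand!r}"
            )
        if self.offset < 0:
            raise ValueError(
                f"layout entry {self.contig_id}/{self.read_id}: negative offset"
            )


@dataclass
class Assembly:
    """Contig consensi plus the read layout and the unassembled singlets.

    Unigenes are the union of contigs and singlets.  Invariants: every layout
    entry names a known contig, every contig carries at least two reads, and
    no read is both laid out and a singlet.
    """

    contigs: list[SequenceRecord]
    layout: list[LayoutEntry]
    singlets: list[SequenceRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        contig_ids = {c.id for c in self.contigs}
        per_contig: dict[str, int] = {}
        seen: set[tuple[str, str]] = set()
        for entry in self.layout:
            if entry.contig_id not in contig_ids:
                raise ValueError(
                    f"layout references unknown contig {entry.contig_id!r}"
                )
            key = (entry.contig_id, entry.read_id)
            if key in seen:
                raise ValueError(
                    f"duplicate layout entry for read {entry.read_id!r} "
                    f"on contig {entry.contig_id!r}"
                )
            seen.add(key)
            per_contig[entry.contig_id] = per_contig.get(entry.contig_id, 0) + 1
        for cid in contig_ids:
            if per_contig.get(cid, 0) < 2:
                raise ValueError(f"contig {cid!r} has fewer than 2 assembled reads")
        laid_out = {e.read_id for e in self.layout}
        for s in self.singlets:
            if s.id in laid_out:
                raise ValueError(f"read {s.id!r} is both assembled and a singlet")

    @property
    def unigene_count(self) -> int:
        return len(self.contigs) + len(self.singlets)

    def contig_by_id(self, contig_id: str) -> SequenceRecord:
        for c in self.contigs:
            if c.id == contig_id:
                return c
        raise KeyError(contig_id)

    def layout_by_contig(self) -> dict[str, list[LayoutEntry]]:
        grouped: dict[str, list[LayoutEntry]] = {}
        for entry in self.layout:
            grouped.setdefault(entry.contig_id, []).append(entry)
        return grouped


@dataclass
class HSP:
    """One local-alignment high-scoring pair.

    ``percent_identity`` is on the 0-100 scale and counts gap columns in the
    denominator.  Query and subject intervals are 0-based half-open with
    ``start < end`` on both axes; a minus-strand match is carried in
    ``strand``, never as swapped subject coordinates.
    """

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    score: int
    e_value: float
    qstart: int
    qend: int
    sstart: int
    send: int
    strand: str = "+"
    mismatches: int = 0
    gap_opens: int = 0
    bit_score: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.percent_identity <= 100.0):
            raise ValueError(
                f"HSP {self.query_id}/{self.subject_id}: percent identity "
                f"{self.percent_identity} outside [0, 100]"
            )
        if self.alignment_length < 1:
            raise ValueError("HSP alignment length must be >= 1")
        if self.qstart >= self.qend or self.sstart >= self.send:
            raise ValueError("HSP intervals must be non-empty with start < end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"HSP strand must be '+' or '-', got {self.strand!r}")
        if self.e_value <= 0:
            raise ValueError("HSP e-value must be positive")
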