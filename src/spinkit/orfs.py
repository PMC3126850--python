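"""Six-frame open-reading-frame scanning.

The default convention is stop-to-stop: an ORF is a maximal stop-free codon
run in one of the six frames, with sequence ends acting as boundaries
(getorf-style).  An ATG-initiated mode is available.  Coordinates are
0-based half-open on the forward strand regardless of frame.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq

from .records import SequenceRecord, reverse_complement

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


@dataclass
class ORF:
    sequence_id: str
    frame: int  # +1,+2,+3 forward; -1,-2,-3 reverse
    start: int  # forward-strand coordinates, 0-based half-open
    end: int
    length_nt: int
    peptide: str

    def __post_init__(self) -> None:
        if self.length_nt != self.end - self.start:
            raise ValueError("ORF length_nt must equal end - start")
        if self.length_nt % 3 != 0:
            raise ValueError("ORF length must be a multiple of 3")


def _frame_runs(seq: str, offset: int, min_codons: int,
                require_atg: bool) -> list[tuple[int, int]]:
    """Stop-free codon runs in one frame of ``seq``; offsets are on ``seq``."""
    runs: list[tuple[int, int]] = []
    n = len(seq)
    run_start = offset
    pos = offset
    while pos + 3 <= n:
        if seq[pos:pos + 3] in STOP_CODONS:
            if pos > run_start:
                runs.append((run_start, pos))
            run_start = pos + 3
        pos += 3
    if pos > run_start:
        runs.append((run_start, pos))
    if require_atg:
        trimmed = []
        for a, b in runs:
            p = a
            while p + 3 <= b and seq[p:p + 3] != "ATG":
                p += 3
            if p + 3 <= b:
                trimmed.append((p, b))
        runs = trimmed
    return [(a, b) for a, b in runs if (b - a) // 3 >= min_codons]


def find_orfs(record: SequenceRecord, min_length_nt: int = 100,
              require_atg: bool = False) -> list[ORF]:
    """All ORFs of at least ``min_length_nt`` in the six frames of a record.

    Returned sorted by descending length (ties: frame order, then start).
    Typical screening cutoffs are 100 nt (any short peptide) and 300 nt
    (a 100-aa protein).
    """
    if min_length_nt < 3:
        raise ValueError("min_length_nt must be >= 3")
    min_codons = (min_length_nt + 2) // 3
    seq = record.sequence.upper()
    n = len(seq)
    rc = reverse_complement(seq)
    orfs: list[ORF] = []
    for frame_idx in range(3):
        for a, b in _frame_runs(seq, frame_idx, min_codons, require_atg):
            orfs.append(ORF(record.id, frame_idx + 1, a, b, b - a,
                            str(Seq(seq[a:b]).translate())))
        for a, b in _frame_runs(rc, frame_idx, min_codons, require_atg):
            # map reverse-strand run back onto forward coordinates
            orfs.append(ORF(record.id, -(frame_idx + 1), n - b, n - a, b - a,
                            str(Seq(rc[a:b]).translate())))
    orfs.sort(key=lambda o: (-o.length_nt, abs(o.frame), o.frame < 0, o.start))
    return orfs


def count_orfs(records: list[SequenceRecord], min_length_nt: int) -> int:
    """Total number of ORFs at the cutoff across a record set."""
    return sum(len(find_orfs(r, min_length_nt)) for r in records)
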