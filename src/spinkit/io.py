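"""On-disk formats: FASTA/FASTQ, layout TSV / minimal ACE, BLAST-style tabular.

FASTA/FASTQ go through Biopython's SeqIO.  The alignment table is the
standard 12-column tab-separated dialect (qseqid sseqid pident length
mismatch gapopen qstart qend sstart send evalue bitscore) with 1-based
inclusive coordinates on disk; minus strand is encoded there as
``sstart > send`` and converted to the in-memory ``strand`` field.
"""

from __future__ import annotations

import os
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

from .records import HSP, Assembly, LayoutEntry, SequenceRecord

LAYOUT_HEADER = ("contig_id", "read_id", "strand", "offset")


def _check_unique(records: list[SequenceRecord]) -> None:
    seen: set[str] = set()
    for r in records:
        if r.id in seen:
            raise ValueError(f"duplicate sequence id {r.id!r}")
        seen.add(r.id)


def read_sequences(path: str | os.PathLike, format: str = "fasta",
                   alphabet: str = "nucleotide") -> list[SequenceRecord]:
    """Read a FASTA or FASTQ file into :class:`SequenceRecord` objects.

    FASTQ qualities are Phred+33 (Sanger); no offset auto-detection.  An
    empty file yields an empty list.  Duplicate ids raise ``ValueError``.
    """
    if format not in ("fasta", "fastq"):
        raise ValueError(f"unsupported sequence format {format!r}")
    records: list[SequenceRecord] = []
    for bio in SeqIO.parse(str(path), format):
        quals = None
        if format == "fastq":
            quals = list(bio.letter_annotations["phred_quality"])
        seq = str(bio.seq).upper()
        records.append(
            SequenceRecord(id=bio.id, sequence=seq,
                           description=_strip_id(bio.description, bio.id),
                           qualities=quals)
        )
    _check_unique(records)
    return records


def _strip_id(description: str, rec_id: str) -> str:
    if description.startswith(rec_id):
        return description[len(rec_id):].strip()
    return description


def write_sequences(records: Iterable[SequenceRecord], path: str | os.PathLike,
                    format: str = "fasta") -> None:
    """Write records as FASTA or FASTQ (Phred+33)."""
    if format not in ("fasta", "fastq"):
        raise ValueError(f"unsupported sequence format {format!r}")
    bio_records = []
    for r in records:
        bio = _BioRecord(Seq(r.sequence), id=r.id, description=r.description)
        if format == "fastq":
            quals = r.qualities if r.qualities is not None else [40] * len(r.sequence)
            bio.letter_annotations["phred_quality"] = list(quals)
        bio_records.append(bio)
    SeqIO.write(bio_records, str(path), format)


# ---------------------------------------------------------------------------
# assembly layout


def parse_assembly_layout(consensus_path: str | os.PathLike,
                          layout_path: str | os.PathLike,
                          dialect: str = "tsv",
                          singlets_path: str | os.PathLike | None = None) -> Assembly:
    """Build an :class:`Assembly` from a consensus FASTA plus a layout file.

    ``tsv`` expects 4 columns (contig_id, read_id, strand, offset) with
    0-based offsets and an optional header line; ``ace-min`` parses only the
    CO and AF records of an ACE file, mapping orientation U to ``+`` and C to
    ``-`` and converting ACE's 1-based offsets to 0-based.  Singlets, if any,
    come from a separate FASTA given as ``singlets_path``.
    """
    contigs = read_sequences(consensus_path, "fasta")
    if dialect == "tsv":
        layout = _parse_layout_tsv(layout_path)
    elif dialect == "ace-min":
        layout = _parse_layout_ace(layout_path)
    else:
        raise ValueError(f"unknown layout dialect {dialect!r}")
    singlets = read_sequences(singlets_path, "fasta") if singlets_path else []
    return Assembly(contigs=contigs, layout=layout, singlets=singlets)


def _parse_layout_tsv(path: str | os.PathLike) -> list[LayoutEntry]:
    entries: list[LayoutEntry] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if tuple(fields) == LAYOUT_HEADER:
                continue
            if len(fields) != 4:
                raise ValueError(
                    f"{path}:{lineno}: expected 4 layout columns, got {len(fields)}"
                )
            contig_id, read_id, strand, offset = fields
            if strand not in ("+", "-"):
                raise ValueError(
                    f"{path}:{lineno}: strand token {strand!r} not in {{+,-}}"
                )
            entries.append(LayoutEntry(contig_id, read_id, strand, int(offset)))
    return entries


def _parse_layout_ace(path: str | os.PathLike) -> list[LayoutEntry]:
    entries: list[LayoutEntry] = []
    current_contig: str | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if parts[0] == "CO":
                if len(parts) < 2:
                    raise ValueError(f"{path}:{lineno}: CO record without contig id")
                current_contig = parts[1]
            elif parts[0] == "AF":
                if current_contig is None:
                    raise ValueError(f"{path}:{lineno}: AF record before any CO record")
                if len(parts) != 4:
                    raise ValueError(f"{path}:{lineno}: malformed AF record")
                read_id, orient, start = parts[1], parts[2], parts[3]
                if orient not in ("U", "C"):
                    raise ValueError(
                        f"{path}:{lineno}: orientation token {orient!r} not in {{U,C}}"
                    )
                strand = "+" if orient == "U" else "-"
                entries.append(LayoutEntry(current_contig, read_id, strand,
                                           int(start) - 1))
    return entries


def write_layout(layout: Iterable[LayoutEntry], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(LAYOUT_HEADER) + "\n")
        for e in layout:
            fh.write(f"{e.contig_id}\t{e.read_id}\t{e.strand}\t{e.offset}\n")


# ---------------------------------------------------------------------------
# 12-column alignment table


def read_alignment_table(path: str | os.PathLike) -> list[HSP]:
    """Parse a 12-column tab-separated alignment table into HSPs.

    Coordinates on disk are 1-based inclusive; ``sstart > send`` encodes a
    minus-strand match.  In memory all intervals become 0-based half-open
    with ``start < end`` and the orientation moves to ``strand``.
    """
    hsps: list[HSP] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ValueError(
                    f"{path}:{lineno}: expected 12 columns, got {len(fields)}"
                )
            try:
                (qid, sid, pident, length, mism, gapo,
                 qstart, qend, sstart, send, evalue, bits) = fields
                pident_f = float(pident)
                length_i = int(length)
                mism_i = int(mism)
                gapo_i = int(gapo)
                qs, qe = int(qstart), int(qend)
                ss, se = int(sstart), int(send)
                evalue_f = float(evalue)
                bits_f = float(bits)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric field: {exc}") from None
            strand = "+" if ss <= se else "-"
            if strand == "-":
                ss, se = se, ss
            hsps.append(HSP(
                query_id=qid, subject_id=sid, percent_identity=pident_f,
                alignment_length=length_i, mismatches=mism_i, gap_opens=gapo_i,
                qstart=qs - 1, qend=qe, sstart=ss - 1, send=se,
                e_value=evalue_f, bit_score=bits_f, strand=strand,
                score=int(round(bits_f)),
            ))
    return hsps


def write_alignment_table(hsps: Iterable[HSP], path: str | os.PathLike) -> None:
    """Write HSPs in the 12-column dialect (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        for h in hsps:
            ss, se = h.sstart + 1, h.send
            if h.strand == "-":
                ss, se = se, ss
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t{h.percent_identity:.2f}\t"
                f"{h.alignment_length}\t{h.mismatches}\t{h.gap_opens}\t"
                f"{h.qstart + 1}\t{h.qend}\t{ss}\t{se}\t"
                f"{h.e_value:.2e}\t{h.bit_score:.1f}\n"
            )
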