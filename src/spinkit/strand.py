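"""Antisense-read analysis by the per-contig majority-strand rule.

Without a reference genome the biological sense of a cluster is unknown, so
a read is called antisense when its layout strand differs from the majority
strand of its contig's reads.  Contigs with equal plus and minus counts are
ties: the majority is undefined there, so tied contigs are counted in their
own class and contribute no antisense reads.
"""

from __future__ import annotations

from dataclasses import dataclass

from .records import Assembly, LayoutEntry


@dataclass
class ContigStrandSummary:
    contig_id: str
    n_plus: int
    n_minus: int
    majority_strand: str  # '+', '-' or 'tie'
    n_antisense: int
    is_tied: bool


@dataclass
class AntisenseReport:
    n_contigs: int
    n_contigs_with_antisense: int
    pct_contigs_with_antisense: float  # full precision; display rounds to int
    total_antisense_reads: int
    n_tied_contigs: int
    per_contig: list[ContigStrandSummary]


def contig_strand_summary(entries: list[LayoutEntry]) -> ContigStrandSummary:
    """Majority strand and antisense count for one contig's layout entries."""
    if not entries:
        raise ValueError("contig strand summary requires at least one layout entry")
    contig_id = entries[0].contig_id
    for e in entries:
        if e.contig_id != contig_id:
            raise ValueError("layout entries span multiple contigs")
    n_plus = sum(1 for e in entries if e.strand == "+")
    n_minus = len(entries) - n_plus
    if n_plus == n_minus:
        return ContigStrandSummary(contig_id, n_plus, n_minus, "tie", 0, True)
    majority = "+" if n_plus > n_minus else "-"
    return ContigStrandSummary(contig_id, n_plus, n_minus, majority,
                               min(n_plus, n_minus), False)


def antisense_report(assembly: Assembly) -> AntisenseReport:
    """Dataset-level antisense summary over all contigs.

    The percentage denominator is all contigs (ties included); tied contigs
    are excluded from the antisense read total and from the with-antisense
    contig count but reported in their own counter.
    """
    per_contig = [contig_strand_summary(entries)
                  for _, entries in sorted(assembly.layout_by_contig().items())]
    n_contigs = len(per_contig)
    with_antisense = sum(1 for s in per_contig
                         if not s.is_tied and s.n_antisense >= 1)
    total_antisense = sum(s.n_antisense for s in per_contig if not s.is_tied)
    n_tied = sum(1 for s in per_contig if s.is_tied)
    pct = 100.0 * with_antisense / n_contigs if n_contigs else 0.0
    return AntisenseReport(
        n_contigs=n_contigs,
        n_contigs_with_antisense=with_antisense,
        pct_contigs_with_antisense=pct,
        total_antisense_reads=total_antisense,
        n_tied_contigs=n_tied,
        per_contig=per_contig,
    )
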