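"""Assembly consistency indices.

The internal consistency index (ICI) scores how well a read maps back onto
its own contig consensus: after resolving overlapping HSPs on the read
axis,

    ICI = 100 * sum_h (L_h * I_h) / R

where L_h is the HSP alignment length, I_h its fractional identity and R
the read length.  100 means the entire read mapped at 100% identity.  The
external consistency index (ECI) is the same statistic computed between two
different contig consensi (R = query contig length); it is directional, and
pairs scoring above 75 flag clusters that likely represent the same gene
and should have been merged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .records import HSP, Assembly

logger = logging.getLogger(__name__)


@dataclass
class ConsistencyScore:
    query_id: str
    subject_id: str
    score: float
    n_hsps_used: int
    had_any_hsp: bool


@dataclass
class ConsistencyReport:
    per_read_ici: list[ConsistencyScore] = field(default_factory=list)
    average_ici: float = 0.0
    no_hit_reads: list[str] = field(default_factory=list)
    per_pair_eci: list[ConsistencyScore] = field(default_factory=list)
    average_eci: float = 0.0
    flagged_pairs: list[tuple[str, str, float]] = field(default_factory=list)


def select_nonoverlapping_hsps(hsps: list[HSP], axis: str = "query") -> list[HSP]:
    """Greedy maximal set of HSPs with pairwise-disjoint intervals on one axis.

    HSPs are taken by descending score (ties: ascending start); an HSP is
    kept iff its interval on the chosen axis is disjoint from every interval
    already kept.  All HSPs must share one (query, subject) pair.
    """
    if axis not in ("query", "subject"):
        raise ValueError(f"axis must be 'query' or 'subject', got {axis!r}")
    if not hsps:
        return []
    pairs = {(h.query_id, h.subject_id) for h in hsps}
    if len(pairs) > 1:
        raise ValueError(f"HSPs span multiple query/subject pairs: {sorted(pairs)}")

    def interval(h: HSP) -> tuple[int, int]:
        return (h.qstart, h.qend) if axis == "query" else (h.sstart, h.send)

    ordered = sorted(hsps, key=lambda h: (-h.score, interval(h)[0]))
    kept: list[HSP] = []
    taken: list[tuple[int, int]] = []
    for h in ordered:
        lo, hi = interval(h)
        if all(hi <= a or lo >= b for a, b in taken):
            kept.append(h)
            taken.append((lo, hi))
    return kept


def _sum_index(length: int, hsps: list[HSP], label: str) -> tuple[float, int, bool]:
    """Shared ICI/ECI arithmetic: overlap-resolve then normalized SUM."""
    if length <= 0:
        raise ValueError(f"{label}: length must be positive, got {length}")
    if not hsps:
        return 0.0, 0, False
    chosen = select_nonoverlapping_hsps(hsps, axis="query")
    total = sum(h.alignment_length * (h.percent_identity / 100.0) for h in chosen)
    score = 100.0 * total / length
    if score > 100.0:
        # gap columns inflate alignment length beyond the query span
        logger.info("%s: index %.3f clamped to 100 (gap-column inflation)",
                    label, score)
        score = 100.0
    return score, len(chosen), True


def ici_score(read_length: int, hsps_to_own_contig: list[HSP]) -> float:
    """ICI of one read against its own contig consensus (0-100)."""
    score, _, _ = _sum_index(read_length, hsps_to_own_contig, "ICI")
    return score


def eci_score(query_contig_length: int, hsps_to_other_contig: list[HSP]) -> float:
    """Directional ECI of a query contig against another contig (0-100)."""
    for h in hsps_to_other_contig:
        if h.query_id == h.subject_id:
            raise ValueError(f"ECI is defined between different contigs, got "
                             f"self-pair {h.query_id!r}")
    score, _, _ = _sum_index(query_contig_length, hsps_to_other_contig, "ECI")
    return score


def consistency_report(assembly: Assembly, read_hsps: list[HSP],
                       contig_hsps: list[HSP], flag_threshold: float = 75.0,
                       read_lengths: dict[str, int] | None = None,
                       ) -> ConsistencyReport:
    """Full ICI/ECI report for one assembly.

    Every assembled read gets an ICI (0 when it has no HSP to its contig;
    such reads are also listed in ``no_hit_reads``).  ECI is computed for
    every ordered contig pair with at least one HSP; the average is over
    those pairs.  Flagged pairs (ECI > threshold) are deduplicated to
    unordered pairs carrying the larger of the two directional scores.

    ``read_lengths`` maps read id to length; required because the layout
    alone does not carry read lengths.  When omitted, lengths are inferred
    from each read's HSPs (max qend), which is exact only for full-length
    mappings.
    """
    report = ConsistencyReport()
    read_to_contig = {e.read_id: e.contig_id for e in assembly.layout}

    by_read: dict[str, list[HSP]] = {}
    for h in read_hsps:
        if h.query_id not in read_to_contig:
            raise ValueError(f"HSP query {h.query_id!r} is not an assembled read")
        if h.subject_id == read_to_contig[h.query_id]:
            by_read.setdefault(h.query_id, []).append(h)

    for read_id, contig_id in sorted(read_to_contig.items()):
        hsps = by_read.get(read_id, [])
        if read_lengths is not None:
            length = read_lengths[read_id]
        else:
            length = max((h.qend for h in hsps), default=1)
        if not hsps:
            report.no_hit_reads.append(read_id)
            report.per_read_ici.append(
                ConsistencyScore(read_id, contig_id, 0.0, 0, False))
            continue
        score, n_used, _ = _sum_index(length, hsps, f"ICI[{read_id}]")
        report.per_read_ici.append(
            ConsistencyScore(read_id, contig_id, score, n_used, True))
    if report.per_read_ici:
        report.average_ici = (sum(s.score for s in report.per_read_ici)
                              / len(report.per_read_ici))

    contig_len = {c.id: len(c.sequence) for c in assembly.contigs}
    by_pair: dict[tuple[str, str], list[HSP]] = {}
    for h in contig_hsps:
        if h.query_id == h.subject_id:
            continue
        if h.query_id in contig_len and h.subject_id in contig_len:
            by_pair.setdefault((h.query_id, h.subject_id), []).append(h)

    directional: dict[tuple[str, str], float] = {}
    for (qid, sid), hsps in sorted(by_pair.items()):
        score, n_used, _ = _sum_index(contig_len[qid], hsps, f"ECI[{qid},{sid}]")
        directional[(qid, sid)] = score
        report.per_pair_eci.append(ConsistencyScore(qid, sid, score, n_used, True))
    if report.per_pair_eci:
        report.average_eci = (sum(s.score for s in report.per_pair_eci)
                              / len(report.per_pair_eci))

    flagged: dict[tuple[str, str], float] = {}
    for (qid, sid), score in directional.items():
        if score > flag_threshold:
            key = (min(qid, sid), max(qid, sid))
            flagged[key] = max(flagged.get(key, 0.0), score)
    report.flagged_pairs = sorted((a, b, s) for (a, b), s in flagged.items())
    return report
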