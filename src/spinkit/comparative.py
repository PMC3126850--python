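"""Cross-dataset unigene matching, NMU extraction, KOG annotation and the
KOG-ratio gene-family expansion statistic.

The KOG ratio of an ortholog group is the count of distinct unigenes
annotated to it in dataset A divided by the count in dataset B; a ratio of
at least 4 flags a lineage-specific family expansion and ratios above 10
mark strong amplifications.  Counts are raw (not library-size normalized);
a per-10,000-unigenes normalized column can be derived downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .records import HSP


@dataclass
class CrossMatchResult:
    """Counts for one directional unigene-set comparison.

    ``n_query_matching`` = distinct queries with at least one HSP at or
    below the cutoff ("query genes"); ``n_subject_matched`` = distinct
    subjects hit by such an HSP ("subject genes").
    """

    query_set_id: str
    subject_set_id: str
    n_query_matching: int
    n_subject_matched: int
    evalue_cutoff: float


@dataclass
class KOGAnnotation:
    unigene_id: str
    kog_id: str
    kog_category: str
    evalue: float
    subject_coverage: float


@dataclass
class KOGRatioRow:
    kog_id: str
    count_a: int
    count_b: int
    ratio: float  # math.inf when count_b == 0 and count_a > 0
    expanded_at_4: bool = field(init=False)
    expanded_at_10: bool = field(init=False)

    def __post_init__(self) -> None:
        self.expanded_at_4 = self.ratio >= 4
        self.expanded_at_10 = self.ratio >= 10


def crossmatch_counts(hsps: list[HSP], query_set: set[str], subject_set: set[str],
                      evalue_cutoff: float = 1e-10,
                      query_set_id: str = "A", subject_set_id: str = "B",
                      ) -> CrossMatchResult:
    """Count matching query genes and matched subject genes at a cutoff."""
    matching_q: set[str] = set()
    matched_s: set[str] = set()
    for h in hsps:
        if h.query_id not in query_set and h.subject_id not in subject_set:
            raise ValueError(
                f"HSP ids {h.query_id!r}/{h.subject_id!r} absent from both sets")
        if h.e_value > evalue_cutoff:
            continue
        if h.query_id in query_set:
            matching_q.add(h.query_id)
        if h.subject_id in subject_set:
            matched_s.add(h.subject_id)
    return CrossMatchResult(query_set_id, subject_set_id,
                            len(matching_q), len(matched_s), evalue_cutoff)


def extract_nmus(unigenes: list[str], database_hsps: list[HSP],
                 evalue_cutoff: float = 1e-05) -> set[str]:
    """No-match unigenes: ids with zero hits at or below the cutoff.

    ``database_hsps`` may pool searches against several reference sets; a
    unigene is an NMU only when it has no qualifying hit anywhere (union
    semantics over databases).
    """
    hit = {h.query_id for h in database_hsps if h.e_value <= evalue_cutoff}
    return {u for u in unigenes if u not in hit}


def assign_kog(hsps_vs_kog_proteins: list[HSP],
               kog_catalog: dict[str, tuple[str, str]],
               min_coverage: float = 0.5,
               evalue_cutoff: float = 1e-10) -> list[KOGAnnotation]:
    """Annotate unigenes to ortholog groups by coverage- and e-value-gated hits.

    ``kog_catalog`` maps reference protein id -> (kog_id, category).  A
    unigene is annotated to group K when its best HSP against any protein
    of K passes both gates; a unigene may be annotated to several groups
    (multifunctional genes).  Ties on e-value break by higher coverage,
    then lexicographic protein id.  ``subject_coverage`` on the HSP side is
    the covered fraction of the reference protein, computed from the HSP's
    subject span over the protein length recorded in the catalog when
    available; otherwise the HSP must carry it via ``send``/``sstart``
    against a known length.
    """
    # best hit per (unigene, kog): (evalue, -coverage, protein_id)
    best: dict[tuple[str, str], tuple[float, float, str, float]] = {}
    for h in hsps_vs_kog_proteins:
        if h.subject_id not in kog_catalog:
            raise ValueError(f"HSP subject {h.subject_id!r} absent from KOG catalog")
        kog_id, _ = kog_catalog[h.subject_id]
        coverage = getattr(h, "subject_coverage", None)
        if coverage is None:
            raise ValueError(
                f"HSP {h.query_id!r} vs {h.subject_id!r} lacks subject coverage")
        if h.e_value > evalue_cutoff or coverage < min_coverage:
            continue
        key = (h.query_id, kog_id)
        cand = (h.e_value, -coverage, h.subject_id, coverage)
        if key not in best or cand < best[key]:
            best[key] = cand
    annotations = []
    for (unigene, kog_id), (ev, _negcov, _pid, cov) in sorted(best.items()):
        category = kog_catalog[_pid][1]
        annotations.append(KOGAnnotation(unigene, kog_id, category, ev, cov))
    return annotations


def hsp_subject_coverage(h: HSP, subject_length: int) -> float:
    """Fraction of the reference protein covered by one HSP's subject span."""
    if subject_length <= 0:
        raise ValueError("subject length must be positive")
    return (h.send - h.sstart) / subject_length


def with_subject_coverage(hsps: list[HSP],
                          subject_lengths: dict[str, int]) -> list[HSP]:
    """Attach ``subject_coverage`` to HSPs from a subject-length table."""
    for h in hsps:
        h.subject_coverage = hsp_subject_coverage(h, subject_lengths[h.subject_id])  # type: ignore[attr-defined]
    return hsps


def category_distribution(annotations: list[KOGAnnotation]) -> dict[str, int]:
    """Annotation counts per one-letter KOG functional category."""
    counts: dict[str, int] = {}
    for a in annotations:
        counts[a.kog_category] = counts.get(a.kog_category, 0) + 1
    return counts


def kog_ratio_table(annotations_a: list[KOGAnnotation],
                    annotations_b: list[KOGAnnotation]) -> list[KOGRatioRow]:
    """Per-KOG distinct-unigene counts in two datasets and their ratio.

    Rows cover every KOG present in either dataset, sorted by descending
    ratio with infinite ratios first (those by descending count_a).
    """
    def distinct_counts(annotations: list[KOGAnnotation]) -> dict[str, int]:
        per_kog: dict[str, set[str]] = {}
        for a in annotations:
            per_kog.setdefault(a.kog_id, set()).add(a.unigene_id)
        return {k: len(v) for k, v in per_kog.items()}

    counts_a = distinct_counts(annotations_a)
    counts_b = distinct_counts(annotations_b)
    rows = []
    for kog_id in sorted(set(counts_a) | set(counts_b)):
        ca = counts_a.get(kog_id, 0)
        cb = counts_b.get(kog_id, 0)
        if cb == 0:
            ratio = math.inf if ca > 0 else 0.0
        else:
            ratio = ca / cb
        rows.append(KOGRatioRow(kog_id, ca, cb, ratio))
    rows.sort(key=lambda r: (not math.isinf(r.ratio),
                             -r.count_a if math.isinf(r.ratio) else 0.0,
                             -r.ratio if not math.isinf(r.ratio) else 0.0,
                             r.kog_id))
    return rows


def expanded_families(ratio_table: list[KOGRatioRow],
                      threshold: float = 4.0) -> list[KOGRatioRow]:
    """Rows with ratio >= threshold; infinite ratios qualify only when
    count_a itself reaches the threshold.  Input order is preserved."""
    out = []
    for row in ratio_table:
        if math.isinf(row.ratio):
            if row.count_a >= threshold:
                out.append(row)
        elif row.ratio >= threshold:
            out.append(row)
    return out
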