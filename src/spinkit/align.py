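"""Seed-and-extend local nucleotide aligner producing BLAST-style HSPs.

Exact k-mer seeds on both strands locate candidate diagonals; each diagonal
cluster is resolved by a banded affine-gap Smith-Waterman with full
traceback, so on homologous pairs whose optimal alignment stays inside the
band the reported score equals the unrestricted local-alignment optimum.
Raw scores are converted to e-values with Karlin-Altschul statistics under
uniform base frequencies: lambda is solved numerically from
``sum_ij p_i p_j exp(lambda * s_ij) = 1`` and K is fixed at 0.35, a
documented approximation adequate for thresholding (the e-value is a
ranking/cutoff device here, not a calibrated p-value).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from numba import njit

from .records import HSP, Assembly, SequenceRecord, reverse_complement

_ENCODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i
    _ENCODE[_b + 32] = _i


def encode(sequence: str) -> np.ndarray:
    """Map a nucleotide string to int8 codes (A,C,G,T -> 0..3, other -> 4)."""
    return _ENCODE[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]


@dataclass
class AlignParams:
    """Scoring scheme and search thresholds.

    Match/mismatch +1/-2 with affine gaps (open -5 covers the first gap
    base, extend -2 each additional one) is a megablast-like scheme suited
    to read-to-consensus and cross-species nucleotide matching.  Default
    e-value cutoffs: 1e-05 for database-style screens, 1e-10 for strict
    cross-dataset matching (pass explicitly).
    """

    k: int = 11
    match: int = 1
    mismatch: int = -2
    gap_open: int = -5
    gap_extend: int = -2
    xdrop: int = 20
    evalue_max: float = 1e-05
    both_strands: bool = True
    band: int = 32
    karlin_k: float = 0.35

    def __post_init__(self) -> None:
        if self.k < 4:
            raise ValueError("seed word size k must be >= 4")
        if not (self.match > 0 > self.mismatch):
            raise ValueError("require match > 0 > mismatch")


@lru_cache(maxsize=None)
def karlin_lambda(match: int, mismatch: int) -> float:
    """Solve sum_ij p_i p_j exp(lambda*s_ij) = 1 for lambda under p_i = 1/4."""
    from scipy.optimize import brentq

    def f(lam: float) -> float:
        return 0.25 * math.exp(lam * match) + 0.75 * math.exp(lam * mismatch) - 1.0

    # f(0+) < 0 since expected score is negative; bracket upward
    hi = 1.0
    while f(hi) < 0:
        hi *= 2.0
    return float(brentq(f, 1e-9, hi))


def evalue(score: int, m: int, n: int, params: AlignParams) -> float:
    lam = karlin_lambda(params.match, params.mismatch)
    e = params.karlin_k * m * n * math.exp(-lam * score)
    return max(e, 1e-300)


def bit_score(score: int, params: AlignParams) -> float:
    lam = karlin_lambda(params.match, params.mismatch)
    return (lam * score - math.log(params.karlin_k)) / math.log(2.0)


@njit(cache=True)
def _banded_sw(q, s, d_lo, d_hi, match, mismatch, gap_open, gap_extend):  # pragma: no cover
    """Banded affine local alignment over diagonals j - i in [d_lo, d_hi].

    Returns int64 array [score, qstart, qend, sstart, send, matches,
    columns, gap_opens]; all-zero score means no positive-scoring cell.
    """
    m = q.shape[0]
    n = s.shape[0]
    W = d_hi - d_lo + 1
    NEG = -(10 ** 9)

    H = np.full((m + 1, W), NEG, dtype=np.int64)
    E = np.full((m + 1, W), NEG, dtype=np.int64)
    F = np.full((m + 1, W), NEG, dtype=np.int64)
    ptr = np.zeros((m + 1, W), dtype=np.uint8)   # 0 stop, 1 diag, 2 left(E), 3 up(F)
    eopen = np.zeros((m + 1, W), dtype=np.uint8)
    fopen = np.zeros((m + 1, W), dtype=np.uint8)

    for k in range(W):
        j = d_lo + k
        if 0 <= j <= n:
            H[0, k] = 0

    best = 0
    bi = -1
    bk = -1
    for i in range(1, m + 1):
        qi = q[i - 1]
        for k in range(W):
            j = i + d_lo + k
            if j < 0 or j > n:
                continue
            if j == 0:
                H[i, k] = 0
                continue
            # E: gap in query (consume subject base j)
            if k >= 1:
                op = H[i, k - 1] + gap_open
                ex = E[i, k - 1] + gap_extend
                if op >= ex:
                    E[i, k] = op
                    eopen[i, k] = 1
                else:
                    E[i, k] = ex
            # F: gap in subject (consume query base i)
            if k + 1 < W:
                op = H[i - 1, k + 1] + gap_open
                ex = F[i - 1, k + 1] + gap_extend
                if op >= ex:
                    F[i, k] = op
                    fopen[i, k] = 1
                else:
                    F[i, k] = ex
            sc = match if (qi == s[j - 1] and qi < 4) else mismatch
            diag = H[i - 1, k] + sc
            h = 0
            p = 0
            if diag > h:
                h = diag
                p = 1
            if E[i, k] > h:
                h = E[i, k]
                p = 2
            if F[i, k] > h:
                h = F[i, k]
                p = 3
            H[i, k] = h
            ptr[i, k] = p
            if h > best:
                best = h
                bi = i
                bk = k

    out = np.zeros(8, dtype=np.int64)
    if best <= 0:
        return out

    # traceback
    i = bi
    k = bk
    j = i + d_lo + k
    qe = i
    se = j
    matches = 0
    columns = 0
    gapo = 0
    state = 0  # 0 = H, 1 = E, 2 = F
    while True:
        if state == 0:
            p = ptr[i, k]
            if p == 0:
                break
            if p == 1:
                columns += 1
                if q[i - 1] == s[j - 1] and q[i - 1] < 4:
                    matches += 1
                i -= 1
                j -= 1
            elif p == 2:
                state = 1
            else:
                state = 2
        elif state == 1:
            columns += 1
            if eopen[i, k] == 1:
                state = 0
                gapo += 1
            k -= 1
            j -= 1
        else:
            columns += 1
            if fopen[i, k] == 1:
                state = 0
                gapo += 1
            i -= 1
            k += 1

    out[0] = best
    out[1] = i
    out[2] = qe
    out[3] = j
    out[4] = se
    out[5] = matches
    out[6] = columns
    out[7] = gapo
    return out


class _SubjectIndex:
    """Exact k-mer position index over one subject sequence."""

    __slots__ = ("k", "positions", "length")

    def __init__(self, sequence: str, k: int, max_per_kmer: int = 64):
        self.k = k
        self.length = len(sequence)
        positions: dict[str, list[int]] = {}
        for j in range(len(sequence) - k + 1):
            kmer = sequence[j:j + k]
            if "N" in kmer:
                continue
            lst = positions.setdefault(kmer, [])
            if len(lst) < max_per_kmer:
                lst.append(j)
        self.positions = positions


def _cluster_diagonals(diags: list[int], band: int) -> list[tuple[int, int]]:
    """Group sorted diagonals into clusters separated by more than band."""
    diags = sorted(set(diags))
    clusters: list[tuple[int, int]] = []
    lo = hi = diags[0]
    for d in diags[1:]:
        if d - hi <= band:
            hi = d
        else:
            clusters.append((lo, hi))
            lo = hi = d
    clusters.append((lo, hi))
    return clusters


def _extend_clusters(query_seq: str, subject_seq: str, index: _SubjectIndex,
                     params: AlignParams) -> list[tuple]:
    """Seed, cluster, and run the banded DP; return raw stat tuples."""
    k = params.k
    m = len(query_seq)
    n = index.length
    if m < k or n < k:
        return []
    diags: list[int] = []
    for i in range(m - k + 1):
        kmer = query_seq[i:i + k]
        for j in index.positions.get(kmer, ()):
            diags.append(j - i)
    if not diags:
        return []
    q = encode(query_seq)
    s = encode(subject_seq)
    results = []
    seen: set[tuple[int, int, int, int]] = set()
    for lo, hi in _cluster_diagonals(diags, params.band):
        d_lo = max(lo - params.band // 2, -(m - 1))
        d_hi = min(hi + params.band // 2, n - 1)
        stats = _banded_sw(q, s, d_lo, d_hi, params.match, params.mismatch,
                           params.gap_open, params.gap_extend)
        if stats[0] <= 0:
            continue
        key = (int(stats[1]), int(stats[2]), int(stats[3]), int(stats[4]))
        if key in seen:
            continue
        seen.add(key)
        results.append(tuple(int(x) for x in stats))
    return results


def _stats_to_hsp(stats: tuple, query: SequenceRecord, subject: SequenceRecord,
                  strand: str, params: AlignParams) -> HSP:
    score, qs, qe, ss, se, matches, columns, gapo = stats
    n = len(subject.sequence)
    # columns = paired + gap columns; paired = (qspan + sspan) - columns
    mismatches = (qe - qs) + (se - ss) - columns - matches
    if strand == "-":
        # coordinates were computed on the reverse complement of the subject
        ss, se = n - se, n - ss
    pid = 100.0 * matches / columns
    return HSP(
        query_id=query.id, subject_id=subject.id,
        percent_identity=pid, alignment_length=columns,
        mismatches=mismatches,
        gap_opens=gapo,
        score=score, e_value=evalue(score, len(query.sequence), n, params),
        bit_score=bit_score(score, params),
        qstart=qs, qend=qe, sstart=ss, send=se, strand=strand,
    )


def _align_to_indexed(query: SequenceRecord, subject: SequenceRecord,
                      fwd_index: _SubjectIndex, rev_index: _SubjectIndex | None,
                      rev_seq: str | None, params: AlignParams) -> list[HSP]:
    hsps: list[HSP] = []
    for stats in _extend_clusters(query.sequence, subject.sequence, fwd_index, params):
        hsps.append(_stats_to_hsp(stats, query, subject, "+", params))
    if rev_index is not None and rev_seq is not None:
        for stats in _extend_clusters(query.sequence, rev_seq, rev_index, params):
            hsps.append(_stats_to_hsp(stats, query, subject, "-", params))
    hsps = [h for h in hsps if h.e_value <= params.evalue_max]
    hsps.sort(key=lambda h: (-h.score, h.qstart, h.sstart))
    return hsps


def find_hsps(query: SequenceRecord, subject: SequenceRecord,
              params: AlignParams | None = None) -> list[HSP]:
    """Local alignments between one query and one subject, best score first.

    Sequences shorter than the seed size yield an empty list.
    """
    params = params or AlignParams()
    fwd = _SubjectIndex(subject.sequence, params.k)
    rev_seq = reverse_complement(subject.sequence) if params.both_strands else None
    rev = _SubjectIndex(rev_seq, params.k) if rev_seq is not None else None
    return _align_to_indexed(query, subject, fwd, rev, rev_seq, params)


def batch_align(queries: list[SequenceRecord], subjects: list[SequenceRecord],
                params: AlignParams | None = None, mode: str = "all_vs_all",
                layout: list | Assembly | None = None) -> list[HSP]:
    """Align many queries against many subjects.

    ``reads_to_contigs`` restricts each read to its own contig as given by
    ``layout`` (a list of layout entries or an :class:`Assembly`);
    ``all_vs_all`` aligns every ordered pair except self-pairs.
    """
    params = params or AlignParams()
    if mode not in ("all_vs_all", "reads_to_contigs"):
        raise ValueError(f"unknown mode {mode!r}")

    out: list[HSP] = []
    if mode == "reads_to_contigs":
        if layout is None:
            raise ValueError("reads_to_contigs mode requires a layout")
        entries = layout.layout if isinstance(layout, Assembly) else layout
        read_to_contig = {e.read_id: e.contig_id for e in entries}
        subj_by_id = {s.id: s for s in subjects}
        cache: dict[str, tuple] = {}
        for read in queries:
            cid = read_to_contig.get(read.id)
            if cid is None:
                raise ValueError(f"read {read.id!r} has no layout entry")
            if cid not in cache:
                subject = subj_by_id[cid]
                rev_seq = (reverse_complement(subject.sequence)
                           if params.both_strands else None)
                cache[cid] = (
                    subject,
                    _SubjectIndex(subject.sequence, params.k),
                    _SubjectIndex(rev_seq, params.k) if rev_seq else None,
                    rev_seq,
                )
            subject, fwd, rev, rev_seq = cache[cid]
            out.extend(_align_to_indexed(read, subject, fwd, rev, rev_seq, params))
        return out

    for subject in subjects:
        fwd = _SubjectIndex(subject.sequence, params.k)
        rev_seq = reverse_complement(subject.sequence) if params.both_strands else None
        rev = _SubjectIndex(rev_seq, params.k) if rev_seq else None
        for query in queries:
            if query.id == subject.id:
                continue
            out.extend(_align_to_indexed(query, subject, fwd, rev, rev_seq, params))
    return out
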