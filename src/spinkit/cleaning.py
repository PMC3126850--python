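"""EST read cleaning: terminal trimming plus three rejection categories.

Mirrors the seqclean-style cleaning summary (short / dust / low-quality
counts), with each read assigned to exactly one category.  The category
algorithms are declared approximations: dust is the classical windowed
triplet-composition score, low quality is mean Phred below a threshold.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .records import SequenceRecord


@dataclass
class CleaningThresholds:
    """Cleaning parameters.

    min_length_nt=70 is the minimum size limit for a valid EST; dust_threshold
    is on the 0-100 windowed triplet score (random sequence scores ~1.5,
    simple repeats approach 100); min_mean_quality is mean Phred;
    trim_terminal_run_min is the homopolymer length at a read end that
    triggers trimming (poly-A/T tails, 454 artifacts).
    """

    min_length_nt: int = 70
    dust_threshold: float = 7.0
    min_mean_quality: float = 20.0
    trim_terminal_run_min: int = 10

    def __post_init__(self) -> None:
        if self.min_length_nt < 1:
            raise ValueError("min_length_nt must be >= 1")
        if self.dust_threshold < 0:
            raise ValueError("dust_threshold must be >= 0")


@dataclass
class CleaningReport:
    """Per-run cleaning summary; categories partition the input."""

    n_input: int = 0
    n_short: int = 0
    n_dust: int = 0
    n_low_quality: int = 0
    n_kept: int = 0
    bases_input: int = 0
    bases_kept: int = 0

    def validate(self) -> None:
        if self.n_input != self.n_short + self.n_dust + self.n_low_quality + self.n_kept:
            raise ValueError("cleaning categories do not partition the input")


def dust_score(sequence: str, window: int = 64) -> float:
    """Low-complexity score in [0, 100] from windowed triplet counts.

    Per window of length w the score is ``100 * sum_t c_t(c_t-1)/2`` over
    triplet counts, normalized by ``(w-2)(w-3)/2`` (its value when a single
    triplet fills the window).  The sequence score is the maximum over
    windows stepped by half a window.  Sequences shorter than 5 nt score 0.
    """
    n = len(sequence)
    if n < 5:
        return 0.0
    best = 0.0
    step = max(window // 2, 1)
    starts = list(range(0, max(n - window, 0) + 1, step))
    if starts[-1] != max(n - window, 0):
        starts.append(max(n - window, 0))
    for start in starts:
        chunk = sequence[start:start + window]
        w = len(chunk)
        counts: dict[str, int] = {}
        for i in range(w - 2):
            t = chunk[i:i + 3]
            counts[t] = counts.get(t, 0) + 1
        raw = sum(c * (c - 1) // 2 for c in counts.values())
        denom = (w - 2) * (w - 3) / 2
        if denom > 0:
            best = max(best, 100.0 * raw / denom)
    return min(best, 100.0)


_TERMINAL_RE_CACHE: dict[int, re.Pattern] = {}


def trim_terminal_runs(sequence: str, qualities: list[int] | None,
                       run_min: int = 10) -> tuple[str, list[int] | None]:
    """Strip terminal homopolymer runs >= run_min plus flanking Ns, both ends."""
    pat = _TERMINAL_RE_CACHE.get(run_min)
    if pat is None:
        pat = re.compile(
            r"^N*(?:A{%d,}|C{%d,}|G{%d,}|T{%d,})N*" % ((run_min,) * 4)
        )
        _TERMINAL_RE_CACHE[run_min] = pat
    start, end = 0, len(sequence)
    m = pat.match(sequence)
    if m:
        start = m.end()
    m = pat.match(sequence[start:end][::-1])
    if m:
        end -= m.end()
    # leading/trailing Ns alone are trimmed too
    while start < end and sequence[start] == "N":
        start += 1
    while end > start and sequence[end - 1] == "N":
        end -= 1
    trimmed = sequence[start:end]
    quals = qualities[start:end] if qualities is not None else None
    return trimmed, quals


def clean_reads(reads: list[SequenceRecord],
                thresholds: CleaningThresholds | None = None,
                ) -> tuple[list[SequenceRecord], CleaningReport]:
    """Trim and validate reads; each read lands in exactly one category.

    Order per read: trim terminal homopolymer runs and flanking Ns, then
    reject short (< min length), then dust (low complexity), then low
    quality (mean Phred; skipped when the read has no qualities).  Kept
    reads carry their trimmed sequences.
    """
    thresholds = thresholds or CleaningThresholds()
    report = CleaningReport()
    kept: list[SequenceRecord] = []
    for read in reads:
        report.n_input += 1
        report.bases_input += len(read.sequence)
        seq, quals = trim_terminal_runs(read.sequence, read.qualities,
                                        thresholds.trim_terminal_run_min)
        if not seq:
            # whole-read homopolymer: not a terminal artifact but contamination;
            # leave untrimmed so the dust test classifies it
            seq, quals = read.sequence, read.qualities
        if len(seq) < thresholds.min_length_nt:
            report.n_short += 1
            continue
        if dust_score(seq) >= thresholds.dust_threshold:
            report.n_dust += 1
            continue
        if quals is not None and sum(quals) / len(quals) < thresholds.min_mean_quality:
            report.n_low_quality += 1
            continue
        report.n_kept += 1
        report.bases_kept += len(seq)
        kept.append(SequenceRecord(id=read.id, sequence=seq,
                                   description=read.description, qualities=quals))
    report.validate()
    return kept, report
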