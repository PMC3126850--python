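"""Spidroin repeat-motif grammar profiling.

Orbicularian silk proteins are dominated by four short amino-acid motifs:
polyalanine runs, (GA)n repeats, GGX (X a variable residue) and GPGX(X)
units; mygalomorph spidroins are instead serine/alanine-rich, so S/A/T
composition is reported alongside.  The candidate flag is a reproducible,
declared approximation of manual spidroin curation: a peptide is a
candidate when motif coverage and length pass configurable thresholds.

Scanning grammar (deterministic, shared with the test oracle):
 - polyA: maximal runs of 'A', length >= 4;
 - (GA)n: maximal runs of the 'GA' dimer, >= 3 units;
 - GPGX(X): left-to-right units 'GPG'+1-2 residues, preferring the 5-mer
   unless that would consume the 'G' opening an immediately following unit;
 - GGX: left-to-right 3-mer units 'GG'+1 residue.
Classes are applied in that priority order and may not overlap residues
already covered by an earlier class; within a class matches are maximal
and non-overlapping.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

_AA_RE = re.compile(r"^[ACDEFGHIKLMNPQRSTVWYX*]+$")


@dataclass
class MotifThresholds:
    candidate_coverage: float = 0.30
    min_candidate_len: int = 60
    polya_min_run: int = 4
    ga_min_units: int = 3


@dataclass
class MotifProfile:
    protein_id: str
    length: int
    counts: dict[str, int] = field(default_factory=dict)
    covered_residues: dict[str, int] = field(default_factory=dict)
    fraction_ser: float = 0.0
    fraction_ala: float = 0.0
    fraction_thr: float = 0.0
    coverage: float = 0.0
    ggx_x_composition: dict[str, int] = field(default_factory=dict)
    is_spidroin_candidate: bool = False


def _scan_polya(peptide: str, covered: list[bool], min_run: int):
    spans = []
    for m in re.finditer(r"A{%d,}" % min_run, peptide):
        if not any(covered[m.start():m.end()]):
            spans.append((m.start(), m.end()))
    return spans


def _scan_ga(peptide: str, covered: list[bool], min_units: int):
    spans = []
    for m in re.finditer(r"(?:GA){%d,}" % min_units, peptide):
        if not any(covered[m.start():m.end()]):
            spans.append((m.start(), m.end()))
    return spans


def _scan_gpgx(peptide: str, covered: list[bool]):
    """Unit-by-unit GPGX(X) scan; returns one span per unit."""
    spans = []
    n = len(peptide)
    i = 0
    while i + 4 <= n:
        if peptide[i:i + 3] != "GPG" or any(covered[i:i + 3]):
            i += 1
            continue
        take = 0
        if i + 5 <= n and peptide[i + 4:i + 7] != "GPG" and not any(covered[i + 3:i + 5]):
            take = 5
        elif not covered[i + 3]:
            take = 4
        if take:
            spans.append((i, i + take))
            i += take
        else:
            i += 1
    return spans


def _scan_ggx(peptide: str, covered: list[bool]):
    spans = []
    n = len(peptide)
    i = 0
    while i + 3 <= n:
        if peptide[i:i + 2] == "GG" and not any(covered[i:i + 3]):
            spans.append((i, i + 3))
            i += 3
        else:
            i += 1
    return spans


def motif_profile(peptide: str, thresholds: MotifThresholds | None = None,
                  protein_id: str = "") -> MotifProfile:
    """Scan one peptide for the four spidroin motif classes.

    Returns per-class occurrence counts and covered-residue totals, the
    union coverage fraction, S/A/T composition, the composition of the X
    residue in GGX matches, and the curation-approximation candidate flag.
    """
    thresholds = thresholds or MotifThresholds()
    if not peptide:
        raise ValueError("empty peptide")
    pep = peptide.upper()
    if not _AA_RE.match(pep):
        bad = sorted(set(re.sub(r"[ACDEFGHIKLMNPQRSTVWYX*]", "", pep)))
        raise ValueError(f"non-amino-acid characters in peptide: {bad}")

    n = len(pep)
    covered = [False] * n
    profile = MotifProfile(protein_id=protein_id, length=n)

    scanners = [
        ("polyA", lambda: _scan_polya(pep, covered, thresholds.polya_min_run)),
        ("GAn", lambda: _scan_ga(pep, covered, thresholds.ga_min_units)),
        ("GPGX", lambda: _scan_gpgx(pep, covered)),
        ("GGX", lambda: _scan_ggx(pep, covered)),
    ]
    for name, scan in scanners:
        spans = scan()
        profile.counts[name] = len(spans)
        profile.covered_residues[name] = sum(b - a for a, b in spans)
        for a, b in spans:
            for i in range(a, b):
                covered[i] = True
            if name == "GGX":
                x = pep[b - 1]
                profile.ggx_x_composition[x] = profile.ggx_x_composition.get(x, 0) + 1

    profile.coverage = sum(covered) / n
    profile.fraction_ser = pep.count("S") / n
    profile.fraction_ala = pep.count("A") / n
    profile.fraction_thr = pep.count("T") / n
    profile.is_spidroin_candidate = (
        profile.coverage >= thresholds.candidate_coverage
        and n >= thresholds.min_candidate_len
    )
    return profile
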