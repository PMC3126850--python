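"""End-to-end orchestration: clean -> import assembly -> align -> consistency
-> antisense -> comparative -> ORF/motif, with TSV outputs and a manifest.

The assembler itself is an import boundary: assemblies are consumed as a
consensus FASTA plus a read layout (or produced by the synthetic truth
assembler for demo runs); the pipeline never shells out to CAP3/MIRA/Celera.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import os
import time
from dataclasses import dataclass, field

import yaml

from . import io as sio
from .align import AlignParams, batch_align
from .cleaning import CleaningThresholds, clean_reads
from .comparative import expanded_families, kog_ratio_table
from .consistency import consistency_report
from .motifs import MotifThresholds, motif_profile
from .orfs import find_orfs
from .records import SequenceRecord
from .strand import antisense_report

logger = logging.getLogger(__name__)


def unigene_count(n_clean_reads: int, n_reads_clustered: int, n_contigs: int) -> int:
    """Unigenes = singlets + contigs = (clean - clustered) + contigs."""
    return n_clean_reads - n_reads_clustered + n_contigs


def percent(part: float, whole: float, digits: int = 1) -> float:
    """Percentage of ``part`` in ``whole`` rounded to ``digits`` decimals.

    With digits=0 the result is still a float (73.0), matching report
    display conventions for whole-number percentages.
    """
    if whole == 0:
        return 0.0
    return round(100.0 * part / whole, digits)


@dataclass
class PipelineConfig:
    """One run's inputs and thresholds (defaults are the standard cutoffs)."""

    reads_path: str = ""
    reads_format: str = "fastq"
    consensus_path: str = ""
    layout_path: str = ""
    singlets_path: str | None = None
    layout_dialect: str = "tsv"
    read_alignments_path: str | None = None   # external table, replaces aligner
    contig_alignments_path: str | None = None
    min_length_nt: int = 70
    dust_threshold: float = 7.0
    min_mean_quality: float = 20.0
    evalue_database: float = 1e-05
    evalue_crossmatch: float = 1e-10
    eci_flag_threshold: float = 75.0
    kog_ratio_threshold: float = 4.0
    kog_ratio_strong: float = 10.0
    orf_min_short: int = 100
    orf_min_long: int = 300
    motif_candidate_coverage: float = 0.30
    seed: int = 0
    outdir: str = "spinkit_out"

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        for label, path in (("reads", self.reads_path),
                            ("consensus", self.consensus_path),
                            ("layout", self.layout_path)):
            if not path or not os.path.exists(path):
                raise FileNotFoundError(f"{label} path missing or absent: {path!r}")

    def content_hash(self) -> str:
        payload = json.dumps(vars(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _write_tsv(path: str, header: list[str], rows: list[tuple]) -> int:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
    return len(rows)


def spidroin_candidates(records: list[SequenceRecord], min_orf_nt: int = 180,
                        thresholds: MotifThresholds | None = None) -> list[str]:
    """Ids of records with a motif-grammar spidroin-candidate ORF.

    A reproducible approximation of manual spidroin curation: a record is a
    candidate when any ORF of at least ``min_orf_nt`` translates to a
    peptide whose motif coverage passes the candidate thresholds.
    """
    out = []
    for rec in records:
        for orf in find_orfs(rec, min_length_nt=min_orf_nt):
            if motif_profile(orf.peptide.rstrip("*"), thresholds,
                             protein_id=rec.id).is_spidroin_candidate:
                out.append(rec.id)
                break
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the summary dict also written to disk.

    Rerunning with the same config and inputs reproduces byte-identical
    TSVs.  On a stage failure, earlier outputs are kept and the manifest
    marks the failed stage.
    """
    config.validate()
    os.makedirs(config.outdir, exist_ok=True)
    out = lambda name: os.path.join(config.outdir, name)  # noqa: E731
    manifest: dict = {"config_hash": config.content_hash(), "seed": config.seed,
                      "stages": {}}
    summary: dict = {}
    t_start = time.time()

    def stage(name):
        def deco(fn):
            t0 = time.time()
            logger.info("stage %s: start", name)
            try:
                rows = fn()
            except Exception as exc:
                manifest["stages"][name] = {"status": "failed", "error": str(exc)}
                _finish(manifest, config, t_start)
                raise
            manifest["stages"][name] = {
                "status": "ok", "rows": rows,
                "seconds": round(time.time() - t0, 3),
            }
            logger.info("stage %s: done (%s rows)", name, rows)
        return deco

    # -- clean ------------------------------------------------------------
    reads = sio.read_sequences(config.reads_path, config.reads_format)
    state: dict = {}

    @stage("clean")
    def _clean():
        kept, rep = clean_reads(reads, CleaningThresholds(
            min_length_nt=config.min_length_nt,
            dust_threshold=config.dust_threshold,
            min_mean_quality=config.min_mean_quality))
        state["kept"] = kept
        sio.write_sequences(kept, out("clean_reads.fasta"))
        summary.update(n_input_reads=rep.n_input, n_short=rep.n_short,
                       n_dust=rep.n_dust, n_low_quality=rep.n_low_quality,
                       n_clean_reads=rep.n_kept, bases_input=rep.bases_input,
                       bases_kept=rep.bases_kept)
        return _write_tsv(out("clean_report.tsv"), ["field", "value"], [
            ("n_input", rep.n_input), ("n_short", rep.n_short),
            ("n_dust", rep.n_dust), ("n_low_quality", rep.n_low_quality),
            ("n_kept", rep.n_kept), ("bases_input", rep.bases_input),
            ("bases_kept", rep.bases_kept)])

    # -- assembly import ---------------------------------------------------
    @stage("assembly")
    def _assembly():
        state["assembly"] = sio.parse_assembly_layout(
            config.consensus_path, config.layout_path,
            dialect=config.layout_dialect, singlets_path=config.singlets_path)
        asm = state["assembly"]
        summary.update(
            n_contigs=len(asm.contigs),
            n_singlets=len(asm.singlets),
            n_reads_clustered=len(asm.layout),
            n_unigenes=unigene_count(summary["n_clean_reads"],
                                     len(asm.layout), len(asm.contigs))
            if config.singlets_path is None else asm.unigene_count,
        )
        return len(asm.layout)

    # -- alignments --------------------------------------------------------
    @stage("align")
    def _align():
        asm = state["assembly"]
        laid = {e.read_id for e in asm.layout}
        # the assembly is authoritative about which reads were clustered:
        # laid-out reads are aligned from the input set even if the cleaning
        # stage would have rejected them under the current thresholds
        assembled = [r for r in reads if r.id in laid]
        missing = laid - {r.id for r in reads}
        if missing:
            raise ValueError(
                f"{len(missing)} laid-out reads absent from the input reads, "
                f"e.g. {sorted(missing)[:3]}")
        if config.read_alignments_path:
            state["read_hsps"] = sio.read_alignment_table(config.read_alignments_path)
        else:
            state["read_hsps"] = batch_align(
                assembled, asm.contigs, AlignParams(),
                mode="reads_to_contigs", layout=asm)
            sio.write_alignment_table(state["read_hsps"], out("reads_vs_contigs.tsv"))
        if config.contig_alignments_path:
            state["contig_hsps"] = sio.read_alignment_table(
                config.contig_alignments_path)
        else:
            state["contig_hsps"] = batch_align(
                asm.contigs, asm.contigs, AlignParams(), mode="all_vs_all")
            sio.write_alignment_table(state["contig_hsps"],
                                      out("contigs_vs_contigs.tsv"))
        state["read_lengths"] = {r.id: len(r.sequence) for r in assembled}
        return len(state["read_hsps"]) + len(state["contig_hsps"])

    # -- consistency -------------------------------------------------------
    @stage("consistency")
    def _consistency():
        rep = consistency_report(state["assembly"], state["read_hsps"],
                                 state["contig_hsps"],
                                 flag_threshold=config.eci_flag_threshold,
                                 read_lengths=state["read_lengths"])
        summary.update(average_ici=round(rep.average_ici, 2),
                       average_eci=round(rep.average_eci, 2),
                       n_no_hit_reads=len(rep.no_hit_reads),
                       n_flagged_contig_pairs=len(rep.flagged_pairs))
        _write_tsv(out("per_read_ici.tsv"), ["read_id", "contig_id", "ici"],
                   [(s.query_id, s.subject_id, f"{s.score:.2f}")
                    for s in rep.per_read_ici])
        _write_tsv(out("per_pair_eci.tsv"), ["query_contig", "subject_contig", "eci"],
                   [(s.query_id, s.subject_id, f"{s.score:.2f}")
                    for s in rep.per_pair_eci])
        _write_tsv(out("flagged_pairs.tsv"), ["contig_a", "contig_b", "eci"],
                   [(a, b, f"{s:.2f}") for a, b, s in rep.flagged_pairs])
        return len(rep.per_read_ici)

    # -- antisense ---------------------------------------------------------
    @stage("antisense")
    def _antisense():
        rep = antisense_report(state["assembly"])
        summary.update(
            n_contigs_with_antisense=rep.n_contigs_with_antisense,
            pct_contigs_with_antisense=round(rep.pct_contigs_with_antisense),
            total_antisense_reads=rep.total_antisense_reads,
            n_tied_contigs=rep.n_tied_contigs)
        return _write_tsv(
            out("antisense_per_contig.tsv"),
            ["contig_id", "n_plus", "n_minus", "majority", "n_antisense", "tied"],
            [(s.contig_id, s.n_plus, s.n_minus, s.majority_strand,
              s.n_antisense, int(s.is_tied)) for s in rep.per_contig])

    # -- ORFs and motifs ---------------------------------------------------
    @stage("orf_motif")
    def _orf_motif():
        asm = state["assembly"]
        unigenes = list(asm.contigs) + list(asm.singlets)
        n_short_orfs = sum(len(find_orfs(u, config.orf_min_short)) for u in unigenes)
        n_long_orfs = sum(len(find_orfs(u, config.orf_min_long)) for u in unigenes)
        candidates = spidroin_candidates(
            unigenes,
            thresholds=MotifThresholds(
                candidate_coverage=config.motif_candidate_coverage))
        summary.update(n_orfs_at_short_cutoff=n_short_orfs,
                       n_orfs_at_long_cutoff=n_long_orfs,
                       n_spidroin_candidates=len(candidates))
        return _write_tsv(out("spidroin_candidates.tsv"), ["unigene_id"],
                          [(c,) for c in candidates])

    _write_tsv(out("summary.tsv"), ["field", "value"],
               sorted(summary.items()))
    _finish(manifest, config, t_start)
    return summary


def _finish(manifest: dict, config: PipelineConfig, t_start: float) -> None:
    manifest["total_seconds"] = round(time.time() - t_start, 3)
    with open(os.path.join(config.outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def kog_ratio_report(annotations_a, annotations_b, threshold: float = 4.0,
                     strong: float = 10.0, outpath: str | None = None):
    """KOG-ratio table plus the expanded-family subset; optionally to TSV."""
    table = kog_ratio_table(annotations_a, annotations_b)
    expanded = expanded_families(table, threshold)
    if outpath:
        _write_tsv(outpath,
                   ["kog_id", "count_a", "count_b", "ratio",
                    "expanded_at_threshold", "expanded_strong"],
                   [(r.kog_id, r.count_a, r.count_b,
                     "inf" if math.isinf(r.ratio) else f"{r.ratio:.3f}",
                     int(r.ratio >= threshold if not math.isinf(r.ratio)
                         else r.count_a >= threshold),
                     int(r.ratio >= strong)) for r in table])
    return table, expanded
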