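"""End-to-end orchestration of the two enrichment pipelines and the final
knockout-aware ranking.

Pipeline A (differential motif enrichment): WT and KO peaks are
independently extended to a uniform width around their summits, sequences
are extracted, and every motif's central enrichment is tested in
differential (Fisher) mode with KO as the negative set.

Pipeline B (differential peak calling): a differentially called peak set —
or, when none is supplied, a labelled locus-subtraction approximation
(WT peaks with zero overlap against KO peaks) — is extended and tested in
non-differential (binomial) mode.

The final step assembles, per motif, A_WT / A_KO from Pipeline A's matched
positive/negative peaks and B from Pipeline B's matched peaks, filters
non-significant motifs, computes r and ranks.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .enrichment import (
    EnrichmentReport,
    ScanConfig,
    scan_enrichment,
    write_report,
)
from .intervals import (
    PeakSet,
    extend_to_uniform,
    read_chrom_sizes,
    read_narrowpeak,
    subtract_all,
    write_bed,
)
from .motifs import read_fasta, read_meme
from .ranking import (
    PeakoInput,
    PeakoRecord,
    numerator_regions,
    records_to_frame,
    score_and_rank,
)

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "ConfigError", "run_pipeline_a", "run_pipeline_b", "run_peako"]


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """File paths and parameters for a full run.

    ``diff_peaks`` may be omitted when ``approximate_diff`` is set, in
    which case Pipeline B uses the locus-subtraction approximation of a
    differential peak set (logged and recorded in the manifest as an
    approximation).
    """

    wt_peaks: Path | None = None
    ko_peaks: Path | None = None
    diff_peaks: Path | None = None
    genome: Path | None = None
    motif_db: Path | None = None
    chrom_sizes: Path | None = None
    outdir: Path = Path("peako_out")
    peak_width: int = 500
    alpha: float = 0.1
    filter_mode: str = "both"
    scan: ScanConfig = field(default_factory=ScanConfig)
    approximate_diff: bool = False
    clip_boundary: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("wt_peaks", "ko_peaks", "diff_peaks", "genome", "motif_db",
                     "chrom_sizes"):
            value = getattr(self, name)
            if value is not None:
                setattr(self, name, Path(value))
        self.outdir = Path(self.outdir)


def _require(cfg: RunConfig, names: list[str]) -> None:
    for name in names:
        path = getattr(cfg, name)
        if path is None:
            raise ConfigError(f"required input {name!r} not configured")
        if not Path(path).exists():
            raise ConfigError(f"{name} path does not exist: {path}")


def _load_chrom_sizes(cfg: RunConfig) -> dict[str, int]:
    if cfg.chrom_sizes is not None:
        return read_chrom_sizes(cfg.chrom_sizes)
    from pyfaidx import Fasta

    fa = Fasta(str(cfg.genome))
    try:
        return {name: len(fa[name]) for name in fa.keys()}
    finally:
        fa.close()


def _load_motifs_and_scan(cfg: RunConfig) -> tuple[list, ScanConfig]:
    motifs, file_bg = read_meme(cfg.motif_db)
    scan = cfg.scan
    if scan.background is None and file_bg is not None:
        scan = dataclasses.replace(scan, background=file_bg)
    scan = dataclasses.replace(scan, alpha=cfg.alpha)
    return motifs, scan


def _safe_name(motif_id: str) -> str:
    return re.sub(r"[^A-Za-z0-9._-]", "_", motif_id)


def _write_matched_beds(report: EnrichmentReport, outdir: Path) -> None:
    peaks_dir = outdir / "matched_peaks"
    peaks_dir.mkdir(parents=True, exist_ok=True)
    for res in report.results:
        write_bed(res.matched_pos_peaks, peaks_dir / f"{_safe_name(res.motif_id)}_pos.bed")
        if res.mode == "fisher":
            write_bed(
                res.matched_neg_peaks, peaks_dir / f"{_safe_name(res.motif_id)}_neg.bed"
            )


def _extend(cfg: RunConfig, records, chrom_sizes, what: str) -> PeakSet:
    peaks = extend_to_uniform(
        records, cfg.peak_width, chrom_sizes, clip=cfg.clip_boundary, label=what
    )
    if len(records) and not len(peaks):
        raise RuntimeError(
            f"all {len(records)} {what} peaks were dropped during uniform "
            f"extension to {cfg.peak_width} bp (chromosome-boundary crossings)"
        )
    return peaks


def run_pipeline_a(cfg: RunConfig, write: bool = True) -> EnrichmentReport:
    """Differential motif enrichment: WT (positive) vs KO (negative)."""
    _require(cfg, ["wt_peaks", "ko_peaks", "genome", "motif_db"])
    chrom_sizes = _load_chrom_sizes(cfg)
    motifs, scan = _load_motifs_and_scan(cfg)

    wt_records = read_narrowpeak(cfg.wt_peaks)
    ko_records = read_narrowpeak(cfg.ko_peaks)
    wt_peaks = _extend(cfg, wt_records, chrom_sizes, "WT")
    ko_peaks = _extend(cfg, ko_records, chrom_sizes, "KO")
    if not len(ko_peaks):
        log.warning("Pipeline A: KO peak set is empty; Fisher test is degenerate")

    pos_seqs = read_fasta(cfg.genome, regions=wt_peaks)
    neg_seqs = read_fasta(cfg.genome, regions=ko_peaks)
    report = scan_enrichment(pos_seqs, neg_seqs, motifs, scan)
    if write:
        outdir = cfg.outdir / "pipeline_a"
        outdir.mkdir(parents=True, exist_ok=True)
        write_report(report, outdir / "report.tsv")
        _write_matched_beds(report, outdir)
    return report


def run_pipeline_b(cfg: RunConfig, write: bool = True) -> EnrichmentReport:
    """Non-differential enrichment on the differential peak set."""
    _require(cfg, ["genome", "motif_db"])
    chrom_sizes = _load_chrom_sizes(cfg)
    motifs, scan = _load_motifs_and_scan(cfg)

    if cfg.diff_peaks is not None:
        _require(cfg, ["diff_peaks"])
        diff_records = read_narrowpeak(cfg.diff_peaks)
    elif cfg.approximate_diff:
        _require(cfg, ["wt_peaks", "ko_peaks"])
        wt_records = read_narrowpeak(cfg.wt_peaks)
        ko_ivs = PeakSet([r.interval for r in read_narrowpeak(cfg.ko_peaks)])
        wt_ivs = PeakSet([r.interval for r in wt_records])
        surviving = {iv.key for iv in subtract_all(wt_ivs, ko_ivs)}
        diff_records = [r for r in wt_records if r.interval.key in surviving]
        log.warning(
            "Pipeline B: using locus-subtraction APPROXIMATION of a "
            "differential peak set (%d of %d WT peaks); a differentially "
            "called set (e.g. from MACS2 with the KO as control) is the "
            "intended input",
            len(diff_records),
            len(wt_records),
        )
    else:
        raise ConfigError(
            "Pipeline B needs diff_peaks (a differentially called peak set, "
            "e.g. MACS2 with the KO dataset as control) or "
            "approximate_diff=True to derive one by locus subtraction"
        )

    if not diff_records:
        log.warning("Pipeline B: differential peak set is empty; empty report")
        return EnrichmentReport(results=[], n_tests=0, mode="binomial")

    diff_peaks = _extend(cfg, diff_records, chrom_sizes, "DIFF")
    pos_seqs = read_fasta(cfg.genome, regions=diff_peaks)
    report = scan_enrichment(pos_seqs, None, motifs, scan)
    if write:
        outdir = cfg.outdir / "pipeline_b"
        outdir.mkdir(parents=True, exist_ok=True)
        write_report(report, outdir / "report.tsv")
        _write_matched_beds(report, outdir)
    return report


def assemble_inputs(
    report_a: EnrichmentReport, report_b: EnrichmentReport
) -> list[PeakoInput]:
    """Join the two reports into per-motif score inputs.

    A motif present in only one report keeps an empty peak set and a
    ``None`` significance value on the missing side (treated as
    non-significant by the filter).
    """
    ids = sorted(
        {res.motif_id for res in report_a.results}
        | {res.motif_id for res in report_b.results}
    )
    inputs = []
    for motif_id in ids:
        res_a = report_a.get(motif_id)
        res_b = report_b.get(motif_id)
        if res_a is None or res_b is None:
            log.info("motif %s present in only one pipeline report", motif_id)
        inputs.append(
            PeakoInput(
                motif_id=motif_id,
                a_wt=res_a.matched_pos_peaks if res_a else PeakSet(),
                a_ko=res_a.matched_neg_peaks if res_a else PeakSet(),
                b=res_b.matched_pos_peaks if res_b else PeakSet(),
                e_value_a=res_a.e_value if res_a else None,
                e_value_b=res_b.e_value if res_b else None,
                corrected_p_a=res_a.corrected_p if res_a else None,
                corrected_p_b=res_b.corrected_p if res_b else None,
            )
        )
    return inputs


def run_peako(
    cfg: RunConfig,
    report_a: EnrichmentReport | None = None,
    report_b: EnrichmentReport | None = None,
) -> list[PeakoRecord]:
    """Full run: both pipelines, then filter, score and rank by r.

    Writes ``peako.tsv`` (the master ranking), per-motif numerator-region
    BED files, and a JSON run manifest under ``cfg.outdir``.
    """
    cfg.outdir.mkdir(parents=True, exist_ok=True)
    if report_a is None:
        report_a = run_pipeline_a(cfg)
    if report_b is None:
        report_b = run_pipeline_b(cfg)

    inputs = assemble_inputs(report_a, report_b)
    records = score_and_rank(inputs, alpha=cfg.alpha, mode=cfg.filter_mode)

    records_to_frame(records).to_csv(cfg.outdir / "peako.tsv", sep="\t", index=False)
    regions_dir = cfg.outdir / "numerator_regions"
    regions_dir.mkdir(parents=True, exist_ok=True)
    by_id = {inp.motif_id: inp for inp in inputs}
    for rec in records:
        inp = by_id[rec.motif_id]
        write_bed(
            numerator_regions(inp.a_wt, inp.a_ko, inp.b),
            regions_dir / f"{_safe_name(rec.motif_id)}.bed",
        )

    manifest = {
        "peako_version": __version__,
        "seed": cfg.seed,
        "peak_width": cfg.peak_width,
        "alpha": cfg.alpha,
        "filter_mode": cfg.filter_mode,
        "scan": {
            "pseudocount": cfg.scan.pseudocount,
            "min_score": cfg.scan.min_score,
            "max_window": cfg.scan.max_window,
            "correction": cfg.scan.correction,
        },
        "approximate_diff": cfg.approximate_diff and cfg.diff_peaks is None,
        "paths": {
            name: str(getattr(cfg, name)) if getattr(cfg, name) is not None else None
            for name in ("wt_peaks", "ko_peaks", "diff_peaks", "genome", "motif_db")
        },
        "n_motifs_ranked": len(records),
        "n_tests_a": report_a.n_tests,
        "n_tests_b": report_b.n_tests,
    }
    with open(cfg.outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return records
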