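"""End-to-end orchestration: simulate or load → DE → classify → assign →
motif join → summaries → report bundle.

Each stage consumes and emits the standard on-disk formats, so the stages
are independently runnable from the CLI; this module wires them together,
stamps every output with the tool version, seed and a config hash, and
enforces the two arithmetic identities (peak-class partition and
activated + repressed = associated) before anything is reported.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .diffexpr import (
    FOLD_PRESETS,
    Thresholds,
    de_table,
    threshold_sets,
    venn,
    write_de_table,
)
from .genome_io import (
    CountMatrix,
    GenomeAnnotation,
    Peak,
    SampleSheet,
    read_annotation,
    read_counts,
    read_fasta,
    read_peaks,
)
from .motif import DEFAULT_CONSENSUS, DEFAULT_MIN_MATCHES, MotifConsensus, match_count, scan, write_hits_bed
from .regulon import (
    DEFAULT_MAX_DISTANCE,
    RegulonSummary,
    assign_peaks,
    classify_peaks,
    summarize_regulon,
    write_regulon_table,
    write_summary_json,
)
from .synthetic import SimulationParams, SyntheticDataset, simulate_dataset, write_dataset

logger = logging.getLogger(__name__)

#: DE contrasts the pipeline computes. The gate contrast for the regulon
#: table defaults to the pooled mutant-vs-WT comparison (all samples of
#: each genotype); the per-condition contrasts feed the Venn reports.
CONTRASTS = ("pooled", "glucose", "limitation")


@dataclass
class PipelineConfig:
    """Inputs, gates and outputs of one pipeline run.

    Either ``simulation`` or the four real-input paths (annotation, peaks,
    counts, sheet) must be set. ``fasta_path`` is optional for real inputs;
    without it the motif join is skipped.
    """

    outdir: str | Path = "regulon_out"
    seed: int = 0
    simulation: SimulationParams | None = None
    annotation_path: str | Path | None = None
    peaks_path: str | Path | None = None
    counts_path: str | Path | None = None
    sheet_path: str | Path | None = None
    fasta_path: str | Path | None = None
    thresholds: Thresholds = field(default_factory=Thresholds)
    max_distance: int = DEFAULT_MAX_DISTANCE
    consensus: str = DEFAULT_CONSENSUS
    min_matches: int = DEFAULT_MIN_MATCHES
    gate_contrast: str = "pooled"

    def __post_init__(self) -> None:
        real = [self.annotation_path, self.peaks_path, self.counts_path, self.sheet_path]
        if self.simulation is None and any(p is None for p in real):
            raise ValueError(
                "config needs either a simulation block or all of "
                "annotation/peaks/counts/sheet paths"
            )
        if self.gate_contrast not in CONTRASTS:
            raise ValueError(f"gate_contrast must be one of {CONTRASTS}")

    def hash(self) -> str:
        """Short digest of the analysis parameters (output location excluded)."""
        payload = dataclasses.asdict(self)
        payload.pop("outdir", None)
        payload = json.loads(json.dumps(payload, default=str, sort_keys=True))
        digest = hashlib.sha256(json.dumps(payload, sort_keys=True).encode())
        return digest.hexdigest()[:12]


@dataclass
class PipelineResult:
    """In-memory bundle of everything one run produced."""

    config: PipelineConfig
    annotation: GenomeAnnotation
    peaks: list[Peak]
    counts: CountMatrix
    sheet: SampleSheet
    de_tables: dict[str, pd.DataFrame]
    regulon: pd.DataFrame
    summary: RegulonSummary
    report_text: str
    report: dict
    dataset: SyntheticDataset | None = None
    output_paths: dict[str, Path] = field(default_factory=dict)


def _contrast_groups(
    sheet: SampleSheet, contrast: str
) -> tuple[list[str], list[str]]:
    """(WT, mutant) sample groups for a named contrast."""
    condition = None if contrast == "pooled" else contrast
    return (
        sheet.samples(genotype="WT", condition=condition),
        sheet.samples(genotype="mutant", condition=condition),
    )


def _best_motif_matches(
    peaks: list[Peak], sequences: dict[str, str], consensus: MotifConsensus
) -> dict[str, int]:
    """Best window match count inside each peak interval (0 if too short)."""
    best: dict[str, int] = {}
    for peak in peaks:
        seq = sequences.get(peak.contig, "")[peak.start : peak.end]
        if len(seq) < len(consensus):
            best[peak.peak_id] = 0
            continue
        hits = scan(seq, consensus, min_matches=0, dedupe_mirrors=True)
        best[peak.peak_id] = max(h.match_count for h in hits)
    return best


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run every stage and write the report bundle under ``config.outdir``.

    Writes (when applicable): the simulated dataset files, one DE TSV per
    contrast, the regulon table TSV, motif hits BED, summary JSON and a
    plain-text report. Outputs are byte-stable for a fixed config + seed.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stamp = [
        f"regulonkit {__version__}",
        f"config_hash={config.hash()}",
        f"seed={config.seed}",
    ]
    paths: dict[str, Path] = {}
    dataset = None

    if config.simulation is not None:
        params = dataclasses.replace(config.simulation, seed=config.seed)
        dataset = simulate_dataset(params, consensus=config.consensus)
        paths.update(write_dataset(dataset, outdir))
        annotation, peaks = dataset.annotation, dataset.peaks
        counts, sheet = dataset.counts, dataset.sheet
        sequences = dataset.sequences
    else:
        annotation = read_annotation(config.annotation_path)
        peaks = read_peaks(config.peaks_path)
        counts, sheet = read_counts(config.counts_path, config.sheet_path)
        sequences = read_fasta(config.fasta_path) if config.fasta_path else {}

    de_tables: dict[str, pd.DataFrame] = {}
    for contrast in CONTRASTS:
        wt, mut = _contrast_groups(sheet, contrast)
        if not wt or not mut:
            logger.warning("contrast %s has an empty group; skipped", contrast)
            continue
        table = de_tables[contrast] = de_table(
            counts, wt, mut, thresholds=config.thresholds
        )
        path = paths[f"de_{contrast}"] = outdir / f"de_{contrast}.tsv"
        write_de_table(table, path, header_lines=stamp + [f"contrast={contrast}"])

    peak_classes = classify_peaks(peaks, annotation)
    gate_table = de_tables[config.gate_contrast]
    regulon = assign_peaks(
        peaks,
        gate_table,
        annotation,
        max_distance=config.max_distance,
        thresholds=config.thresholds,
        peak_classes=peak_classes,
    )

    consensus = MotifConsensus(config.consensus)
    if sequences:
        best = _best_motif_matches(peaks, sequences, consensus)
        direct = regulon["status"] == "direct"
        regulon["motif_best_match"] = pd.array(
            [
                best[pid] if isinstance(pid, str) else pd.NA
                for pid in regulon["peak_id"]
            ],
            dtype="Int64",
        )
        regulon["motif_hit"] = regulon["motif_best_match"] >= config.min_matches
        regulon.loc[~direct, "motif_hit"] = pd.NA

        all_hits = []
        for contig, seq in sequences.items():
            for h in scan(seq, consensus, min_matches=config.min_matches):
                all_hits.append((contig, h))
        paths["hits_bed"] = outdir / "motif_hits.bed"
        with open(paths["hits_bed"], "w") as fh:
            for contig, h in all_hits:
                fh.write(
                    f"{contig}\t{h.position}\t{h.position + len(consensus)}\t"
                    f"{h.match_count}\t{h.match_count}\t{h.strand}\n"
                )

    summary = summarize_regulon(peak_classes, regulon)
    paths["regulon"] = outdir / "regulon.tsv"
    write_regulon_table(regulon, paths["regulon"], header_lines=stamp)

    report_text, report = make_report(summary, de_tables, regulon, config)
    paths["summary"] = outdir / "summary.json"
    write_summary_json(summary, paths["summary"], extra={"config_hash": config.hash(), "seed": config.seed})
    paths["report_txt"] = outdir / "report.txt"
    Path(paths["report_txt"]).write_text(report_text)
    paths["report_json"] = outdir / "report.json"
    Path(paths["report_json"]).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")

    return PipelineResult(
        config=config,
        annotation=annotation,
        peaks=peaks,
        counts=counts,
        sheet=sheet,
        de_tables=de_tables,
        regulon=regulon,
        summary=summary,
        report_text=report_text,
        report=report,
        dataset=dataset,
        output_paths=paths,
    )


def make_report(
    summary: RegulonSummary,
    de_tables: dict[str, pd.DataFrame],
    regulon: pd.DataFrame,
    config: PipelineConfig | None = None,
) -> tuple[str, dict]:
    """Assemble the plain-text report and its JSON twin.

    Reports DE set sizes at the 2/4/5-fold presets per contrast, Venn
    overlaps between the two condition contrasts, peak-class counts and the
    associated/activated/repressed tally. Violated identities raise —
    never a silent report.
    """
    if summary.n_intergenic + summary.n_intragenic + summary.n_spanning != summary.n_peaks_total:
        raise ValueError("peak class partition identity violated")
    if summary.n_activated + summary.n_repressed != summary.n_associated_genes:
        raise ValueError("direction identity violated")

    alpha = config.thresholds.alpha if config else 0.05
    payload: dict = {"summary": summary.to_dict(), "de_sets": {}, "venn": {}}
    lines = ["# regulon pipeline report", ""]
    if config is not None:
        lines += [f"version: {__version__}", f"seed: {config.seed}",
                  f"config_hash: {config.hash()}", ""]
    lines.append("## differential expression set sizes (lower/higher in mutant)")
    for contrast, table in de_tables.items():
        payload["de_sets"][contrast] = {}
        for fold in FOLD_PRESETS:
            thr = Thresholds(fold=fold, alpha=alpha)
            lower, higher = threshold_sets(table, thr)
            payload["de_sets"][contrast][f"{fold:g}"] = {
                "lower": len(lower), "higher": len(higher),
            }
            lines.append(
                f"  {contrast:<11} {fold:>3g}-fold: {len(lower):>4} lower, "
                f"{len(higher):>4} higher"
            )
    if "glucose" in de_tables and "limitation" in de_tables:
        lines += ["", "## Venn overlaps, glucose vs limitation contrasts"]
        for fold in FOLD_PRESETS:
            thr = Thresholds(fold=fold, alpha=alpha)
            overlaps = venn(
                threshold_sets(de_tables["glucose"], thr),
                threshold_sets(de_tables["limitation"], thr),
            )
            payload["venn"][f"{fold:g}"] = {
                d: dataclasses.asdict(v) for d, v in overlaps.items()
            }
            for direction, v in overlaps.items():
                lines.append(
                    f"  {fold:>3g}-fold {direction:<6}: glucose-only {v.a_only}, "
                    f"limitation-only {v.b_only}, both {v.both}"
                )
    lines += [
        "",
        "## peak classification",
        f"  total peaks      : {summary.n_peaks_total}",
        f"  intergenic       : {summary.n_intergenic}",
        f"  intragenic       : {summary.n_intragenic}",
        f"  spanning         : {summary.n_spanning}",
        "  partition check  : "
        f"{summary.n_intergenic} + {summary.n_intragenic} + {summary.n_spanning} "
        f"= {summary.n_peaks_total}",
        "",
        "## direct regulon",
        f"  associated genes : {summary.n_associated_genes}",
        f"  activated        : {summary.n_activated}",
        f"  repressed        : {summary.n_repressed}",
        "  direction check  : "
        f"{summary.n_activated} + {summary.n_repressed} = {summary.n_associated_genes}",
        f"  indirect (no peak within range): {summary.n_indirect_genes}",
        "",
        "## peaks not associated with expression changes",
    ]
    for cls, n in summary.n_unassociated_peaks.items():
        lines.append(f"  {cls:<10}: {n}")
    return "\n".join(lines) + "\n", payload
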