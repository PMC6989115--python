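"""Peak classification, peak-to-gene assignment, and the direct-regulon table.

This is the pipeline's bespoke step: each ChIP peak is classified against
the union of annotated gene intervals (intragenic when every base lies in a
gene, intergenic when none does, spanning otherwise), and peaks are then
attached to differentially expressed genes lying within a distance cutoff
(default 500 bp, edge-to-edge). One peak may attach to several nearby
genes. A gene passing the expression gates with no attached peak is kept
and flagged as an indirect target — differentially expressed, but with no
evidence of nearby binding.

Strand plays no role in classification or assignment; the relative
orientation of each peak-gene pair is reported for downstream filtering.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .diffexpr import Thresholds
from .genome_io import Gene, GenomeAnnotation, Peak

#: Assignment radius, in bp, between a peak edge and a gene edge.
DEFAULT_MAX_DISTANCE = 500


class PeakClass(enum.Enum):
    INTERGENIC = "intergenic"
    INTRAGENIC = "intragenic"
    SPANNING = "spanning"


def _merged_overlaps(genes: Sequence[Gene], start: int, end: int) -> list[tuple[int, int]]:
    """Union of gene intervals clipped to [start, end), merged and sorted."""
    clipped = sorted((max(g.start, start), min(g.end, end)) for g in genes)
    merged: list[tuple[int, int]] = []
    for s, e in clipped:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def classify_peak(peak: Peak, annotation: GenomeAnnotation) -> PeakClass:
    """Classify a peak as intergenic, intragenic, or spanning.

    Intragenic means every base of the peak overlaps at least one annotated
    gene (the union of genes, so a peak inside two overlapping genes still
    counts); intergenic means no base does; anything else spans both region
    types. Raises on a contig the annotation does not know.
    """
    if peak.contig not in annotation.contigs:
        raise ValueError(f"peak {peak.peak_id}: unknown contig {peak.contig!r}")
    genes = annotation.overlapping(peak.contig, peak.start, peak.end)
    if not genes:
        return PeakClass.INTERGENIC
    merged = _merged_overlaps(genes, peak.start, peak.end)
    covered = merged[0][0] <= peak.start and merged[-1][1] >= peak.end and all(
        merged[i][1] >= merged[i + 1][0] for i in range(len(merged) - 1)
    )
    return PeakClass.INTRAGENIC if covered else PeakClass.SPANNING


def classify_peaks(
    peaks: Iterable[Peak], annotation: GenomeAnnotation
) -> dict[str, PeakClass]:
    """Classify every peak; returns {peak_id: PeakClass}."""
    return {p.peak_id: classify_peak(p, annotation) for p in peaks}


def peak_gene_distance(peak: Peak, gene: Gene, use_summit: bool = False) -> int | None:
    """Distance in bp between a peak and a gene; None across contigs.

    Zero when the intervals overlap, else the gap between the nearest edges
    under half-open coordinates (gene [1000,2000) to peak [2400,2600) is
    400). With ``use_summit`` the peak is collapsed to its 1-bp summit
    before measuring.
    """
    if peak.contig != gene.contig:
        return None
    p_start, p_end = (
        (peak.summit, peak.summit + 1) if use_summit else (peak.start, peak.end)
    )
    if p_start < gene.end and gene.start < p_end:
        return 0
    if p_start >= gene.end:
        return p_start - gene.end
    return gene.start - p_end


def _orientation(peak: Peak, gene: Gene) -> str:
    """Peak position relative to the gene's transcription direction."""
    if peak.start < gene.end and gene.start < peak.end:
        return "overlapping"
    downstream_side = peak.start >= gene.end
    if gene.strand == "-":
        downstream_side = not downstream_side
    return "downstream" if downstream_side else "upstream"


REGULON_COLUMNS = [
    "gene_id", "direction", "log2fc", "p_adj", "status",
    "peak_id", "peak_class", "distance_bp", "orientation",
]


def assign_peaks(
    peaks: Sequence[Peak],
    de_results: pd.DataFrame,
    annotation: GenomeAnnotation,
    max_distance: int = DEFAULT_MAX_DISTANCE,
    thresholds: Thresholds = Thresholds(),
    use_summit: bool = False,
    peak_classes: Mapping[str, PeakClass] | None = None,
) -> pd.DataFrame:
    """Build the regulon table: gated genes joined to nearby peaks.

    A gene enters the table when p_adj < alpha and |log2fc| ≥ log2(fold);
    its direction is ``activated`` when expression is lower in the
    regulator-null mutant (log2fc ≤ −log2(fold)) and ``repressed`` when
    higher. Every peak within ``max_distance`` bp attaches (one row per
    peak-gene pair; a peak may appear under several genes). Gated genes
    with no peak in range get a single row with status ``indirect`` and
    empty peak fields.
    """
    missing = [g.gene_id for g in annotation if g.gene_id not in de_results.index]
    if missing:
        raise ValueError(
            f"DE results missing {len(missing)} annotated genes (e.g. {missing[:3]})"
        )
    if peak_classes is None:
        peak_classes = classify_peaks(peaks, annotation)

    trees: dict[str, IntervalTree] = {}
    for p in peaks:
        trees.setdefault(p.contig, IntervalTree()).addi(p.start, p.end, p)

    gate = np.log2(thresholds.fold)
    rows: list[dict] = []
    for gene in annotation:
        lfc = float(de_results.at[gene.gene_id, "log2fc"])
        padj = float(de_results.at[gene.gene_id, "p_adj"])
        if padj >= thresholds.alpha or abs(lfc) < gate:
            continue
        direction = "activated" if lfc < 0 else "repressed"
        tree = trees.get(gene.contig)
        nearby: list[tuple[int, Peak]] = []
        if tree is not None:
            for iv in tree.overlap(gene.start - max_distance, gene.end + max_distance):
                d = peak_gene_distance(iv.data, gene, use_summit=use_summit)
                if d is not None and d <= max_distance:
                    nearby.append((d, iv.data))
        if nearby:
            nearby.sort(key=lambda t: (t[0], t[1].start, t[1].peak_id))
            for d, peak in nearby:
                rows.append(
                    {
                        "gene_id": gene.gene_id,
                        "direction": direction,
                        "log2fc": lfc,
                        "p_adj": padj,
                        "status": "direct",
                        "peak_id": peak.peak_id,
                        "peak_class": peak_classes[peak.peak_id].value,
                        "distance_bp": d,
                        "orientation": _orientation(peak, gene),
                    }
                )
        else:
            rows.append(
                {
                    "gene_id": gene.gene_id,
                    "direction": direction,
                    "log2fc": lfc,
                    "p_adj": padj,
                    "status": "indirect",
                    "peak_id": pd.NA,
                    "peak_class": pd.NA,
                    "distance_bp": pd.NA,
                    "orientation": pd.NA,
                }
            )
    return pd.DataFrame(rows, columns=REGULON_COLUMNS)


@dataclass(frozen=True)
class RegulonSummary:
    """Counts over the classified peak set and the direct-regulon table.

    Invariants (enforced on construction): the class counts partition the
    peak total, and activated + repressed = associated genes.
    """

    n_peaks_total: int
    n_intergenic: int
    n_intragenic: int
    n_spanning: int
    n_associated_genes: int
    n_activated: int
    n_repressed: int
    n_indirect_genes: int
    n_unassociated_peaks: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_intergenic + self.n_intragenic + self.n_spanning != self.n_peaks_total:
            raise ValueError("peak class counts do not partition the total")
        if self.n_activated + self.n_repressed != self.n_associated_genes:
            raise ValueError("activated + repressed != associated genes")

    def to_dict(self) -> dict:
        return asdict(self)


def summarize_regulon(
    peak_classes: Mapping[str, PeakClass], regulon: pd.DataFrame
) -> RegulonSummary:
    """Summarize classification and assignment into the headline counts.

    ``n_associated_genes`` counts genes with ≥1 attached peak (direct
    targets); unassociated peaks are reported per class — binding with no
    accompanying expression change at the gates.
    """
    direct = regulon[regulon["status"] == "direct"] if len(regulon) else regulon
    table_peaks = set() if len(regulon) == 0 else set(direct["peak_id"])
    unknown = table_peaks - set(peak_classes)
    if unknown:
        raise ValueError(f"regulon table references unclassified peaks: {sorted(unknown)[:5]}")

    class_counts = {cls: 0 for cls in PeakClass}
    for cls in peak_classes.values():
        class_counts[cls] += 1
    associated = (
        direct.groupby("gene_id")["direction"].first() if len(direct) else pd.Series(dtype=object)
    )
    unassoc = {cls.value: 0 for cls in PeakClass}
    for peak_id, cls in peak_classes.items():
        if peak_id not in table_peaks:
            unassoc[cls.value] += 1
    n_indirect = (
        regulon.loc[regulon["status"] == "indirect", "gene_id"].nunique()
        if len(regulon)
        else 0
    )
    return RegulonSummary(
        n_peaks_total=len(peak_classes),
        n_intergenic=class_counts[PeakClass.INTERGENIC],
        n_intragenic=class_counts[PeakClass.INTRAGENIC],
        n_spanning=class_counts[PeakClass.SPANNING],
        n_associated_genes=int(len(associated)),
        n_activated=int((associated == "activated").sum()),
        n_repressed=int((associated == "repressed").sum()),
        n_indirect_genes=int(n_indirect),
        n_unassociated_peaks=unassoc,
    )


def write_regulon_table(
    regulon: pd.DataFrame, path: str | Path, header_lines: Iterable[str] = ()
) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        regulon.to_csv(fh, sep="\t", index=False)


def write_summary_json(summary: RegulonSummary, path: str | Path, extra: dict | None = None) -> None:
    payload = summary.to_dict()
    if extra:
        payload = {**payload, **extra}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
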