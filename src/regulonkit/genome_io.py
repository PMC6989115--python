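"""On-disk formats and the shared coordinate model.

Everything downstream works in 0-based half-open coordinates on named
contigs. GFF3 (1-based, end-inclusive) is converted on read and write;
narrowPeak intervals pass through unchanged because the format is already
0-based half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from gffutils.feature import feature_from_line
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

NARROWPEAK_COLUMNS = [
    "contig", "start", "end", "peak_id", "display_score",
    "strand", "score", "pvalue_neglog10", "qvalue_neglog10", "summit_offset",
]


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class Gene:
    """A named, stranded interval on a contig (0-based half-open)."""

    gene_id: str
    contig: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"gene {self.gene_id}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Peak:
    """A ChIP peak interval with summit offset and enrichment score."""

    peak_id: str
    contig: str
    start: int
    end: int
    summit_offset: int
    score: float = 0.0
    qvalue_neglog10: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"peak {self.peak_id}: invalid interval [{self.start}, {self.end})"
            )
        if not 0 <= self.summit_offset < self.end - self.start:
            raise ValueError(
                f"peak {self.peak_id}: summit offset {self.summit_offset} outside peak"
            )
        if self.score < 0:
            raise ValueError(f"peak {self.peak_id}: negative score")

    @property
    def summit(self) -> int:
        """Absolute summit position on the contig."""
        return self.start + self.summit_offset

    def __len__(self) -> int:
        return self.end - self.start


class GenomeAnnotation:
    """An ordered gene set queryable by interval overlap.

    Parameters
    ----------
    genes
        Genes in any order; order is preserved. gene_ids must be unique.
    contig_lengths
        Optional contig → length map. When given, every gene must lie
        within its contig.
    """

    def __init__(
        self,
        genes: Iterable[Gene],
        contig_lengths: Mapping[str, int] | None = None,
    ) -> None:
        self.genes: tuple[Gene, ...] = tuple(genes)
        self.contig_lengths: dict[str, int] = dict(contig_lengths or {})
        seen: dict[str, Gene] = {}
        for g in self.genes:
            if g.gene_id in seen:
                raise ValueError(f"duplicate gene ID {g.gene_id!r}")
            seen[g.gene_id] = g
            if self.contig_lengths:
                length = self.contig_lengths.get(g.contig)
                if length is None:
                    raise ValueError(
                        f"gene {g.gene_id}: contig {g.contig!r} has no recorded length"
                    )
                if g.end > length:
                    raise ValueError(
                        f"gene {g.gene_id}: end {g.end} exceeds contig length {length}"
                    )
        self._by_id = seen
        self._trees: dict[str, IntervalTree] = {}
        for g in self.genes:
            self._trees.setdefault(g.contig, IntervalTree()).addi(g.start, g.end, g)

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[Gene]:
        return iter(self.genes)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    @property
    def contigs(self) -> set[str]:
        return set(self._trees) | set(self.contig_lengths)

    def by_id(self, gene_id: str) -> Gene:
        return self._by_id[gene_id]

    def overlapping(self, contig: str, start: int, end: int) -> list[Gene]:
        """Genes overlapping [start, end) on ``contig``, in position order."""
        tree = self._trees.get(contig)
        if tree is None:
            return []
        hits = [iv.data for iv in tree.overlap(start, end)]
        hits.sort(key=lambda g: (g.start, g.end, g.gene_id))
        return hits


class CountMatrix:
    """Gene × sample integer counts, backed by a pandas DataFrame."""

    def __init__(self, counts: pd.DataFrame) -> None:
        if counts.index.has_duplicates or counts.columns.has_duplicates:
            raise ValueError("duplicate gene or sample IDs in count matrix")
        values = counts.to_numpy()
        if not pd.api.types.is_integer_dtype(counts.dtypes.iloc[0]) or not all(
            pd.api.types.is_integer_dtype(dt) for dt in counts.dtypes
        ):
            raise FormatError("count matrix must be all-integer")
        if (values < 0).any():
            raise FormatError("count matrix contains negative values")
        counts = counts.rename_axis(index="gene_id", columns=None)
        self.counts = counts

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape


class SampleSheet:
    """Per-sample genotype / condition / replicate labels.

    Genotype ∈ {WT, mutant} and condition ∈ {glucose, limitation}; the frame
    is indexed by sample_id.
    """

    GENOTYPES = ("WT", "mutant")
    CONDITIONS = ("glucose", "limitation")

    def __init__(self, frame: pd.DataFrame) -> None:
        required = {"genotype", "condition", "replicate"}
        missing = required - set(frame.columns)
        if missing:
            raise FormatError(f"sample sheet is missing columns: {sorted(missing)}")
        if frame.index.has_duplicates:
            raise FormatError("sample sheet lists a sample more than once")
        bad_gt = set(frame["genotype"]) - set(self.GENOTYPES)
        if bad_gt:
            raise FormatError(f"unknown genotypes {sorted(bad_gt)}")
        bad_cond = set(frame["condition"]) - set(self.CONDITIONS)
        if bad_cond:
            raise FormatError(f"unknown conditions {sorted(bad_cond)}")
        self.frame = frame

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    def samples(
        self, genotype: str | None = None, condition: str | None = None
    ) -> list[str]:
        """Sample IDs matching the given labels (None = no constraint)."""
        mask = pd.Series(True, index=self.frame.index)
        if genotype is not None:
            mask &= self.frame["genotype"] == genotype
        if condition is not None:
            mask &= self.frame["condition"] == condition
        return list(self.frame.index[mask])


# ---------------------------------------------------------------------------
# GFF3


def read_annotation(
    path: str | Path,
    feature_type: str = "gene",
    contig_lengths: Mapping[str, int] | None = None,
) -> GenomeAnnotation:
    """Read a GFF3 file into a :class:`GenomeAnnotation`.

    Only features of ``feature_type`` are kept (the classification contract
    is against annotated genes, not their CDS parts; override for
    annotations that label coding features differently). Coordinates are
    converted from GFF3's 1-based inclusive convention to 0-based half-open.
    ``##sequence-region`` pragmas populate contig lengths when present.
    """
    genes: list[Gene] = []
    lengths: dict[str, int] = dict(contig_lengths or {})
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if line.startswith("##sequence-region"):
                parts = line.split()
                if len(parts) >= 4:
                    lengths[parts[1]] = int(parts[3])
                continue
            if not line or line.startswith("#"):
                continue
            feature = feature_from_line(line)
            if feature.featuretype != feature_type:
                continue
            ids = feature.attributes.get("ID")
            if not ids:
                raise FormatError(
                    f"{path}:{lineno}: {feature_type} feature has no ID attribute"
                )
            if feature.end < feature.start:
                raise FormatError(
                    f"{path}:{lineno}: end ({feature.end}) < start ({feature.start})"
                )
            genes.append(
                Gene(
                    gene_id=ids[0],
                    contig=feature.seqid,
                    start=feature.start - 1,
                    end=feature.end,
                    strand=feature.strand if feature.strand in "+-" else "+",
                )
            )
    try:
        return GenomeAnnotation(genes, contig_lengths=lengths or None)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_annotation(
    annotation: GenomeAnnotation,
    path: str | Path,
    feature_type: str = "gene",
    source: str = "regulonkit",
) -> None:
    """Write a GFF3 file (1-based inclusive on disk)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for contig in sorted(annotation.contig_lengths):
            fh.write(
                f"##sequence-region {contig} 1 {annotation.contig_lengths[contig]}\n"
            )
        for g in annotation.genes:
            fh.write(
                "\t".join(
                    [
                        g.contig, source, feature_type,
                        str(g.start + 1), str(g.end),
                        ".", g.strand, ".", f"ID={g.gene_id}",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# narrowPeak


def read_peaks(path: str | Path) -> list[Peak]:
    """Read an ENCODE narrowPeak (BED6+4) file.

    A summit offset of −1 (summit unknown) is replaced by the interval
    midpoint, with a logged note.
    """
    try:
        frame = pd.read_csv(
            path, sep="\t", header=None, comment="#", dtype={0: str, 3: str},
            float_precision="round_trip",
        )
    except pd.errors.EmptyDataError:
        return []
    if frame.shape[1] < 10:
        raise FormatError(
            f"{path}: narrowPeak requires 10 columns, found {frame.shape[1]}"
        )
    frame = frame.iloc[:, :10]
    frame.columns = NARROWPEAK_COLUMNS
    peaks: list[Peak] = []
    for row in frame.itertuples(index=False):
        start, end = int(row.start), int(row.end)
        if start >= end:
            raise FormatError(
                f"{path}: peak {row.peak_id}: start {start} >= end {end}"
            )
        summit = int(row.summit_offset)
        if summit == -1:
            summit = (end - start) // 2
            logger.info(
                "peak %s: summit unknown (-1); using interval midpoint", row.peak_id
            )
        peaks.append(
            Peak(
                peak_id=str(row.peak_id),
                contig=str(row.contig),
                start=start,
                end=end,
                summit_offset=summit,
                score=float(row.score),
                qvalue_neglog10=float(row.qvalue_neglog10),
            )
        )
    return peaks


def write_peaks(peaks: Iterable[Peak], path: str | Path) -> None:
    """Write peaks as ENCODE narrowPeak."""
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(
                "\t".join(
                    [
                        p.contig, str(p.start), str(p.end), p.peak_id,
                        "0", ".", repr(p.score), "-1",
                        repr(p.qvalue_neglog10), str(p.summit_offset),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# counts + sample sheet


def read_counts(
    counts_path: str | Path, sheet_path: str | Path
) -> tuple[CountMatrix, SampleSheet]:
    """Read a gene × sample count TSV and its sample sheet.

    The first counts column is the gene ID; sample order is taken from the
    counts header. Every sample must appear in the sheet.
    """
    frame = pd.read_csv(counts_path, sep="\t", index_col=0)
    values = frame.to_numpy()
    if not np.issubdtype(values.dtype, np.integer):
        rounded = np.round(values.astype(float))
        if np.isnan(values.astype(float)).any() or not (values == rounded).all():
            raise FormatError(f"{counts_path}: count matrix contains non-integer values")
        frame = frame.astype("int64")
    matrix = CountMatrix(frame)

    sheet_frame = pd.read_csv(sheet_path, sep="\t", index_col=0)
    sheet = SampleSheet(sheet_frame)
    missing = set(matrix.sample_ids) - set(sheet.sample_ids)
    if missing:
        raise FormatError(
            f"{sheet_path}: samples missing from sheet: {sorted(missing)}"
        )
    # keep the sheet in counts-header order
    sheet = SampleSheet(sheet_frame.loc[matrix.sample_ids])
    return matrix, sheet


def write_counts(
    matrix: CountMatrix, sheet: SampleSheet, counts_path: str | Path,
    sheet_path: str | Path,
) -> None:
    matrix.counts.rename_axis("gene_id").to_csv(counts_path, sep="\t")
    sheet.frame.rename_axis("sample_id").to_csv(sheet_path, sep="\t")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into {contig: uppercase sequence}."""
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")
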