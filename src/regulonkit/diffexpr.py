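"""Differential expression: normalization, fold changes, ANOVA p-values, FDR.

A deliberately transparent two-group analysis: median-of-ratios size
factors, log2 fold changes of pseudocounted normalized means, a one-way
two-group ANOVA (equivalently a pooled-variance t test) on
log2(normalized count + pseudocount), and Benjamini-Hochberg adjustment.
This replaces a full negative-binomial DE model on purpose — the pipeline's
contracts (threshold sets, Venn overlaps, the regulon gate) only need a
deterministic, self-contained test, and results on real deposited data will
differ from tables produced with shrinkage-based tools.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genome_io import CountMatrix

logger = logging.getLogger(__name__)

#: Fold-change gates used across the study's reports: 2-fold and 5-fold for
#: the DE set / Venn figures, 4-fold for the regulon table.
FOLD_PRESETS = (2.0, 4.0, 5.0)


@dataclass(frozen=True)
class Thresholds:
    """Gates for calling a gene differentially expressed.

    fold is on the linear scale (a gene passes when |log2fc| ≥ log2(fold),
    inclusive); alpha applies to BH-adjusted p-values; pseudocount is added
    to normalized counts before logs and ratios.
    """

    fold: float = 4.0
    alpha: float = 0.05
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        if self.fold <= 1:
            raise ValueError("fold threshold must exceed 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be ≥ 0")


def _as_frame(counts: CountMatrix | pd.DataFrame) -> pd.DataFrame:
    return counts.counts if isinstance(counts, CountMatrix) else counts


def size_factors(
    counts: CountMatrix | pd.DataFrame,
    control_genes: Sequence[str] | None = None,
) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    For genes with nonzero counts in every sample, each sample's factor is
    the median of that sample's counts over the gene-wise geometric mean.
    If no gene is nonzero everywhere the estimator is undefined; a
    library-size ratio fallback is applied with a warning.

    ``control_genes`` restricts the estimator to a subset believed not to
    be differentially expressed; when strong regulation is concentrated in
    one direction the all-gene median picks up a small library-composition
    bias, and re-estimating on apparently unregulated genes removes it (see
    :func:`de_table`).
    """
    frame = _as_frame(counts)
    if control_genes is not None:
        frame = frame.loc[list(control_genes)]
    values = frame.to_numpy(dtype=float)
    if values.shape[1] == 1:
        return pd.Series([1.0], index=frame.columns, name="size_factor")
    all_nonzero = (values > 0).all(axis=1)
    if all_nonzero.any():
        used = values[all_nonzero]
        log_geomean = np.log(used).mean(axis=1, keepdims=True)
        factors = np.exp(np.median(np.log(used) - log_geomean, axis=0))
    else:
        warnings.warn(
            "no gene has nonzero counts in every sample; median-of-ratios "
            "size factors are undefined — falling back to library-size ratios",
            stacklevel=2,
        )
        libsize = values.sum(axis=0)
        if (libsize == 0).any():
            raise ValueError("sample with zero total counts; cannot normalize")
        factors = libsize
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=frame.columns, name="size_factor")


def _normalized(frame: pd.DataFrame, factors: pd.Series) -> pd.DataFrame:
    return frame / factors.reindex(frame.columns)


def log2_fold_change(
    counts: CountMatrix | pd.DataFrame,
    factors: pd.Series,
    group_a: Sequence[str],
    group_b: Sequence[str],
    pseudocount: float = 1.0,
) -> pd.Series:
    """Per-gene log2((mean_B + c) / (mean_A + c)) on normalized counts.

    Convention: A is the baseline (wild type), B the contrast group
    (mutant); positive values mean higher in B.
    """
    if len(group_a) == 0 or len(group_b) == 0:
        raise ValueError("both groups must be non-empty")
    norm = _normalized(_as_frame(counts), factors)
    mean_a = norm[list(group_a)].mean(axis=1)
    mean_b = norm[list(group_b)].mean(axis=1)
    lfc = np.log2(mean_b + pseudocount) - np.log2(mean_a + pseudocount)
    lfc.name = "log2fc"
    return lfc


def de_test(
    counts: CountMatrix | pd.DataFrame,
    factors: pd.Series,
    group_a: Sequence[str],
    group_b: Sequence[str],
    pseudocount: float = 1.0,
) -> pd.Series:
    """Two-group one-way ANOVA p-values on log2(normalized count + c).

    With two groups the ANOVA F test is identical to the two-sided
    pooled-variance t test, which is what is computed. Degenerate genes are
    resolved deterministically: if both groups are the same constant the
    p-value is 1; if within-group variance is zero but the means differ it
    is 0. Both cases are logged.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs ≥2 samples for a variance estimate")
    norm = _normalized(_as_frame(counts), factors)
    log_a = np.log2(norm[list(group_a)].to_numpy() + pseudocount)
    log_b = np.log2(norm[list(group_b)].to_numpy() + pseudocount)
    with np.errstate(divide="ignore", invalid="ignore"):
        result = stats.ttest_ind(log_a, log_b, axis=1, equal_var=True)
    p = np.asarray(result.pvalue, dtype=float).copy()

    pooled_var = log_a.var(axis=1, ddof=1) + log_b.var(axis=1, ddof=1)
    degenerate = ~np.isfinite(p) | (pooled_var == 0)
    if degenerate.any():
        means_equal = np.isclose(log_a.mean(axis=1), log_b.mean(axis=1))
        p[degenerate & means_equal] = 1.0
        p[degenerate & ~means_equal] = 0.0
        logger.info(
            "%d genes with zero within-group variance: p set to 0/1 by mean equality",
            int(degenerate.sum()),
        )
    return pd.Series(p, index=_as_frame(counts).index, name="p")


def bh_adjust(p: Sequence[float] | np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (input order preserved)."""
    arr = np.asarray(p, dtype=float)
    if arr.size == 0:
        return arr.copy()
    if np.isnan(arr).any() or (arr < 0).any() or (arr > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


def de_table(
    counts: CountMatrix | pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
    thresholds: Thresholds = Thresholds(),
    factors: pd.Series | None = None,
    refine_factors: bool = True,
) -> pd.DataFrame:
    """Full per-gene DE table for the A (WT) vs B (mutant) contrast.

    Columns: mean_wt, mean_mut (normalized means), log2fc, p, p_adj and
    call ∈ {lower, higher, ns} at the given thresholds.

    Unless ``factors`` is supplied, size factors are estimated in two
    passes: an all-gene median-of-ratios pass, then a second pass
    restricted to genes whose preliminary |log2fc| is below 1 (an apparent
    control set). This guards the fold-change scale against library-
    composition bias when regulation is predominantly one-directional.
    """
    frame = _as_frame(counts)
    if factors is None:
        factors = size_factors(frame)
        if refine_factors:
            prelim = log2_fold_change(
                frame, factors, group_a, group_b, thresholds.pseudocount
            )
            controls = frame.index[prelim.abs() < 1.0]
            if len(controls) >= max(10, len(frame) // 10):
                factors = size_factors(frame, control_genes=controls)
    norm = _normalized(frame, factors)
    table = pd.DataFrame(
        {
            "mean_wt": norm[list(group_a)].mean(axis=1),
            "mean_mut": norm[list(group_b)].mean(axis=1),
            "log2fc": log2_fold_change(
                frame, factors, group_a, group_b, thresholds.pseudocount
            ),
            "p": de_test(frame, factors, group_a, group_b, thresholds.pseudocount),
        },
        index=frame.index,
    )
    table["p_adj"] = bh_adjust(table["p"])
    lower, higher = threshold_sets(table, thresholds)
    table["call"] = "ns"
    table.loc[sorted(lower), "call"] = "lower"
    table.loc[sorted(higher), "call"] = "higher"
    table.index.name = "gene_id"
    return table


def threshold_sets(
    results: pd.DataFrame, thresholds: Thresholds
) -> tuple[set[str], set[str]]:
    """DE gene sets at a fold/alpha gate.

    Returns (lower_in_mutant, higher_in_mutant): genes with p_adj < alpha
    and log2fc ≤ −log2(fold), respectively ≥ +log2(fold). The fold gate is
    inclusive. The sets are disjoint by construction.
    """
    gate = np.log2(thresholds.fold)
    significant = results["p_adj"] < thresholds.alpha
    lower = set(results.index[significant & (results["log2fc"] <= -gate)])
    higher = set(results.index[significant & (results["log2fc"] >= gate)])
    return lower, higher


@dataclass(frozen=True)
class VennCounts:
    """Overlap counts for one direction of a two-contrast comparison."""

    a_only: int
    b_only: int
    both: int

    @property
    def total_a(self) -> int:
        return self.a_only + self.both

    @property
    def total_b(self) -> int:
        return self.b_only + self.both


def venn(
    sets_a: tuple[set[str], set[str]], sets_b: tuple[set[str], set[str]]
) -> dict[str, VennCounts]:
    """Venn overlaps between two contrasts' (lower, higher) set pairs."""
    out: dict[str, VennCounts] = {}
    for name, a, b in (
        ("lower", sets_a[0], sets_b[0]),
        ("higher", sets_a[1], sets_b[1]),
    ):
        out[name] = VennCounts(
            a_only=len(a - b), b_only=len(b - a), both=len(a & b)
        )
    return out


def write_de_table(table: pd.DataFrame, path: str | Path, header_lines: Iterable[str] = ()) -> None:
    """Write the DE table as TSV with optional ``#`` header lines."""
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        table.to_csv(fh, sep="\t")
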