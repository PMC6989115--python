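"""qPCR quantification arithmetic: ΔCt expression, ΔΔCt fold changes,
ChIP fold enrichment over mock, and barcode-based strain abundances.

All quantities assume exponential amplification with per-cycle efficiency E
(default 2, perfect doubling), so template abundance scales as E^(−Ct).
Replicates are aggregated on the ratio scale, matching how such figures are
drawn, with SEM = sd/√n over biological replicates.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: Columns expected of a Ct table on disk.
CT_COLUMNS = ["sample_id", "target", "fraction", "ct", "dilution", "replicate"]


def _check_efficiency(efficiency: float) -> None:
    if efficiency <= 1:
        raise ValueError("amplification efficiency must exceed 1")


def relative_expression(
    ct_target: float,
    ct_ref: float,
    dilution_target: float = 1.0,
    dilution_ref: float = 1.0,
    efficiency: float = 2.0,
) -> float:
    """Target abundance relative to a reference transcript (ΔCt method).

    E^(ct_ref − ct_target) · (dilution_target / dilution_ref). The dilution
    correction makes measurements from differently diluted cDNA comparable
    (e.g. a target from 10-fold-diluted cDNA against 16S rRNA from
    1,000-fold-diluted cDNA).
    """
    _check_efficiency(efficiency)
    if dilution_target <= 0 or dilution_ref <= 0:
        raise ValueError("dilutions must be positive")
    return efficiency ** (ct_ref - ct_target) * (dilution_target / dilution_ref)


def fold_change(rel_condition: float, rel_baseline: float) -> float:
    """Ratio of two relative expressions (the ΔΔCt fold change)."""
    if rel_condition <= 0 or rel_baseline <= 0:
        raise ValueError("relative expressions must be positive")
    return rel_condition / rel_baseline


def chip_fold_enrichment(
    ct_ip_target: float,
    ct_mock_target: float,
    ct_ip_ref: float,
    ct_mock_ref: float,
    efficiency: float = 2.0,
) -> float:
    """ChIP enrichment of a target locus over mock, normalized to a
    reference locus (e.g. the rpoD promoter):

    E^[(ct_mock_target − ct_ip_target) − (ct_mock_ref − ct_ip_ref)]

    Invariant to adding a constant to all four Cts, so plate-wide shifts
    cancel. See :func:`chip_percent_input` for the percent-input
    alternative.
    """
    _check_efficiency(efficiency)
    ddct = (ct_mock_target - ct_ip_target) - (ct_mock_ref - ct_ip_ref)
    return efficiency**ddct


def chip_percent_input(
    ct_ip: float,
    ct_input: float,
    input_fraction: float = 1.0,
    efficiency: float = 2.0,
) -> float:
    """Percent-input ChIP quantification: 100 · f · E^(ct_input − ct_ip),
    where f corrects for the fraction of chromatin reserved as input."""
    _check_efficiency(efficiency)
    if not 0 < input_fraction <= 1:
        raise ValueError("input_fraction must be in (0, 1]")
    return 100.0 * input_fraction * efficiency ** (ct_input - ct_ip)


def barcode_abundance(
    cts: Mapping[str, float] | pd.Series, efficiency: float = 2.0
) -> pd.Series:
    """Relative strain abundances from barcode Cts within one sample.

    Each barcode's template abundance is E^(−Ct); fractions are normalized
    to sum to 1.
    """
    _check_efficiency(efficiency)
    series = pd.Series(dict(cts), dtype=float)
    if series.empty:
        raise ValueError("no barcode measurements supplied")
    # work in log space so extreme Cts cannot underflow
    log_a = -series * math.log(efficiency)
    log_a -= log_a.max()
    abundance = np.exp(log_a)
    fractions = abundance / abundance.sum()
    fractions.name = "fraction"
    return fractions


@dataclass(frozen=True)
class QuantResult:
    """A replicate-aggregated quantity: mean, SEM (sd/√n), and n."""

    value: float
    n_replicates: int
    sem: float


def aggregate_replicates(values: Sequence[float]) -> QuantResult:
    """Mean ± SEM over biological replicates (sample sd, n−1 denominator)."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("no replicate values")
    if arr.size == 1:
        warnings.warn("single replicate: SEM reported as 0", stacklevel=2)
        return QuantResult(value=float(arr[0]), n_replicates=1, sem=0.0)
    return QuantResult(
        value=float(arr.mean()),
        n_replicates=int(arr.size),
        sem=float(arr.std(ddof=1) / np.sqrt(arr.size)),
    )


def expression_from_table(
    ct_table: pd.DataFrame,
    target: str,
    reference: str = "16S",
    efficiency: float = 2.0,
) -> pd.DataFrame:
    """Per-(sample, replicate) relative expression of ``target`` vs the
    reference transcript, from a long-format Ct table.

    The table needs the columns in :data:`CT_COLUMNS`; only rows with
    fraction ``input`` or ``NA`` are used (ChIP fractions have their own
    arithmetic). Returns a frame with sample_id, replicate and
    relative_expression.
    """
    missing = set(CT_COLUMNS) - set(ct_table.columns)
    if missing:
        raise ValueError(f"Ct table missing columns {sorted(missing)}")
    usable = ct_table[ct_table["fraction"].isin(["input", "NA"]) | ct_table["fraction"].isna()]
    rows = []
    for (sample, rep), group in usable.groupby(["sample_id", "replicate"]):
        t = group[group["target"] == target]
        r = group[group["target"] == reference]
        if len(t) != 1 or len(r) != 1:
            raise ValueError(
                f"sample {sample} replicate {rep}: need exactly one {target} "
                f"and one {reference} row"
            )
        rows.append(
            {
                "sample_id": sample,
                "replicate": rep,
                "relative_expression": relative_expression(
                    float(t["ct"].iloc[0]),
                    float(r["ct"].iloc[0]),
                    float(t["dilution"].iloc[0]),
                    float(r["dilution"].iloc[0]),
                    efficiency,
                ),
            }
        )
    return pd.DataFrame(rows)


def fold_change_between(
    expr: pd.DataFrame, sample_condition: str, sample_baseline: str
) -> QuantResult:
    """Replicate-wise fold change between two samples' relative expressions,
    aggregated on the ratio scale."""
    cond = expr[expr["sample_id"] == sample_condition].set_index("replicate")
    base = expr[expr["sample_id"] == sample_baseline].set_index("replicate")
    shared = cond.index.intersection(base.index)
    if shared.empty:
        raise ValueError("no shared replicates between the two samples")
    ratios = [
        fold_change(
            float(cond.at[r, "relative_expression"]),
            float(base.at[r, "relative_expression"]),
        )
        for r in shared
    ]
    return aggregate_replicates(ratios)
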