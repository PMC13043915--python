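"""Normalization chain turning filtered read counts into condition metrics.

Raw counts from one condition's library are combined into three layers:

* ``peak_percent`` — window-evidence ("peak") reads as a percentage of all
  unique reads mapped to the minigene contig; the headline per-condition
  binding metric.
* ``minigene_fraction`` — minigene-mapped unique reads over all unique
  mapped reads; controls for library size.
* transfection adjustment — the minigene fraction of the non-reference
  condition is divided by the relative transfection rate (mutant/WT,
  measured from matched input libraries), making minigene-derived signal
  comparable when plasmid uptake differed between conditions.

Empty denominators propagate as NaN rather than raising, so small runs
with zero counts produce a report instead of a crash.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import pandas as pd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CountSet:
    """Per-condition unique-read counts after deduplication."""

    condition: str
    peak_reads: int
    minigene_reads: int
    total_unique_reads: int
    input_minigene_reads: Optional[int] = None

    def __post_init__(self) -> None:
        if not 0 <= self.peak_reads <= self.minigene_reads <= self.total_unique_reads:
            raise ValueError(
                f"{self.condition}: counts must satisfy 0 <= peak_reads "
                f"<= minigene_reads <= total_unique_reads, got "
                f"({self.peak_reads}, {self.minigene_reads}, "
                f"{self.total_unique_reads})"
            )


@dataclass(frozen=True)
class QuantConfig:
    """``transfection_rate`` is the mutant/WT relative plasmid uptake
    (the adjustment divides the non-reference condition by it)."""

    transfection_rate: float = 0.796
    reference_condition: str = "WT"

    def __post_init__(self) -> None:
        if self.transfection_rate <= 0:
            raise ValueError("transfection_rate must be > 0")


def peak_percent(cs: CountSet) -> float:
    """Peak reads as % of minigene-mapped unique reads; NaN when empty."""
    if cs.minigene_reads == 0:
        logger.warning("%s: no minigene reads; peak percent undefined", cs.condition)
        return math.nan
    return 100.0 * cs.peak_reads / cs.minigene_reads


def minigene_fraction(cs: CountSet) -> float:
    """Minigene-mapped unique reads over all unique mapped reads."""
    if cs.total_unique_reads == 0:
        logger.warning("%s: no mapped reads; fraction undefined", cs.condition)
        return math.nan
    return cs.minigene_reads / cs.total_unique_reads


def adjust_transfection(fraction: float, cfg: QuantConfig, condition: str) -> float:
    """Divide the non-reference condition's fraction by the transfection
    rate; the reference condition passes through unchanged."""
    if condition == cfg.reference_condition:
        return fraction
    return fraction / cfg.transfection_rate


def transfection_rate_from_inputs(wt: CountSet, mut: CountSet) -> float:
    """Relative transfection rate (mutant/WT) from matched input-library
    minigene read counts."""
    if wt.input_minigene_reads is None or mut.input_minigene_reads is None:
        raise ValueError("both conditions need input_minigene_reads")
    if wt.input_minigene_reads == 0:
        raise ValueError("reference input minigene count is zero")
    return mut.input_minigene_reads / wt.input_minigene_reads


def compare_conditions(
    wt: CountSet, mut: CountSet, cfg: QuantConfig = QuantConfig()
) -> pd.DataFrame:
    """Build the two-condition report.

    One row per condition with raw counts, peak percent, raw and
    transfection-adjusted minigene fractions, plus the mutant/WT ratio of
    peak percents in a ``peak_percent_ratio`` column (on the non-reference
    row; NaN denominators propagate).
    """
    rows = []
    pcts = {}
    for cs in (wt, mut):
        pct = peak_percent(cs)
        frac = minigene_fraction(cs)
        pcts[cs.condition] = pct
        rows.append(
            {
                "condition": cs.condition,
                "peak_reads": cs.peak_reads,
                "minigene_reads": cs.minigene_reads,
                "total_unique_reads": cs.total_unique_reads,
                "peak_percent": pct,
                "minigene_fraction": frac,
                "minigene_fraction_adjusted": adjust_transfection(
                    frac, cfg, cs.condition
                ),
            }
        )
    report = pd.DataFrame(rows)
    ref_pct = pcts.get(cfg.reference_condition, math.nan)
    ratio = [
        math.nan
        if row["condition"] == cfg.reference_condition
        else (row["peak_percent"] / ref_pct if ref_pct else math.nan)
        for _, row in report.iterrows()
    ]
    report["peak_percent_ratio"] = ratio
    return report


def write_report(report: pd.DataFrame, path: str | Path) -> None:
    report.to_csv(path, sep="\t", index=False, float_format="%.6g")


def format_report(report: pd.DataFrame, cfg: QuantConfig = QuantConfig()) -> str:
    """Human-readable per-condition summary."""
    lines = []
    for _, row in report.iterrows():
        lines.append(
            f"{row['condition']}: peak={int(row['peak_reads'])} reads "
            f"({row['peak_percent']:.3f}% of {int(row['minigene_reads'])} "
            f"minigene reads); minigene fraction "
            f"{row['minigene_fraction']:.4f} "
            f"(adjusted {row['minigene_fraction_adjusted']:.4f})"
        )
        if not math.isnan(row["peak_percent_ratio"]):
            lines.append(
                f"  peak-percent ratio vs {cfg.reference_condition}: "
                f"{row['peak_percent_ratio']:.3f}"
            )
    return "\n".join(lines)


def counts_from_library(
    records: list,
    summary_contig_counts: dict[str, int],
    minigene_contig: str,
    condition: str,
    input_minigene_reads: Optional[int] = None,
) -> CountSet:
    """Assemble a CountSet from filter records and per-contig unique-read
    counts (as produced by counting a deduplicated alignment file)."""
    return CountSet(
        condition=condition,
        peak_reads=len(records),
        minigene_reads=summary_contig_counts.get(minigene_contig, 0),
        total_unique_reads=sum(summary_contig_counts.values()),
        input_minigene_reads=input_minigene_reads,
    )
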