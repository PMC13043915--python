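"""Small-table normalizations for the orthogonal quantitative assays.

Three routine calculations used alongside the sequencing pipeline:

* relative qPCR quantification by the comparative-Ct (2^-ddCt) method with
  a reference gene;
* RNA-immunoprecipitation digital-PCR copy numbers normalized by the
  negative-control IgG pulldown and by minigene transfection efficiency;
* dual secreted-reporter assays (Gaussia luciferase over secreted alkaline
  phosphatase, the internal transfection control).

Table-level wrappers operate on tidy pandas DataFrames read from TSV;
group summaries report mean and min-max range per group.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import pandas as pd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CtRecord:
    """One qPCR measurement: target and reference-gene Ct for one sample."""

    sample_id: str
    group: str
    target: str
    ct_target: float
    ct_reference: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.ct_target) and math.isfinite(self.ct_reference)):
            raise ValueError(f"{self.sample_id}: Ct values must be finite")

    @property
    def delta_ct(self) -> float:
        return self.ct_target - self.ct_reference


@dataclass(frozen=True)
class DpcrRecord:
    """One RIP-dPCR measurement (copies per input cDNA)."""

    sample_id: str
    copies_antibody: float
    copies_igg: float
    transfection_efficiency: float = 1.0

    def __post_init__(self) -> None:
        if self.copies_antibody < 0 or self.copies_igg < 0:
            raise ValueError(f"{self.sample_id}: copy numbers must be >= 0")
        if self.transfection_efficiency <= 0:
            raise ValueError(f"{self.sample_id}: transfection efficiency must be > 0")


@dataclass(frozen=True)
class ReporterRecord:
    """One dual-reporter measurement (luminescence units)."""

    sample_id: str
    gluc: float
    seap: float


def ddct_fold_change(treated: CtRecord, control: CtRecord) -> float:
    """Fold change 2^-((dCt_treated) - (dCt_control)); requires matching targets."""
    if treated.target != control.target:
        raise ValueError(
            f"target mismatch: {treated.target!r} vs {control.target!r}"
        )
    return 2.0 ** -(treated.delta_ct - control.delta_ct)


def rip_normalize(rec: DpcrRecord) -> float:
    """(antibody copies / IgG copies) / transfection efficiency; NaN when
    the IgG control detected nothing."""
    if rec.copies_igg == 0:
        logger.warning("%s: IgG control is zero; ratio undefined", rec.sample_id)
        return math.nan
    return (rec.copies_antibody / rec.copies_igg) / rec.transfection_efficiency


def reporter_ratio(rec: ReporterRecord) -> float:
    """Gluc luminescence normalized by the SEAP transfection control."""
    if rec.seap <= 0:
        logger.warning("%s: non-positive SEAP signal; ratio undefined", rec.sample_id)
        return math.nan
    return rec.gluc / rec.seap


# ---------------------------------------------------------------------------
# Table-level wrappers


def ddct_table(df: pd.DataFrame, control_group: str = "control") -> pd.DataFrame:
    """Per-sample fold changes against the mean dCt of the control group.

    Expects columns sample_id, group, target, ct_target, ct_reference; one
    control baseline is computed per target. A ``p_value`` column is
    carried through if present (externally computed), else left empty.
    """
    df = df.copy()
    df["delta_ct"] = df["ct_target"] - df["ct_reference"]
    out_rows = []
    for target, sub in df.groupby("target", sort=False):
        control = sub[sub["group"] == control_group]
        if control.empty:
            raise ValueError(f"no {control_group!r} samples for target {target!r}")
        baseline = control["delta_ct"].mean()
        for _, row in sub.iterrows():
            out_rows.append(
                {
                    "sample_id": row["sample_id"],
                    "group": row["group"],
                    "target": target,
                    "fold_change": 2.0 ** -(row["delta_ct"] - baseline),
                    "p_value": row.get("p_value", math.nan),
                }
            )
    return pd.DataFrame(out_rows)


def rip_table(df: pd.DataFrame) -> pd.DataFrame:
    """Normalized copy ratios for a table with columns sample_id,
    copies_antibody, copies_igg and optional transfection_efficiency."""
    if "transfection_efficiency" not in df.columns:
        df = df.assign(transfection_efficiency=1.0)
    out = df.copy()
    out["normalized_ratio"] = [
        rip_normalize(
            DpcrRecord(
                sample_id=str(r.sample_id),
                copies_antibody=r.copies_antibody,
                copies_igg=r.copies_igg,
                transfection_efficiency=r.transfection_efficiency,
            )
        )
        for r in df.itertuples()
    ]
    return out


def reporter_table(df: pd.DataFrame) -> pd.DataFrame:
    """Gluc/SEAP ratios for a table with columns sample_id, gluc, seap."""
    out = df.copy()
    out["normalized_activity"] = [
        reporter_ratio(ReporterRecord(str(r.sample_id), r.gluc, r.seap))
        for r in df.itertuples()
    ]
    return out


def group_summary(df: pd.DataFrame, value_col: str, group_col: str = "group") -> pd.DataFrame:
    """Mean and min-max range per group (matching dot-plot style summaries)."""
    agg = df.groupby(group_col, sort=False)[value_col].agg(["mean", "min", "max", "count"])
    return agg.reset_index()
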