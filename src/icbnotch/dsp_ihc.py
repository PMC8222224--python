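"""Digital spatial profiling (DSP) normalization and IHC quantification.

DSP region-of-interest (ROI) protein counts are normalized per protein
by the mean, across patients, of each patient's median ROI value:
negative-control ROIs are excluded throughout and only tumor-annotated
ROIs are retained. IHC staining is summarized by the H-score,
1x(%1+ cells) + 2x(%2+) + 3x(%3+), range 0-300; cleaved-NOTCH1 status
is positive at 5% or more positive cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import ValidationError

__all__ = [
    "DSP_COLUMNS",
    "IHCRecord",
    "validate_dsp_table",
    "normalize_dsp",
    "h_score",
    "notch1_positivity",
]

DSP_COLUMNS = ("patient_id", "roi_id", "protein", "value", "tumor_annotated", "is_negative_control")


def validate_dsp_table(t: pd.DataFrame) -> pd.DataFrame:
    for col in DSP_COLUMNS:
        if col not in t.columns:
            raise ValidationError(f"DSP table missing column {col!r}")
    if (pd.to_numeric(t["value"], errors="coerce").isna()).any():
        raise ValidationError("DSP values must be numeric")
    if (t["value"].astype(float) < 0).any():
        raise ValidationError("DSP values must be non-negative")
    key = t[["patient_id", "roi_id", "protein"]].astype(str).agg("|".join, axis=1)
    if key.duplicated().any():
        raise ValidationError(
            f"duplicate (patient, roi, protein) record: {key[key.duplicated()].iloc[0]!r}"
        )
    return t


def normalize_dsp(t: pd.DataFrame) -> pd.DataFrame:
    """Normalize DSP ROI values per protein by the mean of per-patient
    median ROI values.

    Eligible ROIs are tumor-annotated and not negative controls. Per
    protein: each patient's median over their eligible ROIs is taken,
    those medians are averaged over patients, and every eligible ROI
    value is divided by that mean. Patients with no eligible ROI for a
    protein are dropped from that protein with a warning. Only eligible
    ROIs appear in the output. The construction makes the mean of
    per-patient medians exactly 1 for every protein, and is idempotent.
    """
    t = validate_dsp_table(t)
    eligible = t[t["tumor_annotated"].astype(bool) & ~t["is_negative_control"].astype(bool)].copy()
    if eligible.empty:
        raise ValidationError("no tumor-annotated, non-control ROIs in the DSP table")
    eligible["value"] = eligible["value"].astype(float)
    out_blocks: list[pd.DataFrame] = []
    for protein, block in eligible.groupby("protein", sort=True):
        medians = block.groupby("patient_id")["value"].median()
        n_all = t.loc[t["protein"] == protein, "patient_id"].nunique()
        if len(medians) < n_all:
            warnings.warn(
                f"protein {protein!r}: {n_all - len(medians)} patient(s) without "
                "eligible ROIs dropped from the normalization mean",
                stacklevel=2,
            )
        mean_of_medians = float(medians.mean())
        if mean_of_medians == 0:
            raise ValidationError(f"zero mean of per-patient medians for protein {protein!r}")
        norm = block.copy()
        norm["value"] = norm["value"] / mean_of_medians
        out_blocks.append(norm)
    return pd.concat(out_blocks, axis=0).reset_index(drop=True)


@dataclass
class IHCRecord:
    """One IHC measurement: intensity-bin percentages and % positive cells."""

    sample_id: str
    marker: str
    pct_1plus: float = 0.0
    pct_2plus: float = 0.0
    pct_3plus: float = 0.0
    pct_positive_cells: float = 0.0

    def __post_init__(self) -> None:
        bins = (self.pct_1plus, self.pct_2plus, self.pct_3plus)
        for v in bins:
            if not 0.0 <= v <= 100.0:
                raise ValidationError(f"intensity-bin percentage out of [0,100]: {v}")
        if sum(bins) > 100.0 + 1e-9:
            raise ValidationError(f"intensity bins sum to {sum(bins)} > 100")
        if not 0.0 <= self.pct_positive_cells <= 100.0:
            raise ValidationError(
                f"pct_positive_cells out of [0,100]: {self.pct_positive_cells}"
            )


def h_score(r: IHCRecord) -> float:
    """H-score = 1x(%1+) + 2x(%2+) + 3x(%3+), in [0, 300]."""
    return 1.0 * r.pct_1plus + 2.0 * r.pct_2plus + 3.0 * r.pct_3plus


def notch1_positivity(r: IHCRecord, threshold: float = 5.0) -> bool:
    """Cleaved-NOTCH1 positive iff >= threshold % positive cells
    (inclusive: exactly 5% is positive)."""
    return bool(r.pct_positive_cells >= threshold)
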