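"""Resection-completeness (Subtraction) biomarkers.

Subtraction-X for a patient is the biomarker X averaged over all resected
non-artifact channels minus its average over all preserved non-artifact
channels.  A higher value means the interictally abnormal territory (high HFO
rate / high MI) was more completely removed.  For z-scored variants, any NA
entering either side's mean makes the patient's Subtraction NA; such patients
are dropped listwise from the affected model only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["SubtractionBiomarker", "subtraction_biomarker", "patient_biomarker_matrix"]


@dataclass
class SubtractionBiomarker:
    value: float  # NaN when a z-variant side is undefined
    variant: str
    n_resected: int
    n_preserved: int
    reason_na: str | None = None


def subtraction_biomarker(
    table: pd.DataFrame, value_column: str, variant: str | None = None
) -> SubtractionBiomarker:
    """mean(resected) - mean(preserved) for one biomarker column.

    Artifact channels are excluded entirely; both sides must be non-empty.
    NaN biomarker values (failed z-normalization) make the result NA rather
    than being silently dropped.
    """
    variant = variant or value_column
    ok = ~table["artifact"].astype(bool)
    res = table.loc[ok & table["resected"].astype(bool), value_column].to_numpy(dtype=float)
    pres = table.loc[ok & ~table["resected"].astype(bool), value_column].to_numpy(dtype=float)
    if res.size == 0:
        raise ValueError("no resected non-artifact channels")
    if pres.size == 0:
        raise ValueError("no preserved non-artifact channels")
    if np.isnan(res).any() or np.isnan(pres).any():
        return SubtractionBiomarker(
            value=float("nan"),
            variant=variant,
            n_resected=res.size,
            n_preserved=pres.size,
            reason_na="NA biomarker values (z-normalization undefined)",
        )
    return SubtractionBiomarker(
        value=float(res.mean() - pres.mean()),
        variant=variant,
        n_resected=res.size,
        n_preserved=pres.size,
    )


def patient_biomarker_matrix(
    channel_tables: dict[str, pd.DataFrame], value_columns: list[str]
) -> pd.DataFrame:
    """One row per patient, one Subtraction column per biomarker variant.

    Missing variants or NA z-sides propagate as NaN entries (reported, not
    imputed): the affected patient drops out of that one model's fit.
    """
    rows = {}
    for pid, table in channel_tables.items():
        row = {}
        for col in value_columns:
            if col not in table.columns:
                row[col] = float("nan")
                continue
            try:
                row[col] = subtraction_biomarker(table, col).value
            except ValueError:
                row[col] = float("nan")
        rows[pid] = row
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "patient"
    return out
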