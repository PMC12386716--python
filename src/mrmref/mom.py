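"""Multiples-of-the-median transformation and reference statistics.

A measurement is expressed as a multiple of the cohort median for its
analyte, C_MoM = C / median(C); 1 MoM is the population-typical level. The
transformation is scale-free, which is what makes reference ranges portable
across platforms. Per-protein descriptive statistics (median, SD, CV,
min/max, 5%/95% quantiles, the q95/q5 fold change, and the central-90% MoM
interval) form the reference table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import PipelineConfig


class MoMError(ValueError):
    pass


def to_mom(matrix: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Divide each cell by its protein's cohort median (over non-missing
    cells). Returns (MoM matrix, medians used as denominators)."""
    medians = matrix.median(axis=0, skipna=True)
    all_missing = medians.index[matrix.notna().sum(axis=0) == 0].tolist()
    if all_missing:
        raise MoMError(f"all-missing protein column(s): {all_missing}")
    if (matrix.dropna(how="all") <= 0).any().any():
        raise MoMError("MoM transformation requires strictly positive values")
    return matrix.div(medians, axis=1), medians


@dataclass
class ReferenceEntry:
    protein_id: str
    n: int
    median: float
    sd: float
    cv: float
    min: float
    max: float
    q05: float
    q95: float
    fold_change: float  # q95 / q05
    mom_q05: float = np.nan
    mom_q95: float = np.nan
    mom_width: float = np.nan
    reliable: bool = True


def summarize_protein(
    values: pd.Series,
    protein_id: str = "",
    config: PipelineConfig | None = None,
) -> ReferenceEntry:
    """Descriptive reference statistics for one protein.

    Quantiles use the linear-interpolation estimator (numpy default).
    Entries with fewer than ``min_reference_n`` non-missing observations are
    flagged unreliable rather than rejected.
    """
    config = config or PipelineConfig()
    v = values.dropna().to_numpy(dtype=float)
    lo, hi = config.quantiles
    if v.size == 0:
        return ReferenceEntry(
            protein_id, 0, *(np.nan,) * 8, np.nan, reliable=False
        )
    q05, q95 = np.quantile(v, [lo, hi])
    mean = v.mean()
    sd = v.std(ddof=1) if v.size > 1 else 0.0
    return ReferenceEntry(
        protein_id=protein_id,
        n=int(v.size),
        median=float(np.median(v)),
        sd=float(sd),
        cv=float(sd / mean) if mean != 0 else np.nan,
        min=float(v.min()),
        max=float(v.max()),
        q05=float(q05),
        q95=float(q95),
        fold_change=float(q95 / q05) if q05 > 0 else np.inf,
        reliable=v.size >= config.min_reference_n,
    )


def build_reference_table(
    mom_matrix: pd.DataFrame,
    raw_matrix: pd.DataFrame,
    config: PipelineConfig | None = None,
) -> tuple[pd.DataFrame, float]:
    """One reference row per protein, sorted most-variable first.

    Concentration statistics come from ``raw_matrix`` (the quantified or
    normalized concentrations, nM); the MoM central interval from
    ``mom_matrix``. Also returns the overall dynamic range in decades,
    log10(max median / min median).
    """
    config = config or PipelineConfig()
    lo, hi = config.quantiles
    rows = []
    for protein in mom_matrix.columns:
        entry = summarize_protein(raw_matrix[protein], protein, config)
        momv = mom_matrix[protein].dropna().to_numpy(dtype=float)
        if momv.size:
            mq05, mq95 = np.quantile(momv, [lo, hi])
            entry.mom_q05, entry.mom_q95 = float(mq05), float(mq95)
            entry.mom_width = float(mq95 - mq05)
        rows.append(entry.__dict__)
    table = pd.DataFrame(rows).sort_values(
        "fold_change", ascending=False, kind="mergesort"
    )
    medians = table["median"].dropna()
    dynamic_range = (
        float(np.log10(medians.max() / medians.min())) if len(medians) else np.nan
    )
    return table.reset_index(drop=True), dynamic_range
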