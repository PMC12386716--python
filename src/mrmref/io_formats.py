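"""Tables the pipeline reads and writes.

The canonical interchange for transition-level data is a long (tidy) CSV with
one row per (sample, peptide, replicate) measurement — the shape of a Skyline
transition report after peak-area-ratio extraction. Concentration matrices
travel as samples x proteins CSV with a header row and a sample index column.
All downstream modules receive validated pandas objects and stay free of
file-format logic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .config import DEFAULT_LEVELS


class FormatError(ValueError):
    """Raised when an input table violates the format contract."""


#: QC role labels: three surrogate-matrix levels plus the pooled-serum control.
QC_LABELS: tuple[str, ...] = ("QCA", "QCB", "QCC", "CLP")

PEAK_COLUMNS = ["sample_id", "role", "batch", "replicate", "peptide", "ratio"]
ANNOTATION_COLUMNS = [
    "sample_id",
    "age",
    "bmi",
    "ga_collection",
    "parity",
    "myoma",
    "fetal_sex_male",
    "batch",
]
COVARIATE_COLUMNS = ["age", "bmi", "ga_collection", "parity", "myoma", "fetal_sex_male"]


# ---------------------------------------------------------------------------
# panel definition
# ---------------------------------------------------------------------------


@dataclass
class PanelEntry:
    """Assay metadata for one protein/peptide pair.

    ``level_concs`` maps calibration level labels (ascending, A..G by
    default) to nominal concentrations in fmol/uL; the lowest level is the
    LLOQ and the highest the HLOQ. ``sis_conc`` is the concentration of the
    spiked heavy internal-standard peptide. ``qc_concs`` optionally records
    nominal concentrations of the surrogate-matrix QC levels (the pooled
    serum control has no nominal and is not listed).
    """

    protein_id: str
    peptide_id: str
    level_concs: dict[str, float]
    sis_conc: float
    qc_concs: dict[str, float] = field(default_factory=dict)
    notes: str = ""

    def __post_init__(self) -> None:
        labels = list(self.level_concs)
        concs = [self.level_concs[k] for k in labels]
        if any(c <= 0 for c in concs) or self.sis_conc <= 0:
            raise FormatError(
                f"panel entry {self.peptide_id}: all concentrations must be > 0"
            )
        if any(b <= a for a, b in zip(concs, concs[1:])):
            raise FormatError(
                f"panel entry {self.peptide_id}: level concentrations must be "
                "strictly increasing with level order"
            )
        if any(c <= 0 for c in self.qc_concs.values()):
            raise FormatError(
                f"panel entry {self.peptide_id}: QC concentrations must be > 0"
            )

    @property
    def levels(self) -> tuple[str, ...]:
        return tuple(self.level_concs)

    @property
    def lloq(self) -> float:
        return next(iter(self.level_concs.values()))

    @property
    def hloq(self) -> float:
        return list(self.level_concs.values())[-1]


@dataclass
class Panel:
    """The full assay panel: one :class:`PanelEntry` per peptide."""

    entries: list[PanelEntry]

    def __post_init__(self) -> None:
        seen = set()
        for e in self.entries:
            if e.peptide_id in seen:
                raise FormatError(f"duplicate peptide in panel: {e.peptide_id}")
            seen.add(e.peptide_id)
        levels = {e.levels for e in self.entries}
        if len(levels) > 1:
            raise FormatError("all panel entries must share the same level labels")

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, peptide_id: str) -> PanelEntry:
        for e in self.entries:
            if e.peptide_id == peptide_id:
                return e
        raise KeyError(peptide_id)

    @property
    def peptides(self) -> list[str]:
        return [e.peptide_id for e in self.entries]

    @property
    def proteins(self) -> list[str]:
        return [e.protein_id for e in self.entries]

    @property
    def levels(self) -> tuple[str, ...]:
        return self.entries[0].levels if self.entries else DEFAULT_LEVELS


def write_panel(panel: Panel, path: str | Path) -> None:
    levels = panel.levels
    rows = []
    for e in panel:
        row: dict[str, object] = {
            "protein_id": e.protein_id,
            "peptide_id": e.peptide_id,
            "sis_conc": e.sis_conc,
        }
        for lv in levels:
            row[f"conc_{lv}"] = e.level_concs[lv]
        for qc, conc in e.qc_concs.items():
            row[f"qc_{qc}"] = conc
        row["notes"] = e.notes
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_panel(path: str | Path) -> Panel:
    df = pd.read_csv(path, dtype={"protein_id": str, "peptide_id": str})
    level_cols = [c for c in df.columns if c.startswith("conc_")]
    qc_cols = [c for c in df.columns if c.startswith("qc_")]
    entries = []
    for _, row in df.iterrows():
        entries.append(
            PanelEntry(
                protein_id=row["protein_id"],
                peptide_id=row["peptide_id"],
                level_concs={c[len("conc_"):]: float(row[c]) for c in level_cols},
                sis_conc=float(row["sis_conc"]),
                qc_concs={
                    c[len("qc_"):]: float(row[c])
                    for c in qc_cols
                    if np.isfinite(row[c])
                },
                notes="" if pd.isna(row.get("notes", "")) else str(row.get("notes", "")),
            )
        )
    return Panel(entries)


# ---------------------------------------------------------------------------
# peak table
# ---------------------------------------------------------------------------


def valid_roles(level_labels: Sequence[str] = DEFAULT_LEVELS) -> set[str]:
    roles = {"cohort", "blank"}
    roles.update(f"standard:{lv}" for lv in level_labels)
    roles.update(f"qc:{q}" for q in QC_LABELS)
    return roles


def validate_peak_table(
    df: pd.DataFrame, level_labels: Sequence[str] = DEFAULT_LEVELS
) -> pd.DataFrame:
    missing_cols = [c for c in PEAK_COLUMNS if c not in df.columns]
    if missing_cols:
        raise FormatError(f"peak table missing columns: {missing_cols}")
    df = df.loc[:, PEAK_COLUMNS].copy()
    allowed = valid_roles(level_labels)
    bad = df.loc[~df["role"].isin(allowed)]
    if len(bad):
        row = bad.iloc[0]
        raise FormatError(
            f"unknown role label {row['role']!r} at row {bad.index[0]} "
            f"(sample {row['sample_id']!r}); allowed: {sorted(allowed)}"
        )
    df["ratio"] = pd.to_numeric(df["ratio"], errors="coerce")
    neg = df.loc[df["ratio"] < 0]
    if len(neg):
        row = neg.iloc[0]
        raise FormatError(
            f"negative response ratio {row['ratio']} at row {neg.index[0]} "
            f"(sample {row['sample_id']!r}, peptide {row['peptide']!r})"
        )
    df["replicate"] = df["replicate"].astype(int)
    dup = df.duplicated(subset=["sample_id", "peptide", "replicate"])
    if dup.any():
        row = df.loc[dup].iloc[0]
        raise FormatError(
            "duplicate (sample_id, peptide, replicate) key: "
            f"({row['sample_id']!r}, {row['peptide']!r}, {row['replicate']})"
        )
    return df


def read_peak_table(
    path: str | Path, level_labels: Sequence[str] = DEFAULT_LEVELS
) -> pd.DataFrame:
    """Read a long-format transition table (empty ratio cells become NaN)."""
    df = pd.read_csv(
        path,
        dtype={"sample_id": str, "role": str, "batch": str, "peptide": str},
    )
    return validate_peak_table(df, level_labels)


def write_peak_table(df: pd.DataFrame, path: str | Path) -> None:
    df.loc[:, PEAK_COLUMNS].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# sample annotations
# ---------------------------------------------------------------------------


def validate_annotations(
    df: pd.DataFrame, ga_window: tuple[float, float] = (11.0, 14.0)
) -> pd.DataFrame:
    missing_cols = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing_cols:
        raise FormatError(f"annotation table missing columns: {missing_cols}")
    df = df.loc[:, ANNOTATION_COLUMNS].copy()
    for col in ("age", "bmi", "ga_collection"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    incomplete = df.loc[df[COVARIATE_COLUMNS].isna().any(axis=1), "sample_id"]
    if len(incomplete):
        raise FormatError(
            f"missing covariates for cohort samples: {sorted(incomplete.tolist())}"
        )
    df["parity"] = df["parity"].astype(int)
    if (df["parity"] < 1).any():
        bad = df.loc[df["parity"] < 1, "sample_id"].tolist()
        raise FormatError(
            f"parity must be >= 1 (counts completed pregnancies): {bad}"
        )
    for col in ("myoma", "fetal_sex_male"):
        vals = df[col].astype(int)
        if not vals.isin((0, 1)).all():
            raise FormatError(f"{col} must be binary 0/1")
        df[col] = vals
    lo, hi = ga_window
    out = df.loc[(df["ga_collection"] < lo) | (df["ga_collection"] > hi)]
    if len(out):
        raise FormatError(
            "gestational age at collection outside window "
            f"[{lo}, {hi}] for samples: {out['sample_id'].tolist()}"
        )
    if df["sample_id"].duplicated().any():
        raise FormatError("duplicate sample_id in annotations")
    df["batch"] = df["batch"].astype(str)
    return df.set_index("sample_id")


def read_annotations(
    path: str | Path, ga_window: tuple[float, float] = (11.0, 14.0)
) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"sample_id": str, "batch": str})
    return validate_annotations(df, ga_window)


def write_annotations(df: pd.DataFrame, path: str | Path) -> None:
    df.reset_index().loc[:, ANNOTATION_COLUMNS].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# matrices
# ---------------------------------------------------------------------------


def write_matrix(df: pd.DataFrame, path: str | Path) -> None:
    """Write a samples x proteins matrix with the sample index as first column."""
    df.to_csv(path, index_label="sample_id")


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="sample_id")
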