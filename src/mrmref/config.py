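"""Run configuration for the quantification / reference-range pipeline.

Every acceptance threshold of the bioanalytical workflow is exposed here so
the gating logic is testable at its boundaries rather than hard-coded.
Defaults follow ICH M10-style acceptance rules for ligand-free LC-MRM-MS
assays with stable-isotope internal standards.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

#: Calibration level labels in ascending concentration order (LLOQ..HLOQ).
DEFAULT_LEVELS: tuple[str, ...] = ("A", "B", "C", "D", "E", "F", "G")


@dataclass
class PipelineConfig:
    """Thresholds and numerical policies of the processing pipeline.

    Parameters
    ----------
    accuracy_tol : float
        Maximum allowed relative deviation of a back-calculated standard or
        QC from its nominal concentration (0.20 = +/-20%).
    precision_tol : float
        Maximum allowed CV across replicate back-calculations of one
        calibration level.
    min_standards_pass : int
        Minimum number of calibration levels that must pass accuracy and
        precision for a curve to be acceptable.
    total_standards : int
        Number of calibration levels in the design (labels taken from
        ``level_labels``).
    qc_pass_frac : float
        Minimum fraction of QC measurements within ``accuracy_tol`` for a
        batch to be valid.
    curve_pass_frac : float
        Minimum fraction of acceptable calibration curves for a batch to be
        valid.
    r2_min : float
        Weighted-fit R^2 a curve must exceed (strictly) for its protein to
        count as quantified.
    detect_frac : float
        Maximum fraction of cohort cells clamped or missing before a protein
        is excluded (strictly more than this fraction excludes).
    cv_exclude : float
        Proteins with mean control CV at or above this are excluded.
    p_enter_exit : float
        Significance level used both by the association screen and by
        backward elimination (a predictor with p >= this is dropped).
    quantiles : tuple[float, float]
        Lower/upper reference quantiles (default central 90%).
    ga_window : tuple[float, float]
        Accepted gestational-age-at-collection window in weeks.
    min_reference_n : int
        Minimum non-missing observations for a reliable reference entry.
    expected_mom_floor : float
        Floor applied to model-expected MoM before dividing, preventing
        explosion of adjusted values.
    """

    accuracy_tol: float = 0.20
    precision_tol: float = 0.20
    min_standards_pass: int = 5
    total_standards: int = 7
    qc_pass_frac: float = 0.66
    curve_pass_frac: float = 0.90
    r2_min: float = 0.99
    detect_frac: float = 0.50
    cv_exclude: float = 0.20
    p_enter_exit: float = 0.05
    quantiles: tuple[float, float] = (0.05, 0.95)
    ga_window: tuple[float, float] = (11.0, 14.0)
    min_reference_n: int = 20
    expected_mom_floor: float = 0.1
    level_labels: tuple[str, ...] = DEFAULT_LEVELS

    def __post_init__(self) -> None:
        if len(self.level_labels) != self.total_standards:
            # regenerate labels for a non-default level count: A, B, C, ...
            self.level_labels = tuple(
                chr(ord("A") + i) for i in range(self.total_standards)
            )
        if not 0 < self.min_standards_pass <= self.total_standards:
            raise ValueError("min_standards_pass must be in 1..total_standards")
        lo, hi = self.quantiles
        if not 0 < lo < hi < 1:
            raise ValueError("quantiles must satisfy 0 < lo < hi < 1")

    # -- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["quantiles"] = list(self.quantiles)
        d["ga_window"] = list(self.ga_window)
        d["level_labels"] = list(self.level_labels)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        kwargs = dict(d)
        for key in ("quantiles", "ga_window", "level_labels"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def hash(self) -> str:
        """Stable short hash of the configuration, recorded in run logs."""
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]
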