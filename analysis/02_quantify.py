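"""Calibrate and quantify the simulated experiment.

Fits 1/x^2-weighted calibration curves per peptide and batch, applies the
ICH M10-style gates (level accuracy/precision, curve pass, batch QC and
curve fractions), back-calculates cohort concentrations with LLOQ/HLOQ
clamping, and applies the quantifiability filter (R^2 > 0.99 in every valid
batch, <= 50% out-of-range cells).
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from mrmref.config import PipelineConfig
from mrmref.io_formats import read_panel, read_peak_table, write_matrix
from mrmref.pipeline import run_quantify


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--results", type=Path, default=Path("results/run"))
    args = ap.parse_args()

    cfg = PipelineConfig()
    panel = read_panel(args.results / "panel.csv")
    peaks = read_peak_table(args.results / "peaks.csv", cfg.level_labels)
    res = run_quantify(peaks, panel, cfg)

    write_matrix(res.quant.conc, args.results / "quant.csv")
    write_matrix(res.quant.flags, args.results / "quant_flags.csv")
    pd.DataFrame(
        [{"peptide": c.peptide_id, "batch": c.batch_id, "slope": c.slope,
          "intercept": c.intercept, "r2": c.r2, "curve_pass": c.curve_pass}
         for c in res.curves.values()]
    ).to_csv(args.results / "curves.csv", index=False)
    report = {
        "batch_verdicts": {
            b: {"valid": v.valid, "qc_pass_frac": v.qc_pass_frac_observed,
                "curve_pass_frac": v.curve_pass_frac_observed}
            for b, v in res.verdicts.items()
        },
        "retained": res.retained,
        "exclusions": res.exclusions,
    }
    (args.results / "quantify_report.json").write_text(json.dumps(report, indent=1))

    for b, v in res.verdicts.items():
        print(f"batch {b}: QC pass {v.qc_pass_frac_observed:.0%}, "
              f"curves pass {v.curve_pass_frac_observed:.0%}, valid={v.valid}")
    print(f"quantified {len(res.retained)}/{len(panel)} proteins "
          f"({100 * len(res.retained) / len(panel):.1f}%); "
          f"{len(res.exclusions)} excluded")


if __name__ == "__main__":
    main()
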