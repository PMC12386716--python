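"""Build the MoM reference table.

Transforms the normalized cohort matrix to multiples of the median and
tabulates per-protein reference statistics: median concentration (nM), SD,
CV, min/max, 5%/95% quantiles, the q95/q5 fold change and the central-90%
MoM interval, sorted most-variable first.
"""

import argparse
from pathlib import Path

from mrmref.config import PipelineConfig
from mrmref.io_formats import read_matrix, write_matrix
from mrmref.pipeline import run_reference


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--results", type=Path, default=Path("results/run"))
    ap.add_argument("--method", default=None,
                    help="normalization method (default: the one step 03 selected)")
    args = ap.parse_args()

    method = args.method or (args.results / "selected_method.txt").read_text().strip()
    mat = read_matrix(args.results / f"normalized_{method}.csv")
    retained_path = args.results / "cv_retained.txt"
    if retained_path.exists():
        keep = retained_path.read_text().split()
        mat = mat[[c for c in mat.columns if c in keep]]
    res = run_reference(mat, PipelineConfig())
    write_matrix(res.mom, args.results / "mom.csv")
    res.table.to_csv(args.results / "reference_table.csv", index=False)

    t = res.table
    print(f"reference table: {len(t)} proteins, "
          f"dynamic range {res.dynamic_range:.2f} decades")
    print(f"{int((t['fold_change'] < 3).sum())} proteins with fold change < 3")
    print("most variable proteins:")
    for _, row in t.head(4).iterrows():
        print(f"  {row['protein_id']:<10} fold change {row['fold_change']:6.1f}  "
              f"median {row['median']:10.2f} nM")
    print(f"median central-90% MoM width: {t['mom_width'].median():.2f} MoM")


if __name__ == "__main__":
    main()
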