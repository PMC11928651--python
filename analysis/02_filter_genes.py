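#!/usr/bin/env python
"""Apply the pan-cancer gene-space filters to the study compendium.

Stage 1 drops genes that are exactly zero in >= 80% of samples; stage 2
drops the lowest-variance 20% of the survivors.  The retained space is what
pan-cancer outlier calling and similarity use; pan-disease calling keeps the
full gene list.  Writes retained/dropped lists and a one-row summary table.
"""

import argparse
from pathlib import Path

import pandas as pd

import panoutlier as po


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=Path("scratch/data"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    c = po.load_compendium(args.data / "matrix.tsv", args.data / "metadata.tsv")
    params = po.Parameters()
    space = po.pan_cancer_gene_space(c, params)

    out = args.out
    out.mkdir(parents=True, exist_ok=True)
    po.write_gene_list(space.retained, out / "retained_genes.txt")
    po.write_gene_list(sorted(space.dropped_zero), out / "dropped_zero.txt")
    po.write_gene_list(sorted(space.dropped_variance), out / "dropped_variance.txt")
    summary = pd.DataFrame(
        [
            {
                "n_genes": c.n_genes,
                "dropped_zero": len(space.dropped_zero),
                "dropped_variance": len(space.dropped_variance),
                "retained": len(space.retained),
            }
        ]
    )
    summary.to_csv(out / "gene_filter_summary.tsv", sep="\t", index=False)
    print(summary.to_string(index=False))
    print(f"pan-cancer gene space: {len(space.retained)}/{c.n_genes} genes retained")


if __name__ == "__main__":
    main()
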