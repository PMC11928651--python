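#!/usr/bin/env python
"""Molecular-similarity threshold, neighbors and comparator cohorts for the
focus sample.

Computes all pairwise Spearman correlations on the filtered gene space,
derives the 95th-percentile similarity threshold, and builds the four
personalized pan-disease cohorts plus the four predefined cohorts.  Writes a
ranked neighbor table and a cohort summary.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

import panoutlier as po


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=Path("scratch/data"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    c = po.load_compendium(args.data / "matrix.tsv", args.data / "metadata.tsv")
    truth = json.loads((args.data / "truth.json").read_text())
    focus = truth["focus"]
    params = po.Parameters(min_cohort_size=10)

    space = po.pan_cancer_gene_space(c, params)
    sim = po.compute_similarity(c, params, space.retained)
    rhos = sim.correlations[focus].drop(index=focus).sort_values(ascending=False)
    neighbors = po.first_degree_neighbors(sim.correlations, focus, sim.threshold)
    pd.DataFrame(
        {
            "sample": rhos.index,
            "rho": rhos.values,
            "disease": [c.metadata[s].disease for s in rhos.index],
            "first_degree": [s in neighbors for s in rhos.index],
        }
    ).to_csv(args.out / "neighbors.tsv", sep="\t", index=False)

    cohorts = dict(po.build_pan_disease_cohorts(focus, c, sim, params))
    cohorts.update(po.build_predefined_cohorts(focus, c, params))
    rows = [
        {
            "cohort": name,
            "size": spec.size,
            "usable": spec.usable(params.min_cohort_size),
            "provenance": spec.provenance,
        }
        for name, spec in cohorts.items()
    ]
    pd.DataFrame(rows).to_csv(args.out / "cohorts.tsv", sep="\t", index=False)

    focus_disease = c.metadata[focus].disease
    own = truth["disease_assignments"]
    top6 = po.top_k_correlated(sim.correlations, focus, 6)
    same_disease_top = sum(own[s] == focus_disease for s in top6)
    print(f"similarity threshold {sim.threshold:.4f} ({sim.method})")
    print(f"focus {focus} ({focus_disease}): {len(neighbors)} first-degree neighbors")
    print(f"top-6 most correlated: {same_disease_top}/6 share the focus diagnosis")
    for r in rows:
        print(f"  {r['cohort']:>20}: {r['size']:4d} members ({'ok' if r['usable'] else 'UNUSABLE'})")


if __name__ == "__main__":
    main()
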