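#!/usr/bin/env python
"""Generate the synthetic study compendium used by the downstream analyses.

Emulates a multi-disease tumor RNA-seq compendium (log2(TPM+1)) with
adult/pediatric and TCGA/institution strata, an 8-disease correlation
structure, one focus sample with planted druggable overexpression outliers,
and a gene-set collection containing one supported pathway.  Writes the
matrix, metadata, druggable list, gene sets and ground truth under
scratch/data/.
"""

import argparse
import json
from pathlib import Path

import numpy as np

import panoutlier as po


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("scratch/data"))
    args = ap.parse_args()
    out = args.out
    out.mkdir(parents=True, exist_ok=True)

    c, truth = po.generate_compendium(
        n_genes=1000, n_samples=240, n_diseases=8,
        adult_fraction=0.6, tcga_fraction=0.6, seed=args.seed,
    )
    rng = np.random.default_rng(args.seed + 1)
    focus = str(rng.choice(c.samples))
    planted = rng.choice(truth.druggable_genes, size=10, replace=False).tolist()
    c, truth = po.plant_outliers(c, focus, planted, effect=3.0, truth=truth)
    gene_sets = po.generate_gene_sets(truth, c.genes, n_sets=10, seed=args.seed + 2)

    po.write_expression_matrix(c, out / "matrix.tsv")
    po.write_metadata(list(c.metadata.values()), out / "metadata.tsv")
    po.write_gene_list(truth.druggable_genes, out / "druggable.txt")
    po.write_gmt(gene_sets, out / "gene_sets.gmt")
    (out / "truth.json").write_text(
        json.dumps({"focus": focus, **truth.to_dict()}, indent=2, sort_keys=True) + "\n"
    )

    issues = po.validate_compendium(c)
    ages = [m.age_at_diagnosis for m in c.metadata.values()]
    print(f"compendium: {c.n_genes} genes x {c.n_samples} samples, 8 diseases")
    print(f"pediatric share: {np.mean([a < 30 for a in ages]):.2f}")
    print(f"focus sample {focus}: {len(planted)} druggable outliers planted at +3.0 log2")
    print(f"validation issues: {len(issues)}")
    print(f"written to {out}/")


if __name__ == "__main__":
    main()
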