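#!/usr/bin/env python
"""Tissue-specificity Z-scores from the enrichment odds ratios.

For every TE family the per-tissue odds ratios in active chromatin are
standardised across tissues, z = (OR - mean(OR)) / sd(OR); the tissue with
the row-maximum z is where the family's enrichment is most tissue-specific.
"""

import argparse
from pathlib import Path

import pandas as pd

from techromatin.pipeline import FDR_THRESHOLD
from techromatin.tissue_specificity import compute_zscores, or_matrix_from_enrichment


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--enrichment", type=Path, default=Path("results/enrichment.tsv"))
    ap.add_argument("--out", type=Path, default=Path("results/zscores.tsv"))
    args = ap.parse_args()

    enrichment = pd.read_csv(args.enrichment, sep="\t")
    active = enrichment[enrichment["activity"] == "active"]
    z = compute_zscores(or_matrix_from_enrichment(active))
    z.to_csv(args.out, sep="\t", float_format="%.10g")

    enriched = set(active.loc[active["q_value"] < FDR_THRESHOLD, "key"])
    print(f"Z-score matrix: {z.shape[0]} families x {z.shape[1]} tissues -> {args.out}")
    for fam in sorted(enriched):
        if fam in z.index and z.loc[fam].notna().any():
            top = z.loc[fam].idxmax()
            print(f"  {fam}: most tissue-specific in {top} (z = {z.loc[fam, top]:.2f})")


if __name__ == "__main__":
    main()
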