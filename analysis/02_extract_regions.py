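#!/usr/bin/env python
"""Split each tissue's chromHMM segmentation into active and repressed region sets.

Active states: TssA, TssAFlnk, TxFlnk, Tx, TxWk, EnhG, Enh, TssBiv, EnhBiv.
Repressed states: Het (H3K9me3), ReprPC, ReprPCWk (H3K27me3). Writes one
BED4 per (tissue, activity) with the source state in column 4, plus a
summary table of region counts and union bp.
"""

import argparse
from pathlib import Path

from techromatin.chromatin_regions import (
    ACTIVE, REPRESSED, extract_regions, region_summary, write_region_bed,
)
from techromatin.io_formats import read_chrom_sizes, read_segmentation


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data-dir", type=Path, default=Path("results/data"))
    ap.add_argument("--out-dir", type=Path, default=Path("results/regions"))
    args = ap.parse_args()

    genome = read_chrom_sizes(args.data_dir / "chrom.sizes")
    args.out_dir.mkdir(parents=True, exist_ok=True)
    sets = []
    for seg_path in sorted(args.data_dir.glob("segmentation_*.bed")):
        tissue = seg_path.stem.removeprefix("segmentation_")
        seg = read_segmentation(seg_path, genome=genome)
        for activity in (ACTIVE, REPRESSED):
            rs = extract_regions(seg, activity, tissue_id=tissue)
            write_region_bed(rs, args.out_dir / f"{tissue}_{activity}.bed")
            sets.append(rs)
    summary = region_summary(sets)
    summary.to_csv(args.out_dir / "region_summary.tsv", sep="\t", index=False)
    total = dict(summary.groupby("activity")["total_bp"].mean())
    print(summary.to_string(index=False))
    print(f"mean union bp per tissue: active {total.get(ACTIVE, 0):,.0f}, "
          f"repressed {total.get(REPRESSED, 0):,.0f}")


if __name__ == "__main__":
    main()
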