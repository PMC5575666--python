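#!/usr/bin/env python
"""Two-group differential expression between the breed groups.

Welch's t on log2(FPKM + 0.25) per feature, BH-adjusted, calls at q < 0.05;
fold changes follow log2(FPKM_YY / FPKM_WH). Reports DELs (differentially
expressed lincRNAs) and DEGs (protein-coding genes) separately.
"""

import argparse
from pathlib import Path

from lincpipe import io as lio
from lincpipe.diffexp import de_test


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--alpha", type=float, default=0.05)
    args = ap.parse_args()

    expr = lio.read_expression(
        args.data / "expression.tsv",
        lio.read_group_map(args.data / "groups.tsv"),
        group_order=("YY", "WH"),
    )
    de = de_test(expr, alpha=args.alpha)
    de.to_csv(args.out / "de.tsv", sep="\t", float_format="%.6g")

    lincs = {t.transcript_id for t in lio.read_gtf(args.out / "lincRNAs.gtf")}
    called = de[de["call"] != "ns"]
    dels = called[called.index.isin(lincs)]
    degs = called[called.index.str.startswith("GENE_")]
    print(f"{len(called)} features differentially expressed at q < {args.alpha}")
    print(f"  {len(dels)} DELs ({(dels['call'] == 'up').sum()} up in YY, "
          f"{(dels['call'] == 'down').sum()} up in WH)")
    print(f"  {len(degs)} DEGs")


if __name__ == "__main__":
    main()
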