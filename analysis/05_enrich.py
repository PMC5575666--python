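#!/usr/bin/env python
"""Over-representation analysis of the predicted target genes.

Hypergeometric test of the trans target set against the term annotation,
within each category (biological process / pathway), BH-adjusted.
"""

import argparse
from pathlib import Path

import pandas as pd

from lincpipe import io as lio
from lincpipe.enrich import hypergeom_enrich


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--ease", action="store_true")
    args = ap.parse_args()

    edges = pd.read_csv(args.out / "edges.tsv", sep="\t")
    query = set(edges.loc[edges["mode"] == "trans", "gene_id"])
    annotation = lio.read_annotation_gtf(args.data / "annotation.gtf")
    universe = {t.gene_id for t in annotation.subset("protein_coding")}
    terms = lio.read_term_map(args.data / "term_map.tsv", args.data / "term_names.tsv")

    res = hypergeom_enrich(query, terms, universe, ease=args.ease)
    res.to_csv(args.out / "enrichment.tsv", sep="\t", index=False, float_format="%.6g")
    sig = res[res["significant"]]
    print(f"{len(query)} target genes tested against {len(terms)} terms")
    for cat, sub in sig.groupby("category"):
        print(f"  {len(sub)} {cat} terms at p < 0.05")
    if len(sig):
        print(sig.head(5)[["term_id", "k", "K", "p", "q"]].to_string(index=False))


if __name__ == "__main__":
    main()
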