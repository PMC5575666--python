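#!/usr/bin/env python
"""Predict potential target genes of the differentially expressed lincRNAs.

cis: protein-coding genes within 10 kb of a DEL. trans: Pearson screen on
log2 FPKM over DEL x gene pairs detectable in all samples (|r| >= 0.95,
BH q <= 0.05). Signs edges by fold-change concordance, tallies directions
per DEL, and writes the network as TSV and GraphML.
"""

import argparse
import dataclasses
from pathlib import Path

import networkx as nx
import pandas as pd

from lincpipe import io as lio
from lincpipe.targets import (
    cis_targets,
    direction_tally,
    edges_to_frame,
    majority_summary,
    network_graph,
    shared_target_count,
    sign_edges,
    trans_targets,
)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    d, out = args.data, args.out

    lincs = lio.read_gtf(out / "lincRNAs.gtf")
    annotation = lio.read_annotation_gtf(d / "annotation.gtf")
    expr = lio.read_expression(d / "expression.tsv", lio.read_group_map(d / "groups.tsv"),
                               group_order=("YY", "WH"))
    de = pd.read_csv(out / "de.tsv", sep="\t", index_col=0)
    dels = [t for t in lincs if de.loc[t.transcript_id, "call"] != "ns"]
    gene_ids = sorted({t.gene_id for t in annotation.subset("protein_coding")})

    cis = cis_targets(dels, annotation)
    trans = trans_targets(expr, [t.transcript_id for t in dels], gene_ids)
    edges = sign_edges(cis + trans, de)
    edges_to_frame(edges).to_csv(out / "edges.tsv", sep="\t", index=False,
                                 float_format="%.6g")
    nx.write_graphml(network_graph(edges), out / "network.graphml")

    tallies = direction_tally(trans, de)
    pd.DataFrame([dataclasses.asdict(t) for t in tallies]).to_csv(
        out / "tallies.tsv", sep="\t", index=False
    )
    n_cis_de = sum(1 for e in cis if de.loc[e.gene_id, "call"] != "ns")
    print(f"cis: {len(cis)} edges for {len({e.lincRNA_id for e in cis})} DELs "
          f"({n_cis_de} targets themselves DE)")
    n_targets, n_multi = shared_target_count(trans)
    print(f"trans: {len(trans)} edges, {n_targets} distinct target genes, "
          f"{n_multi} regulated by more than one DEL")
    if tallies:
        up, down, ties = majority_summary(tallies)
        print(f"direction tallies: {up} DELs majority-concordant, "
              f"{down} majority-discordant, {ties} tied")


if __name__ == "__main__":
    main()
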