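#!/usr/bin/env python
"""Identify lincRNAs from the candidate transcripts.

Runs the six-filter cascade (intergenic class, size/exons, coding potential,
domain hits, homology hits, expression), classifies survivors as novel vs
overlapping known annotation, groups them into loci, and characterises their
structure against known lincRNAs and protein-coding transcripts.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from lincpipe import coding, io as lio
from lincpipe.identify import characterize, classify_novelty, run_cascade
from lincpipe.models import group_loci


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    d, out = args.data, args.out
    out.mkdir(parents=True, exist_ok=True)

    candidates = lio.read_gtf(d / "candidates.gtf")
    annotation = lio.read_annotation_gtf(d / "annotation.gtf")
    expr = lio.read_expression(d / "expression.tsv", lio.read_group_map(d / "groups.tsv"),
                               group_order=("YY", "WH"))
    scores = coding.score_table(
        candidates, mode="external", external=lio.read_coding_scores(d / "coding_scores.tsv")
    )
    lincs, report = run_cascade(
        candidates, expr, scores,
        lio.read_hit_table(d / "domain_hits.tsv", "domain"),
        lio.read_hit_table(d / "homology_hits.tsv", "homology"),
    )
    lio.write_gtf(lincs, out / "lincRNAs.gtf")
    (out / "filter_report.json").write_text(json.dumps(report.to_dict(), indent=1))

    novelty = classify_novelty(lincs, annotation)
    pd.Series(novelty, name="novelty").rename_axis("transcript_id").to_csv(
        out / "novelty.tsv", sep="\t"
    )
    loci = group_loci(lincs)
    summary, per_t = characterize(
        lincs, annotation.subset("known_lincRNA"), annotation.subset("protein_coding"), expr
    )
    summary.to_csv(out / "characterization.tsv", sep="\t", float_format="%.6g")
    per_t.to_csv(out / "characterization_per_transcript.tsv", sep="\t", index=False)

    print("cascade survivors per stage:",
          dict(zip(report.stage_names, report.survivors_per_stage)))
    n_novel = sum(1 for v in novelty.values() if v == "novel")
    print(f"{len(lincs)} putative lincRNAs in {len(loci)} loci; {n_novel} novel")
    print(summary.round(1).to_string())


if __name__ == "__main__":
    main()
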