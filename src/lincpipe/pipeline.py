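"""End-to-end orchestration: identify -> DE -> targets -> enrich -> validate.

A single config (dict or YAML) either points at existing input files or
contains a ``simulate`` block; stages run in order, fail fast, and write
their outputs plus a machine-readable run report under one directory.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path
from typing import Optional

import pandas as pd

from . import coding as _coding
from . import io as _io
from . import simulate as _sim
from .diffexp import de_features, de_test
from .enrich import hypergeom_enrich
from .identify import CascadeParams, characterize, classify_novelty, run_cascade
from .models import PROTEIN_CODING, group_loci
from .targets import (
    cis_targets,
    direction_tally,
    edges_to_frame,
    majority_summary,
    shared_target_count,
    sign_edges,
    trans_targets,
    validate_pairs,
)

logger = logging.getLogger(__name__)

__version__ = "0.1.0"

DEFAULTS = {
    "alpha": 0.05,
    "pseudocount": 0.25,
    "window": 10_000,
    "r_min": 0.95,
    "positive_only": False,
    "detect_threshold": 0.0,
    "ease": False,
}


def run_all(config: dict, out_dir, seed: Optional[int] = None) -> dict:
    """Run the full pipeline from one config; returns the run report dict.

    ``config`` keys: optional ``simulate`` (SimulationConfig field overrides),
    else input paths (``candidates_gtf``, ``annotation_gtf``, ``fasta`` or
    ``coding_scores``, ``expression``, ``groups``, ``domain_hits``,
    ``homology_hits``, ``term_map``, optional ``expression_validation``),
    plus any of the analysis parameters in ``DEFAULTS``.
    """
    t0 = time.time()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = {**DEFAULTS, **{k: v for k, v in config.items() if k in DEFAULTS}}

    if "simulate" in config:
        sim_overrides = dict(config["simulate"] or {})
        if seed is not None:
            sim_overrides["seed"] = seed
        sim_cfg = _sim.SimulationConfig(**sim_overrides)
        bundle = _sim.build(sim_cfg)
        seed = sim_cfg.seed
        candidates = bundle.candidates
        annotation = bundle.annotation
        expr = bundle.expr
        expr2 = bundle.expr_validation
        domain_hits, homology_hits = bundle.domain_hits, bundle.homology_hits
        scores = {
            tid: _coding.CodingScore(tid, r.score_forward, r.score_reverse)
            for tid, r in bundle.coding_scores.iterrows()
        }
        term_map = bundle.term_map
    else:
        for key in ("candidates_gtf", "annotation_gtf", "expression", "groups"):
            if key not in config or not Path(config[key]).exists():
                raise FileNotFoundError(f"config input {key!r} missing or not found")
        candidates = _io.read_gtf(config["candidates_gtf"])
        annotation = _io.read_annotation_gtf(config["annotation_gtf"])
        group_map = _io.read_group_map(config["groups"])
        expr = _io.read_expression(config["expression"], group_map, config.get("group_order"))
        expr2 = None
        if config.get("expression_validation"):
            vmap_path = config.get("validation_groups")
            if vmap_path:
                vmap = _io.read_group_map(vmap_path)
            else:
                df = pd.read_csv(config["expression_validation"], sep="\t", index_col=0, nrows=0)
                vmap = {s: "all" for s in df.columns}
            expr2 = _io.read_expression(config["expression_validation"], vmap)
        domain_hits = (
            _io.read_hit_table(config["domain_hits"], "domain")
            if config.get("domain_hits")
            else pd.DataFrame(columns=["query_id", "evalue"])
        )
        homology_hits = (
            _io.read_hit_table(config["homology_hits"], "homology")
            if config.get("homology_hits")
            else pd.DataFrame(columns=["query_id", "evalue"])
        )
        if config.get("coding_scores"):
            ext = _io.read_coding_scores(config["coding_scores"])
            scores = _coding.score_table(candidates, mode="external", external=ext)
        else:
            if config.get("fasta"):
                _io.attach_sequences(candidates, config["fasta"])
            scores = _coding.score_table(candidates, mode="heuristic")
        term_map = (
            _io.read_term_map(config["term_map"], config.get("term_names"))
            if config.get("term_map")
            else None
        )

    cascade_params = CascadeParams(**config.get("cascade", {}))

    # -- identification -----------------------------------------------------
    lincs, report = run_cascade(
        candidates, expr, scores, domain_hits, homology_hits, cascade_params
    )
    logger.info("cascade: %d candidates -> %d lincRNAs", len(candidates), len(lincs))
    loci = group_loci(lincs)
    novelty = classify_novelty(lincs, annotation)
    _io.write_gtf(lincs, out / "lincRNAs.gtf")
    (out / "filter_report.json").write_text(json.dumps(report.to_dict(), indent=1))
    pd.Series(novelty, name="novelty").rename_axis("transcript_id").to_csv(
        out / "novelty.tsv", sep="\t"
    )
    coding_set = annotation.subset(PROTEIN_CODING)
    known_set = annotation.subset("known_lincRNA")
    if lincs and len(coding_set) and len(known_set):
        summary, _ = characterize(lincs, known_set, coding_set, expr)
        summary.to_csv(out / "characterization.tsv", sep="\t", float_format="%.6g")

    # -- differential expression -------------------------------------------
    de = de_test(expr, alpha=params["alpha"], pseudocount=params["pseudocount"])
    de.to_csv(out / "de.tsv", sep="\t", float_format="%.6g")
    linc_ids = [t.transcript_id for t in lincs]
    gene_ids = sorted({t.gene_id for t in coding_set})
    dels = [f for f in de_features(de) if f in set(linc_ids)]
    degs = [f for f in de_features(de) if f in set(gene_ids)]
    logger.info("DE: %d DELs, %d DEGs", len(dels), len(degs))

    # -- target prediction ---------------------------------------------------
    del_transcripts = [t for t in lincs if t.transcript_id in set(dels)]
    cis = cis_targets(del_transcripts, annotation, window=params["window"])
    trans = trans_targets(
        expr,
        dels,
        gene_ids,
        r_min=params["r_min"],
        alpha=params["alpha"],
        detect_threshold=params["detect_threshold"],
        positive_only=params["positive_only"],
    )
    edges = sign_edges(cis + trans, de)
    edges_to_frame(edges).to_csv(out / "edges.tsv", sep="\t", index=False, float_format="%.6g")
    tallies = direction_tally(trans, de)
    pd.DataFrame([dataclasses.asdict(t) for t in tallies]).to_csv(
        out / "tallies.tsv", sep="\t", index=False
    )
    deptgs = sorted(
        {e.gene_id for e in trans if de.loc[e.gene_id, "call"] != "ns"}
    )
    n_targets, n_multi = shared_target_count(trans)
    majority = majority_summary(tallies) if tallies else (0, 0, 0)

    # -- enrichment ----------------------------------------------------------
    n_enriched = 0
    if term_map is not None and trans:
        universe = set(gene_ids)
        query = {e.gene_id for e in trans}
        enr = hypergeom_enrich(query, term_map, universe, ease=params["ease"], alpha=params["alpha"])
        enr.to_csv(out / "enrichment.tsv", sep="\t", index=False, float_format="%.6g")
        n_enriched = int(enr["significant"].sum())

    # -- cross-dataset validation -------------------------------------------
    sign_agreement = None
    if expr2 is not None and trans:
        val = validate_pairs(trans, expr2)
        val.to_csv(out / "validation.tsv", sep="\t", index=False, float_format="%.6g")
        if len(val):
            sign_agreement = float(val["sign_agrees"].mean())

    report_dict = {
        "version": __version__,
        "seed": seed,
        "parameters": params,
        "counts": {
            "transcripts_in": len(candidates),
            "lincRNAs": len(lincs),
            "lincRNA_loci": len(loci),
            "novel_lincRNAs": sum(1 for v in novelty.values() if v == "novel"),
            "DELs": len(dels),
            "DEGs": len(degs),
            "cis_edges": len(cis),
            "trans_edges": len(trans),
            "trans_PTGs": n_targets,
            "DEPTGs": len(deptgs),
            "multi_regulated_targets": n_multi,
            "majority_up_DELs": majority[0],
            "majority_down_DELs": majority[1],
            "majority_tied_DELs": majority[2],
            "enriched_terms": n_enriched,
        },
        "validation_sign_agreement": sign_agreement,
    }
    logger.info("pipeline finished in %.2f s", time.time() - t0)
    (out / "report.json").write_text(json.dumps(report_dict, indent=1))
    return report_dict
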