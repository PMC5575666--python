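"""The six-step lincRNA identification cascade with per-stage accounting.

Candidate transcripts from a merged assembly are filtered, in the fixed
published order, to intergenic ('u' class code), multi-exonic transcripts of
at least 200 bp, with no coding potential on either strand, no known protein
domain, no protein homology, and detectable expression (FPKM >= 0.5 in at
least one sample). Retained transcripts are the putative lincRNAs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from . import coding as _coding
from .models import (
    AnnotationSet,
    ExpressionMatrix,
    LincpipeError,
    TranscriptModel,
)

STAGE_NAMES = (
    "intergenic_class",
    "size_and_exons",
    "coding_potential",
    "domain_hit",
    "homology_hit",
    "expression",
)

RETAINED = "retained"


@dataclass
class CascadeParams:
    """Thresholds of the identification cascade (defaults as published)."""

    required_class: str = "u"
    min_len: int = 200        # bp; strictly shorter transcripts are removed
    min_exons: int = 2
    cpc_cut: float = 0.0      # score > cut on either strand removes
    evalue: float = 1e-5      # strict < removes
    min_fpkm: float = 0.5     # FPKM < 0.5 in ALL samples removes


@dataclass
class FilterReport:
    """Per-stage survivor counts and per-transcript fate."""

    stage_names: tuple = STAGE_NAMES
    survivors_per_stage: list = field(default_factory=list)
    fate: Dict[str, str] = field(default_factory=dict)

    @property
    def n_input(self) -> int:
        return len(self.fate)

    @property
    def n_retained(self) -> int:
        return sum(1 for f in self.fate.values() if f == RETAINED)

    def to_dict(self) -> dict:
        return {
            "stage_names": list(self.stage_names),
            "survivors_per_stage": list(self.survivors_per_stage),
            "n_input": self.n_input,
            "n_retained": self.n_retained,
            "fate": dict(self.fate),
        }


def stage_predicates(
    expr: ExpressionMatrix,
    scores: Mapping[str, _coding.CodingScore],
    domain_hits: pd.DataFrame,
    homology_hits: pd.DataFrame,
    params: CascadeParams,
):
    """Return the six keep-predicates, indexed like ``STAGE_NAMES``.

    Each predicate is total over transcripts except the expression stage,
    which raises for transcripts absent from the matrix.
    """

    def sig_queries(hits: pd.DataFrame) -> set:
        if len(hits) == 0:
            return set()
        return set(hits.loc[hits["evalue"] < params.evalue, "query_id"])

    sig_domain = sig_queries(domain_hits)
    sig_homology = sig_queries(homology_hits)

    def keep_class(t: TranscriptModel) -> bool:
        return t.class_code == params.required_class

    def keep_size(t: TranscriptModel) -> bool:
        return t.exon_count >= params.min_exons and t.length >= params.min_len

    def keep_noncoding(t: TranscriptModel) -> bool:
        s = scores.get(t.transcript_id)
        if s is None:
            raise LincpipeError(
                f"no coding score for transcript {t.transcript_id}"
            )
        return not (s.score_forward > params.cpc_cut or s.score_reverse > params.cpc_cut)

    def keep_no_domain(t: TranscriptModel) -> bool:
        return t.transcript_id not in sig_domain

    def keep_no_homology(t: TranscriptModel) -> bool:
        return t.transcript_id not in sig_homology

    def keep_expressed(t: TranscriptModel) -> bool:
        if t.transcript_id not in expr:
            raise LincpipeError(
                f"transcript {t.transcript_id} missing from expression matrix"
            )
        return float(expr.values.loc[t.transcript_id].max()) >= params.min_fpkm

    return (
        keep_class,
        keep_size,
        keep_noncoding,
        keep_no_domain,
        keep_no_homology,
        keep_expressed,
    )


def run_cascade(
    transcripts: Iterable[TranscriptModel],
    expr: ExpressionMatrix,
    scores: Mapping[str, _coding.CodingScore],
    domain_hits: pd.DataFrame,
    homology_hits: pd.DataFrame,
    params: Optional[CascadeParams] = None,
):
    """Apply the six filters in published order.

    Returns ``(lincRNAs, report)`` where ``lincRNAs`` is the list of
    retained :class:`TranscriptModel` and ``report`` the
    :class:`FilterReport` attributing each removed transcript to the first
    stage whose predicate it failed.
    """
    params = params or CascadeParams()
    ts = list(transcripts)
    preds = stage_predicates(expr, scores, domain_hits, homology_hits, params)

    report = FilterReport()
    alive = ts
    for stage, pred in zip(STAGE_NAMES, preds):
        survivors = []
        for t in alive:
            if pred(t):
                survivors.append(t)
            else:
                report.fate[t.transcript_id] = stage
        alive = survivors
        report.survivors_per_stage.append(len(alive))
    for t in alive:
        report.fate[t.transcript_id] = RETAINED
    return alive, report


def classify_novelty(
    lincRNAs: Iterable[TranscriptModel],
    known: AnnotationSet,
    mode: str = "span",
    strand_aware: bool = False,
) -> dict:
    """Label each lincRNA ``novel`` or ``known_overlap`` against an annotation.

    A transcript is novel iff it shares zero positional overlap with any
    annotated transcript. The default compares genomic spans ignoring strand;
    ``mode='exon'`` compares exon intervals, and ``strand_aware=True``
    restricts overlap to the same strand.
    """
    by_chrom: dict[str, list] = {}
    for a in known:
        by_chrom.setdefault(a.chrom, []).append(a)

    def overlap(t: TranscriptModel, a: TranscriptModel) -> bool:
        if strand_aware and t.strand != a.strand and "." not in (t.strand, a.strand):
            return False
        if mode == "span":
            return t.span.overlaps(a.span)
        return any(te.overlaps(ae) for te in t.exons for ae in a.exons)

    out = {}
    for t in lincRNAs:
        hits = by_chrom.get(t.chrom, [])
        out[t.transcript_id] = (
            "known_overlap" if any(overlap(t, a) for a in hits) else "novel"
        )
    return out


def _feature_stats(transcripts: list) -> dict:
    lengths = [t.length for t in transcripts]
    exon_lengths = [e.length for t in transcripts for e in t.exons]
    exon_counts = [t.exon_count for t in transcripts]
    return {
        "n": len(transcripts),
        "mean_transcript_length": float(np.mean(lengths)),
        "mean_exon_length": float(np.mean(exon_lengths)),
        "mean_exon_number": float(np.mean(exon_counts)),
    }


def characterize(
    lincRNAs: Iterable[TranscriptModel],
    known_lincs: AnnotationSet,
    coding_genes: AnnotationSet,
    expr: Optional[ExpressionMatrix] = None,
):
    """Summarise structural features of novel lincRNAs vs reference classes.

    Returns ``(summary, per_transcript)`` data frames. ``summary`` holds mean
    transcript length, mean exon length and mean exon number for novel
    lincRNAs, known lincRNAs and protein-coding transcripts, plus group-wise
    mean FPKM for lincRNAs vs coding genes when an expression matrix is
    given.
    """
    lincs = list(lincRNAs)
    known = list(known_lincs)
    codings = list(coding_genes)
    if not lincs or not known or not codings:
        raise ValueError("all three transcript sets must be non-empty")

    rows = {
        "novel_lincRNA": _feature_stats(lincs),
        "known_lincRNA": _feature_stats(known),
        "protein_coding": _feature_stats(codings),
    }
    summary = pd.DataFrame(rows).T

    if expr is not None:
        linc_ids = [t.transcript_id for t in lincs if t.transcript_id in expr]
        gene_ids = sorted(
            {t.gene_id for t in codings if t.gene_id in expr}
            | {t.transcript_id for t in codings if t.transcript_id in expr}
        )
        for group in expr.groups:
            gv = expr.group_values(group)
            summary.loc["novel_lincRNA", f"mean_fpkm_{group}"] = float(
                gv.loc[linc_ids].to_numpy().mean()
            ) if linc_ids else np.nan
            summary.loc["protein_coding", f"mean_fpkm_{group}"] = float(
                gv.loc[gene_ids].to_numpy().mean()
            ) if gene_ids else np.nan

    per_transcript = pd.DataFrame(
        [
            {
                "transcript_id": t.transcript_id,
                "set": name,
                "transcript_length": t.length,
                "exon_number": t.exon_count,
                "mean_exon_length": t.length / t.exon_count,
            }
            for name, ts in (
                ("novel_lincRNA", lincs),
                ("known_lincRNA", known),
                ("protein_coding", codings),
            )
            for t in ts
        ]
    )
    return summary, per_transcript
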