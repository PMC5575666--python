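"""Potential-target-gene (PTG) prediction and the signed co-expression network.

cis targets are protein-coding genes transcribed within a genomic window
(default < 10 kb, strict, strand-ignorant) of a lincRNA. trans targets come
from a Pearson correlation screen over all lincRNA x gene pairs with
detectable expression in every sample, keeping pairs with |r| >= r_min and
BH-adjusted p <= alpha. For differentially expressed lincRNAs (DELs) and
their differentially expressed targets (DEPTGs), edges are signed
concordant/discordant by fold-change direction and tallied per DEL.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .diffexp import bh_adjust
from .models import (
    PROTEIN_CODING,
    AnnotationSet,
    ExpressionMatrix,
    LincpipeError,
    TranscriptModel,
)

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = 10_000
DEFAULT_R_MIN = 0.95
DEFAULT_ALPHA = 0.05

CONCORDANT = "concordant"
DISCORDANT = "discordant"


@dataclass
class TargetEdge:
    """A lincRNA -> gene association, by proximity (cis) or correlation (trans)."""

    lincRNA_id: str
    gene_id: str
    mode: str                      # "cis" | "trans"
    distance: Optional[int] = None  # bp span gap, cis only
    r: Optional[float] = None       # signed Pearson r, trans only
    p: Optional[float] = None
    q: Optional[float] = None
    sign: Optional[str] = None      # concordant/discordant, set for DEL-DEPTG pairs


@dataclass
class DirectionTally:
    """Per-DEL counts of differentially expressed targets by direction."""

    lincRNA_id: str
    n_deptg: int
    n_up: int     # targets moving in the DEL's direction ("upregulated by")
    n_down: int

    def __post_init__(self) -> None:
        if self.n_up + self.n_down != self.n_deptg:
            raise ValueError(
                f"{self.lincRNA_id}: up {self.n_up} + down {self.n_down} "
                f"!= DEPTGs {self.n_deptg}"
            )


def cis_targets(
    lincRNAs: Iterable[TranscriptModel],
    genes: AnnotationSet,
    window: int = DEFAULT_WINDOW,
) -> List[TargetEdge]:
    """Protein-coding genes within ``window`` bp of a lincRNA span (strict <).

    Distance is the gap between the lincRNA span and the gene footprint
    (union of its transcripts), 0 when they overlap; both directions along
    the chromosome count, and strand is ignored.
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    coding = genes.subset(PROTEIN_CODING)
    spans = coding.gene_spans()
    by_chrom: dict[str, list] = {}
    for gid, span in spans.items():
        by_chrom.setdefault(span.chrom, []).append((gid, span))

    edges: List[TargetEdge] = []
    for t in lincRNAs:
        lspan = t.span
        for gid, gspan in by_chrom.get(t.chrom, []):
            gap = lspan.gap_to(gspan)
            if gap is not None and gap < window:
                edges.append(
                    TargetEdge(t.transcript_id, gid, mode="cis", distance=gap)
                )
    edges.sort(key=lambda e: (e.lincRNA_id, e.gene_id))
    return edges


def pearson_r(x: Sequence[float], y: Sequence[float]) -> tuple:
    """Sample Pearson r with its two-sided p (t distribution, n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    if x.size < 3:
        raise ValueError("need n >= 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise LincpipeError("constant vector: correlation undefined")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def _corr_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlations between two (features x samples) blocks."""
    az = (a - a.mean(axis=1, keepdims=True))
    bz = (b - b.mean(axis=1, keepdims=True))
    az /= np.linalg.norm(az, axis=1, keepdims=True)
    bz /= np.linalg.norm(bz, axis=1, keepdims=True)
    return np.clip(az @ bz.T, -1.0, 1.0)


def trans_targets(
    expr: ExpressionMatrix,
    lincRNA_ids: Sequence[str],
    gene_ids: Sequence[str],
    r_min: float = DEFAULT_R_MIN,
    alpha: float = DEFAULT_ALPHA,
    detect_threshold: float = 0.0,
    positive_only: bool = False,
    log_scale: bool = True,
) -> List[TargetEdge]:
    """Correlation screen over all lincRNA x gene pairs.

    Only features with FPKM strictly above ``detect_threshold`` in every
    sample ("detectable expression in all samples") enter the screen. With
    ``log_scale`` (default) correlations are computed on log2 FPKM — the
    detectability filter guarantees positive values, and the log scale keeps
    strong negative co-regulation detectable, which multiplicative
    (fold-change) effects squash towards zero on the raw scale. BH
    adjustment runs over the full tested pair family. An edge requires
    |r| >= r_min (or r >= r_min with ``positive_only``) and q <= alpha;
    the signed r is kept on the edge. Constant-expression features are
    skipped and counted in the log.
    """
    if not (0 < r_min <= 1):
        raise ValueError("r_min must lie in (0, 1]")
    n_samples = len(expr.sample_ids)
    if n_samples < 3:
        raise ValueError("need >= 3 samples for a correlation screen")

    values = expr.values
    detectable = values.gt(detect_threshold).all(axis=1)

    def usable(ids: Sequence[str]) -> list:
        out = []
        n_const = 0
        for fid in ids:
            if fid not in values.index or not detectable.get(fid, False):
                continue
            row = values.loc[fid].to_numpy()
            if np.ptp(row) == 0:
                n_const += 1
                continue
            out.append(fid)
        if n_const:
            logger.info("skipped %d constant-expression features", n_const)
        return out

    lincs = usable(lincRNA_ids)
    genes = usable(gene_ids)
    if not lincs or not genes:
        return []

    a = values.loc[lincs].to_numpy(dtype=float)
    b = values.loc[genes].to_numpy(dtype=float)
    if log_scale:
        a = np.log2(a)
        b = np.log2(b)
    r = _corr_matrix(a, b)
    df = n_samples - 2
    with np.errstate(divide="ignore"):
        t = r * np.sqrt(df / np.maximum(1.0 - r * r, np.finfo(float).tiny))
    p = 2 * stats.t.sf(np.abs(t), df)
    p = np.minimum(p, 1.0)
    q = bh_adjust(p.ravel()).reshape(p.shape)

    keep = (r >= r_min) if positive_only else (np.abs(r) >= r_min)
    keep &= q <= alpha
    edges = [
        TargetEdge(
            lincs[i],
            genes[j],
            mode="trans",
            r=float(r[i, j]),
            p=float(p[i, j]),
            q=float(q[i, j]),
        )
        for i, j in zip(*np.nonzero(keep))
    ]
    edges.sort(key=lambda e: (e.lincRNA_id, e.gene_id))
    return edges


def sign_edges(edges: Iterable[TargetEdge], de: pd.DataFrame) -> List[TargetEdge]:
    """Set concordant/discordant sign on edges whose both ends are DE."""
    out = []
    for e in edges:
        if e.lincRNA_id in de.index and e.gene_id in de.index:
            lc, gc = de.loc[e.lincRNA_id, "call"], de.loc[e.gene_id, "call"]
            if lc != "ns" and gc != "ns":
                e.sign = CONCORDANT if lc == gc else DISCORDANT
        out.append(e)
    return out


def direction_tally(edges: Iterable[TargetEdge], de: pd.DataFrame) -> List[DirectionTally]:
    """Tally DE targets of each DEL by fold-change concordance.

    For each differentially expressed lincRNA appearing in the edge list,
    counts its differentially expressed targets whose log2 fold-change sign
    matches the lincRNA's (``n_up``, read as "upregulated by" the DEL)
    versus the rest (``n_down``).
    """
    by_linc: dict[str, set] = {}
    for e in edges:
        for fid in (e.lincRNA_id, e.gene_id):
            if fid not in de.index:
                raise LincpipeError(f"edge endpoint {fid} missing from DE results")
        by_linc.setdefault(e.lincRNA_id, set()).add(e.gene_id)

    tallies = []
    for linc in sorted(by_linc):
        lcall = de.loc[linc, "call"]
        if lcall == "ns":
            continue
        n_up = n_down = 0
        for gid in by_linc[linc]:
            gcall = de.loc[gid, "call"]
            if gcall == "ns":
                continue
            if gcall == lcall:
                n_up += 1
            else:
                n_down += 1
        tallies.append(DirectionTally(linc, n_up + n_down, n_up, n_down))
    return tallies


def majority_summary(tallies: Sequence[DirectionTally]) -> tuple:
    """(n majority-up, n majority-down, ties) over per-DEL tallies."""
    if not tallies:
        raise ValueError("no tallies to summarise")
    up = sum(1 for t in tallies if t.n_up > t.n_down)
    down = sum(1 for t in tallies if t.n_up < t.n_down)
    ties = len(tallies) - up - down
    return up, down, ties


def shared_target_count(edges: Iterable[TargetEdge]) -> tuple:
    """(distinct target genes, targets hit by >= 2 distinct lincRNAs)."""
    regulators: dict[str, set] = {}
    for e in edges:
        regulators.setdefault(e.gene_id, set()).add(e.lincRNA_id)
    multi = sum(1 for s in regulators.values() if len(s) >= 2)
    return len(regulators), multi


def validate_pairs(
    edges: Sequence[TargetEdge],
    expr2: ExpressionMatrix,
    log_scale: bool = True,
) -> pd.DataFrame:
    """Recompute each edge's correlation on an independent dataset.

    Returns one row per evaluable edge with the validation ``r``/``p`` and
    whether the correlation sign agrees with the discovery edge. The scale
    matches the discovery screen (log2 FPKM by default); edges with an
    endpoint missing from the second matrix, constant, or — on the log
    scale — not detected in every sample, are skipped and logged.
    """
    if len(expr2.sample_ids) < 3:
        raise ValueError("validation matrix needs >= 3 samples")
    rows = []
    skipped = 0
    for e in edges:
        if e.lincRNA_id not in expr2 or e.gene_id not in expr2:
            skipped += 1
            continue
        x = expr2.values.loc[e.lincRNA_id].to_numpy()
        y = expr2.values.loc[e.gene_id].to_numpy()
        if log_scale:
            if (x <= 0).any() or (y <= 0).any():
                skipped += 1
                continue
            x, y = np.log2(x), np.log2(y)
        try:
            r2, p2 = pearson_r(x, y)
        except LincpipeError:
            skipped += 1
            continue
        rows.append(
            {
                "lincRNA_id": e.lincRNA_id,
                "gene_id": e.gene_id,
                "r_discovery": e.r,
                "r_validation": r2,
                "p_validation": p2,
                "sign_agrees": bool(e.r is not None and np.sign(r2) == np.sign(e.r)),
            }
        )
    if skipped:
        logger.info("validation skipped %d edges with missing/constant endpoints", skipped)
    return pd.DataFrame(
        rows,
        columns=[
            "lincRNA_id",
            "gene_id",
            "r_discovery",
            "r_validation",
            "p_validation",
            "sign_agrees",
        ],
    )


def edges_to_frame(edges: Iterable[TargetEdge]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "lincRNA_id": e.lincRNA_id,
                "gene_id": e.gene_id,
                "mode": e.mode,
                "distance": e.distance,
                "r": e.r,
                "p": e.p,
                "q": e.q,
                "sign": e.sign,
            }
            for e in edges
        ],
        columns=["lincRNA_id", "gene_id", "mode", "distance", "r", "p", "q", "sign"],
    )


def network_graph(edges: Iterable[TargetEdge]):
    """Bipartite lincRNA-target graph (networkx) for export/visualisation."""
    import networkx as nx

    g = nx.Graph()
    for e in edges:
        g.add_node(e.lincRNA_id, kind="lincRNA")
        g.add_node(e.gene_id, kind="gene")
        g.add_edge(
            e.lincRNA_id,
            e.gene_id,
            mode=e.mode,
            sign=e.sign or "",
            r=float("nan") if e.r is None else e.r,
        )
    return g
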