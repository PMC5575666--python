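"""Seeded generator of every input the pipeline consumes, with ground truth.

The generator lays out a toy two-chromosome genome with protein-coding genes
and known lincRNAs, then plants candidate transcripts whose fates through
the six-filter cascade are known by construction: wrong class code, too
short/single exon, planted open reading frame, domain hit, homology hit,
undetectable expression, or retained. Expression follows a log-normal FPKM
model: a two-group design (three samples per group by default, mirroring a
lean-type vs fat-type breed comparison), multiplicatively planted fold
changes, and lincRNA-gene trans pairs driven by a shared latent factor with
a controllable target correlation. A second, larger cohort (18 samples) is
drawn from the same latent structure for cross-dataset validation.

Structural feature distributions default to the published characterisation
means: novel lincRNAs ~1226 bp / 466 bp exons / 2.6 exons, known lincRNAs
~1362/451/2.8, protein-coding transcripts ~1983/228/8.7.

All randomness flows from one integer seed; identical seeds give
byte-identical output files.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from . import coding as _coding
from . import io as _io
from .enrich import BIOLOGICAL_PROCESS, PATHWAY, TermMap
from .identify import STAGE_NAMES, RETAINED
from .models import (
    KNOWN_LINCRNA,
    PROTEIN_CODING,
    AnnotationSet,
    ExpressionMatrix,
    GenomicInterval,
    TranscriptModel,
)

_BASES = np.array(list("ACGT"))


@dataclass
class ClassProfile:
    """Structural feature distribution for one transcript class.

    ``exon_number`` is 2 + Poisson(exon_rate) (multi-exonic), exon lengths
    are log-normal with the given arithmetic mean, introns uniform in the
    given range.
    """

    exon_rate: float
    mean_exon_len: float
    exon_len_sigma: float = 0.45  # sigma of log exon length
    min_exon_len: int = 60
    intron_range: Tuple[int, int] = (200, 2000)

    @property
    def mean_exon_number(self) -> float:
        return 2.0 + self.exon_rate

    @property
    def mean_transcript_length(self) -> float:
        return self.mean_exon_number * self.mean_exon_len


@dataclass
class SimulationConfig:
    """Study conditions emulated by the generator (defaults as published)."""

    seed: int = 0
    # genome layout
    n_chromosomes: int = 2
    spacing: int = 60_000          # bp between consecutive placed elements
    window: int = 10_000           # cis window being planted around
    # annotation
    n_coding_genes: int = 120
    n_known_lincs: int = 40
    coding_profile: ClassProfile = field(
        default_factory=lambda: ClassProfile(exon_rate=6.7, mean_exon_len=228.0)
    )
    known_linc_profile: ClassProfile = field(
        default_factory=lambda: ClassProfile(exon_rate=0.8, mean_exon_len=451.0)
    )
    novel_linc_profile: ClassProfile = field(
        default_factory=lambda: ClassProfile(exon_rate=0.6, mean_exon_len=466.0)
    )
    # candidate fates: 20 per removal stage, 20 retained
    n_per_stage: int = 20
    n_retained_novel: int = 12
    n_retained_known_overlap: int = 8
    # cis planting (among retained lincRNAs)
    n_cis_inside: int = 5
    n_cis_outside: int = 5
    cis_inside_gap: Tuple[int, int] = (2_000, 8_000)
    cis_outside_gap: Tuple[int, int] = (12_000, 25_000)
    # expression design
    groups: Tuple[str, str] = ("YY", "WH")
    n_samples_per_group: int = 3
    n_validation_samples: int = 18
    baseline_log2_coding: float = 4.0    # ~16 FPKM
    baseline_log2_linc: float = 2.3      # ~5 FPKM
    baseline_sigma: float = 1.2
    sigma_log2: float = 0.5              # per-sample log2 noise
    de_log2fc: float = 3.0               # planted |log2 fold change| (8-fold)
    de_frac_coding: float = 0.15         # independent DEGs among free coding genes
    # trans structure
    trans_rho: float = 0.99
    n_singleton_pairs: int = 8
    n_negative_singletons: int = 2
    n_shared_groups: int = 1             # groups of 2 lincRNAs x 2 genes
    n_extra_dels: int = 4                # DELs without planted trans partners
    # ORF planting
    orf_fraction: float = 0.8
    theta: float = 0.3
    # term annotation
    n_bp_terms: int = 25
    n_pathway_terms: int = 12
    term_size_range: Tuple[int, int] = (5, 30)


@dataclass
class GroundTruth:
    """Planted labels enabling exact recovery checks."""

    fate: Dict[str, str] = field(default_factory=dict)
    novelty: Dict[str, str] = field(default_factory=dict)
    de_direction: Dict[str, str] = field(default_factory=dict)  # feature -> up/down (group a vs b)
    trans_edges: List[dict] = field(default_factory=list)       # planted factor pairs
    confound_pairs: List[dict] = field(default_factory=list)    # co-DE, no shared factor
    cis_inside: List[dict] = field(default_factory=list)
    cis_outside: List[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class SimBundle:
    """In-memory fixture: everything the pipeline consumes, plus truth."""

    candidates: List[TranscriptModel]
    annotation: AnnotationSet
    sequences: Dict[str, str]
    expr: ExpressionMatrix
    expr_validation: ExpressionMatrix
    domain_hits: pd.DataFrame
    homology_hits: pd.DataFrame
    coding_scores: pd.DataFrame
    term_map: TermMap
    truth: GroundTruth
    config: SimulationConfig


# ---------------------------------------------------------------- sequences


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _noncoding_seq(rng: np.random.Generator, length: int, theta: float) -> str:
    """Random sequence whose longest-ORF fraction stays below theta on both strands."""
    for _ in range(200):
        seq = _random_seq(rng, length)
        fwd, rev = _coding.longest_orf_by_strand(seq)
        if max(fwd, rev) / length < theta:
            return seq
    raise RuntimeError("could not draw a noncoding sequence")  # pragma: no cover


_STOPS = {"TAA", "TAG", "TGA"}


def _coding_seq(rng: np.random.Generator, length: int, orf_fraction: float) -> str:
    """Random sequence with one planted ATG..stop ORF covering ~orf_fraction."""
    n_codons = max(int(length * orf_fraction) // 3, 4)
    codons = ["ATG"]
    while len(codons) < n_codons - 1:
        c = _random_seq(rng, 3)
        if c not in _STOPS and c != "ATG":
            codons.append(c)
    codons.append("TAA")
    orf = "".join(codons)
    tail = _random_seq(rng, length - len(orf))
    return orf + tail


# ------------------------------------------------------------------ layout


class _Layout:
    """Sequential placement of elements along synthetic chromosomes."""

    def __init__(self, config: SimulationConfig, rng: np.random.Generator):
        self.cfg = config
        self.rng = rng
        self.cursor = {f"chr{i + 1}": 1_000 for i in range(config.n_chromosomes)}
        self._round_robin = 0

    def next_chrom(self) -> str:
        chroms = sorted(self.cursor)
        c = chroms[self._round_robin % len(chroms)]
        self._round_robin += 1
        return c

    def exons_at(self, chrom: str, start: int, profile: ClassProfile, strand: str) -> list:
        rng = self.rng
        n_exons = 2 + rng.poisson(profile.exon_rate)
        mu = np.log(profile.mean_exon_len) - profile.exon_len_sigma**2 / 2
        lens = np.maximum(
            rng.lognormal(mu, profile.exon_len_sigma, size=n_exons).astype(int),
            profile.min_exon_len,
        )
        exons = []
        pos = start
        for i, ln in enumerate(lens):
            exons.append(GenomicInterval(chrom, pos, pos + int(ln), strand))
            pos += int(ln)
            if i < n_exons - 1:
                pos += int(rng.integers(*profile.intron_range))
        return exons

    def place(self, profile: ClassProfile, chrom: Optional[str] = None, gap: Optional[int] = None, strand: Optional[str] = None) -> list:
        """Place a transcript ``gap`` bp after the previous element (default spacing)."""
        chrom = chrom or self.next_chrom()
        strand = strand or ("+" if self.rng.random() < 0.5 else "-")
        start = self.cursor[chrom] + (self.cfg.spacing if gap is None else gap)
        exons = self.exons_at(chrom, start, profile, strand)
        self.cursor[chrom] = exons[-1].end
        return exons


# ---------------------------------------------------------------- generator


def build(config: Optional[SimulationConfig] = None, seed: Optional[int] = None) -> SimBundle:
    """Generate the full in-memory fixture from the configured conditions."""
    cfg = config or SimulationConfig()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    truth = GroundTruth()
    layout = _Layout(cfg, rng)

    # --- reference annotation ---------------------------------------------
    coding_ts: List[TranscriptModel] = []
    for i in range(cfg.n_coding_genes):
        exons = layout.place(cfg.coding_profile)
        gid = f"GENE_{i + 1:04d}"
        coding_ts.append(TranscriptModel(f"{gid}.t1", gid, exons, class_code="="))
    known_ts: List[TranscriptModel] = []
    for i in range(cfg.n_known_lincs):
        exons = layout.place(cfg.known_linc_profile)
        gid = f"KLINC_{i + 1:04d}"
        known_ts.append(TranscriptModel(f"{gid}.t1", gid, exons, class_code="="))
    annotation = AnnotationSet.from_transcripts(
        coding_ts + known_ts,
        {
            **{t.transcript_id: PROTEIN_CODING for t in coding_ts},
            **{t.transcript_id: KNOWN_LINCRNA for t in known_ts},
        },
    )

    # --- candidates with planted fates ------------------------------------
    candidates: List[TranscriptModel] = []
    sequences: Dict[str, str] = {}
    domain_rows: List[dict] = []
    homology_rows: List[dict] = []
    n_cand = 0

    def new_id() -> str:
        nonlocal n_cand
        n_cand += 1
        return f"TCONS_{n_cand:08d}"

    def add_candidate(exons, class_code, seq, fate) -> TranscriptModel:
        tid = new_id()
        t = TranscriptModel(tid, f"XLOC_{n_cand:06d}", exons, class_code=class_code, sequence=seq)
        candidates.append(t)
        sequences[tid] = seq
        truth.fate[tid] = fate
        return t

    linc_profile = cfg.novel_linc_profile

    def noncoding_for(exons) -> str:
        return _noncoding_seq(rng, sum(e.length for e in exons), cfg.theta)

    # stage 1: wrong class code, overlapping an annotated gene
    for i in range(cfg.n_per_stage):
        host = coding_ts[i % len(coding_ts)]
        start = host.span.start + 50
        exons = [
            GenomicInterval(host.chrom, start, start + 400, host.strand),
            GenomicInterval(host.chrom, start + 900, start + 1400, host.strand),
        ]
        add_candidate(exons, "j", _noncoding_seq(rng, 900, cfg.theta), STAGE_NAMES[0])

    # stage 2: single exon, or multi-exon but < 200 bp
    for i in range(cfg.n_per_stage):
        chrom = layout.next_chrom()
        start = layout.cursor[chrom] + cfg.spacing
        if i % 2 == 0:  # single exon, long enough
            exons = [GenomicInterval(chrom, start, start + 800, "+")]
        else:  # two exons, 160 bp total
            exons = [
                GenomicInterval(chrom, start, start + 80, "+"),
                GenomicInterval(chrom, start + 500, start + 580, "+"),
            ]
        layout.cursor[chrom] = exons[-1].end
        add_candidate(exons, "u", noncoding_for(exons), STAGE_NAMES[1])

    # stage 3: planted ORF -> positive heuristic coding score
    for _ in range(cfg.n_per_stage):
        exons = layout.place(linc_profile)
        length = sum(e.length for e in exons)
        add_candidate(exons, "u", _coding_seq(rng, length, cfg.orf_fraction), STAGE_NAMES[2])

    # stage 4 / 5: clean sequence, but a significant domain / homology hit
    for stage, rows, db in (
        (STAGE_NAMES[3], domain_rows, "PF"),
        (STAGE_NAMES[4], homology_rows, "NR"),
    ):
        for _ in range(cfg.n_per_stage):
            exons = layout.place(linc_profile)
            t = add_candidate(exons, "u", noncoding_for(exons), stage)
            rows.append(
                {
                    "query_id": t.transcript_id,
                    "evalue": float(10.0 ** rng.uniform(-30, -6)),
                }
            )

    # stage 6: passes every sequence filter, FPKM < 0.5 everywhere
    for _ in range(cfg.n_per_stage):
        exons = layout.place(linc_profile)
        add_candidate(exons, "u", noncoding_for(exons), STAGE_NAMES[5])

    # retained: novel (intergenic, some planted as cis neighbours) ...
    retained: List[TranscriptModel] = []
    cis_gene_idx = iter(range(cfg.n_coding_genes // 2, cfg.n_coding_genes))
    for i in range(cfg.n_retained_novel):
        if i < cfg.n_cis_inside or i < cfg.n_cis_inside + cfg.n_cis_outside:
            inside = i < cfg.n_cis_inside
            lo, hi = cfg.cis_inside_gap if inside else cfg.cis_outside_gap
            gap = int(rng.integers(lo, hi))
            host = coding_ts[next(cis_gene_idx)]
            exons = layout.exons_at(host.chrom, host.span.end + gap, linc_profile, "+")
            # keep the global cursor ahead of this placement
            layout.cursor[host.chrom] = max(layout.cursor[host.chrom], exons[-1].end)
            t = add_candidate(exons, "u", noncoding_for(exons), RETAINED)
            true_gap = exons[0].start - host.span.end
            rec = {"lincRNA_id": t.transcript_id, "gene_id": host.gene_id, "distance": true_gap}
            (truth.cis_inside if inside else truth.cis_outside).append(rec)
        else:
            exons = layout.place(linc_profile)
            t = add_candidate(exons, "u", noncoding_for(exons), RETAINED)
        truth.novelty[t.transcript_id] = "novel"
        retained.append(t)

    # ... and retained transcripts overlapping known lincRNAs
    for i in range(cfg.n_retained_known_overlap):
        host = known_ts[i % len(known_ts)]
        start = host.span.start + 10
        exons = [
            GenomicInterval(host.chrom, start, start + 500, host.strand),
            GenomicInterval(host.chrom, start + 900, start + 1500, host.strand),
        ]
        t = add_candidate(exons, "u", noncoding_for(exons), RETAINED)
        truth.novelty[t.transcript_id] = "known_overlap"
        retained.append(t)

    # boundary-exercising hit rows that must NOT remove anyone (E = 1e-5 exactly)
    if retained:
        domain_rows.append({"query_id": retained[0].transcript_id, "evalue": 1e-5})
        homology_rows.append({"query_id": retained[-1].transcript_id, "evalue": 1e-5})

    domain_hits = pd.DataFrame(domain_rows, columns=["query_id", "evalue"])
    homology_hits = pd.DataFrame(homology_rows, columns=["query_id", "evalue"])

    # external coding-score table mirrors the heuristic on every candidate
    scores = _coding.score_table(candidates, mode="heuristic", theta=cfg.theta)
    coding_scores = pd.DataFrame(
        {
            "score_forward": {tid: s.score_forward for tid, s in scores.items()},
            "score_reverse": {tid: s.score_reverse for tid, s in scores.items()},
        }
    ).rename_axis("transcript_id")

    # --- latent structure for expression ----------------------------------
    # factor groups: members (feature_id, loading); DELs load positively so the
    # factor's group shift fixes their DE direction.
    factor_groups: List[dict] = []
    linc_pool = [t.transcript_id for t in retained]
    gene_pool = [t.gene_id for t in coding_ts]
    li = gi = 0
    for k in range(cfg.n_singleton_pairs):
        sign = -1.0 if k < cfg.n_negative_singletons else 1.0
        factor_groups.append(
            {
                "lincs": [(linc_pool[li], 1.0)],
                "genes": [(gene_pool[gi], sign)],
                "delta_sign": 1.0 if k % 2 == 0 else -1.0,
            }
        )
        li += 1
        gi += 1
    for _ in range(cfg.n_shared_groups):
        factor_groups.append(
            {
                "lincs": [(linc_pool[li], 1.0), (linc_pool[li + 1], 1.0)],
                "genes": [(gene_pool[gi], 1.0), (gene_pool[gi + 1], 1.0)],
                "delta_sign": 1.0,
            }
        )
        li += 2
        gi += 2

    factor_of: Dict[str, Tuple[int, float]] = {}
    for fi, grp in enumerate(factor_groups):
        for fid, loading in grp["lincs"] + grp["genes"]:
            factor_of[fid] = (fi, loading)
        for lid, ll in grp["lincs"]:
            for gid, gl in grp["genes"]:
                truth.trans_edges.append(
                    {"lincRNA_id": lid, "gene_id": gid, "sign": int(np.sign(ll * gl))}
                )
        d = grp["delta_sign"]
        for fid, loading in grp["lincs"] + grp["genes"]:
            truth.de_direction[fid] = "up" if loading * d > 0 else "down"

    # independent DELs (no planted trans partner) and independent DEGs
    indep_de: Dict[str, float] = {}
    for tid in linc_pool[li : li + cfg.n_extra_dels]:
        d = 1.0 if rng.random() < 0.5 else -1.0
        indep_de[tid] = d
        truth.de_direction[tid] = "up" if d > 0 else "down"
    free_genes = [g for g in gene_pool[gi:]]
    n_deg = int(round(cfg.de_frac_coding * len(free_genes)))
    for gid in free_genes[:n_deg]:
        d = 1.0 if rng.random() < 0.5 else -1.0
        indep_de[gid] = d
        truth.de_direction[gid] = "up" if d > 0 else "down"

    # co-DE pairs without a shared factor: genuinely correlated through the
    # group design, recorded so edge accounting can separate them from nulls
    de_lincs = [t.transcript_id for t in retained if t.transcript_id in truth.de_direction]
    de_genes = [g for g in gene_pool if g in truth.de_direction]
    planted = {(e["lincRNA_id"], e["gene_id"]) for e in truth.trans_edges}
    for lid in de_lincs:
        for gid in de_genes:
            if (lid, gid) not in planted and not (
                factor_of.get(lid, (None,))[0] is not None
                and factor_of.get(lid, (None,))[0] == factor_of.get(gid, (None,))[0]
            ):
                truth.confound_pairs.append({"lincRNA_id": lid, "gene_id": gid})

    # --- expression matrices ----------------------------------------------
    feature_ids = (
        [t.transcript_id for t in candidates]
        + gene_pool
        + [t.gene_id for t in known_ts]
    )
    baselines = {}
    for fid in feature_ids:
        base = cfg.baseline_log2_coding if fid.startswith("GENE_") else cfg.baseline_log2_linc
        baselines[fid] = base + rng.normal(0.0, cfg.baseline_sigma)

    stage6_ids = {tid for tid, f in truth.fate.items() if f == STAGE_NAMES[5]}

    def draw_matrix(sample_ids, group_sign, latent_sd: float) -> pd.DataFrame:
        """Log-normal FPKM draw; group_sign maps sample -> +-0.5 (0 = no design)."""
        n = len(sample_ids)
        delta_f = cfg.de_log2fc / (cfg.sigma_log2 * np.sqrt(cfg.trans_rho))
        f = {
            fi: rng.normal(0.0, latent_sd, size=n)
            + delta_f * grp["delta_sign"] * np.asarray([group_sign[s] for s in sample_ids])
            for fi, grp in enumerate(factor_groups)
        }
        rows = {}
        for fid in feature_ids:
            if fid in stage6_ids:
                rows[fid] = rng.uniform(0.02, 0.45, size=n)
                continue
            z = rng.normal(0.0, 1.0, size=n)
            if fid in factor_of:
                fi, loading = factor_of[fid]
                val = (
                    baselines[fid]
                    + loading * cfg.sigma_log2 * np.sqrt(cfg.trans_rho) * f[fi]
                    + cfg.sigma_log2 * np.sqrt(1.0 - cfg.trans_rho) * z
                )
            else:
                shift = indep_de.get(fid, 0.0) * cfg.de_log2fc
                g = np.asarray([group_sign[s] for s in sample_ids])
                val = baselines[fid] + shift * g + cfg.sigma_log2 * z
            fpkm = np.power(2.0, val)
            if truth.fate.get(fid) == RETAINED and fpkm.max() < 0.5:
                fpkm = fpkm * (0.6 / fpkm.max())  # keep retained detectable
            rows[fid] = fpkm
        return pd.DataFrame.from_dict(rows, orient="index", columns=sample_ids).loc[feature_ids]

    ga, gb = cfg.groups
    samples = [f"{ga}{i + 1}" for i in range(cfg.n_samples_per_group)] + [
        f"{gb}{i + 1}" for i in range(cfg.n_samples_per_group)
    ]
    group_of = {s: (ga if s.startswith(ga) else gb) for s in samples}
    group_sign = {s: (0.5 if group_of[s] == ga else -0.5) for s in samples}
    expr = ExpressionMatrix(
        draw_matrix(samples, group_sign, latent_sd=1.0), group_of, cfg.groups
    )

    vsamples = [f"V{i + 1:02d}" for i in range(cfg.n_validation_samples)]
    vgroup_of = {s: ("VA" if i < len(vsamples) // 2 else "VB") for i, s in enumerate(vsamples)}
    vsign = {s: 0.0 for s in vsamples}
    expr_validation = ExpressionMatrix(
        draw_matrix(vsamples, vsign, latent_sd=1.5), vgroup_of
    )

    # --- term annotation ---------------------------------------------------
    term_entries: Dict[str, Tuple[str, str, frozenset]] = {}
    factor_gene_ids = [gid for grp in factor_groups for gid, _ in grp["genes"]]
    for i in range(cfg.n_bp_terms):
        size = int(rng.integers(*cfg.term_size_range))
        if i == 0:  # one term enriched in planted target genes
            genes = set(factor_gene_ids) | set(
                rng.choice(gene_pool, size=5, replace=False)
            )
        else:
            genes = set(rng.choice(gene_pool, size=size, replace=False))
        tid = f"TERM_BP_{i + 1:04d}"
        term_entries[tid] = (f"biological process {i + 1}", BIOLOGICAL_PROCESS, frozenset(genes))
    for i in range(cfg.n_pathway_terms):
        size = int(rng.integers(*cfg.term_size_range))
        genes = set(rng.choice(gene_pool, size=size, replace=False))
        tid = f"TERM_PW_{i + 1:04d}"
        term_entries[tid] = (f"pathway {i + 1}", PATHWAY, frozenset(genes))
    term_map = TermMap(term_entries)

    return SimBundle(
        candidates=candidates,
        annotation=annotation,
        sequences=sequences,
        expr=expr,
        expr_validation=expr_validation,
        domain_hits=domain_hits,
        homology_hits=homology_hits,
        coding_scores=coding_scores,
        term_map=term_map,
        truth=truth,
        config=cfg,
    )


def generate(config: Optional[SimulationConfig] = None, out_dir=".", seed: Optional[int] = None) -> dict:
    """Write the complete fixture bundle to ``out_dir``; returns file paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = build(config, seed=seed)

    paths = {
        "candidates_gtf": out / "candidates.gtf",
        "annotation_gtf": out / "annotation.gtf",
        "fasta": out / "candidates.fa",
        "expression": out / "expression.tsv",
        "groups": out / "groups.tsv",
        "expression_validation": out / "expression_validation.tsv",
        "domain_hits": out / "domain_hits.tsv",
        "homology_hits": out / "homology_hits.tsv",
        "coding_scores": out / "coding_scores.tsv",
        "term_map": out / "term_map.tsv",
        "term_names": out / "term_names.tsv",
        "ground_truth": out / "ground_truth.json",
    }
    _io.write_gtf(bundle.candidates, paths["candidates_gtf"])
    _io.write_annotation_gtf(bundle.annotation, paths["annotation_gtf"])
    _io.write_fasta(bundle.sequences, paths["fasta"])
    _io.write_expression(bundle.expr, paths["expression"])
    pd.Series(bundle.expr.group_of).to_csv(paths["groups"], sep="\t", header=False)
    _io.write_expression(bundle.expr_validation, paths["expression_validation"])
    _io.write_hit_table(bundle.domain_hits, paths["domain_hits"])
    _io.write_hit_table(bundle.homology_hits, paths["homology_hits"])
    bundle.coding_scores.to_csv(paths["coding_scores"], sep="\t", header=False, float_format="%.6g")
    pairs, names = bundle.term_map.to_frames()
    pairs.to_csv(paths["term_map"], sep="\t", header=False, index=False)
    names.to_csv(paths["term_names"], sep="\t", header=False, index=False)
    paths["ground_truth"].write_text(json.dumps(bundle.truth.to_dict(), indent=1, sort_keys=True))
    return {k: str(v) for k, v in paths.items()}
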