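"""Readers and writers for GTF, expression TSV, FASTA, and hit tables.

GTF records are 1-based inclusive on disk and converted to the package's
0-based half-open convention on read (and back on write).
"""

from __future__ import annotations

import collections
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from Bio import SeqIO
from gffutils.feature import feature_from_line

from .models import (
    AnnotationSet,
    ExpressionMatrix,
    GenomicInterval,
    LincpipeError,
    TranscriptModel,
)


class GtfParseError(LincpipeError):
    pass


def read_gtf(path, class_code_attr: str = "class_code") -> list:
    """Read exon features from a GTF file into :class:`TranscriptModel` objects.

    Exon records are grouped by ``transcript_id``; 1-based inclusive
    coordinates become 0-based half-open. The transcript's class code is
    taken from ``class_code_attr`` when present, else ``'.'`` (the attribute
    name is configurable because assembler versions differ).
    """
    exons: dict[str, list[GenomicInterval]] = collections.defaultdict(list)
    gene_of: dict[str, str] = {}
    class_of: dict[str, str] = {}
    order: list[str] = []
    for lineno, raw in enumerate(Path(path).open(), start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9 or not (fields[3].isdigit() and fields[4].isdigit()):
            raise GtfParseError(f"{path}: malformed GTF at line {lineno}")
        try:
            feat = feature_from_line(line, dialect=None)
        except Exception as exc:  # gffutils raises assorted parse errors
            raise GtfParseError(f"{path}: malformed GTF at line {lineno}: {exc}") from exc
        if feat.featuretype != "exon":
            continue
        if feat.end < feat.start:
            raise GtfParseError(
                f"{path}: line {lineno}: exon end {feat.end} < start {feat.start}"
            )
        attrs = feat.attributes
        if "transcript_id" not in attrs or "gene_id" not in attrs:
            raise GtfParseError(
                f"{path}: line {lineno}: exon lacks transcript_id/gene_id"
            )
        tid = attrs["transcript_id"][0]
        exons[tid].append(
            GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand or ".")
        )
        gene_of[tid] = attrs["gene_id"][0]
        if class_code_attr in attrs:
            class_of[tid] = attrs[class_code_attr][0]
        if tid not in order:
            order.append(tid)

    transcripts = []
    for tid in order:
        try:
            transcripts.append(
                TranscriptModel(
                    transcript_id=tid,
                    gene_id=gene_of[tid],
                    exons=exons[tid],
                    class_code=class_of.get(tid, "."),
                )
            )
        except ValueError as exc:
            raise GtfParseError(f"{path}: transcript {tid}: {exc}") from exc
    return transcripts


def write_gtf(transcripts: Iterable[TranscriptModel], path, source: str = "lincpipe") -> None:
    """Write transcripts as GTF exon records (1-based inclusive coordinates).

    Output ordering is deterministic: by (chrom, span start, transcript_id).
    """
    ts = sorted(transcripts, key=lambda t: (t.chrom, t.span.start, t.transcript_id))
    with Path(path).open("w") as fh:
        for t in ts:
            for e in t.exons:
                attrs = (
                    f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}"; '
                    f'class_code "{t.class_code}";'
                )
                fh.write(
                    "\t".join(
                        [
                            e.chrom,
                            source,
                            "exon",
                            str(e.start + 1),
                            str(e.end),
                            ".",
                            e.strand,
                            ".",
                            attrs,
                        ]
                    )
                    + "\n"
                )


def read_annotation_gtf(path, biotype_attr: str = "biotype") -> AnnotationSet:
    """Read a reference annotation GTF whose exons carry a biotype attribute."""
    transcripts = read_gtf(path, class_code_attr="class_code")
    bio: dict[str, str] = {}
    for lineno, raw in enumerate(Path(path).open(), start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        feat = feature_from_line(line, dialect=None)
        if feat.featuretype != "exon":
            continue
        tid = feat.attributes["transcript_id"][0]
        if biotype_attr in feat.attributes:
            bio[tid] = feat.attributes[biotype_attr][0]
    return AnnotationSet.from_transcripts(
        transcripts, {t.transcript_id: bio.get(t.transcript_id, "other") for t in transcripts}
    )


def write_annotation_gtf(annotation: AnnotationSet, path, source: str = "lincpipe") -> None:
    """Write an annotation set with a per-exon ``biotype`` attribute."""
    ts = sorted(annotation, key=lambda t: (t.chrom, t.span.start, t.transcript_id))
    with Path(path).open("w") as fh:
        for t in ts:
            for e in t.exons:
                attrs = (
                    f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}"; '
                    f'biotype "{annotation.biotype[t.transcript_id]}";'
                )
                fh.write(
                    "\t".join(
                        [e.chrom, source, "exon", str(e.start + 1), str(e.end), ".", e.strand, ".", attrs]
                    )
                    + "\n"
                )


def attach_sequences(transcripts: Iterable[TranscriptModel], fasta_path) -> None:
    """Attach spliced sequences from a FASTA file in place, matched by id."""
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    for t in transcripts:
        if t.transcript_id in seqs:
            seq = seqs[t.transcript_id]
            if len(seq) != t.length:
                raise ValueError(
                    f"{t.transcript_id}: FASTA length {len(seq)} != exon sum {t.length}"
                )
            t.sequence = seq


def write_fasta(sequences: Mapping[str, str], path, width: int = 70) -> None:
    with Path(path).open("w") as fh:
        for name in sequences:
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_group_map(path) -> dict:
    """Two-column TSV (sample, group) -> dict."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "group"], dtype=str)
    return dict(zip(df["sample"], df["group"]))


def read_expression(
    path,
    group_map: Mapping[str, str],
    group_order: Optional[Sequence[str]] = None,
) -> ExpressionMatrix:
    """Read an FPKM TSV (first column feature ids, header row sample ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate feature id {dup!r}")
    return ExpressionMatrix(df, group_map, group_order)


def write_expression(expr: ExpressionMatrix, path, float_format: str = "%.6g") -> None:
    expr.values.to_csv(path, sep="\t", index_label="feature_id", float_format=float_format)


def read_hit_table(path, source: str = "domain") -> pd.DataFrame:
    """Read a (query_id, evalue) hit table.

    Accepts either a two-column TSV or the standard 12-column tabular
    alignment format, in which case columns 1 (query) and 11 (E-value) are
    used. Returns a DataFrame with columns ``query_id``, ``evalue`` and a
    ``source`` attribute in ``df.attrs``.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] >= 12:
        out = df.iloc[:, [0, 10]].copy()
    elif df.shape[1] == 2:
        out = df.copy()
    else:
        raise ValueError(
            f"{path}: expected 2 or 12 columns in hit table, got {df.shape[1]}"
        )
    out.columns = ["query_id", "evalue"]
    out["query_id"] = out["query_id"].astype(str)
    out["evalue"] = out["evalue"].astype(float)
    if (out["evalue"] < 0).any():
        raise ValueError(f"{path}: negative E-value in hit table")
    out.attrs["source"] = source
    return out


def write_hit_table(df: pd.DataFrame, path) -> None:
    df[["query_id", "evalue"]].to_csv(path, sep="\t", header=False, index=False)


def read_coding_scores(path) -> pd.DataFrame:
    """TSV (transcript_id, score_forward, score_reverse) -> DataFrame indexed by id."""
    df = pd.read_csv(
        path, sep="\t", header=None, names=["transcript_id", "score_forward", "score_reverse"]
    )
    return df.set_index("transcript_id")


def read_term_map(map_path, names_path=None):
    """Read a gene->term two-column TSV plus an optional term-description TSV.

    Returns the :class:`lincpipe.enrich.TermMap`.
    """
    from .enrich import TermMap

    df = pd.read_csv(map_path, sep="\t", header=None, names=["gene_id", "term_id"], dtype=str)
    names: dict[str, tuple] = {}
    if names_path is not None:
        nd = pd.read_csv(
            map_path if names_path is None else names_path,
            sep="\t",
            header=None,
            names=["term_id", "term_name", "category"],
            dtype=str,
        )
        names = {r.term_id: (r.term_name, r.category) for r in nd.itertuples()}
    terms: dict[str, dict] = {}
    for r in df.itertuples():
        entry = terms.setdefault(
            r.term_id,
            {
                "name": names.get(r.term_id, (r.term_id, "biological_process"))[0],
                "category": names.get(r.term_id, (r.term_id, "biological_process"))[1],
                "genes": set(),
            },
        )
        entry["genes"].add(r.gene_id)
    return TermMap(
        {tid: (e["name"], e["category"], frozenset(e["genes"])) for tid, e in terms.items()}
    )
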