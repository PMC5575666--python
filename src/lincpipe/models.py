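"""Domain types for assembled transcripts, annotations, and FPKM expression.

Coordinates are 0-based half-open throughout the package; GTF input/output
converts at the boundary (:mod:`lincpipe.io`). All overlap and window
arithmetic therefore works directly on ``[start, end)`` intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

VALID_STRANDS = ("+", "-", ".")


class LincpipeError(Exception):
    """Base class for errors raised by this package."""


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on one chromosome.

    Parameters
    ----------
    chrom : str
        Chromosome name.
    start : int
        0-based inclusive start.
    end : int
        0-based exclusive end; must be greater than ``start``.
    strand : str
        One of ``+``, ``-`` or ``.`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must be > start, got [{self.start}, {self.end})"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"strand must be one of {VALID_STRANDS}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """Positional overlap, ignoring strand."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def gap_to(self, other: "GenomicInterval") -> Optional[int]:
        """Gap in bp between the two intervals; 0 if they overlap.

        Returns ``None`` when the intervals lie on different chromosomes.
        """
        if self.chrom != other.chrom:
            return None
        return max(other.start - self.end, self.start - other.end, 0)


@dataclass
class TranscriptModel:
    """One assembled transcript: ordered exons on a single chromosome/strand.

    ``class_code`` carries the assembler's comparison category against the
    reference annotation ('u' marks intergenic transcripts). ``sequence``,
    when present, is the spliced transcript sequence and must match the
    summed exon length.
    """

    transcript_id: str
    gene_id: str
    exons: Sequence[GenomicInterval]
    class_code: str = "."
    sequence: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript needs >=1 exon")
        self.exons = tuple(sorted(self.exons, key=lambda e: e.start))
        chroms = {e.chrom for e in self.exons}
        if len(chroms) != 1:
            raise ValueError(
                f"{self.transcript_id}: exons on multiple chromosomes {sorted(chroms)}"
            )
        strands = {e.strand for e in self.exons}
        if len(strands) != 1:
            raise ValueError(f"{self.transcript_id}: exons on multiple strands")
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"{self.transcript_id}: overlapping exons "
                    f"[{a.start},{a.end}) and [{b.start},{b.end})"
                )
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError(
                f"{self.transcript_id}: sequence length {len(self.sequence)} "
                f"!= summed exon length {self.length}"
            )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def length(self) -> int:
        """Spliced transcript length: sum of exon lengths."""
        return sum(e.length for e in self.exons)

    @property
    def exon_count(self) -> int:
        return len(self.exons)

    @property
    def span(self) -> GenomicInterval:
        """Genomic footprint from first exon start to last exon end."""
        return GenomicInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )


# Biotype labels used by AnnotationSet.
PROTEIN_CODING = "protein_coding"
KNOWN_LINCRNA = "known_lincRNA"
OTHER = "other"


@dataclass
class AnnotationSet:
    """A reference annotation: transcripts with a biotype label each."""

    transcripts: dict = field(default_factory=dict)
    biotype: dict = field(default_factory=dict)

    @classmethod
    def from_transcripts(
        cls,
        transcripts: Iterable[TranscriptModel],
        biotype: Mapping[str, str] | str = OTHER,
    ) -> "AnnotationSet":
        """Build a set from transcripts plus a per-id biotype map or a single label."""
        tdict: dict[str, TranscriptModel] = {}
        bdict: dict[str, str] = {}
        for t in transcripts:
            if t.transcript_id in tdict:
                raise ValueError(f"duplicate transcript id {t.transcript_id}")
            tdict[t.transcript_id] = t
            if isinstance(biotype, str):
                bdict[t.transcript_id] = biotype
            else:
                bdict[t.transcript_id] = biotype[t.transcript_id]
        return cls(tdict, bdict)

    def __iter__(self):
        return iter(self.transcripts.values())

    def __len__(self) -> int:
        return len(self.transcripts)

    def subset(self, biotype: str) -> "AnnotationSet":
        keep = {i for i, b in self.biotype.items() if b == biotype}
        return AnnotationSet(
            {i: t for i, t in self.transcripts.items() if i in keep},
            {i: biotype for i in keep},
        )

    def gene_spans(self) -> dict:
        """Per-gene genomic footprint: union span of all transcripts of a gene.

        Genes whose transcripts sit on several chromosomes are not expected in
        valid annotations and raise.
        """
        spans: dict[str, GenomicInterval] = {}
        for t in self:
            s = t.span
            prev = spans.get(t.gene_id)
            if prev is None:
                spans[t.gene_id] = s
            else:
                if prev.chrom != s.chrom:
                    raise ValueError(
                        f"gene {t.gene_id} has transcripts on multiple chromosomes"
                    )
                strand = prev.strand if prev.strand == s.strand else "."
                spans[t.gene_id] = GenomicInterval(
                    s.chrom, min(prev.start, s.start), max(prev.end, s.end), strand
                )
        return spans


def group_loci(transcripts: Iterable[TranscriptModel]) -> dict:
    """Cluster transcripts into loci by single-linkage span overlap.

    Transcripts whose genomic spans overlap on the same chromosome and strand
    are merged into one locus. Returns ``{locus_id: set of transcript_ids}``
    with deterministic locus ids ``LOCUS_<n>`` ordered by genomic position.
    """
    ts = sorted(transcripts, key=lambda t: (t.chrom, t.strand, t.span.start, t.transcript_id))
    loci: dict[str, set] = {}
    n = 0
    cur_ids: list[str] = []
    cur_key = None
    cur_end = -1
    for t in ts:
        key = (t.chrom, t.strand)
        s = t.span
        if cur_key == key and s.start < cur_end:
            cur_ids.append(t.transcript_id)
            cur_end = max(cur_end, s.end)
        else:
            if cur_ids:
                n += 1
                loci[f"LOCUS_{n}"] = set(cur_ids)
            cur_ids = [t.transcript_id]
            cur_key = key
            cur_end = s.end
    if cur_ids:
        n += 1
        loci[f"LOCUS_{n}"] = set(cur_ids)
    return loci


class ExpressionMatrix:
    """FPKM values for features x samples with a two-group sample design.

    Thin wrapper around a :class:`pandas.DataFrame` (rows = features,
    columns = samples) plus a ``sample -> group`` assignment. Group order is
    preserved from ``group_order`` (or first appearance among samples) and
    fixes the numerator of fold changes downstream.
    """

    def __init__(
        self,
        values: pd.DataFrame,
        group_of: Mapping[str, str],
        group_order: Optional[Sequence[str]] = None,
    ) -> None:
        if values.index.duplicated().any():
            dup = values.index[values.index.duplicated()][0]
            raise ValueError(f"duplicate feature id {dup!r}")
        if values.columns.duplicated().any():
            raise ValueError("duplicate sample ids")
        arr = values.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise ValueError("expression values must be finite")
        if (arr < 0).any():
            raise ValueError("expression values must be non-negative (FPKM)")
        missing = [s for s in values.columns if s not in group_of]
        if missing:
            raise ValueError(f"samples missing from group map: {missing}")
        self.values = values.astype(float)
        self.group_of = {s: group_of[s] for s in values.columns}
        seen: list[str] = []
        for s in values.columns:
            g = self.group_of[s]
            if g not in seen:
                seen.append(g)
        if group_order is not None:
            if sorted(group_order) != sorted(seen):
                raise ValueError("group_order does not match groups present")
            self.groups = tuple(group_order)
        else:
            self.groups = tuple(seen)

    @property
    def feature_ids(self) -> list:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list:
        return list(self.values.columns)

    def group_samples(self, group: str) -> list:
        return [s for s in self.values.columns if self.group_of[s] == group]

    def group_values(self, group: str) -> pd.DataFrame:
        return self.values[self.group_samples(group)]

    def subset(self, feature_ids: Iterable[str]) -> "ExpressionMatrix":
        ids = [f for f in feature_ids if f in self.values.index]
        return ExpressionMatrix(self.values.loc[ids], self.group_of, self.groups)

    def __contains__(self, feature_id: str) -> bool:
        return feature_id in self.values.index
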