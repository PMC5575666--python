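"""Sequence-level coding-potential filters.

Implements six-frame translation, an ORF-fraction coding score that mirrors
the sign convention of coding-potential classifiers (score > 0 flags a
transcript as coding, on either strand), and exclusion of candidates by
external domain/homology hit tables at a strict E-value cutoff.

The built-in score is a documented heuristic — the fraction of the
transcript covered by its longest ATG-to-stop open reading frame, minus a
margin ``theta`` — and an ``external`` mode accepts real classifier output
(e.g. CPC/CPAT scores) verbatim.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Set

import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

from .models import LincpipeError, TranscriptModel

_CODON_TABLE = dict(standard_dna_table.forward_table)
_STOP_CODONS = set(standard_dna_table.stop_codons)
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

DEFAULT_EVALUE = 1e-5
DEFAULT_THETA = 0.3


@dataclass(frozen=True)
class CodingScore:
    """Per-strand coding score for one transcript (positive = coding)."""

    transcript_id: str
    score_forward: float
    score_reverse: float

    @property
    def is_coding(self) -> bool:
        return self.score_forward > 0 or self.score_reverse > 0


def reverse_complement(sequence: str) -> str:
    return sequence.translate(_COMPLEMENT)[::-1]


def _translate_codon(codon: str) -> str:
    # Any codon containing N is rendered 'X', even where the ambiguity would
    # resolve (e.g. GGN); keeps ORF handling conservative and deterministic.
    if "N" in codon:
        return "X"
    if codon in _STOP_CODONS:
        return "*"
    return _CODON_TABLE[codon]


def _translate_frame(sequence: str, frame: int) -> str:
    s = sequence[frame:]
    n = len(s) - len(s) % 3  # trailing 1-2 nt ignored
    return "".join(_translate_codon(s[i : i + 3]) for i in range(0, n, 3))


def six_frame_translate(sequence: str):
    """Translate a nucleotide sequence in all six reading frames.

    Returns a list of six peptide strings: frames +1, +2, +3 of the given
    sequence, then frames +1, +2, +3 of its reverse complement. Stop codons
    appear as ``*``; codons containing ``N`` appear as ``X``.
    """
    seq = _validate_sequence(sequence)
    if len(seq) < 3:
        raise ValueError("sequence shorter than one codon")
    rc = reverse_complement(seq)
    return [_translate_frame(seq, f) for f in range(3)] + [
        _translate_frame(rc, f) for f in range(3)
    ]


def _validate_sequence(sequence: str) -> str:
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"invalid nucleotides {sorted(bad)}")
    return seq


def _longest_orf_in_frame(seq: str, frame: int) -> int:
    """Longest ATG..stop ORF (nt, including the stop codon) in one frame.

    An N-containing codon never extends an ORF: open starts are abandoned
    when one is met.
    """
    best = 0
    open_starts: list[int] = []
    i = frame
    while i + 3 <= len(seq):
        codon = seq[i : i + 3]
        if "N" in codon:
            open_starts.clear()
        elif codon in _STOP_CODONS:
            if open_starts:
                best = max(best, i + 3 - open_starts[0])
                open_starts.clear()
        elif codon == "ATG":
            open_starts.append(i)
        i += 3
    return best


def longest_orf_length(sequence: str) -> int:
    """Length (nt, incl. stop) of the longest complete ORF over all six frames."""
    seq = _validate_sequence(sequence)
    rc = reverse_complement(seq)
    return max(
        max(_longest_orf_in_frame(seq, f) for f in range(3)),
        max(_longest_orf_in_frame(rc, f) for f in range(3)),
    )


def longest_orf_by_strand(sequence: str) -> tuple:
    """(forward, reverse) longest complete ORF lengths in nt."""
    seq = _validate_sequence(sequence)
    rc = reverse_complement(seq)
    return (
        max(_longest_orf_in_frame(seq, f) for f in range(3)),
        max(_longest_orf_in_frame(rc, f) for f in range(3)),
    )


def coding_score(
    transcript: TranscriptModel,
    mode: str = "heuristic",
    external: Optional[pd.DataFrame] = None,
    theta: float = DEFAULT_THETA,
) -> CodingScore:
    """Score a transcript's coding potential on both strands.

    ``heuristic`` mode scores each strand as
    ``longest ORF length / transcript length - theta`` so that a score > 0
    flags the strand as coding. ``external`` mode returns the transcript's
    row of an externally computed score table verbatim (same sign
    convention).
    """
    tid = transcript.transcript_id
    if mode == "external":
        if external is None or tid not in external.index:
            raise LincpipeError(f"no external coding score for transcript {tid}")
        row = external.loc[tid]
        return CodingScore(tid, float(row["score_forward"]), float(row["score_reverse"]))
    if mode != "heuristic":
        raise ValueError(f"unknown coding score mode {mode!r}")
    if transcript.sequence is None:
        raise LincpipeError(f"transcript {tid} has no sequence for heuristic scoring")
    fwd, rev = longest_orf_by_strand(transcript.sequence)
    length = len(transcript.sequence)
    return CodingScore(tid, fwd / length - theta, rev / length - theta)


def score_table(
    transcripts: Iterable[TranscriptModel],
    mode: str = "heuristic",
    external: Optional[pd.DataFrame] = None,
    theta: float = DEFAULT_THETA,
) -> dict:
    """Score many transcripts; returns ``{transcript_id: CodingScore}``."""
    return {
        t.transcript_id: coding_score(t, mode=mode, external=external, theta=theta)
        for t in transcripts
    }


def hit_filter(
    candidates: Set[str],
    hits: pd.DataFrame,
    evalue_threshold: float = DEFAULT_EVALUE,
) -> set:
    """Drop candidates with any hit below the E-value threshold (strict <).

    Candidates absent from the hit table survive; a hit at exactly the
    threshold also survives.
    """
    if evalue_threshold <= 0:
        raise ValueError("evalue_threshold must be > 0")
    if len(hits) == 0:
        return set(candidates)
    significant = set(hits.loc[hits["evalue"] < evalue_threshold, "query_id"])
    return set(candidates) - significant
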