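"""The six-filter cascade: boundaries, fate accounting, novelty, characterization."""

import itertools

import numpy as np
import pandas as pd
import pytest

from lincpipe import coding, simulate as sim
from lincpipe.identify import (
    RETAINED,
    CascadeParams,
    characterize,
    classify_novelty,
    run_cascade,
    stage_predicates,
)
from lincpipe.models import (
    AnnotationSet,
    ExpressionMatrix,
    GenomicInterval,
    LincpipeError,
    TranscriptModel,
)


def _expr(values, features):
    df = pd.DataFrame(
        values, index=features, columns=["YY1", "YY2", "YY3", "WH1", "WH2", "WH3"]
    )
    groups = {s: s[:2] for s in df.columns}
    return ExpressionMatrix(df, groups, ("YY", "WH"))


def _score(tid, fwd=-0.3, rev=-0.3):
    return coding.CodingScore(tid, fwd, rev)


def _empty_hits():
    return pd.DataFrame(columns=["query_id", "evalue"])


def _cascade_inputs(transcripts, fpkm=2.0):
    ids = [t.transcript_id for t in transcripts]
    expr = _expr(np.full((len(ids), 6), fpkm), ids)
    scores = {i: _score(i) for i in ids}
    return expr, scores, _empty_hits(), _empty_hits()


class TestCascadeBoundaries:
    def test_single_exon_long_transcript_removed_at_size_stage(self):
        t = TranscriptModel("t1", "g1", [GenomicInterval("chr1", 0, 1500)], class_code="u")
        _, report = run_cascade([t], *_cascade_inputs([t]))
        assert report.fate["t1"] == "size_and_exons"

    def test_exactly_200_bp_two_exons_passes_size_stage(self):
        t = TranscriptModel(
            "t1", "g1",
            [GenomicInterval("chr1", 0, 100), GenomicInterval("chr1", 500, 600)],
            class_code="u",
        )
        lincs, report = run_cascade([t], *_cascade_inputs([t]))
        assert report.fate["t1"] == RETAINED
        assert [x.transcript_id for x in lincs] == ["t1"]

    def test_199_bp_removed(self):
        t = TranscriptModel(
            "t1", "g1",
            [GenomicInterval("chr1", 0, 100), GenomicInterval("chr1", 500, 599)],
            class_code="u",
        )
        _, report = run_cascade([t], *_cascade_inputs([t]))
        assert report.fate["t1"] == "size_and_exons"

    def test_fpkm_exactly_half_retained(self):
        t = TranscriptModel(
            "t1", "g1",
            [GenomicInterval("chr1", 0, 100), GenomicInterval("chr1", 500, 600)],
            class_code="u",
        )
        expr, scores, dh, hh = _cascade_inputs([t], fpkm=0.0)
        expr.values.iloc[0, 0] = 0.5  # one sample at the boundary
        _, report = run_cascade([t], expr, scores, dh, hh)
        assert report.fate["t1"] == RETAINED

    def test_fpkm_below_half_everywhere_removed(self):
        t = TranscriptModel(
            "t1", "g1",
            [GenomicInterval("chr1", 0, 100), GenomicInterval("chr1", 500, 600)],
            class_code="u",
        )
        _, report = run_cascade([t], *_cascade_inputs([t], fpkm=0.49))
        assert report.fate["t1"] == "expression"

    def test_coding_score_positive_on_either_strand_removed(self):
        t = TranscriptModel(
            "t1", "g1",
            [GenomicInterval("chr1", 0, 100), GenomicInterval("chr1", 500, 600)],
            class_code="u",
        )
        expr, _, dh, hh = _cascade_inputs([t])
        _, report = run_cascade([t], expr, {"t1": _score("t1", rev=0.1)}, dh, hh)
        assert report.fate["t1"] == "coding_potential"

    def test_missing_expression_raises_naming_transcript(self):
        t = TranscriptModel(
            "t1", "g1",
            [GenomicInterval("chr1", 0, 100), GenomicInterval("chr1", 500, 600)],
            class_code="u",
        )
        expr = _expr(np.ones((1, 6)), ["other"])
        with pytest.raises(LincpipeError, match="t1"):
            run_cascade([t], expr, {"t1": _score("t1")}, _empty_hits(), _empty_hits())


class TestCascadeOnFixture:
    def test_fate_recovers_planted_truth_exactly(self, bundle):
        scores = {
            tid: coding.CodingScore(tid, r.score_forward, r.score_reverse)
            for tid, r in bundle.coding_scores.iterrows()
        }
        _, report = run_cascade(
            bundle.candidates, bundle.expr, scores,
            bundle.domain_hits, bundle.homology_hits,
        )
        assert report.fate == bundle.truth.fate

    def test_survivor_counts_non_increasing(self, bundle):
        scores = coding.score_table(bundle.candidates, theta=bundle.config.theta)
        _, report = run_cascade(
            bundle.candidates, bundle.expr, scores,
            bundle.domain_hits, bundle.homology_hits,
        )
        assert all(
            a >= b
            for a, b in zip(report.survivors_per_stage, report.survivors_per_stage[1:])
        )
        assert report.survivors_per_stage[-1] == report.n_retained

    def test_retained_satisfy_all_predicates(self, bundle):
        scores = coding.score_table(bundle.candidates, theta=bundle.config.theta)
        lincs, _ = run_cascade(
            bundle.candidates, bundle.expr, scores,
            bundle.domain_hits, bundle.homology_hits,
        )
        preds = stage_predicates(
            bundle.expr, scores, bundle.domain_hits, bundle.homology_hits,
            CascadeParams(),
        )
        for t in lincs:
            assert all(p(t) for p in preds), t.transcript_id

    def test_stage_order_does_not_change_survivors(self, bundle):
        """Filters are independent predicates: any order of stages 2-5 gives
        the same final lincRNA set (fate attribution may differ)."""
        scores = coding.score_table(bundle.candidates, theta=bundle.config.theta)
        preds = stage_predicates(
            bundle.expr, scores, bundle.domain_hits, bundle.homology_hits,
            CascadeParams(),
        )
        baseline = {
            t.transcript_id
            for t in bundle.candidates
            if all(p(t) for p in preds)
        }
        for perm in itertools.islice(itertools.permutations(range(1, 5)), 5):
            order = [0] + list(perm) + [5]
            alive = list(bundle.candidates)
            for k in order:
                alive = [t for t in alive if preds[k](t)]
            assert {t.transcript_id for t in alive} == baseline


class TestNovelty:
    def _linc(self, start, end, tid="L1", strand="+"):
        return TranscriptModel(tid, "g", [GenomicInterval("chr1", start, end, strand)],
                               class_code="u")

    def _known(self, start, end, strand="+"):
        t = TranscriptModel("K1", "kg", [GenomicInterval("chr1", start, end, strand)])
        return AnnotationSet.from_transcripts([t], "known_lincRNA")

    def test_distant_transcript_is_novel(self):
        res = classify_novelty([self._linc(0, 1000)], self._known(6000, 7000))
        assert res == {"L1": "novel"}

    def test_single_base_overlap_is_known(self):
        res = classify_novelty([self._linc(0, 1000)], self._known(999, 2000))
        assert res == {"L1": "known_overlap"}

    def test_overlap_is_strand_ignorant_by_default(self):
        res = classify_novelty([self._linc(0, 1000, strand="+")],
                               self._known(500, 1500, strand="-"))
        assert res == {"L1": "known_overlap"}
        res = classify_novelty([self._linc(0, 1000, strand="+")],
                               self._known(500, 1500, strand="-"), strand_aware=True)
        assert res == {"L1": "novel"}

    def test_fixture_flags_recovered(self, bundle):
        scores = coding.score_table(bundle.candidates, theta=bundle.config.theta)
        lincs, _ = run_cascade(
            bundle.candidates, bundle.expr, scores,
            bundle.domain_hits, bundle.homology_hits,
        )
        assert classify_novelty(lincs, bundle.annotation) == bundle.truth.novelty


class TestCharacterize:
    def test_arithmetic_identity(self):
        t = TranscriptModel(
            "t1", "g1",
            [GenomicInterval("chr1", 0, 100), GenomicInterval("chr1", 500, 700)],
            class_code="u",
        )
        one = AnnotationSet.from_transcripts([t], "other")
        summary, per_t = characterize([t], one, one)
        row = summary.loc["novel_lincRNA"]
        assert row["mean_transcript_length"] == 300
        assert row["mean_exon_length"] == 150
        assert row["mean_exon_number"] == 2
        assert len(per_t) == 3

    def test_empty_set_rejected(self):
        t = TranscriptModel("t1", "g1", [GenomicInterval("chr1", 0, 100)])
        one = AnnotationSet.from_transcripts([t], "other")
        with pytest.raises(ValueError):
            characterize([], one, one)

    def test_generator_means_recovered_within_three_se(self):
        """Feature distributions drawn at n=500 recover the configured means."""
        cfg = sim.SimulationConfig(seed=3)
        rng = np.random.default_rng(3)
        layout = sim._Layout(cfg, rng)
        profile = cfg.novel_linc_profile
        ts = [
            TranscriptModel(f"t{i}", f"g{i}", layout.place(profile), class_code="u")
            for i in range(500)
        ]
        lengths = np.array([t.length for t in ts])
        exon_counts = np.array([t.exon_count for t in ts])
        exon_lens = np.array([e.length for t in ts for e in t.exons])
        for observed, expected in [
            (lengths, profile.mean_transcript_length),
            (exon_counts, profile.mean_exon_number),
            (exon_lens, profile.mean_exon_len),
        ]:
            se = observed.std(ddof=1) / np.sqrt(len(observed))
            assert abs(observed.mean() - expected) < 3 * se + 1.0
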