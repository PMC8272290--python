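import numpy as np
import pytest

from chronotome.io_formats import TranscriptModel, ValidationError
from chronotome.splice_events import (
    ASEvent,
    as_ratio_series,
    build_composite_model,
    call_events,
    classify_gene,
    event_expression_series,
    event_type_shares,
    representative_event_counts,
)
from conftest import make_matrix


def tx(tid, exons, gene="g1", chrom="chr1", strand="+"):
    return TranscriptModel.from_coords(tid, gene, chrom, strand, exons)


class TestCompositeModel:
    def test_single_isoform_composite(self):
        t = tx("t1", [(0, 100), (200, 300)])
        comp = build_composite_model([t])
        assert comp.merged_exons == ((0, 100), (200, 300))
        assert dict(comp.intron_catalogue) == {(100, 200): frozenset({"t1"})}

    def test_overlapping_isoforms_merge_and_pool_introns(self):
        a = tx("a", [(0, 100), (200, 300)])
        b = tx("b", [(50, 150), (200, 300)])
        comp = build_composite_model([a, b])
        assert comp.merged_exons == ((0, 150), (200, 300))
        assert set(comp.intron_catalogue) == {(100, 200), (150, 200)}

    def test_identical_isoforms_idempotent_with_both_contributors(self):
        a = tx("a", [(0, 100), (200, 300)])
        b = tx("b", [(0, 100), (200, 300)])
        comp = build_composite_model([a, b])
        assert comp.merged_exons == ((0, 100), (200, 300))
        assert comp.intron_catalogue[(100, 200)] == frozenset({"a", "b"})

    def test_mixed_strand_rejected(self):
        a = tx("a", [(0, 100), (200, 300)], strand="+")
        b = tx("b", [(0, 100), (200, 300)], strand="-")
        with pytest.raises(ValidationError):
            build_composite_model([a, b])


class TestCallEvents:
    def test_identical_alternative_isoform_yields_no_events(self):
        ref = tx("t1", [(0, 100), (200, 300), (400, 500)])
        alt = tx("t2", [(0, 100), (200, 300), (400, 500)])
        comp = build_composite_model([ref, alt])
        assert call_events(comp, alt) == []

    def test_consecutive_skipped_exons_merge_into_one_event(self, five_exon_layout):
        # alternative joins E1 -> E4 skipping E2 and E3: ONE ES, run length 2
        ref = tx("t1", five_exon_layout)
        alt = tx("t2", [five_exon_layout[0]] + five_exon_layout[3:])
        comp = build_composite_model([ref, alt])
        events = call_events(comp, alt)
        assert [(e.event_type, e.span, e.merged_count) for e in events] == [
            ("ES", (200, 500), 2)
        ]

    def test_terminal_intron_retention_is_omitted(self, five_exon_layout):
        # alternative's FIRST exon retains the intron after the reference's
        # first exon -> no event
        ref = tx("t1", five_exon_layout)
        alt = tx("t2", [(0, 300)] + five_exon_layout[2:])
        comp = build_composite_model([ref, alt])
        assert call_events(comp, alt) == []
        assert classify_gene([ref, alt]).status == "no_AS"

    def test_internal_intron_retention_called_once(self, five_exon_layout):
        ref = tx("t1", five_exon_layout)
        alt = tx("t2", [(0, 100), (200, 500), (600, 700), (800, 900)])
        comp = build_composite_model([ref, alt])
        events = call_events(comp, alt)
        assert [(e.event_type, e.span) for e in events] == [("IR", (300, 400))]

    def test_shared_donor_different_acceptor_is_aa_on_plus(self):
        # reference intron [100,200); alternative intron [100,250)
        ref = tx("t1", [(0, 100), (200, 300), (400, 500), (600, 700)])
        alt = tx("t2", [(0, 100), (250, 300), (400, 500), (600, 700)])
        comp = build_composite_model([ref, alt])
        ev_alt = call_events(comp, alt)
        assert [(e.event_type, e.span) for e in ev_alt] == [("AA", (100, 250))]
        ev_ref = call_events(comp, ref)
        assert [(e.event_type, e.span) for e in ev_ref] == [("AA", (100, 200))]

    def test_same_change_on_minus_strand_is_ad(self):
        ref = tx("t1", [(0, 100), (200, 300), (400, 500), (600, 700)], strand="-")
        alt = tx("t2", [(0, 100), (250, 300), (400, 500), (600, 700)], strand="-")
        comp = build_composite_model([ref, alt])
        assert [e.event_type for e in call_events(comp, alt)] == ["AD"]

    def test_mutually_exclusive_exons(self):
        ref = tx("t1", [(0, 100), (200, 300), (400, 500), (700, 800), (900, 1000)])
        alt = tx("t2", [(0, 100), (200, 300), (550, 650), (700, 800), (900, 1000)])
        comp = build_composite_model([ref, alt])
        for iso in (ref, alt):
            events = call_events(comp, iso)
            assert [(e.event_type, e.span, e.merged_count) for e in events] == [
                ("ME", (400, 650), 1)
            ]

    def test_skip_intron_does_not_double_as_alt_site(self, five_exon_layout):
        # the ES junction shares its donor/acceptor with reference introns;
        # no spurious AA/AD may be reported on the reference isoform
        ref = tx("t1", five_exon_layout)
        alt = tx("t2", [five_exon_layout[0]] + five_exon_layout[3:])
        comp = build_composite_model([ref, alt])
        assert call_events(comp, ref) == []

    def test_gene_mismatch_rejected(self):
        comp = build_composite_model([tx("t1", [(0, 100), (200, 300)])])
        with pytest.raises(ValidationError):
            call_events(comp, tx("x", [(0, 100), (200, 300)], gene="g2"))

    def test_strand_reflection_swaps_aa_and_ad(self):
        # mirroring coordinates while keeping the strand annotation turns a
        # donor-side change into an acceptor-side change
        layout_ref = [(0, 100), (200, 300), (400, 500), (600, 700)]
        layout_alt = [(0, 100), (250, 300), (400, 500), (600, 700)]
        L = 700

        def mirror(exons):
            return sorted((L - e, L - s) for s, e in exons)

        for strand in "+-":
            fwd = classify_gene(
                [tx("t1", layout_ref, strand=strand), tx("t2", layout_alt, strand=strand)]
            )
            rev = classify_gene(
                [
                    tx("t1", mirror(layout_ref), strand=strand),
                    tx("t2", mirror(layout_alt), strand=strand),
                ]
            )
            swap = {"AA": "AD", "AD": "AA", "IR": "IR", "ES": "ES", "ME": "ME"}
            fwd_types = sorted(swap[e.event_type] for e in fwd.events)
            rev_types = sorted(e.event_type for e in rev.events)
            assert fwd_types == rev_types and len(fwd_types) > 0


class TestEventQuantification:
    def _ir_gene(self):
        ref = tx("g1.1", [(0, 100), (200, 300), (400, 500), (600, 700)])
        alt = tx("g1.2", [(0, 100), (200, 500), (600, 700)])
        return [ref, alt]

    def test_representative_transcript_is_highest_expressed(self):
        isoforms = self._ir_gene()
        expr = make_matrix({"g1.1": [1] * 8, "g1.2": [5] * 8})
        assert representative_event_counts(isoforms, expr) == {"IR": 1}

    def test_reference_representative_has_no_events(self):
        isoforms = self._ir_gene()
        expr = make_matrix({"g1.1": [5] * 8, "g1.2": [1] * 8})
        assert representative_event_counts(isoforms, expr) == {}

    def test_expression_tie_breaks_to_smaller_id(self):
        isoforms = self._ir_gene()
        expr = make_matrix({"g1.1": [2] * 8, "g1.2": [2] * 8})
        assert representative_event_counts(isoforms, expr) == {}

    def test_event_expression_multiplies_by_merged_count(self):
        ev_ir = ASEvent("g1", "g1.2", "IR", "chr1", 300, 400, "+", 1)
        ev_es = ASEvent("g1", "g1.2", "ES", "chr1", 200, 700, "+", 2)
        expr = make_matrix({"g1.2": [3] * 8})
        out = event_expression_series([ev_ir, ev_es], expr)
        assert (out.loc["IR"] == 3).all()
        assert (out.loc["ES"] == 6).all()
        assert (out.loc["ME"] == 0).all()

    def test_no_events_gives_zero_series(self):
        expr = make_matrix({"g1.2": [3] * 8})
        assert (event_expression_series([], expr).to_numpy() == 0).all()


class TestASRatio:
    def _annotation(self):
        return {"g1": TestEventQuantification()._ir_gene()}

    def test_reference_only_gene_has_zero_transcript_ratio(self):
        ann = {"g1": [tx("g1.1", [(0, 100), (200, 300)])]}
        expr = make_matrix({"g1.1": [8] * 8})
        res = as_ratio_series(ann, expr, mode="transcript")
        assert (res.per_gene.loc["g1"] == 0).all()

    def test_transcript_mode_ratio_arithmetic(self):
        expr = make_matrix({"g1.1": [8] * 8, "g1.2": [2] * 8})
        res = as_ratio_series(self._annotation(), expr, mode="transcript")
        assert np.allclose(res.per_gene.loc["g1"], 0.2)
        assert np.allclose(res.genome_wide, 0.2)

    def test_event_mode_uses_merged_count_weighting(self, five_exon_layout):
        # one ES with merged_count 2, AS isoform at 2, gene total 10 -> 0.4
        ref = tx("g1.1", five_exon_layout)
        alt = tx("g1.2", [five_exon_layout[0]] + five_exon_layout[3:])
        expr = make_matrix({"g1.1": [8] * 8, "g1.2": [2] * 8})
        res = as_ratio_series({"g1": [ref, alt]}, expr, mode="event")
        assert np.allclose(res.per_gene.loc["g1"], 0.4)

    def test_zero_expression_sample_flagged_not_zero(self):
        expr = make_matrix({"g1.1": [8] * 7 + [0], "g1.2": [2] * 7 + [0]})
        res = as_ratio_series(self._annotation(), expr, mode="transcript")
        assert np.isnan(res.per_gene.loc["g1"].iloc[-1])
        assert np.isnan(res.genome_wide.iloc[-1])

    def test_transcript_ratio_bounded_and_monotone(self):
        base = make_matrix({"g1.1": [8] * 8, "g1.2": [2] * 8})
        more = make_matrix({"g1.1": [8] * 8, "g1.2": [3] * 8})
        r0 = as_ratio_series(self._annotation(), base, mode="transcript").per_gene
        r1 = as_ratio_series(self._annotation(), more, mode="transcript").per_gene
        assert ((r0 >= 0) & (r0 <= 1)).all().all()
        assert (r1.to_numpy() >= r0.to_numpy()).all()


class TestEventTypeShares:
    def test_single_type_is_100_percent(self):
        assert event_type_shares({"IR": 7}) == {"IR": 100.0}

    def test_equal_counts_split_evenly(self):
        shares = event_type_shares({t: 3 for t in ("IR", "AA", "AD", "ES", "ME")})
        assert all(v == 20.0 for v in shares.values())

    def test_half_up_rounding_to_one_decimal(self):
        assert event_type_shares({"a": 1, "b": 799})["a"] == 0.1  # 0.125 -> 0.1
        assert event_type_shares({"a": 1, "b": 399})["a"] == 0.3  # 0.25 -> 0.3
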