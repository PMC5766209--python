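"""Gene-model derivation, pair enumeration, and category assignment."""
import pytest

from spliceorder.gene_models import (
    AdjacentIntronPair,
    CategoryLabel,
    CircleRecord,
    GenomicInterval,
    apply_alt_ss_labels,
    apply_skip_labels,
    assign_positional_categories,
    assign_positional_category,
    build_gene_models,
    collapse_alt_ss,
    enumerate_adjacent_pairs,
    find_skippable_exons,
    flag_unique_introns,
    is_circle_negative,
    match_circles,
    predict_circle_candidates,
)

from conftest import make_model


class TestIntronDerivation:
    def test_plus_strand_gaps(self, three_exon_plus):
        ivs = [(i.interval.start, i.interval.end) for i in three_exon_plus.introns]
        assert ivs == [(200, 300), (400, 500)]
        assert [i.index for i in three_exon_plus.introns] == [1, 2]

    def test_minus_strand_transcription_order(self, three_exon_minus):
        first = three_exon_minus.introns[0]
        assert (first.interval.start, first.interval.end) == (400, 500)
        assert first.index == 1

    def test_single_exon_no_introns(self):
        (m,) = build_gene_models([("t", "g", "chr1", "+", [(10, 50)])])
        assert m.introns == []

    def test_overlapping_exons_skipped(self, caplog):
        models = build_gene_models(
            [("bad", "g", "chr1", "+", [(10, 100), (50, 200)])]
        )
        assert models == []

    def test_exons_and_introns_tile_span(self, six_exon_plus):
        """Round-trip invariant: exons and introns tile the transcript with
        no overlap and no gap."""
        pieces = [(e.start, e.end) for e in six_exon_plus.exons] + [
            (i.interval.start, i.interval.end) for i in six_exon_plus.introns
        ]
        pieces.sort()
        for (s1, e1), (s2, e2) in zip(pieces, pieces[1:]):
            assert e1 == s2
        span = six_exon_plus.span
        assert pieces[0][0] == span.start and pieces[-1][1] == span.end

    def test_strand_relabel_preserves_intervals_reverses_order(self):
        spans = [(0, 100), (200, 300), (500, 600), (900, 1000)]
        plus = make_model("p", "+", spans)
        minus = make_model("m", "-", spans)
        plus_ivs = {(i.interval.start, i.interval.end) for i in plus.introns}
        minus_ivs = {(i.interval.start, i.interval.end) for i in minus.introns}
        assert plus_ivs == minus_ivs
        n = len(spans) - 1
        for pi in plus.introns:
            mi = next(
                i for i in minus.introns if i.interval.start == pi.interval.start
            )
            assert mi.index == n - pi.index + 1


class TestPairEnumeration:
    @pytest.mark.parametrize(
        "n_exons,expected_pairs", [(4, 2), (2, 0), (6, 4)]
    )
    def test_pair_count(self, n_exons, expected_pairs):
        spans = [(i * 1000, i * 1000 + 100) for i in range(n_exons)]
        pairs = enumerate_adjacent_pairs([make_model("t", "+", spans)])
        assert len(pairs) == expected_pairs

    def test_two_transcripts_counts_add(self):
        spans_a = [(i * 1000, i * 1000 + 100) for i in range(5)]
        spans_b = [(i * 1000 + 50_000, i * 1000 + 50_100) for i in range(5)]
        models = [make_model("a", "+", spans_a), make_model("b", "+", spans_b)]
        assert len(enumerate_adjacent_pairs(models)) == 6

    def test_identical_pair_merged_across_isoforms(self):
        spans = [(0, 100), (200, 300), (400, 500)]
        models = [make_model("a", "+", spans), make_model("b", "+", spans)]
        pairs = enumerate_adjacent_pairs(models)
        assert len(pairs) == 1
        assert sorted(pairs[0].transcript_ids) == ["a", "b"]

    def test_pair_indices_consecutive(self, six_exon_plus):
        for p in enumerate_adjacent_pairs([six_exon_plus]):
            assert p.upstream.index + 1 == p.downstream.index
            assert p.internal_exon.start >= 0


class TestUniqueness:
    def test_singleton_sites_unique(self, six_exon_plus):
        pairs = enumerate_adjacent_pairs([six_exon_plus])
        flag_unique_introns(pairs, six_exon_plus.introns)
        assert all(p.unique for p in pairs)

    def test_shared_alt_ss_not_unique(self):
        # isoform b's first intron shares its 3'ss with a's but has a
        # different 5'ss -> the a pair containing that intron is non-unique
        a = make_model("a", "+", [(0, 100), (300, 400), (600, 700), (900, 950)])
        b = make_model("b", "+", [(0, 150), (300, 400), (600, 700), (900, 950)])
        pairs = enumerate_adjacent_pairs([a, b])
        introns = a.introns + b.introns
        flag_unique_introns(pairs, introns)
        by_id = {p.pair_id: p for p in pairs}
        first_pairs = [p for p in pairs if p.upstream.interval.start in (100, 150)]
        assert first_pairs and all(not p.unique for p in first_pairs)

    def test_duplicate_isoform_not_unique_by_default(self):
        spans = [(0, 100), (300, 400), (600, 700)]
        models = [make_model("a", "+", spans), make_model("b", "+", spans)]
        pairs = enumerate_adjacent_pairs(models)
        introns = [i for m in models for i in m.introns]
        flag_unique_introns(pairs, introns)
        assert all(not p.unique for p in pairs)
        # relaxed gene scope treats the duplicate as one intron
        flag_unique_introns(
            pairs, introns, scope="gene", transcript_to_gene={"a": "g", "b": "g"}
        )
        assert all(p.unique for p in pairs)


class TestPositionalCategories:
    def test_first_middle_last_partition(self, six_exon_plus):
        pairs = enumerate_adjacent_pairs([six_exon_plus])
        labels = [assign_positional_category(p, six_exon_plus) for p in pairs]
        assert labels.count(CategoryLabel.FIRST) == 1
        assert labels.count(CategoryLabel.LAST) == 1
        assert labels.count(CategoryLabel.MIDDLE) == len(pairs) - 2
        assert len(pairs) == six_exon_plus.n_introns - 1

    def test_two_intron_transcript_excluded(self, three_exon_plus):
        pairs = enumerate_adjacent_pairs([three_exon_plus])
        assert assign_positional_category(pairs[0], three_exon_plus) is None

    def test_bulk_assignment_mutually_exclusive(self, six_exon_plus):
        pairs = enumerate_adjacent_pairs([six_exon_plus])
        assign_positional_categories(pairs, [six_exon_plus])
        for p in pairs:
            positional = p.categories & {
                CategoryLabel.FIRST, CategoryLabel.MIDDLE, CategoryLabel.LAST
            }
            assert len(positional) == 1


class TestSkipping:
    def _inclusion_and_skip(self):
        # inclusion isoform: 5 exons / 4 introns; skip isoform joins
        # ss5 of intron 2 to ss3 of intron 3, skipping exon 3
        inc = make_model(
            "inc", "+",
            [(0, 100), (200, 300), (400, 500), (600, 700), (800, 900)],
        )
        skp = make_model(
            "skp", "+", [(0, 100), (200, 300), (600, 700), (800, 900)]
        )
        return inc, skp

    def test_single_skip_detected_and_labeled(self):
        inc, skp = self._inclusion_and_skip()
        events = find_skippable_exons([inc, skp])
        single = [e for e in events if len(e.skipped_exons) == 1]
        assert len(single) == 1
        ev = single[0]
        assert (ev.skip_intron.start, ev.skip_intron.end) == (300, 600)
        assert [(e.start, e.end) for e in ev.skipped_exons] == [(400, 500)]
        # skip intron coordinates reconstructible from run + internal exon
        run = ev.intron_run
        assert ev.skip_intron.start == run[0].start
        assert ev.skip_intron.end == run[-1].end

        pairs = enumerate_adjacent_pairs([inc, skp])
        apply_skip_labels(pairs, [inc, skp], events=[ev])
        by_cat = {
            c: {p.pair_id for p in pairs if c in p.categories}
            for c in (
                CategoryLabel.SKIP_BEFORE,
                CategoryLabel.SKIP_INTERNAL,
                CategoryLabel.SKIP_AFTER,
            )
        }
        assert all(len(v) == 1 for v in by_cat.values())
        internal = next(iter(by_cat[CategoryLabel.SKIP_INTERNAL]))
        assert "300-400" in internal and "500-600" in internal

    def test_multi_skip_middle_and_flank(self):
        inc = make_model(
            "inc", "+",
            [(0, 100), (200, 300), (400, 500), (600, 700), (800, 900), (1000, 1100)],
        )
        skp = make_model("skp", "+", [(0, 100), (200, 300), (800, 900), (1000, 1100)])
        events = [e for e in find_skippable_exons([inc, skp]) if len(e.skipped_exons) == 2]
        assert len(events) == 1
        pairs = enumerate_adjacent_pairs([inc, skp])
        apply_skip_labels(pairs, [inc, skp], events=events)
        middles = [p for p in pairs if CategoryLabel.MULTI_SKIP_MIDDLE in p.categories]
        flanks = [p for p in pairs if CategoryLabel.MULTI_SKIP_FLANK in p.categories]
        assert len(middles) == 2 and len(flanks) == 2

    def test_no_matching_intron_no_events(self, six_exon_plus):
        assert find_skippable_exons([six_exon_plus]) == []


class TestAltSS:
    def test_alt5_group_shortest_representative(self):
        a = make_model("a", "+", [(0, 100), (500, 600), (900, 1000)])
        b = make_model("b", "+", [(0, 200), (500, 600), (900, 1000)])
        alt5, alt3, reps = collapse_alt_ss(a.introns + b.introns)
        assert len(alt5) == 1
        rep = next(iter(reps["alt5"]))
        assert (rep.start, rep.end) == (200, 500)  # the shorter intron

    def test_alt3_group_shortest_representative(self):
        a = make_model("a", "+", [(0, 100), (400, 500), (900, 1000)])
        b = make_model("b", "+", [(0, 100), (500, 600), (900, 1000)])
        _, alt3, reps = collapse_alt_ss(a.introns + b.introns)
        assert len(alt3) == 1
        rep = next(iter(reps["alt3"]))
        assert (rep.start, rep.end) == (100, 400)

    def test_unique_sites_no_group(self, six_exon_plus):
        alt5, alt3, reps = collapse_alt_ss(six_exon_plus.introns)
        assert alt5 == [] and alt3 == []

    def test_pair_labels(self):
        a = make_model("a", "+", [(0, 100), (500, 600), (900, 1000)])
        b = make_model("b", "+", [(0, 200), (500, 600), (900, 1000)])
        pairs = enumerate_adjacent_pairs([a, b])
        _, _, reps = collapse_alt_ss(a.introns + b.introns)
        apply_alt_ss_labels(pairs, reps)
        labeled = [p for p in pairs if CategoryLabel.ALT5_FLANK in p.categories]
        assert labeled and all(
            p.upstream.interval.start == 200 or p.downstream.interval.start == 200
            for p in labeled
        )


class TestCircles:
    def _pair(self):
        m = make_model("t", "+", [(0, 100), (300, 400), (600, 700), (900, 1000)])
        return m, enumerate_adjacent_pairs([m])

    def test_before_match(self):
        m, pairs = self._pair()
        before, after, n_un = match_circles([CircleRecord("chr1", 300, 400)], pairs)
        assert n_un == 0
        # circle starting at exon [300,400) matches the pair whose upstream
        # intron ends at 300
        assert any(p.upstream.interval.end == 300 for p in before)
        assert all(CategoryLabel.CIRCLE_BEFORE in p.categories for p in before)

    def test_after_match(self):
        m, pairs = self._pair()
        before, after, _ = match_circles([CircleRecord("chr1", 600, 700)], pairs)
        assert any(p.downstream.interval.start == 700 for p in after)

    def test_unaligned_circle_dropped(self):
        m, pairs = self._pair()
        before, after, n_un = match_circles([CircleRecord("chr1", 310, 390)], pairs)
        assert (before, after, n_un) == ([], [], 1)

    def test_minus_strand_match(self):
        m = make_model("tm", "-", [(0, 100), (300, 400), (600, 700), (900, 1000)])
        pairs = enumerate_adjacent_pairs([m])
        before, after, _ = match_circles([CircleRecord("chr1", 600, 700)], pairs)
        # on '-' the circle's transcription-first boundary is its genomic end:
        # upstream intron [700,900) starts (genomically) at 700
        assert any(p.upstream.interval.start == 700 for p in before)


class TestCirclePrediction:
    def _long_flank_model(self, up, down):
        return make_model(
            "t", "+", [(0, 100), (100 + up, 200 + up), (200 + up + down, 300 + up + down)]
        )

    @pytest.mark.parametrize(
        "up,down,expected", [(12_000, 15_000, 1), (12_000, 8_000, 0)]
    )
    def test_flank_threshold(self, up, down, expected):
        m = self._long_flank_model(up, down)
        assert len(predict_circle_candidates([m])) == expected

    def test_whitelist_filters(self):
        m = self._long_flank_model(12_000, 15_000)
        exon = m.exons[1]
        key = (exon.chrom, exon.start, exon.end)
        assert predict_circle_candidates([m], exon_whitelist={key})
        assert not predict_circle_candidates([m], exon_whitelist={("chrX", 0, 1)})

    def test_negative_predicate_short_flanks(self):
        m = self._long_flank_model(200, 200)
        assert is_circle_negative(m, 1)
        m2 = self._long_flank_model(200, 400)
        assert not is_circle_negative(m2, 1)
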