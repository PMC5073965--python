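"""IgBLAST tabular parsing, hit grouping, combination selection, regions."""

import pytest

from conftest import convert_text
from vdjml.btop import parse_btop, summarize
from vdjml.fixtures import make_canonical_fixture, make_random_fixture
from vdjml.igblast import (
    HitRow,
    IgBlastParseError,
    IgBlastRecord,
    RegionRow,
    group_hits,
    map_regions,
    parse_igblast_stream,
    select_combination,
    summary_to_flags,
)
from vdjml.model import validate_document


def _lines(text):
    return iter(text.splitlines(True))


def _hit(seg, name, qs, qe, ss, btop, score):
    return HitRow(
        segment_type=seg, subject_name=name, percent_identity=100.0,
        alignment_length=qe - qs + 1, mismatches=0, gap_opens=0,
        q_start=qs, q_end=qe, s_start=ss, s_end=ss + (qe - qs),
        e_value=1e-10, bit_score=score, btop=btop,
    )


class TestParseStream:
    def test_canonical_text_yields_one_record_with_nine_hits(self, canonical):
        text, _ = canonical
        records = parse_igblast_stream(_lines(text))
        assert len(records) == 1
        rec = records[0]
        assert rec.query_id == "canonical_read_1"
        assert len(rec.hits) == 9
        assert [h.segment_type for h in rec.hits] == list("VVVDDDJJJ")
        assert rec.rearrangement_summary["stop_codon"] == "No"
        assert rec.rearrangement_summary["strand"] == "+"
        assert [r.name for r in rec.alignment_summary] == [
            "FR1", "CDR1", "FR2", "CDR2", "FR3"]  # Total row is skipped
        assert len(rec.junction_details) == 5

    def test_zero_hit_block_gives_empty_hits(self):
        text = "# Query: q1\n# Hit table (the first field indicates the chain type of the hit)\n# 0 hits found\n"
        (rec,) = parse_igblast_stream(_lines(text))
        assert rec.query_id == "q1"
        assert rec.hits == []

    def test_concatenated_blocks_preserve_order(self, canonical):
        text, _ = canonical
        two = text + text.replace("canonical_read_1", "canonical_read_2")
        records = parse_igblast_stream(_lines(two))
        assert [r.query_id for r in records] == ["canonical_read_1", "canonical_read_2"]

    def test_bad_column_count_reports_line_number(self, canonical):
        text, _ = canonical
        lines = text.splitlines(True)
        # truncate the last hit row to half its columns
        lines[-1] = "\t".join(lines[-1].split("\t")[:6]) + "\n"
        with pytest.raises(IgBlastParseError) as exc:
            parse_igblast_stream(iter(lines))
        assert exc.value.lineno == len(lines)

    def test_unrecognized_header_is_an_error(self):
        with pytest.raises(IgBlastParseError, match="unrecognized"):
            parse_igblast_stream(_lines("# Mystery section nobody ordered\n"))


class TestGroupHits:
    def test_canonical_hits_collapse_to_seven_matches(self, canonical):
        text, _ = canonical
        (rec,) = parse_igblast_stream(_lines(text))
        matches = group_hits(rec.hits)
        assert len(matches) == 7
        first = matches[0]
        assert [g.name for g in first.gl_seg_matches] == ["IGHV3-23*01", "IGHV3-23D*01"]
        assert [m.segment_match_id for m in matches] == [str(i) for i in range(1, 8)]
        # every hit row maps to exactly one match: grouping is a partition
        assert sum(len(m.gl_seg_matches) for m in matches) == len(rec.hits)

    def test_same_gene_at_two_positions_stays_two_matches(self):
        hits = [
            _hit("D", "IGHD2-21*01", 100, 113, 1, "14", 28.0),
            _hit("D", "IGHD2-21*01", 103, 114, 1, "12", 22.0),
        ]
        matches = group_hits(hits)
        assert len(matches) == 2
        assert all(len(m.gl_seg_matches) == 1 for m in matches)

    def test_single_hit_is_a_single_match(self):
        (m,) = group_hits([_hit("J", "IGHJ4*02", 200, 246, 1, "47", 90.0)])
        assert [g.name for g in m.gl_seg_matches] == ["IGHJ4*02"]
        assert (m.read_pos0, m.read_len, m.gl_len) == (199, 47, 47)

    def test_identity_and_mutation_counts_come_from_the_btop(self):
        (m,) = group_hits([_hit("V", "IGHV1-2*01", 1, 47, 1, "7AG39", 100.0)])
        assert m.identity == pytest.approx(97.9, abs=0.05)
        assert m.annotations.substitutions == 1
        assert m.annotations.insertions == 0

    def test_inconsistent_grouped_lengths_raise(self):
        a = _hit("V", "IGHV1-2*01", 1, 47, 1, "47", 100.0)
        b = HitRow(**{**a.__dict__, "subject_name": "IGHV1-2*02", "alignment_length": 46})
        from vdjml.igblast import InconsistentGroupError

        with pytest.raises(InconsistentGroupError):
            group_hits([a, b])


class TestSelectCombination:
    def test_canonical_selection_is_1_3_5(self, canonical):
        text, _ = canonical
        (rec,) = parse_igblast_stream(_lines(text))
        combo = select_combination(group_hits(rec.hits))
        assert combo.segments == ["1", "3", "5"]

    def test_light_chain_without_d_gives_two_segments(self):
        hits = [
            _hit("V", "IGKV1-5*01", 1, 200, 1, "200", 300.0),
            _hit("J", "IGKJ2*01", 210, 247, 1, "38", 70.0),
        ]
        combo = select_combination(group_hits(hits))
        assert len(combo.segments) == 2

    def test_equal_scores_pick_the_first_listed(self):
        hits = [
            _hit("V", "IGHV1-2*01", 1, 100, 1, "100", 200.0),
            _hit("V", "IGHV4-4*01", 2, 101, 1, "100", 200.0),  # distinct alignment, tied score
            _hit("J", "IGHJ4*02", 120, 166, 1, "47", 90.0),
        ]
        matches = group_hits(hits)
        combo = select_combination(matches)
        v = next(m for m in matches if m.segment_match_id == combo.segments[0])
        assert v.gl_seg_matches[0].name == "IGHV1-2*01"

    def test_empty_input_is_an_error(self):
        with pytest.raises(ValueError):
            select_combination([])


class TestMapRegions:
    def test_summary_row_coordinates_convert_to_0_based(self):
        rec = IgBlastRecord(query_id="q", alignment_summary=[
            RegionRow("FR1", 124, 198, 75, 70, 5, 0, 93.3)])
        hits = [_hit("V", "IGHV1-2*01", 124, 418, 1, "295", 400.0),
                _hit("J", "IGHJ4*02", 441, 487, 1, "47", 90.0)]
        matches = group_hits(hits)
        combo = select_combination(matches)
        regions = map_regions(rec, combo, matches)
        fr1 = regions[0]
        assert (fr1.name, fr1.read_pos0, fr1.read_len) == ("FR1", 123, 75)

    def test_vd_and_dj_junctions_are_computed_from_the_combination(self, canonical):
        text, _ = canonical
        (rec,) = parse_igblast_stream(_lines(text))
        matches = group_hits(rec.hits)
        combo = select_combination(matches)
        regions = {r.name: r for r in map_regions(rec, combo, matches)}
        assert (regions["VD_junction"].read_pos0, regions["VD_junction"].read_len) == (418, 4)
        assert (regions["DJ_junction"].read_pos0, regions["DJ_junction"].read_len) == (436, 4)

    def test_abutting_segments_give_a_zero_length_junction(self):
        hits = [_hit("V", "IGHV1-2*01", 1, 100, 1, "100", 300.0),
                _hit("D", "IGHD2-2*01", 101, 114, 1, "14", 28.0),
                _hit("J", "IGHJ4*02", 115, 161, 1, "47", 90.0)]
        matches = group_hits(hits)
        combo = select_combination(matches)
        regions = {r.name: r for r in map_regions(IgBlastRecord("q"), combo, matches)}
        assert regions["VD_junction"].read_len == 0
        assert regions["DJ_junction"].read_len == 0

    def test_no_d_match_yields_a_vj_junction(self):
        hits = [_hit("V", "IGKV1-5*01", 1, 200, 1, "200", 300.0),
                _hit("J", "IGKJ2*01", 205, 242, 1, "38", 70.0)]
        matches = group_hits(hits)
        combo = select_combination(matches)
        regions = {r.name: r for r in map_regions(IgBlastRecord("q"), combo, matches)}
        assert (regions["VJ_junction"].read_pos0, regions["VJ_junction"].read_len) == (200, 4)


class TestSummaryToFlags:
    @pytest.mark.parametrize(
        "stop, frame, strand, expected",
        [
            ("Yes", "In-frame", "+", (True, False, False)),
            ("No", "Out-of-frame", "-", (False, True, True)),
        ],
    )
    def test_direct_mapping(self, stop, frame, strand, expected):
        rec = IgBlastRecord(query_id="q", rearrangement_summary={
            "stop_codon": stop, "vj_frame": frame, "strand": strand})
        flags = summary_to_flags(rec)
        assert (flags.stop_codon, flags.out_frame_vdj, flags.inverted) == expected

    def test_absent_summary_leaves_flags_unset(self):
        flags = summary_to_flags(IgBlastRecord(query_id="q"))
        assert flags.stop_codon is None
        assert flags.out_frame_vdj is None
        assert flags.inverted is None


class TestConvert:
    def test_canonical_fixture_matches_expected_document(self, canonical):
        text, expected = canonical
        doc = convert_text(text)
        assert validate_document(doc) == []
        assert doc == expected

    def test_empty_input_gives_zero_reads(self):
        doc = convert_text("")
        assert doc.reads == []
        assert validate_document(doc) == []

    def test_random_fixture_ground_truth_is_recovered(self):
        text, expected = make_random_fixture(seed=17, n_reads=25)
        doc = convert_text(text)
        assert doc == expected

    def test_recomputed_identity_agrees_with_printed_column(self, canonical):
        text, _ = canonical
        (rec,) = parse_igblast_stream(_lines(text))
        for hit in rec.hits:
            derived = summarize(parse_btop(hit.btop)).identity
            assert derived == pytest.approx(hit.percent_identity, abs=0.05)
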