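"""BTOP engine: grammar, statistics, alignment reconstruction."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from vdjml.btop import (
    BtopError,
    BtopOps,
    MatchRun,
    Mismatch,
    ReadDeletion,
    ReadInsertion,
    expand,
    parse_btop,
    serialize_btop,
    stats_to_flags,
    summarize,
)


class TestParse:
    @pytest.mark.parametrize(
        "text, ops",
        [
            ("47", (MatchRun(47),)),
            ("7AG39", (MatchRun(7), Mismatch("A", "G"), MatchRun(39))),
            (
                "5C-3-T2",
                (MatchRun(5), ReadInsertion("C"), MatchRun(3), ReadDeletion("T"), MatchRun(2)),
            ),
            ("AGCT", (Mismatch("A", "G"), Mismatch("C", "T"))),
            ("ag", (Mismatch("A", "G"),)),  # lowercase accepted, uppercased
        ],
    )
    def test_tokenization(self, text, ops):
        assert parse_btop(text).ops == ops

    @pytest.mark.parametrize(
        "text, offset",
        [
            ("AC-", 2),  # dangling single character
            ("--", 0),  # double gap is not a column
            ("5Z", 1),  # not a nucleotide code... wait, Z after digit is dangling
            ("3!4", 1),  # illegal character
        ],
    )
    def test_malformed_input_reports_offset(self, text, offset):
        with pytest.raises(BtopError) as exc:
            parse_btop(text)
        assert exc.value.offset == offset

    def test_adjacent_match_runs_are_canonicalized(self):
        # spliced ops with adjacent runs serialize as one merged digit run
        assert serialize_btop(BtopOps((MatchRun(12), MatchRun(3)))) == "15"
        # and parser output never contains adjacent MatchRun ops
        ops = parse_btop("5AG7C-3").ops
        for a, b in zip(ops, ops[1:]):
            assert not (isinstance(a, MatchRun) and isinstance(b, MatchRun))


class TestSummarize:
    @pytest.mark.parametrize(
        "text, matches, subs, ins, dels, read_span, gl_span, identity",
        [
            ("47", 47, 0, 0, 0, 47, 47, 100.0),
            ("7AG39", 46, 1, 0, 0, 47, 47, 97.87),
            ("5C-3-T2", 10, 0, 1, 1, 11, 11, 83.33),
        ],
    )
    def test_counts_and_identity(self, text, matches, subs, ins, dels,
                                 read_span, gl_span, identity):
        stats = summarize(parse_btop(text))
        assert (stats.matches, stats.substitutions, stats.insertions,
                stats.deletions) == (matches, subs, ins, dels)
        assert (stats.read_span, stats.gl_span) == (read_span, gl_span)
        assert stats.identity == pytest.approx(identity, abs=0.05)


class TestExpand:
    @pytest.mark.parametrize(
        "read, text, gapped_read, gapped_gl",
        [
            ("ACGT", "4", "ACGT", "ACGT"),
            ("AACGT", "1AG3", "AACGT", "AGCGT"),
        ],
    )
    def test_reconstruction(self, read, text, gapped_read, gapped_gl):
        assert expand(read, parse_btop(text)) == (gapped_read, gapped_gl)

    def test_gaps_are_inserted_on_both_rows(self):
        gr, gg = expand("ACCTAC", parse_btop("2C-3"))
        assert gr == "ACCTAC"
        assert gg == "AC-TAC"
        gr, gg = expand("ACTAC", parse_btop("2-G3"))
        assert gr == "AC-TAC"
        assert gg == "ACGTAC"

    def test_span_mismatch_is_an_error(self):
        with pytest.raises(ValueError, match="span"):
            expand("ACGT", parse_btop("2"))

    def test_base_conflict_names_the_position(self):
        with pytest.raises(ValueError, match="offset 1"):
            expand("AC", parse_btop("1TG"))


class TestFlags:
    @pytest.mark.parametrize(
        "text, out_frame, subs",
        [
            ("5" + "AG" * 20 + "5", False, 20),  # substitutions never shift frame
            ("3C-3", True, 0),  # one net insertion
            ("3C-A-2-T-G1", False, 0),  # 2 insertions, 2 deletions: net 0
            ("1C-A-G-2", False, 0),  # 3 insertions: net multiple of 3
        ],
    )
    def test_out_frame_indel(self, text, out_frame, subs):
        flags = stats_to_flags(summarize(parse_btop(text)))
        assert flags.out_frame_indel is out_frame
        assert flags.substitutions == subs


# ---------------------------------------------------------------------------
# properties


def _random_alignment(rng):
    """Independent oracle: build an alignment base by base, tracking truth.

    Returns (btop_text, read_subseq, counts) where counts are the ground
    truth (matches, substitutions, insertions, deletions).  The BTOP text
    is assembled by string concatenation, independent of the parser's op
    classes.
    """
    bases = "ACGT"
    parts = []
    read = []
    matches = subs = ins = dels = 0
    run = 0
    for _ in range(rng.randint(1, 120)):
        r = rng.random()
        if r < 0.70:
            b = rng.choice(bases)
            read.append(b)
            run += 1
            matches += 1
        else:
            if run:
                parts.append(str(run))
                run = 0
            if r < 0.85:
                gl = rng.choice(bases)
                rd = rng.choice([b for b in bases if b != gl])
                parts.append(rd + gl)
                read.append(rd)
                subs += 1
            elif r < 0.93:
                b = rng.choice(bases)
                parts.append(b + "-")
                read.append(b)
                ins += 1
            else:
                parts.append("-" + rng.choice(bases))
                dels += 1
    if run:
        parts.append(str(run))
    return "".join(parts), "".join(read), (matches, subs, ins, dels)


def test_oracle_equivalence_on_1000_random_alignments():
    """parse+summarize must reproduce the generator's truth exactly."""
    rng = random.Random(20_24)
    for _ in range(1000):
        text, read, (m, s, i, d) = _random_alignment(rng)
        if not text:
            continue
        stats = summarize(parse_btop(text))
        assert (stats.matches, stats.substitutions, stats.insertions,
                stats.deletions) == (m, s, i, d)
        # span conservation
        assert stats.read_span - stats.gl_span == stats.insertions - stats.deletions
        assert stats.read_span == len(read)
        gr, gg = expand(read, parse_btop(text))
        assert len(gr) == len(gg)
        assert gr.replace("-", "") == read


_base = st.sampled_from("ACGT")
_op_strings = st.one_of(
    st.integers(min_value=1, max_value=99).map(str),
    st.tuples(_base, _base).map("".join),
    _base.map(lambda b: b + "-"),
    _base.map(lambda b: "-" + b),
)


@settings(derandomize=True, max_examples=200)
@given(st.lists(_op_strings, min_size=1, max_size=30))
def test_round_trip_on_canonical_text(chunks):
    """serialize(parse(s)) == s for any canonical BTOP (merged digit runs)."""
    # canonicalize: merge adjacent digit runs in the generated chunk list
    merged = []
    for c in chunks:
        if c.isdigit() and merged and merged[-1].isdigit():
            merged[-1] = str(int(merged[-1]) + int(c))
        else:
            merged.append(c)
    text = "".join(merged)
    assert serialize_btop(parse_btop(text)) == text
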