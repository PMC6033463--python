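import io

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from xldisc import (
    CrossLinkIdentification,
    DomainBounds,
    Restraint,
    classify,
    deduplicate,
    filter_identifications,
    lysine_coverage,
    lysine_positions,
    parse_xlink_table,
    read_restraints,
    table1_identifications,
    write_restraints,
    write_xl_table,
)


def _table_text(ids):
    buf = io.StringIO()
    write_xl_table(ids, buf)
    return buf.getvalue()


class TestParse:
    def test_fixture_table_parses_fully(self):
        ids = table1_identifications()
        result = parse_xlink_table(io.StringIO(_table_text(ids)))
        assert len(result.identifications) == 27
        assert not result.errors
        first = result.identifications[0]
        assert (first.pos_a, first.pos_b) == (1, 95)
        assert first.peptide_a and first.peptide_b

    def test_header_only_table_gives_empty_list(self):
        text = "id\tpeptide_a\tpeptide_b\tpos_a\tpos_b\txquest_score\tdelta_s\tfdr\n"
        result = parse_xlink_table(io.StringIO(text))
        assert result.identifications == [] and result.errors == []

    def test_malformed_row_reported_not_dropped_silently(self):
        ids = table1_identifications()
        text = _table_text(ids).replace("\t95\t", "\tabc\t", 1)
        result = parse_xlink_table(io.StringIO(text))
        assert len(result.identifications) == 26
        assert len(result.errors) == 1

    def test_missing_required_column_is_fatal(self):
        text = "peptide_a\tpos_a\tdelta_s\tfdr\nAAA\t1\t0.1\t0.0\n"
        with pytest.raises(ValueError, match="pos_b"):
            parse_xlink_table(io.StringIO(text))

    def test_dialect_maps_column_names(self):
        text = "ResA,ResB,dS,FDR\n5,9,0.2,0.0\n"
        result = parse_xlink_table(
            io.StringIO(text),
            dialect={"pos_a": "ResA", "pos_b": "ResB", "delta_s": "dS", "fdr": "FDR"},
        )
        assert [(i.pos_a, i.pos_b) for i in result.identifications] == [(5, 9)]


def _ident(pos_a=1, pos_b=95, fdr=0.0, delta_s=0.5):
    return CrossLinkIdentification("PEPA", "PEPB", pos_a, pos_b, 30.0, delta_s, fdr)


class TestFilter:
    @pytest.mark.parametrize(
        "fdr,delta_s,kept",
        [
            (0.0, 0.5, True),     # perfectly confident identification survives
            (0.06, 0.5, False),   # FDR over threshold
            (0.0, 0.95, False),   # deltaS exactly at threshold: strict "below"
            (0.05, 0.5, False),   # FDR exactly at threshold
            (0.049, 0.949, True),
        ],
    )
    def test_strict_thresholds(self, fdr, delta_s, kept):
        out = filter_identifications([_ident(fdr=fdr, delta_s=delta_s)])
        assert (len(out) == 1) is kept

    def test_order_preserved(self):
        ids = [_ident(pos_a=i, pos_b=i + 50) for i in range(1, 6)]
        assert filter_identifications(ids) == ids


class TestDeduplicate:
    def test_fixture_collapses_27_to_22(self):
        restraints = deduplicate(table1_identifications())
        assert len(restraints) == 22
        assert sum(r.support for r in restraints) == 27

    def test_symmetric_pairs_collapse(self):
        ids = [_ident(95, 72), _ident(72, 95)]
        out = deduplicate(ids)
        assert len(out) == 1
        assert out[0].pair == (72, 95)
        assert out[0].support == 2

    def test_self_links_excluded(self):
        out = deduplicate([_ident(95, 95), _ident(72, 95)])
        assert [r.pair for r in out] == [(72, 95)]

    def test_idempotent(self, table1_restraints):
        again = deduplicate(table1_restraints)
        assert again == table1_restraints

    @given(
        pairs=st.lists(
            st.tuples(st.integers(1, 299), st.integers(1, 299)),
            min_size=1, max_size=40,
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_support_sums_to_non_selflink_count(self, pairs):
        ids = [_ident(a, b) for a, b in pairs]
        out = deduplicate(ids)
        expected = sum(1 for a, b in pairs if a != b)
        assert sum(r.support for r in out) == expected
        assert all(r.res_a < r.res_b for r in out)

    def test_distinct_pairs_stay_distinct(self):
        ids = [_ident(i, i + 100) for i in range(1, 11)]
        assert len(deduplicate(ids)) == 10


class TestClassify:
    @pytest.mark.parametrize(
        "pair,category",
        [((1, 95), "intra_NT"), ((233, 242), "intra_CT"), ((72, 282), "inter_domain"),
         ((95, 200), "other")],  # 200 sits in the 192-209 linker
    )
    def test_examples(self, pair, category):
        assert classify(Restraint(*pair)) == category

    def test_symmetric_in_residues(self):
        bounds = DomainBounds()
        for a, b in [(1, 95), (72, 282), (233, 242)]:
            assert classify(Restraint(a, b), bounds) == classify(Restraint(a, b), bounds)
            # canonical ordering enforced by the type; symmetry is inherent
        with pytest.raises(ValueError):
            Restraint(95, 1)


class TestCoverage:
    def test_fixture_covers_11_of_12_lysines(self, table1_restraints):
        covered, uncovered = lysine_coverage(table1_restraints, lysine_positions())
        assert len(covered) == 11
        assert uncovered == {146}

    def test_empty_restraints(self):
        covered, uncovered = lysine_coverage([], {1, 2, 3})
        assert covered == set() and uncovered == {1, 2, 3}

    def test_full_coverage(self):
        restraints = [Restraint(1, 5), Restraint(3, 9)]
        covered, uncovered = lysine_coverage(restraints, {1, 3, 5, 9})
        assert uncovered == set()


def test_restraint_tsv_round_trip(tmp_path, table1_restraints):
    path = tmp_path / "restraints.tsv"
    write_restraints(table1_restraints, str(path))
    assert read_restraints(str(path)) == table1_restraints


def test_identification_invariants_enforced():
    with pytest.raises(ValueError):
        CrossLinkIdentification("A", "B", 0, 5, 30.0, 0.5, 0.0)
    with pytest.raises(ValueError):
        CrossLinkIdentification("A", "B", 1, 5, 30.0, 1.5, 0.0)
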