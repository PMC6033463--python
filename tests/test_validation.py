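import numpy as np
import pytest

from xldisc import (
    Conformation,
    Restraint,
    ca_distance,
    tabulate_comparison,
    validate_frames,
    validate_model,
)

from conftest import random_rotation


def _conf(coords):
    return Conformation(np.asarray(coords, dtype=float))


class TestCaDistance:
    def test_coincident_points(self):
        conf = _conf([[0, 0, 0], [0, 0, 0]])
        assert ca_distance(conf, Restraint(1, 2)) == 0.0

    def test_3_4_5_triangle(self):
        conf = _conf([[0, 0, 0], [3, 4, 0]])
        assert ca_distance(conf, Restraint(1, 2)) == 5.0

    def test_matches_brute_force_on_random_chains(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            coords = rng.normal(scale=20.0, size=(50, 3))
            conf = _conf(coords)
            a, b = sorted(rng.choice(50, size=2, replace=False) + 1)
            expected = sum((coords[a - 1][k] - coords[b - 1][k]) ** 2 for k in range(3)) ** 0.5
            assert abs(ca_distance(conf, Restraint(int(a), int(b))) - expected) < 1e-9

    def test_out_of_range_residue_fatal(self):
        conf = _conf([[0, 0, 0], [1, 0, 0]])
        with pytest.raises(IndexError, match="5"):
            ca_distance(conf, Restraint(1, 5))


class TestValidateModel:
    def test_table1_pattern_totals(self, reference_confs, table1_restraints):
        opened = validate_model(reference_confs["table1_opened"], table1_restraints)
        compact = validate_model(reference_confs["table1_compact"], table1_restraints)
        assert opened.totals == (12, 22)
        assert compact.totals == (19, 22)

    def test_exact_cutoff_not_satisfied(self):
        conf = _conf([[0, 0, 0], [30.0, 0, 0]])
        report = validate_model(conf, [Restraint(1, 2)])
        assert report.n_satisfied == 0

    def test_just_below_cutoff_satisfied(self):
        conf = _conf([[0, 0, 0], [29.99, 0, 0]])
        assert validate_model(conf, [Restraint(1, 2)]).n_satisfied == 1

    def test_empty_restraints_fatal(self):
        with pytest.raises(ValueError):
            validate_model(_conf([[0, 0, 0]]), [])

    def test_invariant_under_rigid_motion(self, reference_confs, table1_restraints):
        rng = np.random.default_rng(5)
        conf = reference_confs["table1_opened"]
        base = validate_model(conf, table1_restraints).rows["satisfied"].tolist()
        rot = random_rotation(rng)
        moved = conf.transformed(rot, rng.normal(scale=100.0, size=3))
        assert validate_model(moved, table1_restraints).rows["satisfied"].tolist() == base

    def test_satisfied_count_monotone_in_cutoff(self, reference_confs, table1_restraints):
        conf = reference_confs["hairpin_186_opened"]
        counts = [
            validate_model(conf, table1_restraints, cutoff=c).n_satisfied
            for c in (10, 20, 30, 40, 60, 100)
        ]
        assert counts == sorted(counts)

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            coords = rng.normal(scale=15.0, size=(50, 3))
            conf = _conf(coords)
            pairs = {
                tuple(sorted(rng.choice(50, size=2, replace=False) + 1))
                for _ in range(8)
            }
            restraints = [Restraint(int(a), int(b)) for a, b in sorted(pairs)]
            report = validate_model(conf, restraints)
            expected = 0
            for r in restraints:
                d = np.linalg.norm(coords[r.res_a - 1] - coords[r.res_b - 1])
                if d < 30.0:
                    expected += 1
            assert report.n_satisfied == expected


class TestValidateFrames:
    def test_identical_frames_match_single_model(self, reference_confs, table1_restraints):
        conf = reference_confs["table1_opened"]
        frames = [conf] * 10
        framed = validate_frames(frames, table1_restraints)
        single = validate_model(conf, table1_restraints)
        assert framed.totals == single.totals

    def test_mean_mode_averages_window(self):
        # 9 frames at 29 A, one at 33 A: mean 29.4 -> satisfied
        near = _conf([[0, 0, 0], [29.0, 0, 0]])
        far = _conf([[0, 0, 0], [33.0, 0, 0]])
        frames = [near] * 9 + [far]
        report = validate_frames(frames, [Restraint(1, 2)], window=1.0, mode="mean")
        assert report.n_satisfied == 1
        assert np.isclose(report.rows["distance"].iloc[0], 29.4)

    def test_all_mode_requires_every_frame(self):
        near = _conf([[0, 0, 0], [29.0, 0, 0]])
        far = _conf([[0, 0, 0], [33.0, 0, 0]])
        frames = [near] * 9 + [far]
        report = validate_frames(frames, [Restraint(1, 2)], window=1.0, mode="all")
        assert report.n_satisfied == 0

    def test_window_selects_trailing_frames(self):
        far = _conf([[0, 0, 0], [50.0, 0, 0]])
        near = _conf([[0, 0, 0], [10.0, 0, 0]])
        frames = [far] * 9 + [near]
        report = validate_frames(frames, [Restraint(1, 2)], window=0.1)
        assert report.n_satisfied == 1

    def test_no_frames_fatal(self):
        with pytest.raises(ValueError):
            validate_frames([], [Restraint(1, 2)])


class TestTabulate:
    def test_totals_row_matches_reports(self, reference_confs, table1_restraints):
        reports = {
            "opened": validate_model(reference_confs["table1_opened"], table1_restraints),
            "compact": validate_model(reference_confs["table1_compact"], table1_restraints),
        }
        table = tabulate_comparison(reports)
        assert len(table) == 23  # 22 pairs + Total
        total = table.iloc[-1]
        assert total["opened"] == "12/22" and total["compact"] == "19/22"

    def test_single_report(self, reference_confs, table1_restraints):
        report = validate_model(reference_confs["table1_opened"], table1_restraints)
        table = tabulate_comparison({"only": report})
        assert list(table.columns) == ["pair", "only"]

    def test_mismatched_restraint_sets_fatal(self, reference_confs, table1_restraints):
        r1 = validate_model(reference_confs["table1_opened"], table1_restraints)
        r2 = validate_model(reference_confs["table1_opened"], table1_restraints[:-1])
        with pytest.raises(ValueError, match="different restraint set"):
            tabulate_comparison({"a": r1, "b": r2})
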