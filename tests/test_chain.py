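import math

import numpy as np
import pytest

from xldisc import (
    Conformation,
    apoe4_sequence,
    assign_ss_ca,
    helix_fraction,
    ideal_helix_coords,
    load_topology,
    longest_helical_span,
    read_pdb,
    write_pdb,
)
from xldisc.builder import assemble_extended

from conftest import random_rotation


def chord_rise(k, rise=1.5, twist=100.0, radius=2.3):
    """Closed-form Calpha(i)-Calpha(i+k) distance of the ideal helix."""
    chord = 2.0 * radius * abs(math.sin(math.radians(twist * k / 2.0)))
    return math.hypot(chord, rise * k)


class TestIdealHelix:
    def test_consecutive_distance_matches_chord_rise_formula(self):
        coords = ideal_helix_coords(30)
        d = np.linalg.norm(np.diff(coords, axis=0), axis=1)
        assert np.allclose(d, chord_rise(1), atol=1e-9)
        assert abs(chord_rise(1) - 3.83) < 0.01

    @pytest.mark.parametrize("k,expected", [(3, 5.05), (4, 6.20)])
    def test_i_i3_and_i_i4_distances(self, k, expected):
        coords = ideal_helix_coords(20)
        d = np.linalg.norm(coords[k:] - coords[:-k], axis=1)
        assert np.allclose(d, chord_rise(k), atol=1e-9)
        assert abs(chord_rise(k) - expected) < 0.01

    def test_axial_extent(self):
        n = 41
        coords = ideal_helix_coords(n)
        assert np.isclose(coords[-1, 2] - coords[0, 2], (n - 1) * 1.5)

    def test_single_residue_allowed_zero_fatal(self):
        assert ideal_helix_coords(1).shape == (1, 3)
        with pytest.raises(ValueError):
            ideal_helix_coords(0)


class TestSecondaryStructure:
    def test_ideal_helix_fully_helical(self):
        labels = assign_ss_ca(ideal_helix_coords(50))
        assert helix_fraction(labels) >= 0.9

    @pytest.mark.parametrize("n", [10, 17, 25, 40])
    def test_short_ideal_helices_mostly_helical(self, n):
        assert helix_fraction(assign_ss_ca(ideal_helix_coords(n))) >= 0.9

    def test_extended_chain_has_no_helix(self):
        coords = np.column_stack([3.8 * np.arange(60), np.zeros(60), np.zeros(60)])
        assert helix_fraction(assign_ss_ca(coords)) == 0.0

    def test_chain_shorter_than_window_is_coil(self):
        assert list(assign_ss_ca(ideal_helix_coords(4))) == ["C"] * 4

    def test_partial_helix_fraction_matches_construction(self):
        # 180 of 299 residues in ideal helix geometry -> ~60.2% helix
        helix = ideal_helix_coords(180)
        tail_start = helix[-1] + np.array([0.0, 0.0, 3.5])
        tail = tail_start + np.outer(np.arange(119), [3.8, 0.0, 0.0])
        labels = assign_ss_ca(np.vstack([helix, tail]))
        assert abs(helix_fraction(labels) - 180 / 299) < 0.02

    def test_fraction_invariant_under_rigid_motion(self):
        rng = np.random.default_rng(7)
        coords = assemble_extended(load_topology("default")).coords
        base = helix_fraction(assign_ss_ca(coords))
        for _ in range(3):
            rot = random_rotation(rng)
            moved = coords @ rot.T + rng.normal(scale=50.0, size=3)
            assert helix_fraction(assign_ss_ca(moved)) == base


class TestLongestSpan:
    def test_elongated_topology_yields_50_residue_helix(self):
        conf = assemble_extended(load_topology("elongated_h4"))
        labels = assign_ss_ca(conf)
        span = longest_helical_span(labels, within=(120, 209))
        assert span == (131, 180, 50)

    def test_split_runs(self):
        labels = np.array(["C"] * 299)
        labels[130:163] = "H"  # residues 131-163
        labels[168:180] = "H"  # residues 169-180
        span = longest_helical_span(labels, within=(120, 209))
        assert span == (131, 163, 33)

    def test_all_coil(self):
        assert longest_helical_span(["C"] * 50, within=(1, 50)).length == 0

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            labels = rng.choice(["H", "C"], size=80)
            lo, hi = sorted(rng.integers(1, 81, size=2)) or (1, 80)
            if lo == hi:
                hi = min(hi + 1, 80)
            got = longest_helical_span(labels, within=(lo, hi))
            best = 0
            i = 0
            while i < 80:
                if labels[i] == "H":
                    j = i
                    while j < 80 and labels[j] == "H":
                        j += 1
                    if i + 1 <= hi and j >= lo:
                        best = max(best, j - i)
                    i = j
                else:
                    i += 1
            assert got.length == best


class TestTopology:
    def test_default_tiles_whole_chain(self):
        topo = load_topology("default")
        assert topo.n_res == 299
        assert topo.segments[0].start == 1 and topo.segments[-1].end == 299

    def test_with_hinge_trims_overlapping_helix_end(self):
        topo = load_topology("default").with_hinge((164, 168))
        assert topo.helix("H4").end == 163
        assert topo.is_coil_window((164, 168))

    def test_with_hinge_noop_when_already_coil(self):
        topo = load_topology("default").with_hinge((186, 193))
        assert topo.helix("H4").end == 164

    def test_hinge_inside_helix_is_fatal(self):
        with pytest.raises(ValueError, match="inside helix"):
            load_topology("default").with_hinge((140, 148))

    def test_conformation_geometry_checks(self):
        conf = Conformation(ideal_helix_coords(20))
        conf.check_geometry()
        bad = Conformation(np.zeros((3, 3)))
        with pytest.raises(ValueError):
            bad.check_geometry()


class TestPdbIO:
    def test_single_model_round_trip(self, tmp_path):
        conf = assemble_extended(load_topology("default"))
        path = str(tmp_path / "model.pdb")
        write_pdb(path, conf, sequence=apoe4_sequence())
        frames = read_pdb(path)
        assert len(frames) == 1 and len(frames[0]) == 1
        assert np.allclose(frames[0][0].coords, conf.coords, atol=1e-2)

    def test_multi_model_round_trip(self, tmp_path):
        conf = assemble_extended(load_topology("default"))
        shifted = Conformation(conf.coords + [0.0, 0.0, 5.0])
        path = str(tmp_path / "traj.pdb")
        write_pdb(path, None, sequence=apoe4_sequence(), frames=[[conf], [shifted]])
        frames = read_pdb(path)
        assert len(frames) == 2
        assert np.allclose(frames[1][0].coords - frames[0][0].coords,
                           [0.0, 0.0, 5.0], atol=1e-2)
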