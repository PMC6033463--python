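import numpy as np
import pytest
from scipy.spatial.distance import pdist

from xldisc import (
    DiscAssembly,
    DiscSpec,
    build_lipid_disc,
    density_profile,
    estimate_lipid_count,
    measure_dimensions,
    wrap_dimer,
)
from xldisc.chain import Conformation


class TestLipidCount:
    def test_default_arithmetic(self):
        # r_lipid = 115/2 - 10 = 47.5 A; 2*pi*r^2 / 68.3 rounds to 208
        assert estimate_lipid_count(DiscSpec()) == 208

    def test_within_15_percent_of_measured_stoichiometry(self):
        assert abs(estimate_lipid_count() - 200) / 200 <= 0.15

    def test_huge_area_per_lipid_gives_zero(self):
        spec = DiscSpec(area_per_lipid=1e9)
        assert estimate_lipid_count(spec) == 0

    def test_doubling_core_radius_quadruples_count(self):
        small = DiscSpec(outer_diameter=115.0, belt_width=10.0)
        big = DiscSpec(outer_diameter=2 * (2 * 47.5) + 20.0, belt_width=10.0)
        assert big.lipid_core_radius == 2 * small.lipid_core_radius
        ratio = estimate_lipid_count(big) / estimate_lipid_count(small)
        assert abs(ratio - 4.0) < 0.01


class TestBuildDisc:
    def test_default_build_places_estimated_count(self):
        disc = build_lipid_disc()
        assert disc.n_lipids == 208
        assert np.sum((disc.role == "head") & (disc.leaflet == "top")) == 104
        assert np.sum((disc.role == "head") & (disc.leaflet == "bottom")) == 104

    def test_heads_exactly_on_head_planes(self):
        disc = build_lipid_disc()
        z = disc.coords[disc.role == "head", 2]
        assert np.all(np.isclose(np.abs(z), 19.5))

    def test_two_lipids_one_per_leaflet(self):
        disc = build_lipid_disc(n_lipids=2)
        assert disc.n_lipids == 2
        assert set(disc.leaflet) == {"top", "bottom"}

    def test_leaflets_mirror_symmetric(self):
        disc = build_lipid_disc(n_lipids=200)
        top = disc.coords[(disc.role == "head") & (disc.leaflet == "top")]
        bottom = disc.coords[(disc.role == "head") & (disc.leaflet == "bottom")]
        flipped = bottom * [1, 1, -1]
        assert np.allclose(np.sort(top, axis=0), np.sort(flipped, axis=0))

    def test_over_capacity_is_fatal(self):
        with pytest.raises(ValueError, match="capacity"):
            build_lipid_disc(n_lipids=100000)

    def test_heads_within_lipid_core(self):
        disc = build_lipid_disc()
        r = np.linalg.norm(disc.coords[disc.role == "head", :2], axis=1)
        assert r.max() <= DiscSpec().lipid_core_radius + 1e-9

    def test_deterministic_layout(self):
        a = build_lipid_disc()
        b = build_lipid_disc()
        assert np.array_equal(a.coords, b.coords)


def _belt_monomer(n=60, radius=52.0, z=3.0):
    theta = np.linspace(0.0, np.pi, n)
    coords = np.column_stack(
        [radius * np.cos(theta), radius * np.sin(theta), np.full(n, z)]
    )
    return Conformation(coords, label="belt")


class TestWrapDimer:
    def test_head_to_tail_is_rotation_about_disc_axis(self):
        mono = _belt_monomer()
        asm = wrap_dimer(mono, "head_to_tail", build_lipid_disc(n_lipids=20))
        a, b = asm.chains
        assert np.allclose(b.coords, a.coords * [-1, -1, 1], atol=1e-9)

    def test_head_to_head_flips_z(self):
        mono = _belt_monomer()
        asm = wrap_dimer(mono, "head_to_head", build_lipid_disc(n_lipids=20))
        a, b = asm.chains
        assert np.allclose(b.coords[:, 2], -a.coords[:, 2], atol=1e-9)

    def test_assembly_has_two_chains(self):
        asm = wrap_dimer(_belt_monomer(), "head_to_tail", build_lipid_disc(n_lipids=20))
        assert len(asm.chains) == 2

    def test_per_chain_internal_distances_preserved(self):
        mono = _belt_monomer()
        asm = wrap_dimer(mono, "head_to_head", build_lipid_disc(n_lipids=20))
        assert np.allclose(pdist(asm.chains[1].coords), pdist(mono.coords))

    def test_not_belt_shaped_fatal(self):
        wide = Conformation(np.array([[0.0, 0.0, 0.0], [120.0, 0.0, 3.0]]))
        with pytest.raises(ValueError, match="belt-shaped"):
            wrap_dimer(wide, "head_to_tail", build_lipid_disc(n_lipids=20))

    def test_bad_orientation_rejected(self):
        with pytest.raises(ValueError):
            wrap_dimer(_belt_monomer(), "sideways", build_lipid_disc(n_lipids=20))


class TestMeasure:
    def test_default_disc_with_belt_in_experimental_bands(self):
        asm = wrap_dimer(_belt_monomer(), "head_to_tail", build_lipid_disc())
        dims = measure_dimensions(asm)
        assert 105.0 <= dims.diameter <= 125.0
        assert 40.0 <= dims.thickness <= 60.0
        assert not dims.protein_only

    def test_thickness_is_head_extent_plus_radii(self):
        asm = DiscAssembly(lipids=build_lipid_disc(), chains=[], spec=DiscSpec())
        dims = measure_dimensions(asm)
        assert np.isclose(dims.thickness, 2 * 19.5 + 2 * 3.5)

    def test_protein_only_flagged(self):
        asm = DiscAssembly(lipids=None, chains=[_belt_monomer()], spec=DiscSpec())
        dims = measure_dimensions(asm)
        assert dims.protein_only


class TestDensityProfile:
    def test_histograms_normalized(self):
        asm = wrap_dimer(_belt_monomer(), "head_to_tail", build_lipid_disc())
        prof = density_profile(asm, bin_width=1.0)
        widths = np.diff(prof["edges"])
        for name in ("head", "tail", "protein"):
            assert np.isclose(np.sum(prof[name] * widths), 1.0)

    def test_head_profile_bimodal_at_head_planes(self):
        asm = DiscAssembly(lipids=build_lipid_disc(), chains=[], spec=DiscSpec())
        prof = density_profile(asm, bin_width=1.0)
        centers = 0.5 * (prof["edges"][:-1] + prof["edges"][1:])
        occupied = centers[prof["head"] > 0]
        assert np.all(np.isclose(np.abs(occupied), 19.5, atol=1.0))

    def test_protein_overlaps_tail_z_range(self):
        asm = wrap_dimer(_belt_monomer(), "head_to_tail", build_lipid_disc())
        prof = density_profile(asm, bin_width=1.0)
        centers = 0.5 * (prof["edges"][:-1] + prof["edges"][1:])
        tail_z = centers[prof["tail"] > 0]
        protein_z = centers[prof["protein"] > 0]
        assert protein_z.min() <= tail_z.max() and protein_z.max() >= tail_z.min()

    def test_nonpositive_bin_width_fatal(self):
        asm = DiscAssembly(lipids=build_lipid_disc(n_lipids=10), chains=[], spec=DiscSpec())
        with pytest.raises(ValueError):
            density_profile(asm, bin_width=0.0)
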