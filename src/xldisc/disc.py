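"""Explicit coarse lipid discs and measurable nanodisc assemblies.

Lipids are three-bead pseudo-particles (one head, two tails) packed on a
hexagonal lattice at a prescribed area per lipid, in two mirror-symmetric
leaflets whose head planes sit at the phosphate positions of a POPC bilayer.
The observables the model supports -- lipid count, particle diameter,
bilayer thickness and the per-component density profile along the disc
normal -- depend only on this packing geometry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.distance import pdist

from .chain import Conformation
from .geometry import rotation_matrix

__all__ = [
    "DiscSpec",
    "LipidDisc",
    "DiscAssembly",
    "Dimensions",
    "estimate_lipid_count",
    "build_lipid_disc",
    "wrap_dimer",
    "measure_dimensions",
    "density_profile",
    "write_assembly_pdb",
]


@dataclass(frozen=True)
class DiscSpec:
    """Geometry of the nanodisc: a lipid core ringed by a protein belt."""

    outer_diameter: float = 115.0
    belt_width: float = 10.0
    area_per_lipid: float = 68.3
    head_plane_z: float = 19.5
    head_radius: float = 3.5
    tail_radius: float = 3.0
    ca_radius: float = 3.0
    tail_dz: float = 6.5  # spacing of the two tail beads below the head

    def __post_init__(self) -> None:
        if self.outer_diameter <= 2 * self.belt_width:
            raise ValueError("outer diameter must exceed twice the belt width")
        for name in ("belt_width", "area_per_lipid", "head_plane_z",
                     "head_radius", "tail_radius", "ca_radius"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def lipid_core_radius(self) -> float:
        return self.outer_diameter / 2.0 - self.belt_width


@dataclass
class LipidDisc:
    """Lipid pseudo-particle beads of both leaflets."""

    coords: np.ndarray           # (n_beads, 3)
    role: np.ndarray             # 'head' | 'tail'
    leaflet: np.ndarray          # 'top' | 'bottom'
    spec: DiscSpec

    @property
    def n_lipids(self) -> int:
        return int(np.sum(self.role == "head"))

    def radii(self) -> np.ndarray:
        return np.where(self.role == "head", self.spec.head_radius, self.spec.tail_radius)


@dataclass
class DiscAssembly:
    """Explicit nanodisc model: lipid disc plus one or two protein chains."""

    lipids: LipidDisc | None
    chains: list[Conformation]
    spec: DiscSpec
    metadata: dict = field(default_factory=dict)


@dataclass(frozen=True)
class Dimensions:
    diameter: float
    thickness: float
    protein_only: bool = False


def estimate_lipid_count(spec: DiscSpec | None = None) -> int:
    """Lipid complement of the disc: two leaflets of core area / APL."""
    spec = spec or DiscSpec()
    r = spec.lipid_core_radius
    return int(round(2.0 * math.pi * r * r / spec.area_per_lipid))


def _hex_lattice(radius: float, spacing: float) -> np.ndarray:
    """Hexagonal lattice points within a disc, nearest-first, deterministic.

    Two centerings are tried (lattice point at the origin, and half-cell
    offset) and the one holding more sites within the radius is kept, so the
    packing capacity is not lost to an unlucky origin.
    """
    n_max = int(radius / spacing) + 2
    i, j = np.meshgrid(np.arange(-n_max, n_max + 1), np.arange(-n_max, n_max + 1))
    base = np.column_stack(
        [(i + 0.5 * (j % 2)).ravel() * spacing, j.ravel() * (spacing * math.sqrt(3) / 2)]
    )
    best = None
    for offset in (np.zeros(2), np.array([0.5 * spacing, spacing * math.sqrt(3) / 4])):
        pts = base + offset
        pts = pts[np.linalg.norm(pts, axis=1) <= radius]
        if best is None or len(pts) > len(best):
            best = pts
    order = np.lexsort((best[:, 1], best[:, 0], np.round(np.linalg.norm(best, axis=1), 6)))
    return best[order]


def build_lipid_disc(spec: DiscSpec | None = None, n_lipids: int | None = None) -> LipidDisc:
    """Place lipids on hexagonal leaflet lattices; deterministic layout.

    ``n_lipids`` defaults to :func:`estimate_lipid_count` and must not exceed
    the packing capacity of the lattice at the given area per lipid.
    """
    spec = spec or DiscSpec()
    n_lipids = estimate_lipid_count(spec) if n_lipids is None else int(n_lipids)
    if n_lipids < 2:
        raise ValueError("need at least one lipid per leaflet")
    spacing = math.sqrt(2.0 * spec.area_per_lipid / math.sqrt(3.0))
    sites = _hex_lattice(spec.lipid_core_radius, spacing)
    n_top = n_lipids // 2 + n_lipids % 2
    n_bottom = n_lipids // 2
    if max(n_top, n_bottom) > len(sites):
        raise ValueError(
            f"{n_lipids} lipids exceed the hexagonal packing capacity "
            f"({2 * len(sites)} at {spec.area_per_lipid} A^2 per lipid)"
        )
    coords, role, leaflet = [], [], []
    for sign, name, count in ((1.0, "top", n_top), (-1.0, "bottom", n_bottom)):
        xy = sites[:count]
        for x, y in xy:
            z_head = sign * spec.head_plane_z
            coords.append((x, y, z_head))
            role.append("head")
            leaflet.append(name)
            for k in (1, 2):
                coords.append((x, y, z_head - sign * k * spec.tail_dz))
                role.append("tail")
                leaflet.append(name)
    return LipidDisc(
        coords=np.array(coords, dtype=float),
        role=np.array(role),
        leaflet=np.array(leaflet),
        spec=spec,
    )


def wrap_dimer(
    monomer: Conformation,
    orientation: str,
    disc: LipidDisc | None = None,
    clash_cutoff: float | None = None,
) -> DiscAssembly:
    """Wrap two symmetry-related copies of a belt-shaped monomer on the disc.

    ``head_to_tail`` generates chain B by a 180 degree rotation about the
    disc axis; ``head_to_head`` by a 180 degree rotation about an in-plane
    axis (flipping z).  Inter-chain clashes are counted and reported in the
    assembly metadata, not fatal.
    """
    if orientation not in ("head_to_head", "head_to_tail"):
        raise ValueError("orientation must be head_to_head or head_to_tail")
    spec = disc.spec if disc is not None else DiscSpec()
    r_xy = np.linalg.norm(monomer.coords[:, :2], axis=1).max()
    if r_xy > 1.5 * spec.outer_diameter / 2.0:
        raise ValueError(
            f"monomer extends to {r_xy:.0f} A from the axis; not belt-shaped "
            f"for an outer radius of {spec.outer_diameter / 2:.0f} A"
        )
    axis = np.array([0.0, 0.0, 1.0]) if orientation == "head_to_tail" else np.array(
        [1.0, 0.0, 0.0]
    )
    rot = rotation_matrix(axis, math.pi)
    chain_b = monomer.transformed(rot, np.zeros(3))
    chain_b.label = (monomer.label or "chain") + "_B"
    clash_cutoff = 2.0 * spec.ca_radius if clash_cutoff is None else clash_cutoff
    from scipy.spatial import cKDTree

    tree = cKDTree(monomer.coords)
    clashes = sum(len(hits) for hits in tree.query_ball_point(chain_b.coords, clash_cutoff))
    return DiscAssembly(
        lipids=disc,
        chains=[monomer, chain_b],
        spec=spec,
        metadata={"orientation": orientation, "chain_clashes": int(clashes)},
    )


def _all_beads(assembly: DiscAssembly) -> tuple[np.ndarray, np.ndarray]:
    coords, radii = [], []
    if assembly.lipids is not None and len(assembly.lipids.coords):
        coords.append(assembly.lipids.coords)
        radii.append(assembly.lipids.radii())
    for chain in assembly.chains:
        coords.append(chain.coords)
        radii.append(np.full(chain.n_res, assembly.spec.ca_radius))
    if not coords:
        raise ValueError("empty assembly")
    return np.vstack(coords), np.concatenate(radii)


def measure_dimensions(assembly: DiscAssembly) -> Dimensions:
    """Particle diameter (in-plane) and bilayer thickness (along z).

    Diameter: maximal pairwise in-plane center distance over all beads plus
    twice the largest bead radius.  Thickness: z extent of the lipid beads
    plus twice the head-bead radius; without lipids the protein extent is
    used and the result flagged ``protein_only``.
    """
    coords, radii = _all_beads(assembly)
    diameter = float(pdist(coords[:, :2]).max() + 2.0 * radii.max())
    if assembly.lipids is not None and len(assembly.lipids.coords):
        z = assembly.lipids.coords[:, 2]
        thickness = float(z.max() - z.min() + 2.0 * assembly.spec.head_radius)
        protein_only = False
    else:
        z = coords[:, 2]
        thickness = float(z.max() - z.min() + 2.0 * assembly.spec.ca_radius)
        protein_only = True
    return Dimensions(diameter=diameter, thickness=thickness, protein_only=protein_only)


def density_profile(assembly: DiscAssembly, bin_width: float = 1.0) -> dict[str, np.ndarray]:
    """Normalized per-component bead density along the disc normal.

    Returns ``{"edges": ..., "head": ..., "tail": ..., "protein": ...}``;
    each histogram integrates to one over z (components without beads are
    omitted).  The head profile of a built disc is bimodal with modes at the
    two head planes; the protein of a belted assembly overlaps the tail
    region in z.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    groups: dict[str, np.ndarray] = {}
    if assembly.lipids is not None and len(assembly.lipids.coords):
        lip = assembly.lipids
        groups["head"] = lip.coords[lip.role == "head", 2]
        groups["tail"] = lip.coords[lip.role == "tail", 2]
    if assembly.chains:
        groups["protein"] = np.concatenate([c.coords[:, 2] for c in assembly.chains])
    if not groups:
        raise ValueError("empty assembly")
    z_all = np.concatenate(list(groups.values()))
    lo = math.floor(z_all.min() / bin_width) * bin_width
    hi = math.ceil(z_all.max() / bin_width) * bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    out: dict[str, np.ndarray] = {"edges": edges}
    for name, z in groups.items():
        hist, _ = np.histogram(z, bins=edges, density=True)
        out[name] = hist
    return out


def write_assembly_pdb(dest: str, assembly: DiscAssembly, sequence: str | None = None) -> None:
    """Write the assembly as PDB: protein chains A/B, lipids as POP HETATM."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    from .chain import _atom_array

    arrays = []
    if assembly.chains:
        arrays.append(_atom_array(assembly.chains, sequence))
    if assembly.lipids is not None and len(assembly.lipids.coords):
        lip = assembly.lipids
        atoms = []
        res_id = 0
        tail_no = 0
        for pos, role in zip(lip.coords, lip.role):
            if role == "head":
                res_id += 1
                tail_no = 0
                name = "HD"
            else:
                tail_no += 1
                name = f"T{tail_no}"
            atoms.append(
                struc.Atom(
                    pos, chain_id="L", res_id=res_id, res_name="POP",
                    atom_name=name, element="C", hetero=True,
                )
            )
        arrays.append(struc.array(atoms))
    merged = arrays[0]
    for arr in arrays[1:]:
        merged += arr
    pdb = PDBFile()
    pdb.set_structure(merged)
    pdb.write(dest)
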