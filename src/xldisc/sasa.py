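"""Bead-level solvent-accessible surface area (Shrake-Rupley).

SASA is computed on the coarse bead representation (Calpha spheres and lipid
pseudo-beads) with a deterministic golden-spiral point set: a surface point
on the probe-inflated sphere of a bead counts as accessible when it falls
outside every neighbor's inflated sphere.  Normalized accessibility divides
a bead's area by its isolated-sphere value, giving a per-residue number in
[0, 1]; this is a model-level accessibility, not an atomic SASA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .disc import DiscAssembly
from .geometry import golden_spiral_points
from .seqdata import receptor_binding_site

__all__ = ["SasaResult", "shrake_rupley", "site_accessibility"]

DEFAULT_PROBE = 1.4
DEFAULT_N_POINTS = 960


@dataclass
class SasaResult:
    areas: np.ndarray        # per-bead accessible area, A^2
    normalized: np.ndarray   # per-bead area / isolated-sphere area, in [0, 1]
    probe: float
    n_points: int


def shrake_rupley(
    coords: np.ndarray,
    radii: np.ndarray | float,
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
    subset: np.ndarray | None = None,
) -> SasaResult:
    """Per-bead solvent-accessible areas.

    ``subset`` restricts the computation to the given bead indices (all other
    beads still occlude); areas of beads outside the subset are NaN.
    Coincident beads are rejected, as they have no defined surface.
    """
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    radii = np.broadcast_to(np.asarray(radii, dtype=float), (n,)).copy()
    if n_points < 12:
        raise ValueError("need at least 12 sphere points")
    if np.any(radii <= 0):
        raise ValueError("radii must be positive")

    tree = cKDTree(coords)
    if tree.query_pairs(1e-6):
        raise ValueError("coincident beads")

    sphere = golden_spiral_points(n_points)
    inflated = radii + probe
    reach = 2.0 * inflated.max()
    targets = np.arange(n) if subset is None else np.asarray(subset, dtype=int)

    areas = np.full(n, np.nan)
    for i in targets:
        neighbors = [j for j in tree.query_ball_point(coords[i], reach)
                     if j != i and np.linalg.norm(coords[j] - coords[i]) < inflated[i] + inflated[j]]
        pts = coords[i] + inflated[i] * sphere
        if neighbors:
            diff = pts[:, None, :] - coords[neighbors][None, :, :]
            buried = (np.linalg.norm(diff, axis=2) < inflated[neighbors][None, :]).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        areas[i] = frac * 4.0 * math.pi * inflated[i] ** 2
    iso = 4.0 * math.pi * inflated**2
    normalized = np.clip(areas / iso, 0.0, 1.0)
    return SasaResult(areas=areas, normalized=normalized, probe=probe, n_points=n_points)


def site_accessibility(
    assembly: DiscAssembly,
    site: Sequence[int] | None = None,
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
) -> dict[str, dict]:
    """Mean normalized accessibility of a residue site, per protein chain.

    ``site`` defaults to the packaged receptor-binding residues (basic
    residues in 136-150 plus 172).  Lipid beads are included as occluders.
    Returns ``{chain_label: {"mean": float, "per_residue": {res: value}}}``.
    """
    site = tuple(site) if site is not None else receptor_binding_site()
    if not site:
        raise ValueError("empty residue site")
    if not assembly.chains:
        raise ValueError("assembly has no protein chains")

    blocks = []
    radii_blocks = []
    chain_offsets = []
    offset = 0
    for chain in assembly.chains:
        chain_offsets.append(offset)
        blocks.append(chain.coords)
        radii_blocks.append(np.full(chain.n_res, assembly.spec.ca_radius))
        offset += chain.n_res
    if assembly.lipids is not None and len(assembly.lipids.coords):
        blocks.append(assembly.lipids.coords)
        radii_blocks.append(assembly.lipids.radii())
    coords = np.vstack(blocks)
    radii = np.concatenate(radii_blocks)

    subset = []
    for chain, off in zip(assembly.chains, chain_offsets):
        for res in site:
            if not 1 <= res <= chain.n_res:
                raise IndexError(f"site residue {res} outside chain of {chain.n_res}")
            subset.append(off + res - 1)
    result = shrake_rupley(coords, radii, probe=probe, n_points=n_points,
                           subset=np.array(subset))

    out: dict[str, dict] = {}
    for idx, (chain, off) in enumerate(zip(assembly.chains, chain_offsets)):
        per_res = {res: float(result.normalized[off + res - 1]) for res in site}
        label = chain.label or f"chain_{idx}"
        out[label] = {"mean": float(np.mean(list(per_res.values()))), "per_residue": per_res}
    return out
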