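"""Declarative geometric constraints and their flat-bottom pseudo-energy.

Constraints drive coarse model generation: distance bands between residue
pairs (including expanded helix-helix zippers), radial and axial bands
relative to the implicit lipid disc (axis = z), and an excluded-volume floor.
Every soft term is a flat-bottom quadratic penalty, zero inside its band and
weight * violation^2 outside, so the pseudo-energy is continuous and exactly
zero for a fully satisfied conformation.

Excluded volume and chain connectivity are treated as hard feasibility
conditions by the annealer (moves violating them are rejected), so their
energy contribution is reported but stays at zero along a valid trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Union

import numpy as np
from scipy.spatial.distance import pdist

__all__ = [
    "DistanceBand",
    "RadialBand",
    "ZBand",
    "Zipper",
    "ExcludedVolume",
    "GeometricConstraint",
    "ImplicitDisc",
    "PseudoEnergy",
    "ConstraintSet",
]


@dataclass(frozen=True)
class ImplicitDisc:
    """Implicit lipid disc: protein belts its rim, the bilayer fills |z|."""

    belt_radius: float = 46.5
    half_thickness: float = 20.0

    def __post_init__(self) -> None:
        if self.belt_radius <= 0 or self.half_thickness <= 0:
            raise ValueError("disc dimensions must be positive")


@dataclass(frozen=True)
class DistanceBand:
    i: int  # 1-based residues
    j: int
    dmin: float
    dmax: float
    weight: float = 1.0
    tag: str = "distance"

    def __post_init__(self) -> None:
        if self.dmin > self.dmax:
            raise ValueError("dmin > dmax")


@dataclass(frozen=True)
class RadialBand:
    residues: tuple[int, int]  # inclusive interval
    rmin: float
    rmax: float = np.inf
    weight: float = 1.0
    tag: str = "radial"


@dataclass(frozen=True)
class ZBand:
    residues: tuple[int, int]
    zmin: float
    zmax: float
    weight: float = 1.0
    tag: str = "z"


@dataclass(frozen=True)
class Zipper:
    """Registered pairing of two equal-length helix intervals.

    Pairs the k-th residue of range_a with the k-th (parallel) or the
    (last-k)-th (antiparallel) residue of range_b at a packing target of
    ~10 A, expanded into per-residue distance bands of target +/- 3 A.
    """

    range_a: tuple[int, int]
    range_b: tuple[int, int]
    orientation: str = "antiparallel"
    target: float = 10.0
    half_width: float = 3.0
    weight: float = 1.0

    def __post_init__(self) -> None:
        la = self.range_a[1] - self.range_a[0]
        lb = self.range_b[1] - self.range_b[0]
        if la != lb:
            raise ValueError(f"zipper ranges differ in length: {self.range_a} vs {self.range_b}")
        if self.orientation not in ("parallel", "antiparallel"):
            raise ValueError("orientation must be parallel or antiparallel")

    def expand(self, tag: str = "zipper") -> list[DistanceBand]:
        a0, a1 = self.range_a
        b0, b1 = self.range_b
        bands = []
        for k in range(a1 - a0 + 1):
            i = a0 + k
            j = b0 + k if self.orientation == "parallel" else b1 - k
            bands.append(
                DistanceBand(
                    i, j, self.target - self.half_width, self.target + self.half_width,
                    weight=self.weight, tag=tag,
                )
            )
        return bands


@dataclass(frozen=True)
class ExcludedVolume:
    min_sep: float = 4.0
    weight: float = 1.0


GeometricConstraint = Union[DistanceBand, RadialBand, ZBand, Zipper, ExcludedVolume]


@dataclass
class PseudoEnergy:
    total: float
    breakdown: dict[str, float]

    @classmethod
    def from_breakdown(cls, breakdown: dict[str, float]) -> "PseudoEnergy":
        return cls(total=float(sum(breakdown.values())), breakdown=breakdown)


class ConstraintSet:
    """A compiled set of geometric constraints over one chain."""

    def __init__(self, constraints: Iterable[GeometricConstraint], n_res: int):
        self.n_res = n_res
        self.constraints = list(constraints)
        self.excluded_volume: ExcludedVolume | None = None

        bands: list[DistanceBand] = []
        radial: list[RadialBand] = []
        zbands: list[ZBand] = []
        for c in self.constraints:
            if isinstance(c, DistanceBand):
                bands.append(c)
            elif isinstance(c, Zipper):
                bands.extend(c.expand())
            elif isinstance(c, RadialBand):
                radial.append(c)
            elif isinstance(c, ZBand):
                zbands.append(c)
            elif isinstance(c, ExcludedVolume):
                self.excluded_volume = c
            else:
                raise TypeError(f"unknown constraint {c!r}")

        for b in bands:
            if not (1 <= b.i <= n_res and 1 <= b.j <= n_res):
                raise ValueError(f"distance band {b.i}-{b.j} outside chain")
        self._tags = sorted({b.tag for b in bands}) or []
        self._pair_idx = {}
        for tag in self._tags:
            sel = [b for b in bands if b.tag == tag]
            self._pair_idx[tag] = (
                np.array([b.i - 1 for b in sel]),
                np.array([b.j - 1 for b in sel]),
                np.array([b.dmin for b in sel]),
                np.array([b.dmax for b in sel]),
                np.array([b.weight for b in sel]),
            )
        self._radial = radial
        self._zbands = zbands

        # condensed-distance mask of non-adjacent pairs for excluded volume
        if self.excluded_volume is not None:
            iu, ju = np.triu_indices(n_res, k=1)
            self._nonadj = (ju - iu) >= 2
        else:
            self._nonadj = None

    def distance_bands(self, tag: str | None = None) -> list[DistanceBand]:
        bands = []
        for c in self.constraints:
            if isinstance(c, DistanceBand) and (tag is None or c.tag == tag):
                bands.append(c)
            elif isinstance(c, Zipper) and tag in (None, "zipper"):
                bands.extend(c.expand())
        return bands

    # -- evaluation ----------------------------------------------------------

    def energy(self, coords: np.ndarray) -> PseudoEnergy:
        breakdown: dict[str, float] = {}
        for tag in self._tags:
            ii, jj, dmin, dmax, w = self._pair_idx[tag]
            d = np.linalg.norm(coords[ii] - coords[jj], axis=1)
            viol = np.maximum(dmin - d, 0.0) + np.maximum(d - dmax, 0.0)
            breakdown[tag] = float(np.sum(w * viol**2))

        if self._radial:
            r = np.linalg.norm(coords[:, :2], axis=1)
            e = 0.0
            for band in self._radial:
                lo, hi = band.residues
                rr = r[lo - 1 : hi]
                viol = np.maximum(band.rmin - rr, 0.0)
                if np.isfinite(band.rmax):
                    viol = viol + np.maximum(rr - band.rmax, 0.0)
                e += band.weight * float(np.sum(viol**2))
            breakdown["radial"] = e

        if self._zbands:
            e = 0.0
            for band in self._zbands:
                lo, hi = band.residues
                zz = coords[lo - 1 : hi, 2]
                viol = np.maximum(band.zmin - zz, 0.0) + np.maximum(zz - band.zmax, 0.0)
                e += band.weight * float(np.sum(viol**2))
            breakdown["z"] = e

        if self.excluded_volume is not None:
            d = pdist(coords)[self._nonadj]
            viol = np.maximum(self.excluded_volume.min_sep - d, 0.0)
            breakdown["excluded_volume"] = self.excluded_volume.weight * float(
                np.sum(viol**2)
            )

        return PseudoEnergy.from_breakdown(breakdown)

    def excluded_volume_ok(self, coords: np.ndarray) -> bool:
        if self.excluded_volume is None:
            return True
        d = pdist(coords)[self._nonadj]
        return bool(d.min() >= self.excluded_volume.min_sep) if d.size else True
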