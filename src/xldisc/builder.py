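"""Constraint recipes and simulated annealing for lipid-bound hairpin models.

The two-domain apolipoprotein is modeled wrapped around an implicit lipid
disc as a hairpin: the long C-terminal (CT) helix runs along the disc rim,
a hinge in the NT-CT linker folds the chain back, and the N-terminal helices
run antiparallel along the CT helix.  Two recipes are provided:

* ``opened`` -- the turn between NT helices 3 and 4 is unfurled and both
  helices are zipped along the CT helix (H3 on the belt); helices 1-3 stay
  mutually zipped with H2 pushed radially outside the lipid core.
* ``compact`` -- the NT four-helix bundle is retained (H1-H2, H2-H3, H3-H4
  zippers) and laid along the CT helix with only H4 on the belt and H3
  radially outside it.

Both recipes add the belt/bilayer placement of the CT helix, displacement of
the flexible CT tail outside the disc, a loose containment band keeping the
chain at the particle, and excluded volume.  The hairpin fold-back pairing is
registered by arc length measured from the hinge (helix residues advance
1.5 A of arc, coil residues a calibrated ~0.65 A), so that the two arms of
the hairpin stay in register even though they contain different amounts of
coil.

Models are generated by Metropolis simulated annealing over a fixed move set:
pivot rotations at coil residues, crankshaft rotations between coil residues,
small rigid-body perturbations of helix segments and single-bead coil moves.
Chain connectivity (virtual bonds in 2.8-4.2 A) and excluded volume are hard
feasibility conditions: violating proposals are rejected outright, so every
visited conformation is sterically valid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .chain import BOND_BAND, Conformation, Segment, SegmentTopology
from .constraints import (
    ConstraintSet,
    DistanceBand,
    ExcludedVolume,
    ImplicitDisc,
    PseudoEnergy,
    RadialBand,
    ZBand,
    Zipper,
)
from .geometry import rotate_about_point
from .restraints import Restraint

__all__ = [
    "BuilderParams",
    "AnnealSchedule",
    "AnnealResult",
    "assemble_belt",
    "assemble_extended",
    "assemble_hairpin",
    "restraint_bands",
    "constraints_for_variant",
    "anneal",
    "build_model",
    "enumerate_hinge_models",
    "HingeRanking",
]

PAPER_HINGES: tuple[tuple[int, int], ...] = ((164, 168), (186, 193), (201, 208))


@dataclass(frozen=True)
class BuilderParams:
    """Band geometry and weights of the constraint recipes (Angstrom)."""

    belt_offset: tuple[float, float] = (1.0, 7.0)  # belt band, relative to disc radius
    ct_z: tuple[float, float] = (-10.0, 0.0)       # CT helix below midplane
    arm_z: tuple[float, float] = (0.0, 10.0)       # hairpin arm above it
    h2_out_offset: tuple[float, float] = (4.0, 10.0)   # opened: H2 outside the core
    h3_out_offset: tuple[float, float] = (7.0, 13.0)   # compact: H3 outside H4
    tail_out_offset: float = 5.0                   # CT tail pushed off the disc
    containment_offset: float = 11.0               # everything within the belt annulus
    containment_z: float = 28.0
    zipper_target: float = 10.0
    zipper_half_width: float = 3.0
    coil_arc_advance: float = 0.65                 # arc per coil residue in the register
    helix_arc_advance: float = 1.5
    w_zipper: float = 1.0
    w_foldback: float = 1.0
    w_radial: float = 0.5
    w_z: float = 0.5
    w_tail: float = 1.0
    w_containment: float = 0.6
    closure_max: float = 22.0   # opened: hairpin arm ends meet opposite the apex
                                # (stands in for the second chain's steric claim
                                # on the other half of the belt, hence heavy)
    w_closure: float = 4.0
    ev_min_sep: float = 4.0


@dataclass(frozen=True)
class AnnealSchedule:
    """Geometric temperature ladder and move amplitudes."""

    n_steps: int = 15000
    n_rungs: int = 10
    t_start: float | None = None     # None -> calibrated from trial moves
    t_end_ratio: float = 0.002
    p_pivot: float = 0.35
    p_crank: float = 0.25
    p_rigid: float = 0.20
    p_bead: float = 0.20
    pivot_sigma: tuple[float, float] = (0.6, 0.05)   # radians, start -> end
    crank_sigma: tuple[float, float] = (0.8, 0.08)
    rigid_rot_sigma: tuple[float, float] = (0.15, 0.02)
    rigid_trans_sigma: tuple[float, float] = (0.8, 0.10)
    bead_sigma: tuple[float, float] = (0.8, 0.10)
    trace_interval: int = 500
    convergence_tol: float = 25.0


@dataclass
class AnnealResult:
    energy: PseudoEnergy
    trace: np.ndarray  # columns: step, temperature, current, best
    seed: int
    n_steps: int
    acceptance_rate: float
    converged: bool


# --- initial assembly -------------------------------------------------------

_INIT_COIL_STEP = 3.3
_INIT_BOUNDARY_STEP = 2.8


def _arc_steps(topology: SegmentTopology) -> np.ndarray:
    """Per-residue arc advance for the initial spiral assembly."""
    ss = np.array(["C"] * topology.n_res)
    for seg in topology.segments:
        if seg.ss == "helix":
            ss[seg.start - 1 : seg.end] = "H"
    steps = np.zeros(topology.n_res)
    for i in range(1, topology.n_res):
        if ss[i] == ss[i - 1]:
            steps[i] = 1.5 if ss[i] == "H" else _INIT_COIL_STEP
        else:
            steps[i] = _INIT_BOUNDARY_STEP
    return steps


def assemble_belt(
    topology: SegmentTopology,
    disc: ImplicitDisc | None = None,
    params: BuilderParams | None = None,
    pitch_per_turn: float = 12.0,
) -> Conformation:
    """Initial conformation: segments threaded along a gentle belt spiral.

    Helices are ideal and wind about the spiral axis; coil beads sit on the
    axis.  The slight z pitch keeps successive wraps clash-free.
    """
    disc = disc or ImplicitDisc()
    params = params or BuilderParams()
    radius = disc.belt_radius + 0.5 * sum(params.belt_offset)
    s = np.cumsum(_arc_steps(topology))
    theta = s / radius
    z_axis = pitch_per_turn * theta / (2.0 * math.pi)
    axis = np.column_stack(
        [radius * np.cos(theta), radius * np.sin(theta), z_axis]
    )
    coords = axis.copy()
    for seg in topology.segments:
        if seg.ss != "helix":
            continue
        idx = np.arange(seg.start - 1, seg.end)
        phase = np.deg2rad(100.0) * np.arange(len(idx))
        u = np.column_stack([np.cos(theta[idx]), np.sin(theta[idx]), np.zeros(len(idx))])
        v = np.array([0.0, 0.0, 1.0])
        coords[idx] = axis[idx] + 2.3 * (
            np.cos(phase)[:, None] * u + np.sin(phase)[:, None] * v
        )
    return Conformation(coords, topology, label="belt_init")


def assemble_extended(topology: SegmentTopology) -> Conformation:
    """Initial conformation: segments threaded along a straight line."""
    steps = _arc_steps(topology)
    s = np.cumsum(steps)
    coords = np.column_stack([s, np.zeros_like(s), np.zeros_like(s)])
    for seg in topology.segments:
        if seg.ss != "helix":
            continue
        idx = np.arange(seg.start - 1, seg.end)
        phase = np.deg2rad(100.0) * np.arange(len(idx))
        coords[idx, 1] = 2.3 * np.cos(phase)
        coords[idx, 2] = 2.3 * np.sin(phase)
    return Conformation(coords, topology, label="extended_init")


# --- hairpin assembly -------------------------------------------------------

def _repair_clashes(
    coords: np.ndarray,
    movable: np.ndarray,
    min_sep: float = 2.1,
    bond_band: tuple[float, float] = (2.85, 4.15),
    max_iter: int = 1200,
    accumulate: bool = False,
) -> None:
    """Deterministic local relaxation removing bead clashes in threaded coils.

    Pairs of non-adjacent beads closer than ``min_sep`` are pushed apart
    (only ``movable`` beads move) and virtual bonds are re-projected into
    their band, until the trace is sterically valid.
    """
    from scipy.spatial import cKDTree

    n = len(coords)
    for _ in range(max_iter):
        tree = cKDTree(coords)
        dirty = False
        # accumulate all pushes per bead before applying, so a bead caught
        # between several occluders escapes along the net direction
        shift = np.zeros_like(coords)
        for i, j in sorted(tree.query_pairs(min_sep)):
            if j - i < 2 or not (movable[i] or movable[j]):
                continue
            diff = coords[j] - coords[i]
            dist = np.linalg.norm(diff)
            unit = diff / dist if dist > 1e-9 else np.array([0.0, 0.0, 1.0])
            push = (0.45 if accumulate else 0.6) * (min_sep - dist) + 0.04
            target = shift if accumulate else coords
            if movable[i] and movable[j]:
                target[i] -= 0.5 * push * unit
                target[j] += 0.5 * push * unit
            elif movable[j]:
                target[j] += push * unit
            else:
                target[i] -= push * unit
            dirty = True
        if accumulate:
            norms = np.linalg.norm(shift, axis=1)
            too_big = norms > 0.8
            shift[too_big] *= (0.8 / norms[too_big])[:, None]
            coords += shift
        for k in range(n - 1):
            diff = coords[k + 1] - coords[k]
            dist = np.linalg.norm(diff)
            if bond_band[0] <= dist <= bond_band[1]:
                continue
            target = np.clip(dist, bond_band[0] + 0.05, bond_band[1] - 0.05)
            corr = (dist - target) * diff / dist
            if movable[k + 1] and movable[k]:
                coords[k + 1] -= 0.5 * corr
                coords[k] += 0.5 * corr
            elif movable[k + 1]:
                coords[k + 1] -= corr
            elif movable[k]:
                coords[k] += corr
            dirty = True
        if not dirty:
            return
    raise RuntimeError("clash repair did not converge")


def _axis_point(theta: float, radius: float, z: float) -> np.ndarray:
    return np.array([radius * math.cos(theta), radius * math.sin(theta), z])


def _place_helix_arc(coords: np.ndarray, residues: np.ndarray, thetas: np.ndarray,
                     radius: float, z: float) -> None:
    """Ideal helical wheel about an arc axis with prescribed per-residue angles."""
    phase = np.deg2rad(100.0) * np.arange(len(residues))
    up = np.array([0.0, 0.0, 1.0])
    for k, (res, th) in enumerate(zip(residues, thetas)):
        u = np.array([math.cos(th), math.sin(th), 0.0])
        coords[res - 1] = _axis_point(th, radius, z) + 2.3 * (
            math.cos(phase[k]) * u + math.sin(phase[k]) * up
        )


def _fill_extrapolate(thetas: np.ndarray) -> np.ndarray:
    """Fill NaN angles by a linear fit over the defined ones."""
    idx = np.arange(len(thetas))
    ok = ~np.isnan(thetas)
    if ok.sum() < 2:
        raise ValueError("cannot extrapolate helix angles")
    slope, intercept = np.polyfit(idx[ok], thetas[ok], 1)
    out = thetas.copy()
    out[~ok] = slope * idx[~ok] + intercept
    return out


_THREAD_STEP = 3.4
#: inter-helix stacking offset of the idealized hairpin layout; inside the
#: zipper band yet wide enough that helical-wheel beads clear excluded volume
_STACK = 9.5


def _solenoid_between(
    p: np.ndarray, q: np.ndarray, path_length: float, n_interior: int,
    phase: float = 0.0, turn_radius: float = 6.0,
) -> np.ndarray:
    """Interior beads of a tapered solenoid from p to q of given contour length.

    Long flexible linkers are wound around the gap chord with a
    sine-tapered radius (zero at both ends), keeping the slack compact
    instead of ballooning away from the particle.
    """
    chord = q - p
    d = float(np.linalg.norm(chord))
    e1 = chord / max(d, 1e-9)
    ref = np.array([0.0, 0.0, 1.0]) if abs(e1[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    e2 = np.cross(e1, ref)
    e2 /= np.linalg.norm(e2)
    e3 = np.cross(e1, e2)
    slack = math.sqrt(max(path_length**2 - d**2, 1.0))
    n_turns = max(1, round(slack / (2.0 * math.pi * turn_radius)))

    t_dense = np.linspace(0.0, 1.0, 40 * (n_interior + 2))

    def curve(rho: float) -> np.ndarray:
        taper = rho * np.sin(math.pi * t_dense)
        ang = 2.0 * math.pi * n_turns * t_dense + phase
        return (
            p[None, :]
            + t_dense[:, None] * chord[None, :]
            + taper[:, None] * (np.cos(ang)[:, None] * e2 + np.sin(ang)[:, None] * e3)
        )

    def arclen(rho: float) -> float:
        pts = curve(rho)
        return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())

    lo_r, hi_r = 0.0, 40.0
    for _ in range(60):
        mid_r = 0.5 * (lo_r + hi_r)
        if arclen(mid_r) < path_length:
            lo_r = mid_r
        else:
            hi_r = mid_r
    pts = curve(0.5 * (lo_r + hi_r))
    s = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))])
    targets = np.linspace(0.0, s[-1], n_interior + 2)[1:-1]
    out = np.empty((n_interior, 3))
    for axis in range(3):
        out[:, axis] = np.interp(targets, s, pts[:, axis])
    return out


def _thread_linkers(coords: np.ndarray, topo: SegmentTopology,
                    hinge: tuple[int, int]) -> None:
    """Fill unplaced (coil) residues with arcs/straight tails between helices.

    If the clash repair cannot untangle a threading, the long linkers are
    re-threaded with a rotated solenoid winding and the repair retried.
    """
    base = coords.copy()
    movable = np.zeros(topo.n_res, dtype=bool)
    for seg in topo.segments:
        if seg.ss == "coil":
            movable[seg.start - 1 : seg.end] = True
    last_error: RuntimeError | None = None
    for low_route in (False, True):
        for phase in (0.0, math.pi / 2, math.pi, 3 * math.pi / 2):
            for accumulate in (False, True):
                coords[:] = base
                _fill_gaps(coords, topo, hinge, phase, low_route)
                _clamp_to_particle(coords, movable)
                try:
                    _repair_clashes(
                        coords, movable,
                        min_sep=BuilderParams().ev_min_sep + 0.05,
                        accumulate=accumulate,
                    )
                    return
                except RuntimeError as err:
                    last_error = err
    raise last_error


def _clamp_to_particle(
    coords: np.ndarray, movable: np.ndarray,
    r_max: float = 57.0, z_max: float = 27.0,
) -> None:
    """Pull flexible beads that stick out of the particle envelope back in."""
    r = np.linalg.norm(coords[:, :2], axis=1)
    out = movable & (r > r_max)
    scale = np.where(out, r_max / np.maximum(r, 1e-9), 1.0)
    coords[:, 0] *= scale
    coords[:, 1] *= scale
    zc = coords[:, 2]
    coords[:, 2] = np.where(movable, np.clip(zc, -z_max, z_max), zc)


def _fill_gaps(coords: np.ndarray, topo: SegmentTopology,
               hinge: tuple[int, int], phase: float = 0.0,
               low_route: bool = False) -> None:
    from .geometry import arc_between

    placed = ~np.isnan(coords[:, 0])
    first = int(np.argmax(placed)) + 1
    last = topo.n_res - int(np.argmax(placed[::-1]))

    # terminal tails: straight, pointing radially out and away from the disc
    for anchor, residues, z_sign in (
        (first, range(first - 1, 0, -1), +1.0),
        (last, range(last + 1, topo.n_res + 1), -1.0),
    ):
        p = coords[anchor - 1]
        direction = np.array([p[0], p[1], 0.0])
        direction = direction / np.linalg.norm(direction) + np.array([0.0, 0.0, 0.8 * z_sign])
        direction /= np.linalg.norm(direction)
        for k, res in enumerate(residues, start=1):
            coords[res - 1] = p + k * _THREAD_STEP * direction

    # interior gaps between placed helices
    gap_index = 0
    res = first
    while res <= last:
        if not np.isnan(coords[res - 1, 0]):
            res += 1
            continue
        lo = res
        hi = lo
        while np.isnan(coords[hi - 1, 0]):
            hi += 1
        p, q = coords[lo - 2], coords[hi - 1]
        n_interior = hi - lo
        length = (n_interior + 1) * _THREAD_STEP
        mid = 0.5 * (p + q)
        radial = np.array([mid[0], mid[1], 0.0])
        radial /= max(np.linalg.norm(radial), 1e-9)
        if n_interior > 14:
            if low_route:
                # detour below the bilayer edge when the direct chord is
                # blocked by the helix bundle
                mid = 0.5 * (p + q)
                radial = np.array([mid[0], mid[1], 0.0])
                radial /= max(np.linalg.norm(radial), 1e-9)
                w = mid + 4.0 * radial
                w[2] = -13.0
                n1 = (n_interior - 1) // 2
                n2 = n_interior - 1 - n1
                coords[lo - 1 : lo - 1 + n1] = _solenoid_between(
                    p, w, (n1 + 1) * _THREAD_STEP, n1, phase)
                coords[lo - 1 + n1] = w
                coords[lo + n1 : hi - 1] = _solenoid_between(
                    w, q, (n2 + 1) * _THREAD_STEP, n2, phase)
            else:
                # long linker: coil it compactly around the gap chord
                coords[lo - 1 : hi - 1] = _solenoid_between(p, q, length, n_interior, phase)
        else:
            if lo <= hinge[1] and hi >= hinge[0]:
                # apex loop: bulge tangentially past the hairpin apex
                theta_m = math.atan2(mid[1], mid[0])
                bulge = np.array([math.sin(theta_m), -math.cos(theta_m), 0.3])
            elif gap_index % 2 == 0:
                bulge = np.array([0.0, 0.0, 1.0]) + 0.5 * radial
            else:
                bulge = radial + np.array([0.0, 0.0, 0.6])
            coords[lo - 1 : hi - 1] = arc_between(p, q, length, bulge, n_interior)
        gap_index += 1
        res = hi


def assemble_hairpin(
    topology: SegmentTopology,
    variant: str,
    hinge: tuple[int, int] | None = None,
    disc: ImplicitDisc | None = None,
    params: BuilderParams | None = None,
    label: str = "",
) -> Conformation:
    """Initial conformation laid out as the recipe's idealized hairpin.

    The CT helix and the hairpin arm run along belt arcs below/above the
    bilayer midplane, off-belt helices sit at their band radii in zipper
    register, and linkers are threaded with matching contour length.  The
    hinge must already lie in coil (``topology.with_hinge``).  Annealing
    then refines this arrangement against the full constraint set.
    """
    disc = disc or ImplicitDisc()
    params = params or BuilderParams()
    hinge = tuple(hinge or topology.hinge_window)
    if not topology.is_coil_window(hinge):
        raise ValueError(f"hinge {hinge} is not inside a coil segment")
    if variant not in ("opened", "compact"):
        raise ValueError(f"unknown variant {variant!r}")

    r_belt = disc.belt_radius + 0.5 * sum(params.belt_offset)
    z_ct = 0.5 * sum(params.ct_z)
    z_arm = 0.5 * sum(params.arm_z)
    z_top = z_arm + _STACK
    s_back, s_fwd = _hinge_register(topology, hinge, params)
    h1, h2, h3 = topology.helix("H1"), topology.helix("H2"), topology.helix("H3")
    h4, ct = topology.helix("H4"), topology.helix("CT")
    res_of = lambda seg: np.arange(seg.start, seg.end + 1)

    def theta_back(residues: np.ndarray) -> np.ndarray:
        vals = np.where((residues >= 1) & (residues <= topology.n_res), residues, 1)
        th = s_back[vals - 1] / r_belt
        th[(residues < 1) | (residues > topology.n_res)] = np.nan
        return _fill_extrapolate(th)

    def zip_thetas(helix: Segment, zipped: Zipper, theta_of: dict[int, float]) -> np.ndarray:
        a0 = zipped.range_a[0]
        b1 = zipped.range_b[1]
        residues = res_of(helix)
        partners = b1 - (residues - a0)
        return _fill_extrapolate(
            np.array([theta_of.get(int(p), np.nan) for p in partners])
        )

    coords = np.full((topology.n_res, 3), np.nan)
    _place_helix_arc(coords, res_of(ct), s_fwd[res_of(ct) - 1] / r_belt, r_belt, z_ct)
    th_h4 = theta_back(res_of(h4))

    if variant == "opened":
        # arm helices ride the belt in hinge-anchored register; H2 stacked
        # above and slightly outside; H1 on top
        r_out = disc.belt_radius + 0.5 * sum(params.h2_out_offset)
        _place_helix_arc(coords, res_of(h4), th_h4, r_belt, z_arm)
        th_h3 = theta_back(res_of(h3))
        _place_helix_arc(coords, res_of(h3), th_h3, r_belt, z_arm)
        th_h2 = zip_thetas(h2, _zip_adjacent(h2, h3, params),
                           dict(zip(res_of(h3), th_h3)))
        _place_helix_arc(coords, res_of(h2), th_h2, r_out, z_top)
        th_h1 = zip_thetas(h1, _zip_adjacent(h1, h2, params),
                           dict(zip(res_of(h2), th_h2)))
        _place_helix_arc(coords, res_of(h1), th_h1, r_out, z_top + _STACK)
    else:
        # closed bundle: 2 x 2 cross-section, H4 inner/low, H3 outer/low,
        # H2 outer/high, H1 inner/high
        r_in = disc.belt_radius + params.belt_offset[0]
        r_out = r_in + _STACK
        _place_helix_arc(coords, res_of(h4), th_h4, r_in, z_arm)
        th_h3 = zip_thetas(h3, _zip_adjacent(h3, h4, params),
                           dict(zip(res_of(h4), th_h4)))
        _place_helix_arc(coords, res_of(h3), th_h3, r_out, z_arm)
        th_h2 = zip_thetas(h2, _zip_adjacent(h2, h3, params),
                           dict(zip(res_of(h3), th_h3)))
        _place_helix_arc(coords, res_of(h2), th_h2, r_out, z_top)
        th_h1 = zip_thetas(h1, _zip_adjacent(h1, h2, params),
                           dict(zip(res_of(h2), th_h2)))
        _place_helix_arc(coords, res_of(h1), th_h1, r_in, z_top)

    # the N-terminal tail is a floppy coil: wind it as a compact blob just
    # off H1's outer end rather than marching it around the belt
    tail_rate = 3.3 / params.helix_arc_advance
    n_nt = h1.start - 1
    if n_nt > 0:
        p = coords[h1.start - 1]
        if variant == "opened":
            # extend tangentially past H1's outer end, staying inside the
            # containment annulus
            direction = np.array([-p[1], p[0], 0.0])
            direction /= np.linalg.norm(direction)
            away = coords[h1.start - 1] - coords[h1.end - 1]
            if np.dot(direction, away) < 0:
                direction = -direction
        else:
            # the compact bundle occupies the outer shell; tuck the tail
            # inward and above the bilayer instead
            radial = np.array([p[0], p[1], 0.0])
            radial /= np.linalg.norm(radial)
            direction = -0.7 * radial + np.array([0.0, 0.0, 0.7])
            direction /= np.linalg.norm(direction)
        q = p + 12.0 * direction
        blob = _solenoid_between(p, q, (n_nt + 1) * _THREAD_STEP, n_nt,
                                 turn_radius=6.0)
        coords[:n_nt] = blob[::-1]  # residue n_nt sits next to H1's start
    # the CT tail ramps radially outward off the disc along the belt arc
    if ct.end < topology.n_res:
        th_ct = s_fwd[res_of(ct) - 1] / r_belt
        slope = (th_ct[-1] - th_ct[0]) / max(len(th_ct) - 1, 1)
        n_tail = topology.n_res - ct.end
        r_target = disc.belt_radius + params.tail_out_offset + 3.0
        for k, res in enumerate(range(ct.end + 1, topology.n_res + 1), start=1):
            th = th_ct[-1] + k * slope * tail_rate
            r_tail = r_belt + (r_target - r_belt) * k / n_tail
            coords[res - 1] = _axis_point(th, r_tail, z_ct)

    _thread_linkers(coords, topology, hinge)
    conf = Conformation(coords, topology,
                        label=label or f"{variant}_hairpin_init_{hinge[0]}-{hinge[1]}")
    conf.check_geometry()
    return conf


# --- constraint recipes -----------------------------------------------------

def restraint_bands(
    restraints: Sequence[Restraint], weight: float = 2.0, margin: float = 2.0
) -> list[DistanceBand]:
    """Cross-link restraints as flat-bottom upper-bound distance bands.

    The band closes ``margin`` Angstrom below the restraint ceiling so that a
    satisfied band also passes the strict < cutoff validation rule.
    """
    return [
        DistanceBand(r.res_a, r.res_b, 0.0, max(r.cutoff - margin, 1.0), weight, tag="restraint")
        for r in restraints
    ]


def _hinge_register(
    topology: SegmentTopology, hinge: tuple[int, int], params: BuilderParams
) -> tuple[np.ndarray, np.ndarray]:
    """Arc coordinate of every residue measured backward/forward from the hinge.

    Returns (s_back, s_fwd): s_back[i] is the arc distance of 1-based residue
    i+1 walking backward from the hinge start, NaN for residues at/after the
    hinge; s_fwd the analogue walking forward from the hinge end.
    """
    n = topology.n_res
    adv = np.empty(n)
    for seg in topology.segments:
        adv[seg.start - 1 : seg.end] = (
            params.helix_arc_advance if seg.ss == "helix" else params.coil_arc_advance
        )
    lo, hi = hinge
    s_back = np.full(n, np.nan)
    acc = 0.0
    for res in range(lo - 1, 0, -1):
        acc += adv[res - 1]
        s_back[res - 1] = acc
    s_fwd = np.full(n, np.nan)
    acc = 0.0
    for res in range(hi + 1, n + 1):
        acc += adv[res - 1]
        s_fwd[res - 1] = acc
    return s_back, s_fwd


def _foldback_bands(
    topology: SegmentTopology,
    hinge: tuple[int, int],
    arm_helices: Sequence[Segment],
    ct_helix: Segment,
    params: BuilderParams,
) -> list[DistanceBand]:
    """Antiparallel fold-back pairing of arm helices with the CT helix.

    The register is anchored at the hinge and advances by arc length, with
    coil residues contributing ``coil_arc_advance`` each; that single
    parameter is calibrated against the opened model's printed NT-CT contact
    pattern and leaves the hinge-186 register near-balanced (the arm end
    falls close to the CT helix end, as the half-belt dimer geometry
    requires).
    """
    s_back, s_fwd = _hinge_register(topology, hinge, params)
    ct_res = np.arange(ct_helix.start, ct_helix.end + 1)
    ct_s = s_fwd[ct_res - 1]
    bands = []
    for helix in arm_helices:
        for i in range(helix.start, helix.end + 1):
            s = s_back[i - 1]
            if np.isnan(s) or s < ct_s[0] - 1.0 or s > ct_s[-1] + 1.0:
                continue
            j = int(round(float(np.interp(s, ct_s, ct_res))))
            bands.append(
                DistanceBand(
                    i, j,
                    params.zipper_target - params.zipper_half_width,
                    params.zipper_target + params.zipper_half_width,
                    weight=params.w_foldback, tag="foldback",
                )
            )
    return bands


def _zip_adjacent(a: Segment, b: Segment, params: BuilderParams) -> Zipper:
    """Antiparallel zipper between two consecutive bundle helices.

    The register is centered (helix midpoints align, the longer helix
    overhanging both ends equally), as in a packed antiparallel bundle.
    """
    length = min(len(a), len(b))
    a0 = a.start + (len(a) - length) // 2
    b0 = b.start + (len(b) - length) // 2
    return Zipper(
        range_a=(a0, a0 + length - 1),
        range_b=(b0, b0 + length - 1),
        orientation="antiparallel",
        target=params.zipper_target,
        half_width=params.zipper_half_width,
        weight=params.w_zipper,
    )


def constraints_for_variant(
    topology: SegmentTopology,
    variant: str,
    hinge: tuple[int, int] | None = None,
    disc: ImplicitDisc | None = None,
    params: BuilderParams | None = None,
) -> ConstraintSet:
    """Emit the full constraint recipe for the opened or compact hairpin.

    The hinge window must lie in coil (use ``topology.with_hinge`` first when
    it clips a helix end).  Requires segments labeled H1..H4 and CT.
    """
    if variant not in ("opened", "compact"):
        raise ValueError(f"variant must be 'opened' or 'compact', got {variant!r}")
    disc = disc or ImplicitDisc()
    params = params or BuilderParams()
    hinge = tuple(hinge or topology.hinge_window)
    if not topology.is_coil_window(hinge):
        raise ValueError(
            f"hinge {hinge} is not inside a coil segment; "
            "trim the topology with with_hinge() first"
        )

    h1, h2, h3 = topology.helix("H1"), topology.helix("H2"), topology.helix("H3")
    h4, ct = topology.helix("H4"), topology.helix("CT")
    r = disc.belt_radius
    belt = (r + params.belt_offset[0], r + params.belt_offset[1])

    cons: list = []
    # CT helix on the belt, inside the bilayer; flexible tail pushed outside
    cons.append(RadialBand((ct.start, ct.end), belt[0], belt[1], params.w_radial))
    cons.append(ZBand((ct.start, ct.end), params.ct_z[0], params.ct_z[1], params.w_z))
    if ct.end < topology.n_res:
        cons.append(
            RadialBand((ct.end + 1, topology.n_res), r + params.tail_out_offset,
                       np.inf, params.w_tail)
        )
    # keep the whole chain at the particle
    cons.append(
        RadialBand((1, topology.n_res), 0.0, r + params.containment_offset,
                   params.w_containment, tag="containment")
    )
    cons.append(
        ZBand((1, topology.n_res), -params.containment_z, params.containment_z,
              params.w_containment, tag="containment")
    )
    cons.append(ExcludedVolume(min_sep=params.ev_min_sep))

    if variant == "opened":
        arm = [h4, h3]
        cons.append(RadialBand((h3.start, h3.end), belt[0], belt[1], params.w_radial))
        cons.append(ZBand((h3.start, h3.end), params.arm_z[0], params.arm_z[1], params.w_z))
        cons.append(ZBand((h4.start, h4.end), params.arm_z[0], params.arm_z[1], params.w_z))
        cons.append(
            RadialBand((h2.start, h2.end), r + params.h2_out_offset[0],
                       r + params.h2_out_offset[1], params.w_radial)
        )
        cons.append(_zip_adjacent(h1, h2, params))
        cons.append(_zip_adjacent(h2, h3, params))
        # both arms of the opened hairpin span the same half-belt (the second
        # chain of the dimer occupies the other half), so the hinge-distal
        # ends of the two arms close up opposite the apex
        cons.append(
            DistanceBand(h3.start, ct.end, 0.0, params.closure_max,
                         params.w_closure, tag="closure")
        )
    else:  # compact: closed bundle, only H4 on the belt, H3 radially outside
        arm = [h4]
        cons.append(RadialBand((h4.start, h4.end), belt[0], belt[1], params.w_radial))
        cons.append(ZBand((h4.start, h4.end), params.arm_z[0], params.arm_z[1], params.w_z))
        cons.append(
            RadialBand((h3.start, h3.end), r + params.h3_out_offset[0],
                       r + params.h3_out_offset[1], params.w_radial)
        )
        cons.append(_zip_adjacent(h1, h2, params))
        cons.append(_zip_adjacent(h2, h3, params))
        cons.append(_zip_adjacent(h3, h4, params))

    cons.extend(_foldback_bands(topology, hinge, arm, ct, params))
    return ConstraintSet(cons, topology.n_res)


# --- simulated annealing ----------------------------------------------------

def _interp(lohi: tuple[float, float], frac: float) -> float:
    return lohi[0] + (lohi[1] - lohi[0]) * frac


def _bonds_ok(coords: np.ndarray) -> bool:
    b = np.linalg.norm(np.diff(coords, axis=0), axis=1)
    return bool(b.min() >= BOND_BAND[0] and b.max() <= BOND_BAND[1])


class _MoveSet:
    def __init__(self, topology: SegmentTopology, schedule: AnnealSchedule, rng):
        self.rng = rng
        self.schedule = schedule
        self.n = topology.n_res
        coil = topology.coil_residues() - 1  # 0-based
        self.pivot_sites = coil[(coil > 0) & (coil < self.n - 1)]
        self.bead_sites = coil
        self.helices = [(h.start - 1, h.end - 1) for h in topology.helices()]
        probs = np.array(
            [schedule.p_pivot, schedule.p_crank, schedule.p_rigid, schedule.p_bead]
        )
        self.probs = probs / probs.sum()

    def _unit(self) -> np.ndarray:
        v = self.rng.normal(size=3)
        return v / np.linalg.norm(v)

    def propose(self, coords: np.ndarray, frac: float) -> np.ndarray | None:
        """Return proposed coordinates, or None when no move is applicable."""
        rng = self.rng
        kind = rng.choice(4, p=self.probs)
        s = self.schedule
        new = coords.copy()
        if kind == 0 and len(self.pivot_sites):
            k = int(rng.choice(self.pivot_sites))
            angle = rng.normal(0.0, _interp(s.pivot_sigma, frac))
            axis, point = self._unit(), coords[k]
            if rng.random() < 0.5:
                new[k + 1 :] = rotate_about_point(coords[k + 1 :], axis, angle, point)
            else:
                new[:k] = rotate_about_point(coords[:k], axis, angle, point)
            return new
        if kind == 1 and len(self.pivot_sites) >= 2:
            for _ in range(8):
                k, l = sorted(rng.choice(self.pivot_sites, size=2, replace=False))
                if 3 <= l - k <= 60:
                    axis = coords[l] - coords[k]
                    if np.linalg.norm(axis) < 1e-6:
                        continue
                    angle = rng.normal(0.0, _interp(s.crank_sigma, frac))
                    new[k + 1 : l] = rotate_about_point(
                        coords[k + 1 : l], axis, angle, coords[k]
                    )
                    return new
            return None
        if kind == 2 and self.helices:
            s0, s1 = self.helices[int(rng.integers(len(self.helices)))]
            block = coords[s0 : s1 + 1]
            center = block.mean(axis=0)
            angle = rng.normal(0.0, _interp(s.rigid_rot_sigma, frac))
            shift = rng.normal(0.0, _interp(s.rigid_trans_sigma, frac), size=3)
            new[s0 : s1 + 1] = rotate_about_point(block, self._unit(), angle, center) + shift
            return new
        if len(self.bead_sites):
            k = int(rng.choice(self.bead_sites))
            new[k] += rng.normal(0.0, _interp(s.bead_sigma, frac), size=3)
            return new
        return None


def anneal(
    conf0: Conformation,
    constraints: ConstraintSet,
    seed: int,
    n_steps: int | None = None,
    schedule: AnnealSchedule | None = None,
) -> tuple[Conformation, AnnealResult]:
    """Anneal a conformation against a constraint set; fully seed-determined.

    Returns the best-energy conformation visited (the input itself when it
    already satisfies everything) and the energy/trace record.  Results carry
    ``converged=False`` when the final pseudo-energy stays above the schedule
    tolerance.
    """
    schedule = schedule or AnnealSchedule()
    if n_steps is not None:
        schedule = replace(schedule, n_steps=n_steps)
    if conf0.topology is None:
        raise ValueError("conf0 must carry a topology")
    rng = np.random.default_rng(seed)
    moves = _MoveSet(conf0.topology, schedule, rng)

    coords = conf0.coords.copy()
    if not _bonds_ok(coords):
        raise ValueError("initial conformation violates the connectivity band")
    if not constraints.excluded_volume_ok(coords):
        raise ValueError("initial conformation violates excluded volume")

    def soft_energy(c: np.ndarray) -> float:
        e = constraints.energy(c)
        return e.total - e.breakdown.get("excluded_volume", 0.0)

    e_cur = soft_energy(coords)
    best = coords.copy()
    e_best = e_cur

    # start temperature proportional to the initial strain: a layout that
    # already satisfies its constraints is only locally refined, while a
    # frustrated one is melted and restructured
    if schedule.t_start is None:
        t0 = float(np.clip(e_cur / 50.0, 1.0, 200.0))
    else:
        t0 = schedule.t_start
    t_end = t0 * schedule.t_end_ratio

    n_total = schedule.n_steps
    per_rung = max(n_total // schedule.n_rungs, 1)
    trace = []
    accepted = 0
    step = 0
    for rung in range(schedule.n_rungs):
        frac = rung / max(schedule.n_rungs - 1, 1)
        temp = t0 * (t_end / t0) ** frac
        for _ in range(per_rung):
            step += 1
            prop = moves.propose(coords, frac)
            if prop is None:
                continue
            if not _bonds_ok(prop) or not constraints.excluded_volume_ok(prop):
                continue
            e_new = soft_energy(prop)
            de = e_new - e_cur
            if de <= 0 or rng.random() < math.exp(-de / temp):
                coords, e_cur = prop, e_new
                accepted += 1
                if e_cur < e_best - 1e-12:
                    best, e_best = coords.copy(), e_cur
            if step % schedule.trace_interval == 0:
                trace.append((step, temp, e_cur, e_best))
    trace.append((step, t_end, e_cur, e_best))

    energy = constraints.energy(best)
    result = AnnealResult(
        energy=energy,
        trace=np.array(trace),
        seed=seed,
        n_steps=schedule.n_steps,
        acceptance_rate=accepted / max(step, 1),
        converged=bool(energy.total <= schedule.convergence_tol),
    )
    label = f"{conf0.label}_annealed_seed{seed}" if conf0.label else f"annealed_seed{seed}"
    return Conformation(best, conf0.topology, label=label), result


def build_model(
    variant: str,
    hinge: tuple[int, int],
    seed: int,
    topology: SegmentTopology | None = None,
    disc: ImplicitDisc | None = None,
    params: BuilderParams | None = None,
    schedule: AnnealSchedule | None = None,
    extra_bands: Sequence[DistanceBand] = (),
) -> tuple[Conformation, AnnealResult]:
    """Assemble, constrain and anneal one monomer model for a given hinge."""
    from .chain import load_topology

    topology = topology or load_topology("default")
    disc = disc or ImplicitDisc()
    params = params or BuilderParams()
    topo = topology.with_hinge(hinge)
    cs = constraints_for_variant(topo, variant, hinge, disc, params)
    if extra_bands:
        cs = ConstraintSet(cs.constraints + list(extra_bands), topo.n_res)
    conf0 = assemble_hairpin(topo, variant, hinge, disc, params)
    model, result = anneal(conf0, cs, seed=seed, schedule=schedule)
    model.label = f"{variant}_hinge{hinge[0]}-{hinge[1]}_seed{seed}"
    return model, result


@dataclass
class HingeRanking:
    table: "object"                  # pandas.DataFrame, one row per (hinge, seed)
    ranking: list[tuple[int, int]]   # hinges, best first
    models: dict[tuple[tuple[int, int], int], Conformation]


def enumerate_hinge_models(
    topology: SegmentTopology,
    variant: str,
    hinges: Sequence[tuple[int, int]],
    restraints: Sequence[Restraint],
    seeds: Sequence[int],
    disc: ImplicitDisc | None = None,
    params: BuilderParams | None = None,
    schedule: AnnealSchedule | None = None,
) -> HingeRanking:
    """Build one model per (hinge, seed) and rank hinges by restraint fit.

    Models are generated from the constraint recipe alone; the cross-link
    restraints only score them.  Hinges are ranked by mean satisfied-restraint
    count, ties broken by lower mean pseudo-energy, then by input order.
    """
    import pandas as pd

    from .validation import validate_model

    if not hinges:
        raise ValueError("need at least one hinge")
    rows = []
    models: dict[tuple[tuple[int, int], int], Conformation] = {}
    for hinge in hinges:
        hinge = tuple(hinge)
        for seed in seeds:
            model, result = build_model(
                variant, hinge, seed, topology=topology, disc=disc,
                params=params, schedule=schedule,
            )
            report = validate_model(model, restraints)
            models[(hinge, seed)] = model
            rows.append(
                {
                    "hinge": f"{hinge[0]}-{hinge[1]}",
                    "seed": seed,
                    "satisfied": report.n_satisfied,
                    "total": report.n_total,
                    "energy": result.energy.total,
                    "converged": result.converged,
                }
            )
    table = pd.DataFrame(rows)
    order = (
        table.groupby("hinge", sort=False)
        .agg(mean_satisfied=("satisfied", "mean"), mean_energy=("energy", "mean"))
        .reset_index()
    )
    order["input_order"] = order["hinge"].map(
        {f"{h[0]}-{h[1]}": k for k, h in enumerate(hinges)}
    )
    order = order.sort_values(
        ["mean_satisfied", "mean_energy", "input_order"],
        ascending=[False, True, True],
        kind="stable",
    )
    ranking = [tuple(int(x) for x in h.split("-")) for h in order["hinge"]]
    return HingeRanking(table=table, ranking=ranking, models=models)
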