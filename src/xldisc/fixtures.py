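"""Synthetic inputs: reference conformations, XL tables and pose sets.

Everything the test surface needs is generated here, deterministically:

* toy belt conformations of the 299-residue chain embodying the competing
  lipid-bound topologies -- a fully extended superhelical belt and hairpins
  folded at each candidate hinge, in opened- and compact-bundle flavors;
* two special conformations whose 22 lysine-pair distances reproduce a
  prescribed yes/no compatibility pattern exactly (pairs marked yes are
  placed well under the 30 A ceiling, pairs marked no well over it);
* simulated cross-link identification tables from any conformation, with
  detection probability, false-positive rate and peptide-level duplication;
* docked pose sets with a known ground-truth minimum anchor span.

The packaged compatibility pattern (22 lysine pairs, two model columns) is
stored as plain data so tests never depend on regenerating annealed models.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .builder import (
    BuilderParams,
    _repair_clashes,
    assemble_belt,
    assemble_hairpin,
)
from .chain import Conformation, SegmentTopology, load_topology
from .docking import Pose, PoseSet
from .geometry import arc_between
from .restraints import CrossLinkIdentification
from .seqdata import apoe4_sequence, lysine_positions, tryptic_peptide

__all__ = [
    "XlSimulationParams",
    "compatibility_pattern",
    "make_reference_conformations",
    "table1_identifications",
    "identifications_to_frame",
    "write_xl_table",
    "simulate_crosslinks",
    "make_pose_fixtures",
]

_STEP = 3.4  # linker threading step of the pattern conformations, A


@dataclass(frozen=True)
class XlSimulationParams:
    """Parameters of the synthetic cross-linking experiment."""

    seed: int
    cutoff: float = 30.0
    detection_prob: float = 0.85
    false_positive_rate: float = 0.02
    duplication: float = 27.0 / 22.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.detection_prob <= 1.0:
            raise ValueError("detection_prob outside [0, 1]")
        if not 0.0 <= self.false_positive_rate <= 1.0:
            raise ValueError("false_positive_rate outside [0, 1]")
        if self.cutoff <= 0 or self.duplication < 1.0:
            raise ValueError("cutoff must be positive and duplication >= 1")


@lru_cache(maxsize=1)
def compatibility_pattern() -> pd.DataFrame:
    """Packaged 22-pair yes/no compatibility pattern (columns opened/compact)."""
    text = resources.files("xldisc.data").joinpath("table1_pattern.tsv").read_text()
    import io

    frame = pd.read_csv(io.StringIO(text), sep="\t")
    frame["opened"] = frame["opened"] == "yes"
    frame["compact"] = frame["compact"] == "yes"
    return frame


# --- toy belt conformations -------------------------------------------------

def _hairpin_reference(variant: str, hinge: tuple[int, int], label: str) -> Conformation:
    """Deterministic toy hairpin wrapped on the belt, folded at ``hinge``."""
    topo = load_topology("default").with_hinge(hinge)
    return assemble_hairpin(topo, variant, hinge, label=label)


def _pattern_conformation(column: str) -> Conformation:
    """Chain whose lysine-pair distances realize one compatibility column.

    Anchor (lysine) positions are solved by bounded least squares -- pairs
    marked yes are pulled under 24 A, pairs marked no pushed beyond 36 A,
    consecutive anchors kept within the reach of the chain between them --
    and the remaining residues are threaded along deterministic arcs of the
    right contour length.
    """
    pattern = compatibility_pattern()
    anchors = sorted(set(pattern["res_a"]) | set(pattern["res_b"]))
    index = {res: k for k, res in enumerate(anchors)}
    yes = [(index[a], index[b]) for a, b, s in
           zip(pattern["res_a"], pattern["res_b"], pattern[column]) if s]
    no = [(index[a], index[b]) for a, b, s in
          zip(pattern["res_a"], pattern["res_b"], pattern[column]) if not s]
    consec = [
        (index[a], index[b], 3.0 * (b - a))
        for a, b in zip(anchors, anchors[1:])
    ]

    def residuals(x: np.ndarray) -> np.ndarray:
        pts = x.reshape(-1, 3)
        out = []
        for i, j in yes:
            out.append(max(0.0, np.linalg.norm(pts[i] - pts[j]) - 24.0))
        for i, j in no:
            out.append(max(0.0, 36.0 - np.linalg.norm(pts[i] - pts[j])))
        for i, j, reach in consec:
            out.append(max(0.0, np.linalg.norm(pts[i] - pts[j]) - reach))
        for i in range(len(anchors)):
            for j in range(i + 1, len(anchors)):
                out.append(max(0.0, 6.0 - np.linalg.norm(pts[i] - pts[j])))
        return np.array(out)

    # deterministic, loosely hairpin-like start: two offset rows of anchors
    x0 = np.array(
        [((k % 4) * 13.0, (k // 4) * 15.0, (k % 3) * 9.0) for k in range(len(anchors))]
    )
    sol = least_squares(residuals, x0.ravel(), xtol=1e-12, ftol=1e-12, gtol=1e-12)
    if residuals(sol.x).max() > 1e-6:
        raise RuntimeError(f"anchor layout for pattern '{column}' did not converge")
    pts = sol.x.reshape(-1, 3)

    n_res = 299
    coords = np.full((n_res, 3), np.nan)
    for res, k in index.items():
        coords[res - 1] = pts[k]
    bulges = [
        np.array(v, dtype=float)
        for v in [(0, 0, 1), (0, 1, 0.4), (1, 0, 0.4), (0, 0, -1), (0, -1, 0.4), (-1, 0, 0.4)]
    ]
    for g, (a, b) in enumerate(zip(anchors, anchors[1:])):
        gap = b - a
        if gap > 1:
            coords[a : b - 1] = arc_between(
                coords[a - 1], coords[b - 1], gap * _STEP, bulges[g % len(bulges)], gap - 1
            )
    centroid = pts.mean(axis=0)
    direction = coords[anchors[-1] - 1] - centroid
    direction /= np.linalg.norm(direction)
    for k, res in enumerate(range(anchors[-1] + 1, n_res + 1), start=1):
        coords[res - 1] = coords[anchors[-1] - 1] + k * _STEP * direction

    movable = np.ones(n_res, dtype=bool)
    for res in anchors:
        movable[res - 1] = False  # anchor distances encode the pattern
    _repair_clashes(coords, movable)

    conf = Conformation(coords, load_topology("default"), label=f"table1_{column}")
    conf.check_geometry()
    return conf


def make_reference_conformations() -> dict[str, Conformation]:
    """Deterministic named toy conformations of the 299-residue chain.

    ``extended_belt`` winds the whole chain around the disc rim as a single
    superhelix (the double-belt-style decoy); ``hairpin_*`` fold back at
    each candidate hinge; ``table1_opened``/``table1_compact`` realize the
    packaged compatibility pattern exactly.
    """
    topo = load_topology("default")
    extended = assemble_belt(topo, pitch_per_turn=40.0)
    extended.label = "extended_belt"
    return {
        "extended_belt": extended,
        "hairpin_164": _hairpin_reference("opened", (164, 168), "hairpin_164"),
        "hairpin_186_opened": _hairpin_reference("opened", (186, 193), "hairpin_186_opened"),
        "hairpin_186_compact": _hairpin_reference("compact", (186, 193), "hairpin_186_compact"),
        "hairpin_201": _hairpin_reference("opened", (201, 208), "hairpin_201"),
        "table1_opened": _pattern_conformation("opened"),
        "table1_compact": _pattern_conformation("compact"),
    }


# --- simulated identification tables ---------------------------------------

def _make_id(pos_a: int, pos_b: int, xquest: float, delta_s: float,
             n_res: int) -> CrossLinkIdentification:
    if n_res == len(apoe4_sequence()):
        pep_a, pep_b = tryptic_peptide(pos_a), tryptic_peptide(pos_b)
    else:
        pep_a, pep_b = f"PEP{pos_a}", f"PEP{pos_b}"
    return CrossLinkIdentification(
        peptide_a=pep_a, peptide_b=pep_b, pos_a=pos_a, pos_b=pos_b,
        xquest_score=xquest, delta_s=delta_s, fdr=0.0,
    )


def simulate_crosslinks(
    conf: Conformation,
    lys_positions: Sequence[int] | None = None,
    params: XlSimulationParams | None = None,
) -> list[CrossLinkIdentification]:
    """Simulate an identification table from a conformation.

    Every lysine pair closer than the cutoff is reported with probability
    ``detection_prob``; pairs beyond it appear at ``false_positive_rate``;
    redundant peptide-level rows are injected per the duplication factor.
    Scores are filled with values that pass the default confidence filter.
    """
    if params is None:
        raise ValueError("params (with a seed) are required")
    lys = tuple(lys_positions) if lys_positions is not None else lysine_positions()
    rng = np.random.default_rng(params.seed)
    base: list[CrossLinkIdentification] = []
    for i, a in enumerate(lys):
        for b in lys[i + 1 :]:
            d = float(np.linalg.norm(conf.position(a) - conf.position(b)))
            prob = params.detection_prob if d < params.cutoff else params.false_positive_rate
            if rng.random() < prob:
                base.append(
                    _make_id(a, b, float(rng.uniform(25, 45)),
                             float(rng.uniform(0.0, 0.9)), conf.n_res)
                )
    n_extra = int(round((params.duplication - 1.0) * len(base)))
    ids = list(base)
    if base and n_extra:
        for k in rng.choice(len(base), size=n_extra, replace=n_extra > len(base)):
            src = base[int(k)]
            ids.append(
                _make_id(src.pos_b, src.pos_a, float(rng.uniform(25, 45)),
                         float(rng.uniform(0.0, 0.9)), conf.n_res)
            )
    return ids


def table1_identifications() -> list[CrossLinkIdentification]:
    """The packaged 27-row identification fixture over the 22 pattern pairs.

    Twenty-two rows cover each unique pair once; five peptide-level
    duplicates (the first five pairs, positions swapped) bring the table to
    27 rows, mirroring a realistic redundancy level.  Fully deterministic.
    """
    pattern = compatibility_pattern()
    ids = []
    for k, (a, b) in enumerate(zip(pattern["res_a"], pattern["res_b"])):
        ids.append(_make_id(int(a), int(b), 30.0 + 0.5 * k, (0.05 + 0.03 * k) % 0.9, 299))
    for k in range(5):
        a, b = int(pattern["res_a"][k]), int(pattern["res_b"][k])
        ids.append(_make_id(b, a, 28.0 + k, (0.11 + 0.05 * k) % 0.9, 299))
    return ids


def identifications_to_frame(ids: Sequence[CrossLinkIdentification]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": range(1, len(ids) + 1),
            "peptide_a": [i.peptide_a for i in ids],
            "peptide_b": [i.peptide_b for i in ids],
            "pos_a": [i.pos_a for i in ids],
            "pos_b": [i.pos_b for i in ids],
            "xquest_score": [i.xquest_score for i in ids],
            "delta_s": [i.delta_s for i in ids],
            "fdr": [i.fdr for i in ids],
        }
    )


def write_xl_table(ids: Sequence[CrossLinkIdentification], dest) -> None:
    identifications_to_frame(ids).to_csv(dest, sep="\t", index=False)


# --- pose fixtures ----------------------------------------------------------

def make_pose_fixtures(
    n_a: int,
    n_b: int,
    min_span: float = 35.0,
    spread: float = 25.0,
    seed: int = 0,
    anchor_a: tuple[int, str] = (167, "CA"),
    anchor_b: tuple[int, str] = (179, "CA"),
) -> tuple[PoseSet, PoseSet]:
    """Two pose sets whose ground-truth minimum anchor span is ``min_span``.

    The designated closest pair realizes the minimum exactly; every other
    pair is placed strictly farther (up to ``min_span + spread``).  The true
    minimum is recorded in both sets' metadata.
    """
    if n_a < 1 or n_b < 1:
        raise ValueError("pose counts must be >= 1")
    rng = np.random.default_rng(seed)

    def pose(anchor: tuple[int, str], position: np.ndarray, label: str) -> Pose:
        res, name = anchor
        atoms = {
            (res, name): position,
            (res, "C"): position + np.array([1.3, 0.4, 0.0]),
            (res + 1, name): position + np.array([2.4, -1.9, 1.4]),
        }
        return Pose(atoms=atoms, label=label)

    a_pts = [np.array([5.0, 0.0, 0.0])]
    for _ in range(n_a - 1):
        v = rng.normal(size=3)
        a_pts.append(4.9 * rng.random() ** (1 / 3) * v / np.linalg.norm(v))
    b_pts = [np.array([5.0 + min_span, 0.0, 0.0])]
    for _ in range(n_b - 1):
        v = rng.normal(size=3)
        radius = min_span + 5.0 + rng.uniform(0.5, max(spread, 0.6))
        b_pts.append(radius * v / np.linalg.norm(v))

    set_a = PoseSet(
        poses=[pose(anchor_a, p, f"A{k}") for k, p in enumerate(a_pts)],
        anchor=anchor_a, label="module_A",
        metadata={"min_span": float(min_span), "seed": seed},
    )
    set_b = PoseSet(
        poses=[pose(anchor_b, p, f"B{k}") for k, p in enumerate(b_pts)],
        anchor=anchor_b, label="module_B",
        metadata={"min_span": float(min_span), "seed": seed},
    )
    return set_a, set_b
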