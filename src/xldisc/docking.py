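"""Linker-span screening of docked receptor-module pose pairs.

When two receptor modules (e.g. the LA4 and LA5 repeats of the LDL receptor)
are docked independently onto the same ligand, the physically admissible
combinations are those whose anchor atoms -- the residues joined by the
inter-module linker -- lie within the linker's reach.  The default bound is
n_linker * 3.8 A (an extended Calpha-Calpha step), 45.6 A for the 12-residue
LA4-LA5 loop.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["Pose", "PoseSet", "ScreenResult", "pair_span", "screen_pairs", "load_pose_set"]


@dataclass
class Pose:
    """One docked coordinate model: (res_id, atom_name) -> position."""

    atoms: dict[tuple[int, str], np.ndarray]
    label: str = ""

    def atom(self, res_id: int, atom_name: str) -> np.ndarray:
        key = (res_id, atom_name)
        if key not in self.atoms:
            raise KeyError(
                f"pose '{self.label}' has no atom {atom_name} in residue {res_id}"
            )
        return self.atoms[key]


@dataclass
class PoseSet:
    poses: list[Pose]
    anchor: tuple[int, str]          # (residue index, atom name)
    label: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pose in self.poses:
            pose.atom(*self.anchor)  # fail fast if an anchor is unresolvable

    def __len__(self) -> int:
        return len(self.poses)


@dataclass
class ScreenResult:
    compatible: pd.DataFrame   # index_a, index_b, span; ascending by span
    n_evaluated: int
    bound: float

    @property
    def min_span(self) -> float:
        return float(self.all_spans.min())

    all_spans: np.ndarray = field(default=None, repr=False)


def pair_span(
    pose_a: Pose, pose_b: Pose, anchor_a: tuple[int, str], anchor_b: tuple[int, str]
) -> float:
    """Euclidean distance between the two anchor atoms (Angstrom)."""
    return float(np.linalg.norm(pose_a.atom(*anchor_a) - pose_b.atom(*anchor_b)))


def screen_pairs(
    set_a: PoseSet,
    set_b: PoseSet,
    n_linker: int = 12,
    per_res: float = 3.8,
) -> ScreenResult:
    """Evaluate all |A| x |B| pose pairs against the linker-span bound.

    A pair is compatible when its anchor span is at most n_linker * per_res.
    The compatible list is sorted ascending by span with a deterministic
    (index_a, index_b) tie-break.
    """
    if not len(set_a) or not len(set_b):
        raise ValueError("both pose sets must be non-empty")
    bound = n_linker * per_res
    a_pts = np.array([p.atom(*set_a.anchor) for p in set_a.poses])
    b_pts = np.array([p.atom(*set_b.anchor) for p in set_b.poses])
    spans = np.linalg.norm(a_pts[:, None, :] - b_pts[None, :, :], axis=2)
    ia, ib = np.meshgrid(np.arange(len(set_a)), np.arange(len(set_b)), indexing="ij")
    table = pd.DataFrame(
        {"index_a": ia.ravel(), "index_b": ib.ravel(), "span": spans.ravel()}
    )
    compatible = (
        table[table["span"] <= bound]
        .sort_values(["span", "index_a", "index_b"], kind="stable")
        .reset_index(drop=True)
    )
    return ScreenResult(
        compatible=compatible,
        n_evaluated=len(set_a) * len(set_b),
        bound=bound,
        all_spans=spans,
    )


def load_pose_set(
    path: str, anchor: tuple[int, str], label: str = ""
) -> PoseSet:
    """Load poses from a (possibly multi-model) PDB file."""
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile.read(path)
    stack = pdb.get_structure(model=None)
    poses = []
    for model_idx in range(stack.stack_depth()):
        arr = stack[model_idx]
        atoms = {
            (int(r), str(a)): c
            for r, a, c in zip(arr.res_id, arr.atom_name, arr.coord)
        }
        poses.append(Pose(atoms=atoms, label=f"{label}[{model_idx}]"))
    return PoseSet(poses=poses, anchor=anchor, label=label)
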