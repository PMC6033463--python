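"""Scoring conformations and trajectories against cross-link restraints.

A restraint is satisfied when the Euclidean distance between the two linked
Calpha atoms is strictly below the restraint ceiling (30 A by default for a
DSS-bridged lysine pair); an exact tie at the ceiling fails.  Trajectories
are judged on the final window of frames, either on the window-averaged
distance (default) or requiring every window frame below the ceiling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .chain import Conformation
from .restraints import Restraint

__all__ = [
    "ValidationReport",
    "ca_distance",
    "validate_model",
    "validate_frames",
    "tabulate_comparison",
]


@dataclass
class ValidationReport:
    rows: pd.DataFrame  # res_a, res_b, distance, satisfied
    cutoff: float

    @property
    def n_satisfied(self) -> int:
        return int(self.rows["satisfied"].sum())

    @property
    def n_total(self) -> int:
        return len(self.rows)

    @property
    def totals(self) -> tuple[int, int]:
        return self.n_satisfied, self.n_total

    def pairs_satisfied(self) -> dict[tuple[int, int], bool]:
        return {
            (int(r.res_a), int(r.res_b)): bool(r.satisfied)
            for r in self.rows.itertuples()
        }

    def __str__(self) -> str:
        return f"{self.n_satisfied}/{self.n_total} restraints < {self.cutoff:g} A"


def ca_distance(conf: Conformation, restraint: Restraint) -> float:
    """Euclidean Calpha-Calpha distance of a restrained pair (Angstrom)."""
    return float(
        np.linalg.norm(conf.position(restraint.res_a) - conf.position(restraint.res_b))
    )


def _report(distances: np.ndarray, restraints: Sequence[Restraint], cutoff: float):
    rows = pd.DataFrame(
        {
            "res_a": [r.res_a for r in restraints],
            "res_b": [r.res_b for r in restraints],
            "distance": distances,
            "satisfied": distances < cutoff,
        }
    )
    return ValidationReport(rows=rows, cutoff=cutoff)


def validate_model(
    conf: Conformation, restraints: Sequence[Restraint], cutoff: float = 30.0
) -> ValidationReport:
    """Per-restraint distances and strict < cutoff satisfaction for one model."""
    if not restraints:
        raise ValueError("restraint list is empty")
    d = np.array([ca_distance(conf, r) for r in restraints])
    return _report(d, restraints, cutoff)


def validate_frames(
    frames: Sequence[Conformation],
    restraints: Sequence[Restraint],
    cutoff: float = 30.0,
    window: float = 0.1,
    mode: str = "mean",
) -> ValidationReport:
    """Validate a trajectory on its final window of frames.

    ``window`` is the trailing fraction of frames considered (at least one
    frame).  ``mode='mean'`` applies the cutoff to the window-averaged
    distance; ``mode='all'`` requires every window frame below the cutoff.
    """
    if not frames:
        raise ValueError("no frames")
    if not restraints:
        raise ValueError("restraint list is empty")
    if mode not in ("mean", "all"):
        raise ValueError("mode must be 'mean' or 'all'")
    n_window = int(np.ceil(window * len(frames)))
    if n_window < 1:
        raise ValueError(f"window {window} selects zero frames")
    tail = frames[len(frames) - n_window :]
    dists = np.array(
        [[ca_distance(f, r) for r in restraints] for f in tail]
    )  # (n_window, n_restraints)
    if mode == "mean":
        d = dists.mean(axis=0)
        return _report(d, restraints, cutoff)
    # mode == "all": report the worst frame's distance per pair
    d = dists.max(axis=0)
    return _report(d, restraints, cutoff)


def tabulate_comparison(reports: Mapping[str, ValidationReport]) -> pd.DataFrame:
    """Side-by-side yes/no table across models sharing one restraint set.

    One row per pair plus a ``Total`` row of satisfied counts, mirroring the
    usual compatibility-table layout of XL-MS validation studies.
    """
    if not reports:
        raise ValueError("no reports")
    names = list(reports)
    first = reports[names[0]]
    key = list(zip(first.rows["res_a"], first.rows["res_b"]))
    for name in names[1:]:
        other = list(zip(reports[name].rows["res_a"], reports[name].rows["res_b"]))
        if other != key:
            raise ValueError(f"report '{name}' covers a different restraint set")
    data = {"pair": [f"Lys{a}-Lys{b}" for a, b in key]}
    for name in names:
        data[name] = ["yes" if s else "no" for s in reports[name].rows["satisfied"]]
    table = pd.DataFrame(data)
    total = {"pair": "Total"}
    for name in names:
        total[name] = f"{reports[name].n_satisfied}/{reports[name].n_total}"
    return pd.concat([table, pd.DataFrame([total])], ignore_index=True)
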