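"""Calpha-level chain representation: segment topology and conformations.

The protein is modeled as an ordered tiling of helix and coil segments over a
1-based residue range.  Conformations are bare Calpha traces (n x 3 arrays in
Angstrom); helices are parametrized as ideal alpha-helical wheels (1.5 A rise,
100 degree twist, 2.3 A radius), which puts consecutive Calpha atoms ~3.8 A
apart and the i/i+3 and i/i+4 pairs at ~5.05 and ~6.20 A.

Secondary structure is assigned from Calpha geometry alone: a five-residue
window is helical when its i/i+3 and i/i+4 distances both fall in bands
centered on the ideal values, and every residue covered by a passing window is
labeled helix.  This is a bead-level criterion, deliberately tolerant to the
noise of annealed models while rejecting extended chains (i/i+3 = 11.4 A).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import yaml

from .restraints import DomainBounds

__all__ = [
    "Segment",
    "SegmentTopology",
    "Conformation",
    "load_topology",
    "ideal_helix_coords",
    "assign_ss_ca",
    "helix_fraction",
    "HelixSpan",
    "longest_helical_span",
    "write_pdb",
    "read_pdb",
]

HELIX_RISE = 1.5
HELIX_TWIST = 100.0
HELIX_RADIUS = 2.3

#: Acceptance bands for the Calpha secondary-structure criterion (Angstrom).
D13_BAND = (4.5, 5.7)
D14_BAND = (5.6, 6.9)

#: Virtual-bond band for consecutive Calpha atoms in optimized conformations.
BOND_BAND = (2.8, 4.2)
MIN_SEPARATION = 2.0


@dataclass(frozen=True)
class Segment:
    label: str
    start: int
    end: int
    ss: str  # "helix" | "coil"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"segment {self.label}: start > end")
        if self.ss not in ("helix", "coil"):
            raise ValueError(f"segment {self.label}: ss must be helix or coil")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def residues(self) -> range:
        return range(self.start, self.end + 1)


@dataclass(frozen=True)
class SegmentTopology:
    """Ordered helix/coil segmentation with hinge window and domain bounds."""

    n_res: int
    segments: tuple[Segment, ...]
    hinge_window: tuple[int, int] = (186, 193)
    bounds: DomainBounds = field(default_factory=DomainBounds)

    def __post_init__(self) -> None:
        expect = 1
        for seg in self.segments:
            if seg.start != expect:
                raise ValueError(
                    f"segments must tile 1..{self.n_res}: gap/overlap at {seg.label}"
                )
            expect = seg.end + 1
        if expect != self.n_res + 1:
            raise ValueError(f"segments end at {expect - 1}, expected {self.n_res}")

    def helices(self) -> list[Segment]:
        return [s for s in self.segments if s.ss == "helix"]

    def helix(self, label: str) -> Segment:
        for s in self.segments:
            if s.label == label and s.ss == "helix":
                return s
        raise KeyError(f"no helix segment '{label}'")

    def segment_of(self, residue: int) -> Segment:
        for s in self.segments:
            if s.start <= residue <= s.end:
                return s
        raise IndexError(f"residue {residue} outside 1..{self.n_res}")

    def coil_residues(self) -> np.ndarray:
        return np.array(
            [r for s in self.segments if s.ss == "coil" for r in s.residues()], dtype=int
        )

    def is_coil_window(self, window: tuple[int, int]) -> bool:
        lo, hi = window
        return all(self.segment_of(r).ss == "coil" for r in range(lo, hi + 1))

    def with_hinge(self, window: tuple[int, int]) -> "SegmentTopology":
        """Return a topology whose hinge window lies entirely in coil.

        A hinge overlapping the terminal residues of a helix trims that helix
        back (the turn is declared unstructured); a hinge buried strictly
        inside a helix is rejected.
        """
        lo, hi = window
        if lo > hi or lo < 1 or hi > self.n_res:
            raise ValueError(f"invalid hinge window {window}")
        new_segments: list[Segment] = []
        for seg in self.segments:
            if seg.ss == "coil" or hi < seg.start or lo > seg.end:
                new_segments.append(seg)
                continue
            if lo <= seg.start and hi >= seg.end:
                new_segments.append(replace(seg, ss="coil"))
            elif lo <= seg.start:  # hinge covers the helix N-terminal end
                new_segments.append(replace(seg, start=hi + 1))
                new_segments.append(Segment(seg.label + "_trim", seg.start, hi, "coil"))
            elif hi >= seg.end:  # hinge covers the helix C-terminal end
                new_segments.append(replace(seg, end=lo - 1))
                new_segments.append(Segment(seg.label + "_trim", lo, seg.end, "coil"))
            else:
                raise ValueError(
                    f"hinge {window} lies inside helix {seg.label} "
                    f"({seg.start}-{seg.end}); hinges must sit in coil"
                )
        new_segments.sort(key=lambda s: s.start)
        # merge is unnecessary: trimmed pieces already tile the range
        return SegmentTopology(
            self.n_res, tuple(new_segments), hinge_window=(lo, hi), bounds=self.bounds
        )


def load_topology(variant: str = "default", path: str | None = None) -> SegmentTopology:
    """Load a named topology from the packaged config (or a user YAML file)."""
    if path is None:
        text = resources.files("xldisc.data").joinpath("default_topology.yaml").read_text()
    else:
        with open(path, "r", encoding="utf-8") as fh:
            text = fh.read()
    doc = yaml.safe_load(text)
    if variant not in doc:
        raise KeyError(f"topology variant '{variant}' not in config (have {sorted(doc)})")
    entry = doc[variant]
    segments = tuple(
        Segment(s["label"], int(s["start"]), int(s["end"]), s["ss"]) for s in entry["segments"]
    )
    dom = entry.get("domains", {})
    bounds = DomainBounds(
        tuple(dom.get("nt", (1, 191))), tuple(dom.get("ct", (210, int(entry["n_res"]))))
    )
    return SegmentTopology(
        int(entry["n_res"]),
        segments,
        hinge_window=tuple(entry.get("hinge_window", (186, 193))),
        bounds=bounds,
    )


@dataclass
class Conformation:
    """Per-residue Calpha coordinates (Angstrom) of one chain."""

    coords: np.ndarray
    topology: SegmentTopology | None = None
    label: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be (n, 3)")

    @property
    def n_res(self) -> int:
        return len(self.coords)

    def position(self, residue: int) -> np.ndarray:
        """Calpha position of a 1-based residue index."""
        if not 1 <= residue <= self.n_res:
            raise IndexError(f"residue {residue} outside chain 1..{self.n_res}")
        return self.coords[residue - 1]

    def bond_lengths(self) -> np.ndarray:
        return np.linalg.norm(np.diff(self.coords, axis=0), axis=1)

    def check_geometry(self, bond_band: tuple[float, float] = BOND_BAND,
                       min_separation: float = MIN_SEPARATION) -> None:
        """Raise if virtual bonds leave their band or any two beads collide."""
        bonds = self.bond_lengths()
        if bonds.size and (bonds.min() < bond_band[0] or bonds.max() > bond_band[1]):
            raise ValueError(
                f"virtual bond outside {bond_band}: min {bonds.min():.2f}, "
                f"max {bonds.max():.2f}"
            )
        from scipy.spatial.distance import pdist

        if self.n_res > 2:
            d = pdist(self.coords)
            iu = np.triu_indices(self.n_res, k=1)
            nonadjacent = (iu[1] - iu[0]) >= 2
            if d[nonadjacent].min() < min_separation:
                raise ValueError(f"bead clash below {min_separation} A")

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Conformation":
        return Conformation(self.coords @ rotation.T + translation, self.topology, self.label)


def ideal_helix_coords(
    n: int,
    rise: float = HELIX_RISE,
    twist: float = HELIX_TWIST,
    radius: float = HELIX_RADIUS,
) -> np.ndarray:
    """Calpha trace of an ideal alpha helix winding about the local z axis.

    Residue i sits at angle i*twist on a cylinder of the given radius, with the
    helix starting at z = 0 (segment start).  Consecutive residues end up
    sqrt((2 r sin(twist/2))^2 + rise^2) ~ 3.83 A apart at the defaults.
    """
    if n < 1:
        raise ValueError("helix length must be >= 1")
    i = np.arange(n)
    ang = np.deg2rad(twist) * i
    return np.column_stack([radius * np.cos(ang), radius * np.sin(ang), rise * i])


def assign_ss_ca(conf: Conformation | np.ndarray) -> np.ndarray:
    """Per-residue helix/coil labels ('H'/'C') from Calpha geometry.

    A five-residue window starting at i is helical when d(i, i+3) and
    d(i, i+4) fall in the ideal-helix bands; every residue covered by at
    least one passing window is labeled 'H'.  Chains shorter than five
    residues are all coil.
    """
    coords = conf.coords if isinstance(conf, Conformation) else np.asarray(conf, float)
    n = len(coords)
    labels = np.full(n, "C", dtype="<U1")
    if n < 5:
        return labels
    d13 = np.linalg.norm(coords[3:] - coords[:-3], axis=1)[: n - 4]
    d14 = np.linalg.norm(coords[4:] - coords[:-4], axis=1)
    ok = (
        (d13 >= D13_BAND[0]) & (d13 <= D13_BAND[1])
        & (d14 >= D14_BAND[0]) & (d14 <= D14_BAND[1])
    )
    for i in np.flatnonzero(ok):
        labels[i : i + 5] = "H"
    return labels


def helix_fraction(labels: np.ndarray | Sequence[str]) -> float:
    labels = np.asarray(labels)
    return float(np.mean(labels == "H")) if len(labels) else 0.0


class HelixSpan(NamedTuple):
    start: int
    end: int
    length: int


def longest_helical_span(
    labels: np.ndarray | Sequence[str],
    within: tuple[int, int] | None = None,
) -> HelixSpan:
    """Maximal contiguous helix run intersecting a 1-based residue interval.

    Ties go to the earlier run.  Returns (0, 0, 0) when no helical run
    intersects the interval.
    """
    labels = np.asarray(labels)
    lo, hi = within if within is not None else (1, len(labels))
    best = HelixSpan(0, 0, 0)
    run_start = None
    for idx in range(len(labels) + 1):
        helical = idx < len(labels) and labels[idx] == "H"
        if helical and run_start is None:
            run_start = idx + 1
        elif not helical and run_start is not None:
            run_end = idx
            if run_start <= hi and run_end >= lo:
                length = run_end - run_start + 1
                if length > best.length:
                    best = HelixSpan(run_start, run_end, length)
            run_start = None
    return best


# --- PDB I/O (Calpha traces, chains A/B, plain single- or multi-model) ------

def _atom_array(confs: Sequence[Conformation], sequence: str | None):
    import biotite.structure as struc

    try:
        from biotite.sequence import ProteinSequence

        three = ProteinSequence.convert_letter_1to3
    except Exception:  # pragma: no cover
        three = lambda aa: "ALA"

    atoms = []
    for chain_id, conf in zip("ABCDEFGH", confs):
        seq = sequence if sequence is not None and len(sequence) == conf.n_res else None
        for res_id in range(1, conf.n_res + 1):
            atom = struc.Atom(
                conf.position(res_id),
                chain_id=chain_id,
                res_id=res_id,
                res_name=three(seq[res_id - 1]).upper() if seq else "ALA",
                atom_name="CA",
                element="C",
            )
            atoms.append(atom)
    return struc.array(atoms)


def write_pdb(
    dest: str,
    conformations: Conformation | Sequence[Conformation],
    sequence: str | None = None,
    frames: Sequence[Sequence[Conformation]] | None = None,
) -> None:
    """Write chains as a Calpha-only PDB; pass ``frames`` for a multi-model file."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile()
    if frames is not None:
        template = _atom_array(frames[0], sequence)
        coords = np.stack(
            [np.concatenate([c.coords for c in frame]) for frame in frames]
        )
        stack = struc.from_template(template, coords)
        pdb.set_structure(stack)
    else:
        if isinstance(conformations, Conformation):
            conformations = [conformations]
        pdb.set_structure(_atom_array(conformations, sequence))
    pdb.write(dest)


def read_pdb(source: str) -> list[list[Conformation]]:
    """Read a Calpha PDB into frames of per-chain conformations.

    Returns a list with one entry per model; each entry lists one
    :class:`Conformation` per chain (in chain-id order).
    """
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile.read(source)
    stack = pdb.get_structure(model=None)
    if stack.stack_depth() == 0:
        raise ValueError(f"no models in {source}")
    template = stack[0]
    ca_mask = template.atom_name == "CA"
    frames = []
    for model_idx in range(stack.stack_depth()):
        arr = stack[model_idx][ca_mask]
        chains = []
        for chain_id in sorted(set(arr.chain_id)):
            sel = arr[arr.chain_id == chain_id]
            order = np.argsort(sel.res_id, kind="stable")
            chains.append(Conformation(sel.coord[order], label=f"chain_{chain_id}"))
        frames.append(chains)
    return frames
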