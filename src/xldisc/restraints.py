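"""Cross-link identification tables and their reduction to distance restraints.

XL-MS search engines (xQuest/xProphet-style pipelines) emit one row per
identified cross-linked peptide pair, with absolute positions of the linked
residues, a composite score, a delta score and an FDR.  This module parses
such tables, applies the confidence filter, collapses redundant peptide-level
identifications onto unique residue pairs and classifies each pair by domain.

A restraint carries a Calpha-Calpha distance ceiling (30 A by default, the
conventional upper bound for DSS/BS3-bridged lysines) and a category telling
whether it lies within the N-terminal bundle, within the C-terminal domain,
or bridges the two.  All identifications are treated as intramolecular,
mirroring an experiment where the monomeric gel band is digested; the parsed
records carry an ``intramolecular`` flag recording that assumption.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence, TextIO

import pandas as pd

__all__ = [
    "CrossLinkIdentification",
    "Restraint",
    "DomainBounds",
    "RowError",
    "ParseResult",
    "DEFAULT_COLUMNS",
    "parse_xlink_table",
    "filter_identifications",
    "deduplicate",
    "classify",
    "lysine_coverage",
    "write_restraints",
    "read_restraints",
]

#: Default column-name map from logical field to header name.
DEFAULT_COLUMNS: dict[str, str] = {
    "peptide_a": "peptide_a",
    "peptide_b": "peptide_b",
    "pos_a": "pos_a",
    "pos_b": "pos_b",
    "xquest_score": "xquest_score",
    "delta_s": "delta_s",
    "fdr": "fdr",
}

_REQUIRED = ("pos_a", "pos_b", "delta_s", "fdr")


@dataclass(frozen=True)
class CrossLinkIdentification:
    """One identified cross-linked peptide pair."""

    peptide_a: str
    peptide_b: str
    pos_a: int
    pos_b: int
    xquest_score: float
    delta_s: float
    fdr: float
    intramolecular: bool = True

    def __post_init__(self) -> None:
        if self.pos_a < 1 or self.pos_b < 1:
            raise ValueError(f"residue positions must be >= 1, got {self.pos_a}, {self.pos_b}")
        if not 0.0 <= self.delta_s <= 1.0:
            raise ValueError(f"delta_s outside [0, 1]: {self.delta_s}")
        if not 0.0 <= self.fdr <= 1.0:
            raise ValueError(f"fdr outside [0, 1]: {self.fdr}")


@dataclass(frozen=True)
class Restraint:
    """A unique unordered residue pair with a distance ceiling."""

    res_a: int
    res_b: int
    cutoff: float = 30.0
    category: str = "other"
    support: int = 1

    def __post_init__(self) -> None:
        if self.res_a >= self.res_b:
            raise ValueError(f"restraint not canonical: res_a={self.res_a} >= res_b={self.res_b}")
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if self.support < 1:
            raise ValueError("support must be >= 1")

    @property
    def pair(self) -> tuple[int, int]:
        return (self.res_a, self.res_b)


@dataclass(frozen=True)
class DomainBounds:
    """Inclusive residue intervals of the two folded domains.

    Residues falling between the two intervals (the 192-209 linker for apoE)
    belong to neither domain and make a pair ``other``.
    """

    nt_range: tuple[int, int] = (1, 191)
    ct_range: tuple[int, int] = (210, 299)

    def __post_init__(self) -> None:
        (a0, a1), (b0, b1) = self.nt_range, self.ct_range
        if not (a0 <= a1 and b0 <= b1):
            raise ValueError("domain intervals must be non-empty")
        if max(a0, b0) <= min(a1, b1):
            raise ValueError("domain intervals overlap")

    def domain_of(self, residue: int) -> str:
        if self.nt_range[0] <= residue <= self.nt_range[1]:
            return "nt"
        if self.ct_range[0] <= residue <= self.ct_range[1]:
            return "ct"
        return "linker"


@dataclass(frozen=True)
class RowError:
    """A data row that could not be converted into an identification."""

    row_index: int
    message: str


@dataclass
class ParseResult:
    identifications: list[CrossLinkIdentification] = field(default_factory=list)
    errors: list[RowError] = field(default_factory=list)


def _sep_for(text: str) -> str:
    header = text.splitlines()[0] if text else ""
    return "\t" if "\t" in header else ","


def parse_xlink_table(
    source: str | TextIO,
    dialect: Mapping[str, str] | None = None,
) -> ParseResult:
    """Parse a TSV/CSV cross-link identification table.

    ``source`` is a path or an open text stream with a header row.  ``dialect``
    maps logical field names (keys of :data:`DEFAULT_COLUMNS`) to the actual
    header names.  Malformed rows are collected into ``errors`` rather than
    silently dropped; a missing required column is fatal.
    """
    cols = dict(DEFAULT_COLUMNS)
    if dialect:
        cols.update(dialect)

    if hasattr(source, "read"):
        text = source.read()
    else:
        with open(source, "r", encoding="utf-8") as fh:
            text = fh.read()
    frame = pd.read_csv(io.StringIO(text), sep=_sep_for(text), dtype=str)

    for logical in _REQUIRED:
        if cols[logical] not in frame.columns:
            raise ValueError(f"required column '{cols[logical]}' (field '{logical}') not found")

    result = ParseResult()
    for idx, row in frame.iterrows():
        try:
            ident = CrossLinkIdentification(
                peptide_a=str(row.get(cols["peptide_a"], "")),
                peptide_b=str(row.get(cols["peptide_b"], "")),
                pos_a=int(row[cols["pos_a"]]),
                pos_b=int(row[cols["pos_b"]]),
                xquest_score=float(row.get(cols["xquest_score"], "nan")),
                delta_s=float(row[cols["delta_s"]]),
                fdr=float(row[cols["fdr"]]),
            )
        except (ValueError, TypeError) as exc:
            result.errors.append(RowError(int(idx), str(exc)))
            continue
        result.identifications.append(ident)
    return result


def filter_identifications(
    ids: Iterable[CrossLinkIdentification],
    fdr_max: float = 0.05,
    delta_s_max: float = 0.95,
) -> list[CrossLinkIdentification]:
    """Keep identifications with fdr < fdr_max and delta_s < delta_s_max.

    Both comparisons are strict ("below" the threshold), so a record sitting
    exactly at a threshold is removed.  Order is preserved.
    """
    if not 0.0 <= fdr_max <= 1.0 or not 0.0 <= delta_s_max <= 1.0:
        raise ValueError("thresholds must lie in [0, 1]")
    return [i for i in ids if i.fdr < fdr_max and i.delta_s < delta_s_max]


def deduplicate(
    ids: Sequence[CrossLinkIdentification] | Sequence[Restraint],
    cutoff: float = 30.0,
    bounds: DomainBounds | None = None,
) -> list[Restraint]:
    """Collapse identifications onto unique canonical residue pairs.

    Pairs are canonicalized with ``res_a < res_b``; ``support`` counts the
    identifications collapsed onto each pair.  Self-links are excluded.  The
    operation is idempotent: feeding its own output back reproduces it.
    Restraints are returned sorted by pair.
    """
    bounds = bounds or DomainBounds()
    counts: dict[tuple[int, int], int] = {}
    for ident in ids:
        if isinstance(ident, Restraint):
            a, b, n = ident.res_a, ident.res_b, ident.support
        else:
            a, b, n = ident.pos_a, ident.pos_b, 1
        if a == b:
            continue
        key = (min(a, b), max(a, b))
        counts[key] = counts.get(key, 0) + n
    out = []
    for (a, b), n in sorted(counts.items()):
        r = Restraint(a, b, cutoff=cutoff, support=n)
        out.append(replace(r, category=classify(r, bounds)))
    return out


def classify(restraint: Restraint, bounds: DomainBounds | None = None) -> str:
    """Domain category of a pair: intra_NT, intra_CT, inter_domain or other."""
    bounds = bounds or DomainBounds()
    da = bounds.domain_of(restraint.res_a)
    db = bounds.domain_of(restraint.res_b)
    if da == db == "nt":
        return "intra_NT"
    if da == db == "ct":
        return "intra_CT"
    if {da, db} == {"nt", "ct"}:
        return "inter_domain"
    return "other"


def lysine_coverage(
    restraints: Iterable[Restraint],
    lys_positions: Iterable[int],
) -> tuple[set[int], set[int]]:
    """Split the lysine set into (covered, uncovered) by the restraint set.

    Residues appearing in restraints but absent from ``lys_positions`` are
    tolerated (they may be the reactive N-terminus) and simply ignored.
    """
    lys = set(lys_positions)
    if not lys:
        raise ValueError("lys_positions must be non-empty")
    seen = {r for rest in restraints for r in rest.pair}
    covered = lys & seen
    return covered, lys - covered


_RESTRAINT_HEADER = ["res_a", "res_b", "cutoff_A", "category", "support"]


def write_restraints(restraints: Sequence[Restraint], dest: str | TextIO) -> None:
    """Write restraints as the canonical five-column TSV."""
    frame = pd.DataFrame(
        [(r.res_a, r.res_b, r.cutoff, r.category, r.support) for r in restraints],
        columns=_RESTRAINT_HEADER,
    )
    frame.to_csv(dest, sep="\t", index=False)


def read_restraints(source: str | TextIO) -> list[Restraint]:
    """Read restraints written by :func:`write_restraints`."""
    frame = pd.read_csv(source, sep="\t")
    return [
        Restraint(int(r.res_a), int(r.res_b), cutoff=float(r.cutoff_A),
                  category=str(r.category), support=int(r.support))
        for r in frame.itertuples()
    ]
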