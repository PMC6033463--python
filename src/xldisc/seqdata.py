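"""Packaged apoE4 sequence and residue-level lookups.

The mature apolipoprotein E4 chain (299 residues, Arg112/Arg158) ships with
the package so that lysine positions, tryptic peptides and the receptor
binding site can be derived without any external download.  Numbering is
1-based over the mature chain; the N-terminal residue (a lysine here) doubles
as the amine-reactive protein N-terminus.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

__all__ = [
    "apoe4_sequence",
    "lysine_positions",
    "basic_residues",
    "receptor_binding_site",
    "tryptic_peptide",
]

_BASIC = set("RKH")


@lru_cache(maxsize=1)
def apoe4_sequence() -> str:
    """Return the mature apoE4 sequence as a 299-character string."""
    text = resources.files("xldisc.data").joinpath("apoe4_mature.fasta").read_text()
    return "".join(line.strip() for line in text.splitlines() if not line.startswith(">"))


@lru_cache(maxsize=1)
def lysine_positions() -> tuple[int, ...]:
    """1-based positions of all lysines in the mature chain (12 for apoE4)."""
    return tuple(i + 1 for i, aa in enumerate(apoe4_sequence()) if aa == "K")


def basic_residues(start: int, end: int) -> tuple[int, ...]:
    """Arg/Lys/His positions within the inclusive interval [start, end]."""
    seq = apoe4_sequence()
    return tuple(i for i in range(start, end + 1) if seq[i - 1] in _BASIC)


def receptor_binding_site() -> tuple[int, ...]:
    """Residues taken as the LDL-receptor recognition site.

    All basic residues in the 136-150 stretch of helix 4 plus Arg172, the
    downstream arginine that aligns with them once helix 4 elongates.
    """
    return tuple(sorted(set(basic_residues(136, 150)) | {172}))


def tryptic_peptide(position: int) -> str:
    """Tryptic peptide (cut after K/R) containing the given residue.

    Used by the synthetic cross-link generator to fill peptide columns with
    sequences consistent with the packaged chain.
    """
    seq = apoe4_sequence()
    if not 1 <= position <= len(seq):
        raise IndexError(f"residue {position} outside chain of length {len(seq)}")
    cuts = [0] + [i + 1 for i, aa in enumerate(seq) if aa in "KR"]
    if cuts[-1] != len(seq):
        cuts.append(len(seq))
    for lo, hi in zip(cuts, cuts[1:]):
        if lo < position <= hi:
            return seq[lo:hi]
    raise AssertionError("unreachable")
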