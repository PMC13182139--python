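"""Clade-quartet and species-quartet enumeration and polarized pattern counting.

A clade-quartet is the outgroup clade plus one of the C(k,3) triplets of
ingroup clades; a species-quartet picks one species from each of its four
clades.  For each species-quartet three rooted topologies are compared,
distinguished by which ingroup pair is grouped:

    x1: (O,(c,(a,b)))    x2: (O,(b,(a,c)))    x3: (O,(a,(b,c)))

where a, b, c are the ingroup species ordered by their clade labels.
A usable alignment column strictly supports the topology grouping (i, j)
when i and j share a state, the third ingroup taxon matches the outgroup
(plesiomorphic state), and the shared state is derived (differs from the
outgroup).  Columns where the third taxon matches neither the pair nor the
outgroup are ambiguous about polarity and support nothing.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np

from .matrix_io import CladeAssignment, Supermatrix, MISSING

logger = logging.getLogger(__name__)

#: canonical topology identifiers; the tuple gives the grouped pair as
#: indices into the (a, b, c) ingroup rows of the subalignment.
TOPOLOGIES: dict[str, tuple[int, int]] = {"x1": (0, 1), "x2": (0, 2), "x3": (1, 2)}
TOPOLOGY_IDS: tuple[str, str, str] = ("x1", "x2", "x3")


@dataclass(frozen=True, order=True)
class CladeQuartet:
    """Outgroup clade plus three ingroup clades, canonically ordered."""

    outgroup: str
    ingroups: tuple[str, str, str]

    def __post_init__(self) -> None:
        if len(set(self.ingroups)) != 3:
            raise ValueError("ingroup clades must be distinct")
        object.__setattr__(self, "ingroups", tuple(sorted(self.ingroups)))

    @property
    def id(self) -> str:
        return "".join(sorted(self.ingroups + (self.outgroup,)))

    def grouped_clades(self, topology: str) -> tuple[str, str]:
        i, j = TOPOLOGIES[topology]
        return self.ingroups[i], self.ingroups[j]


@dataclass(frozen=True)
class SpeciesQuartet:
    """One species per clade of a clade-quartet; ingroups ordered by clade."""

    clade_quartet: CladeQuartet
    ingroup_species: tuple[str, str, str]  # aligned with clade_quartet.ingroups
    outgroup_species: str

    @property
    def id(self) -> str:
        return "|".join(self.ingroup_species + (self.outgroup_species,))

    @property
    def species(self) -> tuple[str, str, str, str]:
        return self.ingroup_species + (self.outgroup_species,)


@dataclass(frozen=True)
class PatternCounts:
    """Strict-synapomorphy counts per rooted topology for one species-quartet."""

    na: dict[str, int]
    n_usable: int
    n_informative: int

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.na.values()):
            raise ValueError("negative pattern count")
        if sum(self.na.values()) > self.n_informative or self.n_informative > self.n_usable:
            raise ValueError("inconsistent pattern counts")


def enumerate_clade_quartets(ca: CladeAssignment) -> list[CladeQuartet]:
    """All C(k,3) ingroup-clade triplets combined with the outgroup clade."""
    return [
        CladeQuartet(outgroup=ca.outgroup_clade, ingroups=trip)
        for trip in itertools.combinations(ca.ingroup_clades, 3)
    ]


def enumerate_species_quartets(
    cq: CladeQuartet, ca: CladeAssignment
) -> list[SpeciesQuartet]:
    """Cartesian product of member species across the four clades."""
    pools = [ca.members(c) for c in cq.ingroups]
    out = ca.members(cq.outgroup)
    for clade, pool in zip(cq.ingroups + (cq.outgroup,), pools + [out]):
        if not pool:
            raise ValueError(f"clade {clade!r} has no species")
    return [
        SpeciesQuartet(clade_quartet=cq, ingroup_species=(a, b, c), outgroup_species=o)
        for a, b, c in itertools.product(*pools)
        for o in out
    ]


def extract_quartet_subalignment(
    m: Supermatrix, q: SpeciesQuartet
) -> tuple[np.ndarray, np.ndarray]:
    """4-row code matrix (rows a, b, c, O) and its usable-column mask.

    A column is usable when all four characters are unambiguous nucleotides
    (no gap, no IUPAC ambiguity).
    """
    for sp in q.species:
        if sp not in m.taxa:
            raise KeyError(f"species {sp!r} absent from supermatrix")
    codes = m.encoded()
    rows = np.stack([codes[m.taxa.index(sp)] for sp in q.species])
    usable = (rows != MISSING).all(axis=0)
    return rows, usable


def _pattern_codes(rows: np.ndarray, usable: np.ndarray) -> np.ndarray:
    """Histogram of the 256 (a,b,c,O) nucleotide patterns over usable columns."""
    sub = rows[:, usable].astype(np.int64)
    flat = ((sub[0] * 4 + sub[1]) * 4 + sub[2]) * 4 + sub[3]
    return np.bincount(flat, minlength=256)


def class_masks() -> dict[str, np.ndarray]:
    """Boolean masks over the 256 pattern codes, one per topology class.

    Pattern code = ((a*4 + b)*4 + c)*4 + O.  Each class holds exactly the
    strict-synapomorphy patterns for its topology: the grouped pair shares a
    derived state, the remaining ingroup taxon carries the outgroup
    (plesiomorphic) state.
    """
    masks = {}
    codes = np.arange(256)
    a, b, c, o = codes // 64, (codes // 16) % 4, (codes // 4) % 4, codes % 4
    states = {"x1": (a, b, c), "x2": (a, c, b), "x3": (b, c, a)}
    for topo, (i, j, k) in states.items():
        masks[topo] = (i == j) & (k == o) & (i != o)
    return masks


_CLASS_MASKS = class_masks()


def count_polarized_patterns(rows: np.ndarray, usable: np.ndarray) -> PatternCounts:
    """Count strict synapomorphic columns per topology.

    The three support classes are mutually exclusive, so the informative
    column count is the sum of the three class counts.
    """
    hist = _pattern_codes(rows, usable)
    na = {t: int(hist[m].sum()) for t, m in _CLASS_MASKS.items()}
    return PatternCounts(
        na=na,
        n_usable=int(usable.sum()),
        n_informative=sum(na.values()),
    )


def check_min_informative(pc: PatternCounts, min_cols: int = 20) -> bool:
    """Quartet passes when it has at least ``min_cols`` informative columns."""
    ok = pc.n_informative >= min_cols
    if not ok:
        logger.info(
            "quartet excluded before scoring: %d informative columns < %d",
            pc.n_informative,
            min_cols,
        )
    return ok
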