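"""Supermatrix and clade-assignment I/O.

Alignments are held as byte matrices (one row per taxon) together with
optional locus boundary records, so that a concatenation of thousands of
loci behaves like a single matrix.  Characters are uppercased on read;
IUPAC ambiguity codes are preserved but downstream signal computations
treat anything outside {A, C, G, T} as missing.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import AlignIO, SeqIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
import dendropy

logger = logging.getLogger(__name__)

#: nucleotide -> small integer code used by the signal layers:
#: A=0 C=1 G=2 T=3, anything else (gap, ?, IUPAC ambiguity) = 4 (missing).
MISSING = 4
_VALID_CHARS = set(b"ACGTURYSWKMBDHVN-?.")

_CODE_LUT = np.full(256, MISSING, dtype=np.uint8)
for _i, _c in enumerate(b"ACGT"):
    _CODE_LUT[_c] = _i
_CODE_LUT[ord("U")] = 3


class AlignmentError(ValueError):
    """Malformed alignment input (duplicate taxa, ragged rows, ...)."""


@dataclass(frozen=True)
class Locus:
    """Half-open [start, end) column range of one locus in a supermatrix."""

    name: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid locus range [{self.start}, {self.end})")


@dataclass
class Supermatrix:
    """Aligned DNA matrix with taxon labels and optional locus boundaries."""

    taxa: list[str]
    data: np.ndarray  # (n_taxa, n_sites), dtype 'S1', uppercase
    loci: list[Locus] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(set(self.taxa)) != len(self.taxa):
            dup = sorted({t for t in self.taxa if self.taxa.count(t) > 1})
            raise AlignmentError(f"duplicate taxon label(s): {', '.join(dup)}")
        if self.data.ndim != 2 or self.data.shape[0] != len(self.taxa):
            raise AlignmentError("matrix shape does not match taxon list")
        prev = 0
        for loc in self.loci:
            if loc.start < prev:
                raise AlignmentError(f"locus {loc.name} overlaps/disordered")
            if loc.end > self.n_sites:
                raise AlignmentError(f"locus {loc.name} exceeds alignment length")
            prev = loc.end

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_sites(self) -> int:
        return int(self.data.shape[1])

    def row(self, taxon: str) -> np.ndarray:
        return self.data[self.taxa.index(taxon)]

    def encoded(self) -> np.ndarray:
        """uint8 code matrix: A=0 C=1 G=2 T=3, everything else 4 (missing)."""
        return _CODE_LUT[self.data.view(np.uint8)]

    def sequence(self, taxon: str) -> str:
        return self.row(taxon).tobytes().decode("ascii")


@dataclass(frozen=True)
class CladeAssignment:
    """Species -> clade map with one designated outgroup clade."""

    clade_of: dict[str, str]
    outgroup_clade: str

    def __post_init__(self) -> None:
        clades = set(self.clade_of.values())
        if self.outgroup_clade not in clades:
            raise ValueError(f"outgroup clade {self.outgroup_clade!r} has no species")
        if len(self.ingroup_clades) < 3:
            raise ValueError("need at least 3 ingroup clades to form quartets")

    @property
    def ingroup_clades(self) -> tuple[str, ...]:
        return tuple(
            sorted(set(self.clade_of.values()) - {self.outgroup_clade})
        )

    def members(self, clade: str) -> tuple[str, ...]:
        return tuple(sorted(s for s, c in self.clade_of.items() if c == clade))

    @property
    def outgroup_species(self) -> tuple[str, ...]:
        return self.members(self.outgroup_clade)

    def validate_against(self, taxa: Iterable[str]) -> None:
        missing = sorted(set(taxa) - set(self.clade_of))
        if missing:
            raise ValueError(
                "alignment taxa missing from clade assignment: " + ", ".join(missing)
            )


@dataclass(frozen=True)
class AlignmentSummary:
    n_sites: int
    pct_indels: float
    n_parsimony_informative: int
    pct_parsimony_informative: float


def _records_to_matrix(records: Sequence[tuple[str, str]]) -> Supermatrix:
    taxa: list[str] = []
    rows: list[bytes] = []
    length = None
    for name, seq in records:
        if name in taxa:
            raise AlignmentError(f"duplicate taxon label(s): {name}")
        seq = seq.upper().replace("U", "T")
        if length is None:
            length = len(seq)
        elif len(seq) != length:
            raise AlignmentError(
                f"taxon {name!r} has length {len(seq)}, expected {length}"
            )
        taxa.append(name)
        rows.append(seq.encode("ascii"))
    data = np.frombuffer(b"".join(rows), dtype="S1").reshape(len(taxa), length or 0)
    bad = set(data.tobytes()) - {c for c in _VALID_CHARS}
    if bad:
        logger.warning(
            "unknown characters %s mapped to fully-ambiguous state N",
            sorted(chr(c) for c in bad),
        )
        data = data.copy()
        u8 = data.view(np.uint8)
        mask = np.isin(u8, np.frombuffer(bytes(_VALID_CHARS), dtype=np.uint8), invert=True)
        u8[mask] = ord("N")
    return Supermatrix(taxa=taxa, data=data)


def read_alignment(path: str | Path, fmt: str = "fasta") -> Supermatrix:
    """Read a FASTA or relaxed-PHYLIP alignment into a :class:`Supermatrix`.

    Duplicate taxon labels and ragged rows raise :class:`AlignmentError`;
    characters outside the DNA/IUPAC alphabet are replaced by ``N`` with a
    logged warning.
    """
    path = Path(path)
    if fmt == "fasta":
        records = [(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]
    elif fmt == "phylip":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            aln = AlignIO.read(str(path), "phylip-relaxed")
        records = [(r.id, str(r.seq)) for r in aln]
    else:
        raise ValueError(f"unknown alignment format {fmt!r}")
    if not records:
        raise AlignmentError(f"no sequences found in {path}")
    return _records_to_matrix(records)


def write_alignment(m: Supermatrix, path: str | Path, fmt: str = "fasta") -> None:
    path = Path(path)
    recs = [
        SeqRecord(Seq(m.sequence(t)), id=t, description="") for t in m.taxa
    ]
    if fmt == "fasta":
        SeqIO.write(recs, str(path), "fasta")
    elif fmt == "phylip":
        AlignIO.write(MultipleSeqAlignment(recs), str(path), "phylip-relaxed")
    else:
        raise ValueError(f"unknown alignment format {fmt!r}")


def concatenate_loci(
    paths: Sequence[str | Path], fmt: str = "fasta"
) -> Supermatrix:
    """Concatenate per-locus alignments into a supermatrix.

    Taxon sets may differ between loci; a taxon absent from a locus is
    padded with gaps across that locus' columns.  Locus boundaries are
    recorded in input order as half-open column ranges.
    """
    if not paths:
        raise ValueError("no locus alignments given")
    parts = [read_alignment(p, fmt) for p in paths]
    taxa: list[str] = []
    for part in parts:
        for t in part.taxa:
            if t not in taxa:
                taxa.append(t)
    total = sum(p.n_sites for p in parts)
    data = np.full((len(taxa), total), b"-", dtype="S1")
    loci: list[Locus] = []
    offset = 0
    for path, part in zip(paths, parts):
        end = offset + part.n_sites
        for i, t in enumerate(part.taxa):
            data[taxa.index(t), offset:end] = part.data[i]
        loci.append(Locus(name=Path(path).stem, start=offset, end=end))
        offset = end
    return Supermatrix(taxa=taxa, data=data, loci=loci)


def summarize_alignment(m: Supermatrix) -> AlignmentSummary:
    """Alignment composition: size, indel percentage, parsimony-informative sites.

    A column is parsimony-informative when at least two distinct unambiguous
    nucleotides each occur in >= 2 taxa.
    """
    if m.n_sites == 0 or m.n_taxa == 0:
        raise ValueError("empty supermatrix")
    codes = m.encoded()
    counts = np.stack([(codes == k).sum(axis=0) for k in range(4)])  # (4, n_sites)
    informative = (counts >= 2).sum(axis=0) >= 2
    n_inf = int(informative.sum())
    gaps = int((m.data == b"-").sum() + (m.data == b"?").sum())
    total = m.n_taxa * m.n_sites
    return AlignmentSummary(
        n_sites=m.n_sites,
        pct_indels=100.0 * gaps / total,
        n_parsimony_informative=n_inf,
        pct_parsimony_informative=100.0 * n_inf / m.n_sites,
    )


def load_clade_assignment(path: str | Path) -> CladeAssignment:
    """Load a two-column species/clade TSV with a ``#outgroup=<label>`` header."""
    path = Path(path)
    outgroup = None
    clade_of: dict[str, str] = {}
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if body.startswith("outgroup="):
                outgroup = body.split("=", 1)[1].strip()
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        if len(fields) != 2:
            raise ValueError(f"bad clade assignment line: {line!r}")
        species, clade = fields
        if species in clade_of:
            raise ValueError(f"species {species!r} assigned twice")
        clade_of[species] = clade
    if outgroup is None:
        raise ValueError("clade table lacks '#outgroup=<label>' header")
    return CladeAssignment(clade_of=clade_of, outgroup_clade=outgroup)


def palaeognath_assignment() -> CladeAssignment:
    """The packaged 15-taxon, 6-clade palaeognath + chicken assignment."""
    return load_clade_assignment(Path(__file__).parent / "data" / "palaeognath_clades.tsv")


def read_newick(source: str | Path) -> dendropy.Tree:
    """Parse a newick tree (file path or literal string); polytomies allowed."""
    text = None
    if isinstance(source, Path) or (
        isinstance(source, str) and not source.lstrip().startswith("(")
    ):
        text = Path(source).read_text()
    else:
        text = str(source)
    try:
        return dendropy.Tree.get(data=text, schema="newick")
    except Exception as exc:  # dendropy raises several error types
        raise ValueError(f"malformed newick: {exc}") from exc


def write_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True).strip()
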