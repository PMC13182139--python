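"""Synthetic supermatrix generator.

Generates datasets with the statistical structure the quartet pipeline
assumes: a known rooted clade tree with internode lengths in coalescent
units, per-locus gene trees drawn under the multispecies coalescent (so
short internodes produce incomplete-lineage-sorting discordance), clade-
specific substitution-rate scalars (so outgroup-, tinamou- or rhea-like
lineages can be made long, the classic long-branch-attraction regime),
and GTR+Γ+I sequence evolution along each gene tree.

The species tree is specified as an ultrametric newick on clade labels;
each clade leaf is expanded into a fixed shallow caterpillar of its
member species (within-clade phylogeny is not a target of the analysis,
only clade-level signal).  One haploid lineage is sampled per species.
Within every species-tree branch, the k lineages present coalesce at
rate k(k-1)/2 per coalescent unit; lineages surviving to the top of the
branch are handed rootward.  While a lineage traverses a branch it
accrues expected substitutions at ``mu`` x (branch rate scalar) per
coalescent unit, so gene-tree edge lengths come out directly in
substitutions per site.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import dendropy

from .matrix_io import Supermatrix, Locus, CladeAssignment
from .models import SubstitutionModel, build_rate_matrix, gamma_category_rates, _transition_matrices

_NUC = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class ScenarioSpec:
    """Full description of one simulation scenario.

    ``clade_tree_newick`` is an ultrametric rooted newick on clade labels
    with branch lengths in coalescent units; ``species_counts`` expands
    each clade; ``rate_scalars`` multiply the substitution rate on a
    clade's stem and within-clade branches (key ``"internal"`` covers the
    deep internal branches, default 1).  ``mu`` converts coalescent time
    to expected substitutions per site.  A seed is mandatory.
    """

    name: str
    clade_tree_newick: str
    species_counts: dict[str, int]
    outgroup_clade: str
    seed: int
    n_loci: int = 100
    locus_length: int = 500
    mu: float = 0.012
    rate_scalars: dict[str, float] = field(default_factory=dict)
    model: SubstitutionModel = field(
        default_factory=lambda: SubstitutionModel(
            rates=(1.2, 4.0, 0.8, 1.1, 4.5, 1.0),
            freqs=(0.30, 0.20, 0.20, 0.30),
            alpha=0.7,
            p_inv=0.25,
        )
    )
    species_names: dict[str, tuple[str, ...]] | None = None
    within_clade_step: float = 0.05

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("an explicit seed is mandatory")
        if any(n < 1 for n in self.species_counts.values()):
            raise ValueError("every clade needs at least one species")

    def species_of(self, clade: str) -> tuple[str, ...]:
        if self.species_names and clade in self.species_names:
            names = self.species_names[clade]
            if len(names) != self.species_counts[clade]:
                raise ValueError(f"species name list for {clade} has wrong length")
            return names
        return tuple(
            f"{clade}_{i + 1}" for i in range(self.species_counts[clade])
        )

    def assignment(self) -> CladeAssignment:
        clade_of = {
            sp: clade
            for clade in self.species_counts
            for sp in self.species_of(clade)
        }
        return CladeAssignment(clade_of=clade_of, outgroup_clade=self.outgroup_clade)

    def provenance(self) -> dict:
        return {
            "scenario": self.name,
            "seed": self.seed,
            "n_loci": self.n_loci,
            "locus_length": self.locus_length,
            "mu": self.mu,
            "rate_scalars": dict(self.rate_scalars),
            "clade_tree": self.clade_tree_newick,
            "species_counts": dict(self.species_counts),
            "model": {
                "rates": list(self.model.rates),
                "freqs": list(self.model.freqs),
                "alpha": self.model.alpha,
                "p_inv": self.model.p_inv,
            },
        }


class _SNode:
    """Species-tree node: ``height`` in coalescent units above the tips."""

    __slots__ = ("children", "height", "label", "scalar")

    def __init__(self, height: float, label: str | None = None, scalar: float = 1.0):
        self.children: list[_SNode] = []
        self.height = height
        self.label = label
        self.scalar = scalar  # rate scalar of the edge to the parent


class GeneTreeNode:
    """Gene-tree node; edge length to parent in substitutions per site."""

    __slots__ = ("name", "children", "length")

    def __init__(self, name: str | None = None):
        self.name = name
        self.children: list[GeneTreeNode] = []
        self.length = 0.0

    def leaves(self) -> frozenset[str]:
        if not self.children:
            return frozenset([self.name])
        out: frozenset[str] = frozenset()
        for c in self.children:
            out |= c.leaves()
        return out

    def newick(self) -> str:
        def render(n: GeneTreeNode) -> str:
            if not n.children:
                return f"{n.name}:{n.length:.8g}"
            inner = ",".join(render(c) for c in n.children)
            return f"({inner}):{n.length:.8g}"

        inner = ",".join(render(c) for c in self.children)
        return f"({inner});"

    def clades(self) -> list[frozenset[str]]:
        out: list[frozenset[str]] = []

        def walk(n: GeneTreeNode) -> frozenset[str]:
            if not n.children:
                return frozenset([n.name])
            s: frozenset[str] = frozenset()
            for c in n.children:
                s |= walk(c)
            out.append(s)
            return s

        walk(self)
        return out


@dataclass
class SimulatedDataset:
    """Supermatrix plus the truth that generated it."""

    supermatrix: Supermatrix
    assignment: CladeAssignment
    true_clade_tree: tuple  # nested tuple on ingroup clades
    species_tree_newick: str  # substitution-unit branch lengths
    gene_trees: list[GeneTreeNode]
    provenance: dict

    def provenance_json(self) -> str:
        return json.dumps(self.provenance, indent=2, sort_keys=True)


def _build_species_tree(spec: ScenarioSpec) -> _SNode:
    clade_tree = dendropy.Tree.get(data=spec.clade_tree_newick, schema="newick")
    # node heights assuming an ultrametric clade tree
    dists = {}
    for nd in clade_tree.preorder_node_iter():
        dists[nd] = (dists.get(nd.parent_node, 0.0) + (nd.edge.length or 0.0))
    total = max(d for nd, d in dists.items() if nd.is_leaf())

    def scalar_for(label: str | None) -> float:
        if label is None:
            return spec.rate_scalars.get("internal", 1.0)
        return spec.rate_scalars.get(label, 1.0)

    def convert(nd) -> _SNode:
        if nd.is_leaf():
            clade = nd.taxon.label.replace(" ", "_")
            return _clade_caterpillar(spec, clade)
        node = _SNode(height=total - dists[nd], scalar=scalar_for(None))
        node.children = [convert(c) for c in nd.child_nodes()]
        return node

    return convert(clade_tree.seed_node)


def _clade_caterpillar(spec: ScenarioSpec, clade: str) -> _SNode:
    """Fixed shallow caterpillar over a clade's species, scalar = clade's."""
    sc = spec.rate_scalars.get(clade, 1.0)
    names = spec.species_of(clade)
    node = _SNode(height=0.0, label=names[0], scalar=sc)
    for i, name in enumerate(names[1:], start=1):
        parent = _SNode(height=spec.within_clade_step * i, scalar=sc)
        leaf = _SNode(height=0.0, label=name, scalar=sc)
        parent.children = [node, leaf]
        node = parent
    return node


def _species_tree_newick(root: _SNode, mu: float) -> str:
    def render(n: _SNode, parent_height: float) -> str:
        length = (parent_height - n.height) * mu * n.scalar
        if not n.children:
            return f"{n.label}:{length:.8g}"
        inner = ",".join(render(c, n.height) for c in n.children)
        return f"({inner}):{length:.8g}"

    inner = ",".join(render(c, root.height) for c in root.children)
    return f"({inner});"


def _coalesce_in_branch(
    lineages: list[tuple[GeneTreeNode, float]],
    duration: float,
    sub_rate: float,
    rng: np.random.Generator,
) -> list[tuple[GeneTreeNode, float]]:
    """Standard single-population coalescent over one species-tree branch.

    ``lineages`` are (gene-tree node, accumulated substitution length)
    pairs; ``duration`` may be infinite (root branch).  Rate of the next
    coalescence with k lineages is k(k-1)/2 per coalescent unit.
    """
    lineages = list(lineages)
    t = 0.0
    while len(lineages) > 1:
        k = len(lineages)
        wait = rng.exponential(1.0 / (k * (k - 1) / 2.0))
        if t + wait > duration:
            break
        t += wait
        lineages = [(n, acc + wait * sub_rate) for n, acc in lineages]
        i, j = sorted(rng.choice(k, size=2, replace=False))
        (ni, acci) = lineages[i]
        (nj, accj) = lineages[j]
        ni.length = acci
        nj.length = accj
        parent = GeneTreeNode()
        parent.children = [ni, nj]
        rest = [lineages[m] for m in range(k) if m not in (i, j)]
        lineages = rest + [(parent, 0.0)]
    if np.isfinite(duration):
        rem = duration - t
        lineages = [(n, acc + rem * sub_rate) for n, acc in lineages]
    return lineages


def simulate_gene_tree(spec: ScenarioSpec, rng: np.random.Generator) -> GeneTreeNode:
    """One multispecies-coalescent gene tree with substitution-unit edges."""
    root = _build_species_tree(spec)

    def rec(snode: _SNode, parent_height: float) -> list[tuple[GeneTreeNode, float]]:
        if not snode.children:
            incoming = [(GeneTreeNode(name=snode.label), 0.0)]
        else:
            incoming = []
            for c in snode.children:
                incoming.extend(rec(c, snode.height))
        duration = parent_height - snode.height
        return _coalesce_in_branch(
            incoming, duration, spec.mu * snode.scalar, rng
        )

    surviving = rec(root, np.inf)
    assert len(surviving) == 1
    top, acc = surviving[0]
    top.length = 0.0
    return top


def simulate_gene_trees(spec: ScenarioSpec) -> list[GeneTreeNode]:
    """``n_loci`` independent MSC gene trees, deterministic given the seed."""
    rng = np.random.default_rng(spec.seed)
    return [simulate_gene_tree(spec, rng) for _ in range(spec.n_loci)]


def _evolve_sites(
    tree: GeneTreeNode,
    n_sites: int,
    model: SubstitutionModel,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Evolve ``n_sites`` characters down one gene tree; returns code rows."""
    pi = np.asarray(model.freqs)
    Q = build_rate_matrix(model)
    cat_rates = gamma_category_rates(model.alpha, model.n_gamma_categories)
    # per-site rate: 0 for the invariable class, else a gamma category rate
    invariant = rng.random(n_sites) < model.p_inv
    cats = rng.integers(0, model.n_gamma_categories, size=n_sites)
    site_rates = np.where(invariant, 0.0, cat_rates[cats])
    rate_values = np.unique(site_rates)
    root_states = rng.choice(4, size=n_sites, p=pi)
    out: dict[str, np.ndarray] = {}

    def walk(node: GeneTreeNode, states: np.ndarray) -> None:
        if not node.children:
            out[node.name] = states
            return
        for child in node.children:
            child_states = states.copy()
            for r in rate_values:
                if r == 0.0 or child.length == 0.0:
                    continue
                idx = np.nonzero(site_rates == r)[0]
                if idx.size == 0:
                    continue
                P = _transition_matrices(pi, Q, np.array([child.length * r]))[0]
                cum = np.cumsum(P, axis=1)
                cum[:, -1] = 1.0
                u = rng.random(idx.size)
                child_states[idx] = (
                    u[:, None] > cum[states[idx]]
                ).sum(axis=1)
            walk(child, child_states)

    walk(tree, root_states)
    return out


def simulate_alignment(
    gene_trees: Sequence[GeneTreeNode], spec: ScenarioSpec
) -> SimulatedDataset:
    """Evolve each locus along its gene tree and concatenate into a supermatrix."""
    assignment = spec.assignment()
    taxa = sorted(assignment.clade_of)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    blocks: dict[str, list[np.ndarray]] = {t: [] for t in taxa}
    loci = []
    offset = 0
    for li, gt in enumerate(gene_trees):
        rows = _evolve_sites(gt, spec.locus_length, spec.model, rng)
        for t in taxa:
            blocks[t].append(rows[t])
        loci.append(Locus(name=f"locus_{li + 1}", start=offset, end=offset + spec.locus_length))
        offset += spec.locus_length
    data = np.stack([_NUC[np.concatenate(blocks[t])] for t in taxa])
    sm = Supermatrix(taxa=taxa, data=data, loci=loci)
    root = _build_species_tree(spec)
    return SimulatedDataset(
        supermatrix=sm,
        assignment=assignment,
        true_clade_tree=_true_ingroup_tree(spec),
        species_tree_newick=_species_tree_newick(root, spec.mu),
        gene_trees=list(gene_trees),
        provenance=spec.provenance(),
    )


def simulate_dataset(spec: ScenarioSpec) -> SimulatedDataset:
    """Gene trees plus sequence evolution in one call."""
    return simulate_alignment(simulate_gene_trees(spec), spec)


def _true_ingroup_tree(spec: ScenarioSpec) -> tuple:
    from . import supertree as st

    full = st.from_newick(spec.clade_tree_newick)
    ingroups = set(spec.species_counts) - {spec.outgroup_clade}
    return st.canonical(st.prune_to(full, ingroups))


# ---------------------------------------------------------------------------
# presets emulating the palaeognath analysis conditions

_PALAEO_COUNTS = {"E": 2, "K": 4, "R": 2, "S": 1, "T": 5, "O": 1}

_PALAEO_NAMES = {
    "E": ("Casuarius_casuarius", "Dromaius_novaehollandiae"),
    "K": ("Apteryx_hastii", "Apteryx_mantelli", "Apteryx_owenii", "Apteryx_rowi"),
    "R": ("Rhea_americana", "Rhea_pennata"),
    "S": ("Struthio_camelus",),
    "T": (
        "Anomalopteryx_didiformis",
        "Crypturellus_cinnamomeus",
        "Eudromia_elegans",
        "Nothoprocta_perdicaria",
        "Tinamus_guttatus",
    ),
    "O": ("Gallus_gallus",),
}


def _ultrametric_newick(heights: dict[str, float]) -> str:
    """Tinamou-first topology (O,(S,(T,(E,(K,R))))) from join heights."""
    h_kr, h_e, h_t, h_s, h_root = (
        heights["KR"],
        heights["E"],
        heights["T"],
        heights["S"],
        heights["root"],
    )
    return (
        f"(O:{h_root},"
        f"(S:{h_s},"
        f"(T:{h_t},"
        f"(E:{h_e},"
        f"(K:{h_kr},R:{h_kr}):{h_e - h_kr}"
        f"):{h_t - h_e}"
        f"):{h_s - h_t}"
        f"):{h_root - h_s});"
    )


def preset_scenarios(seed: int, n_loci: int = 100, locus_length: int = 500) -> dict[str, ScenarioSpec]:
    """Named scenarios bracketing the regimes the pipeline must handle.

    * ``strong_signal`` — internodes >= 2 coalescent units: little ILS,
      the generating clade tree should be recoverable.
    * ``lba`` — internodes <= 0.1 with >= 5x rate scalars on the
      outgroup, tinamou-like and rhea-like branches: heavy ILS plus
      long-branch attraction pressure.
    * ``polytomy`` — internodes <= 0.01: effectively a hard polytomy
      among the four non-ostrich clades.
    """
    common = dict(
        species_counts=_PALAEO_COUNTS,
        outgroup_clade="O",
        species_names=_PALAEO_NAMES,
        n_loci=n_loci,
        locus_length=locus_length,
    )
    return {
        "strong_signal": ScenarioSpec(
            name="strong_signal",
            clade_tree_newick=_ultrametric_newick(
                {"KR": 2.5, "E": 4.5, "T": 6.5, "S": 8.5, "root": 12.0}
            ),
            seed=seed,
            mu=0.012,
            **common,
        ),
        "lba": ScenarioSpec(
            name="lba",
            clade_tree_newick=_ultrametric_newick(
                {"KR": 1.0, "E": 1.1, "T": 1.2, "S": 1.3, "root": 4.0}
            ),
            seed=seed,
            mu=0.02,
            rate_scalars={"O": 6.0, "T": 6.0, "R": 5.0},
            **common,
        ),
        "polytomy": ScenarioSpec(
            name="polytomy",
            clade_tree_newick=_ultrametric_newick(
                {"KR": 2.0, "E": 2.01, "T": 2.02, "S": 2.03, "root": 6.0}
            ),
            seed=seed,
            mu=0.012,
            **common,
        ),
    }
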