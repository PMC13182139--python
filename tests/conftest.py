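import numpy as np
import pytest

from quartetpol import palaeognath_assignment
from quartetpol.matrix_io import Supermatrix
from quartetpol.models import SubstitutionModel
from quartetpol.simulate import ScenarioSpec, simulate_dataset


@pytest.fixture(scope="session")
def palaeo():
    return palaeognath_assignment()


def matrix_from(seqs: dict[str, str]) -> Supermatrix:
    taxa = list(seqs)
    data = np.array(
        [list(s.upper().encode("ascii")) for s in seqs.values()], dtype=np.uint8
    ).view("S1")
    return Supermatrix(taxa=taxa, data=data)


def tiny_scenario(seed: int, n_loci: int = 12, locus_length: int = 300) -> ScenarioSpec:
    """Three singleton ingroup clades + outgroup: a single species-quartet."""
    return ScenarioSpec(
        name="tiny",
        clade_tree_newick="(O:8,(A:3,(B:2,C:2):1):5);",
        species_counts={"A": 1, "B": 1, "C": 1, "O": 1},
        outgroup_clade="O",
        seed=seed,
        n_loci=n_loci,
        locus_length=locus_length,
        mu=0.02,
    )


@pytest.fixture(scope="session")
def tiny_dataset():
    return simulate_dataset(tiny_scenario(seed=11))


@pytest.fixture(scope="session")
def palaeo_dataset():
    """Small strong-signal palaeognath-structured dataset for structural tests."""
    from quartetpol.simulate import preset_scenarios

    spec = preset_scenarios(seed=5, n_loci=8, locus_length=250)["strong_signal"]
    return simulate_dataset(spec)


def random_model(rng: np.random.Generator) -> SubstitutionModel:
    freqs = rng.dirichlet([10, 10, 10, 10])
    rates = tuple(np.exp(rng.normal(0, 0.5, size=5))) + (1.0,)
    return SubstitutionModel(
        rates=rates,
        freqs=tuple(freqs),
        alpha=float(rng.uniform(0.3, 2.0)),
        p_inv=float(rng.uniform(0.0, 0.5)),
    )
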