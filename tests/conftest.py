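import numpy as np
import pytest

from twistpore import electrolyte as el


@pytest.fixture(scope="session")
def a0a1():
    from twistpore import pore_builder as pb

    return pb.build_bilayer(0, 1)


@pytest.fixture(scope="session")
def full_model_curves():
    """Full primitive-model mixing curves shared by the slow acceptance tests."""
    grid = np.arange(0.0, 0.45, 0.005)
    kpm = el.mixing_curve("KPM", grid)
    free = el.mixing_curve("free_mix", grid)
    return kpm, free


def random_neutral_state(rng, equal_diameter=None):
    """Random electroneutral 1:1 KCl/NaCl-like state for property tests."""
    ck = rng.uniform(0.01, 1.0)
    cna = rng.uniform(0.01, 1.0)
    species = dict(el.DEFAULT_SPECIES)
    if equal_diameter is not None:
        species = {
            name: el.IonSpecies(name, sp.valence, equal_diameter)
            for name, sp in species.items()
        }
    return el.SolutionState(
        {"K": ck, "Na": cna, "Cl": ck + cna}, species=species
    )
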