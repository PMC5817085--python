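import numpy as np
import pytest

from pharmkin.features import FeatureSet, PharmacophoreFeature
from pharmkin.hypothesis import ThresholdScheme
from pharmkin.kinetics import KineticModel
from pharmkin.synthetic import PlantSpec, plant_pharmacophore


@pytest.fixture(scope="session")
def planted():
    """One deterministic planted-pharmacophore data set (ADPRR, 10 actives,
    20 decoys, 0.1 A positional noise in a 20 A box)."""
    return plant_pharmacophore(PlantSpec(seed=42))


@pytest.fixture(scope="session")
def scheme_all_actives():
    """High-affinity thresholds requiring every synthetic active to match."""
    return ThresholdScheme(0.036, 0.001, min_match=10)


@pytest.fixture
def simple_triangle_set():
    """Three typed sites forming a fixed scalene triangle."""
    return FeatureSet(molecule_id="tri", conformer_id=0, features=[
        PharmacophoreFeature("A", (0.0, 0.0, 0.0), (0.0, 0.0, 1.0)),
        PharmacophoreFeature("D", (3.0, 0.0, 0.0), (1.0, 0.0, 0.0)),
        PharmacophoreFeature("H", (0.0, 4.0, 0.0)),
    ])


@pytest.fixture
def binding_only_model():
    """Closed ligand + receptor <-> complex system (mass action)."""
    return KineticModel.from_dict({
        "species": [
            {"name": "L", "init_um": 0.5},
            {"name": "R", "init_um": 1.0},
            {"name": "LR", "init_um": 0.0},
        ],
        "reactions": [
            {"id": "bind", "reactants": [{"species": "L"}, {"species": "R"}],
             "products": [{"species": "LR"}], "law": {"type": "mass_action", "params": {"k": 2.0}}},
            {"id": "unbind", "reactants": [{"species": "LR"}],
             "products": [{"species": "L"}, {"species": "R"}],
             "law": {"type": "mass_action", "params": {"k": 0.5}}},
        ],
    })


@pytest.fixture
def single_mm_model():
    """Enzyme-free single-substrate Michaelis-Menten conversion S -> P."""
    return KineticModel.from_dict({
        "species": [{"name": "S", "init_um": 5.0}, {"name": "P", "init_um": 0.0}],
        "reactions": [{"id": "cat", "reactants": [{"species": "S"}],
                       "products": [{"species": "P"}],
                       "law": {"type": "michaelis_menten", "params": {"Vm": 1.0, "Km": 2.0}}}],
        "readouts": ["P"],
    })


def random_feature_set(rng, molecule_id, n_sites, box=10.0, types="ADHNPR"):
    from pharmkin.features import VECTOR_TYPES

    feats = []
    for _ in range(n_sites):
        t = types[rng.integers(len(types))]
        p = tuple(rng.uniform(0, box, size=3))
        d = None
        if t in VECTOR_TYPES:
            v = rng.normal(size=3)
            d = tuple(v / np.linalg.norm(v))
        feats.append(PharmacophoreFeature(t, p, d))
    return FeatureSet(molecule_id=molecule_id, conformer_id=0, features=feats)
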