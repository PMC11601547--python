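import numpy as np
import pytest

from steerkit.synthetic import ChainSpec, ToySpec, make_toy_complex

#: fixture specs giving exactly one injectable constraint of each kind
VIOLATION_FIXTURES = {
    "chiral_flip": ([ChainSpec("protein", 8),
                     ChainSpec("nonpolymer", template="chiral")], {}),
    "stereo_flip": ([ChainSpec("protein", 8),
                     ChainSpec("nonpolymer", template="stereo_e")], {}),
    "nonplanar": ([ChainSpec("protein", 8),
                   ChainSpec("nonpolymer", template="planar")], {}),
    "bond_stretch": ([ChainSpec("protein", 8),
                      ChainSpec("nonpolymer", template="diatomic")], {}),
    "internal_clash": ([ChainSpec("protein", 8),
                        ChainSpec("nonpolymer", template="butane")], {}),
    "interchain_clash": ([ChainSpec("protein", 8), ChainSpec("protein", 10)], {}),
    "chain_overlap": ([ChainSpec("nonpolymer", template="ring", copies=2)], {}),
    "covalent_break": ([ChainSpec("protein", 8),
                        ChainSpec("nonpolymer", template="butane")],
                       {"links": [(0, 1)]}),
}

VIOLATION_COMPONENT = {
    "chiral_flip": "chiral",
    "stereo_flip": "stereo",
    "nonplanar": "planar",
    "bond_stretch": "geom",
    "internal_clash": "geom",
    "interchain_clash": "clash",
    "chain_overlap": "overlap",
    "covalent_break": "covalent",
}


def toy(kind: str):
    chains, extra = VIOLATION_FIXTURES[kind]
    return make_toy_complex(ToySpec(chains=chains, **extra))


@pytest.fixture
def homodimer():
    return make_toy_complex(ToySpec(chains=[ChainSpec("protein", 10, copies=2)],
                                    separation=12.0))


@pytest.fixture
def protein_ligand():
    """8-residue helix + chiral ligand, close enough for pocket labeling."""
    return make_toy_complex(ToySpec(chains=[
        ChainSpec("protein", 8), ChainSpec("nonpolymer", template="chiral"),
    ], separation=7.0))


@pytest.fixture
def ring_complex():
    """Helix + benzene-like ring ligand (12 graph automorphisms)."""
    return make_toy_complex(ToySpec(chains=[
        ChainSpec("protein", 8), ChainSpec("nonpolymer", template="ring"),
    ], separation=10.0))


def random_rigid(rng):
    from scipy.spatial.transform import Rotation
    return Rotation.random(rng=rng).as_matrix(), rng.standard_normal(3) * 5.0
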