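"""Shared fixtures: all test inputs are generated programmatically."""

import numpy as np
import pytest

from transit.structio import Atom, SegmentAnnotation, Structure
from transit.synthetic import BundleSpec, HingeSpec, make_bundle, make_state_pair


@pytest.fixture(scope="session")
def small_bundle():
    """Compact 6-helix bundle for fast structural tests."""
    return make_bundle(BundleSpec(n_helices=6, residues_per_helix=12,
                                  ring_radius=8.0))


@pytest.fixture(scope="session")
def standard_bundle():
    """The package's standard 10-helix study fixture."""
    return make_bundle(BundleSpec())


@pytest.fixture(scope="session")
def state_pair(standard_bundle):
    """OF/IF pair under the standard hinge (TM2+TM5 bent 25° below z=0)."""
    return make_state_pair(standard_bundle, HingeSpec())


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_toy_structure(coords, names=None, resids=None, chain="A",
                       resnames=None, elements=None):
    """Hand-rolled structure builder for targeted micro-fixtures."""
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    names = names or ["CA"] * n
    resids = resids if resids is not None else list(range(1, n + 1))
    resnames = resnames or ["ALA"] * n
    elements = elements or [nm[0] for nm in names]
    atoms = [Atom(i + 1, names[i], elements[i], resids[i], resnames[i],
                  chain, coords[i]) for i in range(n)]
    return Structure(atoms, SegmentAnnotation())


@pytest.fixture()
def toy_structure_factory():
    return make_toy_structure
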