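"""Shared fixtures: reference materials, beam/target and curve libraries."""

import numpy as np
import pytest

import radioyield as ry


@pytest.fixture(scope="session")
def yb2o3():
    """Enriched [176Yb]Yb2O3 production target material."""
    return ry.yb2o3()


@pytest.fixture(scope="session")
def yb_metal():
    return ry.yb_metal()


@pytest.fixture(scope="session")
def deuteron():
    return ry.DEUTERON


@pytest.fixture(scope="session")
def beam():
    """10 mA, 18 MeV deuteron beam, 98.5% transmission, 1 cm radius."""
    return ry.BeamSpec()


@pytest.fixture(scope="session")
def target(yb2o3):
    """Slab traversed from 18 down to 8 MeV, 99% enriched."""
    return ry.TargetSpec(material=yb2o3, exit_energy_mev=8.0)


@pytest.fixture(scope="session")
def nagai():
    return ry.fixture_curves("nagai")


@pytest.fixture(scope="session")
def tendl():
    return ry.fixture_curves("tendl_dagger")


@pytest.fixture(scope="session")
def dp_curve(nagai):
    return nagai["176Yb(d,p)Yb177"]


@pytest.fixture()
def flat_curve():
    """Constant 100 mb excitation function over 0-30 MeV."""
    rid = ry.ReactionID("Yb176", "p", "Yb177")
    grid = np.linspace(0.0, 30.0, 61)
    return ry.ExcitationFunction(rid, grid, np.full_like(grid, 100.0), provenance="test")
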