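"""Shared fixtures: small, fast toy components."""

import numpy as np
import pytest

from saftscreen.parameters import FusionProperties
from saftscreen.saft_core import (ComponentModel, MixtureSpec,
                                  SegmentParameters, binary_mixture)


@pytest.fixture(scope="session")
def sphere():
    """Single nonassociating spherical segment (m = 1)."""
    seg = SegmentParameters(segment_count_ratio=0.01, sigma=3.5,
                            u_over_kB=250.0)
    return ComponentModel("sphere", 100.0, ((seg, 1.0),))


@pytest.fixture(scope="session")
def toy_api():
    seg = SegmentParameters(0.025, 3.4, 320.0, 1200.0, 0.02, 2, 2)
    return ComponentModel("TAPI", 300.0, ((seg, 1.0),), role="API")


@pytest.fixture(scope="session")
def toy_fusion():
    return FusionProperties(T_m=420.0, dH_fus=30.0, dCp_a=100.0)


@pytest.fixture(scope="session")
def toy_polymer_plain():
    """Nonassociating, weakly attractive polymer (demixes with toy_api)."""
    seg = SegmentParameters(0.03, 3.8, 210.0)
    return ComponentModel("TPOLY", 8000.0, ((seg, 1.0),), role="polymer")


@pytest.fixture(scope="session")
def toy_polymer_acceptor():
    """Polymer with acceptor sites, no self-association (induced HB)."""
    seg = SegmentParameters(0.028, 3.5, 315.0, 0.0, 0.02, 0, 8)
    return ComponentModel("TPACC", 4000.0, ((seg, 1.0),), role="polymer")


@pytest.fixture(scope="session")
def toy_solvent():
    seg = SegmentParameters(0.045, 3.2, 240.0, 2000.0, 0.03, 1, 1)
    return ComponentModel("TSOLV", 60.0, ((seg, 1.0),), role="solvent")


@pytest.fixture(scope="session")
def toy_copolymer():
    seg_a = SegmentParameters(0.030, 3.7, 260.0)
    seg_b = SegmentParameters(0.026, 3.4, 310.0, 0.0, 0.02, 0, 4)
    return ComponentModel("TCOPO", 5000.0, ((seg_a, 0.55), (seg_b, 0.45)),
                          role="polymer")


@pytest.fixture(scope="session")
def api_polymer_mix(toy_api, toy_polymer_acceptor):
    return binary_mixture(toy_api, toy_polymer_acceptor, 0.6)


def random_toy_mixture(rng):
    """A random associating binary with parameters in the drug-like range."""
    seg_a = SegmentParameters(
        segment_count_ratio=rng.uniform(0.01, 0.05),
        sigma=rng.uniform(2.9, 4.5), u_over_kB=rng.uniform(220.0, 480.0),
        epsHB_over_kB=rng.uniform(500.0, 2000.0), kappaHB=0.02,
        n_donor=2, n_acceptor=2)
    seg_b = SegmentParameters(
        segment_count_ratio=rng.uniform(0.01, 0.05),
        sigma=rng.uniform(2.9, 4.5), u_over_kB=rng.uniform(220.0, 480.0))
    a = ComponentModel("RA", float(rng.uniform(150.0, 450.0)),
                       ((seg_a, 1.0),))
    b = ComponentModel("RB", float(rng.uniform(500.0, 5000.0)),
                       ((seg_b, 1.0),), role="polymer")
    x = float(rng.uniform(0.1, 0.9))
    return binary_mixture(a, b, x)
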