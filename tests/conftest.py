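"""Shared fixtures: small networks, forward-simulated data, and a
session-scoped null-reference pool reused by the calibration tests."""

from __future__ import annotations

import numpy as np
import pytest

import sapm
from sapm import (
    Connection,
    FitConfig,
    LatentInput,
    NetworkModel,
    default_pain_network,
)
from sapm.stats import build_null_reference


@pytest.fixture(scope="session")
def pain_network():
    return default_pain_network()


@pytest.fixture()
def chain_network():
    """3-region chain A -> B -> C driven by one variable latent into A."""
    return NetworkModel(
        regions=["A", "B", "C"],
        connections=[Connection("A", "B"), Connection("B", "C")],
        latents=[LatentInput(name="lat0", kind="variable", target_region="A")],
    )


@pytest.fixture()
def ring_network():
    """4-region ring with two variable latents; every connection's DB is
    observable and the L1 tie-break pins the output-scale gauge, so
    parameter recovery from noiseless data is well posed."""
    return NetworkModel(
        regions=["A", "B", "C", "D"],
        connections=[
            Connection("A", "B"),
            Connection("B", "C"),
            Connection("C", "D"),
            Connection("D", "A"),
        ],
        latents=[
            LatentInput(name="lat0", kind="variable", target_region="A"),
            LatentInput(name="lat1", kind="variable", target_region="C"),
        ],
    )


@pytest.fixture()
def identified_network():
    """4-region toy whose DB values are uniquely identified once the D
    values are pinned: the two variable latents enter regions with no
    other inputs (so their time courses are read off directly) and the
    C<->D cycle exposes every remaining connection in the observed inputs."""
    return NetworkModel(
        regions=["A", "B", "C", "D"],
        connections=[
            Connection("A", "C"),
            Connection("B", "D"),
            Connection("C", "D"),
            Connection("D", "C"),
        ],
        latents=[
            LatentInput(name="lat0", kind="variable", target_region="A"),
            LatentInput(name="lat1", kind="variable", target_region="B"),
        ],
    )


def random_small_network(rng: np.random.Generator, max_regions: int = 6) -> NetworkModel:
    """Random valid model for fuzz tests: random edge set, 1-2 variable
    latents, no self-loops or duplicates."""
    n = int(rng.integers(2, max_regions + 1))
    regions = [f"R{i}" for i in range(n)]
    pairs = [(a, b) for a in regions for b in regions if a != b]
    k = int(rng.integers(1, len(pairs) + 1))
    chosen = [pairs[i] for i in rng.choice(len(pairs), size=k, replace=False)]
    n_lat = int(rng.integers(1, 3))
    latents = [
        LatentInput(
            name=f"lat{j}",
            kind="variable",
            target_region=regions[int(rng.integers(n))],
        )
        for j in range(n_lat)
    ]
    return NetworkModel(
        regions=regions,
        connections=[Connection(a, b) for a, b in chosen],
        latents=latents,
    )


def random_parameters(model: NetworkModel, rng: np.random.Generator, db_scale: float = 0.3):
    d = {c.pair: float(rng.uniform(0.5, 1.5)) for c in model.connections}
    db = {c.pair: float(rng.uniform(-db_scale, db_scale)) for c in model.connections}
    return d, db


# ---------------------------------------------------------------------------
# Session-scoped null reference pool (the expensive shared artifact)
# ---------------------------------------------------------------------------

NULL_POOL_SIMS = 56


@pytest.fixture(scope="session")
def null_reference(pain_network):
    """Null reference from Gaussian fits of the default network at the
    study's data shape (10 regions, 5 runs x 40 volumes)."""
    return build_null_reference(
        pain_network, n_sims=NULL_POOL_SIMS, seed=20230, fit_config=FitConfig()
    )
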