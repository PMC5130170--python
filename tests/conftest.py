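"""Shared fixtures: toy networks and (session-cached) EGF-model curves."""

import numpy as np
import pytest

from erknoise.deterministic import pre_equilibrate
from erknoise.doseresponse import build_dose_response
from erknoise.models import build_mini_cascade, load_example_network
from erknoise.network import ReactionNetwork, Reaction, Species, knockout_npc_regulation


def make_ab_network(k_ab=0.05, k_ba=0.0, a0=100, b0=0):
    """A -> B (optionally reversible) toy network."""
    reactions = [
        Reaction(1, (("A", 1),), (("B", 1),), "k_ab", k_ab, "phosphorylation"),
    ]
    if k_ba > 0:
        reactions.append(
            Reaction(2, (("B", 1),), (("A", 1),), "k_ba", k_ba, "dephosphorylation")
        )
    return ReactionNetwork(
        species=[
            Species("A", "cytoplasm", a0),
            Species("B", "cytoplasm", b0),
        ],
        reactions=reactions,
        name="ab_toy",
    )


def make_birth_death(lam=50.0, mu=0.1, a0=None):
    """Birth-death process: 0 -> A at rate lam, A -> 0 at rate mu*n."""
    a0 = int(round(lam / mu)) if a0 is None else a0
    return ReactionNetwork(
        species=[Species("A", "cytoplasm", a0)],
        reactions=[
            Reaction(1, (), (("A", 1),), "lam", lam, "association"),
            Reaction(2, (("A", 1),), (), "mu", mu, "degradation"),
        ],
        name="birth_death",
    )


@pytest.fixture(scope="session")
def egf_network():
    return load_example_network()


@pytest.fixture(scope="session")
def egf_steady_state(egf_network):
    return pre_equilibrate(egf_network)


@pytest.fixture(scope="session")
def mini_network():
    return build_mini_cascade()


#: dose grid shared by the dose-response fixtures: 0 plus log-spaced points
DOSE_GRID = np.concatenate([[0.0], np.geomspace(1e-4, 50.0, 19)])


@pytest.fixture(scope="session")
def wt_curves(egf_network):
    return {
        obs: build_dose_response(egf_network, DOSE_GRID, observable=obs)
        for obs in ("pERK", "nERK")
    }


@pytest.fixture(scope="session")
def ko_curves(egf_network):
    ko = knockout_npc_regulation(egf_network)
    return {
        obs: build_dose_response(ko, DOSE_GRID, observable=obs, variant="npc_knockout")
        for obs in ("pERK", "nERK")
    }
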