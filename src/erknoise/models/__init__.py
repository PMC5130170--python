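"""Packaged model definitions.

``load_example_network("egf_erk_npc")`` loads the shipped EGF-ERK-NPC
fixture JSON; :func:`build_mini_cascade` constructs a small calibrated
cascade used for engine cross-validation at tractable SSA cost.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from ..network import ReactionNetwork, Reaction, Species, load_network
from .egf_builder import build_network, EGF_MOLECULES_PER_NG_ML, PARAMS

__all__ = [
    "load_example_network",
    "example_model_path",
    "build_network",
    "build_mini_cascade",
    "EGF_MOLECULES_PER_NG_ML",
]

_FIXTURES = {"egf_erk_npc": "egf_erk_npc.json"}


def example_model_path(name: str = "egf_erk_npc") -> Path:
    try:
        fname = _FIXTURES[name]
    except KeyError:
        raise KeyError(f"unknown packaged model {name!r}; have {sorted(_FIXTURES)}") from None
    return Path(resources.files(__package__) / fname)


def load_example_network(name: str = "egf_erk_npc") -> ReactionNetwork:
    return load_network(example_model_path(name))


def build_mini_cascade(scale: float = 1.0) -> ReactionNetwork:
    """A small ligand -> kinase -> substrate -> nuclear-shuttling cascade.

    Counts are >= 1000 at ``scale=1`` so the SSA ensemble mean tracks the ODE
    solution to within a couple of percent; ``scale`` multiplies every pool
    (used to probe the 1/sqrt(N) shrinkage of intrinsic noise).
    """

    def n(x):
        return int(round(x * scale))

    species = [
        Species("EGF", "membrane", 0, clamped=True),
        Species("R", "membrane", n(3000)),
        Species("LR", "membrane", 0),
        Species("Ec", "cytoplasm", n(9000)),
        Species("pEc", "cytoplasm", 0),
        Species("En", "nucleus", n(3000)),
        Species("pEn", "nucleus", 0),
    ]
    r = [
        Reaction(1, (("EGF", 1), ("R", 1)), (("LR", 1),), "kon", 1.0e-4, "association"),
        Reaction(2, (("LR", 1),), (("EGF", 1), ("R", 1)), "koff", 0.01, "dissociation"),
        Reaction(3, (("LR", 1), ("Ec", 1)), (("LR", 1), ("pEc", 1)), "kcat", 2.0e-5 / scale, "phosphorylation"),
        Reaction(4, (("pEc", 1),), (("Ec", 1),), "kdeph_c", 0.01, "dephosphorylation"),
        Reaction(5, (("Ec", 1),), (("En", 1),), "kin", 0.002, "translocation"),
        Reaction(6, (("En", 1),), (("Ec", 1),), "kout", 0.006, "translocation"),
        Reaction(7, (("pEc", 1),), (("pEn", 1),), "kin_p", 0.01, "translocation"),
        Reaction(8, (("pEn", 1),), (("pEc", 1),), "kout_p", 0.004, "translocation"),
        Reaction(9, (("pEn", 1),), (("En", 1),), "kdeph_n", 0.01, "dephosphorylation"),
    ]
    return ReactionNetwork(
        species=species,
        reactions=r,
        volumes={"membrane": 1e-13, "cytoplasm": 1e-12, "nucleus": 2.2e-13},
        name="mini_cascade",
        description="Reduced calibrated cascade for engine cross-validation (synthetic).",
        observables={
            "pERK": {"pEc": 1.0, "pEn": 1.0},
            "nuclear_ERK": {"En": 1.0, "pEn": 1.0},
        },
        protein_groups={"R": ["R"], "E": ["Ec", "En"]},
    )
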