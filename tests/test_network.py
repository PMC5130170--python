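"""Model loading, validation, stoichiometry and the NPC-regulation knockout."""

import numpy as np
import pytest

from erknoise.models import load_example_network
from erknoise.models.egf_builder import build_network
from erknoise.network import (
    ModelSchemaError,
    ModelValidationError,
    NPC_REGULATION_INDICES,
    Reaction,
    ReactionNetwork,
    Species,
    knockout_npc_regulation,
    load_network,
    reaction_rates,
)


class TestLoading:
    def test_packaged_model_structure(self, egf_network):
        assert egf_network.n_species == 78
        assert egf_network.n_reactions == 150
        assert sorted(r.index for r in egf_network.reactions) == list(range(1, 151))

    def test_fixture_matches_programmatic_builder(self, egf_network):
        assert egf_network.to_dict() == build_network().to_dict()

    def test_round_trip(self, egf_network, tmp_path):
        p = tmp_path / "model.json"
        egf_network.save(p)
        assert load_network(p).to_dict() == egf_network.to_dict()

    def test_two_species_toy_stoichiometry(self):
        net = ReactionNetwork(
            species=[Species("A", "cytoplasm", 5), Species("B", "cytoplasm", 0)],
            reactions=[
                Reaction(1, (("A", 1),), (("B", 1),), "kf", 1.0, "phosphorylation"),
                Reaction(2, (("B", 1),), (("A", 1),), "kr", 1.0, "dephosphorylation"),
            ],
        )
        assert net.stoichiometric_matrix().tolist() == [[-1, 1], [1, -1]]

    @pytest.mark.parametrize(
        "mutate, error",
        [
            (lambda d: d["reactions"][0]["reactants"].__setitem__(0, ["NoSuch", 1]),
             ModelSchemaError),
            (lambda d: d["species"][1].__setitem__("initial_count", -5),
             ModelValidationError),
            (lambda d: d["reactions"][0].__setitem__("rate_constant", -1.0),
             ModelValidationError),
            (lambda d: d["species"][1].__setitem__("id", d["species"][2]["id"]),
             ModelValidationError),
        ],
        ids=["unknown-species", "negative-count", "negative-rate", "duplicate-id"],
    )
    def test_validation_errors(self, egf_network, mutate, error):
        d = egf_network.to_dict()
        mutate(d)
        with pytest.raises(error):
            ReactionNetwork.from_dict(d)


class TestKnockout:
    def test_zeroes_exactly_the_npc_phosphorylation_rates(self, egf_network):
        ko = knockout_npc_regulation(egf_network)
        for idx in NPC_REGULATION_INDICES:
            r = ko.reaction_by_index(idx)
            assert r.rate_constant == 0.0
            assert r.tag == "phosphorylation"
        # every other reaction is bitwise identical
        for r_ko, r_wt in zip(ko.reactions, egf_network.reactions):
            if r_ko.index not in NPC_REGULATION_INDICES:
                assert r_ko == r_wt
        # species untouched
        assert ko.species == egf_network.species

    def test_idempotent(self, egf_network):
        once = knockout_npc_regulation(egf_network)
        twice = knockout_npc_regulation(once)
        assert once.to_dict() == twice.to_dict()

    def test_missing_indices_reported(self):
        net = ReactionNetwork(
            species=[Species("A", "cytoplasm", 1), Species("B", "cytoplasm", 0)],
            reactions=[Reaction(1, (("A", 1),), (("B", 1),), "k", 1.0, "phosphorylation")],
        )
        with pytest.raises(KeyError, match="137"):
            knockout_npc_regulation(net)


class TestRates:
    def test_unimolecular_mass_action(self):
        net = ReactionNetwork(
            species=[Species("A", "cytoplasm", 10), Species("B", "cytoplasm", 0)],
            reactions=[Reaction(1, (("A", 1),), (("B", 1),), "k", 2.0, "phosphorylation")],
        )
        assert reaction_rates(net, np.array([10.0, 0.0]))[0] == pytest.approx(20.0)

    def test_zero_rate_constant_gives_zero_rate(self, egf_network):
        ko = knockout_npc_regulation(egf_network)
        state = np.full(ko.n_species, 50.0)
        rates = reaction_rates(ko, state)
        idx = [i for i, r in enumerate(ko.reactions) if r.index in NPC_REGULATION_INDICES]
        assert np.all(rates[idx] == 0.0)

    def test_negative_state_rejected(self, egf_network):
        state = egf_network.initial_state()
        state[3] = -1.0
        with pytest.raises(ValueError, match="negative"):
            reaction_rates(egf_network, state)

    def test_random_network_against_per_reaction_oracle(self):
        """Rates on a random 5-reaction toy match independent per-law evaluation."""
        rng = np.random.default_rng(7)
        species = [Species(s, "cytoplasm", 100) for s in "ABCDE"]
        reactions = [
            Reaction(1, (("A", 1),), (("B", 1),), "k1", 0.7, "phosphorylation"),
            Reaction(2, (("A", 1), ("B", 1)), (("C", 1),), "k2", 0.013, "association"),
            Reaction(3, (("C", 2),), (("D", 1),), "k3", 0.002, "association"),
            Reaction(4, (("D", 1),), (("C", 2),), "k4", 1.1, "dissociation"),
            Reaction(5, (), (("E", 1),), "k5", 3.0, "association"),
        ]
        net = ReactionNetwork(species=species, reactions=reactions)
        state = rng.integers(0, 200, size=5).astype(float)
        a, b, c, d, e = state
        expected_det = [0.7 * a, 0.013 * a * b, 0.002 * c * c / 2, 1.1 * d, 3.0]
        expected_sto = [0.7 * a, 0.013 * a * b, 0.002 * c * (c - 1) / 2, 1.1 * d, 3.0]
        assert reaction_rates(net, state, "deterministic") == pytest.approx(expected_det)
        assert reaction_rates(net, state, "stochastic") == pytest.approx(expected_sto)


class TestConservation:
    def test_npc_moiety_is_conserved(self, egf_network):
        """Total pore content (all phospho-states and their complexes) lies in
        the left null space of the stoichiometric matrix."""
        S = egf_network.stoichiometric_matrix()
        npc_members = {
            "NPC", "pNPC", "ppNPC", "ppERKn_NPC", "ppERKn_pNPC",
            "NPCPase_pNPC", "NPCPase_ppNPC",
        } | {s.id for s in egf_network.species if s.id.startswith("T_")}
        v = np.array([1 if s.id in npc_members else 0 for s in egf_network.species])
        assert np.all(S.T @ v == 0)
        basis = egf_network.conserved_moieties()
        coef, res, *_ = np.linalg.lstsq(basis.T.astype(float), v.astype(float), rcond=None)
        assert np.abs(basis.T @ coef - v).max() < 1e-9

    def test_moiety_basis_annihilates_stoichiometry(self, egf_network):
        S = egf_network.stoichiometric_matrix()
        basis = egf_network.conserved_moieties()
        assert basis.shape[0] > 0
        assert np.all(basis @ S == 0)
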