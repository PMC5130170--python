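"""Mass-action reaction networks for signalling models.

A :class:`ReactionNetwork` holds species (with integer molecule counts as the
state unit), elementary mass-action reactions of order <= 2, and per-compartment
volumes.  Bimolecular rate constants stored in a model file are already
volume-scaled (per molecule per second), so the same constant serves both the
deterministic and the stochastic engine.  The stoichiometric matrix and its
integer left null space (conserved moieties) are derived, not stored.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path

import numpy as np

__all__ = [
    "Species",
    "Reaction",
    "ReactionNetwork",
    "ModelValidationError",
    "ModelSchemaError",
    "load_network",
    "knockout_npc_regulation",
    "reaction_rates",
    "NPC_REGULATION_INDICES",
]

COMPARTMENTS = ("membrane", "cytoplasm", "nucleus")
REACTION_TAGS = (
    "association",
    "dissociation",
    "phosphorylation",
    "dephosphorylation",
    "degradation",
    "translocation",
)

#: Reaction indices implementing ERK-mediated phosphorylation of the nuclear
#: pore complex; zeroing them removes the negative autoregulation of nuclear
#: ERK (the "knockout" model variant).
NPC_REGULATION_INDICES = tuple(range(137, 145))


class ModelValidationError(ValueError):
    """A model definition violates a structural invariant."""


class ModelSchemaError(ValueError):
    """A model file does not conform to the model-definition schema."""


@dataclass(frozen=True)
class Species:
    """A chemical species: free protein, complex or modified form."""

    id: str
    compartment: str
    initial_count: int
    clamped: bool = False  # buffered: enters rates, never consumed (e.g. EGF)

    def __post_init__(self):
        if self.compartment not in COMPARTMENTS:
            raise ModelValidationError(
                f"species {self.id!r}: unknown compartment {self.compartment!r}"
            )
        if self.initial_count < 0:
            raise ModelValidationError(
                f"species {self.id!r}: negative initial count {self.initial_count}"
            )


@dataclass(frozen=True)
class Reaction:
    """An elementary mass-action reaction of order <= 2.

    ``rate_constant`` is in 1/s for unimolecular reactions and in
    1/(molecule*s) for bimolecular ones (volume scaling already applied).
    """

    index: int
    reactants: tuple[tuple[str, int], ...]
    products: tuple[tuple[str, int], ...]
    rate_name: str
    rate_constant: float
    tag: str

    def __post_init__(self):
        if self.tag not in REACTION_TAGS:
            raise ModelValidationError(
                f"reaction {self.index}: unknown tag {self.tag!r}"
            )
        if self.rate_constant < 0:
            raise ModelValidationError(
                f"reaction {self.index}: negative rate constant {self.rate_constant}"
            )
        for sid, coeff in self.reactants + self.products:
            if coeff <= 0 or int(coeff) != coeff:
                raise ModelValidationError(
                    f"reaction {self.index}: stoichiometric coefficient of "
                    f"{sid!r} must be a positive integer, got {coeff}"
                )
        if self.order > 2:
            raise ModelValidationError(
                f"reaction {self.index}: order {self.order} exceeds 2 (mass action)"
            )

    @property
    def order(self) -> int:
        return sum(c for _, c in self.reactants)


@dataclass
class ReactionNetwork:
    """Species, reactions, compartment volumes and derived stoichiometry."""

    species: list[Species]
    reactions: list[Reaction]
    volumes: dict[str, float] = field(default_factory=dict)
    name: str = ""
    description: str = ""
    #: named weighted sums of species counts (e.g. total phospho-ERK)
    observables: dict[str, dict[str, float]] = field(default_factory=dict)
    #: protein name -> species ids forming that protein's free initial pool
    protein_groups: dict[str, list[str]] = field(default_factory=dict)
    #: audit mirror of the ERK import/export rate table (see model schema)
    erk_transport: list[dict] = field(default_factory=list)

    def __post_init__(self):
        self._validate()

    # -- structure ---------------------------------------------------------

    def _validate(self) -> None:
        ids = [s.id for s in self.species]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ModelValidationError(f"duplicate species ids: {dupes}")
        known = set(ids)
        indices = [r.index for r in self.reactions]
        if len(set(indices)) != len(indices):
            raise ModelValidationError("duplicate reaction indices")
        for r in self.reactions:
            for sid, _ in r.reactants + r.products:
                if sid not in known:
                    raise ModelSchemaError(
                        f"reaction {r.index} references unknown species {sid!r}"
                    )
        for obs, weights in self.observables.items():
            for sid in weights:
                if sid not in known:
                    raise ModelSchemaError(
                        f"observable {obs!r} references unknown species {sid!r}"
                    )
        for prot, members in self.protein_groups.items():
            for sid in members:
                if sid not in known:
                    raise ModelSchemaError(
                        f"protein group {prot!r} references unknown species {sid!r}"
                    )

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    @property
    def species_ids(self) -> list[str]:
        return [s.id for s in self.species]

    def species_index(self, sid: str) -> int:
        try:
            return self.species_ids.index(sid)
        except ValueError:
            raise KeyError(f"no species {sid!r}") from None

    def reaction_by_index(self, index: int) -> Reaction:
        for r in self.reactions:
            if r.index == index:
                return r
        raise KeyError(f"no reaction with index {index}")

    def initial_state(self) -> np.ndarray:
        return np.array([s.initial_count for s in self.species], dtype=np.float64)

    def clamped_mask(self) -> np.ndarray:
        return np.array([s.clamped for s in self.species], dtype=bool)

    def stoichiometric_matrix(self) -> np.ndarray:
        """Integer (species x reactions) matrix, column = products - reactants.

        Clamped (buffered) species rows are all zero: they participate in rate
        laws but their counts never change.
        """
        pos = {s.id: i for i, s in enumerate(self.species)}
        clamped = {s.id for s in self.species if s.clamped}
        S = np.zeros((self.n_species, self.n_reactions), dtype=np.int64)
        for j, r in enumerate(self.reactions):
            for sid, c in r.reactants:
                if sid not in clamped:
                    S[pos[sid], j] -= c
            for sid, c in r.products:
                if sid not in clamped:
                    S[pos[sid], j] += c
        return S

    def conserved_moieties(self) -> np.ndarray:
        """Integer basis of the left null space of the stoichiometric matrix.

        Each row c satisfies c . state = const along every trajectory.  The
        basis is computed by exact rational Gaussian elimination of S^T and
        scaled to coprime integers.
        """
        S = self.stoichiometric_matrix()
        basis = _rational_nullspace(S.T)
        if not basis:
            return np.zeros((0, self.n_species), dtype=np.int64)
        return np.array(basis, dtype=np.int64)

    def observable_weights(self, name: str) -> np.ndarray:
        try:
            weights = self.observables[name]
        except KeyError:
            raise KeyError(
                f"observable {name!r} not defined for network {self.name!r}; "
                f"available: {sorted(self.observables)}"
            ) from None
        w = np.zeros(self.n_species)
        for sid, weight in weights.items():
            w[self.species_index(sid)] = weight
        return w

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "description": self.description,
            "compartments": {k: {"volume_l": v} for k, v in self.volumes.items()},
            "species": [
                {
                    "id": s.id,
                    "compartment": s.compartment,
                    "initial_count": s.initial_count,
                    **({"clamped": True} if s.clamped else {}),
                }
                for s in self.species
            ],
            "reactions": [
                {
                    "index": r.index,
                    "reactants": [[sid, c] for sid, c in r.reactants],
                    "products": [[sid, c] for sid, c in r.products],
                    "rate_name": r.rate_name,
                    "rate_constant": r.rate_constant,
                    "tag": r.tag,
                }
                for r in self.reactions
            ],
            "observables": self.observables,
            "protein_groups": self.protein_groups,
            "erk_transport": self.erk_transport,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ReactionNetwork":
        try:
            species = [
                Species(
                    id=s["id"],
                    compartment=s["compartment"],
                    initial_count=int(s["initial_count"]),
                    clamped=bool(s.get("clamped", False)),
                )
                for s in d["species"]
            ]
            reactions = [
                Reaction(
                    index=int(r["index"]),
                    reactants=tuple((sid, int(c)) for sid, c in r["reactants"]),
                    products=tuple((sid, int(c)) for sid, c in r["products"]),
                    rate_name=r.get("rate_name", f"k{r['index']}"),
                    rate_constant=float(r["rate_constant"]),
                    tag=r["tag"],
                )
                for r in d["reactions"]
            ]
        except (KeyError, TypeError) as exc:
            raise ModelSchemaError(f"malformed model definition: {exc}") from exc
        volumes = {
            k: float(v["volume_l"]) for k, v in d.get("compartments", {}).items()
        }
        net = cls(
            species=species,
            reactions=reactions,
            volumes=volumes,
            name=d.get("name", ""),
            description=d.get("description", ""),
            observables={
                k: dict(v) for k, v in d.get("observables", {}).items()
            },
            protein_groups={
                k: list(v) for k, v in d.get("protein_groups", {}).items()
            },
            erk_transport=list(d.get("erk_transport", [])),
        )
        _check_transport_table(net)
        return net

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    def with_rate_constants(self, updates: dict[int, float]) -> "ReactionNetwork":
        """Copy of the network with selected reaction rate constants replaced."""
        missing = [i for i in updates if i not in {r.index for r in self.reactions}]
        if missing:
            raise KeyError(f"no reactions with indices {missing}")
        reactions = [
            replace(r, rate_constant=float(updates[r.index]))
            if r.index in updates
            else r
            for r in self.reactions
        ]
        return replace(self, reactions=reactions)

    def with_initial_counts(self, counts: dict[str, int]) -> "ReactionNetwork":
        species = [
            replace(s, initial_count=int(round(counts[s.id]))) if s.id in counts else s
            for s in self.species
        ]
        return replace(self, species=species)


def _rational_nullspace(A: np.ndarray) -> list[list[int]]:
    """Exact integer basis of the null space of integer matrix A."""
    m, n = A.shape
    M = [[Fraction(int(x)) for x in row] for row in A]
    pivots: list[int] = []
    row = 0
    for col in range(n):
        pr = next((r for r in range(row, m) if M[r][col] != 0), None)
        if pr is None:
            continue
        M[row], M[pr] = M[pr], M[row]
        piv = M[row][col]
        M[row] = [x / piv for x in M[row]]
        for r in range(m):
            if r != row and M[r][col] != 0:
                f = M[r][col]
                M[r] = [a - f * b for a, b in zip(M[r], M[row])]
        pivots.append(col)
        row += 1
        if row == m:
            break
    free = [c for c in range(n) if c not in pivots]
    basis = []
    for fc in free:
        v = [Fraction(0)] * n
        v[fc] = Fraction(1)
        for r, pc in enumerate(pivots):
            v[pc] = -M[r][fc]
        denom = np.lcm.reduce([x.denominator for x in v])
        ints = [int(x * denom) for x in v]
        g = np.gcd.reduce([abs(i) for i in ints if i != 0])
        ints = [i // g for i in ints]
        if sum(ints) < 0:
            ints = [-i for i in ints]
        basis.append(ints)
    return basis


def _check_transport_table(net: ReactionNetwork) -> None:
    """Cross-check the audit ERK-transport table against the reaction list."""
    for entry in net.erk_transport:
        for key in ("erk_state", "npc_state", "direction", "reactions"):
            if key not in entry:
                raise ModelSchemaError(f"erk_transport entry missing {key!r}: {entry}")
        for idx in entry["reactions"]:
            try:
                net.reaction_by_index(int(idx))
            except KeyError:
                raise ModelSchemaError(
                    f"erk_transport entry {entry['erk_state']}/{entry['npc_state']}"
                    f"/{entry['direction']} references missing reaction {idx}"
                ) from None


def load_network(path: str | Path) -> ReactionNetwork:
    """Load and validate a model-definition JSON file."""
    path = Path(path)
    try:
        d = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ModelSchemaError(f"{path}: not valid JSON: {exc}") from exc
    return ReactionNetwork.from_dict(d)


def knockout_npc_regulation(network: ReactionNetwork) -> ReactionNetwork:
    """Zero the rate constants of the ERK->NPC phosphorylation reactions.

    Returns a copy with reactions 137-144 set to zero rate; everything else is
    untouched.  Removing this regulation leaves the pore permanently in its
    unphosphorylated, symmetric-transport state, which converts the nuclear
    ERK dose response from switch-like to graded.
    """
    present = {r.index for r in network.reactions}
    missing = [i for i in NPC_REGULATION_INDICES if i not in present]
    if missing:
        raise KeyError(
            f"network has no reactions with indices {missing}; cannot apply "
            "NPC-regulation knockout"
        )
    return network.with_rate_constants({i: 0.0 for i in NPC_REGULATION_INDICES})


def reaction_rates(
    network: ReactionNetwork,
    state: np.ndarray,
    mode: str = "deterministic",
) -> np.ndarray:
    """Per-reaction mass-action rates (1/s) at the given species-count state.

    Homodimerization (A + A -> ...) uses n(n-1)/2 in ``"stochastic"``
    propensity mode and n^2/2 in ``"deterministic"`` mode; the two coincide
    to O(1/n) at the molecule numbers of the packaged models.
    """
    state = np.asarray(state, dtype=np.float64)
    if state.shape != (network.n_species,):
        raise ValueError(
            f"state length {state.shape} != number of species {network.n_species}"
        )
    if np.any(state < 0):
        raise ValueError("negative species count in state")
    if mode not in ("deterministic", "stochastic"):
        raise ValueError(f"unknown mode {mode!r}")
    pos = {s.id: i for i, s in enumerate(network.species)}
    rates = np.empty(network.n_reactions)
    for j, r in enumerate(network.reactions):
        v = r.rate_constant
        for sid, c in r.reactants:
            n = state[pos[sid]]
            if c == 1:
                v *= n
            elif c == 2:
                v *= n * (n - 1) / 2 if mode == "stochastic" else n * n / 2
        rates[j] = v
    return rates
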