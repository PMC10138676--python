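"""Core constraint-based model data structures.

A :class:`MetabolicModel` owns the stoichiometric matrix of a genome-scale
metabolic network: metabolites (with elemental formula, charge and
compartment), reactions (stoichiometry, flux bounds, gene–protein–reaction
rules) and the biomass objective. Conventions follow the BiGG/COBRA
community standard: metabolite ids carry a compartment suffix (``_c``
cytosol, ``_e`` extracellular), exchange reactions are single-metabolite
boundary reactions on extracellular species (``EX_`` prefix by convention)
with uptake encoded as negative flux.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

from .gpr import GPRNode, parse_gpr

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "parse_formula",
    "FormulaError",
    "DEFAULT_BIG",
    "KNOWN_COMPARTMENTS",
]

#: Default magnitude used for effectively unconstrained flux bounds
#: (mmol gDW^-1 h^-1).
DEFAULT_BIG = 1000.0

#: Compartment codes the pipeline reasons about (cytosol, extracellular).
#: Other codes are accepted on read but flagged by model validation.
KNOWN_COMPARTMENTS = ("c", "e")

_ELEMENT_RE = re.compile(r"([A-Z][a-z]?)(\d*)")

# Polymeric / generic group symbols that make a formula non-auditable.
_POLYMER_SYMBOLS = {"R", "X", "*"}


class FormulaError(ValueError):
    """Raised when an elemental formula cannot be parsed."""


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a Hill-style elemental formula into an element→count map.

    Accepts plain element runs such as ``C6H12O6`` or ``C10H12N5O7P``.
    Polymeric group symbols (``R``, ``X``) and anything not reducible to
    element/count tokens raise :class:`FormulaError`; callers treat those
    species as having an unknown formula rather than guessing a balance
    verdict.
    """
    if formula is None or formula == "":
        raise FormulaError("empty formula")
    pos = 0
    counts: dict[str, int] = {}
    for match in _ELEMENT_RE.finditer(formula):
        if match.start() != pos:
            raise FormulaError(f"unparseable formula {formula!r}")
        element, digits = match.groups()
        if element in _POLYMER_SYMBOLS:
            raise FormulaError(f"polymeric group {element!r} in {formula!r}")
        counts[element] = counts.get(element, 0) + (int(digits) if digits else 1)
        pos = match.end()
    if pos != len(formula):
        raise FormulaError(f"unparseable formula {formula!r}")
    return counts


@dataclass(frozen=True)
class Metabolite:
    """A chemical species in a fixed compartment.

    ``formula`` may be empty (unknown composition) and ``charge`` may be
    ``None`` (unknown); both are tolerated everywhere and simply exclude
    the species from balance auditing.
    """

    id: str
    name: str = ""
    formula: str = ""
    charge: int | None = None
    compartment: str = "c"

    def element_counts(self) -> dict[str, int] | None:
        """Element→count map, or ``None`` if the formula is unknown."""
        try:
            return parse_formula(self.formula)
        except FormulaError:
            return None

    def suffix_consistent(self) -> bool:
        """True when the ``_c``/``_e`` id suffix matches ``compartment``."""
        for code in KNOWN_COMPARTMENTS:
            if self.id.endswith(f"_{code}"):
                return code == self.compartment
        return True  # no recognised suffix: nothing to contradict


@dataclass
class Reaction:
    """A stoichiometric conversion with flux bounds and a GPR rule.

    stoichiometry maps metabolite id → signed coefficient (negative =
    consumed). Bounds are in mmol gDW^-1 h^-1; a reaction is reversible iff
    ``lower_bound < 0 < upper_bound``. ``gpr`` is the raw boolean rule
    string (AND = enzyme complex, OR = isozymes); the parsed AST is cached.
    """

    id: str
    name: str = ""
    stoichiometry: dict[str, float] = field(default_factory=dict)
    lower_bound: float = 0.0
    upper_bound: float = DEFAULT_BIG
    gpr: str = ""
    _gpr_ast: GPRNode | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.lower_bound > self.upper_bound:
            raise ValueError(
                f"reaction {self.id}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )

    @property
    def bounds(self) -> tuple[float, float]:
        return (self.lower_bound, self.upper_bound)

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0.0 < self.upper_bound

    @property
    def gpr_ast(self) -> GPRNode | None:
        """Parsed GPR tree, or ``None`` for an empty rule."""
        if self._gpr_ast is None and self.gpr.strip():
            self._gpr_ast = parse_gpr(self.gpr)
        return self._gpr_ast

    def genes(self) -> frozenset[str]:
        ast = self.gpr_ast
        return ast.genes() if ast is not None else frozenset()

    def copy(self) -> "Reaction":
        return replace(self, stoichiometry=dict(self.stoichiometry))


def _is_exchange(reaction: Reaction, metabolites: dict[str, Metabolite]) -> bool:
    if len(reaction.stoichiometry) != 1:
        return False
    (met_id,) = reaction.stoichiometry
    met = metabolites.get(met_id)
    return met is not None and met.compartment == "e"


class MetabolicModel:
    """A genome-scale metabolic model: genes, metabolites, reactions, objective.

    Construction validates referential integrity (every reaction metabolite
    exists, the objective reaction exists) and registers every gene named in
    any GPR. Reaction/metabolite order is preserved and deterministic; it
    defines the column/row order of the stoichiometric matrix built by the
    FBA engine.
    """

    def __init__(
        self,
        id: str,
        metabolites: list[Metabolite] | None = None,
        reactions: list[Reaction] | None = None,
        objective_reaction_id: str | None = None,
        atpm_reaction_id: str | None = None,
        genes: set[str] | None = None,
    ) -> None:
        self.id = id
        self.metabolites: dict[str, Metabolite] = {}
        self.reactions: dict[str, Reaction] = {}
        self.objective_reaction_id = objective_reaction_id
        self.atpm_reaction_id = atpm_reaction_id
        self.genes: set[str] = set(genes or ())
        for met in metabolites or ():
            self.add_metabolite(met)
        for rxn in reactions or ():
            self.add_reaction(rxn)
        if objective_reaction_id is not None and objective_reaction_id not in self.reactions:
            raise ValueError(
                f"objective reaction {objective_reaction_id!r} not in model {id!r}"
            )

    # -- construction -----------------------------------------------------

    def add_metabolite(self, met: Metabolite) -> None:
        if met.id in self.metabolites:
            raise ValueError(f"duplicate metabolite id {met.id!r}")
        self.metabolites[met.id] = met

    def add_reaction(self, rxn: Reaction) -> None:
        if rxn.id in self.reactions:
            raise ValueError(f"duplicate reaction id {rxn.id!r}")
        missing = [m for m in rxn.stoichiometry if m not in self.metabolites]
        if missing:
            raise ValueError(
                f"reaction {rxn.id!r} references unknown metabolites {missing}"
            )
        if any(coeff == 0 for coeff in rxn.stoichiometry.values()):
            raise ValueError(f"reaction {rxn.id!r} has zero stoichiometric coefficients")
        self.reactions[rxn.id] = rxn
        self.genes |= rxn.genes()

    def remove_reaction(self, reaction_id: str) -> None:
        del self.reactions[reaction_id]

    # -- queries ----------------------------------------------------------

    def is_exchange(self, reaction_id: str) -> bool:
        """True for boundary reactions: one metabolite, extracellular."""
        return _is_exchange(self.reactions[reaction_id], self.metabolites)

    def exchange_ids(self) -> list[str]:
        return [rid for rid in self.reactions if self.is_exchange(rid)]

    @property
    def objective_reaction(self) -> Reaction:
        if self.objective_reaction_id is None:
            raise ValueError(f"model {self.id!r} has no objective reaction")
        return self.reactions[self.objective_reaction_id]

    def summary(self) -> tuple[int, int, int]:
        """Counts of unique (reactions, metabolites, genes)."""
        return (len(self.reactions), len(self.metabolites), len(self.genes))

    def flagged_compartments(self) -> set[str]:
        """Compartment codes outside the expected {c, e} pair."""
        return {
            m.compartment
            for m in self.metabolites.values()
            if m.compartment not in KNOWN_COMPARTMENTS
        }

    def copy(self, id: str | None = None) -> "MetabolicModel":
        return MetabolicModel(
            id=id or self.id,
            metabolites=list(self.metabolites.values()),
            reactions=[r.copy() for r in self.reactions.values()],
            objective_reaction_id=self.objective_reaction_id,
            atpm_reaction_id=self.atpm_reaction_id,
            genes=set(self.genes),
        )

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        r, m, g = self.summary()
        return f"<MetabolicModel {self.id}: {r} reactions, {m} metabolites, {g} genes>"


def model_summary(model: MetabolicModel) -> tuple[int, int, int]:
    """Counts of unique reactions, metabolites and genes in the model."""
    return model.summary()
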