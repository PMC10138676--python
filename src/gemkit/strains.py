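"""Template-based derivation of strain-specific models.

Given a high-quality template model and a gene×strain percent-identity
matrix, the workflow is:

1. **Ortholog calling.** A template gene is present in a strain when its
   percent identity reaches 70%. The threshold relaxes to 40% for genes
   that are near-ubiquitous at moderate identity: when the fraction of
   strains with identity strictly above 40% exceeds 0.75, that gene's
   effective threshold drops to 40% for every strain.
2. **GPR pruning.** Each template reaction's gene–protein–reaction rule is
   evaluated against the strain's present-gene set; reactions whose rule is
   False are removed. Reactions without gene evidence (spontaneous,
   orphan transporters), exchanges, and the biomass objective are always
   retained.
3. **Gap filling.** Strains left unable to grow are repaired by adding a
   minimum-cardinality set of reactions from a donor bag (by default the
   reactions pruned from the template), found with a mixed-integer program.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import milp, LinearConstraint, Bounds
from scipy.sparse import lil_matrix

from .fba import GROWTH_THRESHOLD, solve_fba, apply_medium
from .gpr import evaluate_gpr
from .model import MetabolicModel

__all__ = [
    "PresenceMatrix",
    "GapFillResult",
    "call_orthologs",
    "derive_strain_model",
    "gap_fill",
    "multi_gap_fill",
    "PRIMARY_THRESHOLD",
    "RELAXED_THRESHOLD",
    "PREVALENCE",
]

logger = logging.getLogger(__name__)

PRIMARY_THRESHOLD = 70.0
RELAXED_THRESHOLD = 40.0
PREVALENCE = 0.75


@dataclass
class PresenceMatrix:
    """Boolean gene×strain presence calls plus the per-gene threshold used."""

    presence: pd.DataFrame  # genes × strains, bool
    effective_threshold: pd.Series  # per gene: 70 or 40

    def strain_genes(self, strain: str) -> set[str]:
        col = self.presence[strain]
        return set(col.index[col])


def call_orthologs(
    homology: pd.DataFrame,
    primary: float = PRIMARY_THRESHOLD,
    relaxed: float = RELAXED_THRESHOLD,
    prevalence: float = PREVALENCE,
) -> PresenceMatrix:
    """Call ortholog presence from a gene×strain percent-identity matrix.

    Presence requires identity >= ``primary`` (70%), except for genes whose
    identity is strictly above ``relaxed`` (40%) in strictly more than
    ``prevalence`` (75%) of strains — those genes are called with the
    relaxed threshold instead. Boundary semantics are strict on the
    relaxation conditions and inclusive on the threshold comparison itself.
    """
    if homology.shape[1] == 0:
        raise ValueError("homology matrix has no strains")
    if ((homology.values < 0) | (homology.values > 100)).any():
        raise ValueError("homology percentages must lie in [0, 100]")
    frac_over_relaxed = (homology > relaxed).mean(axis=1)
    use_relaxed = frac_over_relaxed > prevalence
    thresholds = pd.Series(
        np.where(use_relaxed, relaxed, primary), index=homology.index, dtype=float
    )
    presence = homology.ge(thresholds, axis=0)
    return PresenceMatrix(presence=presence, effective_threshold=thresholds)


def derive_strain_model(
    template: MetabolicModel,
    present_genes: set[str],
    strain_id: str | None = None,
) -> MetabolicModel:
    """Prune the template down to one strain's gene content.

    Reactions whose GPR evaluates False for ``present_genes`` are removed.
    Exchanges, the biomass objective and GPR-less reactions survive
    unconditionally. The gene list of the derived model is the intersection
    of the template's genes with ``present_genes``.
    """
    strain = template.copy(id=strain_id or f"{template.id}_strain")
    for rid in list(strain.reactions):
        rxn = strain.reactions[rid]
        if rid == strain.objective_reaction_id or strain.is_exchange(rid):
            continue
        if not rxn.gpr.strip():
            continue
        if not evaluate_gpr(rxn.gpr_ast, present_genes):
            strain.remove_reaction(rid)
    strain.genes = template.genes & set(present_genes)
    return strain


@dataclass
class GapFillResult:
    """Outcome of gap-filling one strain on one medium."""

    strain_id: str
    added_reaction_ids: list[str] = field(default_factory=list)
    growth_before: float = 0.0
    growth_after: float = 0.0
    medium_name: str = ""
    status: str = "ok"  # ok | already_growing | unfillable


def _growth(model: MetabolicModel) -> float:
    sol = solve_fba(model)
    return sol.objective_value if sol.optimal else 0.0


def gap_fill(
    model: MetabolicModel,
    donor_reactions: list,
    medium: dict[str, tuple[float, float]] | None = None,
    objective_id: str | None = None,
    target_growth: float = GROWTH_THRESHOLD,
    medium_name: str = "",
    donor_metabolites: dict | None = None,
) -> GapFillResult:
    """Add a minimum-cardinality donor subset restoring growth.

    Solves a mixed-integer program over the union network: steady state
    ``S v = 0``, native bounds, objective flux >= ``target_growth``, and
    for every donor reaction j an inclusion indicator y_j with
    ``lb_j*y_j <= v_j <= ub_j*y_j``; minimize sum(y). Ties between
    minimum-cardinality subsets are broken lexicographically by reaction id
    via an epsilon-weighted objective, making the result deterministic.

    Donor reactions already in the model are ignored. Donor reactions may
    reference metabolites the model lacks when ``donor_metabolites``
    supplies their definitions (e.g. the template's metabolite table);
    donors referencing metabolites defined nowhere are dropped from the
    bag with a warning. If even the full bag cannot restore growth the
    result is flagged ``unfillable``.
    """
    work = apply_medium(model, medium) if medium is not None else model.copy()
    if objective_id is not None:
        work.objective_reaction_id = objective_id
    growth_before = _growth(work)
    if growth_before >= target_growth:
        return GapFillResult(
            strain_id=model.id,
            growth_before=growth_before,
            growth_after=growth_before,
            medium_name=medium_name,
            status="already_growing",
        )

    donor_metabolites = donor_metabolites or {}
    donors = []
    new_mets = {}
    for rxn in sorted(donor_reactions, key=lambda r: r.id):
        if rxn.id in work.reactions:
            continue
        unknown = [m for m in rxn.stoichiometry
                   if m not in work.metabolites and m not in donor_metabolites]
        if unknown:
            logger.warning("donor %s dropped: metabolites %s undefined",
                           rxn.id, unknown)
            continue
        donors.append(rxn)
        for m in rxn.stoichiometry:
            if m not in work.metabolites:
                new_mets[m] = donor_metabolites[m]
    union = work.copy()
    for met in new_mets.values():
        union.add_metabolite(met)
    for rxn in donors:
        union.add_reaction(rxn.copy())

    # Even the full bag failing means no subset can succeed.
    full_growth = _growth(union)
    if full_growth < target_growth:
        return GapFillResult(
            strain_id=model.id,
            growth_before=growth_before,
            growth_after=growth_before,
            medium_name=medium_name,
            status="unfillable",
        )
    # The MILP needs a growth target comfortably above the solver's
    # integrality tolerance, or a binary indicator at ~1e-8 can smuggle the
    # tiny flux through its big-M link. Use an internal target of 1e-3 (or
    # half the full-bag optimum when that is smaller) and verify the user's
    # threshold with an exact LP afterwards.
    internal_target = max(target_growth, min(1e-3, 0.5 * full_growth))

    met_index = {m: i for i, m in enumerate(union.metabolites)}
    rxn_ids = list(union.reactions)
    n_rxn, n_donor = len(rxn_ids), len(donors)
    donor_pos = {r.id: k for k, r in enumerate(donors)}

    # variables: v (n_rxn continuous), y (n_donor binary)
    n_var = n_rxn + n_donor
    S = lil_matrix((len(met_index), n_var))
    lb = np.empty(n_var)
    ub = np.empty(n_var)
    for j, rid in enumerate(rxn_ids):
        rxn = union.reactions[rid]
        lb[j], ub[j] = rxn.bounds
        for mid, coeff in rxn.stoichiometry.items():
            S[met_index[mid], j] = coeff
    lb[n_rxn:], ub[n_rxn:] = 0.0, 1.0

    constraints = [LinearConstraint(S.tocsc(), 0.0, 0.0)]

    # v_j - ub_j * y_j <= 0  and  v_j - lb_j * y_j >= 0 for donor reactions
    link = lil_matrix((2 * n_donor, n_var))
    link_lb = np.empty(2 * n_donor)
    link_ub = np.empty(2 * n_donor)
    for k, rxn in enumerate(donors):
        j = rxn_ids.index(rxn.id)
        link[2 * k, j] = 1.0
        link[2 * k, n_rxn + k] = -rxn.upper_bound
        link_lb[2 * k], link_ub[2 * k] = -np.inf, 0.0
        link[2 * k + 1, j] = 1.0
        link[2 * k + 1, n_rxn + k] = -rxn.lower_bound
        link_lb[2 * k + 1], link_ub[2 * k + 1] = 0.0, np.inf
    if n_donor:
        constraints.append(LinearConstraint(link.tocsc(), link_lb, link_ub))

    # growth requirement, scaled to unit magnitude so the target is not
    # swallowed by the MIP feasibility tolerance
    obj_j = rxn_ids.index(work.objective_reaction_id)
    growth_row = np.zeros(n_var)
    growth_row[obj_j] = 1.0 / internal_target
    constraints.append(LinearConstraint(growth_row, 1.0, np.inf))

    # minimize cardinality; epsilon ranks break ties lexicographically
    c = np.zeros(n_var)
    eps = 1.0 / (4.0 * max(n_donor, 1) ** 2)
    for k in range(n_donor):
        c[n_rxn + k] = 1.0 + eps * k
    integrality = np.zeros(n_var)
    integrality[n_rxn:] = 1

    res = milp(
        c,
        constraints=constraints,
        bounds=Bounds(lb, ub),
        integrality=integrality,
    )
    if not res.success:
        return GapFillResult(
            strain_id=model.id,
            growth_before=growth_before,
            growth_after=growth_before,
            medium_name=medium_name,
            status="unfillable",
        )
    y = res.x[n_rxn:]
    added = [donors[k].id for k in range(n_donor) if y[k] > 0.5]

    repaired = work.copy()
    for rxn in donors:
        if rxn.id in added:
            for m in rxn.stoichiometry:
                if m not in repaired.metabolites:
                    repaired.add_metabolite(new_mets[m])
            repaired.add_reaction(rxn.copy())
    growth_after = _growth(repaired)
    return GapFillResult(
        strain_id=model.id,
        added_reaction_ids=added,
        growth_before=growth_before,
        growth_after=growth_after,
        medium_name=medium_name,
        status="ok" if growth_after >= target_growth else "unfillable",
    )


def multi_gap_fill(
    strain_models: dict[str, MetabolicModel],
    donor_reactions: list,
    media: dict[str, dict[str, tuple[float, float]]],
    target_growth: float = GROWTH_THRESHOLD,
    donor_metabolites: dict | None = None,
) -> dict[str, GapFillResult]:
    """Gap-fill only the strains that grow on none of the given media.

    Strains growing on at least one medium pass through untouched
    (``already_growing``). A strain failing everywhere is gap-filled on the
    first medium of ``media`` (insertion order); if the repair fails it is
    flagged ``unfillable`` but the cohort run continues.
    """
    if not media:
        raise ValueError("multi_gap_fill needs at least one medium")
    results: dict[str, GapFillResult] = {}
    for strain_id, model in strain_models.items():
        try:
            growths = {
                name: _growth(apply_medium(model, medium))
                for name, medium in media.items()
            }
            if any(g >= target_growth for g in growths.values()):
                best = max(growths, key=growths.get)
                results[strain_id] = GapFillResult(
                    strain_id=strain_id,
                    growth_before=growths[best],
                    growth_after=growths[best],
                    medium_name=best,
                    status="already_growing",
                )
                continue
            first_medium = next(iter(media))
            results[strain_id] = gap_fill(
                model,
                donor_reactions,
                medium=media[first_medium],
                target_growth=target_growth,
                medium_name=first_medium,
                donor_metabolites=donor_metabolites,
            )
        except Exception as exc:  # keep the cohort alive; record the failure
            logger.error("gap-fill failed for strain %s: %s", strain_id, exc)
            results[strain_id] = GapFillResult(
                strain_id=strain_id, medium_name="", status="unfillable"
            )
    n_bad = sum(r.status == "unfillable" for r in results.values())
    logger.info(
        "multi_gap_fill: %d strains, %d repaired, %d unfillable",
        len(results),
        sum(r.status == "ok" for r in results.values()),
        n_bad,
    )
    return results
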