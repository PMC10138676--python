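"""Model quality-control diagnostics.

Three audits that flag the defect classes most often introduced during
draft reconstruction of a genome-scale model:

* mass/charge balance of every non-boundary reaction (biomass and exchange
  pseudo-reactions are exempt — they are deliberately unbalanced);
* dead-end metabolites: species that can only be produced or only consumed
  under the current bounds, which forces zero steady-state flux through
  their reactions;
* energy-generating cycles: with every exchange closed no flux should be
  able to hydrolyse ATP; a positive optimum certifies a thermodynamically
  infeasible loop (e.g. a carboxylase left reversible).

All audits detect and report; none mutates the model. Repair is a manual
curation decision, not something to automate silently.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

from .fba import REPORT_TOL, solve_fba
from .model import MetabolicModel

__all__ = [
    "BalanceReport",
    "check_mass_charge_balance",
    "find_dead_end_metabolites",
    "check_energy_generating_cycle",
    "write_qc_report",
]

_BALANCE_TOL = 1e-9


@dataclass
class BalanceReport:
    """Balance audit verdict for one reaction.

    ``element_imbalance`` maps element → net excess on the product side
    (negative = missing from products); ``charge_imbalance`` is the net
    charge produced. ``status`` is one of ``balanced``, ``mass_unbalanced``,
    ``charge_unbalanced`` (possibly both, joined with ``+``) or
    ``unknown_formula`` when any participant lacks a parseable formula.
    """

    reaction_id: str
    element_imbalance: dict[str, float] = field(default_factory=dict)
    charge_imbalance: float | None = 0.0
    status: str = "balanced"


def check_mass_charge_balance(model: MetabolicModel) -> list[BalanceReport]:
    """Audit elemental and charge balance of all non-exchange reactions.

    The biomass objective and exchange reactions are excluded: both are
    pseudo-stoichiometric by design. A reaction touching any metabolite
    with an unknown/unparseable formula is reported ``unknown_formula``
    rather than given a fabricated verdict.
    """
    reports = []
    for rid, rxn in model.reactions.items():
        if model.is_exchange(rid) or rid == model.objective_reaction_id:
            continue
        elements: dict[str, float] = {}
        charge: float | None = 0.0
        unknown = False
        for met_id, coeff in rxn.stoichiometry.items():
            met = model.metabolites[met_id]
            counts = met.element_counts()
            if counts is None:
                unknown = True
                break
            for element, count in counts.items():
                elements[element] = elements.get(element, 0.0) + coeff * count
            if charge is not None:
                charge = charge + coeff * met.charge if met.charge is not None else None
        if unknown:
            reports.append(
                BalanceReport(rid, {}, None, status="unknown_formula")
            )
            continue
        elements = {e: v for e, v in elements.items() if abs(v) > _BALANCE_TOL}
        mass_bad = bool(elements)
        charge_bad = charge is None or abs(charge) > _BALANCE_TOL
        if charge is None:
            status = "unknown_formula"  # unknown charge: cannot certify
        elif mass_bad and charge_bad:
            status = "mass_unbalanced+charge_unbalanced"
        elif mass_bad:
            status = "mass_unbalanced"
        elif charge_bad:
            status = "charge_unbalanced"
        else:
            status = "balanced"
        reports.append(BalanceReport(rid, elements, charge, status))
    return reports


def find_dead_end_metabolites(model: MetabolicModel) -> tuple[list[str], list[str]]:
    """Metabolites that break the material balance: (produced-only, consumed-only).

    Production/consumption capability respects current bounds: a reversible
    reaction (lb < 0 < ub) can both produce and consume all its
    participants; an irreversible one only in its forward direction.
    Exchange reactions count — an extracellular species with an open
    exchange is not a dead end.
    """
    producible: set[str] = set()
    consumable: set[str] = set()
    for rxn in model.reactions.values():
        forward = rxn.upper_bound > 0
        backward = rxn.lower_bound < 0
        for met_id, coeff in rxn.stoichiometry.items():
            if coeff > 0:
                if forward:
                    producible.add(met_id)
                if backward:
                    consumable.add(met_id)
            else:
                if forward:
                    consumable.add(met_id)
                if backward:
                    producible.add(met_id)
    produced_only = [m for m in model.metabolites if m in producible and m not in consumable]
    consumed_only = [m for m in model.metabolites if m in consumable and m not in producible]
    return produced_only, consumed_only


def check_energy_generating_cycle(
    model: MetabolicModel,
    atpm_reaction_id: str | None = None,
    tol: float = REPORT_TOL,
) -> float:
    """Maximal ATP-hydrolysis flux attainable with every exchange closed.

    Closes all exchange reactions to [0, 0], relaxes the maintenance
    reaction's lower bound to 0 (it may carry a forced positive flux in
    normal simulation) and maximizes its flux. Any optimum above ``tol``
    certifies an energy-generating cycle: the network makes ATP from
    nothing. A clean model returns 0.
    """
    atpm = atpm_reaction_id or model.atpm_reaction_id
    if atpm is None or atpm not in model.reactions:
        raise ValueError(
            f"model {model.id!r}: ATP maintenance reaction "
            f"{atpm!r} not found; pass atpm_reaction_id"
        )
    closed = model.copy()
    for rid in closed.exchange_ids():
        closed.reactions[rid].lower_bound = 0.0
        closed.reactions[rid].upper_bound = 0.0
    closed.reactions[atpm].lower_bound = 0.0
    sol = solve_fba(closed, objective_id=atpm, sense="max")
    if not sol.optimal:
        return 0.0
    return sol.objective_value if sol.objective_value > tol else 0.0


def write_qc_report(
    model: MetabolicModel,
    path: str | Path,
    atpm_reaction_id: str | None = None,
) -> dict:
    """Run all audits and write one TSV row per finding; returns a summary."""
    balance = check_mass_charge_balance(model)
    produced_only, consumed_only = find_dead_end_metabolites(model)
    try:
        egc = check_energy_generating_cycle(model, atpm_reaction_id)
        egc_note = f"{egc:.6g}"
    except ValueError:
        egc = None
        egc_note = "not_checked_no_atpm"
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["category", "id", "status", "detail"])
        for rep in balance:
            if rep.status == "balanced":
                continue
            detail = ";".join(
                f"{e}:{v:+g}" for e, v in sorted(rep.element_imbalance.items())
            )
            if rep.charge_imbalance not in (None, 0.0):
                detail += f";charge:{rep.charge_imbalance:+g}"
            writer.writerow(["balance", rep.reaction_id, rep.status, detail])
        for met in produced_only:
            writer.writerow(["dead_end", met, "produced_only", ""])
        for met in consumed_only:
            writer.writerow(["dead_end", met, "consumed_only", ""])
        writer.writerow(["energy_cycle", atpm_reaction_id or model.atpm_reaction_id or "",
                         "checked" if egc is not None else "skipped", egc_note])
    n_unbalanced = sum(r.status != "balanced" for r in balance)
    return {
        "n_reactions_audited": len(balance),
        "n_unbalanced_or_unknown": n_unbalanced,
        "n_produced_only": len(produced_only),
        "n_consumed_only": len(consumed_only),
        "energy_cycle_flux": egc,
    }
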