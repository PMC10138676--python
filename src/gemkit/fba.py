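"""Flux balance analysis and the carbon-source growth screen.

FBA solves the linear program

    max  c^T v
    s.t. S v = 0          (steady state)
         lb <= v <= ub    (thermodynamic / capacity / medium bounds)

where ``S`` is the stoichiometric matrix and the objective is normally the
biomass pseudo-reaction, whose flux is the specific growth rate (h^-1).
The LP is solved with the HiGHS solvers behind :func:`scipy.optimize.linprog`.

The screen fixes each candidate exchange reaction's uptake to a common rate
(10 mmol gDW^-1 h^-1 by default) on an otherwise carbon-free minimal
medium, calls growth on each source, and records secreted byproducts.
Growth rates can be normalized by the carbon count of the source, either by
dividing the rate (``per_carbon``) or by re-solving with a
glucose-carbon-equivalent uptake bound of 60/n_C (``carbon_equivalent_uptake``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog
from scipy.sparse import lil_matrix

from .model import DEFAULT_BIG, MetabolicModel, parse_formula, FormulaError

__all__ = [
    "FluxSolution",
    "GrowthRecord",
    "solve_fba",
    "apply_medium",
    "screen_carbon_sources",
    "normalize_growth",
    "predict_secretion",
    "carbon_count",
    "GROWTH_THRESHOLD",
    "REPORT_TOL",
]

logger = logging.getLogger(__name__)

#: Growth rates above this value (h^-1) count as growth; safely above LP
#: solver tolerance, far below any biologically meaningful rate.
GROWTH_THRESHOLD = 1e-6

#: Fluxes below this magnitude are reported as zero.
REPORT_TOL = 1e-6


@dataclass
class FluxSolution:
    """Outcome of one FBA solve."""

    status: str  # optimal | infeasible | unbounded
    objective_value: float
    fluxes: dict[str, float] = field(default_factory=dict)

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


def _stoichiometric_matrix(model: MetabolicModel):
    met_index = {m: i for i, m in enumerate(model.metabolites)}
    rxn_ids = list(model.reactions)
    S = lil_matrix((len(met_index), len(rxn_ids)))
    for j, rid in enumerate(rxn_ids):
        for mid, coeff in model.reactions[rid].stoichiometry.items():
            S[met_index[mid], j] = coeff
    return S.tocsc(), rxn_ids


def solve_fba(
    model: MetabolicModel,
    objective_id: str | None = None,
    sense: str = "max",
) -> FluxSolution:
    """Solve steady-state FBA for one objective reaction.

    Returns a :class:`FluxSolution`; infeasible and unbounded problems are
    reported through ``status``, never raised. With the default ``sense="max"``
    and the biomass objective the objective value is the growth rate.
    """
    if sense not in ("max", "min"):
        raise ValueError(f"sense must be 'max' or 'min', got {sense!r}")
    objective_id = objective_id or model.objective_reaction_id
    if objective_id is None or objective_id not in model.reactions:
        raise ValueError(f"objective reaction {objective_id!r} not in model {model.id!r}")

    S, rxn_ids = _stoichiometric_matrix(model)
    n = len(rxn_ids)
    c = np.zeros(n)
    c[rxn_ids.index(objective_id)] = -1.0 if sense == "max" else 1.0
    bounds = [model.reactions[r].bounds for r in rxn_ids]
    res = linprog(
        c,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=bounds,
        method="highs",
        options={"primal_feasibility_tolerance": 1e-9, "dual_feasibility_tolerance": 1e-9},
    )
    if res.status == 2:
        return FluxSolution(status="infeasible", objective_value=0.0)
    if res.status == 3:
        return FluxSolution(status="unbounded", objective_value=float("inf"))
    if not res.success:
        return FluxSolution(status="infeasible", objective_value=0.0)
    fluxes = {rid: float(v) for rid, v in zip(rxn_ids, res.x)}
    return FluxSolution(
        status="optimal",
        objective_value=float(fluxes[objective_id]),
        fluxes=fluxes,
    )


def apply_medium(
    model: MetabolicModel,
    medium: dict[str, tuple[float, float]],
) -> MetabolicModel:
    """Return a copy of the model with exchange bounds set by the medium.

    Exchanges named in the medium receive its bounds verbatim; every other
    exchange is closed for uptake (lower bound 0) with secretion left open
    (upper bound ``DEFAULT_BIG``). Non-exchange reactions are untouched.
    """
    exchange_ids = set(model.exchange_ids())
    unknown = sorted(set(medium) - exchange_ids)
    if unknown:
        raise ValueError(
            f"medium names exchange reactions absent from model {model.id!r}: {unknown}"
        )
    out = model.copy()
    for rid in exchange_ids:
        rxn = out.reactions[rid]
        if rid in medium:
            rxn.lower_bound, rxn.upper_bound = medium[rid]
        else:
            rxn.lower_bound, rxn.upper_bound = 0.0, DEFAULT_BIG
    return out


def carbon_count(model: MetabolicModel, exchange_id: str) -> int | None:
    """Carbon atoms of the species traded by an exchange reaction.

    Returns ``None`` when the metabolite formula is unknown or unparseable
    (the screen then skips normalization for that source rather than guess).
    """
    (met_id,) = model.reactions[exchange_id].stoichiometry
    try:
        return parse_formula(model.metabolites[met_id].formula).get("C", 0)
    except FormulaError:
        return None


@dataclass
class GrowthRecord:
    """One carbon source's screen outcome for one model."""

    carbon_source_exchange_id: str
    n_carbons: int | None
    growth_rate: float
    normalized_growth: float | None
    grows: bool
    secreted_byproducts: dict[str, float] = field(default_factory=dict)
    normalize_mode: str | None = None


def normalize_growth(
    growth_rate: float,
    n_carbons: int,
    mode: str = "per_carbon",
    resolver=None,
) -> float:
    """Normalize a growth rate by the source's carbon count.

    ``per_carbon`` divides the rate by n_C. ``carbon_equivalent_uptake``
    re-solves the model with the uptake bound scaled to 60/n_C (the carbon
    flux of glucose at uptake 10) and requires a ``resolver`` callback
    ``resolver(uptake) -> growth_rate`` supplying that re-solve.
    """
    if n_carbons < 1:
        raise ValueError("normalization needs a carbon source with n_carbons >= 1")
    if mode == "per_carbon":
        return growth_rate / n_carbons
    if mode == "carbon_equivalent_uptake":
        if resolver is None:
            raise ValueError("carbon_equivalent_uptake mode needs a resolver callback")
        return resolver(60.0 / n_carbons)
    raise ValueError(f"unknown normalization mode {mode!r}")


def predict_secretion(
    model: MetabolicModel, solution: FluxSolution, tol: float = REPORT_TOL
) -> dict[str, float]:
    """Exchange reactions with positive (secretion) flux, sorted descending."""
    if not solution.optimal:
        raise ValueError("secretion prediction requires an optimal FBA solution")
    secreted = {
        rid: solution.fluxes[rid]
        for rid in model.exchange_ids()
        if solution.fluxes.get(rid, 0.0) > tol
    }
    return dict(sorted(secreted.items(), key=lambda kv: (-kv[1], kv[0])))


def screen_carbon_sources(
    model: MetabolicModel,
    base_medium: dict[str, tuple[float, float]],
    candidate_exchanges: list[str],
    uptake: float = 10.0,
    normalize_mode: str | None = "per_carbon",
    growth_threshold: float = GROWTH_THRESHOLD,
) -> list[GrowthRecord]:
    """Screen candidate exchanges as sole carbon sources.

    For each candidate the model is put on ``base_medium`` (which must be
    carbon-free) with the candidate's uptake fixed to ``-uptake``, and
    biomass is maximized. Infeasible solves record zero growth rather than
    aborting the screen.
    """
    records = []
    base = apply_medium(model, base_medium)
    for exchange_id in candidate_exchanges:
        if exchange_id not in model.reactions:
            raise ValueError(f"candidate exchange {exchange_id!r} not in model {model.id!r}")

        trial = base.copy()
        rxn = trial.reactions[exchange_id]
        rxn.lower_bound = -uptake
        if rxn.upper_bound < 0:
            rxn.upper_bound = DEFAULT_BIG
        sol = solve_fba(trial)
        growth = sol.objective_value if sol.optimal else 0.0
        growth = 0.0 if growth < 0 else growth
        n_c = carbon_count(model, exchange_id)

        normalized = None
        if normalize_mode is not None:
            if n_c is None:
                logger.warning(
                    "source %s skipped for normalization: unknown formula", exchange_id
                )
            elif n_c == 0:
                logger.warning("source %s has no carbon; normalization skipped", exchange_id)
            elif growth == 0.0:
                normalized = 0.0
            else:

                def _resolver(up: float) -> float:
                    retrial = base.copy()
                    retrial.reactions[exchange_id].lower_bound = -up
                    rs = solve_fba(retrial)
                    return max(rs.objective_value, 0.0) if rs.optimal else 0.0

                normalized = normalize_growth(growth, n_c, normalize_mode, _resolver)

        records.append(
            GrowthRecord(
                carbon_source_exchange_id=exchange_id,
                n_carbons=n_c,
                growth_rate=growth,
                normalized_growth=normalized,
                grows=growth > growth_threshold,
                secreted_byproducts=(
                    predict_secretion(trial, sol) if sol.optimal else {}
                ),
                normalize_mode=normalize_mode,
            )
        )
    return records
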