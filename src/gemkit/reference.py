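"""Exhaustive reference algorithms for validating the fast paths.

Everything here is deliberately brute force and only tractable on tiny
inputs: LP optimisation by vertex enumeration, gap filling by subset
search, ortholog calling by literal two-pass loops, and a line-by-line
transcription of the biweight midcorrelation formula. None of these share
code with the production implementations they certify; they exist so that
correctness on small problems is checked against an independent route, not
against the implementation itself.
"""

from __future__ import annotations

from itertools import combinations, product
from statistics import median

import numpy as np

from .fba import solve_fba
from .model import MetabolicModel

__all__ = [
    "enumerate_lp_vertices",
    "lp_optimum_by_vertex_enumeration",
    "fba_optimum_by_vertex_enumeration",
    "exhaustive_gap_fill",
    "call_orthologs_two_pass",
    "bicor_direct",
]


def enumerate_lp_vertices(S, lb, ub, tol: float = 1e-7) -> list[np.ndarray]:
    """All vertices of the polytope {v : S v = 0, lb <= v <= ub}.

    A vertex must have at least ``n - rank(S)`` bound constraints active,
    so every vertex is found by fixing each size-(n-rank) subset of
    variables at one of its bounds and solving the resulting square system.
    Exponential; intended for n <= ~10.
    """
    S = np.atleast_2d(np.asarray(S, dtype=float))
    lb = np.asarray(lb, dtype=float)
    ub = np.asarray(ub, dtype=float)
    n = S.shape[1]
    rank = np.linalg.matrix_rank(S) if S.size else 0
    d = n - rank
    vertices: list[np.ndarray] = []
    for subset in combinations(range(n), d):
        for choice in product((0, 1), repeat=d):
            rows = [S] if S.size else []
            rhs = [np.zeros(S.shape[0])] if S.size else []
            for idx, side in zip(subset, choice):
                e = np.zeros(n)
                e[idx] = 1.0
                rows.append(e[None, :])
                rhs.append(np.array([ub[idx] if side else lb[idx]]))
            A = np.vstack(rows)
            b = np.concatenate(rhs)
            if np.linalg.matrix_rank(A) < n:
                continue
            v, *_ = np.linalg.lstsq(A, b, rcond=None)
            if np.max(np.abs(A @ v - b)) > tol:
                continue
            if np.any(v < lb - tol) or np.any(v > ub + tol):
                continue
            if np.max(np.abs(S @ v)) > tol:
                continue
            if not any(np.allclose(v, w, atol=10 * tol) for w in vertices):
                vertices.append(v)
    return vertices


def lp_optimum_by_vertex_enumeration(c, S, lb, ub, sense: str = "max") -> float | None:
    """LP optimum of c^T v over {S v = 0, lb <= v <= ub} by vertex search.

    Valid for bounded polytopes (all bounds finite). Returns ``None`` when
    the polytope is empty.
    """
    vertices = enumerate_lp_vertices(S, lb, ub)
    if not vertices:
        return None
    values = [float(np.dot(c, v)) for v in vertices]
    return max(values) if sense == "max" else min(values)


def fba_optimum_by_vertex_enumeration(
    model: MetabolicModel, objective_id: str | None = None, sense: str = "max"
) -> float | None:
    """FBA optimum of a tiny model computed by vertex enumeration."""
    objective_id = objective_id or model.objective_reaction_id
    met_index = {m: i for i, m in enumerate(model.metabolites)}
    rxn_ids = list(model.reactions)
    S = np.zeros((len(met_index), len(rxn_ids)))
    for j, rid in enumerate(rxn_ids):
        for mid, coeff in model.reactions[rid].stoichiometry.items():
            S[met_index[mid], j] = coeff
    lb = np.array([model.reactions[r].lower_bound for r in rxn_ids])
    ub = np.array([model.reactions[r].upper_bound for r in rxn_ids])
    c = np.zeros(len(rxn_ids))
    c[rxn_ids.index(objective_id)] = 1.0
    return lp_optimum_by_vertex_enumeration(c, S, lb, ub, sense=sense)


def exhaustive_gap_fill(
    model: MetabolicModel,
    donor_reactions: list,
    target_growth: float,
    max_size: int | None = None,
    donor_metabolites: dict | None = None,
) -> list[str] | None:
    """Smallest donor subset restoring growth, found by trying every subset.

    Subsets are scanned in order of (size, lexicographic ids), so the first
    hit is both minimum-cardinality and the lexicographic tie-break winner.
    Returns ``None`` when no subset up to ``max_size`` suffices.
    """
    donor_metabolites = donor_metabolites or {}
    donors = sorted(
        (r for r in donor_reactions if r.id not in model.reactions),
        key=lambda r: r.id,
    )
    limit = len(donors) if max_size is None else min(max_size, len(donors))
    for size in range(limit + 1):
        for subset in combinations(donors, size):
            trial = model.copy()
            for rxn in subset:
                for mid in rxn.stoichiometry:
                    if mid not in trial.metabolites:
                        trial.add_metabolite(donor_metabolites[mid])
                trial.add_reaction(rxn.copy())
            sol = solve_fba(trial)
            if sol.optimal and sol.objective_value >= target_growth:
                return [r.id for r in subset]
    return None


def call_orthologs_two_pass(pct, primary=70.0, relaxed=40.0, prevalence=0.75):
    """Literal two-pass ortholog calling on a genes×strains DataFrame.

    First pass finds, per gene, the fraction of strains with identity
    strictly over the relaxed threshold; the second pass applies 70 or 40
    per gene. Plain loops, no vectorisation.
    """
    genes = list(pct.index)
    strains = list(pct.columns)
    thresholds = {}
    for g in genes:
        over = sum(1 for s in strains if pct.loc[g, s] > relaxed)
        thresholds[g] = relaxed if over / len(strains) > prevalence else primary
    calls = {
        g: {s: bool(pct.loc[g, s] >= thresholds[g]) for s in strains} for g in genes
    }
    return calls, thresholds


def bicor_direct(x, y) -> float:
    """Biweight midcorrelation computed by direct transcription of its formula.

    med/MAD with pure-python statistics, explicit loops over points:
    u_i = (x_i - med x)/(9 MAD x); w_i = (1-u_i^2)^2 if |u_i|<1 else 0;
    x~_i = (x_i - med x) w_i; bicor = sum x~ y~ / sqrt(sum x~^2 sum y~^2).
    """
    x = [float(v) for v in x]
    y = [float(v) for v in y]

    def weighted(vals):
        med_v = median(vals)
        mad = median([abs(v - med_v) for v in vals])
        if mad == 0:
            raise ZeroDivisionError("zero MAD: biweight midcorrelation undefined")
        out = []
        for v in vals:
            u = (v - med_v) / (9.0 * mad)
            w = (1.0 - u * u) ** 2 if abs(u) < 1.0 else 0.0
            out.append((v - med_v) * w)
        return out

    xt = weighted(x)
    yt = weighted(y)
    num = sum(a * b for a, b in zip(xt, yt))
    den = (sum(a * a for a in xt) * sum(b * b for b in yt)) ** 0.5
    return num / den
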