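"""FBA engine: LP correctness, medium handling, screens, normalization."""

import numpy as np
import pytest

from conftest import glucose_medium
from gemkit.fba import (
    GROWTH_THRESHOLD,
    apply_medium,
    carbon_count,
    normalize_growth,
    predict_secretion,
    screen_carbon_sources,
    solve_fba,
)
from gemkit.model import MetabolicModel, Metabolite, Reaction
from gemkit.reference import fba_optimum_by_vertex_enumeration
from gemkit.synth import SourceSpec, ToyGemSpec, make_toy_gem


def _five_reaction_chain():
    """EX -> transport -> convert -> biomass with yield 0.1 per unit uptake."""
    mets = [
        Metabolite(id="s_e", formula="C", charge=0, compartment="e"),
        Metabolite(id="s_c", formula="C", charge=0, compartment="c"),
        Metabolite(id="x_c", formula="C", charge=0, compartment="c"),
    ]
    rxns = [
        Reaction(id="EX_s_e", stoichiometry={"s_e": -1}, lower_bound=-10, upper_bound=1000),
        Reaction(id="T_s", stoichiometry={"s_e": -1, "s_c": 1}, upper_bound=1000),
        Reaction(id="R1", stoichiometry={"s_c": -1, "x_c": 1}, upper_bound=1000),
        Reaction(id="R2", stoichiometry={"x_c": -1}, upper_bound=5),  # capacity cap
        Reaction(id="BIOMASS", stoichiometry={"x_c": -10}, upper_bound=1000),
    ]
    return MetabolicModel(id="chain5", metabolites=mets, reactions=rxns,
                          objective_reaction_id="BIOMASS")


class TestSolveFba:
    def test_toy_chain_matches_vertex_enumeration(self):
        model = _five_reaction_chain()
        sol = solve_fba(model)
        oracle = fba_optimum_by_vertex_enumeration(model)
        # uptake 10, escape valve capped at 5: biomass takes 10 at 0.1/unit
        assert sol.objective_value == pytest.approx(1.0, abs=1e-9)
        assert sol.objective_value == pytest.approx(oracle, abs=1e-8)

    def test_all_exchanges_closed_means_zero_growth(self, toy):
        model, _ = toy
        closed = apply_medium(model, {})
        sol = solve_fba(closed)
        assert sol.optimal
        assert sol.objective_value == pytest.approx(0.0, abs=1e-9)

    def test_generated_optimum_matches_answer_sheet(self, toy):
        model, answers = toy
        for exchange, expected in answers.growth_per_source.items():
            medium = dict(answers.base_medium)
            medium[exchange] = (-10.0, 1000.0)
            sol = solve_fba(apply_medium(model, medium))
            assert sol.objective_value == pytest.approx(expected, abs=1e-6)

    def test_steady_state_mass_conservation(self, toy):
        """|S v|_inf < 1e-6 for every optimal solution."""
        model, answers = toy
        sol = solve_fba(apply_medium(model, glucose_medium(answers)))
        residual = {m: 0.0 for m in model.metabolites}
        for rid, flux in sol.fluxes.items():
            for mid, coeff in model.reactions[rid].stoichiometry.items():
                residual[mid] += coeff * flux
        assert max(abs(v) for v in residual.values()) < 1e-6

    def test_objective_value_reproducible(self, toy):
        model, answers = toy
        medium = glucose_medium(answers)
        values = {solve_fba(apply_medium(model, medium)).objective_value for _ in range(3)}
        assert len(values) == 1

    def test_infeasible_reported_not_raised(self, toy):
        model, _ = toy
        bad = model.copy()
        bad.reactions["ATPM"].lower_bound = 1.0  # forced ATP burn, no fuel
        bad = apply_medium(bad, {})
        assert solve_fba(bad).status == "infeasible"

    def test_minimization_sense(self):
        model = _five_reaction_chain()
        sol = solve_fba(model, sense="min")
        assert sol.objective_value == pytest.approx(0.0, abs=1e-9)

    def test_random_small_networks_match_vertex_enumeration(self):
        """Seeded random bounds on a 6-reaction network: HiGHS optimum equals
        brute-force vertex enumeration every time."""
        rng = np.random.default_rng(42)
        model = _five_reaction_chain()
        for _ in range(10):
            trial = model.copy()
            trial.reactions["EX_s_e"].lower_bound = -float(rng.uniform(1, 20))
            trial.reactions["R2"].upper_bound = float(rng.uniform(0, 10))
            trial.reactions["BIOMASS"].upper_bound = float(rng.uniform(0.1, 3))
            sol = solve_fba(trial)
            oracle = fba_optimum_by_vertex_enumeration(trial)
            assert sol.objective_value == pytest.approx(oracle, abs=1e-8)

    def test_agrees_with_cobrapy_independent_solver(self, toy):
        """Dual-route check: the GLPK solver behind cobrapy reproduces our
        HiGHS growth rate on the same model and medium."""
        from gemkit.io import model_to_cobra

        model, answers = toy
        constrained = apply_medium(model, glucose_medium(answers))
        ours = solve_fba(constrained).objective_value
        cm = model_to_cobra(constrained)
        theirs = cm.optimize().objective_value
        assert ours == pytest.approx(theirs, abs=1e-6)


class TestMedium:
    def test_unknown_exchange_id_is_configuration_error(self, toy):
        model, _ = toy
        with pytest.raises(ValueError, match="EX_ghost_e"):
            apply_medium(model, {"EX_ghost_e": (-10, 1000)})

    def test_unnamed_exchanges_closed_for_uptake_open_for_secretion(self, toy):
        model, answers = toy
        constrained = apply_medium(model, answers.base_medium)
        glc = constrained.reactions["EX_glc__D_e"]
        assert glc.lower_bound == 0.0 and glc.upper_bound > 0

    def test_uptake_relaxation_never_decreases_growth(self, toy):
        """Objective monotonicity in the uptake bound."""
        model, answers = toy
        previous = -1.0
        for uptake in (1.0, 5.0, 10.0, 50.0):
            sol = solve_fba(apply_medium(model, glucose_medium(answers, uptake)))
            assert sol.objective_value >= previous - 1e-9
            previous = sol.objective_value


class TestScreen:
    def test_planted_pathways_and_only_those_grow(self):
        model, answers = make_toy_gem(
            ToyGemSpec(sources=(SourceSpec("glc__D", 6, 0.1), SourceSpec("ac", 2, 0.02)))
        )
        records = screen_carbon_sources(
            model, answers.base_medium, answers.candidate_exchanges
        )
        assert {r.carbon_source_exchange_id: r.grows for r in records} == {
            "EX_glc__D_e": True,
            "EX_ac_e": True,
        }

    def test_disconnected_source_does_not_grow(self):
        model, answers = make_toy_gem(ToyGemSpec(missing_steps=1))
        records = {
            r.carbon_source_exchange_id: r
            for r in screen_carbon_sources(
                model, answers.base_medium, answers.candidate_exchanges
            )
        }
        assert not records[answers.broken_source].grows
        assert records["EX_glc__D_e"].grows

    def test_screen_deterministic(self, toy):
        model, answers = toy
        first = screen_carbon_sources(model, answers.base_medium, answers.candidate_exchanges)
        second = screen_carbon_sources(model, answers.base_medium, answers.candidate_exchanges)
        for a, b in zip(first, second):
            assert a.growth_rate == b.growth_rate
            assert a.grows == b.grows

    def test_anaerobic_mode_blocks_respiratory_sources(self, toy):
        """Closing O2 uptake kills growth on sources that must respire but
        not on the fully assimilated hexose."""
        model, answers = toy
        anaerobic = dict(answers.base_medium)
        anaerobic["EX_o2_e"] = (0.0, 1000.0)
        records = {
            r.carbon_source_exchange_id: r.grows
            for r in screen_carbon_sources(model, anaerobic, answers.candidate_exchanges)
        }
        assert records["EX_glc__D_e"]  # yield 0.1 = full assimilation, no O2
        assert not records["EX_ac_e"]  # partial assimilation requires O2

    def test_byproducts_are_positive_exchange_fluxes(self, toy):
        model, answers = toy
        records = {
            r.carbon_source_exchange_id: r
            for r in screen_carbon_sources(model, answers.base_medium, answers.candidate_exchanges)
        }
        by = records["EX_ac_e"].secreted_byproducts
        assert set(by) == {"EX_co2_e", "EX_h2o_e"}
        assert all(v > 0 for v in by.values())


class TestNormalization:
    def test_per_carbon_arithmetic(self):
        assert normalize_growth(0.6, 6, "per_carbon") == pytest.approx(0.1)
        assert normalize_growth(0.0, 4, "per_carbon") == 0.0

    def test_zero_carbons_rejected(self):
        with pytest.raises(ValueError, match="n_carbons"):
            normalize_growth(0.5, 0, "per_carbon")

    def test_carbon_equivalent_mode_re_solves(self, toy):
        """carbon_equivalent_uptake equals a direct re-solve at uptake 60/n."""
        model, answers = toy
        records = screen_carbon_sources(
            model,
            answers.base_medium,
            answers.candidate_exchanges,
            normalize_mode="carbon_equivalent_uptake",
        )
        for rec in records:
            medium = dict(answers.base_medium)
            medium[rec.carbon_source_exchange_id] = (-60.0 / rec.n_carbons, 1000.0)
            direct = solve_fba(apply_medium(model, medium)).objective_value
            assert rec.normalized_growth == pytest.approx(direct, abs=1e-9)

    def test_both_modes_rank_sources_identically_here(self, toy):
        """With linear pathways, growth scales with uptake, so the two
        normalizations agree up to the factor 6 (glucose-carbon flux)."""
        model, answers = toy
        per_c = screen_carbon_sources(
            model, answers.base_medium, answers.candidate_exchanges, normalize_mode="per_carbon"
        )
        equiv = screen_carbon_sources(
            model,
            answers.base_medium,
            answers.candidate_exchanges,
            normalize_mode="carbon_equivalent_uptake",
        )
        rank = lambda recs: sorted(
            (r.carbon_source_exchange_id for r in recs),
            key=lambda s: next(x.normalized_growth for x in recs if x.carbon_source_exchange_id == s),
        )
        assert rank(per_c) == rank(equiv)

    def test_carbon_count_from_formula(self, toy):
        model, _ = toy
        assert carbon_count(model, "EX_glc__D_e") == 6
        assert carbon_count(model, "EX_ac_e") == 2
        assert carbon_count(model, "EX_o2_e") == 0


class TestSecretion:
    def test_closed_exchange_model_secretes_nothing(self, toy):
        model, _ = toy
        closed = apply_medium(model, {})
        assert predict_secretion(closed, solve_fba(closed)) == {}

    def test_respiring_model_secretes_only_gas_and_water(self, toy):
        model, answers = toy
        medium = dict(answers.base_medium)
        medium["EX_ac_e"] = (-10.0, 1000.0)
        constrained = apply_medium(model, medium)
        secreted = predict_secretion(constrained, solve_fba(constrained))
        assert set(secreted) <= {"EX_co2_e", "EX_h2o_e"}

    def test_requires_optimal_solution(self, toy):
        model, _ = toy
        from gemkit.fba import FluxSolution

        with pytest.raises(ValueError, match="optimal"):
            predict_secretion(model, FluxSolution(status="infeasible", objective_value=0.0))

    def test_sorted_descending(self, toy):
        model, answers = toy
        medium = dict(answers.base_medium)
        medium["EX_cit_e"] = (-10.0, 1000.0)
        constrained = apply_medium(model, medium)
        values = list(predict_secretion(constrained, solve_fba(constrained)).values())
        assert values == sorted(values, reverse=True)
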