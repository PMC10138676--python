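"""Ortholog calling, strain derivation and gap filling."""

import numpy as np
import pandas as pd
import pytest

from conftest import glucose_medium
from gemkit.fba import apply_medium, screen_carbon_sources, solve_fba
from gemkit.reference import call_orthologs_two_pass, exhaustive_gap_fill
from gemkit.strains import (
    call_orthologs,
    derive_strain_model,
    gap_fill,
    multi_gap_fill,
)
from gemkit.synth import ToyGemSpec, make_toy_gem


def _matrix(rows, strains=None, genes=None):
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    genes = genes or [f"g{i}" for i in range(rows.shape[0])]
    strains = strains or [f"s{j}" for j in range(rows.shape[1])]
    return pd.DataFrame(rows, index=genes, columns=strains)


class TestOrthologCalling:
    def test_borderline_gene_rescued_by_prevalence(self):
        """65% identity in one strain is present when >40% identity covers
        80% of strains (threshold relaxes to 40)."""
        pct = _matrix([[65, 80, 85, 90, 30]])  # 4/5 = 80% over 40
        result = call_orthologs(pct)
        assert result.effective_threshold["g0"] == 40.0
        assert bool(result.presence.loc["g0", "s0"]) is True
        assert bool(result.presence.loc["g0", "s4"]) is False

    def test_borderline_gene_dropped_without_prevalence(self):
        pct = _matrix([[65, 80, 30, 20, 10]])  # 2/5 = 40% over 40
        result = call_orthologs(pct)
        assert result.effective_threshold["g0"] == 70.0
        assert bool(result.presence.loc["g0", "s0"]) is False
        assert bool(result.presence.loc["g0", "s1"]) is True

    def test_boundary_semantics_strict(self):
        """Prevalence counts pct strictly over 40, and relaxation needs
        strictly more than 75% of strains."""
        exactly_40 = _matrix([[40, 40, 40, 40]])  # 40 is not "over 40"
        assert call_orthologs(exactly_40).effective_threshold["g0"] == 70.0
        exactly_75 = _matrix([[41, 41, 41, 10]])  # 3/4 = exactly 0.75
        assert call_orthologs(exactly_75).effective_threshold["g0"] == 70.0
        over_75 = _matrix([[41, 41, 41, 41]])
        assert call_orthologs(over_75).effective_threshold["g0"] == 40.0

    def test_randomized_matrix_matches_two_pass_oracle(self):
        rng = np.random.default_rng(7)
        pct = _matrix(rng.uniform(0, 100, size=(50, 20)))
        result = call_orthologs(pct)
        oracle_calls, oracle_thresholds = call_orthologs_two_pass(pct)
        for g in pct.index:
            assert result.effective_threshold[g] == oracle_thresholds[g]
            for s in pct.columns:
                assert bool(result.presence.loc[g, s]) == oracle_calls[g][s]

    def test_empty_strain_set_rejected(self):
        with pytest.raises(ValueError, match="no strains"):
            call_orthologs(pd.DataFrame(index=["g0"], columns=[], dtype=float))


class TestDeriveStrainModel:
    def test_all_genes_present_reproduces_template(self, toy):
        template, _ = toy
        strain = derive_strain_model(template, set(template.genes))
        assert set(strain.reactions) == set(template.reactions)
        assert strain.genes == template.genes

    def test_losing_sole_transporter_gene_kills_that_source(self, toy):
        template, answers = toy
        present = set(template.genes) - {"g_tpt_glc__D"}
        strain = derive_strain_model(template, present)
        assert "T_glc__D" not in strain.reactions
        records = {
            r.carbon_source_exchange_id: r.grows
            for r in screen_carbon_sources(
                strain, answers.base_medium, answers.candidate_exchanges
            )
        }
        assert not records["EX_glc__D_e"]
        assert records["EX_cit_e"]  # other pathways untouched

    def test_isozyme_loss_is_silent_complex_loss_is_not(self, toy):
        """OR-GPR pathways survive losing one isozyme; AND-GPR pathways
        (enzyme complexes) do not survive losing one subunit."""
        template, _ = toy
        strain_or = derive_strain_model(template, set(template.genes) - {"g_cat_glc__Da"})
        assert "CAT_glc__D" in strain_or.reactions  # OR rule, isozyme remains
        # the acetate pathway uses an AND rule (g_cat_aca and g_cat_acb)
        strain_and = derive_strain_model(template, set(template.genes) - {"g_cat_acb"})
        assert "CAT_ac" not in strain_and.reactions

    def test_exchanges_biomass_and_gprless_reactions_always_retained(self, toy):
        template, _ = toy
        strain = derive_strain_model(template, set())
        assert "BIOMASS" in strain.reactions
        assert "ATPM" in strain.reactions  # no GPR
        assert all(rid in strain.reactions for rid in template.exchange_ids())

    def test_strain_reactions_subset_of_template(self, cohort, toy):
        template, _ = toy
        for strain in cohort.strains:
            present = set(cohort.truth_presence.index[cohort.truth_presence[strain]])
            model = derive_strain_model(template, present, strain_id=strain)
            assert set(model.reactions) <= set(template.reactions)

    def test_strain_growth_never_exceeds_template(self, cohort, toy):
        template, answers = toy
        medium = glucose_medium(answers)
        template_growth = solve_fba(apply_medium(template, medium)).objective_value
        for strain in cohort.strains[:4]:
            present = set(cohort.truth_presence.index[cohort.truth_presence[strain]])
            model = derive_strain_model(template, present)
            sol = solve_fba(apply_medium(model, medium))
            growth = sol.objective_value if sol.optimal else 0.0
            assert growth <= template_growth + 1e-9


class TestGapFill:
    def test_already_growing_model_needs_nothing(self, toy):
        model, answers = toy
        result = gap_fill(model, [], medium=glucose_medium(answers))
        assert result.status == "already_growing"
        assert result.added_reaction_ids == []

    @pytest.mark.parametrize("steps", [1, 2])
    def test_planted_gaps_repaired_minimally(self, steps):
        """Planted single/double gap: the MILP returns exactly the removed
        reactions, matching exhaustive subset search."""
        model, answers = make_toy_gem(ToyGemSpec(missing_steps=steps))
        medium = dict(answers.base_medium)
        medium[answers.broken_source] = (-10.0, 1000.0)
        result = gap_fill(model, answers.missing_reactions, medium=medium)
        oracle = exhaustive_gap_fill(
            apply_medium(model, medium), answers.missing_reactions,
            target_growth=1e-6, max_size=3,
        )
        assert result.status == "ok"
        assert sorted(result.added_reaction_ids) == sorted(oracle)
        assert len(result.added_reaction_ids) == steps
        assert result.growth_after > 1e-6

    def test_distractor_donors_not_added(self, toy):
        """With the full template as donor bag the repair is still minimal."""
        template, _ = toy
        model, answers = make_toy_gem(ToyGemSpec(missing_steps=1))
        medium = dict(answers.base_medium)
        medium[answers.broken_source] = (-10.0, 1000.0)
        donor = [r.copy() for r in template.reactions.values()]
        result = gap_fill(model, donor, medium=medium)
        oracle = exhaustive_gap_fill(
            apply_medium(model, medium), donor, target_growth=1e-6, max_size=2
        )
        assert sorted(result.added_reaction_ids) == sorted(oracle) == ["T_xyl__D"]

    def test_unfillable_reported_explicitly(self):
        model, answers = make_toy_gem(ToyGemSpec(missing_steps=2))
        medium = dict(answers.base_medium)
        medium[answers.broken_source] = (-10.0, 1000.0)
        # donor bag missing the catabolic step cannot restore growth
        partial = [r for r in answers.missing_reactions if r.id.startswith("T_")]
        result = gap_fill(model, partial, medium=medium)
        assert result.status == "unfillable"
        assert result.added_reaction_ids == []


class TestMultiGapFill:
    def test_all_growing_cohort_untouched(self, toy, cohort):
        template, answers = toy
        models = {
            s: derive_strain_model(
                template,
                set(cohort.truth_presence.index[cohort.truth_presence[s]]),
                strain_id=s,
            )
            for s in cohort.strains[:4]
        }
        media = {
            src: {**answers.base_medium, src: (-10.0, 1000.0)}
            for src in answers.candidate_exchanges
        }
        results = multi_gap_fill(models, [], media)
        # this seeded cohort keeps at least glucose in every strain
        assert all(r.status == "already_growing" for r in results.values())

    def test_broken_strains_repaired_others_passed_through(self, toy):
        template, answers = toy
        broken_model, broken_answers = make_toy_gem(
            ToyGemSpec(sources=answers_sources_only_last(), missing_steps=1)
        )
        models = {"ok": template.copy(id="ok")}
        for i in range(3):
            models[f"broken{i}"] = broken_model.copy(id=f"broken{i}")
        donor = [r.copy() for r in template.reactions.values()]
        media = {
            broken_answers.broken_source: {
                **broken_answers.base_medium,
                broken_answers.broken_source: (-10.0, 1000.0),
            }
        }
        results = multi_gap_fill(
            models, donor, media, donor_metabolites=template.metabolites
        )
        assert results["ok"].status == "already_growing"
        for i in range(3):
            assert results[f"broken{i}"].status == "ok"
            assert results[f"broken{i}"].added_reaction_ids == ["T_xyl__D"]

    def test_requires_media(self, toy):
        template, _ = toy
        with pytest.raises(ValueError, match="medium"):
            multi_gap_fill({"s": template}, [], {})


def answers_sources_only_last():
    from gemkit.synth import DEFAULT_SOURCES

    return (DEFAULT_SOURCES[-1],)
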