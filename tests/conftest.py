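import pytest

from gemkit.synth import CohortSpec, ToyGemSpec, make_strain_cohort, make_toy_gem


@pytest.fixture(scope="session")
def toy():
    """Clean toy model with its analytic answer sheet."""
    return make_toy_gem(ToyGemSpec(seed=0))


@pytest.fixture(scope="session")
def defective():
    """Toy model with every plantable defect switched on."""
    spec = ToyGemSpec(
        unbalanced_reaction=True,
        charge_unbalanced_reaction=True,
        futile_atp_loop=True,
        n_orphans=2,
        seed=0,
    )
    return make_toy_gem(spec)


@pytest.fixture(scope="session")
def cohort(toy):
    """Small clean cohort (no borderline homology noise) with planted truth."""
    model, answers = toy
    return make_strain_cohort(
        model,
        answers,
        CohortSpec(n_strains=8, deletion_rate=0.1, borderline_frac=0.0, seed=11),
    )


def glucose_medium(answers, uptake=10.0):
    medium = dict(answers.base_medium)
    medium["EX_glc__D_e"] = (-uptake, 1000.0)
    return medium
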