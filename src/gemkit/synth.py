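"""Synthetic fixtures with analytically known answers.

Everything the pipeline consumes can be generated here without downloads:

* **Toy genome-scale models** built from linear catabolic pathways whose
  FBA optimum is forced by construction: each carbon source ``i`` (formula
  (CH2O)_n) is respired via the balanced reaction

      src_i + (n_i - k_i) O2 -> k_i CU + (n_i - k_i) CO2 + (n_i - k_i) H2O

  where CU is a CH2O "carbon unit" and biomass drains 60 CU per unit
  growth, so growth on source i at uptake u is exactly ``k_i/60 * u``
  (the per-unit yield is ``k_i/60``). Catabolism also phosphorylates one
  ADP per substrate, feeding a standard ATP-maintenance reaction. Known
  defects — an unbalanced reaction, a charge-unbalanced reaction, a
  reversible futile ATP loop, orphan metabolites, missing pathway steps —
  can be planted on demand and are recorded in an answer sheet computed by
  construction-time bookkeeping, independent of the modules under test.

* **Strain cohorts** with genes deleted i.i.d. at a planted rate and a
  percent-identity matrix sampled around the deletion truth, optionally
  with a "borderline" fraction of values straddling the 40/70 ortholog
  thresholds.

* **Noisy flux measurements** (Gaussian noise plus magnitude-inflated
  outliers) for exercising the robust flux comparison.

Every generator is a pure function of its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fba import screen_carbon_sources
from .model import DEFAULT_BIG, MetabolicModel, Metabolite, Reaction
from .strains import derive_strain_model

__all__ = [
    "SourceSpec",
    "ToyGemSpec",
    "ToyGemAnswers",
    "CohortSpec",
    "Cohort",
    "make_toy_gem",
    "make_strain_cohort",
    "make_flux_measurements",
    "DEFAULT_SOURCES",
    "BIOMASS_PER_CU",
]

#: Biomass yield per mmol of carbon unit (so a fully assimilated 6-carbon
#: source at uptake 10 gives growth 1.0 h^-1, i.e. per-unit yield 0.1).
BIOMASS_PER_CU = 1.0 / 60.0


@dataclass(frozen=True)
class SourceSpec:
    """One carbon source: BiGG-style base id, carbon count, per-unit yield."""

    name: str
    n_carbons: int
    yield_per_uptake: float  # growth (h^-1) per unit uptake (mmol gDW^-1 h^-1)


#: Default pathway roster: a fully assimilated hexose, a partially respired
#: organic acid, a respired hexose acid and a pentose.
DEFAULT_SOURCES = (
    SourceSpec("glc__D", 6, 0.100),
    SourceSpec("ac", 2, 0.020),
    SourceSpec("cit", 6, 0.050),
    SourceSpec("xyl__D", 5, 0.075),
)


@dataclass
class ToyGemSpec:
    sources: tuple[SourceSpec, ...] = DEFAULT_SOURCES
    unbalanced_reaction: bool = False
    charge_unbalanced_reaction: bool = False
    futile_atp_loop: bool = False
    n_orphans: int = 0
    missing_steps: int = 0  # 0, 1 or 2 steps removed from the last pathway
    seed: int = 0


@dataclass
class ToyGemAnswers:
    """Construction-time bookkeeping: what every audit and solve must find."""

    expected_counts: tuple[int, int, int]  # reactions, metabolites, genes
    growth_per_source: dict[str, float]  # exchange id -> growth at uptake 10
    yield_per_source: dict[str, float]  # exchange id -> growth per unit uptake
    base_medium: dict[str, tuple[float, float]]
    candidate_exchanges: list[str]
    expected_produced_only: list[str]
    expected_consumed_only: list[str]
    unbalanced: dict[str, dict[str, float]]  # reaction -> element imbalance
    charge_unbalanced: dict[str, float]  # reaction -> charge imbalance
    has_energy_cycle: bool
    missing_reactions: list[Reaction]  # donor bag for the planted gaps
    broken_source: str | None  # exchange id whose pathway was broken
    atpm_id: str = "ATPM"


def _met(mid, formula, charge, compartment, name=""):
    return Metabolite(id=mid, name=name or mid, formula=formula, charge=charge,
                      compartment=compartment)


def make_toy_gem(spec: ToyGemSpec | None = None) -> tuple[MetabolicModel, ToyGemAnswers]:
    """Build a toy model and its answer sheet.

    Raises ``ValueError`` for contradictory specs (a yield above the
    stoichiometric maximum n_carbons/60, or more missing steps than the
    pathway has).
    """
    spec = spec or ToyGemSpec()
    if not spec.sources:
        raise ValueError("toy model needs at least one carbon source")
    if spec.missing_steps not in (0, 1, 2):
        raise ValueError("missing_steps must be 0, 1 or 2")

    mets: list[Metabolite] = [
        _met("cu_c", "CH2O", 0, "c", "carbon unit"),
        _met("o2_e", "O2", 0, "e"), _met("o2_c", "O2", 0, "c"),
        _met("co2_e", "CO2", 0, "e"), _met("co2_c", "CO2", 0, "c"),
        _met("h2o_e", "H2O", 0, "e"), _met("h2o_c", "H2O", 0, "c"),
        _met("atp_c", "C10H12N5O13P3", -4, "c"),
        _met("adp_c", "C10H12N5O10P2", -3, "c"),
        _met("pi_c", "HPO4", -2, "c"),
        _met("h_c", "H", 1, "c"),
    ]
    rxns: list[Reaction] = []
    wide = (-DEFAULT_BIG, DEFAULT_BIG)

    def add_rxn(rid, stoich, lb, ub, gpr=""):
        rxns.append(Reaction(id=rid, name=rid, stoichiometry=stoich,
                             lower_bound=lb, upper_bound=ub, gpr=gpr))

    # shared infrastructure: gases/water exchanges, transporters, ATPM
    for base in ("o2", "co2", "h2o"):
        lb = 0.0 if base == "co2" else -DEFAULT_BIG  # CO2 is secretion-only
        add_rxn(f"EX_{base}_e", {f"{base}_e": -1.0}, lb, DEFAULT_BIG)
        add_rxn(f"T_{base}", {f"{base}_e": -1.0, f"{base}_c": 1.0}, *wide)
    add_rxn("ATPM",
            {"atp_c": -1.0, "h2o_c": -1.0, "adp_c": 1.0, "pi_c": 1.0, "h_c": 1.0},
            0.0, DEFAULT_BIG)

    growth, yields = {}, {}
    genes_expected: set[str] = set()
    for i, src in enumerate(spec.sources):
        k = src.yield_per_uptake / BIOMASS_PER_CU
        if k > src.n_carbons + 1e-12:
            raise ValueError(
                f"source {src.name}: yield {src.yield_per_uptake} exceeds the "
                f"stoichiometric maximum {src.n_carbons * BIOMASS_PER_CU:.4g}"
            )
        a = src.n_carbons - k  # O2 / CO2 / H2O coefficient
        n = src.n_carbons
        mets.append(_met(f"{src.name}_e", f"C{n}H{2*n}O{n}", 0, "e"))
        mets.append(_met(f"{src.name}_c", f"C{n}H{2*n}O{n}", 0, "c"))
        add_rxn(f"EX_{src.name}_e", {f"{src.name}_e": -1.0}, *wide)
        tpt_gene = f"g_tpt_{src.name}"
        add_rxn(f"T_{src.name}", {f"{src.name}_e": -1.0, f"{src.name}_c": 1.0},
                0.0, DEFAULT_BIG, gpr=tpt_gene)
        cat_gpr = (
            f"g_cat_{src.name}a or g_cat_{src.name}b" if i % 2 == 0
            else f"g_cat_{src.name}a and g_cat_{src.name}b"
        )
        # respiration core plus one ADP phosphorylation (which condenses
        # out one extra water): src + a O2 + ADP + Pi + H+ ->
        #   k CU + a CO2 + (a+1) H2O + ATP
        stoich = {
            f"{src.name}_c": -1.0,
            "adp_c": -1.0, "pi_c": -1.0, "h_c": -1.0,
            "cu_c": k, "atp_c": 1.0, "h2o_c": 1.0,
        }
        if a > 1e-12:
            stoich["o2_c"] = -a
            stoich["co2_c"] = a
            stoich["h2o_c"] += a
        add_rxn(f"CAT_{src.name}", stoich, 0.0, DEFAULT_BIG, gpr=cat_gpr)
        genes_expected |= {tpt_gene, f"g_cat_{src.name}a", f"g_cat_{src.name}b"}
        growth[f"EX_{src.name}_e"] = 10.0 * src.yield_per_uptake
        yields[f"EX_{src.name}_e"] = src.yield_per_uptake

    add_rxn("BIOMASS", {"cu_c": -1.0 / BIOMASS_PER_CU}, 0.0, DEFAULT_BIG)

    # planted defects ------------------------------------------------------
    unbalanced: dict[str, dict[str, float]] = {}
    charge_unbal: dict[str, float] = {}
    orphans: list[str] = []
    if spec.unbalanced_reaction:
        # combustion of a carbon unit with the water product dropped
        add_rxn("UNBAL_DEFECT", {"cu_c": -1.0, "o2_c": -1.0, "co2_c": 1.0},
                0.0, DEFAULT_BIG)
        unbalanced["UNBAL_DEFECT"] = {"H": -2.0, "O": -1.0}
    if spec.charge_unbalanced_reaction:
        # proton "shadow" species with the same formula but neutral charge
        mets.append(_met("h_shadow_c", "H", 0, "c"))
        add_rxn("CHG_DEFECT", {"h_c": -1.0, "h_shadow_c": 1.0}, *wide)
        charge_unbal["CHG_DEFECT"] = -1.0
    if spec.futile_atp_loop:
        # a phosphotransfer left reversible: its reverse direction makes ATP
        # from ADP+Pi at no cost, closing a cycle with ATPM
        add_rxn("FUTILE_LOOP",
                {"atp_c": -1.0, "h2o_c": -1.0, "adp_c": 1.0, "pi_c": 1.0, "h_c": 1.0},
                *wide)
    for j in range(spec.n_orphans):
        mets.append(_met(f"orphan{j}_c", "CH2O", 0, "c"))
        add_rxn(f"ORPHANSYN{j}", {"cu_c": -1.0, f"orphan{j}_c": 1.0},
                0.0, DEFAULT_BIG)
        orphans.append(f"orphan{j}_c")

    model = MetabolicModel(
        id=f"toy_gem_seed{spec.seed}",
        metabolites=mets,
        reactions=rxns,
        objective_reaction_id="BIOMASS",
        atpm_reaction_id="ATPM",
    )

    # break the last pathway after full assembly so donors keep their GPRs
    missing: list[Reaction] = []
    broken_source = None
    if spec.missing_steps:
        last = spec.sources[-1].name
        broken_source = f"EX_{last}_e"
        for rid in [f"T_{last}", f"CAT_{last}"][: spec.missing_steps]:
            missing.append(model.reactions[rid].copy())
            model.remove_reaction(rid)
        growth[broken_source] = 0.0

    base_medium = {
        "EX_o2_e": (-DEFAULT_BIG, DEFAULT_BIG),
        "EX_co2_e": (0.0, DEFAULT_BIG),
        "EX_h2o_e": (-DEFAULT_BIG, DEFAULT_BIG),
    }
    produced_only = list(orphans)
    consumed_only = []
    if spec.missing_steps == 1:
        # transporter gone: src_c can still be consumed by CAT but nothing
        # produces it
        consumed_only.append(f"{spec.sources[-1].name}_c")
    elif spec.missing_steps == 2:
        # both gone: src_c is disconnected entirely (neither list applies)
        pass

    answers = ToyGemAnswers(
        expected_counts=(len(model.reactions), len(model.metabolites),
                         len(genes_expected)),
        growth_per_source=growth,
        yield_per_source=yields,
        base_medium=base_medium,
        candidate_exchanges=sorted(growth),
        expected_produced_only=produced_only,
        expected_consumed_only=consumed_only,
        unbalanced=unbalanced,
        charge_unbalanced=charge_unbal,
        has_energy_cycle=spec.futile_atp_loop,
        missing_reactions=missing,
        broken_source=broken_source,
    )
    return model, answers


@dataclass
class CohortSpec:
    n_strains: int = 20
    deletion_rate: float = 0.05
    borderline_frac: float = 0.10
    present_range: tuple[float, float] = (85.0, 100.0)
    absent_range: tuple[float, float] = (0.0, 30.0)
    borderline_range: tuple[float, float] = (35.0, 65.0)
    seed: int = 0


@dataclass
class Cohort:
    """A synthetic strain cohort with its planted truth."""

    homology: pd.DataFrame  # genes × strains, percent identity
    truth_presence: pd.DataFrame  # genes × strains, bool
    truth_phenotype: pd.DataFrame  # strains × sources, bool
    strains: list[str] = field(default_factory=list)


def make_strain_cohort(
    template: MetabolicModel,
    answers: ToyGemAnswers,
    spec: CohortSpec | None = None,
    uptake: float = 10.0,
) -> Cohort:
    """Delete template genes i.i.d. per strain and emit the homology matrix.

    The truth phenotype is computed by screening the truth-pruned models —
    generator-side bookkeeping that never touches the ortholog-calling path
    under test. Percent identities are sampled from the presence/absence
    ranges, with a ``borderline_frac`` fraction of entries resampled inside
    the threshold-straddling borderline range.
    """
    spec = spec or CohortSpec()
    if not 0.0 <= spec.deletion_rate <= 1.0:
        raise ValueError("deletion_rate must lie in [0, 1]")
    rng = np.random.default_rng(spec.seed)
    genes = sorted(template.genes)
    strains = [f"S{i:03d}" for i in range(spec.n_strains)]

    deleted = rng.random((len(genes), spec.n_strains)) < spec.deletion_rate
    truth = pd.DataFrame(~deleted, index=genes, columns=strains)

    pct = np.where(
        truth.values,
        rng.uniform(*spec.present_range, size=truth.shape),
        rng.uniform(*spec.absent_range, size=truth.shape),
    )
    if spec.borderline_frac > 0:
        borderline = rng.random(truth.shape) < spec.borderline_frac
        pct = np.where(
            borderline, rng.uniform(*spec.borderline_range, size=truth.shape), pct
        )
    homology = pd.DataFrame(pct, index=genes, columns=strains)

    phenotype = pd.DataFrame(
        False, index=strains, columns=answers.candidate_exchanges
    )
    for strain in strains:
        present = set(truth.index[truth[strain]])
        strain_model = derive_strain_model(template, present, strain_id=strain)
        records = screen_carbon_sources(
            strain_model,
            answers.base_medium,
            answers.candidate_exchanges,
            uptake=uptake,
            normalize_mode=None,
        )
        for rec in records:
            phenotype.loc[strain, rec.carbon_source_exchange_id] = rec.grows
    return Cohort(
        homology=homology,
        truth_presence=truth,
        truth_phenotype=phenotype,
        strains=strains,
    )


def make_flux_measurements(
    true_fluxes: dict[str, float] | pd.Series,
    noise_sd: float = 0.0,
    outlier_frac: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a measured-flux table: truth + Gaussian noise + outliers.

    A fraction ``outlier_frac`` of reactions is replaced by ten times its
    (noisy) magnitude, emulating gross measurement errors. Output follows
    the measured-flux TSV layout (index reaction_id; columns flux,
    orientation).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if not 0.0 <= outlier_frac < 1.0:
        raise ValueError("outlier_frac must lie in [0, 1)")
    series = pd.Series(true_fluxes, dtype=float)
    rng = np.random.default_rng(seed)
    measured = series + rng.normal(0.0, noise_sd, size=len(series))
    if outlier_frac > 0:
        n_out = int(round(outlier_frac * len(series)))
        if n_out:
            idx = rng.choice(len(series), size=n_out, replace=False)
            measured.iloc[idx] = measured.iloc[idx] * 10.0
    return pd.DataFrame(
        {"flux": measured, "orientation": 1},
        index=pd.Index(series.index, name="reaction_id"),
    )
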