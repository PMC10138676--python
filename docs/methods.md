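# Methods

## Constraint-based model and FBA

A model is a stoichiometric network: metabolites with elemental formula,
charge and compartment (`c` cytosol, `e` extracellular; other codes are
accepted on read and flagged), reactions with flux bounds in
mmol gDW⁻¹ h⁻¹ and boolean gene–protein–reaction (GPR) rules, and a
biomass pseudo-reaction whose flux is the specific growth rate (h⁻¹).
Exchange reactions are single-metabolite boundary reactions on
extracellular species; uptake is negative flux, following the BiGG/COBRA
convention. Flux balance analysis solves `max c·v` subject to `S·v = 0`
and `lb ≤ v ≤ ub` with the HiGHS simplex behind `scipy.optimize.linprog`
(primal/dual feasibility 1e-9). Infeasibility and unboundedness are
reported as solution statuses, never exceptions, so cohort screens can
continue past broken strains. Alternate optima are not enumerated: screens
compare objective values and binary growth calls, which are
degeneracy-invariant, rather than individual fluxes.

Applying a medium sets the named exchange bounds verbatim and closes every
other exchange for uptake while leaving secretion open (upper bound 1000,
the conventional "unconstrained" magnitude). Aerobic screens leave O₂
uptake unconstrained; anaerobic mode closes it. The ATP-maintenance lower
bound is honored as read. Growth calls use a threshold of 1e-6 h⁻¹ —
safely above LP tolerance, far below any real growth rate.

Two growth normalizations by carbon count n_C are provided, since either
is defensible and published heatmaps rarely say which was used:
`per_carbon` divides the rate by n_C (the default), and
`carbon_equivalent_uptake` re-solves with the uptake bound set to 60/n_C,
equalizing carbon flux to glucose at uptake 10. On linear pathways the two
rank sources identically; they differ when uptake is not the binding
constraint. Sources with unknown formulas are skipped with a warning
rather than guessed.

## QC audits

*Balance*: per non-boundary reaction, Σ coeff·count(element) and
Σ coeff·charge; anything above 1e-9 is an imbalance. Biomass and exchange
reactions are exempt (pseudo-stoichiometric by design). Formulas are
parsed as Hill-style element runs; polymeric `R`/`X` groups mark the
reaction `unknown_formula` instead of fabricating a verdict.

*Dead ends*: a metabolite is produced-only (consumed-only) when no
reaction can consume (produce) it under current bounds; reversible
reactions count in both directions. These species force zero steady-state
flux through their reactions.

*Energy-generating cycles*: close every exchange to [0,0], relax the
ATP-maintenance lower bound to 0 and maximize its flux. Any optimum above
1e-6 certifies a thermodynamically impossible ATP-from-nothing loop
(classically, a carboxylase left reversible). The maintenance reaction id
is configurable because naming conventions vary between reconstructions.

The audits detect and report only; repair is a curation decision we never
automate.

## Ortholog calling and strain derivation

Presence of template gene g in strain s requires percent identity
pct(g,s) ≥ 70. For genes with pct > 40 (strict) in more than 75% (strict)
of strains, the threshold drops to 40 for all strains — near-ubiquitous
moderate-identity genes are treated as conserved orthologs. Prevalence is
evaluated per gene. Boundary semantics are strict on the relaxation
conditions and inclusive on the threshold comparison; with ties this
matters, so the choices are fixed and tested.

Derivation prunes template reactions whose GPR evaluates false for the
strain's gene set (AND = all complex members required, OR = any isozyme).
Reactions without gene evidence — spontaneous reactions, orphan
transporters — plus exchanges and the biomass reaction are always
retained: deleting them would fabricate evidence of absence. Strain
reaction sets are therefore subsets of the template, and strain growth
never exceeds template growth on any medium.

## Gap filling

Strains growing on none of the configured media are repaired by a
mixed-integer program over the union of the strain network and a donor
bag (default: the template's reactions, metabolite definitions included):
steady state, native bounds, biomass ≥ target, and per donor reaction j a
binary indicator y_j with `lb_j·y_j ≤ v_j ≤ ub_j·y_j`; the objective
minimizes Σy_j with small per-reaction epsilon weights (ε < 1/(4n²)) that
break cardinality ties lexicographically by reaction id, making results
deterministic. Solved with `scipy.optimize.milp` (HiGHS).

Numerical choice: the MILP's internal growth target is
`max(threshold, min(1e-3, full_bag_growth/2))` rather than the raw 1e-6
threshold. With a 1e-6 target the required donor flux (~1e-5) fits inside
the big-M link of an indicator at y ≈ 1e-8, which the solver's integrality
tolerance rounds to zero — the MILP would report an empty repair.
Feasibility at the user's threshold is decided by an exact LP on the full
bag before the MILP runs, and the returned subset is verified by an exact
LP afterwards, so the contract ("grows above threshold, minimum
cardinality") is unchanged. On donor bags small enough to search
exhaustively, the MILP provably returns the same minimum (tested).

## Panphenome

The growth matrix holds raw, normalized and binary layers. Sources are
classified by the fraction f of strains growing: universal (f > 0.90),
core (0.30 ≤ f ≤ 0.90, boundaries inclusive — "between" read literally),
strain-specific (f < 0.30). Counting is exact, so classes are invariant to
strain order and depend only on the binary layer.

Strains are clustered agglomeratively on Manhattan distances over the
normalized layer (configurable), complete linkage by default — a robust
choice with L1 distances; Ward is excluded as incoherent with non-Euclidean
metrics. The k=2 cut labels the group with the higher mean count of
growth-supporting sources HMV, the other LMV; HMV is re-cut (k=2) into α/β
subgroups when it has more than two members. All-identical profiles are
reported as a single degenerate cluster with labeling skipped. Exports:
matrices in dendrogram leaf order, per-source class annotations, per-strain
cluster labels, JSON classification and a Newick dendrogram.

## Biweight midcorrelation

For vector x with median m and unscaled MAD (no 1.4826 consistency factor,
matching the canonical definition with the fixed 9·MAD denominator):
u_i = (x_i − m)/(9·MAD), w_i = (1 − u_i²)²·1[|u_i| < 1],
x̃_i = (x_i − m)·w_i, and bicor = Σx̃ỹ/√(Σx̃²·Σỹ²). Inputs need n ≥ 3 and
nonzero MAD on both sides; degenerate inputs raise explicit errors, and
pathway comparisons report them as skipped. Significance uses a seeded
permutation test ((1+exceed)/(1+N), N = 10⁴ by default) because typical
pathway panels have fewer than ten reactions, too small for the
t-approximation. Measured fluxes reported against the reverse of a model
reaction are negated via the per-reaction orientation column of the
measured table.

## Synthetic data: what it emulates, and what it does not

The toy generator builds aerobic catabolic pathways with exactly known
optima: source i (formula (CH₂O)ₙ) is converted by
`src + (n−k) O₂ + ADP + Pi + H⁺ → k CU + (n−k) CO₂ + (n−k+1) H₂O + ATP`,
where CU is a CH₂O carbon unit and biomass drains 60 CU per unit growth,
so growth at uptake u is exactly (k/60)·u. All non-boundary reactions are
elementally and charge balanced, there are no dead ends, and the
energy-cycle check is 0 — unless a defect is planted: a reaction missing
one H₂O (element excess H:−2, O:−1), a neutral "proton shadow" species
(charge −1 imbalance), a reversible phosphotransfer closing an ATP loop,
k orphan metabolites, or 1–2 missing pathway steps whose reactions form
the gap-fill donor truth. Default roster: a fully assimilated hexose
(yield 0.1 — glucose-like), an acetate-like C2 acid (0.02), a citrate-like
C6 acid (0.05) and a pentose (0.075), values in the range reported for
aerobic heterotrophic growth.

Cohorts delete genes i.i.d. per strain (default 5%, within the 2–10% span
typical of intra-species gene-content variation); percent identity samples
U[85,100] for present genes, U[0,30] for absent ones, and a borderline
fraction (default 10%) resamples entries in U[35,65] to straddle the 40/70
thresholds and stress the relaxation rule. Truth phenotypes are computed
by screening the truth-pruned models — construction-side bookkeeping,
independent of the ortholog-calling path under test. Flux measurements add
Gaussian noise and replace a fraction of reactions with 10× magnitude
outliers. Every generator is a pure function of its seed.

What passing these tests shows: the algorithms are correct on networks
whose ground truth is known. What it does not show: performance on real
genome-scale reconstructions, whose pathways are branched and interlocked,
whose GPRs are deeper, whose homology distributions are not two clean
blocks, and whose biomass functions couple dozens of precursors. The toy
networks deliberately do not mimic real *B. subtilis* topology or genome
scale; verification problem sizes (tens of reactions, 8–20 strains,
50-gene matrices) were chosen so every brute-force reference — vertex
enumeration, exhaustive subset search, truth-table enumeration — remains
exact.

## Known limitations

- No flux variability analysis, pFBA, MOMA or kinetic integration; no
  nitrogen-source screening.
- Gap filling minimizes reaction count only; no likelihood weighting of
  donor reactions, and the default donor bag is the template (a universal
  reaction database can be supplied, but none ships with the package).
- The balance auditor does not attempt formula inference for species with
  unknown composition.
- Permutation p-values are exact only in distribution; at N = 10⁴ their
  resolution is ~1e-4.
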