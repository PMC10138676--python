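"""Model and table I/O.

Models are read and written in two community formats:

* COBRA JSON (schema v1) — handled natively; the schema is a flat dict of
  metabolites/reactions/genes.
* SBML Level 3 + FBC v2 — delegated to cobrapy's libsbml-backed reader and
  writer through a lossless converter between :class:`~gemkit.model.MetabolicModel`
  and ``cobra.Model``.

Tabular inputs (medium definitions, homology matrices, measured fluxes) are
plain TSV read with pandas.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import pandas as pd

from .model import DEFAULT_BIG, MetabolicModel, Metabolite, Reaction

__all__ = [
    "read_model",
    "write_model",
    "read_medium_tsv",
    "write_medium_tsv",
    "read_homology_tsv",
    "write_homology_tsv",
    "read_measured_fluxes_tsv",
    "ModelParseError",
]


class ModelParseError(ValueError):
    """A model file failed to parse; the message names the offending element."""


# ---------------------------------------------------------------------------
# COBRA JSON (native)
# ---------------------------------------------------------------------------

def _model_to_json_dict(model: MetabolicModel) -> dict:
    return {
        "id": model.id,
        "version": "1",
        "metabolites": [
            {
                "id": m.id,
                "name": m.name,
                "compartment": m.compartment,
                "formula": m.formula,
                "charge": m.charge,
            }
            for m in model.metabolites.values()
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "metabolites": dict(r.stoichiometry),
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "gene_reaction_rule": r.gpr,
                "objective_coefficient": (
                    1.0 if r.id == model.objective_reaction_id else 0.0
                ),
            }
            for r in model.reactions.values()
        ],
        "genes": [{"id": g, "name": g} for g in sorted(model.genes)],
        "compartments": {"c": "cytosol", "e": "extracellular space"},
        "annotation": (
            {"atpm_reaction_id": model.atpm_reaction_id} if model.atpm_reaction_id else {}
        ),
    }


def _model_from_json_dict(data: dict, source: str) -> MetabolicModel:
    try:
        mets = [
            Metabolite(
                id=m["id"],
                name=m.get("name", ""),
                formula=m.get("formula") or "",
                charge=m.get("charge"),
                compartment=m.get("compartment", "c"),
            )
            for m in data["metabolites"]
        ]
        objective_id = None
        rxns = []
        for r in data["reactions"]:
            if float(r.get("objective_coefficient", 0.0)) != 0.0:
                objective_id = r["id"]
            rxns.append(
                Reaction(
                    id=r["id"],
                    name=r.get("name", ""),
                    stoichiometry={k: float(v) for k, v in r["metabolites"].items()},
                    lower_bound=float(r.get("lower_bound", -DEFAULT_BIG)),
                    upper_bound=float(r.get("upper_bound", DEFAULT_BIG)),
                    gpr=r.get("gene_reaction_rule", "") or "",
                )
            )
    except KeyError as exc:
        raise ModelParseError(f"{source}: missing required field {exc}") from exc
    atpm = (data.get("annotation") or {}).get("atpm_reaction_id")
    model = MetabolicModel(
        id=data.get("id", Path(source).stem),
        metabolites=mets,
        reactions=rxns,
        objective_reaction_id=objective_id,
        atpm_reaction_id=atpm,
    )
    # genes listed but never used in a GPR still belong to the model
    model.genes |= {g["id"] for g in data.get("genes", ())}
    return model


# ---------------------------------------------------------------------------
# cobra.Model conversion (SBML backend + interop)
# ---------------------------------------------------------------------------

def model_to_cobra(model: MetabolicModel):
    """Convert to a ``cobra.Model`` (used for SBML I/O and interop)."""
    import cobra

    cm = cobra.Model(model.id)
    cobra_mets = {
        m.id: cobra.Metabolite(
            m.id,
            name=m.name,
            formula=m.formula or None,
            charge=m.charge,
            compartment=m.compartment,
        )
        for m in model.metabolites.values()
    }
    cobra_rxns = []
    for r in model.reactions.values():
        cr = cobra.Reaction(r.id, name=r.name)
        cr.lower_bound = r.lower_bound
        cr.upper_bound = r.upper_bound
        cobra_rxns.append(cr)
    cm.add_reactions(cobra_rxns)
    for r in model.reactions.values():
        cr = cm.reactions.get_by_id(r.id)
        cr.add_metabolites({cobra_mets[mid]: c for mid, c in r.stoichiometry.items()})
        if r.gpr:
            cr.gene_reaction_rule = r.gpr
    if model.objective_reaction_id is not None:
        cm.objective = model.objective_reaction_id
    return cm


def model_from_cobra(cm, atpm_reaction_id: str | None = None) -> MetabolicModel:
    """Convert a ``cobra.Model`` into a :class:`MetabolicModel`."""
    mets = [
        Metabolite(
            id=m.id,
            name=m.name or "",
            formula=m.formula or "",
            charge=m.charge,
            compartment=m.compartment or "c",
        )
        for m in cm.metabolites
    ]
    objective_id = None
    for r in cm.reactions:
        if r.objective_coefficient:
            objective_id = r.id
    rxns = [
        Reaction(
            id=r.id,
            name=r.name or "",
            stoichiometry={m.id: float(c) for m, c in r.metabolites.items()},
            lower_bound=float(r.lower_bound),
            upper_bound=float(r.upper_bound),
            gpr=r.gene_reaction_rule or "",
        )
        for r in cm.reactions
    ]
    model = MetabolicModel(
        id=cm.id or "model",
        metabolites=mets,
        reactions=rxns,
        objective_reaction_id=objective_id,
        atpm_reaction_id=atpm_reaction_id,
    )
    model.genes |= {g.id for g in cm.genes}
    return model


# ---------------------------------------------------------------------------
# Public reader/writer
# ---------------------------------------------------------------------------

def _infer_format(path: Path, format: str | None) -> str:
    if format is not None:
        if format not in ("sbml", "json"):
            raise ValueError(f"unknown model format {format!r}; expected 'sbml' or 'json'")
        return format
    suffix = path.suffix.lower()
    if suffix in (".xml", ".sbml"):
        return "sbml"
    if suffix == ".json":
        return "json"
    raise ValueError(f"cannot infer model format from {path.name!r}; pass format=")


def read_model(path: str | Path, format: str | None = None) -> MetabolicModel:
    """Read a model from COBRA JSON or SBML L3+FBC.

    ``format`` is inferred from the file suffix when omitted. Malformed
    files raise :class:`ModelParseError` naming the offending element.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt == "json":
        try:
            data = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise ModelParseError(f"{path}: invalid JSON ({exc})") from exc
        return _model_from_json_dict(data, str(path))
    import cobra.io

    try:
        cm = cobra.io.read_sbml_model(str(path))
    except Exception as exc:
        raise ModelParseError(f"{path}: SBML parse failed ({exc})") from exc
    return model_from_cobra(cm)


def write_model(model: MetabolicModel, path: str | Path, format: str | None = None) -> None:
    """Write a model as COBRA JSON or SBML L3+FBC (round-trip stable)."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "json":
        path.write_text(json.dumps(_model_to_json_dict(model), indent=1, sort_keys=False))
        return
    import cobra.io

    cobra.io.write_sbml_model(model_to_cobra(model), str(path))


# ---------------------------------------------------------------------------
# Tabular formats
# ---------------------------------------------------------------------------

def read_medium_tsv(path: str | Path) -> dict[str, tuple[float, float]]:
    """Read a medium TSV (columns: exchange_id, lb, ub) into a bounds dict."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"exchange_id", "lb", "ub"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: medium TSV needs columns {sorted(required)}")
    medium = {}
    for row in df.itertuples(index=False):
        lb, ub = float(row.lb), float(row.ub)
        if math.isinf(lb):
            lb = -DEFAULT_BIG
        if math.isinf(ub):
            ub = DEFAULT_BIG
        medium[str(row.exchange_id)] = (lb, ub)
    return medium


def write_medium_tsv(medium: dict[str, tuple[float, float]], path: str | Path) -> None:
    df = pd.DataFrame(
        [(k, lb, ub) for k, (lb, ub) in medium.items()],
        columns=["exchange_id", "lb", "ub"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_homology_tsv(path: str | Path) -> pd.DataFrame:
    """Read a gene×strain percent-identity matrix (genes as row index).

    Missing values are filled with 0 (no detectable homolog); values are
    validated to lie in [0, 100].
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df = df.fillna(0.0).astype(float)
    if ((df.values < 0) | (df.values > 100)).any():
        raise ValueError(f"{path}: homology percentages must lie in [0, 100]")
    return df


def write_homology_tsv(pct: pd.DataFrame, path: str | Path) -> None:
    pct.to_csv(path, sep="\t")


def read_measured_fluxes_tsv(path: str | Path) -> pd.DataFrame:
    """Read a measured-flux table (columns: reaction_id, flux[, orientation]).

    ``orientation`` is +1 when the measurement follows the model reaction's
    direction and -1 when it was reported for the reverse reaction; it
    defaults to +1.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    if not {"reaction_id", "flux"}.issubset(df.columns):
        raise ValueError(f"{path}: measured-flux TSV needs columns reaction_id, flux")
    if "orientation" not in df.columns:
        df["orientation"] = 1
    df["orientation"] = df["orientation"].astype(int)
    if not set(df["orientation"]) <= {1, -1}:
        raise ValueError(f"{path}: orientation must be +1 or -1")
    return df.set_index("reaction_id")
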