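"""End-to-end orchestration: derive strains, gap-fill, screen, classify,
cluster, export.

Each stage writes its artifacts to the run directory (strain models as
COBRA JSON, matrices as TSV) before the next stage starts, so a failed run
leaves inspectable partial output and any stage can be re-run in isolation
from the previous stage's files. The full configuration is serialized into
the output directory for provenance.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as gio
from .fba import GROWTH_THRESHOLD
from .model import MetabolicModel
from .panphenome import (
    build_growth_matrix,
    classify_sources,
    cluster_strains,
    export_heatmap_data,
    SPECIFIC_FRACTION,
    UNIVERSAL_FRACTION,
)
from .strains import (
    call_orthologs,
    derive_strain_model,
    multi_gap_fill,
    PREVALENCE,
    PRIMARY_THRESHOLD,
    RELAXED_THRESHOLD,
)

__all__ = ["RunConfig", "PipelineResult", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one panphenome run."""

    template_path: str
    homology_path: str
    medium_path: str
    sources: list[str] = field(default_factory=list)  # exchange ids to screen
    out_dir: str = "panphenome_run"
    primary_threshold: float = PRIMARY_THRESHOLD
    relaxed_threshold: float = RELAXED_THRESHOLD
    prevalence: float = PREVALENCE
    universal_fraction: float = UNIVERSAL_FRACTION
    specific_fraction: float = SPECIFIC_FRACTION
    growth_threshold: float = GROWTH_THRESHOLD
    uptake: float = 10.0
    normalize_mode: str = "per_carbon"
    cluster_layer: str = "normalized"
    linkage_method: str = "complete"
    seed: int = 0

    def validate(self) -> None:
        if not 0 <= self.relaxed_threshold <= self.primary_threshold <= 100:
            raise ValueError("need 0 <= relaxed <= primary <= 100")
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence must lie in (0, 1)")
        if not 0 <= self.specific_fraction <= self.universal_fraction <= 1:
            raise ValueError("need 0 <= specific <= universal <= 1")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls(**data)


@dataclass
class PipelineResult:
    strain_models: dict[str, MetabolicModel]
    gap_fill_results: dict
    growth_matrix: object
    classification: object
    clustering: object
    n_non_functional: int
    out_dir: Path


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run derive → multi-gap-fill → screen → classify → cluster → export.

    Returns the in-memory results; all stage artifacts are also written
    under ``config.out_dir``. Raises on unusable input (e.g. an empty
    strain set); per-strain failures inside a stage are logged and flagged,
    never fatal to the cohort.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(
        json.dumps(dataclasses.asdict(config), indent=1)
    )

    template = gio.read_model(config.template_path)
    homology = gio.read_homology_tsv(config.homology_path)
    medium = gio.read_medium_tsv(config.medium_path)
    sources = config.sources or sorted(
        rid for rid in template.exchange_ids() if rid not in medium
    )
    if homology.shape[1] == 0:
        raise ValueError("no strains in homology matrix")
    logger.info("pipeline: %d strains, %d candidate sources",
                homology.shape[1], len(sources))

    # stage 1: ortholog calling + strain derivation
    presence = call_orthologs(
        homology,
        primary=config.primary_threshold,
        relaxed=config.relaxed_threshold,
        prevalence=config.prevalence,
    )
    presence.presence.astype(int).to_csv(out / "presence.tsv", sep="\t")
    strain_dir = out / "strains"
    strain_dir.mkdir(exist_ok=True)
    strain_models = {}
    for strain in presence.presence.columns:
        model = derive_strain_model(
            template, presence.strain_genes(strain), strain_id=strain
        )
        strain_models[strain] = model
        gio.write_model(model, strain_dir / f"{strain}.json")

    # stage 2: gap-fill strains that grow on no source
    media = {}
    for src in sources:
        m = dict(medium)
        m[src] = (-config.uptake, m.get(src, (0.0, 1000.0))[1])
        media[src] = m
    donor = [template.reactions[r].copy() for r in template.reactions]
    gf_results = multi_gap_fill(
        strain_models, donor, media,
        target_growth=config.growth_threshold,
        donor_metabolites=template.metabolites,
    )
    repaired = 0
    for strain, res in gf_results.items():
        if res.status == "ok" and res.added_reaction_ids:
            model = strain_models[strain]
            for rid in res.added_reaction_ids:
                model.add_reaction(template.reactions[rid].copy())
            gio.write_model(model, strain_dir / f"{strain}.json")
            repaired += 1
    pd.DataFrame(
        [
            {
                "strain": r.strain_id,
                "status": r.status,
                "medium": r.medium_name,
                "growth_before": r.growth_before,
                "growth_after": r.growth_after,
                "added": ";".join(r.added_reaction_ids),
            }
            for r in gf_results.values()
        ]
    ).to_csv(out / "gap_fill.tsv", sep="\t", index=False)

    non_functional = [s for s, r in gf_results.items() if r.status == "unfillable"]
    functional = {s: m for s, m in strain_models.items() if s not in non_functional}
    logger.info("pipeline: %d functional models (%d repaired, %d non-functional)",
                len(functional), repaired, len(non_functional))
    if not functional:
        raise ValueError("no functional strain models; nothing to screen")

    # stage 3–5: screen, classify, cluster
    matrix = build_growth_matrix(
        functional,
        sources,
        medium,
        uptake=config.uptake,
        normalize_mode=config.normalize_mode,
        growth_threshold=config.growth_threshold,
    )
    classification = classify_sources(
        matrix,
        universal=config.universal_fraction,
        specific=config.specific_fraction,
    )
    clustering = cluster_strains(
        matrix, layer=config.cluster_layer, linkage_method=config.linkage_method
    )
    annotations = pd.DataFrame(
        {"model_genes": {s: len(m.genes) for s, m in functional.items()},
         "model_reactions": {s: len(m.reactions) for s, m in functional.items()}}
    )
    export_heatmap_data(matrix, classification, clustering, out,
                        strain_annotations=annotations)
    return PipelineResult(
        strain_models=strain_models,
        gap_fill_results=gf_results,
        growth_matrix=matrix,
        classification=classification,
        clustering=clustering,
        n_non_functional=len(non_functional),
        out_dir=out,
    )
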