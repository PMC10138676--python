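"""Panphenome construction: strain×carbon-source growth matrix, source
classification and metabolic-versatility clustering.

The panphenome of a species is the union of in-silico growth phenotypes of
its strain models. Sources are classified by the fraction of strains they
support: *universal* (> 90% of strains grow), *core* (30–90%, inclusive)
and *strain-specific* (< 30%). Strains are hierarchically clustered on
their growth profiles with Manhattan distance; the two-group cut separates
high- from low-metabolic-versatility strains (HMV / LMV), with an optional
k=2 re-cut of HMV into α/β subgroups.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy.spatial.distance import pdist

from .fba import GROWTH_THRESHOLD, screen_carbon_sources
from .model import MetabolicModel

__all__ = [
    "GrowthMatrix",
    "SourceClassification",
    "StrainClustering",
    "build_growth_matrix",
    "classify_sources",
    "cluster_strains",
    "export_heatmap_data",
    "UNIVERSAL_FRACTION",
    "SPECIFIC_FRACTION",
]

logger = logging.getLogger(__name__)

UNIVERSAL_FRACTION = 0.90
SPECIFIC_FRACTION = 0.30


@dataclass
class GrowthMatrix:
    """Strain×source growth rates: raw (h^-1), normalized, and binary calls."""

    raw_growth: pd.DataFrame
    normalized_growth: pd.DataFrame
    binary_growth: pd.DataFrame
    failed_strains: list[str] = field(default_factory=list)

    @property
    def strains(self) -> list[str]:
        return list(self.raw_growth.index)

    @property
    def carbon_sources(self) -> list[str]:
        return list(self.raw_growth.columns)

    def layer(self, name: str) -> pd.DataFrame:
        return {
            "raw": self.raw_growth,
            "normalized": self.normalized_growth,
            "binary": self.binary_growth,
        }[name]


def build_growth_matrix(
    strain_models: dict[str, MetabolicModel],
    sources: list[str],
    base_medium: dict[str, tuple[float, float]],
    uptake: float = 10.0,
    normalize_mode: str | None = "per_carbon",
    growth_threshold: float = GROWTH_THRESHOLD,
) -> GrowthMatrix:
    """Screen every strain model against every carbon source.

    One FBA screen per strain (one solve per source). A strain whose screen
    raises is recorded in ``failed_strains`` with a row of zeros, and the
    cohort run continues.
    """
    raw = pd.DataFrame(0.0, index=list(strain_models), columns=sources)
    norm = raw.copy()
    failed = []
    for strain_id, model in strain_models.items():
        try:
            records = screen_carbon_sources(
                model,
                base_medium,
                sources,
                uptake=uptake,
                normalize_mode=normalize_mode,
                growth_threshold=growth_threshold,
            )
        except Exception as exc:
            logger.error("screen failed for strain %s: %s", strain_id, exc)
            failed.append(strain_id)
            continue
        for rec in records:
            raw.loc[strain_id, rec.carbon_source_exchange_id] = rec.growth_rate
            norm.loc[strain_id, rec.carbon_source_exchange_id] = (
                rec.normalized_growth if rec.normalized_growth is not None else np.nan
            )
    binary = raw > growth_threshold
    return GrowthMatrix(
        raw_growth=raw,
        normalized_growth=norm if normalize_mode is not None else raw.copy(),
        binary_growth=binary,
        failed_strains=failed,
    )


@dataclass
class SourceClassification:
    """Panphenome class per carbon source, with the growth fraction behind it."""

    classes: dict[str, str]  # source -> universal | core | strain_specific
    growth_fraction: dict[str, float]

    def sources_in(self, cls: str) -> list[str]:
        return [s for s, c in self.classes.items() if c == cls]


def classify_sources(
    matrix: GrowthMatrix,
    universal: float = UNIVERSAL_FRACTION,
    specific: float = SPECIFIC_FRACTION,
) -> SourceClassification:
    """Classify sources by the fraction of strains they support.

    f > universal → universal; specific <= f <= universal → core;
    f < specific → strain_specific. The boundaries belong to the core class
    (read inclusively). Counting is exact, so classes depend only on the
    binary layer and the two thresholds.
    """
    if matrix.binary_growth.empty:
        raise ValueError("cannot classify an empty growth matrix")
    fractions = matrix.binary_growth.mean(axis=0)
    classes = {}
    for source, f in fractions.items():
        if f > universal:
            classes[source] = "universal"
        elif f < specific:
            classes[source] = "strain_specific"
        else:
            classes[source] = "core"
    return SourceClassification(classes=classes, growth_fraction=dict(fractions))


@dataclass
class StrainClustering:
    """Hierarchical clustering of strains on their growth profiles."""

    linkage_matrix: np.ndarray | None
    leaf_order: list[str]
    labels: dict[str, str]  # strain -> HMV | LMV (or "all" when degenerate)
    hmv_subgroups: dict[str, str] = field(default_factory=dict)  # strain -> alpha|beta
    degenerate: bool = False


def _newick(node, names) -> str:
    if node.is_leaf():
        return names[node.id]
    left = _newick(node.get_left(), names)
    right = _newick(node.get_right(), names)
    return f"({left}:{node.get_left().dist:.6g},{right}:{node.get_right().dist:.6g})"


def cluster_strains(
    matrix: GrowthMatrix,
    layer: str = "normalized",
    linkage_method: str = "complete",
    k: int = 2,
) -> StrainClustering:
    """Cluster strains with Manhattan distance and label the versatility groups.

    Agglomerative clustering (default complete linkage) on the chosen
    growth layer, cut into ``k`` groups. The group with the higher mean
    count of growth-supporting sources is labeled HMV, the other LMV. The
    HMV group is re-cut (k=2) into α/β subgroups when it has more than two
    members. With all-identical profiles clustering is degenerate: a single
    cluster is reported and labeling skipped.
    """
    data = matrix.layer(layer).fillna(0.0)
    strains = list(data.index)
    if len(strains) < 2:
        raise ValueError("clustering needs at least 2 strains")
    X = data.values
    if np.allclose(X, X[0]):
        return StrainClustering(
            linkage_matrix=None,
            leaf_order=strains,
            labels={s: "all" for s in strains},
            degenerate=True,
        )
    distances = pdist(X, metric="cityblock")
    Z = linkage(distances, method=linkage_method)
    order = [strains[i] for i in leaves_list(Z)]
    assignment = fcluster(Z, t=k, criterion="maxclust")

    positive_counts = matrix.binary_growth.sum(axis=1)
    group_means = {
        g: positive_counts[[s for s, a in zip(strains, assignment) if a == g]].mean()
        for g in sorted(set(assignment))
    }
    hmv_group = max(group_means, key=lambda g: (group_means[g], -g))
    labels = {
        s: ("HMV" if a == hmv_group else "LMV") for s, a in zip(strains, assignment)
    }

    subgroups: dict[str, str] = {}
    hmv_strains = [s for s in strains if labels[s] == "HMV"]
    if len(hmv_strains) > 2:
        sub = data.loc[hmv_strains].values
        if not np.allclose(sub, sub[0]):
            sub_Z = linkage(pdist(sub, metric="cityblock"), method=linkage_method)
            sub_assign = fcluster(sub_Z, t=2, criterion="maxclust")
            sub_counts = positive_counts[hmv_strains]
            sub_means = {
                g: sub_counts[[s for s, a in zip(hmv_strains, sub_assign) if a == g]].mean()
                for g in sorted(set(sub_assign))
            }
            alpha = max(sub_means, key=lambda g: (sub_means[g], -g))
            subgroups = {
                s: ("alpha" if a == alpha else "beta")
                for s, a in zip(hmv_strains, sub_assign)
            }
    return StrainClustering(
        linkage_matrix=Z,
        leaf_order=order,
        labels=labels,
        hmv_subgroups=subgroups,
    )


def export_heatmap_data(
    matrix: GrowthMatrix,
    classification: SourceClassification,
    clustering: StrainClustering,
    out_dir: str | Path,
    strain_annotations: pd.DataFrame | None = None,
) -> dict[str, Path]:
    """Write the heatmap bundle: matrices in leaf order, class annotations,
    cluster labels, classification JSON and a Newick dendrogram.

    ``strain_annotations`` (optional) carries side-annotation columns such
    as total genome genes and model genes per strain.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    order = clustering.leaf_order
    paths = {}
    for name in ("raw", "normalized", "binary"):
        df = matrix.layer(name).loc[order]
        if name == "binary":
            df = df.astype(int)
        p = out_dir / f"growth_{name}.tsv"
        df.to_csv(p, sep="\t")
        paths[name] = p

    ann = pd.DataFrame(
        {
            "class": pd.Series(classification.classes),
            "growth_fraction": pd.Series(classification.growth_fraction),
        }
    )
    ann.index.name = "carbon_source"
    paths["sources"] = out_dir / "source_classes.tsv"
    ann.loc[matrix.carbon_sources].to_csv(paths["sources"], sep="\t")

    strain_df = pd.DataFrame(
        {
            "cluster": pd.Series(clustering.labels),
            "hmv_subgroup": pd.Series(clustering.hmv_subgroups, dtype=object),
        }
    ).reindex(order)
    strain_df.index.name = "strain"
    if strain_annotations is not None:
        strain_df = strain_df.join(strain_annotations)
    paths["strains"] = out_dir / "strain_clusters.tsv"
    strain_df.to_csv(paths["strains"], sep="\t")

    paths["classification"] = out_dir / "classification.json"
    paths["classification"].write_text(
        json.dumps(
            {
                "classes": classification.classes,
                "growth_fraction": classification.growth_fraction,
            },
            indent=1,
            sort_keys=True,
        )
    )

    if clustering.linkage_matrix is not None:
        from scipy.cluster.hierarchy import to_tree

        tree = to_tree(clustering.linkage_matrix)
        strains = list(matrix.strains)
        paths["dendrogram"] = out_dir / "dendrogram.nwk"
        paths["dendrogram"].write_text(_newick(tree, strains) + ";\n")
    return paths
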