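"""End-to-end orchestration: build the reference map, predict new ILs.

``build_reference_model`` runs descriptors → autoscaling → PCA → Ward
clustering → property overlays and packs the result into a single
serializable :class:`ModelBundle`.  ``predict_new`` replays the projection
side of that pipeline for query ILs: descriptors, map coordinates, nearest
cluster, and the four qualitative property levels.  Every stage logs one
structured line; everything is deterministic given (inputs, config).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import constitutional
from .chem_io import ILRecord, StructureParseError, ValidationError, parse_structure
from .chemspace import (ChemSpaceModel, ScalingStats, autoscale, fit_pca,
                        interpret_loadings, project)
from .clustering import ClusterModel, assign_cluster, cut_and_label, ward_linkage
from .constitutional import constitutional_vector, il_vector, IL_REGISTRY
from .elements import ELEMENT_TABLE_VERSION
from .property_map import (DEFAULT_BIN_EDGES, DEFAULT_LEVEL_CUTS,
                           DEFAULT_TREND_WEIGHTS, PROPERTIES, PropertyRecord,
                           bin_to_levels, qualitative_predict,
                           standardize_property, trend_scores)

log = logging.getLogger("ilpc")


@dataclass(frozen=True)
class PipelineConfig:
    n_components: int = 2
    k_clusters: int = 6
    loading_threshold: float = 0.7
    bin_edges: tuple[float, ...] = DEFAULT_BIN_EDGES
    trend_weights: dict = field(default_factory=lambda: {
        k: list(v) for k, v in DEFAULT_TREND_WEIGHTS.items()})
    level_cuts: tuple[float, float] = DEFAULT_LEVEL_CUTS

    def hash(self) -> str:
        doc = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(doc.encode()).hexdigest()[:16]


@dataclass(frozen=True)
class ModelBundle:
    """Everything needed to place and interpret a new IL on the map."""

    stats: ScalingStats
    chemspace: ChemSpaceModel
    clusters: ClusterModel
    training_trends: dict[str, list[float]]     # property -> trend scores
    property_z: dict[str, dict[str, float]]     # property -> il_id -> z
    config: PipelineConfig
    registry_version: str = constitutional.REGISTRY_VERSION
    element_table_version: str = ELEMENT_TABLE_VERSION

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "stats": {"names": list(self.stats.names),
                      "mean": self.stats.mean.tolist(),
                      "sd": self.stats.sd.tolist(),
                      "dropped": list(self.stats.dropped)},
            "chemspace": {"loadings": self.chemspace.loadings.tolist(),
                          "eigenvalues": self.chemspace.eigenvalues.tolist(),
                          "explained_fraction": self.chemspace.explained_fraction.tolist(),
                          "training_scores": self.chemspace.training_scores.tolist(),
                          "n_components": self.chemspace.n_components,
                          "descriptor_names": list(self.chemspace.descriptor_names),
                          "il_ids": list(self.chemspace.il_ids)},
            "clusters": {"linkage": self.clusters.linkage.tolist(),
                         "k": self.clusters.k,
                         "labels": list(self.clusters.labels),
                         "centroids": self.clusters.centroids.tolist(),
                         "centroid_labels": list(self.clusters.centroid_labels)},
            "training_trends": self.training_trends,
            "property_z": self.property_z,
            "config": asdict(self.config),
            "registry_version": self.registry_version,
            "element_table_version": self.element_table_version,
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "ModelBundle":
        required = ("stats", "chemspace", "clusters", "training_trends",
                    "property_z", "config", "registry_version")
        missing = [k for k in required if k not in doc]
        if missing:
            from .chem_io import SchemaError
            raise SchemaError(f"bundle document missing field(s) {missing}")
        s, c, cl = doc["stats"], doc["chemspace"], doc["clusters"]
        cfg = doc["config"]
        registry = doc["registry_version"]
        if registry != constitutional.REGISTRY_VERSION:
            from .chem_io import SchemaError
            raise SchemaError(f"bundle registry {registry!r} does not match "
                              f"{constitutional.REGISTRY_VERSION!r}")
        unknown = [n for n in s["names"] if n not in IL_REGISTRY]
        if unknown:
            from .chem_io import SchemaError
            raise SchemaError(f"bundle names unknown to the registry: {unknown[:5]}")
        return cls(
            stats=ScalingStats(names=tuple(s["names"]),
                               mean=np.asarray(s["mean"]),
                               sd=np.asarray(s["sd"]),
                               dropped=tuple(s["dropped"])),
            chemspace=ChemSpaceModel(
                loadings=np.asarray(c["loadings"]),
                eigenvalues=np.asarray(c["eigenvalues"]),
                explained_fraction=np.asarray(c["explained_fraction"]),
                training_scores=np.asarray(c["training_scores"]),
                n_components=int(c["n_components"]),
                descriptor_names=tuple(c["descriptor_names"]),
                il_ids=tuple(c["il_ids"])),
            clusters=ClusterModel(linkage=np.asarray(cl["linkage"]),
                                  k=int(cl["k"]),
                                  labels=tuple(cl["labels"]),
                                  centroids=np.asarray(cl["centroids"]),
                                  centroid_labels=tuple(cl["centroid_labels"])),
            training_trends={k: list(map(float, v))
                             for k, v in doc["training_trends"].items()},
            property_z={k: {i: float(z) for i, z in v.items()}
                        for k, v in doc["property_z"].items()},
            config=PipelineConfig(
                n_components=cfg["n_components"], k_clusters=cfg["k_clusters"],
                loading_threshold=cfg["loading_threshold"],
                bin_edges=tuple(cfg["bin_edges"]),
                trend_weights=cfg["trend_weights"],
                level_cuts=tuple(cfg["level_cuts"])),
            registry_version=registry,
            element_table_version=doc.get("element_table_version",
                                          ELEMENT_TABLE_VERSION),
        )

    def hash(self) -> str:
        doc = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(doc.encode()).hexdigest()

    def trend_weight_map(self) -> dict[str, tuple[float, float]]:
        return {k: tuple(v) for k, v in self.config.trend_weights.items()}


def descriptor_table(records: list[ILRecord]) -> pd.DataFrame:
    """82-column descriptor matrix, one row per IL, indexed by il_id."""
    rows = {}
    for r in records:
        vec = il_vector(constitutional_vector(r.cation),
                        constitutional_vector(r.anion), r.il_id)
        rows[r.il_id] = vec.values
    df = pd.DataFrame.from_dict(rows, orient="index")
    df = df[list(IL_REGISTRY)]
    df.index.name = "il_id"
    return df


def build_reference_model(records: list[ILRecord],
                          properties: list[PropertyRecord],
                          config: PipelineConfig | None = None) -> ModelBundle:
    """Fit the full reference map from IL structures and measured properties."""
    config = config or PipelineConfig()
    if len(records) < 10:
        raise ValueError(f"reference model needs >= 10 ILs, got {len(records)}")
    if not properties:
        raise ValueError("reference model needs at least one property record")

    X = descriptor_table(records)
    log.info("stage=descriptors ils=%d columns=%d", len(X), X.shape[1])

    scaled, stats = autoscale(X)
    log.info("stage=autoscale retained=%d dropped=%d (%s)",
             len(stats.names), len(stats.dropped), ",".join(stats.dropped))

    model = fit_pca(scaled, n_components=config.n_components)
    log.info("stage=pca components=%d explained=%s", config.n_components,
             np.round(model.explained_fraction, 4).tolist())

    linkage = ward_linkage(model.training_scores, ids=model.il_ids)
    clusters = cut_and_label(linkage, model.training_scores, k=config.k_clusters)
    log.info("stage=cluster k=%d sizes=%s", config.k_clusters,
             {lab: list(clusters.labels).count(lab)
              for lab in clusters.centroid_labels})

    weights = {k: tuple(v) for k, v in config.trend_weights.items()}
    training_trends: dict[str, list[float]] = {p: [] for p in weights}
    for pc in model.training_scores:
        ts = trend_scores(float(pc[0]), float(pc[1]) if len(pc) > 1 else 0.0, weights)
        for prop, val in ts.items():
            training_trends[prop].append(float(val))

    property_z: dict[str, dict[str, float]] = {}
    prop_df = pd.DataFrame([{"il_id": p.il_id, "property": p.property,
                             "value": p.value} for p in properties])
    for prop, grp in prop_df.groupby("property"):
        if len(grp) < 2 or grp["value"].nunique() < 2:
            log.info("stage=overlay property=%s skipped (too few distinct values)", prop)
            continue
        z = standardize_property(grp["value"].to_numpy(), property=str(prop))
        property_z[str(prop)] = {str(i): float(v)
                                 for i, v in zip(grp["il_id"], z)}
    log.info("stage=overlay properties=%s", sorted(property_z))

    return ModelBundle(stats=stats, chemspace=model, clusters=clusters,
                       training_trends=training_trends, property_z=property_z,
                       config=config)


def predict_new(bundle: ModelBundle, records: list[ILRecord] | pd.DataFrame
                ) -> pd.DataFrame:
    """Project query ILs onto the fitted map and predict property levels.

    Accepts parsed records or a raw table (il_id, cation_smiles,
    anion_smiles); unparsable rows yield an ``error`` entry while the rest
    are still processed.  Any number of query ILs is accepted.
    """
    weights = bundle.trend_weight_map()
    rows = []
    items: list[tuple[str, ILRecord | None, str | None]] = []
    if isinstance(records, pd.DataFrame):
        for _, row in records.iterrows():
            il_id = str(row["il_id"])
            try:
                rec = ILRecord(il_id=il_id,
                               cation=parse_structure(str(row["cation_smiles"])),
                               anion=parse_structure(str(row["anion_smiles"])))
                items.append((il_id, rec, None))
            except (StructureParseError, ValidationError) as exc:
                items.append((il_id, None, str(exc)))
    else:
        items = [(r.il_id, r, None) for r in records]

    for il_id, rec, error in items:
        if error is not None:
            rows.append({"il_id": il_id, "error": error})
            continue
        vec = il_vector(constitutional_vector(rec.cation),
                        constitutional_vector(rec.anion), il_id)
        pcs = project(bundle.chemspace, bundle.stats, vec.values)
        pc1, pc2 = float(pcs[0]), float(pcs[1]) if len(pcs) > 1 else 0.0
        label, dists, tie = assign_cluster(bundle.clusters, pcs)
        ts = trend_scores(pc1, pc2, weights)
        pred = qualitative_predict(
            il_id, ts,
            {p: np.asarray(v) for p, v in bundle.training_trends.items()},
            label, cuts=bundle.config.level_cuts, pc1=pc1)
        flags = list(pred.flags) + (["cluster-tie"] if tie else [])
        rows.append({
            "il_id": il_id, "PC1": pc1, "PC2": pc2, "cluster": label,
            "visc_level": pred.levels.get("viscosity"),
            "kow_level": pred.levels.get("Kow"),
            "sol_level": pred.levels.get("solubility"),
            "dhf_level": pred.levels.get("enthalpy_of_fusion"),
            "flags": ";".join(flags), "error": "",
        })
    out = pd.DataFrame(rows)
    log.info("stage=predict ils=%d errors=%d", len(out),
             int((out.get("error", "") != "").sum()) if "error" in out else 0)
    return out


def plot_map(bundle: ModelBundle, predictions: pd.DataFrame | None,
             path, highlight_cap: int = 10) -> None:
    """Score plot of the reference map with up to ``highlight_cap`` queries."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 6))
    scores = bundle.chemspace.training_scores
    for lab in bundle.clusters.centroid_labels:
        mask = np.array([l == lab for l in bundle.clusters.labels])
        ax.scatter(scores[mask, 0], scores[mask, 1], s=25, alpha=0.7,
                   label=f"cluster {lab}")
    if predictions is not None:
        ok = predictions[predictions["error"] == ""].head(highlight_cap)
        ax.scatter(ok["PC1"], ok["PC2"], marker="*", s=180, c="black",
                   zorder=5, label="query")
        for _, r in ok.iterrows():
            ax.annotate(r["il_id"], (r["PC1"], r["PC2"]),
                        textcoords="offset points", xytext=(5, 5), fontsize=8)
    frac = bundle.chemspace.explained_fraction
    ax.set_xlabel(f"PC1 ({100 * frac[0]:.1f} %)")
    ax.set_ylabel(f"PC2 ({100 * frac[1]:.1f} %)" if len(frac) > 1 else "PC2")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
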