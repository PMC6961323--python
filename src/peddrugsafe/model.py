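"""The top-level modelling interface.

:class:`DrugSafetyModel` bundles the whole estimation procedure — pair
counting, hypergeometric enrichment with Bonferroni control, Jaccard
drug-drug distances, bootstrap-stability k selection, k-means drug
clustering, kernel diagnosis sets, and (when a label table is supplied)
per-cluster 0-5 safety scoring — behind a statsmodels-style
``model.fit() -> results`` pair.  Every artifact of the pipeline hangs off
the :class:`DrugSafetyResults` object, which can summarise itself and
persist all tables plus a reproducibility manifest.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass, replace

import numpy as np
import pandas as pd

from . import __version__
from ._seeds import derive_seed
from .cluster import (
    ClusteringConfig,
    DrugClustering,
    cluster_drugs,
    cluster_hierarchy,
    embed_2d,
    hierarchy_to_newick,
    kernel_diagnoses,
    select_k,
)
from .distance import distance_matrix
from .enrichment import build_pairs, enrich, significance_matrix
from .io import (
    DrugLabelTable,
    EncounterTable,
    read_drug_labels,
    read_encounters,
    write_matrix,
    write_table,
)
from .safety import (
    assign_safety_levels,
    cluster_safety,
    overall_safety,
    safety_distribution,
)


class DrugSafetyModel:
    """Pediatric drug-safety profile estimated from encounter-level EMRs.

    Parameters
    ----------
    encounters : EncounterTable
        Long-format medication and diagnosis events.
    labels : DrugLabelTable, optional
        Pediatric labeling metadata; when given, fit() also scores safety.
    alpha : float
        Family-wise error-rate level for Bonferroni-adjusted significance.
    clustering : ClusteringConfig, optional
        k range, bootstrap resamples, restarts; defaults to the 10..50
        range.  ``k`` fixes the cluster count and skips model selection.
    family : {"nonzero", "all"}
        Bonferroni family: observed pairs only, or all drug x diagnosis
        cells.
    """

    def __init__(
        self,
        encounters: EncounterTable,
        labels: DrugLabelTable | None = None,
        alpha: float = 0.05,
        clustering: ClusteringConfig | None = None,
        k: int | None = None,
        family: str = "nonzero",
    ):
        self.encounters = encounters
        self.labels = labels
        self.alpha = alpha
        self.clustering_config = clustering or ClusteringConfig()
        self.k = k
        self.family = family

    @classmethod
    def from_files(
        cls,
        medications,
        diagnoses,
        labels=None,
        sep=None,
        **kwargs,
    ) -> "DrugSafetyModel":
        enc = read_encounters(medications=medications, diagnoses=diagnoses, sep=sep)
        lab = read_drug_labels(labels, sep=sep) if labels is not None else None
        return cls(enc, labels=lab, **kwargs)

    def fit(self, seed: int = 0) -> "DrugSafetyResults":
        """Run the full pipeline deterministically under ``seed``."""
        cfg = replace(self.clustering_config, seed=derive_seed(seed, "clustering"))
        pairs = build_pairs(self.encounters)
        assoc = enrich(pairs, alpha=self.alpha, family=self.family)
        binmat = significance_matrix(assoc)
        distmat = distance_matrix(binmat)

        n_drugs = len(distmat)
        degenerate = int(binmat.to_numpy().sum()) == 0
        profile = None
        if degenerate:
            # no significant association anywhere: every drug's diagnosis
            # set is empty and all distances are 0, so the only defensible
            # partition is a single cluster
            clustering = DrugClustering(
                labels=pd.Series(1, index=distmat.index, name="cluster_id"), k=1
            )
        elif self.k is not None:
            clustering = cluster_drugs(
                distmat, self.k, seed=derive_seed(seed, "kmeans"),
                n_init=cfg.n_init, method=cfg.method,
            )
        else:
            k_min = min(cfg.k_min, max(2, n_drugs - 1))
            k_max = min(cfg.k_max, n_drugs - 1)
            cfg = replace(cfg, k_min=k_min, k_max=max(k_min, k_max))
            k_best, profile = select_k(distmat, cfg)
            clustering = cluster_drugs(
                distmat, k_best, seed=derive_seed(seed, "kmeans"),
                n_init=cfg.n_init, method=cfg.method,
            )
            clustering.stability = float(
                profile.loc[profile["k"] == k_best, "mean_jaccard"].iloc[0]
            )
            clustering.stability_profile = profile

        clustering.kernel_sets = kernel_diagnoses(
            clustering, binmat, min_share=cfg.kernel_min_share
        )
        hierarchy = None
        if clustering.k >= 2:
            hierarchy = cluster_hierarchy(clustering.kernel_sets)
        embedding = embed_2d(distmat) if n_drugs >= 3 else None

        safety_by_drug = cluster_table = distribution = overall = None
        if self.labels is not None:
            safety_by_drug = assign_safety_levels(self.labels)
            cluster_table = cluster_safety(clustering, safety_by_drug)
            distribution = safety_distribution(clustering, safety_by_drug)
            overall = overall_safety(
                safety_by_drug[safety_by_drug["drug_code"].isin(clustering.labels.index)]
            )

        return DrugSafetyResults(
            model=self,
            seed=seed,
            pairs=pairs,
            associations=assoc,
            significance=binmat,
            distances=distmat,
            clustering=clustering,
            hierarchy=hierarchy,
            embedding=embedding,
            safety_by_drug=safety_by_drug,
            cluster_safety=cluster_table,
            safety_distribution=distribution,
            overall_safety=overall,
        )


@dataclass
class DrugSafetyResults:
    """Fitted drug-safety profile: all pipeline artifacts plus summaries."""

    model: DrugSafetyModel
    seed: int
    pairs: object
    associations: object
    significance: pd.DataFrame
    distances: pd.DataFrame
    clustering: DrugClustering
    hierarchy: tuple | None
    embedding: pd.DataFrame | None
    safety_by_drug: pd.DataFrame | None
    cluster_safety: pd.DataFrame | None
    safety_distribution: pd.DataFrame | None
    overall_safety: dict | None

    def summary(self) -> str:
        enc = self.model.encounters
        a = self.associations
        lines = [
            "Pediatric drug-safety profile",
            "=" * 64,
            f"Encounters: {enc.n_encounters}    Drugs: {len(enc.drugs)}    "
            f"Diagnoses: {len(enc.diagnoses)}",
            f"Drug-diagnosis pairs (N): {self.pairs.N}",
            f"Tested pairs (m): {a.m}    alpha: {a.alpha}",
            f"Significant associations: {a.n_significant}",
            "",
            f"Clusters (k): {self.clustering.k}",
        ]
        if self.clustering.stability is not None:
            lines.append(
                f"Bootstrap stability at k: {self.clustering.stability:.3f}"
            )
        sizes = self.clustering.sizes()
        lines.append("Cluster sizes: " + ", ".join(f"{c}:{s}" for c, s in sizes.items()))
        if self.cluster_safety is not None:
            lines += [
                "",
                "Per-cluster pediatric safety level (mean +/- sample SD):",
                self.cluster_safety.round(3).to_string(index=False),
                (
                    f"Overall: n={self.overall_safety['n_drugs']} "
                    f"mean={self.overall_safety['mean_level']:.2f} "
                    f"sd={self.overall_safety['sd_level']:.2f}"
                ),
            ]
        return "\n".join(lines)

    def plot_embedding(self, ax=None):
        """Scatter of the 2-D classical-MDS embedding coloured by cluster."""
        import matplotlib.pyplot as plt

        if self.embedding is None:
            raise ValueError("no embedding (fewer than 3 drugs)")
        if ax is None:
            _, ax = plt.subplots()
        labs = self.clustering.labels.reindex(self.embedding.index)
        ax.scatter(
            self.embedding["mds1"], self.embedding["mds2"], c=labs, cmap="tab20", s=18
        )
        ax.set_xlabel("MDS 1")
        ax.set_ylabel("MDS 2")
        return ax

    def save(self, outdir, sep="\t", input_paths=None) -> dict:
        """Write every artifact as delimited text plus ``manifest.json``.

        Returns the manifest.  ``input_paths`` may list input files whose
        checksums should be recorded.
        """
        os.makedirs(outdir, exist_ok=True)
        written = {}

        def _put(name, writer):
            path = os.path.join(outdir, name)
            writer(path)
            written[name] = path

        _put("associations.tsv", lambda p: write_table(self.associations.table, p, sep))
        _put("significance_matrix.tsv", lambda p: write_matrix(self.significance, p, sep))
        _put("distance_matrix.tsv", lambda p: write_matrix(self.distances, p, sep))
        part = self.clustering.labels.rename_axis("drug_code").reset_index()
        _put("partition.tsv", lambda p: write_table(part, p, sep))
        if self.clustering.stability_profile is not None:
            _put(
                "stability_profile.tsv",
                lambda p: write_table(self.clustering.stability_profile, p, sep),
            )
        kern = pd.DataFrame(
            [
                (c, g)
                for c, s in self.clustering.kernel_sets.items()
                for g in sorted(s)
            ],
            columns=["cluster_id", "diagnosis_code"],
        )
        _put("kernel_sets.tsv", lambda p: write_table(kern, p, sep))
        if self.hierarchy is not None:
            Z, ids = self.hierarchy
            newick = hierarchy_to_newick(Z, [f"cluster_{i}" for i in ids])
            _put(
                "cluster_hierarchy.nwk",
                lambda p: open(p, "w").write(newick + "\n"),
            )
        if self.embedding is not None:
            _put(
                "embedding.tsv",
                lambda p: write_table(
                    self.embedding.rename_axis("drug_code").reset_index(), p, sep
                ),
            )
        if self.safety_by_drug is not None:
            _put("safety_levels.tsv", lambda p: write_table(self.safety_by_drug, p, sep))
            _put("cluster_safety.tsv", lambda p: write_table(self.cluster_safety, p, sep))
            _put(
                "safety_distribution.tsv",
                lambda p: write_matrix(self.safety_distribution, p, sep),
            )

        manifest = {
            "package_version": __version__,
            "seed": self.seed,
            "alpha": self.model.alpha,
            "family": self.model.family,
            "clustering_config": asdict(self.model.clustering_config),
            "k": self.clustering.k,
            "n_significant": self.associations.n_significant,
            "artifacts": sorted(written),
            "inputs": {},
        }
        for p in input_paths or []:
            with open(p, "rb") as fh:
                manifest["inputs"][os.path.basename(str(p))] = hashlib.sha256(
                    fh.read()
                ).hexdigest()
        with open(os.path.join(outdir, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2)
        return manifest
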