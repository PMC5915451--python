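"""Orchestration of the full distance-matrix analysis.

From the five raw tables, :func:`run_full_analysis` builds the breed,
human (surname), ecological, historical and geographic distance matrices
and produces:

* simple Mantel tests of breeds against each explanatory matrix;
* partial Mantel tests of breeds against human / ecological / historical
  distances with geography as covariate;
* four correlograms — three partial (classes on the explanatory matrix,
  geography partialled out) and one simple over geographic classes;
* one MRM of breeds on all four explanatory matrices;
* Ward dendrograms and neighbor-joining trees for the breed, human,
  ecological and historical matrices.

All randomness flows from a single seed through a SeedSequence spawn, so
reports are reproducible bit for bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import som as _som
from .correlogram import CorrelogramResult, MantelCorrelogram
from .distances import (breed_composition_distances, ecological_distances,
                        geographic_distances, historical_distances)
from .mantel import MantelResult, MantelTest
from .matrix import DistanceMatrix
from .mrm import DistanceMatrixRegression, MRMResult
from .regions import RegionSet
from .trees import Dendrogram, UnrootedTree, neighbor_joining, ward_cluster

EXPLANATORY = ("human", "ecological", "historical", "geographic")
TREE_THEMES = ("breeds", "human", "ecological", "historical")


@dataclass(frozen=True)
class AnalysisOptions:
    """Analysis settings shared by the CLI and the library entry point."""

    n_permutations: int = 10000
    n_classes: int | None = None          # None -> Sturges
    alpha: float = 0.05
    seed: int = 0
    min_records: int = 20
    concentration_threshold: float = 0.5
    som_grid: tuple[int, int] = (10, 10)
    som_epochs: int = 50
    use_som: bool = True
    correlogram_classes_on: str = "explanatory"   # or "geography"
    tail: str = "greater"


@dataclass
class AnalysisReport:
    """Everything the full analysis produces, with provenance metadata."""

    matrices: dict[str, DistanceMatrix]
    simple_mantel: dict[str, MantelResult]
    partial_mantel: dict[str, MantelResult]
    correlograms: dict[str, CorrelogramResult]
    mrm: MRMResult
    dendrograms: dict[str, Dendrogram]
    nj_trees: dict[str, UnrootedTree]
    surname_classification: _som.SurnameClassification | None
    options: AnalysisOptions
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "matrix_checksums": {k: m.checksum()
                                 for k, m in self.matrices.items()},
            "simple_mantel": {k: r.to_dict()
                              for k, r in self.simple_mantel.items()},
            "partial_mantel": {k: r.to_dict()
                               for k, r in self.partial_mantel.items()},
            "correlograms": {k: c.to_dict()
                             for k, c in self.correlograms.items()},
            "mrm": self.mrm.to_dict(),
            "newick": {k: t.to_newick() for k, t in self.nj_trees.items()},
            "metadata": self.metadata,
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)

    def checksum(self) -> str:
        import hashlib
        return hashlib.sha256(
            self.to_json(sort_keys=True).encode()).hexdigest()[:16]

    def summary(self) -> str:
        parts = ["Full distance-matrix analysis",
                 "=============================", ""]
        parts.append("Simple Mantel tests (breeds ~ X):")
        for k, r in self.simple_mantel.items():
            parts.append(f"  {k:<12} r_M = {r.statistic: .3f}  "
                         f"p = {r.p_value:.4g}")
        parts.append("Partial Mantel tests (breeds ~ X | geographic):")
        for k, r in self.partial_mantel.items():
            parts.append(f"  {k:<12} r_M = {r.statistic: .3f}  "
                         f"p = {r.p_value:.4g}")
        parts += ["", self.mrm.summary(), ""]
        for k, c in self.correlograms.items():
            parts += [c.summary(), ""]
        return "\n".join(parts)

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        (directory / "report.json").write_text(self.to_json(indent=2))
        for k, m in self.matrices.items():
            m.to_csv(directory / f"distances_{k}.csv")
        for k, c in self.correlograms.items():
            c.to_csv(directory / f"correlogram_{k}.csv")
        self.mrm.to_frame().to_csv(directory / "mrm.csv", index=False)
        for k in self.nj_trees:
            (directory / f"nj_{k}.nwk").write_text(
                self.nj_trees[k].to_newick() + "\n")
            self.dendrograms[k].to_merge_csv(directory / f"ward_{k}.csv")
        if self.surname_classification is not None:
            self.surname_classification.to_csv(
                directory / "surname_classification.csv")


def infer_regions(tables: dict[str, pd.DataFrame]) -> RegionSet:
    """Region set from the centroid table's row order."""
    return RegionSet(str(r) for r in tables["centroids"]["region"])


def build_distance_matrices(tables: dict[str, pd.DataFrame],
                            options: AnalysisOptions = AnalysisOptions(),
                            regions: RegionSet | None = None,
                            rng: np.random.Generator | None = None):
    """The five pipeline matrices (plus the surname classification)."""
    if regions is None:
        regions = infer_regions(tables)
    if rng is None:
        rng = np.random.default_rng(options.seed)

    profiles = _som.surname_profiles(tables["surname_counts"], regions,
                                     min_records=options.min_records)
    if options.use_som:
        som_seed = int(rng.integers(2 ** 31))
        model = _som.train_som(profiles, grid_rows=options.som_grid[0],
                               grid_cols=options.som_grid[1],
                               epochs=options.som_epochs, seed=som_seed)
        classification = _som.classify_surnames(
            model, profiles, regions,
            concentration_threshold=options.concentration_threshold)
    else:
        classification = _som.concentration_classification(
            profiles, regions,
            concentration_threshold=options.concentration_threshold)

    matrices = {
        "breeds": breed_composition_distances(tables["breed_census"], regions),
        "human": _som.surname_distances(tables["surname_counts"],
                                        classification, regions),
        "ecological": ecological_distances(tables["occupancy"], regions),
        "historical": historical_distances(tables["membership"], regions),
        "geographic": geographic_distances(tables["centroids"], regions),
    }
    return matrices, classification


def run_full_analysis(tables: dict[str, pd.DataFrame],
                      options: AnalysisOptions = AnalysisOptions()
                      ) -> AnalysisReport:
    """Run the complete analysis; see the module docstring."""
    seedseq = np.random.SeedSequence(options.seed)
    streams = seedseq.spawn(16)
    rng_build = np.random.default_rng(streams[0])

    matrices, classification = build_distance_matrices(
        tables, options, rng=rng_build)
    breeds = matrices["breeds"]
    geo = matrices["geographic"]

    simple = {}
    for i, key in enumerate(EXPLANATORY):
        simple[key] = MantelTest(breeds, matrices[key], tail=options.tail).fit(
            options.n_permutations, np.random.default_rng(streams[1 + i]))

    partial = {}
    for i, key in enumerate(("human", "ecological", "historical")):
        partial[key] = MantelTest(breeds, matrices[key], covariate=geo,
                                  tail=options.tail).fit(
            options.n_permutations, np.random.default_rng(streams[5 + i]))

    correlograms = {}
    for i, key in enumerate(("human", "ecological", "historical")):
        classifier = (matrices[key]
                      if options.correlogram_classes_on == "explanatory"
                      else geo)
        model = MantelCorrelogram(breeds, classifier, covariate=geo,
                                  n_classes=options.n_classes)
        correlograms[key] = model.fit(
            n_permutations=options.n_permutations, alpha=options.alpha,
            seed=np.random.default_rng(streams[8 + i]))
    correlograms["geographic"] = MantelCorrelogram(
        breeds, geo, covariate=None, n_classes=options.n_classes).fit(
        n_permutations=options.n_permutations, alpha=options.alpha,
        seed=np.random.default_rng(streams[11]))

    mrm = DistanceMatrixRegression(
        breeds, [matrices[k] for k in EXPLANATORY],
        names=list(EXPLANATORY)).fit(
        options.n_permutations, np.random.default_rng(streams[12]))

    dendrograms = {k: ward_cluster(matrices[k]) for k in TREE_THEMES}
    nj_trees = {k: neighbor_joining(matrices[k]) for k in TREE_THEMES}

    meta = {
        "seed": options.seed,
        "n_permutations": options.n_permutations,
        "alpha": options.alpha,
        "tail": options.tail,
        "n_regions": len(breeds.regions),
        "n_monophyletic_surnames": len(classification.monophyletic),
        "n_polyphyletic_surnames": len(classification.polyphyletic),
        "correlogram_classes_on": options.correlogram_classes_on,
    }
    return AnalysisReport(matrices=matrices, simple_mantel=simple,
                          partial_mantel=partial, correlograms=correlograms,
                          mrm=mrm, dendrograms=dendrograms, nj_trees=nj_trees,
                          surname_classification=classification,
                          options=options, metadata=meta)
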