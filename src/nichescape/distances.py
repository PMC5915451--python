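"""Builders for the breed, ecological, historical and geographic matrices.

All four constructions are Euclidean: each maps every region to a feature
vector (within-group breed proportions, species occupancy fractions,
one-hot political-division membership, planar coordinates) and returns the
pairwise Euclidean distances between those vectors.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .matrix import DistanceMatrix
from .regions import RegionSet
from .tables import (
    TableValidationError,
    validate_breed_census,
    validate_centroids,
    validate_membership,
    validate_occupancy,
)

log = logging.getLogger(__name__)


def _euclidean(features: np.ndarray, regions: RegionSet,
               name: str) -> DistanceMatrix:
    return DistanceMatrix(squareform(pdist(features, metric="euclidean")),
                          regions, name=name, validate=False)


def breed_composition_distances(census: pd.DataFrame,
                                regions: RegionSet) -> DistanceMatrix:
    """Distances between regions' local-breed compositions.

    Each region is represented by the proportion of its heads, within each
    livestock group, held by each breed; the per-group sub-vectors are
    concatenated over all groups.  A region with no animals in a group
    contributes zeros for all of that group's breeds, keeping feature
    vectors commensurable across regions.
    """
    census = validate_breed_census(census)
    have = set(census["region"].astype(str))
    missing = [r for r in regions if r not in have]
    if missing:
        raise TableValidationError(
            f"regions absent from the breed census: {missing}")

    blocks = []
    for group, sub in sorted(census.groupby("group"), key=lambda kv: str(kv[0])):
        pivot = (sub.pivot_table(index="region", columns="breed",
                                 values="heads", aggfunc="sum", fill_value=0.0)
                 .reindex(list(regions.labels), fill_value=0.0)
                 .sort_index(axis=1))
        mat = pivot.to_numpy(dtype=float)
        totals = mat.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            props = np.where(totals > 0, mat / totals, 0.0)
        blocks.append(props)
    features = np.hstack(blocks)
    return _euclidean(features, regions, "breeds")


def ecological_distances(occupancy: pd.DataFrame,
                         regions: RegionSet) -> DistanceMatrix:
    """Distances between regions' species-occupancy profiles."""
    occupancy = validate_occupancy(occupancy)
    pivot = occupancy.pivot_table(index="region", columns="species",
                                  values="occupied_fraction")
    pivot = pivot.reindex(list(regions.labels))
    if pivot.isna().any().any():
        log.warning("%d missing (region, species) occupancy cells treated "
                    "as 0 occupancy", int(pivot.isna().sum().sum()))
        pivot = pivot.fillna(0.0)
    return _euclidean(pivot.to_numpy(dtype=float), regions, "ecological")


def historical_distances(membership: pd.DataFrame,
                         regions: RegionSet) -> DistanceMatrix:
    """Distances between regions' political-division histories.

    Per time slice, membership is one-hot encoded over that slice's
    division labels; vectors are concatenated over slices, so the squared
    distance equals twice the number of slices in which the two regions
    belonged to different divisions.
    """
    membership = validate_membership(membership)
    have = set(membership["region"].astype(str))
    missing = [r for r in regions if r not in have]
    if missing:
        raise TableValidationError(
            f"regions absent from the membership table: {missing}")

    blocks = []
    for _slice, sub in sorted(membership.groupby("time_slice"),
                              key=lambda kv: kv[0]):
        labels = (sub.set_index("region")["division"]
                  .reindex(list(regions.labels)))
        if labels.isna().any():
            bad = list(labels[labels.isna()].index)
            raise TableValidationError(
                f"missing membership for region(s) {bad} in slice {_slice!r}")
        onehot = pd.get_dummies(labels.astype(str)).to_numpy(dtype=float)
        blocks.append(onehot)
    return _euclidean(np.hstack(blocks), regions, "historical")


def geographic_distances(centroids: pd.DataFrame,
                         regions: RegionSet) -> DistanceMatrix:
    """Planar Euclidean distances between region centroids."""
    centroids = validate_centroids(centroids)
    pts = (centroids.set_index("region")[["x", "y"]]
           .reindex(list(regions.labels)))
    if pts.isna().any().any():
        bad = list(pts[pts.isna().any(axis=1)].index)
        raise TableValidationError(f"no centroid for region(s) {bad}")
    coords = pts.to_numpy(dtype=float)
    d = squareform(pdist(coords))
    off = d[np.triu_indices_from(d, 1)]
    if np.any(off == 0):
        log.warning("coincident centroids: some off-diagonal geographic "
                    "distances are exactly 0")
    return DistanceMatrix(d, regions, name="geographic", validate=False)
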