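import logging
import math

import numpy as np
import pandas as pd
import pytest

from nichescape import (RegionSet, breed_composition_distances,
                        ecological_distances, geographic_distances,
                        historical_distances)
from nichescape.tables import TableValidationError


def census_frame(rows):
    return pd.DataFrame(rows, columns=["region", "breed", "group", "heads"])


# ------------------------------------------------------------------ breeds

def test_breed_distance_zero_for_identical_proportions():
    # same within-group proportions at very different absolute censuses
    rows = [("A", "b1", "cattle", 10), ("A", "b2", "cattle", 30),
            ("B", "b1", "cattle", 1000), ("B", "b2", "cattle", 3000)]
    d = breed_composition_distances(census_frame(rows), RegionSet("AB"))
    assert d.values[0, 1] == pytest.approx(0.0, abs=1e-12)


def test_breed_distance_two_breed_example():
    rows = [("A", "b1", "cattle", 8), ("A", "b2", "cattle", 0),
            ("B", "b1", "cattle", 5), ("B", "b2", "cattle", 5)]
    d = breed_composition_distances(census_frame(rows), RegionSet("AB"))
    assert d.values[0, 1] == pytest.approx(math.sqrt(0.5), abs=1e-12)


def test_breed_distance_matches_brute_force_oracle():
    rng = np.random.default_rng(5)
    regions = ["r1", "r2", "r3", "r4"]
    groups = {"cattle": ["c1", "c2", "c3"], "sheep": ["s1", "s2"]}
    rows = [(r, b, g, int(rng.integers(0, 50)))
            for r in regions for g, breeds in groups.items() for b in breeds]
    census = census_frame(rows)
    d = breed_composition_distances(census, RegionSet(regions))

    # independent hand-coded loop: proportions within group, then Euclidean
    def feature(region):
        vec = []
        for g in sorted(groups):
            heads = {b: 0 for b in groups[g]}
            for rr, b, gg, h in rows:
                if rr == region and gg == g:
                    heads[b] += h
            tot = sum(heads.values())
            vec += [heads[b] / tot if tot else 0.0 for b in sorted(heads)]
        return np.array(vec)

    for i, ri in enumerate(regions):
        for j, rj in enumerate(regions):
            expected = np.linalg.norm(feature(ri) - feature(rj))
            assert d.values[i, j] == pytest.approx(expected, abs=1e-12)


def test_breed_zero_head_group_contributes_zeros():
    # region B has no sheep at all; identical cattle proportions -> the
    # whole distance comes from A's sheep proportions
    rows = [("A", "c1", "cattle", 5), ("A", "s1", "sheep", 7),
            ("B", "c1", "cattle", 50), ("B", "s1", "sheep", 0)]
    d = breed_composition_distances(census_frame(rows), RegionSet("AB"))
    assert d.values[0, 1] == pytest.approx(1.0)   # (1.0 - 0.0) on one breed


def test_breed_validation_errors():
    with pytest.raises(TableValidationError, match="negative"):
        breed_composition_distances(
            census_frame([("A", "b", "cattle", -1), ("B", "b", "cattle", 1)]),
            RegionSet("AB"))
    with pytest.raises(TableValidationError, match="group"):
        breed_composition_distances(
            census_frame([("A", "b", "cattle", 1), ("B", "b", "sheep", 1)]),
            RegionSet("AB"))
    with pytest.raises(TableValidationError, match="absent"):
        breed_composition_distances(
            census_frame([("A", "b", "cattle", 1), ("B", "b", "cattle", 2)]),
            RegionSet("ABC"))


def test_breed_scale_invariance_within_group():
    rng = np.random.default_rng(0)
    rows = [(r, b, "cattle", int(rng.integers(1, 20)))
            for r in "ABCD" for b in ("b1", "b2", "b3")]
    base = breed_composition_distances(census_frame(rows), RegionSet("ABCD"))
    scaled_rows = [(r, b, g, h * 13 if r == "B" else h)
                   for r, b, g, h in rows]
    scaled = breed_composition_distances(census_frame(scaled_rows),
                                         RegionSet("ABCD"))
    np.testing.assert_allclose(base.values, scaled.values, atol=1e-12)


# ------------------------------------------------------------------ ecology

def occupancy_frame(rows):
    return pd.DataFrame(rows, columns=["region", "species",
                                       "occupied_fraction"])


def test_ecological_distance_basic_cases():
    rows = [("A", "sp1", 0.0), ("B", "sp1", 1.0)]
    d = ecological_distances(occupancy_frame(rows), RegionSet("AB"))
    assert d.values[0, 1] == pytest.approx(1.0)
    same = [("A", "sp1", 0.4), ("A", "sp2", 0.7),
            ("B", "sp1", 0.4), ("B", "sp2", 0.7)]
    d2 = ecological_distances(occupancy_frame(same), RegionSet("AB"))
    assert d2.values[0, 1] == pytest.approx(0.0, abs=1e-12)


def test_ecological_distance_matches_brute_force():
    rng = np.random.default_rng(11)
    regions = [f"r{i}" for i in range(5)]
    species = [f"s{i}" for i in range(12)]
    table = occupancy_frame([(r, s, rng.uniform())
                             for r in regions for s in species])
    d = ecological_distances(table, RegionSet(regions))
    pivot = table.pivot(index="region", columns="species",
                        values="occupied_fraction").loc[regions]
    for i in range(5):
        for j in range(5):
            expected = np.linalg.norm(pivot.iloc[i] - pivot.iloc[j])
            assert d.values[i, j] == pytest.approx(expected, abs=1e-12)


def test_ecological_fraction_out_of_range_rejected():
    with pytest.raises(TableValidationError, match=r"\[0, 1\]"):
        ecological_distances(occupancy_frame([("A", "s", 1.2),
                                              ("B", "s", 0.5)]),
                             RegionSet("AB"))


def test_ecological_missing_cells_default_to_zero(caplog):
    rows = [("A", "sp1", 0.8), ("B", "sp1", 0.8), ("B", "sp2", 0.6)]
    with caplog.at_level(logging.WARNING, logger="nichescape.distances"):
        d = ecological_distances(occupancy_frame(rows), RegionSet("AB"))
    assert "missing" in caplog.text
    assert d.values[0, 1] == pytest.approx(0.6)


# ------------------------------------------------------------------ history

def membership_frame(rows):
    return pd.DataFrame(rows, columns=["region", "time_slice", "division"])


def test_historical_distance_identical_and_all_different():
    T = 5
    rows = ([("A", t, f"d{t}") for t in range(T)]
            + [("B", t, f"d{t}") for t in range(T)]
            + [("C", t, f"x{t}") for t in range(T)])
    d = historical_distances(membership_frame(rows), RegionSet("ABC"))
    assert d.values[0, 1] == pytest.approx(0.0, abs=1e-12)
    assert d.values[0, 2] == pytest.approx(math.sqrt(2 * T))


def test_historical_distance_matches_mismatch_oracle():
    rng = np.random.default_rng(2)
    regions = [f"r{i}" for i in range(6)]
    T = 8
    labels = {(r, t): f"div{rng.integers(0, 3)}"
              for r in regions for t in range(T)}
    rows = [(r, t, labels[r, t]) for r in regions for t in range(T)]
    d = historical_distances(membership_frame(rows), RegionSet(regions))
    for i, ri in enumerate(regions):
        for j, rj in enumerate(regions):
            mismatches = sum(labels[ri, t] != labels[rj, t] for t in range(T))
            assert d.values[i, j] == pytest.approx(math.sqrt(2 * mismatches))


def test_historical_label_renaming_invariance():
    rng = np.random.default_rng(3)
    regions = list("ABCDE")
    T = 4
    rows = [(r, t, f"d{rng.integers(0, 3)}") for r in regions
            for t in range(T)]
    base = historical_distances(membership_frame(rows), RegionSet(regions))
    renamed = [(r, t, f"slice{t}_{lab}") for r, t, lab in rows]
    d2 = historical_distances(membership_frame(renamed), RegionSet(regions))
    np.testing.assert_allclose(base.values, d2.values, atol=1e-12)


def test_historical_missing_cell_rejected():
    rows = [("A", 0, "d"), ("A", 1, "d"), ("B", 0, "d")]
    with pytest.raises(TableValidationError, match="missing"):
        historical_distances(membership_frame(rows), RegionSet("AB"))


# ---------------------------------------------------------------- geography

def centroid_frame(rows):
    return pd.DataFrame(rows, columns=["region", "x", "y"])


def test_geographic_distance_pythagorean():
    d = geographic_distances(centroid_frame([("A", 0, 0), ("B", 3, 4)]),
                             RegionSet("AB"))
    assert d.values[0, 1] == pytest.approx(5.0)


def test_geographic_coincident_centroids_warn(caplog):
    with caplog.at_level(logging.WARNING, logger="nichescape.distances"):
        d = geographic_distances(
            centroid_frame([("A", 1, 1), ("B", 1, 1), ("C", 0, 0)]),
            RegionSet("ABC"))
    assert "coincident" in caplog.text
    assert d.values[0, 1] == 0.0


def test_geographic_matches_direct_formula():
    rng = np.random.default_rng(7)
    pts = rng.uniform(size=(10, 2))
    rows = [(f"r{i}", *pts[i]) for i in range(10)]
    d = geographic_distances(centroid_frame(rows),
                             RegionSet(f"r{i}" for i in range(10)))
    for i in range(10):
        for j in range(10):
            assert d.values[i, j] == pytest.approx(
                np.linalg.norm(pts[i] - pts[j]), abs=1e-12)


def test_geographic_duplicate_region_rejected():
    with pytest.raises(TableValidationError, match="duplicate"):
        geographic_distances(centroid_frame([("A", 0, 0), ("A", 1, 1),
                                             ("B", 2, 2)]), RegionSet("AB"))


# -------------------------------------------------------------- equivariance

def test_builders_equivariant_under_region_reordering(small_dataset):
    ds = small_dataset
    regions = list(ds.regions.labels)
    rng = np.random.default_rng(0)
    order = rng.permutation(len(regions))
    shuffled = RegionSet(regions[k] for k in order)

    builders = [
        (breed_composition_distances, ds.breed_census),
        (ecological_distances, ds.occupancy),
        (historical_distances, ds.membership),
        (geographic_distances, ds.centroids),
    ]
    for build, table in builders:
        base = build(table, ds.regions)
        perm = build(table, shuffled)
        np.testing.assert_allclose(perm.values,
                                   base.values[np.ix_(order, order)],
                                   atol=1e-10)
        assert perm.is_euclidean_metric()
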