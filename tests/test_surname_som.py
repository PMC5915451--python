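import numpy as np
import pandas as pd
import pytest

from nichescape import (RegionSet, SimulationConfig, classify_surnames,
                        concentration_classification, simulate_dataset,
                        surname_distances, surname_profiles, train_som)
from nichescape.som import EXCLUDED_LOW_COUNT, MONOPHYLETIC, POLYPHYLETIC
from nichescape.tables import TableValidationError


def counts_frame(rows):
    return pd.DataFrame(rows, columns=["surname", "region", "count"])


REGIONS4 = RegionSet("ABCD")


# ---------------------------------------------------------------- profiles

def test_min_records_threshold_is_strict():
    # exactly 20 records -> excluded, 21 -> retained
    rows = [("at20", "A", 10), ("at20", "B", 10),
            ("at21", "A", 10), ("at21", "B", 11)]
    profiles = surname_profiles(counts_frame(rows), REGIONS4, min_records=20)
    names = [p.surname for p in profiles]
    assert names == ["at21"]
    assert profiles[0].total_records == 21


def test_single_region_surname_has_one_hot_profile():
    rows = [("only_a", "A", 30)]
    (p,) = surname_profiles(counts_frame(rows), REGIONS4)
    np.testing.assert_allclose(p.profile, [1.0, 0.0, 0.0, 0.0])


def test_profiles_sum_to_one():
    rng = np.random.default_rng(0)
    rows = [(f"s{i}", r, int(rng.integers(1, 40)))
            for i in range(8) for r in "ABCD"]
    for p in surname_profiles(counts_frame(rows), REGIONS4):
        assert p.profile.sum() == pytest.approx(1.0, abs=1e-12)


def test_empty_table_rejected():
    with pytest.raises(TableValidationError):
        surname_profiles(counts_frame([]), REGIONS4)


# ---------------------------------------------------------------- SOM

def two_cluster_profiles(n_per=12, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_per):          # cluster 1: mass on A/B
        rows += [(f"x{i}", "A", int(rng.integers(30, 60))),
                 (f"x{i}", "B", int(rng.integers(5, 15)))]
    for i in range(n_per):          # cluster 2: mass on C/D
        rows += [(f"y{i}", "C", int(rng.integers(30, 60))),
                 (f"y{i}", "D", int(rng.integers(5, 15)))]
    return surname_profiles(counts_frame(rows), REGIONS4)


def test_som_training_is_deterministic():
    profiles = two_cluster_profiles()
    m1 = train_som(profiles, grid_rows=3, grid_cols=3, epochs=10, seed=5)
    m2 = train_som(profiles, grid_rows=3, grid_cols=3, epochs=10, seed=5)
    np.testing.assert_array_equal(m1.codebook, m2.codebook)


def test_well_separated_clusters_map_to_disjoint_units():
    profiles = two_cluster_profiles()
    model = train_som(profiles, grid_rows=2, grid_cols=2, epochs=25, seed=1)
    bmus_x = {model.best_matching_unit(p.profile)
              for p in profiles if p.surname.startswith("x")}
    bmus_y = {model.best_matching_unit(p.profile)
              for p in profiles if p.surname.startswith("y")}
    assert bmus_x.isdisjoint(bmus_y)


def test_identical_profiles_share_one_bmu():
    rows = [(f"s{i}", "A", 25) for i in range(10)]
    profiles = surname_profiles(counts_frame(rows), REGIONS4)
    with pytest.warns(UserWarning):     # 10 profiles for 16 units
        model = train_som(profiles, grid_rows=4, grid_cols=4, epochs=5,
                          seed=0)
    assert len({model.best_matching_unit(p.profile) for p in profiles}) == 1


def test_small_grid_rejected():
    with pytest.raises(ValueError):
        train_som(two_cluster_profiles(), grid_rows=1, grid_cols=5)


# ----------------------------------------------------------- classification

def test_one_hot_profile_is_monophyletic_with_that_origin():
    rows = [("pure", "C", 40)]
    profiles = surname_profiles(counts_frame(rows), REGIONS4)
    cls = concentration_classification(profiles, REGIONS4, 0.5)
    (call,) = cls.calls
    assert call.status == MONOPHYLETIC
    assert call.origin_region == "C"
    assert call.concentration == pytest.approx(1.0)


def test_uniform_profile_is_polyphyletic():
    rows = [("flat", r, 12) for r in "ABCD"]
    profiles = surname_profiles(counts_frame(rows), REGIONS4)
    cls = concentration_classification(profiles, REGIONS4, 0.5)
    assert cls.calls[0].status == POLYPHYLETIC
    assert cls.calls[0].origin_region is None


def test_threshold_outside_unit_interval_rejected():
    profiles = surname_profiles(counts_frame([("s", "A", 25)]), REGIONS4)
    for bad in (0.0, 1.0, -0.2, 1.5):
        with pytest.raises(ValueError):
            concentration_classification(profiles, REGIONS4, bad)


def test_classification_invariant_to_count_scaling():
    rng = np.random.default_rng(4)
    rows = [(f"s{i}", r, int(rng.integers(5, 30)))
            for i in range(6) for r in "ABCD"]
    base = concentration_classification(
        surname_profiles(counts_frame(rows), REGIONS4), REGIONS4)
    scaled = concentration_classification(
        surname_profiles(counts_frame([(s, r, c * 9) for s, r, c in rows]),
                         REGIONS4), REGIONS4)
    for a, b in zip(base.calls, scaled.calls):
        assert a.status == b.status
        assert a.concentration == pytest.approx(b.concentration)


def test_classify_with_som_adds_bmu_marker():
    profiles = two_cluster_profiles()
    model = train_som(profiles, grid_rows=2, grid_cols=2, epochs=10, seed=0)
    cls = classify_surnames(model, profiles, REGIONS4, 0.5)
    assert all(c.bmu is not None for c in cls.calls)
    frame = cls.to_frame()
    assert set(frame["status"]) <= {MONOPHYLETIC, POLYPHYLETIC,
                                    EXCLUDED_LOW_COUNT}


# -------------------------------------------------------------- distances

def test_identical_surname_compositions_give_zero_distance():
    rows = [("s1", "A", 10), ("s2", "A", 30),
            ("s1", "B", 20), ("s2", "B", 60)]
    regions = RegionSet("AB")
    profiles = surname_profiles(counts_frame(rows), regions)
    cls = concentration_classification(profiles, regions, 0.2)
    d = surname_distances(counts_frame(rows), cls, regions)
    assert d.values[0, 1] == pytest.approx(0.0, abs=1e-12)


def test_polyphyletic_surnames_do_not_affect_distances():
    rng = np.random.default_rng(1)
    mono_rows = [(f"m{i}", r, int(rng.integers(5, 40)))
                 for i in range(5) for r in "ABCD"]
    poly_rows = [("spread", r, 11) for r in "ABCD"]
    regions = REGIONS4

    profiles_all = surname_profiles(counts_frame(mono_rows + poly_rows),
                                    regions)
    cls_all = concentration_classification(profiles_all, regions, 0.3)
    assert cls_all.status_of("spread") == POLYPHYLETIC

    profiles_mono = surname_profiles(counts_frame(mono_rows), regions)
    cls_mono = concentration_classification(profiles_mono, regions, 0.3)

    d_all = surname_distances(counts_frame(mono_rows + poly_rows), cls_all,
                              regions)
    d_mono = surname_distances(counts_frame(mono_rows), cls_mono, regions)
    np.testing.assert_allclose(d_all.values, d_mono.values, atol=1e-12)


def test_surname_distances_match_normalize_then_euclidean_oracle():
    rng = np.random.default_rng(9)
    regions = RegionSet(f"r{i}" for i in range(5))
    rows = [(f"s{i}", f"r{j}", int(rng.integers(0, 25)))
            for i in range(30) for j in range(5)]
    counts = counts_frame(rows)
    profiles = surname_profiles(counts, regions)
    cls = concentration_classification(profiles, regions, 0.1)
    keep = sorted(c.surname for c in cls.monophyletic)
    d = surname_distances(counts, cls, regions)

    pivot = counts[counts["surname"].isin(keep)].pivot_table(
        index="region", columns="surname", values="count",
        fill_value=0).loc[[f"r{i}" for i in range(5)]]
    comp = pivot.to_numpy(float)
    comp = comp / comp.sum(axis=1, keepdims=True)
    for i in range(5):
        for j in range(5):
            assert d.values[i, j] == pytest.approx(
                np.linalg.norm(comp[i] - comp[j]), abs=1e-12)


def test_no_monophyletic_surname_is_an_error():
    rows = [("flat1", r, 10) for r in "ABCD"] + \
           [("flat2", r, 12) for r in "ABCD"]
    profiles = surname_profiles(counts_frame(rows), REGIONS4)
    cls = concentration_classification(profiles, REGIONS4, 0.9)
    with pytest.raises(TableValidationError, match="monophyletic"):
        surname_distances(counts_frame(rows), cls, REGIONS4)


# --------------------------------------------------------- generator-backed

def test_planted_single_origins_are_recovered():
    """With no planted polyphyletic surnames, >= 95% of retained surnames
    are called monophyletic with their true origin region."""
    ds = simulate_dataset(SimulationConfig(polyphyletic_fraction=0.0,
                                           seed=123))
    profiles = surname_profiles(ds.surname_counts, ds.regions)
    cls = concentration_classification(profiles, ds.regions, 0.5)
    truth = ds.ground_truth.surname_origins
    correct = sum(1 for c in cls.monophyletic
                  if truth.get(c.surname) == c.origin_region)
    assert correct / len(profiles) >= 0.95
    assert len(cls.polyphyletic) / len(profiles) <= 0.05


def test_planted_two_focus_surnames_are_flagged_polyphyletic():
    ds = simulate_dataset(SimulationConfig(seed=77))
    profiles = surname_profiles(ds.surname_counts, ds.regions)
    cls = concentration_classification(profiles, ds.regions, 0.5)
    status = {c.surname: c.status for c in cls.calls}
    planted = ds.ground_truth.polyphyletic_surnames
    flagged = sum(1 for s in planted if status.get(s) == POLYPHYLETIC)
    assert flagged / len(planted) >= 0.9
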