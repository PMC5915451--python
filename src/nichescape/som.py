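"""Surnames as geographic markers: profiles, SOM grouping, QC, distances.

Surnames whose bearers concentrate around a single place of origin act as
markers of historical population structure.  The steps are:

1. :func:`surname_profiles` — per-surname relative-frequency profiles over
   regions, dropping rare surnames (<= ``min_records`` records).
2. :class:`SelfOrganizingMap` / :func:`train_som` — classic online Kohonen
   map grouping surnames with similar regional profiles.
3. :func:`classify_surnames` — monophyletic vs polyphyletic calls from a
   concentration score (the largest single-region share of the profile by
   default), with the best-matching SOM unit kept as a marker.
4. :func:`surname_distances` — the human-population distance matrix from
   per-region compositions of the retained (monophyletic) surnames.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .matrix import DistanceMatrix
from .regions import RegionSet
from .tables import TableValidationError, validate_surname_counts

log = logging.getLogger(__name__)

MONOPHYLETIC = "monophyletic"
POLYPHYLETIC = "polyphyletic"
EXCLUDED_LOW_COUNT = "excluded_low_count"


@dataclass(frozen=True)
class SurnameProfile:
    """Relative regional frequency profile of one surname."""

    surname: str
    total_records: int
    profile: np.ndarray      # over regions, sums to 1

    def __post_init__(self):
        if abs(self.profile.sum() - 1.0) > 1e-9:
            raise ValueError(f"profile of {self.surname!r} does not sum to 1")


def surname_profiles(counts: pd.DataFrame, regions: RegionSet,
                     min_records: int = 20) -> list[SurnameProfile]:
    """Per-surname relative frequencies over regions.

    Surnames with ``total records <= min_records`` are excluded (strictly
    more than ``min_records`` records are required).
    """
    counts = validate_surname_counts(counts)
    pivot = (counts.pivot_table(index="surname", columns="region",
                                values="count", fill_value=0.0)
             .reindex(columns=list(regions.labels), fill_value=0.0))
    out = []
    for surname, row in pivot.iterrows():
        vec = row.to_numpy(dtype=float)
        total = vec.sum()
        if total <= min_records:
            continue
        out.append(SurnameProfile(surname=str(surname),
                                  total_records=int(round(total)),
                                  profile=vec / total))
    if not out:
        raise TableValidationError(
            f"no surname exceeds the {min_records}-record threshold")
    return out


def _profile_matrix(profiles: list[SurnameProfile]) -> np.ndarray:
    x = np.vstack([p.profile for p in profiles])
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite surname profile")
    return x


# ------------------------------------------------------------------ SOM

@dataclass
class SelfOrganizingMap:
    """A trained Kohonen map: grid geometry, codebook, training config."""

    grid_rows: int
    grid_cols: int
    codebook: np.ndarray          # (grid_rows * grid_cols, dim)
    training_config: dict = field(default_factory=dict)

    @property
    def unit_coords(self) -> np.ndarray:
        rr, cc = np.meshgrid(np.arange(self.grid_rows),
                             np.arange(self.grid_cols), indexing="ij")
        return np.column_stack([rr.ravel(), cc.ravel()]).astype(float)

    def best_matching_unit(self, x: np.ndarray) -> int:
        d2 = ((self.codebook - x) ** 2).sum(axis=1)
        return int(np.argmin(d2))

    def bmu_grid_position(self, x: np.ndarray) -> tuple[int, int]:
        u = self.best_matching_unit(x)
        return divmod(u, self.grid_cols)


def train_som(profiles: list[SurnameProfile], grid_rows: int = 10,
              grid_cols: int = 10, epochs: int = 50,
              learning_rate: float = 0.5, radius: float | None = None,
              seed: int | None = None) -> SelfOrganizingMap:
    """Classic online Kohonen training on surname profiles.

    Per epoch the profiles are presented in a seeded random order; the
    best-matching unit is found by Euclidean distance and all units are
    pulled toward the sample with a Gaussian neighborhood whose radius and
    the learning rate both decay exponentially over the run.  Bit-for-bit
    deterministic given the seed.
    """
    if grid_rows < 2 or grid_cols < 2:
        raise ValueError("grid dimensions must both be >= 2")
    x = _profile_matrix(profiles)
    n_units = grid_rows * grid_cols
    if len(profiles) < n_units:
        warnings.warn(
            f"{len(profiles)} profiles for {n_units} SOM units; consider a "
            "smaller grid", stacklevel=2)

    rng = np.random.default_rng(seed)
    radius0 = radius if radius is not None else max(grid_rows, grid_cols) / 2.0
    # init: random data points with a small jitter, seeded
    init_idx = rng.integers(0, len(x), size=n_units)
    codebook = x[init_idx] + rng.normal(0.0, 1e-3, size=(n_units, x.shape[1]))

    rr, cc = np.meshgrid(np.arange(grid_rows), np.arange(grid_cols),
                         indexing="ij")
    grid = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
    grid_d2 = squareform(pdist(grid)) ** 2

    total_steps = epochs * len(x)
    decay = total_steps / 4.0          # e-folding time of both schedules
    t = 0
    for _epoch in range(epochs):
        for i in rng.permutation(len(x)):
            alpha = learning_rate * np.exp(-t / decay)
            sigma = max(radius0 * np.exp(-t / decay), 0.5)
            sample = x[i]
            bmu = int(np.argmin(((codebook - sample) ** 2).sum(axis=1)))
            h = np.exp(-grid_d2[bmu] / (2.0 * sigma * sigma))
            codebook += (alpha * h)[:, None] * (sample - codebook)
            t += 1

    config = {"epochs": epochs, "learning_rate": learning_rate,
              "radius": radius0, "seed": seed}
    return SelfOrganizingMap(grid_rows=grid_rows, grid_cols=grid_cols,
                             codebook=codebook, training_config=config)


# ------------------------------------------------------- classification

@dataclass(frozen=True)
class SurnameCall:
    surname: str
    status: str
    concentration: float
    origin_region: str | None
    bmu: tuple[int, int] | None


@dataclass(frozen=True)
class SurnameClassification:
    """Per-surname monophyly calls with inferred origins."""

    calls: tuple[SurnameCall, ...]
    concentration_threshold: float

    def __iter__(self):
        return iter(self.calls)

    @property
    def monophyletic(self) -> list[SurnameCall]:
        return [c for c in self.calls if c.status == MONOPHYLETIC]

    @property
    def polyphyletic(self) -> list[SurnameCall]:
        return [c for c in self.calls if c.status == POLYPHYLETIC]

    def status_of(self, surname: str) -> str:
        for c in self.calls:
            if c.surname == surname:
                return c.status
        raise KeyError(surname)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "surname": [c.surname for c in self.calls],
            "status": [c.status for c in self.calls],
            "origin_region": [c.origin_region for c in self.calls],
            "concentration": [c.concentration for c in self.calls],
            "bmu_row": [c.bmu[0] if c.bmu else None for c in self.calls],
            "bmu_col": [c.bmu[1] if c.bmu else None for c in self.calls],
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _concentration(profile: np.ndarray,
                   neighbors: dict[int, list[int]] | None) -> float:
    """Largest contiguous-mass share: single-region max, or max over a
    region plus its declared neighbor regions when an adjacency is given."""
    if neighbors is None:
        return float(profile.max())
    best = 0.0
    for r in range(len(profile)):
        mass = profile[r] + sum(profile[q] for q in neighbors.get(r, ()))
        best = max(best, float(mass))
    return min(best, 1.0)


def concentration_classification(
        profiles: list[SurnameProfile], regions: RegionSet,
        concentration_threshold: float = 0.5,
        neighbors: dict[int, list[int]] | None = None) -> SurnameClassification:
    """Monophyly calls from the concentration score alone (no SOM marker)."""
    if not 0.0 < concentration_threshold < 1.0:
        raise ValueError("concentration_threshold must be in (0, 1)")
    calls = []
    for p in profiles:
        conc = _concentration(p.profile, neighbors)
        if conc >= concentration_threshold:
            calls.append(SurnameCall(p.surname, MONOPHYLETIC, conc,
                                     regions[int(np.argmax(p.profile))], None))
        else:
            calls.append(SurnameCall(p.surname, POLYPHYLETIC, conc, None,
                                     None))
    return SurnameClassification(tuple(calls), concentration_threshold)


def classify_surnames(model: SelfOrganizingMap,
                      profiles: list[SurnameProfile],
                      regions: RegionSet,
                      concentration_threshold: float = 0.5,
                      neighbors: dict[int, list[int]] | None = None
                      ) -> SurnameClassification:
    """Monophyly calls plus the best-matching SOM unit per surname."""
    base = concentration_classification(profiles, regions,
                                        concentration_threshold, neighbors)
    calls = []
    for p, call in zip(profiles, base.calls):
        bmu = model.bmu_grid_position(p.profile)
        calls.append(SurnameCall(call.surname, call.status,
                                 call.concentration, call.origin_region, bmu))
    return SurnameClassification(tuple(calls), concentration_threshold)


def surname_distances(counts: pd.DataFrame,
                      classification: SurnameClassification,
                      regions: RegionSet) -> DistanceMatrix:
    """Human-population distances from monophyletic-surname compositions.

    Each region is represented by the relative frequency of every retained
    (monophyletic) surname within the region; distances are Euclidean.
    """
    counts = validate_surname_counts(counts)
    keep = [c.surname for c in classification.monophyletic]
    if not keep:
        raise TableValidationError("no monophyletic surname retained")
    sub = counts[counts["surname"].astype(str).isin(keep)]
    pivot = (sub.pivot_table(index="region", columns="surname",
                             values="count", fill_value=0.0)
             .reindex(list(regions.labels), fill_value=0.0))
    mat = pivot.to_numpy(dtype=float)
    totals = mat.sum(axis=1, keepdims=True)
    if np.any(totals == 0):
        empty = [regions[i] for i in np.flatnonzero(totals.ravel() == 0)]
        log.warning("region(s) %s have no retained surname records; their "
                    "composition vectors are all zero", empty)
    with np.errstate(invalid="ignore", divide="ignore"):
        comp = np.where(totals > 0, mat / totals, 0.0)
    return DistanceMatrix(squareform(pdist(comp)), regions, name="human",
                          validate=False)
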