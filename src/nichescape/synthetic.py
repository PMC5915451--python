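"""Synthetic region systems with planted cultural, ecological, historical
and geographic structure.

The generator emulates the five input tables of the analysis for a
configurable set of regions, together with the ground truth needed for
recovery tests:

* centroids uniform on the unit square;
* a latent *cultural field* — zero-mean Gaussian vectors with spatial
  covariance exp(-d_geo / rho), so cultural similarity decays with
  distance but carries realization noise of its own;
* spatially contiguous *historical divisions* per time slice, assigned by
  nearest-seed with seed points drifting between slices;
* a smooth *environmental gradient* with species occupancies following
  logistic responses with species-specific intercepts and slopes;
* *surnames* diffusing from a planted origin with a kernel decaying in
  latent cultural distance (polyphyletic surnames mix two distant
  origins), so the surname matrix measures the cultural field;
* *breed censuses* whose within-group shares follow a softmax of the
  planted composite dissimilarity w_human * culture + w_eco * gradient +
  w_hist * division mismatch + w_geo * geography to each breed's anchor
  region, plus Gaussian utility noise, sampled multinomially.

Everything is deterministic given (config, seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .matrix import DistanceMatrix
from .regions import RegionSet
from .tables import LIVESTOCK_GROUPS

__all__ = ["SimulationConfig", "GroundTruth", "SyntheticDataset",
           "simulate_dataset", "export_dataset", "load_dataset"]


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic region system.

    The defaults are the package's standard study conditions: 30 regions,
    200 surnames of ~200 records each, 60 species, six livestock groups of
    five breeds, eight historical time slices of four divisions, and
    planted effect weights ordered human > ecological > geographic >
    historical (the qualitative ordering the analysis is meant to
    recover).
    """

    n_regions: int = 30
    n_surnames: int = 200
    polyphyletic_fraction: float = 0.1
    surname_records_scale: float = 200.0
    n_species: int = 60
    n_breeds_per_group: int = 5
    n_time_slices: int = 8
    n_divisions: int = 4
    w_human: float = 1.0
    w_eco: float = 0.6
    w_hist: float = 0.2
    w_geo: float = 0.3
    rho: float = 0.3
    sigma: float = 0.3
    seed: int = 0
    # secondary shape parameters
    latent_dim: int = 2
    surname_kernel_scale: float = 0.3
    surname_origin_mass: float = 0.6
    gradient_noise: float = 0.3
    division_drift: float = 0.05
    division_reseed_prob: float = 0.0
    softmax_sharpness: float = 0.25
    heads_per_group: float = 4000.0
    groups: tuple[str, ...] = LIVESTOCK_GROUPS

    def __post_init__(self):
        if self.n_regions < 3:
            raise ValueError("n_regions must be >= 3")
        for name in ("n_surnames", "n_species", "n_breeds_per_group",
                     "n_time_slices", "n_divisions"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.polyphyletic_fraction <= 1.0:
            raise ValueError("polyphyletic_fraction must be in [0, 1]")
        for name in ("w_human", "w_eco", "w_hist", "w_geo", "sigma"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0")
        if self.rho <= 0:
            raise ValueError("rho must be > 0")

    def replace(self, **kw) -> "SimulationConfig":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["groups"] = list(d["groups"])
        return d


@dataclass(frozen=True)
class GroundTruth:
    """Planted structure behind a synthetic dataset."""

    weights: dict
    culture_distances: DistanceMatrix
    gradient: np.ndarray
    surname_origins: dict              # surname -> origin region label
    polyphyletic_surnames: tuple[str, ...]
    division_labels: pd.DataFrame      # region x time_slice
    breed_anchors: dict                # breed -> anchor region label

    def to_dict(self) -> dict:
        return {
            "weights": self.weights,
            "gradient": {r: float(g) for r, g in
                         zip(self.culture_distances.regions.labels,
                             self.gradient)},
            "surname_origins": self.surname_origins,
            "polyphyletic_surnames": list(self.polyphyletic_surnames),
            "breed_anchors": self.breed_anchors,
        }


@dataclass(frozen=True)
class SyntheticDataset:
    """The five generated tables plus their ground truth."""

    regions: RegionSet
    breed_census: pd.DataFrame
    surname_counts: pd.DataFrame
    occupancy: pd.DataFrame
    membership: pd.DataFrame
    centroids: pd.DataFrame
    ground_truth: GroundTruth
    config: SimulationConfig

    @property
    def tables(self) -> dict[str, pd.DataFrame]:
        return {"breed_census": self.breed_census,
                "surname_counts": self.surname_counts,
                "occupancy": self.occupancy,
                "membership": self.membership,
                "centroids": self.centroids}


def _normalized(mat: np.ndarray) -> np.ndarray:
    """Scale a distance matrix to unit *interaction* spread.

    Additive region effects of a dissimilarity component cancel in the
    breed softmax (they shift every anchor's utility equally), so the
    share-driving scale of a component is the spread of its double-centered
    (interaction) part.  Normalizing by that makes the planted weights act
    as commensurable effect sizes.
    """
    row = mat.mean(axis=1, keepdims=True)
    col = mat.mean(axis=0, keepdims=True)
    inter = mat - row - col + mat.mean()
    sd = inter[np.triu_indices_from(mat, 1)].std()
    return mat / sd if sd > 0 else np.zeros_like(mat)


def _gaussian_field(geo: np.ndarray, rho: float, dim: int,
                    rng: np.random.Generator) -> np.ndarray:
    cov = np.exp(-geo / rho) + 1e-9 * np.eye(geo.shape[0])
    chol = np.linalg.cholesky(cov)
    return chol @ rng.standard_normal((geo.shape[0], dim))


def simulate_dataset(config: SimulationConfig | None = None,
                     seed: int | None = None, **kw) -> SyntheticDataset:
    """Generate one synthetic dataset; see the module docstring."""
    if config is None:
        config = SimulationConfig(**kw)
    elif kw:
        config = config.replace(**kw)
    if seed is not None:
        config = config.replace(seed=seed)
    cfg = config
    if (cfg.w_human == cfg.w_eco == cfg.w_hist == cfg.w_geo == 0.0
            and cfg.sigma == 0.0):
        warnings.warn("all effect weights and sigma are zero: breed shares "
                      "are degenerate-uniform", stacklevel=2)
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_regions
    width = len(str(n))
    labels = [f"R{i + 1:0{width}d}" for i in range(n)]
    regions = RegionSet(labels)

    # (1) geography
    coords = rng.uniform(0.0, 1.0, size=(n, 2))
    centroids = pd.DataFrame({"region": labels,
                              "x": coords[:, 0], "y": coords[:, 1]})
    geo = squareform(pdist(coords))

    # (2) latent cultural field
    culture = _gaussian_field(geo, cfg.rho, cfg.latent_dim, rng)
    culture_dist = squareform(pdist(culture))

    # (3) historical divisions: drifting nearest-seed partitions
    seeds = rng.uniform(0.0, 1.0, size=(cfg.n_divisions, 2))
    division_rows = []
    division_table = np.empty((n, cfg.n_time_slices), dtype=object)
    for t in range(cfg.n_time_slices):
        if t > 0:
            seeds = np.clip(seeds + rng.normal(0.0, cfg.division_drift,
                                               size=seeds.shape), 0.0, 1.0)
            # occasional political upheaval: a division seed relocates
            jump = rng.random(len(seeds)) < cfg.division_reseed_prob
            seeds[jump] = rng.uniform(0.0, 1.0, size=(int(jump.sum()), 2))
        d2 = ((coords[:, None, :] - seeds[None, :, :]) ** 2).sum(axis=2)
        assign = d2.argmin(axis=1)
        for r in range(n):
            name = f"T{t + 1}_D{assign[r] + 1}"
            division_table[r, t] = name
            division_rows.append((labels[r], t + 1, name))
    membership = pd.DataFrame(division_rows,
                              columns=["region", "time_slice", "division"])
    mismatch = np.zeros((n, n))
    for t in range(cfg.n_time_slices):
        col = division_table[:, t]
        mismatch += (col[:, None] != col[None, :]).astype(float)
    hist_frac = mismatch / cfg.n_time_slices

    # (4) environmental gradient and species occupancy
    x, y = coords[:, 0], coords[:, 1]
    gradient = (x + y + 0.5 * np.sin(3.0 * x) * np.cos(3.0 * y)
                + rng.normal(0.0, cfg.gradient_noise, size=n))
    alpha = rng.normal(0.0, 1.0, size=cfg.n_species)
    beta = rng.normal(0.0, 2.5, size=cfg.n_species)
    g_c = gradient - gradient.mean()
    logit = alpha[None, :] + beta[None, :] * g_c[:, None]
    occ = 1.0 / (1.0 + np.exp(-logit))
    occupancy = pd.DataFrame({
        "region": np.repeat(labels, cfg.n_species),
        "species": np.tile([f"sp{s + 1:03d}" for s in range(cfg.n_species)], n),
        "occupied_fraction": occ.ravel(),
    })

    # (5) surnames: cultural diffusion from planted origins
    n_poly = int(round(cfg.polyphyletic_fraction * cfg.n_surnames))
    tau = cfg.surname_kernel_scale
    surname_rows = []
    origins: dict[str, str] = {}
    poly_names: list[str] = []
    median_geo = np.median(geo[np.triu_indices(n, 1)])

    # Emigration kernel: a clear-origin surname keeps `surname_origin_mass`
    # of its records at home; the rest emigrates to *other* regions with
    # probability decaying in cultural distance.  The hollow kernel is
    # Sinkhorn-balanced (every region sends and receives the same total
    # emigrant mass), so regional record totals and composition-vector
    # norms are flat and the pairwise exchange structure — not regional
    # "endemicity" — carries the planted affinity signal.
    kernel = np.exp(-culture_dist / tau)
    np.fill_diagonal(kernel, 0.0)
    for _ in range(200):
        kernel /= kernel.sum(axis=1, keepdims=True)
        kernel /= kernel.sum(axis=0, keepdims=True)
    kernel /= kernel.sum(axis=1, keepdims=True)

    def origin_weights(o: int) -> np.ndarray:
        w = (1.0 - cfg.surname_origin_mass) * kernel[o]
        w[o] += cfg.surname_origin_mass
        return w

    # balanced origin allocation: every region founds (nearly) the same
    # number of monophyletic surnames
    n_mono = cfg.n_surnames - n_poly
    mono_origins = np.resize(np.arange(n), n_mono)
    rng.shuffle(mono_origins)
    mono_iter = iter(mono_origins)

    records = int(round(cfg.surname_records_scale))
    weight_rows = np.empty((cfg.n_surnames, n))
    is_mono = np.zeros(cfg.n_surnames, dtype=bool)
    for s in range(cfg.n_surnames):
        name = f"S{s + 1:04d}"
        if s < n_poly:
            o1 = int(rng.integers(n))
            far = np.flatnonzero(geo[o1] > median_geo)
            o2 = int(rng.choice(far)) if len(far) else int(rng.integers(n))
            weights = 0.5 * origin_weights(o1) + 0.5 * origin_weights(o2)
            poly_names.append(name)
        else:
            o1 = int(next(mono_iter))
            weights = origin_weights(o1)
            origins[name] = labels[o1]
            is_mono[s] = True
        weight_rows[s] = weights / weights.sum()
        counts = rng.multinomial(records, weight_rows[s])
        for r in np.flatnonzero(counts):
            surname_rows.append((name, labels[r], int(counts[r])))
    surname_counts = pd.DataFrame(surname_rows,
                                  columns=["surname", "region", "count"])

    # the planted human-population affinity is the *expected* composition
    # distance over the clear-origin surnames: the population-exchange
    # structure the measured surname matrix estimates (the realization
    # differs only by multinomial sampling noise)
    mono_weights = weight_rows[is_mono]
    col_tot = mono_weights.sum(axis=0, keepdims=True)
    expected_comp = (mono_weights / col_tot).T                # region x surname
    human_affinity = squareform(pdist(expected_comp))

    # (6) breed censuses: softmax over composite dissimilarity to anchors.
    # Each component is the very distance the pipeline later measures
    # (expected surname composition, occupancy profiles, one-hot history,
    # centroid geography), so planted weights act on what is observable.
    eco_dist = squareform(pdist(occ))
    hist_dist = np.sqrt(2.0 * mismatch)
    comp = (cfg.w_human * _normalized(human_affinity)
            + cfg.w_eco * _normalized(eco_dist)
            + cfg.w_hist * _normalized(hist_dist)
            + cfg.w_geo * _normalized(geo))
    breed_rows = []
    anchors: dict[str, str] = {}
    # balanced cradle allocation: every region serves as the anchor
    # ("cradle") of roughly the same number of breeds
    n_breeds_total = len(cfg.groups) * cfg.n_breeds_per_group
    anchor_pool = np.resize(rng.permutation(n), n_breeds_total)
    anchor_iter = iter(anchor_pool)
    for group in cfg.groups:
        anchor_idx = np.array([next(anchor_iter)
                               for _ in range(cfg.n_breeds_per_group)])
        breed_names = [f"{group}_breed{b + 1}"
                       for b in range(cfg.n_breeds_per_group)]
        for bname, a in zip(breed_names, anchor_idx):
            anchors[bname] = labels[int(a)]
        util = (-cfg.softmax_sharpness * comp[:, anchor_idx]
                + cfg.sigma * rng.standard_normal((n, cfg.n_breeds_per_group)))
        util -= util.max(axis=1, keepdims=True)
        shares = np.exp(util)
        shares /= shares.sum(axis=1, keepdims=True)
        totals = rng.poisson(cfg.heads_per_group, size=n)
        for r in range(n):
            heads = rng.multinomial(int(totals[r]), shares[r])
            for b, bname in enumerate(breed_names):
                breed_rows.append((labels[r], bname, group, int(heads[b])))
    breed_census = pd.DataFrame(breed_rows,
                                columns=["region", "breed", "group", "heads"])

    truth = GroundTruth(
        weights={"w_human": cfg.w_human, "w_eco": cfg.w_eco,
                 "w_hist": cfg.w_hist, "w_geo": cfg.w_geo},
        culture_distances=DistanceMatrix(human_affinity, regions,
                                         name="culture", validate=False),
        gradient=gradient,
        surname_origins=origins,
        polyphyletic_surnames=tuple(poly_names),
        division_labels=pd.DataFrame(
            division_table, index=labels,
            columns=[f"slice{t + 1}" for t in range(cfg.n_time_slices)]),
        breed_anchors=anchors,
    )
    return SyntheticDataset(regions=regions, breed_census=breed_census,
                            surname_counts=surname_counts,
                            occupancy=occupancy, membership=membership,
                            centroids=centroids, ground_truth=truth,
                            config=cfg)


# ---------------------------------------------------------------- export

_TABLE_FILES = {"breed_census": "breed_census.csv",
                "surname_counts": "surname_counts.csv",
                "occupancy": "occupancy.csv",
                "membership": "membership.csv",
                "centroids": "centroids.csv"}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def export_dataset(dataset: SyntheticDataset, directory) -> dict:
    """Write the five tables, the ground truth and a checksum manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files = {}
    for key, fname in _TABLE_FILES.items():
        path = directory / fname
        try:
            dataset.tables[key].to_csv(path, index=False,
                                       float_format="%.10g")
        except OSError as exc:
            raise OSError(f"failed writing table {key!r} to {path}: {exc}") \
                from exc
        files[fname] = _sha256(path)
    gt_path = directory / "ground_truth.json"
    payload = dataset.ground_truth.to_dict()
    payload["config"] = dataset.config.to_dict()
    gt_path.write_text(json.dumps(payload, indent=2, sort_keys=True))
    files[gt_path.name] = _sha256(gt_path)
    manifest = {"files": files}
    (directory / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def load_dataset(directory) -> dict[str, pd.DataFrame]:
    """Re-read an exported dataset's five tables through the validators."""
    from . import tables as t
    directory = Path(directory)
    return {
        "breed_census": t.read_breed_census(directory / "breed_census.csv"),
        "surname_counts": t.read_surname_counts(
            directory / "surname_counts.csv"),
        "occupancy": t.read_occupancy(directory / "occupancy.csv"),
        "membership": t.read_membership(directory / "membership.csv"),
        "centroids": t.read_centroids(directory / "centroids.csv"),
    }
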