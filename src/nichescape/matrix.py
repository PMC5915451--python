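"""Labelled symmetric distance matrices — the pipeline's universal currency.

A :class:`DistanceMatrix` couples a square, symmetric, zero-diagonal,
non-negative matrix with the :class:`~nichescape.regions.RegionSet` that
indexes it.  All statistics downstream (Mantel, correlograms, MRM) operate
on the *unfolded* lower triangle, taken in row-major pair order
(i > j): for three regions the order is (2,1), (3,1), (3,2).
"""

from __future__ import annotations

import hashlib

import numpy as np
import pandas as pd

from .regions import RegionSet

_SYM_TOL = 1e-9


class DistanceMatrix:
    """Square symmetric labelled matrix of pairwise distances."""

    __slots__ = ("regions", "values", "name")

    def __init__(self, values: np.ndarray, regions: RegionSet | None = None,
                 name: str | None = None, validate: bool = True):
        values = np.asarray(values, dtype=float)
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise ValueError(f"values must be square, got shape {values.shape}")
        if regions is None:
            regions = RegionSet(str(i + 1) for i in range(values.shape[0]))
        if len(regions) != values.shape[0]:
            raise ValueError(
                f"{len(regions)} region labels for a "
                f"{values.shape[0]}x{values.shape[0]} matrix")
        if validate:
            if not np.all(np.isfinite(values)):
                raise ValueError("non-finite distances")
            if np.any(values < 0):
                raise ValueError("negative distances")
            if np.any(np.abs(np.diagonal(values)) > _SYM_TOL):
                raise ValueError("non-zero diagonal")
            if np.any(np.abs(values - values.T) > _SYM_TOL * (1.0 + values.max())):
                raise ValueError("matrix is not symmetric")
            # exact symmetry and zero diagonal after the tolerance check
            values = (values + values.T) / 2.0
            np.fill_diagonal(values, 0.0)
        self.values = values
        self.regions = regions
        self.name = name

    # ------------------------------------------------------------------
    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def n_pairs(self) -> int:
        return self.n * (self.n - 1) // 2

    def condensed(self) -> np.ndarray:
        """Unfold the lower triangle, row-major with i > j."""
        i, j = np.tril_indices(self.n, -1)
        return self.values[i, j]

    @classmethod
    def from_condensed(cls, vec: np.ndarray, regions: RegionSet,
                       name: str | None = None) -> "DistanceMatrix":
        n = len(regions)
        vec = np.asarray(vec, dtype=float)
        if vec.shape != (n * (n - 1) // 2,):
            raise ValueError(f"condensed vector length {vec.shape} does not "
                             f"match {n} regions")
        out = np.zeros((n, n))
        i, j = np.tril_indices(n, -1)
        out[i, j] = vec
        out[j, i] = vec
        return cls(out, regions, name=name)

    def permute(self, order) -> "DistanceMatrix":
        """Reorder regions (rows and columns jointly) by integer positions."""
        order = np.asarray(order)
        new_regions = RegionSet(self.regions.labels[k] for k in order)
        return DistanceMatrix(self.values[np.ix_(order, order)], new_regions,
                              name=self.name, validate=False)

    def is_euclidean_metric(self, tol: float = 1e-8) -> bool:
        """Check the triangle inequality on every triple."""
        d = self.values
        # d[i,k] <= d[i,j] + d[j,k] for all j  <=>  min_j(d[i,j]+d[j,k]) >= d[i,k]
        via = np.min(d[:, :, None] + d[None, :, :], axis=1)
        return bool(np.all(d <= via + tol))

    # ------------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        labels = list(self.regions.labels)
        return pd.DataFrame(self.values, index=labels, columns=labels)

    def to_csv(self, path) -> None:
        """Full square matrix, labels as header row and first column."""
        df = self.to_frame()
        df.to_csv(path, float_format="%.10g", index_label="region")

    @classmethod
    def from_csv(cls, path, name: str | None = None) -> "DistanceMatrix":
        df = pd.read_csv(path, index_col=0)
        if list(df.index.astype(str)) != [str(c) for c in df.columns]:
            raise ValueError(f"{path}: row and column labels disagree")
        return cls(df.to_numpy(dtype=float),
                   RegionSet(str(c) for c in df.columns), name=name)

    def checksum(self) -> str:
        h = hashlib.sha256()
        h.update("|".join(self.regions.labels).encode())
        h.update(np.ascontiguousarray(np.round(self.values, 12)).tobytes())
        return h.hexdigest()[:16]

    def __repr__(self) -> str:
        tag = f" {self.name!r}" if self.name else ""
        return f"<DistanceMatrix{tag} n={self.n}>"


def unfold(d: DistanceMatrix) -> np.ndarray:
    """Lower-triangle entries of ``d`` in the shared pair order."""
    return d.condensed()


def check_same_regions(*matrices: DistanceMatrix) -> RegionSet:
    regions = matrices[0].regions
    for m in matrices[1:]:
        if m.regions != regions:
            raise ValueError("distance matrices are indexed by different "
                             "region sets (or different orders)")
    return regions
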