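"""Simple and partial Mantel tests with permutation inference.

The standardized Mantel statistic r_M is the Pearson correlation between
the unfolded lower triangles of two distance matrices.  Significance is
assessed by permuting region labels (rows and columns jointly) of one
matrix: the simple test permutes the second matrix, the partial test
permutes the first (response) matrix while holding the other matrix and
the covariate fixed — the classic raw-data permutation scheme.

P-values use the add-one estimator p = (1 + #{r_perm >= r_obs}) / (1 + N),
so they are never zero and never below 1/(N+1).
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field

import numpy as np

from .matrix import DistanceMatrix, check_same_regions

_TIE_TOL = 1e-12

__all__ = [
    "MantelResult", "MantelTest",
    "mantel_statistic", "mantel_test",
    "partial_mantel_statistic", "partial_mantel_test",
    "exact_mantel_p",
]


class DegenerateMatrixError(ValueError):
    """A matrix (or covariate combination) leaves the statistic undefined."""


def _condensed_checked(d: DistanceMatrix, what: str) -> np.ndarray:
    v = d.condensed()
    if np.ptp(v) == 0:
        raise DegenerateMatrixError(
            f"{what} matrix has constant off-diagonal values; "
            "the Mantel statistic is undefined")
    return v


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    return float((xc @ yc) / math.sqrt((xc @ xc) * (yc @ yc)))


def _partial_from_simple(r_ab: float, r_ac: float, r_bc: float) -> float:
    den = (1.0 - r_ac * r_ac) * (1.0 - r_bc * r_bc)
    if den <= _TIE_TOL:
        raise DegenerateMatrixError(
            "covariate is perfectly collinear with one of the matrices; "
            "the partial Mantel statistic is undefined")
    return (r_ab - r_ac * r_bc) / math.sqrt(den)


def mantel_statistic(a: DistanceMatrix, b: DistanceMatrix) -> float:
    """Pearson correlation of the unfolded triangles of ``a`` and ``b``."""
    check_same_regions(a, b)
    if a.n < 3:
        raise ValueError("Mantel statistic requires at least 3 regions")
    return _pearson(_condensed_checked(a, "first"),
                    _condensed_checked(b, "second"))


def partial_mantel_statistic(a: DistanceMatrix, b: DistanceMatrix,
                             c: DistanceMatrix) -> float:
    """First-order partial correlation r_AB.C on unfolded triangles."""
    check_same_regions(a, b, c)
    if a.n < 3:
        raise ValueError("partial Mantel statistic requires at least 3 regions")
    av = _condensed_checked(a, "first")
    bv = _condensed_checked(b, "second")
    cv = _condensed_checked(c, "covariate")
    return _partial_from_simple(_pearson(av, bv), _pearson(av, cv),
                                _pearson(bv, cv))


# ---------------------------------------------------------------- results

@dataclass(frozen=True)
class MantelResult:
    """Outcome of a (partial) Mantel permutation test."""

    statistic: float
    p_value: float
    n_permutations: int
    tail: str
    seed: int | None
    method: str = "mantel"
    matrix_ids: tuple[str, ...] = field(default_factory=tuple)

    @property
    def r_m(self) -> float:
        return self.statistic

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "p_value": self.p_value,
            "n_permutations": self.n_permutations,
            "tail": self.tail,
            "seed": self.seed,
            "method": self.method,
            "matrix_ids": list(self.matrix_ids),
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)

    def summary(self) -> str:
        label = {"mantel": "Mantel test",
                 "partial_mantel": "Partial Mantel test"}[self.method]
        lines = [label,
                 "-" * len(label),
                 f"r_M            {self.statistic: .4f}",
                 f"p-value        {self.p_value:.4g} ({self.tail})",
                 f"permutations   {self.n_permutations}"]
        if self.matrix_ids:
            lines.append("matrices       " + " ~ ".join(self.matrix_ids))
        return "\n".join(lines)


# ---------------------------------------------------------------- model

def _pair_index_matrix(n: int) -> np.ndarray:
    """idx[i, j] = position of pair {i, j} in the condensed vector."""
    idx = np.zeros((n, n), dtype=np.intp)
    i, j = np.tril_indices(n, -1)
    idx[i, j] = np.arange(len(i))
    idx[j, i] = idx[i, j]
    return idx


def _permuted_condensed(v: np.ndarray, pair_idx: np.ndarray,
                        perm: np.ndarray, tril: tuple) -> np.ndarray:
    """Condensed vector of the matrix after relabelling regions by ``perm``."""
    return v[pair_idx[perm[tril[0]], perm[tril[1]]]]


def _tail_count(stats: np.ndarray, observed: float, tail: str) -> int:
    if tail == "greater":
        return int(np.sum(stats >= observed - _TIE_TOL))
    if tail == "two-sided":
        return int(np.sum(np.abs(stats) >= abs(observed) - _TIE_TOL))
    raise ValueError(f"tail must be 'greater' or 'two-sided', got {tail!r}")


class MantelTest:
    """Simple or partial Mantel test between two distance matrices.

    Parameters
    ----------
    a, b :
        The two distance matrices to correlate.  In the partial test the
        permutation scheme relabels ``a`` (the response matrix).
    covariate :
        Optional third matrix; when given, the first-order partial
        correlation r_AB.C is tested.
    tail :
        ``'greater'`` (default; the directional isolation-by-distance
        hypothesis) or ``'two-sided'``.
    """

    def __init__(self, a: DistanceMatrix, b: DistanceMatrix,
                 covariate: DistanceMatrix | None = None,
                 tail: str = "greater"):
        mats = (a, b) if covariate is None else (a, b, covariate)
        self.regions = check_same_regions(*mats)
        if a.n < 3:
            raise ValueError("Mantel test requires at least 3 regions")
        if tail not in ("greater", "two-sided"):
            raise ValueError(f"unknown tail {tail!r}")
        self.a, self.b, self.covariate, self.tail = a, b, covariate, tail

    @property
    def statistic(self) -> float:
        if self.covariate is None:
            return mantel_statistic(self.a, self.b)
        return partial_mantel_statistic(self.a, self.b, self.covariate)

    def fit(self, n_permutations: int = 10000,
            seed: int | np.random.Generator | None = None) -> MantelResult:
        if n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        rng = np.random.default_rng(seed)
        n = self.a.n
        tril = np.tril_indices(n, -1)
        pair_idx = _pair_index_matrix(n)

        av = _condensed_checked(self.a, "first")
        bv = _condensed_checked(self.b, "second")
        perm_stats = np.empty(n_permutations)

        if self.covariate is None:
            observed = _pearson(av, bv)
            for k in range(n_permutations):
                perm = rng.permutation(n)
                perm_stats[k] = _pearson(
                    av, _permuted_condensed(bv, pair_idx, perm, tril))
            method = "mantel"
        else:
            cv = _condensed_checked(self.covariate, "covariate")
            r_bc = _pearson(bv, cv)
            observed = _partial_from_simple(_pearson(av, bv),
                                            _pearson(av, cv), r_bc)
            for k in range(n_permutations):
                perm = rng.permutation(n)
                ap = _permuted_condensed(av, pair_idx, perm, tril)
                perm_stats[k] = _partial_from_simple(
                    _pearson(ap, bv), _pearson(ap, cv), r_bc)
            method = "partial_mantel"

        k = _tail_count(perm_stats, observed, self.tail)
        p = (1.0 + k) / (1.0 + n_permutations)
        ids = tuple(m.name for m in (self.a, self.b, self.covariate)
                    if m is not None and m.name)
        return MantelResult(statistic=observed, p_value=p,
                            n_permutations=n_permutations, tail=self.tail,
                            seed=seed if isinstance(seed, int) else None,
                            method=method, matrix_ids=ids)


# ---------------------------------------------------------------- functions

def mantel_test(a: DistanceMatrix, b: DistanceMatrix,
                n_permutations: int = 10000, tail: str = "greater",
                seed: int | np.random.Generator | None = None) -> MantelResult:
    """Simple Mantel permutation test (permutes the region order of ``b``)."""
    return MantelTest(a, b, tail=tail).fit(n_permutations, seed)


def partial_mantel_test(a: DistanceMatrix, b: DistanceMatrix,
                        c: DistanceMatrix, n_permutations: int = 10000,
                        tail: str = "greater",
                        seed: int | np.random.Generator | None = None) -> MantelResult:
    """Partial Mantel permutation test (permutes the region order of ``a``)."""
    return MantelTest(a, b, covariate=c, tail=tail).fit(n_permutations, seed)


def exact_mantel_p(a: DistanceMatrix, b: DistanceMatrix,
                   tail: str = "greater",
                   partial_covariate: DistanceMatrix | None = None) -> float:
    """Exact permutation p-value over all n! simultaneous relabelings.

    Intended as a small-n oracle; refuses n > 8 (40320 relabelings).
    The identity relabeling is part of the reference set, so the p-value
    is at least 1/n!.
    """
    mats = (a, b) if partial_covariate is None else (a, b, partial_covariate)
    check_same_regions(*mats)
    n = a.n
    if n > 8:
        raise ValueError(f"exact enumeration refused for n = {n} > 8")
    tril = np.tril_indices(n, -1)
    pair_idx = _pair_index_matrix(n)
    av = _condensed_checked(a, "first")
    bv = _condensed_checked(b, "second")

    if partial_covariate is None:
        observed = _pearson(av, bv)

        def stat(perm):
            return _pearson(av, _permuted_condensed(bv, pair_idx, perm, tril))
    else:
        cv = _condensed_checked(partial_covariate, "covariate")
        r_bc = _pearson(bv, cv)
        observed = _partial_from_simple(_pearson(av, bv), _pearson(av, cv),
                                        r_bc)

        def stat(perm):
            ap = _permuted_condensed(av, pair_idx, perm, tril)
            return _partial_from_simple(_pearson(ap, bv), _pearson(ap, cv),
                                        r_bc)

    stats = np.array([stat(np.array(p))
                      for p in itertools.permutations(range(n))])
    return _tail_count(stats, observed, tail) / len(stats)
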