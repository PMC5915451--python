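"""Multiple regression on distance matrices (MRM).

Ordinary least squares of an unfolded response distance matrix on one or
more unfolded predictor matrices.  With ``standardize=True`` (default) all
unfolded vectors are z-scored before fitting, so the intercept is ~0 and
the slopes are standardized coefficients.  Significance comes from
permuting the region order of the response matrix (rows and columns
jointly) and refitting: coefficient p-values are two-sided on |b|, the R²
p-value is one-sided, both with the add-one estimator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import DistanceMatrix, check_same_regions, unfold
from .mantel import _pair_index_matrix, _permuted_condensed, _TIE_TOL

__all__ = ["MRMResult", "DistanceMatrixRegression", "mrm_fit", "unfold"]


class CollinearPredictorsError(ValueError):
    """Two predictor matrices are (numerically) perfectly collinear."""


@dataclass(frozen=True)
class MRMResult:
    """Fitted MRM coefficients with permutation p-values."""

    predictor_names: tuple[str, ...]
    intercept: float
    coefficients: np.ndarray
    coefficient_p_values: np.ndarray
    r_squared: float
    r_squared_p_value: float
    n_permutations: int
    standardize: bool
    seed: int | None = None

    @property
    def params(self) -> np.ndarray:
        return np.concatenate(([self.intercept], self.coefficients))

    def coefficient(self, name: str) -> float:
        return float(self.coefficients[self.predictor_names.index(name)])

    def to_frame(self) -> pd.DataFrame:
        rows = [("intercept", self.intercept, np.nan)]
        rows += list(zip(self.predictor_names, self.coefficients,
                         self.coefficient_p_values))
        return pd.DataFrame(rows, columns=["term", "coefficient", "p_value"])

    def to_dict(self) -> dict:
        return {
            "terms": self.to_frame().where(
                pd.notna(self.to_frame()), None).to_dict(orient="records"),
            "r_squared": self.r_squared,
            "r_squared_p_value": self.r_squared_p_value,
            "n_permutations": self.n_permutations,
            "standardize": self.standardize,
            "seed": self.seed,
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)

    def summary(self) -> str:
        title = "Multiple regression on distance matrices"
        lines = [title, "-" * len(title),
                 f"{'term':<14} {'coef':>9} {'p':>9}",
                 f"{'intercept':<14} {self.intercept:>9.4f} {'':>9}"]
        for name, b, p in zip(self.predictor_names, self.coefficients,
                              self.coefficient_p_values):
            lines.append(f"{name:<14} {b:>9.4f} {p:>9.4g}")
        lines.append(f"R² = {self.r_squared:.4f} "
                     f"(p = {self.r_squared_p_value:.4g}, "
                     f"{self.n_permutations} permutations)")
        return "\n".join(lines)


def _zscore(v: np.ndarray) -> np.ndarray:
    s = v.std()
    if s == 0:
        raise ValueError("constant unfolded vector cannot be standardized")
    return (v - v.mean()) / s


class DistanceMatrixRegression:
    """MRM model: a response distance matrix regressed on predictor matrices.

    Parameters
    ----------
    response :
        Response distance matrix.
    predictors :
        Non-empty list of predictor distance matrices sharing the
        response's region set.
    names :
        Predictor names; defaults to each matrix's ``name`` or ``x{i}``.
    standardize :
        Z-score all unfolded vectors before fitting (default True).
    """

    def __init__(self, response: DistanceMatrix,
                 predictors: list[DistanceMatrix],
                 names: list[str] | None = None, standardize: bool = True):
        if len(predictors) < 1:
            raise ValueError("need at least one predictor matrix")
        self.regions = check_same_regions(response, *predictors)
        self.response = response
        self.predictors = list(predictors)
        if names is None:
            names = [m.name or f"x{i + 1}" for i, m in enumerate(predictors)]
        if len(names) != len(predictors):
            raise ValueError("one name per predictor required")
        self.names = tuple(names)
        self.standardize = standardize

        cols = [unfold(m) for m in predictors]
        if standardize:
            cols = [_zscore(c) for c in cols]
        self._check_collinear(cols)
        self._X = np.column_stack([np.ones(len(cols[0]))] + cols)
        yv = unfold(response)
        self._y = _zscore(yv) if standardize else yv

    def _check_collinear(self, cols: list[np.ndarray]) -> None:
        k = len(cols)
        for i in range(k):
            for j in range(i + 1, k):
                a = cols[i] - cols[i].mean()
                b = cols[j] - cols[j].mean()
                denom = np.linalg.norm(a) * np.linalg.norm(b)
                if denom == 0 or abs(a @ b) / denom > 1 - 1e-10:
                    raise CollinearPredictorsError(
                        f"predictors {self.names[i]!r} and {self.names[j]!r} "
                        "are perfectly collinear")
        if np.linalg.matrix_rank(np.column_stack(cols)) < k:
            raise CollinearPredictorsError(
                "predictor matrices are jointly collinear")

    def fit(self, n_permutations: int = 10000,
            seed: int | np.random.Generator | None = None) -> MRMResult:
        if n_permutations < 0:
            raise ValueError("n_permutations must be >= 0")
        rng = np.random.default_rng(seed)
        X, y = self._X, self._y
        pinv = np.linalg.pinv(X)

        def fit_one(yv):
            beta = pinv @ yv
            resid = yv - X @ beta
            sst = ((yv - yv.mean()) ** 2).sum()
            r2 = 1.0 - (resid @ resid) / sst
            return beta, r2

        beta_obs, r2_obs = fit_one(y)

        n = self.response.n
        tril = np.tril_indices(n, -1)
        pair_idx = _pair_index_matrix(n)
        count_b = np.zeros(len(beta_obs) - 1)
        count_r2 = 0
        for _ in range(n_permutations):
            perm = rng.permutation(n)
            yp = _permuted_condensed(y, pair_idx, perm, tril)
            beta_p, r2_p = fit_one(yp)
            count_b += np.abs(beta_p[1:]) >= np.abs(beta_obs[1:]) - _TIE_TOL
            count_r2 += r2_p >= r2_obs - _TIE_TOL

        denom = 1.0 + n_permutations
        coef_p = (1.0 + count_b) / denom
        r2_p_value = (1.0 + count_r2) / denom
        return MRMResult(predictor_names=self.names,
                         intercept=float(beta_obs[0]),
                         coefficients=beta_obs[1:].copy(),
                         coefficient_p_values=coef_p,
                         r_squared=float(r2_obs),
                         r_squared_p_value=float(r2_p_value),
                         n_permutations=n_permutations,
                         standardize=self.standardize,
                         seed=seed if isinstance(seed, int) else None)


def mrm_fit(response: DistanceMatrix, predictors: list[DistanceMatrix],
            n_permutations: int = 10000, standardize: bool = True,
            seed: int | np.random.Generator | None = None,
            names: list[str] | None = None) -> MRMResult:
    """One-call MRM; see :class:`DistanceMatrixRegression`."""
    return DistanceMatrixRegression(response, predictors, names=names,
                                    standardize=standardize).fit(
                                        n_permutations, seed)
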