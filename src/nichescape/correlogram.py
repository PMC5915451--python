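"""Simple and partial Mantel correlograms.

A correlogram slices the region pairs into distance classes on a
classifying matrix (Sturges' rule by default), builds a 0/1 indicator
model matrix per class, and runs a (partial) Mantel test of the response
against each indicator.  By the default sign convention the raw indicator
correlation is negated, so positive values read "pairs in this class are
more similar than average".

Classes can be *untestable*: when the indicator is constant (an empty or
all-pairs class) or when the response values carry no variation within or
outside the class, the class reports a null statistic and a null p-value.
Significance of testable classes is Bonferroni-corrected (global
alpha / n_testable by default; Legendre's progressive variant optional).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .maths import round_half_up
from .matrix import DistanceMatrix, check_same_regions
from . import mantel as _mantel

__all__ = [
    "sturges_classes", "assign_distance_classes",
    "DistanceClassAssignment", "CorrelogramResult", "MantelCorrelogram",
    "mantel_correlogram",
]


def sturges_classes(n_pairs: int) -> int:
    """Number of distance classes by Sturges' rule, round(1 + log2 m)."""
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    return max(1, round_half_up(1.0 + math.log2(n_pairs)))


@dataclass(frozen=True)
class DistanceClassAssignment:
    """Equal-width distance classes over the off-diagonal values."""

    n_classes: int
    breakpoints: np.ndarray            # length n_classes + 1, increasing
    class_of_pair: np.ndarray          # condensed-order class index per pair
    midpoints: np.ndarray
    counts: np.ndarray

    def indicator(self, k: int) -> np.ndarray:
        """Condensed 0/1 vector flagging pairs in class ``k``."""
        return (self.class_of_pair == k).astype(float)


def assign_distance_classes(classifier: DistanceMatrix,
                            n_classes: int) -> DistanceClassAssignment:
    """Bin all region pairs into equal-width classes of the classifier."""
    if n_classes < 1:
        raise ValueError("n_classes must be >= 1")
    v = classifier.condensed()
    lo, hi = float(v.min()), float(v.max())
    if hi <= lo:
        raise _mantel.DegenerateMatrixError(
            "classifier matrix has constant off-diagonal values")
    edges = np.linspace(lo, hi, n_classes + 1)
    width = (hi - lo) / n_classes
    # upper edge inclusive on the last bin
    cls = np.minimum(((v - lo) / width).astype(int), n_classes - 1)
    mids = (edges[:-1] + edges[1:]) / 2.0
    counts = np.bincount(cls, minlength=n_classes)
    return DistanceClassAssignment(n_classes=n_classes, breakpoints=edges,
                                   class_of_pair=cls, midpoints=mids,
                                   counts=counts)


@dataclass(frozen=True)
class CorrelogramResult:
    """Per-class Mantel statistics of a (partial) correlogram."""

    midpoints: np.ndarray
    counts: np.ndarray
    statistics: list          # float or None per class
    p_values: list            # float or None per class
    testable: np.ndarray      # bool per class
    significant: np.ndarray   # bool per class (after correction)
    n_permutations: int
    alpha: float
    correction: str
    tail: str
    sign_convention: str
    covariate_id: str | None = None
    seed: int | None = None
    breakpoints: np.ndarray | None = None

    @property
    def n_classes(self) -> int:
        return len(self.midpoints)

    @property
    def n_testable(self) -> int:
        return int(self.testable.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "class": np.arange(self.n_classes),
            "midpoint": self.midpoints,
            "n_pairs": self.counts,
            "statistic": [np.nan if s is None else s for s in self.statistics],
            "p_value": [np.nan if p is None else p for p in self.p_values],
            "testable": self.testable,
            "significant_after_correction": self.significant,
        })

    def to_dict(self) -> dict:
        df = self.to_frame()
        records = df.where(pd.notna(df), None).to_dict(orient="records")
        return {"classes": records,
                "n_permutations": self.n_permutations,
                "alpha": self.alpha, "correction": self.correction,
                "tail": self.tail, "sign_convention": self.sign_convention,
                "covariate_id": self.covariate_id, "seed": self.seed}

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.10g")

    def summary(self) -> str:
        title = ("Partial Mantel correlogram" if self.covariate_id
                 else "Mantel correlogram")
        if self.covariate_id:
            title += f" (covariate: {self.covariate_id})"
        rows = [title, "-" * len(title),
                f"{'class':>5} {'midpoint':>10} {'pairs':>6} "
                f"{'r_M':>8} {'p':>8}  sig"]
        for k in range(self.n_classes):
            s, p = self.statistics[k], self.p_values[k]
            rows.append(
                f"{k:>5} {self.midpoints[k]:>10.4g} {self.counts[k]:>6} "
                + (f"{s:>8.4f} {p:>8.4g}" if s is not None
                   else f"{'--':>8} {'--':>8}")
                + ("  *" if self.significant[k] else ""))
        rows.append(f"{self.n_testable} testable classes; "
                    f"{self.correction} correction at alpha = {self.alpha}")
        return "\n".join(rows)

    def plot(self, ax=None, path=None):
        """Correlogram plot: midpoints on x, statistic on y, filled markers
        where significant after correction."""
        import matplotlib
        if path is not None and ax is None:
            matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots(figsize=(5, 3.5))
        for k in range(self.n_classes):
            s = self.statistics[k]
            if s is None:
                continue
            filled = bool(self.significant[k])
            ax.plot(self.midpoints[k], s, marker="D", linestyle="",
                    markerfacecolor="black" if filled else "white",
                    markeredgecolor="black")
        xs = [self.midpoints[k] for k in range(self.n_classes)
              if self.statistics[k] is not None]
        ys = [s for s in self.statistics if s is not None]
        ax.plot(xs, ys, color="black", linewidth=0.8, zorder=0)
        ax.axhline(0.0, color="grey", linewidth=0.6)
        ax.set_xlabel("distance class midpoint")
        ax.set_ylabel("Mantel statistic")
        if path is not None:
            ax.figure.savefig(path, bbox_inches="tight", dpi=150)
            plt.close(ax.figure)
        return ax


class MantelCorrelogram:
    """Correlogram of a response distance matrix over classes of a
    classifying matrix, optionally controlling for a covariate matrix.

    Parameters
    ----------
    response, classifier :
        Response matrix tested per class; classifier matrix whose values
        define the distance classes.
    covariate :
        Optional matrix partialled out of every per-class test.
    n_classes :
        Number of equal-width classes; ``None`` applies Sturges' rule to
        the number of region pairs.
    sign_convention :
        ``'similarity'`` (default) negates the raw indicator correlation so
        positive = within-class similarity; ``'raw'`` keeps it.
    """

    def __init__(self, response: DistanceMatrix, classifier: DistanceMatrix,
                 covariate: DistanceMatrix | None = None,
                 n_classes: int | None = None,
                 sign_convention: str = "similarity"):
        mats = [response, classifier] + ([covariate] if covariate is not None else [])
        self.regions = check_same_regions(*mats)
        if sign_convention not in ("similarity", "raw"):
            raise ValueError(f"unknown sign convention {sign_convention!r}")
        self.response = response
        self.classifier = classifier
        self.covariate = covariate
        self.n_classes = (sturges_classes(response.n_pairs)
                          if n_classes is None else int(n_classes))
        self.sign_convention = sign_convention
        self.assignment = assign_distance_classes(classifier, self.n_classes)

    def _class_testable(self, indicator: np.ndarray,
                        resp: np.ndarray) -> bool:
        inside = indicator > 0
        if inside.all() or not inside.any():
            return False            # constant indicator
        if np.ptp(resp[inside]) == 0 or np.ptp(resp[~inside]) == 0:
            return False            # no variation to correlate against
        return True

    def fit(self, n_permutations: int = 10000, alpha: float = 0.05,
            correction: str = "bonferroni", tail: str = "two-sided",
            seed: int | np.random.Generator | None = None) -> CorrelogramResult:
        if correction not in ("bonferroni", "progressive"):
            raise ValueError(f"unknown correction {correction!r}")
        rng = np.random.default_rng(seed)
        resp = self.response.condensed()
        sign = -1.0 if self.sign_convention == "similarity" else 1.0

        stats: list = [None] * self.n_classes
        pvals: list = [None] * self.n_classes
        testable = np.zeros(self.n_classes, dtype=bool)

        for k in range(self.n_classes):
            ind = self.assignment.indicator(k)
            if not self._class_testable(ind, resp):
                continue
            indicator_matrix = DistanceMatrix.from_condensed(
                ind, self.regions, name=f"class_{k}")
            try:
                test = _mantel.MantelTest(self.response, indicator_matrix,
                                          covariate=self.covariate, tail=tail)
                res = test.fit(n_permutations, rng)
            except _mantel.DegenerateMatrixError:
                continue
            testable[k] = True
            stats[k] = sign * res.statistic
            pvals[k] = res.p_value

        n_testable = int(testable.sum())
        if n_testable == 0:
            raise _mantel.DegenerateMatrixError(
                "no testable distance class in the correlogram")

        significant = np.zeros(self.n_classes, dtype=bool)
        if correction == "bonferroni":
            for k in range(self.n_classes):
                if testable[k]:
                    significant[k] = pvals[k] <= alpha / n_testable
        else:  # progressive: class i (in class order, 1-based) at alpha/i
            rank = 0
            for k in range(self.n_classes):
                if testable[k]:
                    rank += 1
                    significant[k] = pvals[k] <= alpha / rank

        return CorrelogramResult(
            midpoints=self.assignment.midpoints.copy(),
            counts=self.assignment.counts.copy(),
            statistics=stats, p_values=pvals, testable=testable,
            significant=significant, n_permutations=n_permutations,
            alpha=alpha, correction=correction, tail=tail,
            sign_convention=self.sign_convention,
            covariate_id=self.covariate.name if self.covariate is not None else None,
            seed=seed if isinstance(seed, int) else None,
            breakpoints=self.assignment.breakpoints.copy())


def mantel_correlogram(response: DistanceMatrix, classifier: DistanceMatrix,
                       covariate: DistanceMatrix | None = None,
                       n_classes: int | None = None,
                       n_permutations: int = 10000, alpha: float = 0.05,
                       seed: int | np.random.Generator | None = None,
                       **fit_kw) -> CorrelogramResult:
    """One-call (partial) Mantel correlogram; see :class:`MantelCorrelogram`."""
    model = MantelCorrelogram(response, classifier, covariate=covariate,
                              n_classes=n_classes)
    return model.fit(n_permutations=n_permutations, alpha=alpha, seed=seed,
                     **fit_kw)
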