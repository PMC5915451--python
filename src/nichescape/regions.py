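"""Ordered region sets shared by every matrix of one analysis."""

from __future__ import annotations

from collections.abc import Iterable, Sequence


class RegionSet:
    """An ordered collection of unique region identifiers.

    Every distance matrix in an analysis is indexed by one shared
    RegionSet; the label order fixes the row/column order and the
    pair-unfolding order everywhere downstream.
    """

    __slots__ = ("_labels", "_index")

    def __init__(self, labels: Iterable[str]):
        labels = tuple(str(x) for x in labels)
        if len(labels) < 2:
            raise ValueError(f"need at least 2 regions, got {len(labels)}")
        if len(set(labels)) != len(labels):
            seen, dups = set(), []
            for lab in labels:
                if lab in seen:
                    dups.append(lab)
                seen.add(lab)
            raise ValueError(f"duplicate region labels: {sorted(set(dups))}")
        self._labels = labels
        self._index = {lab: i for i, lab in enumerate(labels)}

    @property
    def labels(self) -> tuple[str, ...]:
        return self._labels

    def __len__(self) -> int:
        return len(self._labels)

    def __iter__(self):
        return iter(self._labels)

    def __contains__(self, label: object) -> bool:
        return label in self._index

    def __getitem__(self, i: int) -> str:
        return self._labels[i]

    def index(self, label: str) -> int:
        try:
            return self._index[label]
        except KeyError:
            raise KeyError(f"unknown region {label!r}") from None

    def indices(self, labels: Sequence[str]) -> list[int]:
        return [self.index(lab) for lab in labels]

    @property
    def n_pairs(self) -> int:
        n = len(self._labels)
        return n * (n - 1) // 2

    def __eq__(self, other: object) -> bool:
        return isinstance(other, RegionSet) and self._labels == other._labels

    def __hash__(self) -> int:
        return hash(self._labels)

    def __repr__(self) -> str:
        if len(self._labels) <= 6:
            body = ", ".join(self._labels)
        else:
            body = ", ".join(self._labels[:3]) + ", ..., " + self._labels[-1]
        return f"RegionSet({len(self)}: {body})"
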