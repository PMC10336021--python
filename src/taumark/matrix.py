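"""Labeled symmetric distance matrices with a missing-entry mask.

Every stage of the pipeline — per-locus distances, the genome-wide
reference (core-gene ANI, concatenation-based, user-supplied, or
patristic), and the correlation step — exchanges this one container.
Entries may be *masked* (undefined): a pair with no comparable sites,
or a model correction outside its domain (saturation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["DistanceMatrix"]

_SYM_TOL = 1e-9


@dataclass
class DistanceMatrix:
    """A labeled, symmetric, nonnegative distance matrix.

    Parameters
    ----------
    labels
        Ordered unique genome labels; ``values[i, j]`` is the distance
        between ``labels[i]`` and ``labels[j]``.
    values
        Square float array. Masked cells may hold any value (by
        convention ``nan``).
    mask
        Square boolean array, ``True`` where the entry is undefined.
        Defaults to all-unmasked. The diagonal is never masked.
    meta
        Provenance tag, e.g. ``"identity"``, ``"jc69"``, ``"k80"``,
        ``"core_ani"``, ``"concat"``, ``"patristic"``, ``"user"``.
    """

    labels: list[str]
    values: np.ndarray
    mask: np.ndarray | None = None
    meta: str = "user"
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.labels = [str(x) for x in self.labels]
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError(
                f"values shape {self.values.shape} does not match {n} labels"
            )
        if len(set(self.labels)) != n:
            raise ValueError("duplicate labels in distance matrix")
        if self.mask is None:
            self.mask = np.zeros((n, n), dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != (n, n):
                raise ValueError("mask shape does not match labels")
        if np.any(self.mask != self.mask.T):
            raise ValueError("mask must be symmetric")
        if np.any(np.diag(self.mask)):
            raise ValueError("diagonal entries must not be masked")
        np.fill_diagonal(self.values, 0.0)
        ok = ~self.mask
        if np.any(np.abs(self.values[ok] - self.values.T[ok]) > _SYM_TOL):
            raise ValueError("values must be symmetric where unmasked")
        off = ok.copy()
        np.fill_diagonal(off, False)
        vals = self.values[off]
        if np.any(~np.isfinite(vals)) or np.any(vals < 0):
            raise ValueError("unmasked off-diagonal values must be finite and >= 0")
        self.values = np.where(self.mask, np.nan, self.values)
        self._index = {lab: i for i, lab in enumerate(self.labels)}

    # -- access ---------------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.labels)

    def get(self, a: str, b: str) -> float:
        """Distance between labels *a* and *b* (nan if masked)."""
        return float(self.values[self._index[a], self._index[b]])

    def is_masked(self, a: str, b: str) -> bool:
        return bool(self.mask[self._index[a], self._index[b]])

    def reorder(self, labels: list[str]) -> "DistanceMatrix":
        """Return the submatrix over *labels*, in that order."""
        idx = [self._index[lab] for lab in labels]
        return DistanceMatrix(
            labels=list(labels),
            values=self.values[np.ix_(idx, idx)].copy(),
            mask=self.mask[np.ix_(idx, idx)].copy(),
            meta=self.meta,
        )

    def __eq__(self, other: object) -> bool:  # pragma: no cover - convenience
        if not isinstance(other, DistanceMatrix):
            return NotImplemented
        return (
            self.labels == other.labels
            and np.array_equal(self.mask, other.mask)
            and np.allclose(
                np.where(self.mask, 0.0, self.values),
                np.where(other.mask, 0.0, other.values),
            )
        )
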