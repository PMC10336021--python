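"""Rank correlation of two distance matrices over their common genomes.

The central comparison of the toolkit: flatten a locus matrix and the
genome-wide reference into paired vectors over the genome pairs both
define, then measure how well the locus reproduces the genome-wide
ranking. Kendall's tau-b is the default because distance matrices
routinely contain ties (identical sequences) and tau-b corrects for
ties in both variables; Spearman's rho and Pearson's r² are offered
as alternatives.

Degenerate inputs never raise: a comparison with too few pairs or a
constant vector yields a flagged result that downstream ranking sinks
to the bottom of the table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .matrix import DistanceMatrix

__all__ = [
    "PairedVectors",
    "CorrelationResult",
    "pair_matrices",
    "kendall_tau_b",
    "spearman_rho",
    "pearson_r2",
    "correlate",
    "METHODS",
]

METHODS = ("tau", "spearman", "pearson_r2")

DEFAULT_MIN_PAIRS = 3


@dataclass(frozen=True)
class PairedVectors:
    """Aligned distance vectors over common, unmasked genome pairs.

    Labels are sorted lexicographically and pairs enumerated in
    row-major upper-triangle order, so the pairing is canonical and
    independent of input label order.
    """

    x: np.ndarray
    y: np.ndarray
    n_pairs: int
    common_labels: list[str]


@dataclass(frozen=True)
class CorrelationResult:
    subject_id: str
    method: str
    coefficient: float | None
    n_pairs: int
    flag: str = "ok"  # ok | zero_variance | too_few_pairs
    extra: dict = field(default_factory=dict, compare=False)

    @property
    def ok(self) -> bool:
        return self.flag == "ok"


def pair_matrices(
    a: DistanceMatrix,
    b: DistanceMatrix,
    min_pairs: int = DEFAULT_MIN_PAIRS,
) -> PairedVectors:
    """Extract paired upper-triangle vectors over the matrices' common labels.

    Pairs masked in either matrix are dropped. Fewer than *min_pairs*
    surviving pairs is not an error here; the caller inspects
    ``n_pairs`` (``correlate`` turns it into a ``too_few_pairs`` flag).
    """
    common = sorted(set(a.labels) & set(b.labels))
    if len(common) < 2:
        return PairedVectors(np.empty(0), np.empty(0), 0, common)
    sa = a.reorder(common)
    sb = b.reorder(common)
    iu = np.triu_indices(len(common), k=1)
    keep = ~sa.mask[iu] & ~sb.mask[iu]
    x = sa.values[iu][keep]
    y = sb.values[iu][keep]
    return PairedVectors(x, y, int(keep.sum()), common)


def _tie_term(v: np.ndarray) -> float:
    _, counts = np.unique(v, return_counts=True)
    return float((counts * (counts - 1) // 2).sum())


def kendall_tau_b(x, y) -> float:
    """Tie-corrected Kendall rank correlation.

    ``tau_b = (C - D) / sqrt((n0 - n1)(n0 - n2))`` where C and D count
    concordant and discordant pairs, ``n0 = n(n-1)/2`` and ``n1``,
    ``n2`` are the tie terms of x and y. Returns ``nan`` when either
    denominator factor is zero (a constant vector).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = x.size
    if n < 2:
        return float("nan")
    sx = np.sign(x[:, None] - x[None, :])
    sy = np.sign(y[:, None] - y[None, :])
    iu = np.triu_indices(n, k=1)
    prod = sx[iu] * sy[iu]
    c_minus_d = float(prod.sum())
    n0 = n * (n - 1) / 2.0
    n1 = _tie_term(x)
    n2 = _tie_term(y)
    denom_sq = (n0 - n1) * (n0 - n2)
    if denom_sq <= 0:
        return float("nan")
    return c_minus_d / np.sqrt(denom_sq)


def spearman_rho(x, y) -> float:
    """Spearman rank correlation (Pearson correlation of midranks)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if x.size < 2 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def pearson_r2(x, y) -> tuple[float, float]:
    """Squared Pearson correlation; returns ``(r2, signed_r)``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if x.size < 2 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    r = float(stats.pearsonr(x, y).statistic)
    return r * r, r


def correlate(
    subject: DistanceMatrix,
    reference: DistanceMatrix,
    method: str = "tau",
    min_pairs: int = DEFAULT_MIN_PAIRS,
    subject_id: str | None = None,
) -> CorrelationResult:
    """Correlate a subject matrix against the reference.

    All failure modes (too few common unmasked pairs, zero variance)
    are encoded in the result's ``flag`` rather than raised.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    sid = subject_id if subject_id is not None else subject.meta
    pv = pair_matrices(subject, reference, min_pairs)
    if pv.n_pairs < min_pairs:
        return CorrelationResult(sid, method, None, pv.n_pairs, "too_few_pairs")
    if np.ptp(pv.x) == 0 or np.ptp(pv.y) == 0:
        return CorrelationResult(sid, method, None, pv.n_pairs, "zero_variance")
    extra: dict = {}
    if method == "tau":
        coef = kendall_tau_b(pv.x, pv.y)
    elif method == "spearman":
        coef = spearman_rho(pv.x, pv.y)
    else:
        coef, r = pearson_r2(pv.x, pv.y)
        extra["pearson_r"] = r
    if not np.isfinite(coef):
        return CorrelationResult(sid, method, None, pv.n_pairs, "zero_variance")
    return CorrelationResult(sid, method, float(coef), pv.n_pairs, "ok", extra)
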