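"""Pairwise nucleotide distances: p-distance, JC69, K80, core-gene ANI.

All comparisons use *pairwise deletion*: an alignment column enters a
pair's comparison only when both characters are unambiguous bases
(A, C, G or T). Transitions are the purine and pyrimidine exchanges
A<->G and C<->T; every other mismatch is a transversion.

Model corrections have limited domains. JC69's
``d = -(3/4) ln(1 - 4p/3)`` is undefined for p >= 0.75 and K80's
two-term formula is undefined when a log argument is non-positive;
such saturated pairs are *masked* in the output matrix rather than
capped, because capping manufactures ties that bias rank correlations.
An optional cap is available for users who prefer a finite matrix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .matrix import DistanceMatrix
from .seqio import Alignment

__all__ = [
    "PairwiseComparison",
    "compare_pair",
    "jc69",
    "k80",
    "locus_matrix",
    "core_ani_matrix",
    "concatenate",
    "MODELS",
]

MODELS = ("identity", "jc69", "k80")

# base byte -> code: A=0, C=1, G=2, T=3; anything else 255.
# Purines get even codes and pyrimidines odd codes, so a mismatch is a
# transition exactly when the two codes have equal parity.
_CODE = np.full(256, 255, dtype=np.uint8)
for _b, _c in zip(b"ACGT", (0, 1, 2, 3)):
    _CODE[_b] = _c


@dataclass(frozen=True)
class PairwiseComparison:
    """Mismatch summary for one aligned sequence pair.

    ``p`` is the total mismatch proportion over the ``n_sites``
    comparable columns, split into transition (``P``) and transversion
    (``Q``) proportions with ``P + Q = p``.
    """

    p: float
    n_sites: int
    P: float
    Q: float


def compare_pair(row_a: str, row_b: str) -> PairwiseComparison:
    """Compare two equal-length aligned sequences column by column."""
    if len(row_a) != len(row_b):
        raise ValueError("sequences must have equal length")
    a = _CODE[np.frombuffer(row_a.encode("ascii"), dtype=np.uint8)]
    b = _CODE[np.frombuffer(row_b.encode("ascii"), dtype=np.uint8)]
    valid = (a != 255) & (b != 255)
    n = int(valid.sum())
    if n == 0:
        return PairwiseComparison(0.0, 0, 0.0, 0.0)
    diff = valid & (a != b)
    ts = int((diff & ((a & 1) == (b & 1))).sum())
    tv = int(diff.sum()) - ts
    return PairwiseComparison((ts + tv) / n, n, ts / n, tv / n)


def jc69(p: float) -> float:
    """Jukes–Cantor distance from a mismatch proportion.

    Returns ``nan`` at or beyond the saturation bound p >= 3/4.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must be in [0, 1], got {p}")
    arg = 1.0 - (4.0 / 3.0) * p
    if arg <= 0.0:
        return math.nan
    return -0.75 * math.log(arg)


def k80(P: float, Q: float) -> float:
    """Kimura two-parameter distance from transition/transversion proportions.

    ``d = -(1/2) ln(1 - 2P - Q) - (1/4) ln(1 - 2Q)``; returns ``nan``
    whenever either log argument is non-positive (saturation).
    """
    if P < 0 or Q < 0 or P + Q > 1.0 + 1e-12:
        raise ValueError(f"invalid proportions P={P}, Q={Q}")
    a1 = 1.0 - 2.0 * P - Q
    a2 = 1.0 - 2.0 * Q
    if a1 <= 0.0 or a2 <= 0.0:
        return math.nan
    return -0.5 * math.log(a1) - 0.25 * math.log(a2)


def _pair_stats(aln: Alignment) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized all-pairs (n_sites, P_counts, Q_counts) over an alignment."""
    codes = _CODE[aln.to_array()]
    n = aln.n_taxa
    n_sites = np.zeros((n, n), dtype=np.int64)
    ts = np.zeros((n, n), dtype=np.int64)
    tv = np.zeros((n, n), dtype=np.int64)
    valid = codes != 255
    for i in range(n):
        vi = valid[i]
        ci = codes[i]
        both = vi & valid[i + 1 :]
        diff = both & (ci != codes[i + 1 :])
        is_ts = diff & (((ci & 1) == (codes[i + 1 :] & 1)))
        n_sites[i, i + 1 :] = both.sum(axis=1)
        ts[i, i + 1 :] = is_ts.sum(axis=1)
        tv[i, i + 1 :] = diff.sum(axis=1) - ts[i, i + 1 :]
    n_sites += n_sites.T
    ts += ts.T
    tv += tv.T
    return n_sites, ts, tv


def locus_matrix(
    aln: Alignment,
    model: str = "identity",
    min_sites: int = 1,
    saturation_cap: float | None = None,
) -> DistanceMatrix:
    """Pairwise distance matrix of one locus under the chosen model.

    ``identity`` uses the raw mismatch proportion p (so that all models
    share the same monotone orientation: larger = more divergent).
    Pairs with fewer than ``min_sites`` comparable columns are masked,
    as are saturated model corrections unless ``saturation_cap`` is
    given. Labels are sorted lexicographically.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")
    if aln.n_taxa < 2:
        raise ValueError("distance matrix requires at least 2 taxa")
    order = sorted(aln.taxa)
    aln = aln.subset(order)
    n_sites, ts, tv = _pair_stats(aln)
    n = aln.n_taxa
    with np.errstate(invalid="ignore", divide="ignore"):
        safe = np.maximum(n_sites, 1)
        P = ts / safe
        Q = tv / safe
        p = P + Q
        if model == "identity":
            d = p
        elif model == "jc69":
            arg = 1.0 - (4.0 / 3.0) * p
            d = np.where(arg > 0, -0.75 * np.log(np.maximum(arg, 1e-300)), np.nan)
        else:  # k80
            a1 = 1.0 - 2.0 * P - Q
            a2 = 1.0 - 2.0 * Q
            good = (a1 > 0) & (a2 > 0)
            d = np.where(
                good,
                -0.5 * np.log(np.maximum(a1, 1e-300))
                - 0.25 * np.log(np.maximum(a2, 1e-300)),
                np.nan,
            )
    mask = n_sites < max(min_sites, 1)
    if saturation_cap is not None:
        d = np.where(np.isnan(d) & ~mask, saturation_cap, d)
    else:
        mask |= np.isnan(d)
    np.fill_diagonal(mask, False)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(labels=order, values=d, mask=mask, meta=model)


def core_ani_matrix(loci: list[Alignment]) -> DistanceMatrix:
    """Length-weighted core-gene ANI, expressed as a distance.

    For each genome pair the identity is the mean of per-locus
    identities ``1 - p`` weighted by the number of comparable sites,
    over loci where both genomes are present; the matrix holds
    ``1 - identity``. Pairs with no contributing locus are masked.
    """
    if not loci:
        raise ValueError("core_ani_matrix requires at least one locus")
    universe: set[str] = set()
    for a in loci:
        universe.update(a.taxa)
    labels = sorted(universe)
    idx = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    mism = np.zeros((n, n))
    sites = np.zeros((n, n))
    for aln in loci:
        aln = aln.subset(sorted(aln.taxa))
        n_sites, ts, tv = _pair_stats(aln)
        rows = np.array([idx[t] for t in aln.taxa])
        sub = np.ix_(rows, rows)
        sites[sub] += n_sites
        mism[sub] += ts + tv
    mask = sites == 0
    np.fill_diagonal(mask, False)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(mask, np.nan, mism / np.maximum(sites, 1))
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(labels=labels, values=d, mask=mask, meta="core_ani")


def concatenate(loci: list[Alignment], set_id: str) -> Alignment:
    """Column-wise super-alignment of loci over the union of their taxa.

    Loci are appended in ascending ``locus_id`` order; a taxon missing
    from a locus receives an all-gap filler of that locus's length.
    """
    if not loci:
        raise ValueError("cannot concatenate an empty locus list")
    loci = sorted(loci, key=lambda a: a.locus_id)
    taxa: set[str] = set()
    for a in loci:
        taxa.update(a.taxa)
    order = sorted(taxa)
    parts: dict[str, list[str]] = {t: [] for t in order}
    for a in loci:
        present = set(a.taxa)
        filler = "-" * a.length
        for t in order:
            parts[t].append(a.row(t) if t in present else filler)
    return Alignment(set_id, order, ["".join(parts[t]) for t in order])
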