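"""Rank loci by correlation, group near-ties, build and re-score gene sets.

The headline procedure: single loci are sorted by how well their
distance matrices rank-correlate with the genome-wide reference; loci
whose coefficients differ by less than a small delta (default 0.05)
are grouped as practical ties, since such differences are unlikely to
matter next to wet-lab criteria like primer availability; and the
top-K loci (default K=10) are concatenated into super-alignments whose
correlation is re-evaluated to find complementary marker sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import pandas as pd

from .correlation import CorrelationResult, correlate
from .distances import concatenate, locus_matrix
from .matrix import DistanceMatrix
from .seqio import Alignment

__all__ = [
    "RankedRow",
    "RankedTable",
    "GeneSet",
    "rank_loci",
    "tie_groups",
    "build_gene_sets",
    "evaluate_gene_sets",
]

DEFAULT_TOP_K = 10
DEFAULT_TIE_DELTA = 0.05
EXHAUSTIVE_TOP_K_LIMIT = 15


@dataclass(frozen=True)
class RankedRow:
    rank: int
    result: CorrelationResult
    tie_group: int | None = None


@dataclass
class RankedTable:
    """Correlation results in ranked order, with optional tie groups."""

    rows: list[RankedRow]
    method: str = "tau"
    reference_meta: str = ""

    def __iter__(self):
        return iter(self.rows)

    def __len__(self) -> int:
        return len(self.rows)

    def to_dataframe(self) -> pd.DataFrame:
        recs = []
        for row in self.rows:
            r = row.result
            recs.append(
                {
                    "subject_id": r.subject_id,
                    "method": r.method,
                    "coefficient": r.coefficient,
                    "n_pairs": r.n_pairs,
                    "rank": row.rank,
                    "tie_group": row.tie_group,
                    "flag": r.flag,
                }
            )
        return pd.DataFrame.from_records(recs)


@dataclass
class GeneSet:
    """A candidate multi-locus typing marker (two or more loci)."""

    set_id: str
    members: list[str]
    coefficient: float | None = None

    def __post_init__(self) -> None:
        self.members = sorted(self.members)
        if len(self.members) < 2:
            raise ValueError("a gene set needs at least 2 member loci")
        if len(set(self.members)) != len(self.members):
            raise ValueError("gene set members must be unique")


def _sort_key(r: CorrelationResult):
    # ok results first, then coefficient desc, n_pairs desc, id asc
    coef = r.coefficient if r.ok and r.coefficient is not None else float("-inf")
    return (0 if r.ok else 1, -coef, -r.n_pairs, r.subject_id)


def rank_loci(results: list[CorrelationResult]) -> RankedTable:
    """Total deterministic ordering of correlation results.

    Failed results (``zero_variance``, ``too_few_pairs``) sink to the
    bottom, keeping their flag text; ranks are consecutive from 1.
    """
    if not results:
        raise ValueError("rank_loci requires at least one result")
    ordered = sorted(results, key=_sort_key)
    method = ordered[0].method
    return RankedTable(
        rows=[RankedRow(rank=i + 1, result=r) for i, r in enumerate(ordered)],
        method=method,
    )


def tie_groups(table: RankedTable, delta: float = DEFAULT_TIE_DELTA) -> list[list[RankedRow]]:
    """Greedy single-pass grouping of near-tied coefficients.

    Walking down the ranked table, a row joins the current group when
    its coefficient is within *delta* of the group's maximum, else it
    starts a new group. Failed rows each form their own trailing group.
    The table's rows are annotated with their group index in place.
    """
    if delta < 0:
        raise ValueError("delta must be >= 0")
    groups: list[list[RankedRow]] = []
    group_max: float | None = None
    for row in table.rows:
        r = row.result
        if r.ok and r.coefficient is not None and group_max is not None and (
            group_max - r.coefficient
        ) <= delta:
            groups[-1].append(row)
        else:
            groups.append([row])
            group_max = r.coefficient if r.ok else None
    annotated: list[RankedRow] = []
    for gi, grp in enumerate(groups, start=1):
        for k, row in enumerate(grp):
            new = RankedRow(rank=row.rank, result=row.result, tie_group=gi)
            grp[k] = new
            annotated.append(new)
    table.rows = annotated
    return groups


def build_gene_sets(
    table: RankedTable,
    top_k: int = DEFAULT_TOP_K,
    mode: str = "nested",
    max_size: int | None = None,
) -> list[GeneSet]:
    """Construct candidate gene sets from the top-K ranked loci.

    ``nested`` builds the prefix sets {top-2}, {top-3}, ..., {top-K};
    ``exhaustive`` enumerates every subset of the top-K of size 2 to
    ``max_size`` (guarded to K <= 15 against combinatorial blowup).
    Only flag-ok loci are eligible.
    """
    if top_k < 2:
        raise ValueError("top_k must be >= 2")
    if mode not in ("nested", "exhaustive"):
        raise ValueError(f"unknown set mode {mode!r}")
    if mode == "exhaustive" and top_k > EXHAUSTIVE_TOP_K_LIMIT:
        raise ValueError(
            f"exhaustive mode limited to top_k <= {EXHAUSTIVE_TOP_K_LIMIT} "
            f"(got {top_k}): subset count grows as 2^K"
        )
    ok_ids = [row.result.subject_id for row in table.rows if row.result.ok]
    if len(ok_ids) < 2:
        raise ValueError("need at least 2 successfully scored loci to build sets")
    top = ok_ids[:top_k]
    if max_size is None:
        max_size = len(top)
    sets: list[GeneSet] = []
    if mode == "nested":
        for k in range(2, len(top) + 1):
            members = top[:k]
            sets.append(GeneSet(set_id=f"top{k}", members=members))
    else:
        for size in range(2, min(max_size, len(top)) + 1):
            for combo in combinations(top, size):
                sets.append(
                    GeneSet(set_id="set_" + "+".join(sorted(combo)), members=list(combo))
                )
    return sets


def evaluate_gene_sets(
    sets: list[GeneSet],
    loci_by_id: dict[str, Alignment],
    reference: DistanceMatrix,
    model: str = "identity",
    method: str = "tau",
    min_sites: int = 1,
    min_pairs: int = 3,
) -> RankedTable:
    """Concatenate each gene set, recompute its distance matrix and re-score.

    The set's matrix uses the same distance model as single loci so the
    coefficients are directly comparable. Failures propagate into flags
    rather than exceptions.
    """
    results: list[CorrelationResult] = []
    for gs in sets:
        missing = [m for m in gs.members if m not in loci_by_id]
        if missing:
            raise KeyError(f"gene set {gs.set_id}: unknown loci {missing}")
        superaln = concatenate([loci_by_id[m] for m in gs.members], gs.set_id)
        dm = locus_matrix(superaln, model=model, min_sites=min_sites)
        res = correlate(dm, reference, method=method, min_pairs=min_pairs,
                        subject_id=gs.set_id)
        gs.coefficient = res.coefficient
        res.extra["members"] = list(gs.members)
        results.append(res)
    table = rank_loci(results)
    table.reference_meta = reference.meta
    return table
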