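"""Seed-deterministic synthetic datasets for exercising the pipeline.

The generator emulates the situation the method is designed for: a
collection of conspecific genomes related by one shared phylogeny,
a panel of core loci evolving clock-like on that phylogeny at
per-locus rates, and — to probe ranking power — *decoy* loci whose
signal is decoupled from the true tree by evolving them on a
leaf-label-permuted copy (rate preserved, phylogenetic information
destroyed). Optional dropout removes random (locus, taxon) pairs to
emulate incomplete core-gene presence.

Trees are Yule-style: random pairwise joins with exponential waiting
times, rescaled so the (ultrametric) root-to-tip height equals the
requested divergence in expected substitutions per site. Sequences
evolve under Jukes–Cantor: along a branch of length ``t`` (rate
``r``), each site changes with probability
``(3/4)(1 - exp(-(4/3) r t))``, landing uniformly on the other three
bases. No indels are simulated, so alignments come out gap-free.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .phylo import Node, Tree, write_newick
from .seqio import Alignment, write_fasta_alignment

__all__ = [
    "SimulationConfig",
    "simulate_tree",
    "evolve_locus",
    "simulate_dataset",
    "write_dataset",
]

_BASES = "ACGT"


@dataclass
class SimulationConfig:
    """Ground truth for one synthetic dataset.

    ``tree_height`` is the expected root-to-tip divergence in
    substitutions per site; 0.05 (≈95% ANI between distant strains)
    sits in the intra-species band the method targets.
    """

    n_taxa: int = 12
    tree_height: float = 0.05
    n_loci: int = 20
    locus_length: int | list[int] = 1000
    rate_multipliers: list[float] | None = None
    decoy_flags: list[bool] | None = None
    dropout_prob: float = 0.0
    seed: int = 0

    lengths: list[int] = field(init=False)
    rates: list[float] = field(init=False)
    decoys: list[bool] = field(init=False)

    def __post_init__(self) -> None:
        if self.n_taxa < 2:
            raise ValueError("n_taxa must be >= 2")
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        if not 0.0 <= self.dropout_prob < 1.0:
            raise ValueError("dropout_prob must be in [0, 1)")
        if self.tree_height <= 0:
            raise ValueError("tree_height must be > 0")
        if isinstance(self.locus_length, int):
            self.lengths = [self.locus_length] * self.n_loci
        else:
            self.lengths = list(self.locus_length)
        if len(self.lengths) != self.n_loci or any(L < 1 for L in self.lengths):
            raise ValueError("locus lengths must be >= 1, one per locus")
        self.rates = (
            [1.0] * self.n_loci
            if self.rate_multipliers is None
            else list(self.rate_multipliers)
        )
        if len(self.rates) != self.n_loci or any(r <= 0 for r in self.rates):
            raise ValueError("rate multipliers must be > 0, one per locus")
        self.decoys = (
            [False] * self.n_loci
            if self.decoy_flags is None
            else list(self.decoy_flags)
        )
        if len(self.decoys) != self.n_loci:
            raise ValueError("decoy_flags must have one entry per locus")


def simulate_tree(n_taxa: int, tree_height: float, seed: int) -> Tree:
    """Random Yule-style ultrametric tree with leaves ``G1..Gn``.

    Lineages are joined pairwise at exponential waiting times (rate =
    current lineage count), then all branch lengths are rescaled so the
    root-to-tip height equals *tree_height*.
    """
    if n_taxa < 2:
        raise ValueError("n_taxa must be >= 2")
    rng = np.random.default_rng(seed)
    lineages: list[tuple[Node, float]] = [
        (Node(name=f"G{i + 1}"), 0.0) for i in range(n_taxa)
    ]
    age = 0.0
    while len(lineages) > 1:
        k = len(lineages)
        age += rng.exponential(1.0 / k)
        i, j = sorted(rng.choice(k, size=2, replace=False))
        (a, age_a), (b, age_b) = lineages[i], lineages[j]
        parent = Node()
        a.length = age - age_a
        b.length = age - age_b
        parent.add(a)
        parent.add(b)
        lineages = [lineages[m] for m in range(k) if m not in (i, j)]
        lineages.append((parent, age))
    root, root_age = lineages[0]
    scale = tree_height / root_age
    stack = [root]
    while stack:
        node = stack.pop()
        if node.length is not None:
            node.length *= scale
        stack.extend(node.children)
    root.length = None
    return Tree(root)


def _evolve_branch(parent_seq: np.ndarray, p_change: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Apply JC69 along one branch: each site flips with prob p_change
    to one of the three other bases, uniformly."""
    child = parent_seq.copy()
    hits = rng.random(child.size) < p_change
    n_hit = int(hits.sum())
    if n_hit:
        # offset 1..3 from the current base, mod 4, is uniform over the others
        child[hits] = (child[hits] + rng.integers(1, 4, size=n_hit)) % 4
    return child


def evolve_locus(tree: Tree, length: int, rate: float, seed: int) -> Alignment:
    """Evolve one gap-free locus of *length* sites along *tree* under JC69."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if rate < 0:
        raise ValueError("rate must be >= 0")
    rng = np.random.default_rng(seed)
    root_seq = rng.integers(0, 4, size=length)
    taxa: list[str] = []
    seqs: list[str] = []

    def descend(node: Node, seq: np.ndarray) -> None:
        for child in node.children:
            if child.length is None:
                raise ValueError("evolve_locus requires branch lengths")
            p_change = 0.75 * (1.0 - np.exp(-(4.0 / 3.0) * rate * child.length))
            cseq = _evolve_branch(seq, p_change, rng)
            if child.is_leaf:
                taxa.append(child.name)  # type: ignore[arg-type]
                seqs.append("".join(_BASES[b] for b in cseq))
            else:
                descend(child, cseq)

    if tree.root.is_leaf:
        raise ValueError("tree must have at least 2 leaves")
    descend(tree.root, root_seq)
    order = sorted(range(len(taxa)), key=lambda i: taxa[i])
    return Alignment("locus", [taxa[i] for i in order], [seqs[i] for i in order])


def simulate_dataset(
    cfg: SimulationConfig,
) -> tuple[list[Alignment], Tree, pd.DataFrame]:
    """Generate the full dataset: loci, true tree and a truth manifest.

    Decoy loci evolve on a leaf-permuted copy of the true tree;
    dropout removes (locus, taxon) pairs after evolution (never below
    2 taxa per locus). All randomness derives from ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    tree_seed, evo_seed_base, perm_seed, drop_seed = rng.integers(
        0, 2**31 - 1, size=4
    )
    tree = simulate_tree(cfg.n_taxa, cfg.tree_height, int(tree_seed))
    drop_rng = np.random.default_rng(int(drop_seed))
    perm_rng = np.random.default_rng(int(perm_seed))
    labels = sorted(tree.leaf_labels)

    loci: list[Alignment] = []
    records = []
    width = len(str(cfg.n_loci))
    for k in range(cfg.n_loci):
        locus_id = f"locus{k + 1:0{width}d}"
        if cfg.decoys[k]:
            perm = perm_rng.permutation(len(labels))
            mapping = {labels[i]: labels[perm[i]] for i in range(len(labels))}
            evo_tree = tree.relabel(mapping)
        else:
            evo_tree = tree
        aln = evolve_locus(
            evo_tree, cfg.lengths[k], cfg.rates[k], int(evo_seed_base) + k
        )
        aln.locus_id = locus_id
        dropped: list[str] = []
        if cfg.dropout_prob > 0:
            drops = drop_rng.random(len(labels)) < cfg.dropout_prob
            dropped = [t for t, dr in zip(labels, drops) if dr]
            if len(labels) - len(dropped) >= 2:
                aln = aln.subset([t for t in labels if t not in set(dropped)])
                aln.locus_id = locus_id
            else:
                dropped = []
        loci.append(aln)
        records.append(
            {
                "locus_id": locus_id,
                "length": cfg.lengths[k],
                "rate": cfg.rates[k],
                "decoy": cfg.decoys[k],
                "dropped_taxa": ";".join(dropped),
            }
        )
    manifest = pd.DataFrame.from_records(records)
    return loci, tree, manifest


def write_dataset(
    cfg: SimulationConfig, outdir: str | Path
) -> tuple[list[Path], Path, Path]:
    """Materialize a simulated dataset as FASTA + Newick + manifest TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    loci, tree, manifest = simulate_dataset(cfg)
    loci_dir = outdir / "loci"
    loci_dir.mkdir(exist_ok=True)
    paths = []
    for aln in loci:
        p = loci_dir / f"{aln.locus_id}.fasta"
        write_fasta_alignment(aln, p)
        paths.append(p)
    tree_path = outdir / "true_tree.nwk"
    tree_path.write_text(write_newick(tree) + "\n")
    manifest_path = outdir / "manifest.tsv"
    manifest.to_csv(manifest_path, sep="\t", index=False)
    return paths, tree_path, manifest_path
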