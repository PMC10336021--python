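"""On-disk formats: FASTA alignments, CSV sample sheets, PHYLIP matrices.

Conventions
-----------
* The taxon label of a FASTA record is the header up to the first
  whitespace, and is expected to be a genome ID shared across loci.
* Sequences are uppercased on read and ``U`` is mapped to ``T`` so the
  rest of the toolkit sees a single canonical alphabet.
* Distance matrices are written as *square relaxed PHYLIP*: first line
  is the taxon count, then one row per taxon (label, whitespace, full
  row with 6 decimal places, masked entries as ``NA``). Labels are not
  truncated to 10 characters.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO

from .matrix import DistanceMatrix

__all__ = [
    "Alignment",
    "SampleSheet",
    "read_fasta_alignment",
    "write_fasta_alignment",
    "read_sample_sheet",
    "write_phylip_matrix",
    "read_matrix",
    "collect_loci",
]

logger = logging.getLogger(__name__)

_FASTA_SUFFIXES = {".fa", ".fasta", ".fna", ".aln", ".afa"}

_UPPER_U2T = str.maketrans(
    "abcdefghijklmnopqrstuvwxyzUu", "ABCDEFGHIJKLMNOPQRSTUVWXYZTT"
)


def _canon(seq: str) -> str:
    return seq.translate(_UPPER_U2T)


@dataclass
class Alignment:
    """One locus's gap-padded sequences over a shared genome set."""

    locus_id: str
    taxa: list[str]
    seqs: list[str]

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.seqs):
            raise ValueError("taxa and seqs length mismatch")
        if len(set(self.taxa)) != len(self.taxa):
            dup = sorted({t for t in self.taxa if self.taxa.count(t) > 1})
            raise ValueError(f"duplicate taxon label(s): {', '.join(dup)}")
        lengths = {len(s) for s in self.seqs}
        if len(lengths) > 1:
            ref = len(self.seqs[0])
            for t, s in zip(self.taxa, self.seqs):
                if len(s) != ref:
                    raise ValueError(
                        f"ragged alignment in locus '{self.locus_id}': "
                        f"taxon '{t}' has length {len(s)}, expected {ref}"
                    )
        if self.seqs and len(self.seqs[0]) < 1:
            raise ValueError(f"locus '{self.locus_id}' has zero columns")
        self.seqs = [_canon(s) for s in self.seqs]

    @property
    def length(self) -> int:
        return len(self.seqs[0]) if self.seqs else 0

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def row(self, taxon: str) -> str:
        return self.seqs[self.taxa.index(taxon)]

    def subset(self, taxa: list[str]) -> "Alignment":
        """Restrict to the given taxa (those present), preserving their order."""
        keep = [t for t in taxa if t in set(self.taxa)]
        return Alignment(self.locus_id, keep, [self.row(t) for t in keep])

    def to_array(self) -> np.ndarray:
        """Byte matrix (n_taxa x length) of the uppercased sequences."""
        return np.frombuffer(
            "".join(self.seqs).encode("ascii"), dtype=np.uint8
        ).reshape(self.n_taxa, self.length)


@dataclass
class SampleSheet:
    """Parsed "sample,fasta" sheet declaring the genome universe."""

    entries: list[tuple[str, str]] = field(default_factory=list)

    @property
    def samples(self) -> list[str]:
        return [s for s, _ in self.entries]


def read_fasta_alignment(path: str | Path, locus_id: str | None = None) -> Alignment:
    """Read one locus alignment from a FASTA file.

    The taxon label is the header token before the first whitespace.
    Raises on empty files, duplicate labels and ragged rows.
    """
    path = Path(path)
    if locus_id is None:
        locus_id = path.stem
    taxa: list[str] = []
    seqs: list[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        taxa.append(rec.id)
        seqs.append(str(rec.seq))
    if not taxa:
        raise ValueError(f"no FASTA records in {path}")
    if len(taxa) < 2:
        raise ValueError(f"alignment {path} has fewer than 2 records")
    return Alignment(locus_id, taxa, seqs)


def write_fasta_alignment(aln: Alignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for t, s in zip(aln.taxa, aln.seqs):
            fh.write(f">{t}\n")
            for i in range(0, len(s), 80):
                fh.write(s[i : i + 80] + "\n")


def read_sample_sheet(path: str | Path) -> SampleSheet:
    """Read a CSV sample sheet with the mandatory header ``sample,fasta``.

    Spaces after commas are tolerated; sample IDs must be unique.
    """
    path = Path(path)
    entries: list[tuple[str, str]] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"sample sheet {path} is empty") from None
        header = [h.strip() for h in header]
        if header != ["sample", "fasta"]:
            raise ValueError(
                f"sample sheet {path}: expected header 'sample,fasta', "
                f"got {','.join(header)!r}"
            )
        seen: set[str] = set()
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) != 2:
                raise ValueError(
                    f"sample sheet {path} line {lineno}: expected 2 fields"
                )
            sample, fasta = (c.strip() for c in row)
            if not sample or not fasta:
                raise ValueError(
                    f"sample sheet {path} line {lineno}: empty field"
                )
            if sample in seen:
                raise ValueError(
                    f"sample sheet {path}: duplicate sample '{sample}'"
                )
            seen.add(sample)
            entries.append((sample, fasta))
    return SampleSheet(entries)


def write_phylip_matrix(dm: DistanceMatrix, path: str | Path) -> None:
    """Write a square relaxed-PHYLIP matrix; masked entries become ``NA``."""
    if dm.n == 0:
        raise ValueError("cannot write an empty distance matrix")
    with open(path, "w") as fh:
        fh.write(f"{dm.n}\n")
        for i, lab in enumerate(dm.labels):
            cells = [
                "NA" if dm.mask[i, j] else f"{dm.values[i, j]:.6f}"
                for j in range(dm.n)
            ]
            fh.write(lab + " " + " ".join(cells) + "\n")


_ASYM_TOL = 1e-6


def _finish_matrix(labels: list[str], values: np.ndarray, mask: np.ndarray,
                   meta: str) -> DistanceMatrix:
    both = ~mask & ~mask.T
    diff = np.abs(np.where(both, values - values.T, 0.0))
    if np.nanmax(diff, initial=0.0) > _ASYM_TOL:
        i, j = np.unravel_index(np.argmax(diff), diff.shape)
        raise ValueError(
            f"matrix asymmetric at ({labels[i]}, {labels[j]}): "
            f"{values[i, j]!r} vs {values[j, i]!r}"
        )
    # symmetrize by averaging; a cell masked on one side only adopts the other
    sym_mask = mask & mask.T
    vals = np.where(both, (values + values.T) / 2.0,
                    np.where(mask, values.T, values))
    np.fill_diagonal(vals, 0.0)
    np.fill_diagonal(sym_mask, False)
    return DistanceMatrix(labels=labels, values=vals, mask=sym_mask, meta=meta)


def read_matrix(path: str | Path) -> DistanceMatrix:
    """Read a distance matrix from square PHYLIP or labeled TSV.

    The file is sniffed: a first line holding a single integer means
    PHYLIP, otherwise a TSV with identical row/column label sets is
    expected. The result is symmetrized by averaging; asymmetry beyond
    1e-6 is an error; ``NA`` cells are masked; the diagonal is forced
    to 0.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        if not first.strip():
            raise ValueError(f"matrix file {path} is empty")
        tokens = first.split()
        if len(tokens) == 1 and tokens[0].isdigit():
            return _read_phylip(fh, int(tokens[0]), path)
        return _read_tsv(path)


def _parse_cell(tok: str) -> tuple[float, bool]:
    if tok.upper() in {"NA", "NAN"}:
        return (np.nan, True)
    return (float(tok), False)


def _read_phylip(fh, n: int, path: Path) -> DistanceMatrix:
    labels: list[str] = []
    values = np.zeros((n, n))
    mask = np.zeros((n, n), dtype=bool)
    for i in range(n):
        line = fh.readline()
        if not line.strip():
            raise ValueError(f"{path}: expected {n} matrix rows, got {i}")
        parts = line.split()
        if len(parts) != n + 1:
            raise ValueError(
                f"{path}: row {i + 1} has {len(parts) - 1} cells, expected {n}"
            )
        labels.append(parts[0])
        for j, tok in enumerate(parts[1:]):
            values[i, j], mask[i, j] = _parse_cell(tok)
    if len(set(labels)) != n:
        raise ValueError(f"{path}: duplicate labels")
    return _finish_matrix(labels, values, mask, "user")


def _read_tsv(path: Path) -> DistanceMatrix:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    rows = [str(x) for x in df.index]
    cols = [str(x) for x in df.columns]
    if set(rows) != set(cols):
        raise ValueError(f"{path}: row and column label sets differ")
    if len(set(rows)) != len(rows):
        raise ValueError(f"{path}: duplicate labels")
    df = df.loc[rows, rows]
    values = df.to_numpy(dtype=float)
    mask = np.isnan(values)
    return _finish_matrix(rows, values, mask, "user")


def collect_loci(
    directory: str | Path,
    sheet: SampleSheet | None = None,
    core_fraction: float = 1.0,
) -> list[Alignment]:
    """Load all per-locus FASTA alignments in *directory* and keep the core.

    The taxon universe is the sample sheet's samples when given, else
    the union of taxa across all loci. A locus is kept when it covers at
    least ``core_fraction`` of the universe. When a sheet is given, each
    alignment is restricted to the sheet's taxa. Results are sorted by
    ``locus_id`` so output never depends on filesystem listing order.
    """
    directory = Path(directory)
    if not (0.0 < core_fraction <= 1.0):
        raise ValueError("core_fraction must be in (0, 1]")
    files = sorted(
        p for p in directory.iterdir()
        if p.is_file() and p.suffix.lower() in _FASTA_SUFFIXES
    )
    if not files:
        raise ValueError(f"no FASTA files found in {directory}")
    loci = [read_fasta_alignment(p) for p in files]
    if sheet is not None:
        universe = set(sheet.samples)
        loci = [a.subset(sorted(universe)) for a in loci]
    else:
        universe = set()
        for a in loci:
            universe.update(a.taxa)
    threshold = core_fraction * len(universe)
    kept = [a for a in loci if a.n_taxa >= threshold and a.n_taxa >= 2]
    dropped = [a.locus_id for a in loci if a not in kept]
    if dropped:
        logger.info(
            "collect_loci: discarded %d of %d loci below core_fraction=%g: %s",
            len(dropped), len(loci), core_fraction, ", ".join(dropped),
        )
    if not kept:
        raise ValueError(
            f"no loci cover >= {core_fraction:.0%} of the {len(universe)} "
            "genome universe; consider lowering core_fraction"
        )
    kept.sort(key=lambda a: a.locus_id)
    return kept
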