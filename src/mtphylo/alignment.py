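"""Aligned mtDNA matrices: FASTA input, coordinate masking, informative sites.

An :class:`Alignment` is a taxa x columns character matrix together with the
rCRS position of every column, so that masking and annotation can always be
expressed in reference coordinates even after columns have been removed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
import numpy as np
from Bio import SeqIO

from .reference import RCRS_LENGTH

VALID_CHARS = frozenset(bytes([c]) for c in b"ACGT-N")
_BASES = np.frombuffer(b"ACGT", dtype="S1")


class AlignmentError(ValueError):
    """Raised for malformed alignment input."""


@dataclass
class Alignment:
    """Taxa x sites matrix of single characters with per-column rCRS positions.

    ``matrix`` is a 2-D numpy array of dtype ``S1`` over {A,C,G,T,-,N};
    ``column_positions`` holds the 1-based rCRS position of each column and is
    strictly increasing; ``taxa`` are unique ordered labels.
    """

    taxa: list[str]
    matrix: np.ndarray
    column_positions: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype="S1")
        self.column_positions = np.asarray(self.column_positions, dtype=np.int64)
        if self.matrix.ndim != 2:
            raise AlignmentError("matrix must be 2-D (taxa x columns)")
        if len(self.taxa) != self.matrix.shape[0]:
            raise AlignmentError("taxa count does not match matrix rows")
        if len(set(self.taxa)) != len(self.taxa):
            raise AlignmentError("duplicate taxon labels")
        if self.column_positions.shape[0] != self.matrix.shape[1]:
            raise AlignmentError("column_positions length does not match matrix columns")
        if self.matrix.shape[1] and np.any(np.diff(self.column_positions) <= 0):
            raise AlignmentError("column_positions must be strictly increasing")
        bad = set(np.unique(self.matrix).tolist()) - VALID_CHARS
        if bad:
            raise AlignmentError(f"invalid characters in alignment: {sorted(bad)}")

    @property
    def n_taxa(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]

    def row(self, taxon: str) -> np.ndarray:
        return self.matrix[self.taxa.index(taxon)]

    def select_columns(self, keep: np.ndarray) -> "Alignment":
        """New alignment restricted to the given column index array/mask."""
        return Alignment(
            taxa=list(self.taxa),
            matrix=self.matrix[:, keep],
            column_positions=self.column_positions[keep],
        )

    def sequence_str(self, taxon: str) -> str:
        return self.row(taxon).tobytes().decode()

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for i, t in enumerate(self.taxa):
                fh.write(f">{t}\n{self.matrix[i].tobytes().decode()}\n")


@dataclass(frozen=True)
class SiteReport:
    """Parsimony-informative columns and per-column residue counts.

    A column is informative when at least two states are each carried by at
    least two taxa; only such columns can differ in cost between topologies.
    """

    informative_columns: list[int]
    informative_positions: list[int]
    counts: np.ndarray  # (n_columns, 4) counts of A,C,G,T per column

    @property
    def n_informative(self) -> int:
        return len(self.informative_columns)


def read_fasta_alignment(
    path: str | Path, positions_tsv: str | Path | None = None
) -> Alignment:
    """Read an aligned multi-FASTA (rCRS coordinates, equal lengths).

    Characters are uppercased on read; IUPAC ambiguity codes other than N are
    normalised to N.  ``positions_tsv`` optionally supplies a two-column
    (column index, rCRS position) sidecar for pre-trimmed alignments;
    otherwise columns are numbered 1..L.
    """
    taxa: list[str] = []
    rows: list[np.ndarray] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in taxa:
            raise AlignmentError(f"duplicate taxon label {rec.id!r}")
        seq = str(rec.seq).upper()
        arr = np.frombuffer(seq.encode(), dtype="S1").copy()
        # non-standard ambiguity codes become N
        known = np.isin(arr, np.frombuffer(b"ACGT-N", dtype="S1"))
        arr[~known] = b"N"
        taxa.append(rec.id)
        rows.append(arr)
    if not taxa:
        raise AlignmentError(f"no FASTA records in {path}")
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise AlignmentError(f"unequal sequence lengths: {sorted(lengths)}")
    (length,) = lengths
    if positions_tsv is not None:
        positions = _read_positions_tsv(positions_tsv, length)
    else:
        positions = np.arange(1, length + 1)
    return Alignment(taxa=taxa, matrix=np.vstack(rows), column_positions=positions)


def _read_positions_tsv(path: str | Path, length: int) -> np.ndarray:
    positions = np.full(length, -1, dtype=np.int64)
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            col, pos = line.split()[:2]
            positions[int(col) - 1] = int(pos)
    if np.any(positions < 1):
        raise AlignmentError(f"position track {path} does not cover all columns")
    return positions


def mask_to_range(aln: Alignment, lo: int, hi: int) -> Alignment:
    """Keep exactly the columns whose rCRS position lies in [lo, hi] (1-based)."""
    if not (1 <= lo <= hi <= RCRS_LENGTH):
        raise AlignmentError(f"mask range {lo}..{hi} outside 1..{RCRS_LENGTH}")
    keep = (aln.column_positions >= lo) & (aln.column_positions <= hi)
    return aln.select_columns(keep)


def drop_gapped_columns(aln: Alignment) -> Alignment:
    """Remove every column in which any taxon carries '-' or 'N'."""
    gapped = np.any((aln.matrix == b"-") | (aln.matrix == b"N"), axis=0)
    return aln.select_columns(~gapped)


def base_counts(aln: Alignment) -> np.ndarray:
    """Per-column counts of A, C, G, T, shape (n_columns, 4)."""
    return np.stack([(aln.matrix == b).sum(axis=0) for b in _BASES], axis=1)


def informative_sites(aln: Alignment) -> SiteReport:
    """Classify parsimony-informative columns (>=2 states each in >=2 taxa)."""
    counts = base_counts(aln)
    informative = (counts >= 2).sum(axis=1) >= 2
    cols = np.nonzero(informative)[0]
    return SiteReport(
        informative_columns=cols.tolist(),
        informative_positions=aln.column_positions[cols].tolist(),
        counts=counts,
    )


def variable_columns(aln: Alignment) -> np.ndarray:
    """Indices of columns with more than one residue state (gap-free input)."""
    counts = base_counts(aln)
    return np.nonzero((counts > 0).sum(axis=1) >= 2)[0]
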