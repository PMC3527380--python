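"""Reference genome and gene map in the rCRS coordinate frame.

All positions in this package are 1-based inclusive against the 16,569-bp
revised Cambridge Reference Sequence (rCRS) coordinate frame.  The packaged
gene map is the standard rCRS annotation (37 genes plus the control region).
The packaged *sequence* is a synthetic stand-in (see ``data/``): it has the
correct length and the true rCRS base at every position this package's
documented examples refer to, with deterministic filler elsewhere.  Users
analysing real data should supply the genuine rCRS FASTA via
:func:`load_reference`'s ``fasta`` argument; everything downstream only
assumes the coordinate frame.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
from Bio import SeqIO

RCRS_LENGTH = 16569

#: feature classes in ascending annotation precedence
FEATURE_CLASSES = ("other", "control", "rRNA", "tRNA", "protein")


class ReferenceError(ValueError):
    """Raised when a packaged or user-supplied reference fails validation."""


@dataclass(frozen=True)
class GeneFeature:
    """One annotated feature on the reference, 1-based inclusive coordinates."""

    name: str
    start: int
    end: int
    feature_class: str  # protein / tRNA / rRNA / control / other
    strand: int = 1  # +1 heavy strand, -1 light strand (e.g. ND6)

    def __post_init__(self):
        if not (1 <= self.start <= self.end <= RCRS_LENGTH):
            raise ReferenceError(
                f"{self.name}: coordinates {self.start}..{self.end} outside 1..{RCRS_LENGTH}"
            )
        if self.feature_class not in FEATURE_CLASSES:
            raise ReferenceError(f"{self.name}: unknown feature class {self.feature_class!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end


class GeneMap:
    """The rCRS gene annotation with a deterministic primary class per position.

    Overlapping annotations are resolved by class precedence
    protein > tRNA > rRNA > control > other; ties within a class go to the
    feature listed first (e.g. ATP8 over ATP6 in their overlap).  Every
    position 1..16569 therefore maps to exactly one primary feature class
    ("other" where nothing is annotated).
    """

    def __init__(self, entries: Iterable[GeneFeature]):
        self.entries: list[GeneFeature] = list(entries)
        if not self.entries:
            raise ReferenceError("gene map has no entries")
        # paint per-position primary feature, low precedence first so that
        # higher precedence (and, within a class, earlier-listed) wins
        gene_idx = np.full(RCRS_LENGTH + 1, -1, dtype=np.int32)  # index 0 unused
        for cls in FEATURE_CLASSES:
            for i in reversed(range(len(self.entries))):
                f = self.entries[i]
                if f.feature_class == cls:
                    gene_idx[f.start : f.end + 1] = i
        self._gene_idx = gene_idx
        self._by_name = {f.name: f for f in self.entries}
        if len(self._by_name) != len(self.entries):
            raise ReferenceError("duplicate feature names in gene map")

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, name: str) -> GeneFeature:
        return self._by_name[name]

    def feature_at(self, position: int) -> Optional[GeneFeature]:
        """Primary feature covering ``position``, or None if unannotated."""
        if not (1 <= position <= RCRS_LENGTH):
            raise ReferenceError(f"position {position} outside 1..{RCRS_LENGTH}")
        i = int(self._gene_idx[position])
        return None if i < 0 else self.entries[i]

    def feature_class_at(self, position: int) -> str:
        f = self.feature_at(position)
        return "other" if f is None else f.feature_class

    def protein_genes(self) -> list[GeneFeature]:
        return [f for f in self.entries if f.feature_class == "protein"]

    def validate(self) -> None:
        for f in self.protein_genes():
            # mitochondrial ORFs may end on an incomplete stop codon that is
            # completed by polyadenylation, so length mod 3 may be 0, 1 or 2
            if f.length < 3:
                raise ReferenceError(f"{f.name}: implausibly short protein gene")


@dataclass(frozen=True)
class ReferenceGenome:
    """A complete mtDNA reference in the rCRS coordinate frame."""

    sequence: str
    name: str = "rCRS"
    circular: bool = True

    def __post_init__(self):
        if len(self.sequence) != RCRS_LENGTH:
            raise ReferenceError(
                f"reference length {len(self.sequence)} != {RCRS_LENGTH}"
            )
        if set(self.sequence) - set("ACGT"):
            raise ReferenceError("reference contains non-ACGT characters")

    def base_at(self, position: int) -> str:
        """1-based lookup."""
        if not (1 <= position <= RCRS_LENGTH):
            raise ReferenceError(f"position {position} outside 1..{RCRS_LENGTH}")
        return self.sequence[position - 1]

    def as_array(self) -> np.ndarray:
        return np.frombuffer(self.sequence.encode(), dtype="S1").copy()


def _data_path(fname: str) -> Path:
    return Path(str(resources.files("mtphylo").joinpath("data", fname)))


def load_gene_map(tsv: Optional[str | Path] = None) -> GeneMap:
    """Load a gene map TSV (name, start, end, feature_class, strand)."""
    path = Path(tsv) if tsv is not None else _data_path("rcrs_genes.tsv")
    entries = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:4] != ["name", "start", "end", "feature_class"]:
            raise ReferenceError(f"malformed gene map header in {path}")
        for line in fh:
            if not line.strip():
                continue
            name, start, end, cls, strand = line.rstrip("\n").split("\t")
            entries.append(
                GeneFeature(name, int(start), int(end), cls, -1 if strand == "-" else 1)
            )
    gm = GeneMap(entries)
    gm.validate()
    return gm


def load_reference(
    fasta: Optional[str | Path] = None, gene_map_tsv: Optional[str | Path] = None
) -> tuple[ReferenceGenome, GeneMap]:
    """Load the packaged reference fixture (or user-supplied files).

    Returns the reference genome and its gene map.  Deterministic; raises
    :class:`ReferenceError` on a corrupted fixture.
    """
    path = Path(fasta) if fasta is not None else _data_path("rcrs_synthetic.fasta")
    try:
        record = next(SeqIO.parse(str(path), "fasta"))
    except StopIteration:
        raise ReferenceError(f"no FASTA record in {path}") from None
    ref = ReferenceGenome(sequence=str(record.seq).upper(), name=record.id)
    return ref, load_gene_map(gene_map_tsv)
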