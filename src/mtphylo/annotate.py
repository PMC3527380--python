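"""Variant calling and annotation against the rCRS coordinate frame.

Substitutions are named by rCRS position and derived base ("73G"),
transversions spelled out ("228 GtvT"), deletions marked "del", RNA-gene
changes suffixed "~r" (rRNA) or "~t" (tRNA), and non-synonymous changes in
protein genes carry the amino-acid change in brackets ("8860G[thr-ala]").
Recurrent hits on a tree are flagged with "*" and numbered "(1)", "(2)".
Synonymy is evaluated with the vertebrate mitochondrial genetic code
(translation table 2) in the codon context of a supplied background sequence,
so multi-hit codons are judged against their actual ancestral state rather
than the reference.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

import numpy as np

from .reference import GeneFeature, GeneMap, ReferenceGenome

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: vertebrate mitochondrial code (translation table 2): AGA/AGG stop,
#: ATA Met, TGA Trp; otherwise the standard code.
CODON_TABLE_2 = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "M", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "W", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "*", "AGG": "*",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

AA_THREE = {
    "A": "ala", "R": "arg", "N": "asn", "D": "asp", "C": "cys",
    "Q": "gln", "E": "glu", "G": "gly", "H": "his", "I": "ile",
    "L": "leu", "K": "lys", "M": "met", "F": "phe", "P": "pro",
    "S": "ser", "T": "thr", "W": "trp", "Y": "tyr", "V": "val",
    "*": "ter",
}
THREE_AA = {v: k for k, v in AA_THREE.items()}


class AnnotationError(ValueError):
    pass


@dataclass(frozen=True)
class VariantCall:
    """A single difference in rCRS coordinates.

    ``ref_base`` is the source state of the change (the rCRS base when calling
    a sequence against the reference, or the parent-node state when the call
    sits on a tree branch); ``obs_base`` is the derived state, None for a
    deletion.
    """

    position: int
    ref_base: str
    obs_base: Optional[str]
    kind: str  # transition / transversion / deletion
    feature_class: Optional[str] = None
    gene: Optional[str] = None
    coding_effect: Optional[str] = None  # synonymous/nonsynonymous/rna/noncoding/na
    aa_change: Optional[tuple[str, str]] = None  # three-letter lowercase codes
    is_reversion: Optional[bool] = None
    is_recurrent: bool = False
    occurrence_index: Optional[int] = None


def substitution_kind(ref: str, obs: str) -> str:
    if ref == obs:
        raise AnnotationError(f"{ref}->{obs} is not a substitution")
    pair = {ref, obs}
    return "transition" if pair <= PURINES or pair <= PYRIMIDINES else "transversion"


def call_variants(
    seq: str | np.ndarray | Sequence[str],
    ref: ReferenceGenome,
    positions: Optional[Sequence[int]] = None,
) -> list[VariantCall]:
    """Call differences of an aligned sequence against the reference.

    ``positions`` maps each character of ``seq`` to its rCRS position
    (defaults to 1..len(seq)).  One call per differing position, ordered by
    position; '-' against the reference is emitted as a deletion; 'N' is
    skipped.
    """
    chars = [c.decode() if isinstance(c, bytes) else str(c) for c in seq]
    if positions is None:
        positions = range(1, len(chars) + 1)
    calls = []
    for c, pos in zip(chars, positions):
        c = c.upper()
        rb = ref.base_at(int(pos))
        if c == rb or c == "N":
            continue
        if c == "-":
            calls.append(VariantCall(int(pos), rb, None, "deletion"))
        else:
            calls.append(VariantCall(int(pos), rb, c, substitution_kind(rb, c)))
    calls.sort(key=lambda v: v.position)
    return calls


def _codon_at(
    gene: GeneFeature, position: int, genome: Sequence[str], base_override: str
) -> tuple[str, int]:
    """Codon containing ``position`` with the focal base replaced.

    ``genome`` is a full-genome sequence (1-based position p at index p-1)
    supplying the untouched codon positions; incomplete terminal codons are
    completed with 'A' (polyadenylation convention).  Returns the codon read
    in coding orientation and the 0-based index of the focal base within it.
    Minus-strand genes (ND6) are evaluated on the reverse complement.
    """
    if gene.strand == 1:
        offset = position - gene.start
        within = offset % 3
        first = gene.start + offset - within
        bases = []
        for p in (first, first + 1, first + 2):
            if p == position:
                bases.append(base_override)
            elif p <= gene.end:
                bases.append(genome[p - 1])
            else:
                bases.append("A")
        return "".join(bases), within
    offset = gene.end - position
    within = offset % 3
    first = gene.end - (offset - within)
    bases = []
    for p in (first, first - 1, first - 2):
        if p == position:
            b = base_override
        elif p >= gene.start:
            b = genome[p - 1]
        else:
            b = "A"
        bases.append(COMPLEMENT[b])
    return "".join(bases), within


def classify_coding_effect(
    v: VariantCall, gene_map: GeneMap, background: str | Sequence[str]
) -> VariantCall:
    """Fill feature class and coding effect of a call.

    ``background`` is a full-genome sequence providing the two untouched codon
    positions (use the parent-node reconstruction when annotating a tree
    branch, else the reference itself).
    """
    feature = gene_map.feature_at(v.position)
    if feature is None:
        return replace(v, feature_class="other", gene=None, coding_effect="na")
    if feature.feature_class in ("rRNA", "tRNA"):
        return replace(v, feature_class=feature.feature_class, gene=feature.name,
                       coding_effect="rna")
    if feature.feature_class == "control":
        return replace(v, feature_class="control", gene=feature.name,
                       coding_effect="noncoding")
    if feature.feature_class != "protein":
        return replace(v, feature_class=feature.feature_class, gene=feature.name,
                       coding_effect="na")
    if v.kind == "deletion":
        # frameshift; out of scope for codon-level classification
        return replace(v, feature_class="protein", gene=feature.name, coding_effect="na")
    from_codon, _ = _codon_at(feature, v.position, background, v.ref_base)
    to_codon, _ = _codon_at(feature, v.position, background, v.obs_base)
    aa_from = CODON_TABLE_2[from_codon]
    aa_to = CODON_TABLE_2[to_codon]
    if aa_from == aa_to:
        return replace(v, feature_class="protein", gene=feature.name,
                       coding_effect="synonymous")
    return replace(v, feature_class="protein", gene=feature.name,
                   coding_effect="nonsynonymous",
                   aa_change=(AA_THREE[aa_from], AA_THREE[aa_to]))


def annotate_variants(
    calls: Iterable[VariantCall], gene_map: GeneMap, background: str | Sequence[str]
) -> list[VariantCall]:
    return [classify_coding_effect(v, gene_map, background) for v in calls]


@dataclass(frozen=True)
class BranchLabel:
    """Rendered form of a VariantCall; ``italic`` marks reversions."""

    text: str
    italic: bool = False

    def __str__(self) -> str:
        return self.text


def format_label(v: VariantCall) -> BranchLabel:
    """Render a call in the branch-labelling convention.

    Transitions as position+derived base ("73G"); transversions spelled
    "228 GtvT"; deletions "16166del"; "~r"/"~t" suffixes for rRNA/tRNA genes;
    non-synonymous changes bracketed "[ala-thr]"; recurrent changes starred
    and numbered.  Reversions to the reference base are flagged for italic
    rendering rather than altering the text.
    """
    if v.kind == "deletion":
        core = f"{v.position}del"
    elif v.kind == "transversion":
        core = f"{v.position} {v.ref_base}tv{v.obs_base}"
    else:
        core = f"{v.position}{v.obs_base}"
    if v.feature_class == "rRNA":
        core += "~r"
    elif v.feature_class == "tRNA":
        core += "~t"
    if v.coding_effect == "nonsynonymous" and v.aa_change:
        core += f"[{v.aa_change[0]}-{v.aa_change[1]}]"
    if v.is_recurrent:
        core += "*"
    if v.occurrence_index is not None:
        core += f"({v.occurrence_index})"
    return BranchLabel(text=core, italic=bool(v.is_reversion))


_TRANSITION_PARTNER = {"A": "G", "G": "A", "C": "T", "T": "C"}

_LABEL_RE = re.compile(
    r"^(?P<pos>\d+)"
    r"(?:(?P<del>del)|\s(?P<tvref>[ACGT])tv(?P<tvobs>[ACGT])|(?P<obs>[ACGT]))"
    r"(?P<rna>~[rt])?"
    r"(?:\[(?P<aafrom>[a-z]{3})-(?P<aato>[a-z]{3})\])?"
    r"(?P<star>\*)?"
    r"(?:\((?P<occ>\d+)\))?$"
)


def parse_label(text: str) -> VariantCall:
    """Invert :func:`format_label` as far as the label encodes.

    Transition source bases are recovered as the transition partner of the
    derived base; feature class is recovered from the "~r"/"~t" suffix and
    coding effect from a bracketed amino-acid change where present.
    """
    m = _LABEL_RE.match(text.strip())
    if not m:
        raise AnnotationError(f"unparseable branch label {text!r}")
    pos = int(m.group("pos"))
    if m.group("del"):
        kind, rb, ob = "deletion", "N", None
    elif m.group("tvref"):
        rb, ob = m.group("tvref"), m.group("tvobs")
        kind = substitution_kind(rb, ob)
        if kind != "transversion":
            raise AnnotationError(f"label {text!r} marks a transition as tv")
    else:
        ob = m.group("obs")
        rb = _TRANSITION_PARTNER[ob]
        kind = "transition"
    feature_class = None
    effect = None
    if m.group("rna"):
        feature_class = "rRNA" if m.group("rna") == "~r" else "tRNA"
        effect = "rna"
    aa = None
    if m.group("aafrom"):
        aa = (m.group("aafrom"), m.group("aato"))
        effect = "nonsynonymous"
        feature_class = "protein"
    occ = m.group("occ")
    return VariantCall(
        position=pos, ref_base=rb, obs_base=ob, kind=kind,
        feature_class=feature_class, coding_effect=effect, aa_change=aa,
        is_recurrent=bool(m.group("star")),
        occurrence_index=int(occ) if occ else None,
    )
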