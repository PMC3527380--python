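"""Partition-based lower bounds and parsimony minimality certificates.

The heuristic search supplies an upper bound (the best tree length found).
Partition the variable characters into disjoint blocks, compute for each
block the *exact* minimum parsimony score over all trees (by enumeration on
pattern-collapsed taxa), and sum: because any single tree simultaneously
realises every block, the sum is a lower bound on the length of the best
tree.  When the bound meets the upper bound, the heuristic trees are proven
globally minimal.

The bound is improved by grouping mutually incompatible characters: two
characters that cannot both be homoplasy-free on one tree force an extra
change when scored together ("rectangle" conflicts around recurrent sites),
which singleton blocks cannot see.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .alignment import Alignment, variable_columns
from .parsimony import TreeSet, exhaustive_min_length, fitch_length

__all__ = [
    "CharacterPartition", "ProofCertificate", "SqueezeConfig",
    "block_min_score", "build_rectangle_blocks", "squeeze", "verify_certificate",
]


class SqueezeError(ValueError):
    pass


@dataclass(frozen=True)
class SqueezeConfig:
    """Budget and exactness limits for the partition search.

    ``max_block_patterns`` bounds the number of distinct row patterns a block
    may collapse to before exact enumeration is refused; ``max_pair_checks``
    bounds the number of block-merge evaluations in the hill-climb so the
    search is deterministic without wall-clock dependence.
    """

    max_block_patterns: int = 9
    max_pair_checks: int = 2000


@dataclass
class CharacterPartition:
    """Disjoint blocks of column indices covering all variable columns."""

    blocks: list[list[int]]

    def validate(self, all_columns: Iterable[int]) -> None:
        seen: set[int] = set()
        for b in self.blocks:
            bs = set(b)
            if seen & bs:
                raise SqueezeError("partition blocks overlap")
            seen |= bs
        if seen != set(all_columns):
            raise SqueezeError("partition does not cover the variable columns")


@dataclass
class ProofCertificate:
    """Re-checkable record of a minimality proof attempt."""

    upper_bound: int
    partition: CharacterPartition
    block_minima: list[int]
    lower_bound: int
    status: str  # "proven" | "unproven"
    block_positions: list[list[int]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "upper_bound": self.upper_bound,
            "lower_bound": self.lower_bound,
            "status": self.status,
            "blocks": self.block_positions,
            "block_minima": self.block_minima,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def report(self) -> str:
        lines = [
            f"upper bound (best tree found): {self.upper_bound}",
            f"lower bound (sum of block minima): {self.lower_bound}",
            f"status: {self.status}",
            f"{len(self.block_minima)} blocks:",
        ]
        for pos, m in zip(self.block_positions, self.block_minima):
            lines.append(f"  sites {pos} -> minimum {m}")
        return "\n".join(lines)


def _collapsed_block(aln: Alignment, block: Sequence[int]) -> Alignment:
    """Sub-alignment of the block's columns with identical rows merged."""
    block = sorted(block)
    sub = aln.matrix[:, block]
    uniq = np.unique(sub, axis=0)
    return Alignment(
        taxa=[f"pattern{i}" for i in range(uniq.shape[0])],
        matrix=uniq,
        column_positions=aln.column_positions[block],
    )


def block_min_score(
    aln: Alignment, block: Sequence[int], max_patterns: int = 9
) -> int:
    """Exact minimum parsimony score of a character block over ALL trees.

    Taxa with identical patterns across the block are merged first (they can
    always be attached at zero cost); the minimum is then found by full
    topology enumeration.  Refuses blocks whose collapsed pattern count
    exceeds ``max_patterns`` — exactness is mandatory here, so the caller
    must split such blocks instead.
    """
    if not len(block):
        return 0
    collapsed = _collapsed_block(aln, block)
    k = collapsed.n_taxa
    if k == 1:
        return 0
    if len(block) == 1:
        # one character: its best tree groups each state into one subtree
        states = len({bytes(collapsed.matrix[i, 0]) for i in range(k)})
        return states - 1
    if k > max_patterns:
        raise SqueezeError(
            f"block collapses to {k} patterns (> {max_patterns}); split it"
        )
    score, _ = exhaustive_min_length(collapsed)
    return score


def _pair_conflict(aln: Alignment, c1: int, c2: int, cfg: SqueezeConfig) -> int:
    """Extra changes forced by scoring columns c1 and c2 jointly (0 if compatible)."""
    try:
        joint = block_min_score(aln, [c1, c2], cfg.max_block_patterns)
    except SqueezeError:
        return 0  # too many patterns for exactness; claim nothing
    single = block_min_score(aln, [c1]) + block_min_score(aln, [c2])
    return joint - single


def build_rectangle_blocks(
    aln: Alignment,
    recurrent_sites: Sequence[int],
    config: SqueezeConfig = SqueezeConfig(),
) -> CharacterPartition:
    """Partition guided by conflict rectangles around recurrent sites.

    ``recurrent_sites`` are rCRS positions known (e.g. from branch-mutation
    mapping) to need more than one change on the best trees found.  Each such
    site is grouped with the sites it is pairwise incompatible with, so the
    forced extra changes enter the lower bound; all remaining variable
    columns stay as singleton blocks.
    """
    var = variable_columns(aln).tolist()
    pos_to_col = {int(aln.column_positions[c]): c for c in var}
    used: set[int] = set()
    blocks: list[list[int]] = []
    for pos in recurrent_sites:
        col = pos_to_col.get(int(pos))
        if col is None or col in used:
            continue
        block = [col]
        used.add(col)
        for other in var:
            if other in used:
                continue
            trial = sorted(block + [other])
            k = np.unique(aln.matrix[:, trial], axis=0).shape[0]
            if k > config.max_block_patterns:
                continue
            if _pair_conflict(aln, col, other, config) > 0:
                block.append(other)
                used.add(other)
        blocks.append(sorted(block))
    for c in var:
        if c not in used:
            blocks.append([c])
    part = CharacterPartition(blocks=blocks)
    part.validate(var)
    return part


def squeeze(
    aln: Alignment,
    upper_bound: Optional[int] = None,
    trees: Optional[TreeSet] = None,
    recurrent_sites: Sequence[int] = (),
    config: SqueezeConfig = SqueezeConfig(),
) -> ProofCertificate:
    """Attempt a minimality proof for the given upper bound.

    The upper bound is recomputed from ``trees`` when supplied (and it is an
    error to claim an upper bound no provided tree achieves).  The partition
    search starts from singletons, adds rectangle-guided groupings around
    ``recurrent_sites``, then hill-climbs with pairwise block merges while
    the bound improves, within ``config.max_pair_checks`` evaluations.
    """
    if trees is not None:
        scores = [fitch_length(t, aln) for t in trees.trees]
        achieved = min(scores) if scores else None
        if upper_bound is None:
            upper_bound = achieved
        elif achieved is None or achieved != upper_bound:
            raise SqueezeError(
                f"claimed upper bound {upper_bound} not achieved by the "
                f"provided trees (best recomputed: {achieved})"
            )
    if upper_bound is None:
        raise SqueezeError("need an upper bound or a tree set")

    var = variable_columns(aln).tolist()
    part = build_rectangle_blocks(aln, recurrent_sites, config)

    _cache: dict[tuple, int] = {}

    def bms(block: list[int]) -> int:
        key = tuple(block)
        if key not in _cache:
            _cache[key] = block_min_score(aln, block, config.max_block_patterns)
        return _cache[key]

    minima = [bms(b) for b in part.blocks]
    lower = sum(minima)

    checks = 0
    tried: set[tuple] = set()
    improved = True
    while lower < upper_bound and improved and checks < config.max_pair_checks:
        improved = False
        nb = len(part.blocks)
        for i in range(nb):
            for j in range(i + 1, nb):
                if checks >= config.max_pair_checks:
                    break
                merged = sorted(part.blocks[i] + part.blocks[j])
                key = tuple(merged)
                if key in tried:
                    continue
                tried.add(key)
                k = np.unique(aln.matrix[:, merged], axis=0).shape[0]
                if k > config.max_block_patterns:
                    continue
                checks += 1
                m = bms(merged)
                if m > minima[i] + minima[j]:
                    part.blocks[i] = merged
                    minima[i] = m
                    del part.blocks[j], minima[j]
                    lower = sum(minima)
                    improved = True
                    break
            if improved or checks >= config.max_pair_checks:
                break

    part.validate(var)
    status = "proven" if lower == upper_bound else "unproven"
    if lower > upper_bound:
        raise SqueezeError(
            f"lower bound {lower} exceeds upper bound {upper_bound}: "
            "the upper bound does not come from a valid tree for this alignment"
        )
    positions = [[int(aln.column_positions[c]) for c in b] for b in part.blocks]
    return ProofCertificate(
        upper_bound=int(upper_bound),
        partition=part,
        block_minima=minima,
        lower_bound=int(lower),
        status=status,
        block_positions=positions,
    )


def verify_certificate(cert: ProofCertificate, aln: Alignment) -> bool:
    """Independently re-check a certificate: recompute every block minimum,
    the partition validity, and the bound arithmetic."""
    var = variable_columns(aln).tolist()
    cert.partition.validate(var)
    minima = [block_min_score(aln, b) for b in cert.partition.blocks]
    if minima != cert.block_minima:
        return False
    if sum(minima) != cert.lower_bound:
        return False
    expected = "proven" if cert.lower_bound == cert.upper_bound else "unproven"
    return cert.status == expected
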