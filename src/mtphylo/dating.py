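"""Rho-statistic clade dating from branch-annotated trees.

The rho statistic is the mean number of (filtered) mutations on the paths
from a clade's founder node to each of its leaves; multiplied by a
calibration in years per mutation it estimates the clade's TMRCA.  Two
calibrations are supported: the synonymous-only clock (1 synonymous change
per 6,760 years) and a complete-sequence clock counting all substitutions
except a fixed set of hypervariable control-region positions (16182, 16183,
16194, 16519), whose years-per-change rate the user supplies.

Standard errors use the Saillard-style estimator that treats each branch's
mutation count as Poisson: se(rho)^2 = (1/n^2) * sum over branches of
(leaves below the branch)^2 * (filtered changes on the branch), which for a
star clade reduces to sqrt(rho/n).  The printed uncertainties of heritage
analyses are therefore indicative, not exactly reproduced, and the formula
is isolated here so users can substitute their own.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import sqrt
from typing import Iterable, Mapping, Sequence

from .annotate import VariantCall
from .tree import PhyloTree, TreeError, TreeNode

KIVISILD_YEARS_PER_SYNONYMOUS_CHANGE = 6760.0
SOARES_EXCLUDED_POSITIONS = frozenset({16182, 16183, 16194, 16519})


class DatingError(ValueError):
    pass


@dataclass(frozen=True)
class CalibrationConfig:
    """Which mutations count, and how many years one counted change is worth."""

    method: str  # "kivisild_synonymous" | "soares_complete"
    years_per_change: float
    excluded_positions: frozenset[int] = frozenset()

    def __post_init__(self):
        if self.years_per_change <= 0:
            raise DatingError("years_per_change must be positive")
        if any(not (1 <= p <= 16569) for p in self.excluded_positions):
            raise DatingError("excluded positions must lie in 1..16569")

    @classmethod
    def kivisild(cls) -> "CalibrationConfig":
        return cls(method="kivisild_synonymous",
                   years_per_change=KIVISILD_YEARS_PER_SYNONYMOUS_CHANGE)

    @classmethod
    def soares(cls, years_per_change: float) -> "CalibrationConfig":
        return cls(method="soares_complete", years_per_change=years_per_change,
                   excluded_positions=SOARES_EXCLUDED_POSITIONS)

    def counts(self, v: VariantCall) -> bool:
        """Does this mutation pass the calibration's filter?"""
        if self.method == "kivisild_synonymous":
            if v.kind == "deletion":
                return False
            if v.coding_effect is None:
                raise DatingError(
                    f"unannotated mutation at {v.position}: run coding-effect "
                    "classification before synonymous-clock dating"
                )
            return v.coding_effect == "synonymous"
        if self.method == "soares_complete":
            return (v.kind in ("transition", "transversion")
                    and v.position not in self.excluded_positions)
        raise DatingError(f"unknown calibration method {self.method!r}")


@dataclass
class RhoEstimate:
    """A clade age estimate: rho, its SE, and the calibrated age in years."""

    clade: str
    n_leaves: int
    per_leaf_counts: dict[str, int]
    rho: float
    se_rho: float
    age_years: float
    se_years: float
    method: str

    def to_dict(self) -> dict:
        return {
            "clade": self.clade, "n_leaves": self.n_leaves,
            "rho": self.rho, "se_rho": self.se_rho,
            "age_years": self.age_years, "se_years": self.se_years,
            "method": self.method,
        }


def _clade_branches(clade_root: TreeNode) -> list[TreeNode]:
    """Nodes whose parent branch lies inside the clade (excludes the root)."""
    out = []
    stack = list(clade_root.children)
    while stack:
        n = stack.pop()
        out.append(n)
        stack.extend(n.children)
    return out


def count_path_changes(
    tree: PhyloTree, clade_root: TreeNode, cal: CalibrationConfig
) -> dict[str, int]:
    """Filtered mutation count on the founder-to-leaf path, per leaf.

    A leaf passed as its own clade root is counted on its pendant branch.
    Each occurrence of a recurrent site counts once per change (mutations,
    not states).
    """
    if clade_root.is_leaf:
        return {clade_root.name: sum(1 for v in clade_root.mutations if cal.counts(v))}

    counts: dict[str, int] = {}

    def walk(node: TreeNode, acc: int) -> None:
        acc += sum(1 for v in node.mutations if cal.counts(v))
        if node.is_leaf:
            counts[node.name] = acc
        for c in node.children:
            walk(c, acc)

    for child in clade_root.children:
        walk(child, 0)
    return counts


def estimate_age(
    counts: Mapping[str, int] | Sequence[int],
    cal: CalibrationConfig,
    clade: str = "clade",
) -> RhoEstimate:
    """Rho estimate from per-leaf counts alone (star-genealogy SE form)."""
    if isinstance(counts, Mapping):
        named = dict(counts)
    else:
        named = {f"leaf{i+1}": int(c) for i, c in enumerate(counts)}
    if not named:
        raise DatingError("empty clade: no leaves to average over")
    n = len(named)
    total = sum(named.values())
    rho = total / n
    se_rho = sqrt(total) / n
    return RhoEstimate(
        clade=clade, n_leaves=n, per_leaf_counts=named, rho=rho, se_rho=se_rho,
        age_years=rho * cal.years_per_change,
        se_years=se_rho * cal.years_per_change,
        method=cal.method,
    )


def estimate_clade_age(
    tree: PhyloTree, clade_root: TreeNode, cal: CalibrationConfig,
    clade: str = "clade",
) -> RhoEstimate:
    """Rho estimate for a clade with the branch-weighted Saillard SE.

    se(rho)^2 = n^-2 * sum_b (leaves below b)^2 * (filtered changes on b),
    which equals the star form when the genealogy is a star.
    """
    counts = count_path_changes(tree, clade_root, cal)
    n = len(counts)
    rho = sum(counts.values()) / n
    var = 0.0
    for node in _clade_branches(clade_root) if not clade_root.is_leaf else [clade_root]:
        n_below = sum(1 for _ in _iter_leaves(node))
        l_b = sum(1 for v in node.mutations if cal.counts(v))
        var += (n_below ** 2) * l_b
    se_rho = sqrt(var) / n
    return RhoEstimate(
        clade=clade, n_leaves=n, per_leaf_counts=counts, rho=rho, se_rho=se_rho,
        age_years=rho * cal.years_per_change,
        se_years=se_rho * cal.years_per_change,
        method=cal.method,
    )


def _iter_leaves(node: TreeNode):
    stack = [node]
    while stack:
        n = stack.pop()
        if n.is_leaf:
            yield n
        stack.extend(n.children)


def date_named_clades(
    tree: PhyloTree,
    clade_specs: Mapping[str, Sequence[str]],
    cal: CalibrationConfig,
) -> list[RhoEstimate]:
    """One age estimate per named clade (each spec a list of leaf labels).

    Raises :class:`TreeError` naming the offending extra leaves when a spec
    is not monophyletic on the tree.
    """
    out = []
    for name, leaves in clade_specs.items():
        leaves = list(leaves)
        if len(leaves) == 1:
            node = tree.find(leaves[0])
        else:
            node = tree.mrca(leaves)
            clade_leaves = set(tree.clade_leaf_names(node))
            extra = clade_leaves - set(leaves)
            if extra:
                raise TreeError(
                    f"clade {name!r} is not monophyletic: its MRCA also "
                    f"contains {sorted(extra)}"
                )
        out.append(estimate_clade_age(tree, node, cal, clade=name))
    return out


def dating_table(estimates: Iterable[RhoEstimate]) -> str:
    """TSV rendering: clade, n_leaves, rho, se_rho, age_years, se_years, method."""
    lines = ["clade\tn_leaves\trho\tse_rho\tage_years\tse_years\tmethod"]
    for e in estimates:
        lines.append(
            f"{e.clade}\t{e.n_leaves}\t{e.rho:.4f}\t{e.se_rho:.4f}\t"
            f"{e.age_years:.1f}\t{e.se_years:.1f}\t{e.method}"
        )
    return "\n".join(lines) + "\n"
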