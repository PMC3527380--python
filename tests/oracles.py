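"""Independent brute-force oracles, deliberately naive and separate from the
library's code paths."""

from itertools import combinations

from Bio.Data import CodonTable
from Bio.Seq import Seq

from mtphylo.tree import PhyloTree


def informative_columns_bruteforce(matrix) -> list[int]:
    """Direct per-column classifier: >=2 states each carried by >=2 rows."""
    out = []
    n_rows, n_cols = matrix.shape
    for j in range(n_cols):
        tally = {}
        for i in range(n_rows):
            b = bytes(matrix[i, j])
            tally[b] = tally.get(b, 0) + 1
        if sum(1 for c in tally.values() if c >= 2) >= 2:
            out.append(j)
    return out


def naive_parsimony_score(tree: PhyloTree, sequences: dict[str, str]) -> int:
    """Plain-dict Sankoff with unit costs, one site at a time."""
    length = len(next(iter(sequences.values())))
    total = 0
    for site in range(length):
        def cost(node):
            if node.is_leaf:
                b = sequences[node.name][site]
                return {s: (0 if s == b else 10**9) for s in "ACGT"}
            child_costs = [cost(c) for c in node.children]
            out = {}
            for s in "ACGT":
                acc = 0
                for cc in child_costs:
                    acc += min(cc[t] + (0 if t == s else 1) for t in "ACGT")
                out[s] = acc
            return out
        total += min(cost(tree.root).values())
    return total


def translate_table2(codon: str) -> str:
    """Biopython's vertebrate-mitochondrial translation (oracle)."""
    return str(Seq(codon).translate(table=2))


MITO_TABLE = CodonTable.unambiguous_dna_by_id[2]


def splits_bruteforce(tree: PhyloTree) -> set:
    """Bipartitions by checking every subset-defining internal edge by hand:
    enumerate clades from scratch via leaf-set collection."""
    leaves = frozenset(tree.leaf_names())
    anchor = min(leaves)
    out = set()

    def collect(node):
        if node.is_leaf:
            return frozenset([node.name])
        acc = frozenset()
        for c in node.children:
            acc |= collect(c)
        if 1 < len(acc) < len(leaves) - 1:
            out.add(acc if anchor not in acc else leaves - acc)
        return acc

    collect(tree.root)
    return out


def pairwise_compatible(col_a, col_b) -> bool:
    """Two characters are jointly homoplasy-free iff no pair of states from
    each 'crosses': checked by the generalised four-gamete condition via
    exhaustive intersection patterns."""
    states_a = set(col_a)
    states_b = set(col_b)
    crossing = 0
    for sa in states_a:
        for sb in states_b:
            rows = [i for i in range(len(col_a))
                    if col_a[i] == sa and col_b[i] == sb]
            if rows:
                crossing += 1
    # compatible iff the state-intersection bipartite graph is acyclic
    # (for two characters: observed combinations <= distinct_a + distinct_b - 1)
    return crossing <= len(states_a) + len(states_b) - 1
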