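"""Maximum-parsimony scoring, search, consensus and branch-mutation mapping.

Scoring uses unit-cost Sankoff dynamic programming over {A,C,G,T}, which is
exact for multifurcating as well as binary trees (plain Fitch set operations
are used on binary topologies in the hot enumeration path, where they agree
with Sankoff).  The search mirrors the classic parsimony protocol: stepwise
addition in input order builds a starting tree, then tree
bisection-reconnection (TBR) swapping collects every distinct equal-best
topology encountered, deduplicated by split set.
"""

from __future__ import annotations

import itertools
from collections import deque
from dataclasses import dataclass, replace
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np

from .alignment import Alignment
from .annotate import (VariantCall, call_variants, classify_coding_effect,
                       substitution_kind)
from .reference import GeneMap, ReferenceGenome
from .tree import PhyloTree, TreeError, TreeNode, reroot_at_node

_BASES = b"ACGT"
_BIT = {65: 1, 67: 2, 71: 4, 84: 8}  # ord(A/C/G/T) -> bitmask
_IDX = {65: 0, 67: 1, 71: 2, 84: 3}
BIG = np.int64(1 << 30)


class ParsimonyError(ValueError):
    pass


# ----------------------------------------------------------------------
# pattern encoding
# ----------------------------------------------------------------------

def encode_patterns(
    aln: Alignment, drop_constant: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Collapse alignment columns to unique site patterns.

    Returns ``(states, weights)`` where ``states`` is (n_taxa, n_patterns)
    with rows of 0..3 state indices and ``weights`` counts how many columns
    share each pattern.  Constant columns (score 0 on every tree) are dropped
    by default.  Requires a gap-free alignment.
    """
    m = aln.matrix
    if m.size and np.any((m == b"-") | (m == b"N")):
        raise ParsimonyError("alignment contains gaps/Ns; drop gapped columns first")
    codes = np.frombuffer(m.tobytes(), dtype=np.uint8).reshape(m.shape)
    states = np.zeros_like(codes)
    for byte, idx in _IDX.items():
        states[codes == byte] = idx
    if drop_constant:
        var = np.any(states != states[0], axis=0)
        states = states[:, var]
    if states.shape[1] == 0:
        return np.zeros((m.shape[0], 0), dtype=np.uint8), np.zeros(0, dtype=np.int64)
    uniq, counts = np.unique(states, axis=1, return_counts=True)
    return uniq.astype(np.uint8), counts.astype(np.int64)


def _leaf_masks(states: np.ndarray) -> list[np.ndarray]:
    """Per-taxon bitmask arrays (1/2/4/8 for A/C/G/T) over patterns."""
    return [np.left_shift(1, states[i].astype(np.uint8)) for i in range(states.shape[0])]


def _leaf_costs(states: np.ndarray) -> list[np.ndarray]:
    """Per-taxon (n_patterns, 4) unit-cost Sankoff leaf cost arrays."""
    npat = states.shape[1]
    out = []
    for i in range(states.shape[0]):
        c = np.full((npat, 4), BIG, dtype=np.int64)
        c[np.arange(npat), states[i]] = 0
        out.append(c)
    return out


# ----------------------------------------------------------------------
# scoring
# ----------------------------------------------------------------------

def _sankoff_fold(parent_cost: np.ndarray, child_cost: np.ndarray) -> None:
    """Add a child's contribution to a parent cost array in place."""
    cmin = child_cost.min(axis=1, keepdims=True)
    parent_cost += np.minimum(child_cost, cmin + 1)


def _tree_costs(
    tree: PhyloTree, states: np.ndarray, taxa: Sequence[str]
) -> dict[TreeNode, np.ndarray]:
    """Postorder Sankoff cost arrays for every node."""
    row = {t: i for i, t in enumerate(taxa)}
    leaf_cost = _leaf_costs(states)
    costs: dict[TreeNode, np.ndarray] = {}
    for node in tree.postorder():
        if node.is_leaf:
            try:
                costs[node] = leaf_cost[row[node.name]].copy()
            except KeyError:
                raise ParsimonyError(f"leaf {node.name!r} not in alignment") from None
        else:
            acc = np.zeros((states.shape[1], 4), dtype=np.int64)
            for child in node.children:
                _sankoff_fold(acc, costs[child])
            costs[node] = acc
    return costs


def fitch_length(tree: PhyloTree, aln: Alignment) -> int:
    """Minimum number of substitutions needed on ``tree`` for ``aln``.

    Exact for multifurcating trees and invariant under rooting.
    """
    if set(tree.leaf_names()) != set(aln.taxa):
        raise ParsimonyError("tree leaves do not match alignment taxa")
    states, weights = encode_patterns(aln)
    if states.shape[1] == 0:
        return 0
    costs = _tree_costs(tree, states, aln.taxa)
    return int((costs[tree.root].min(axis=1) * weights).sum())


# ----------------------------------------------------------------------
# exhaustive enumeration (oracle-grade, small n)
# ----------------------------------------------------------------------

@lru_cache(maxsize=8)
def _rooted_shapes(n: int) -> tuple:
    """All rooted binary tree shapes over leaves 1..n (nested int tuples)."""
    trees: list = [1]
    for leaf in range(2, n + 1):
        trees = [t2 for t in trees for t2 in _insertions(t, leaf)]
    return tuple(trees)


def _insertions(t, x):
    yield (t, x)
    if isinstance(t, tuple):
        a, b = t
        for na in _insertions(a, x):
            yield (na, b)
        for nb in _insertions(b, x):
            yield (a, nb)


def _pack_states(states: np.ndarray) -> tuple[list[int], int]:
    """Pack each taxon's site states into one big int, 4 bits per site.

    Fitch set operations on a whole sequence then become single bitwise ops;
    zero nibbles (empty intersections) are counted with bit tricks.
    """
    n, S = states.shape
    ones = sum(1 << (4 * j) for j in range(S))
    packed = []
    for i in range(n):
        v = 0
        row = states[i]
        for j in range(S):
            v |= 1 << (4 * j + int(row[j]))
        packed.append(v)
    return packed, ones


def _fitch_packed(shape, packed: list[int], ones: int, memo: dict) -> int:
    """Fitch score of the unrooted tree {leaf 0} + rooted ``shape`` (packed)."""

    def rec(t):
        if not isinstance(t, tuple):
            return packed[t], 0
        hit = memo.get(t)
        if hit is not None:
            return hit
        ma, ca = rec(t[0])
        mb, cb = rec(t[1])
        inter = ma & mb
        nz = inter | (inter >> 1)
        nz |= nz >> 2
        zeros = ones & ~nz
        cost = ca + cb + zeros.bit_count()
        res = inter | ((ma | mb) & (zeros * 15))
        memo[t] = (res, cost)
        return res, cost

    m, c = rec(shape)
    inter = m & packed[0]
    nz = inter | (inter >> 1)
    nz |= nz >> 2
    return c + (ones & ~nz).bit_count()


def _shape_to_phylo(shape, leaf_labels: Sequence[str]) -> PhyloTree:
    """Unrooted tree (leaf 0 sister to ``shape``) as an arbitrarily rooted PhyloTree."""

    def build(t) -> TreeNode:
        if not isinstance(t, tuple):
            return TreeNode(name=leaf_labels[t])
        node = TreeNode()
        node.add_child(build(t[0]))
        node.add_child(build(t[1]))
        return node

    root = TreeNode()
    root.add_child(TreeNode(name=leaf_labels[0]))
    root.add_child(build(shape))
    return PhyloTree(root, rooted=False)


def exhaustive_min_length(aln: Alignment) -> tuple[int, list]:
    """Exact minimum tree length over ALL unrooted binary topologies.

    Returns (min score, list of optimal shapes); intended as an oracle and as
    the exact engine behind small partition blocks.
    """
    n = aln.n_taxa
    states, weights = encode_patterns(aln)
    if n < 4 or states.shape[1] == 0:
        # single topology (or no variable sites): score is forced
        score = 0
        if states.shape[1]:
            nstate = np.stack([np.bincount(states[:, j], minlength=4) for j in
                               range(states.shape[1])])
            score = int((((nstate > 0).sum(axis=1) - 1) * weights).sum())
        return score, list(_rooted_shapes(n - 1)) if n >= 2 else []
    # repeat each pattern `weight` times so one nibble is one unit of cost
    expanded = np.repeat(states, weights, axis=1)
    packed, ones = _pack_states(expanded)
    best = None
    best_shapes: list = []
    memo: dict = {}
    for shape in _rooted_shapes(n - 1):
        s = _fitch_packed(shape, packed, ones, memo)
        if best is None or s < best:
            best, best_shapes = s, [shape]
        elif s == best:
            best_shapes.append(shape)
    return int(best), best_shapes


@dataclass
class TreeSet:
    """A collection of equally parsimonious trees with their common score."""

    trees: list[PhyloTree]
    score: int

    def __len__(self) -> int:
        return len(self.trees)


def enumerate_mp_trees(aln: Alignment, max_taxa: int = 9) -> TreeSet:
    """All most-parsimonious unrooted binary topologies, by full enumeration.

    Refuses more than ``max_taxa`` taxa ((2n-5)!! topologies grow too fast);
    use :func:`heuristic_search` beyond that.
    """
    n = aln.n_taxa
    if n > max_taxa:
        raise ParsimonyError(
            f"{n} taxa exceeds max_taxa={max_taxa}; use heuristic_search instead"
        )
    if n < 3:
        raise ParsimonyError("need at least 3 taxa")
    score, shapes = exhaustive_min_length(aln)
    trees = [_shape_to_phylo(s, aln.taxa) for s in shapes]
    return TreeSet(trees=trees, score=score)


# ----------------------------------------------------------------------
# heuristic search: stepwise addition + TBR
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class SearchConfig:
    """Controls for the parsimony search.

    ``max_pool`` caps the number of equal-best trees retained; ``max_evals``
    bounds total neighbour evaluations for determinism without wall clocks;
    ``random_restarts`` re-runs stepwise addition with shuffled input orders
    (seeded), keeping the overall best pool.
    """

    max_pool: int = 64
    max_evals: int = 2_000_000
    random_restarts: int = 0
    seed: Optional[int] = None


def _adj_score(adj: dict, masks: list[np.ndarray], weights: np.ndarray) -> int:
    """Fitch score of an unrooted adjacency tree (binary internal nodes)."""
    start = min(k for k in adj if k < len(masks))  # any leaf present
    parent = {start: -1}
    order = [start]
    stack = [start]
    while stack:
        u = stack.pop()
        for v in adj[u]:
            if v != parent[u]:
                parent[v] = u
                order.append(v)
                stack.append(v)
    n_leaves = len(masks)
    mask: dict[int, np.ndarray] = {}
    cost = 0
    for u in reversed(order):
        kids = [v for v in adj[u] if v != parent[u]]
        if not kids:
            mask[u] = masks[u]
            continue
        if u < n_leaves:  # the traversal root is leaf 0: fold its own state too
            m = masks[u]
            rest = kids
        else:
            m = mask[kids[0]]
            rest = kids[1:]
        for k in rest:
            inter = m & mask[k]
            z = inter == 0
            cost += int(weights[z].sum())
            m = np.where(z, m | mask[k], inter)
        mask[u] = m
    return cost


def _adj_edges(adj: dict) -> list[tuple[int, int]]:
    return sorted((u, v) for u, nbrs in adj.items() for v in nbrs if u < v)


def _adj_copy(adj: dict) -> dict:
    return {u: list(vs) for u, vs in adj.items()}


def _subdivide(adj: dict, edge: tuple[int, int], new_id: int) -> None:
    u, v = edge
    adj[u].remove(v)
    adj[v].remove(u)
    adj[new_id] = [u, v]
    adj[u].append(new_id)
    adj[v].append(new_id)


def _splits_key(adj: dict, n_leaves: int) -> frozenset:
    """Canonical split-set hash of an unrooted adjacency tree."""
    parent = {0: -1}
    order = [0]
    stack = [0]
    while stack:
        u = stack.pop()
        for v in adj[u]:
            if v != parent[u]:
                parent[v] = u
                order.append(v)
                stack.append(v)
    below: dict[int, frozenset] = {}
    out = set()
    for u in reversed(order):
        kids = [v for v in adj[u] if v != parent[u]]
        if not kids:
            below[u] = frozenset([u] if u < n_leaves else [])
        else:
            below[u] = frozenset().union(*(below[k] for k in kids))
        if 1 < len(below[u]) < n_leaves - 1:
            out.add(below[u])
    return frozenset(out)


def _stepwise_addition(
    order: Sequence[int], masks, weights
) -> tuple[dict, itertools.count]:
    """Build a starting tree by simple stepwise addition."""
    n = len(order)
    ids = itertools.count(start=n)
    center = next(ids)
    adj: dict[int, list[int]] = {center: list(order[:3])}
    for leaf in order[:3]:
        adj[leaf] = [center]
    for leaf in order[3:]:
        best = None
        best_edge = None
        for edge in _adj_edges(adj):
            trial = _adj_copy(adj)
            x = n * 4  # scratch ids, renumbered below
            trial[leaf] = []
            _subdivide(trial, edge, x)
            trial[x].append(leaf)
            trial[leaf] = [x]
            s = _adj_score(trial, masks, weights)
            if best is None or s < best:
                best, best_edge = s, edge
        x = next(ids)
        adj[leaf] = []
        _subdivide(adj, best_edge, x)
        adj[x].append(leaf)
        adj[leaf] = [x]
    return adj, ids


def _components(adj: dict, cut: tuple[int, int]) -> tuple[set, set]:
    u, v = cut
    seen = {u}
    stack = [u]
    while stack:
        a = stack.pop()
        for b in adj[a]:
            if (a, b) in ((u, v), (v, u)) or b in seen:
                continue
            seen.add(b)
            stack.append(b)
    return seen, set(adj) - seen


def _smooth_degree_two(adj: dict, node: int) -> None:
    a, b = adj[node]
    adj[a].remove(node)
    adj[b].remove(node)
    adj[a].append(b)
    adj[b].append(a)
    del adj[node]


def _tbr_neighbors(adj: dict, n_leaves: int, ids: itertools.count):
    """Yield TBR rearrangements of an unrooted binary adjacency tree."""
    for cut in _adj_edges(adj):
        comp_u, comp_v = _components(adj, cut)
        base = _adj_copy(adj)
        u, v = cut
        base[u].remove(v)
        base[v].remove(u)
        attach_points = {}
        for endpoint, comp in ((u, comp_u), (v, comp_v)):
            sub = {k: list(base[k]) for k in comp}
            if len(comp) == 1:
                attach_points[endpoint] = (sub, None)  # bare node
            else:
                if len(sub[endpoint]) == 2:
                    _smooth_degree_two(sub, endpoint)
                attach_points[endpoint] = (sub, _adj_edges(sub))
        sub_u, edges_u = attach_points[u]
        sub_v, edges_v = attach_points[v]
        for ea in edges_u if edges_u is not None else [None]:
            for eb in edges_v if edges_v is not None else [None]:
                trial = {k: list(vs) for part in (sub_u, sub_v)
                         for k, vs in part.items()}
                if ea is None:
                    x = u
                else:
                    x = next(ids)
                    _subdivide(trial, ea, x)
                if eb is None:
                    y = v
                else:
                    y = next(ids)
                    _subdivide(trial, eb, y)
                trial[x].append(y)
                trial[y].append(x)
                yield trial


def _adj_to_phylo(adj: dict, taxa: Sequence[str]) -> PhyloTree:
    n = len(taxa)
    parent = {0: -1}

    def build(u: int, par: int) -> TreeNode:
        node = TreeNode(name=taxa[u] if u < n else None)
        for v in sorted(adj[u], key=lambda w: (w >= n, w)):
            if v != par:
                node.add_child(build(v, u))
        return node

    root = TreeNode()
    root.add_child(TreeNode(name=taxa[0]))
    root.add_child(build(adj[0][0], 0))
    return PhyloTree(root, rooted=False)


def heuristic_search(aln: Alignment, config: SearchConfig = SearchConfig()) -> TreeSet:
    """Stepwise addition + TBR parsimony search.

    Deterministic given the configuration: taxa are added in input order
    (optionally reshuffled per seeded restart), TBR neighbours are generated
    in canonical edge order, and all distinct equal-best topologies found are
    returned (deduplicated by split set, capped at ``config.max_pool``).
    """
    n = aln.n_taxa
    if n < 4:
        return enumerate_mp_trees(aln)
    states, weights = encode_patterns(aln)
    if states.shape[1] == 0:
        # no variable sites: any topology scores 0; return the stepwise tree
        states = np.zeros((n, 1), dtype=np.uint8)
        weights = np.zeros(1, dtype=np.int64)
    masks = _leaf_masks(states)

    orders = [list(range(n))]
    if config.random_restarts:
        rng = np.random.default_rng(config.seed)
        for _ in range(config.random_restarts):
            orders.append(list(rng.permutation(n)))

    best_score: Optional[int] = None
    pool: dict[frozenset, dict] = {}
    evals = 0
    for order in orders:
        adj, ids = _stepwise_addition(order, masks, weights)
        score = _adj_score(adj, masks, weights)
        if best_score is None or score < best_score:
            best_score = score
            pool = {}
        if score == best_score:
            key = _splits_key(adj, n)
            pool.setdefault(key, adj)
        frontier = deque(pool.keys())
        while frontier and evals < config.max_evals:
            current = pool.get(frontier.popleft())
            if current is None:
                continue
            for nb in _tbr_neighbors(current, n, ids):
                evals += 1
                s = _adj_score(nb, masks, weights)
                if s < best_score:
                    best_score = s
                    key = _splits_key(nb, n)
                    pool = {key: nb}
                    frontier = deque([key])
                elif s == best_score and len(pool) < config.max_pool:
                    key = _splits_key(nb, n)
                    if key not in pool:
                        pool[key] = nb
                        frontier.append(key)
                if evals >= config.max_evals:
                    break
    trees = [_adj_to_phylo(adj, aln.taxa) for adj in pool.values()]
    trees.sort(key=lambda t: t.to_newick())
    return TreeSet(trees=trees, score=int(best_score))


# ----------------------------------------------------------------------
# strict consensus
# ----------------------------------------------------------------------

def strict_consensus(ts: TreeSet) -> PhyloTree:
    """Strict consensus: keep exactly the splits present in every tree.

    Conflicting regions collapse to polytomies; a single-tree set returns a
    copy of that tree's topology.
    """
    if not ts.trees:
        raise ParsimonyError("empty tree set")
    leafsets = {frozenset(t.leaf_names()) for t in ts.trees}
    if len(leafsets) != 1:
        raise ParsimonyError("trees have different leaf sets")
    (leafset,) = leafsets
    common = frozenset.intersection(*(t.splits() for t in ts.trees))
    anchor = min(leafset)
    clusters = sorted(common, key=len, reverse=True)  # anchor-free sides
    root = TreeNode()
    node_of: list[tuple[frozenset, TreeNode]] = []
    for cl in clusters:
        parent = root
        for other, nd in node_of:
            if cl < other:
                parent = nd  # smallest enclosing seen so far (sorted desc)
        node = TreeNode()
        parent.add_child(node)
        node_of.append((cl, node))
    for leaf in sorted(leafset):
        parent = root
        best_size = None
        for cl, nd in node_of:
            if leaf in cl and (best_size is None or len(cl) < best_size):
                parent, best_size = nd, len(cl)
        parent.add_child(TreeNode(name=leaf))
    return PhyloTree(root, rooted=False)


def incompatible_splits(ts: TreeSet) -> list[tuple[frozenset, frozenset]]:
    """Pairs of splits from the tree set that conflict with each other.

    Summarises the consensus-network content that the strict consensus
    collapses: two splits conflict when all four intersections of their
    sides (over the shared leaf set) are non-empty.
    """
    leafset = frozenset(ts.trees[0].leaf_names())
    all_splits = sorted(frozenset().union(*(t.splits() for t in ts.trees)),
                       key=sorted)
    out = []
    for a, b in itertools.combinations(all_splits, 2):
        ac, bc = leafset - a, leafset - b
        if all((a & b, a & bc, ac & b, ac & bc)):
            out.append((a, b))
    return out


# ----------------------------------------------------------------------
# branch-mutation mapping
# ----------------------------------------------------------------------

@dataclass
class MutationMapping:
    """A rooted tree with per-branch variant calls plus root-level calls.

    ``root_variants`` are the differences of the inferred root haplotype from
    the reference (the ancestral-vertex change list); ``recurrent_positions``
    maps each position hit more than once on the tree to its hit count.
    """

    tree: PhyloTree
    root_variants: list[VariantCall]
    recurrent_positions: dict[int, int]
    total_changes: int


def _root_on_leaf_edge(tree: PhyloTree, leaf_name: str) -> PhyloTree:
    """Root on the pendant branch of the named leaf (outgroup rooting)."""
    t = tree.copy()
    leaf = t.find(leaf_name)
    if leaf.parent is None:
        raise TreeError(f"{leaf_name!r} is already the root")
    attach = leaf.parent
    rooted = reroot_at_node(t, attach)
    # pull the outgroup leaf up so the root separates it from the ingroup
    new_leaf = rooted.find(leaf_name)
    top = rooted.root
    if new_leaf.parent is not top:
        raise TreeError("outgroup rooting failed")
    root = TreeNode()
    top.children.remove(new_leaf)
    root.add_child(new_leaf)
    root.add_child(top)
    return PhyloTree(root, rooted=True)


def _reference_root(
    tree: PhyloTree, states: np.ndarray, weights: np.ndarray,
    taxa: Sequence[str], ref_states: np.ndarray
) -> PhyloTree:
    """Root at the node minimising changes to an attached reference haplotype."""
    base = tree.copy()
    candidates = [n for n in base.postorder() if not n.is_leaf]
    best = None
    best_tree = None
    for node in candidates:
        rooted = reroot_at_node(base, node)
        costs = _tree_costs(rooted, states, taxa)
        c = costs[rooted.root]
        attach = np.minimum(
            c[np.arange(c.shape[0]), ref_states],
            c.min(axis=1) + 1,
        )
        d = int((attach * weights).sum())
        if best is None or d < best:
            best, best_tree = d, rooted
    return best_tree


def map_mutations(
    tree: PhyloTree,
    aln: Alignment,
    ref: ReferenceGenome,
    gene_map: GeneMap,
    root: Optional[str] = "reference",
) -> MutationMapping:
    """Assign each site's changes to branches and annotate them.

    ``root`` selects the rooting: a taxon name roots on that leaf's pendant
    branch (outgroup rooting); ``"reference"`` roots at the internal node
    whose reconstructed state is closest to the reference haplotype; ``None``
    requires ``tree.rooted``.  State assignment is a Sankoff traceback with a
    deterministic tie-break that prefers placing changes on the branch
    closest to the root and prefers the reference state at the root.
    Changes hitting the same position more than once are flagged recurrent
    and numbered in preorder.  The sum of branch mutation counts equals the
    tree's parsimony score (change conservation).
    """
    if set(tree.leaf_names()) != set(aln.taxa):
        raise ParsimonyError("tree leaves do not match alignment taxa")
    # full per-column states (no pattern collapse: column identity matters here)
    m = aln.matrix
    if m.size and np.any((m == b"-") | (m == b"N")):
        raise ParsimonyError("alignment contains gaps/Ns; drop gapped columns first")
    codes = np.frombuffer(m.tobytes(), dtype=np.uint8).reshape(m.shape)
    col_states = np.zeros_like(codes)
    for byte, idx in _IDX.items():
        col_states[codes == byte] = idx
    var_cols = np.nonzero(np.any(col_states != col_states[0], axis=0))[0]
    var_states = col_states[:, var_cols]
    weights = np.ones(var_cols.shape[0], dtype=np.int64)

    ref_arr = ref.as_array()
    ref_codes = np.frombuffer(ref_arr.tobytes(), dtype=np.uint8)
    ref_col_states = np.array(
        [_IDX[b] for b in ref_codes[aln.column_positions - 1]], dtype=np.uint8
    )

    if root is None:
        if not tree.rooted:
            raise ParsimonyError("tree is unrooted; choose a root for mapping")
        rooted = tree.copy()
    elif root == "reference":
        rooted = _reference_root(
            tree, var_states, weights, aln.taxa, ref_col_states[var_cols]
        )
    else:
        rooted = _root_on_leaf_edge(tree, root)

    costs = _tree_costs(rooted, var_states, aln.taxa)
    nodes = list(rooted.preorder())
    assign: dict[TreeNode, np.ndarray] = {}
    nvar = var_cols.shape[0]
    ref_var = ref_col_states[var_cols]
    for node in nodes:
        c = costs[node]
        cmin = c.min(axis=1)
        if node.parent is None:
            # root: prefer the reference base on ties
            choice = np.argmin(c, axis=1).astype(np.uint8)
            ref_ok = c[np.arange(nvar), ref_var] == cmin
            choice[ref_ok] = ref_var[ref_ok]
            assign[node] = choice
            continue
        p = assign[node.parent]
        stay = c[np.arange(nvar), p]
        total_stay = stay
        total_move = cmin + 1
        choice = p.copy()
        move = total_move <= total_stay  # tie -> change on this branch (near root)
        # among minimising states when moving, take the smallest index != parent
        if np.any(move):
            cm = c[move]
            pm = p[move]
            masked = cm.copy()
            masked[np.arange(cm.shape[0]), pm] = BIG
            choice[move] = np.argmin(masked, axis=1).astype(np.uint8)
        assign[node] = choice

    # attach mutations to branches, with ancestral codon context
    base_chars = "ACGT"
    genomes: dict[TreeNode, np.ndarray] = {}
    total = 0
    per_position: dict[int, list[tuple[int, TreeNode, VariantCall]]] = {}
    col_positions = aln.column_positions
    # constant columns may still differ from the reference everywhere
    const_cols = np.setdiff1d(np.arange(aln.n_columns), var_cols)
    order_index = {node: i for i, node in enumerate(nodes)}
    for node in nodes:
        node.mutations = []
        g = ref_arr.copy() if node.parent is None else genomes[node.parent].copy()
        if node.parent is None:
            for ci in const_cols:
                g[col_positions[ci] - 1] = m[0, ci]
            for vi, ci in enumerate(var_cols):
                g[col_positions[ci] - 1] = base_chars[assign[node][vi]].encode()
        else:
            changed = np.nonzero(assign[node] != assign[node.parent])[0]
            parent_str = genomes[node.parent].tobytes().decode() if changed.size else ""
            for vi in changed:
                ci = var_cols[vi]
                pos = int(col_positions[ci])
                from_b = base_chars[assign[node.parent][vi]]
                to_b = base_chars[assign[node][vi]]
                call = VariantCall(pos, from_b, to_b, substitution_kind(from_b, to_b))
                call = classify_coding_effect(call, gene_map, parent_str)
                rb = ref.base_at(pos)
                call = replace(call, is_reversion=(to_b == rb and from_b != rb))
                node.mutations.append(call)
                per_position.setdefault(pos, []).append(
                    (order_index[node], node, call)
                )
                g[pos - 1] = to_b.encode()
                total += 1
            node.mutations.sort(key=lambda v: v.position)
        genomes[node] = g

    recurrent = {}
    for pos, hits in per_position.items():
        if len(hits) < 2:
            continue
        recurrent[pos] = len(hits)
        hits.sort(key=lambda h: h[0])
        for k, (_, node, call) in enumerate(hits, start=1):
            idx = node.mutations.index(call)
            node.mutations[idx] = replace(call, is_recurrent=True, occurrence_index=k)

    root_genome = genomes[rooted.root]
    root_variants = call_variants(root_genome.tobytes().decode(), ref)
    return MutationMapping(
        tree=rooted,
        root_variants=root_variants,
        recurrent_positions=recurrent,
        total_changes=total,
    )
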