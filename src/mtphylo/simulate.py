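"""Synthetic complete-mtDNA data with known genealogy, mutations and TMRCA.

Generates rCRS-anchored alignments by dropping Poisson mutation events onto
a genealogy with branch durations in years, with separate genome-wide rates
per mutation class (synonymous, non-synonymous, RNA-gene, control-region),
a transition bias, and an optional tendency to re-hit previously mutated
sites.  Synonymous and non-synonymous events are placed context-aware: a
candidate site/base is rejection-sampled until the change has the requested
effect in the *current* background, so classifications stay correct under
multiple hits.  The full truth (genealogy, every event, clade TMRCAs) is
recorded so each pipeline stage can be checked against it.

The default synonymous rate of 1/6760 per lineage-year matches the
synonymous-clock calibration used for dating, making parameter-recovery
experiments self-consistent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .annotate import (CODON_TABLE_2, VariantCall, _codon_at, substitution_kind)
from .reference import RCRS_LENGTH, GeneMap, ReferenceGenome, load_reference
from .alignment import Alignment
from .tree import PhyloTree, TreeNode

_BASES = ("A", "C", "G", "T")
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": ("C", "T"), "G": ("C", "T"), "C": ("A", "G"), "T": ("A", "G")}


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class SimConfig:
    """Study-condition defaults for the generator.

    Rates are genome-wide expected events per lineage-year for each class;
    the synonymous default is the 1/6760 clock rate.  ``ti_tv_ratio`` is the
    transition:transversion ratio (20:1, typical of human mtDNA).
    ``recurrent_prob`` is the chance an event re-hits an already-mutated
    site, creating parallel/reverting changes.
    """

    n_leaves: int = 7
    genealogy: str = "star"  # star | yule | coalescent
    tmrca_years: float = 22430.0
    rate_synonymous: float = 1.0 / 6760.0
    rate_nonsynonymous: float = 1.0 / 20000.0
    rate_rna: float = 1.0 / 40000.0
    rate_control: float = 1.0 / 8000.0
    ti_tv_ratio: float = 20.0
    recurrent_prob: float = 0.0
    time_scale_years: float = 1.0  # years per coalescent time unit
    root_variants: tuple = ()  # ((position, base), ...) applied to the root
    seed: int = 0

    def __post_init__(self):
        if self.n_leaves < 2:
            raise SimulationError("need at least 2 leaves")
        for r in (self.rate_synonymous, self.rate_nonsynonymous,
                  self.rate_rna, self.rate_control):
            if r < 0:
                raise SimulationError("rates must be non-negative")
        if self.genealogy not in ("star", "yule", "coalescent"):
            raise SimulationError(f"unknown genealogy {self.genealogy!r}")


@dataclass
class MutationEvent:
    """One simulated mutation: where on the tree, where on the genome."""

    branch: str  # name of the child node below the branch
    time_years: float  # measured from the start (rootward end) of the branch
    position: int
    from_base: str
    to_base: str
    effect_class: str  # synonymous | nonsynonymous | rna | control

    def to_dict(self) -> dict:
        return {
            "branch": self.branch, "time_years": self.time_years,
            "position": self.position, "from": self.from_base,
            "to": self.to_base, "class": self.effect_class,
        }


@dataclass
class SimulationTruth:
    """Complete generating record: replaying events reproduces the leaves."""

    tree: PhyloTree  # durations in years; branch mutations as VariantCalls
    mutation_events: list[MutationEvent]
    clade_tmrcas: dict[str, float]
    seed: int
    root_sequence: str

    def events_for_branch(self, name: str) -> list[MutationEvent]:
        return sorted(
            (e for e in self.mutation_events if e.branch == name),
            key=lambda e: e.time_years,
        )

    def to_json(self, path) -> None:
        payload = {
            "newick": self.tree.to_newick(lengths=True),
            "events": [e.to_dict() for e in self.mutation_events],
            "clade_tmrcas": self.clade_tmrcas,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


# ----------------------------------------------------------------------
# genealogies
# ----------------------------------------------------------------------

def simulate_genealogy(cfg: SimConfig) -> PhyloTree:
    """A genealogy with branch durations in years; deterministic per seed.

    ``star``: n branches of length ``tmrca_years`` from one root.
    ``yule``: a random ultrametric birth-order topology scaled to
    ``tmrca_years`` depth.  ``coalescent``: Kingman n-coalescent with
    exponential waiting times in coalescent units times
    ``time_scale_years`` (the year scale is direct; no effective population
    size parameter is modelled).
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_leaves
    leaf_names = [f"L{i+1:02d}" for i in range(n)]
    if cfg.genealogy == "star":
        root = TreeNode(name="root")
        for name in leaf_names:
            root.add_child(TreeNode(name=name, length=cfg.tmrca_years))
        return PhyloTree(root, rooted=True)
    if cfg.genealogy == "yule":
        return _yule(rng, leaf_names, cfg.tmrca_years)
    return _coalescent(rng, leaf_names, cfg.time_scale_years)


def _yule(rng, leaf_names: list[str], depth: float) -> PhyloTree:
    n = len(leaf_names)
    # pure-birth waiting times (rate k with k lineages), rescaled to `depth`
    waits = np.array([rng.exponential(1.0 / k) for k in range(2, n + 1)])
    total = waits.sum()
    split_times = np.concatenate([[0.0], np.cumsum(waits[:-1])]) * (depth / total)
    root = TreeNode(name="root")
    active: list[tuple[TreeNode, float]] = []
    for _ in range(2):
        c = TreeNode()
        root.add_child(c)
        active.append((c, 0.0))
    for k in range(1, n - 1):
        t = float(split_times[k])
        i = int(rng.integers(len(active)))
        node, born = active.pop(i)
        node.length = t - born
        c1, c2 = TreeNode(), TreeNode()
        node.add_child(c1)
        node.add_child(c2)
        active.append((c1, t))
        active.append((c2, t))
    for (node, born), nm in zip(active, leaf_names):
        node.name = nm
        node.length = depth - born
    return PhyloTree(root, rooted=True)


def _coalescent(rng, leaf_names: list[str], time_scale: float) -> PhyloTree:
    lineages = [(TreeNode(name=nm), 0.0) for nm in leaf_names]
    t = 0.0
    while len(lineages) > 1:
        k = len(lineages)
        t += rng.exponential(2.0 / (k * (k - 1))) * time_scale
        i, j = sorted(rng.choice(k, size=2, replace=False))
        (a, ta) = lineages.pop(j)
        (b, tb) = lineages.pop(i)
        parent = TreeNode()
        a.length = t - ta
        b.length = t - tb
        parent.add_child(b)
        parent.add_child(a)
        lineages.append((parent, t))
    root, _ = lineages[0]
    root.name = "root"
    return PhyloTree(root, rooted=True)


def tree_depth_years(tree: PhyloTree) -> float:
    """Root-to-leaf duration (max over leaves)."""

    def depth(node: TreeNode) -> float:
        own = node.length or 0.0
        return own + (max((depth(c) for c in node.children), default=0.0))

    return max(depth(c) for c in tree.root.children)


# ----------------------------------------------------------------------
# sequence evolution
# ----------------------------------------------------------------------

class _SitePools:
    def __init__(self, gene_map: GeneMap):
        classes = np.array(
            [gene_map.feature_class_at(p) for p in range(1, RCRS_LENGTH + 1)]
        )
        self.protein = np.nonzero(classes == "protein")[0] + 1
        self.rna = np.nonzero((classes == "rRNA") | (classes == "tRNA"))[0] + 1
        self.control = np.nonzero(classes == "control")[0] + 1

    def pool(self, effect_class: str) -> np.ndarray:
        if effect_class in ("synonymous", "nonsynonymous"):
            return self.protein
        if effect_class == "rna":
            return self.rna
        return self.control


def _propose_base(current: str, rng, ti_tv_ratio: float) -> str:
    p_ti = ti_tv_ratio / (ti_tv_ratio + 2.0)
    if rng.random() < p_ti:
        return _TRANSITION[current]
    return _TRANSVERSIONS[current][int(rng.integers(2))]


def _is_synonymous(pos: int, from_b: str, to_b: str, gene_map: GeneMap,
                   genome: np.ndarray) -> bool:
    gene = gene_map.feature_at(pos)
    bg = genome.tobytes().decode()
    c_from, _ = _codon_at(gene, pos, bg, from_b)
    c_to, _ = _codon_at(gene, pos, bg, to_b)
    return CODON_TABLE_2[c_from] == CODON_TABLE_2[c_to]


def evolve_sequences(
    tree: PhyloTree,
    ref: ReferenceGenome,
    gene_map: GeneMap,
    cfg: SimConfig,
    clade_tmrcas: Optional[dict[str, float]] = None,
) -> tuple[Alignment, SimulationTruth]:
    """Drop Poisson mutations along a genealogy and emit the leaf alignment.

    Events are applied in time order within each branch so multi-hit sites
    evolve through their actual intermediate states.  Branches of the
    returned truth tree carry classified :class:`VariantCall` lists (the
    per-event ``ref_base`` is the immediate ancestral base, not the rCRS).
    """
    rng = np.random.default_rng(cfg.seed + 1)
    pools = _SitePools(gene_map)
    rates = {
        "synonymous": cfg.rate_synonymous,
        "nonsynonymous": cfg.rate_nonsynonymous,
        "rna": cfg.rate_rna,
        "control": cfg.rate_control,
    }
    root_genome = ref.as_array()
    for pos, base in cfg.root_variants:
        root_genome[int(pos) - 1] = base.encode()

    # stable names for unnamed internal nodes
    counter = 0
    for node in tree.preorder():
        if node.name is None:
            node.name = f"node{counter}"
            counter += 1

    events: list[MutationEvent] = []
    hit_sites: list[int] = []
    leaf_seqs: dict[str, np.ndarray] = {}

    def classify_event(pos, from_b, to_b, effect_class) -> VariantCall:
        fc = gene_map.feature_class_at(pos)
        effect = {"synonymous": "synonymous", "nonsynonymous": "nonsynonymous",
                  "rna": "rna", "control": "noncoding"}[effect_class]
        return VariantCall(
            position=pos, ref_base=from_b, obs_base=to_b,
            kind=substitution_kind(from_b, to_b),
            feature_class=fc, coding_effect=effect,
        )

    def sample_event(effect_class: str, genome: np.ndarray):
        pool = pools.pool(effect_class)
        for _ in range(10000):
            if (cfg.recurrent_prob > 0 and hit_sites
                    and rng.random() < cfg.recurrent_prob):
                candidates = [p for p in hit_sites if p in pool]
                if not candidates:
                    pos = int(pool[rng.integers(pool.size)])
                else:
                    pos = candidates[int(rng.integers(len(candidates)))]
            else:
                pos = int(pool[rng.integers(pool.size)])
            cur = genome[pos - 1].decode()
            new = _propose_base(cur, rng, cfg.ti_tv_ratio)
            if effect_class == "synonymous":
                if _is_synonymous(pos, cur, new, gene_map, genome):
                    return pos, cur, new
            elif effect_class == "nonsynonymous":
                if not _is_synonymous(pos, cur, new, gene_map, genome):
                    return pos, cur, new
            else:
                return pos, cur, new
        raise SimulationError(
            f"could not place a {effect_class} event (rejection cap reached)"
        )

    def walk(node: TreeNode, genome: np.ndarray) -> None:
        node.mutations = []
        if node.parent is not None:
            duration = node.length or 0.0
            drawn = []
            for effect_class, rate in rates.items():
                k = rng.poisson(rate * duration) if rate > 0 and duration > 0 else 0
                for _ in range(k):
                    drawn.append((float(rng.uniform(0, duration)), effect_class))
            drawn.sort(key=lambda x: x[0])
            for t, effect_class in drawn:
                pos, cur, new = sample_event(effect_class, genome)
                genome[pos - 1] = new.encode()
                hit_sites.append(pos)
                events.append(MutationEvent(node.name, t, pos, cur, new,
                                            effect_class))
                node.mutations.append(classify_event(pos, cur, new, effect_class))
        if node.is_leaf:
            leaf_seqs[node.name] = genome.copy()
        for child in node.children:
            walk(child, genome.copy())

    walk(tree.root, root_genome.copy())

    taxa = [n.name for n in tree.leaves()]
    aln = Alignment(
        taxa=taxa,
        matrix=np.vstack([leaf_seqs[t] for t in taxa]),
        column_positions=np.arange(1, RCRS_LENGTH + 1),
    )
    truth = SimulationTruth(
        tree=tree,
        mutation_events=events,
        clade_tmrcas=dict(clade_tmrcas or {}),
        seed=cfg.seed,
        root_sequence=root_genome.tobytes().decode(),
    )
    return aln, truth


def replay_events(truth: SimulationTruth) -> dict[str, str]:
    """Re-apply the recorded events along the tree from the root sequence.

    Returns leaf name -> sequence; used to check the truth-replay invariant.
    """
    out: dict[str, str] = {}

    def walk(node: TreeNode, genome: bytearray) -> None:
        if node.parent is not None:
            for e in truth.events_for_branch(node.name):
                if genome[e.position - 1] != ord(e.from_base):
                    raise SimulationError(
                        f"event replay mismatch at {e.position} on {node.name}"
                    )
                genome[e.position - 1] = ord(e.to_base)
        if node.is_leaf:
            out[node.name] = genome.decode()
        for c in node.children:
            walk(c, bytearray(genome))

    walk(truth.tree.root, bytearray(truth.root_sequence.encode()))
    return out


# ----------------------------------------------------------------------
# presets
# ----------------------------------------------------------------------

#: ancestral-vertex haplotype applied to preset roots: the classic list of
#: changes from the rCRS carried by the M macrohaplogroup founder
M_VERTEX_VARIANTS = (
    (73, "G"), (263, "G"), (489, "C"), (750, "G"), (1438, "G"), (2706, "G"),
    (4769, "G"), (7028, "T"), (8701, "G"), (8860, "G"), (9540, "C"),
    (10398, "G"), (10400, "T"), (10873, "C"), (11719, "A"), (12705, "T"),
    (14766, "T"), (14783, "C"), (15043, "A"), (15301, "A"), (15326, "G"),
    (16223, "T"),
)


def q2a_preset(
    seed: int,
    ref: Optional[ReferenceGenome] = None,
    gene_map: Optional[GeneMap] = None,
) -> tuple[Alignment, SimulationTruth]:
    """An 11-genome clade shaped like a rapidly expanding island haplogroup.

    A 7-way star radiation at the clade root (TMRCA 22,430 y) whose children
    are four long private lineages, two 2-leaf subgroups and one 3-leaf
    subgroup — the arrangement seen in the Q2a radiation (FA093/PD047,
    PB036/FA064 and PD057/K058/KI018 style groups).  The root haplotype
    carries the M-vertex changes relative to the reference.  Deterministic:
    a fixed seed yields byte-identical FASTA.
    """
    if ref is None or gene_map is None:
        ref, gene_map = load_reference()
    depth = 22430.0
    sub = {"trio": 6760.0, "pair1": 9000.0, "pair2": 12000.0}
    root = TreeNode(name="Q2A")
    for nm in ("Q2X1", "Q2X2", "Q2X3", "Q2X4"):
        root.add_child(TreeNode(name=nm, length=depth))
    trio = root.add_child(TreeNode(name="TRIO", length=depth - sub["trio"]))
    for nm in ("PD057", "K058", "KI018"):
        trio.add_child(TreeNode(name=nm, length=sub["trio"]))
    pair1 = root.add_child(TreeNode(name="PAIR1", length=depth - sub["pair1"]))
    for nm in ("PB036", "FA064"):
        pair1.add_child(TreeNode(name=nm, length=sub["pair1"]))
    pair2 = root.add_child(TreeNode(name="PAIR2", length=depth - sub["pair2"]))
    for nm in ("FA093", "PD047"):
        pair2.add_child(TreeNode(name=nm, length=sub["pair2"]))
    tree = PhyloTree(root, rooted=True)

    cfg = SimConfig(
        n_leaves=11,
        genealogy="star",  # shape is explicit above; field kept for the record
        tmrca_years=depth,
        recurrent_prob=0.02,
        root_variants=M_VERTEX_VARIANTS,
        seed=seed,
    )
    clades = {
        "Q2A": depth,
        "PD057_K058_KI018": sub["trio"],
        "PB036_FA064": sub["pair1"],
        "FA093_PD047": sub["pair2"],
    }
    return evolve_sequences(tree, ref, gene_map, cfg, clade_tmrcas=clades)
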