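# Methods

## Scope and model

The package analyses small sets (tens) of complete human mtDNA genomes
aligned to the rCRS coordinate frame. The inferential model is maximum
parsimony over unrooted trees on {A,C,G,T}: the score of a tree is the
minimum number of substitutions over all internal labelings, and the target
of inference is the set of all trees attaining the global minimum score.
For closely related sequences this is also the maximum-likelihood estimate
under low-rate models, which is the regime complete-mtDNA haplogroup data
live in. Multifurcating trees and internal nodes coinciding with observed
haplotypes are first-class: zero-length branches are retained, and
consensus polytomies are scored exactly.

## Scoring

`fitch_length` runs unit-cost Sankoff dynamic programming (per node, per
site, per state: sum over children of min(child cost, child min + 1)).
This is exact for any degree of multifurcation and invariant under rooting;
plain Fitch set operations agree with it on binary trees and are used in
the enumeration hot path, where site states are packed four bits per site
into Python integers so one tree node costs a few big-int operations.
Alignment columns are collapsed to unique patterns with multiplicities
before scoring; constant columns are dropped (score contribution zero).

## Search

`heuristic_search` follows the classic protocol: stepwise addition in input
order builds the start tree (each new taxon tried on every edge, first
best edge kept), then tree bisection–reconnection: every edge is cut, the
two fragments re-joined across every pair of edges. All distinct topologies
at the best score are pooled, deduplicated by canonical split set, and the
frontier of unexplored pool members is swapped until closure. Determinism:
canonical edge enumeration order, fixed tie-breaks, and an iteration budget
(`max_evals`) instead of wall-clock limits. Optional seeded random restarts
permute the addition order only. The pool is capped (`max_pool`, default
64): a star-like dataset can have thousands of equal-score binary
resolutions, and the cap bounds memory while the strict consensus of the
pool still collapses unsupported edges. `enumerate_mp_trees` scores every
unrooted binary topology (refusing more than 9 taxa) and is the oracle the
search is validated against.

## Minimality certificates

The squeeze takes the search score as an upper bound and builds a lower
bound by partitioning the variable characters into disjoint blocks and
summing each block's *exact* minimum score over all trees (computed on
pattern-collapsed taxa by full enumeration; blocks collapsing to more than
9 patterns are refused rather than approximated — exactness is what makes
the certificate a proof). Any one tree realises every block simultaneously,
so the sum can never exceed the true minimum; equality with the upper bound
proves minimality. The partition search starts from singletons (each
variable column contributes states−1), groups recurrent sites with the
sites they are pairwise incompatible with (the "rectangle" conflicts that
force an extra change), then hill-climbs over pairwise block merges while
the bound improves, under a deterministic evaluation budget
(`max_pair_checks`). Certificates are self-contained and re-checkable:
`verify_certificate` recomputes every block minimum from the stored column
lists. A failed proof is reported as `unproven`, never silently upgraded.

## Branch annotation

`map_mutations` roots the tree (on a named outgroup leaf, or at the
internal node whose reconstructed state is nearest the reference haplotype
— "nearest" meaning the attachment cost of the reference sequence, with
deterministic tie-breaks), then assigns states by Sankoff traceback. Ties
prefer placing a change on the branch closest to the root, and prefer the
reference base at the root. Each change is classified in the codon context
of its *parent node's* reconstructed genome, so multi-hit codons are judged
against their actual ancestral state; ND6 is evaluated on the light strand;
incomplete stop codons are completed with A (polyadenylation). Changes
hitting one position more than once tree-wide are flagged recurrent and
numbered in preorder. The root's differences from the rCRS are reported
separately as the ancestral-vertex change list. Conservation holds by
construction and is asserted in tests: branch mutation counts sum to the
tree score. Deletion columns are excluded before mapping (whole-column gap
removal), so branch mutations are substitutions only; deletions still
appear when calling an individual sequence against the reference.

## Dating

The rho statistic averages filtered root-to-leaf mutation counts.
Calibrations:

* `kivisild_synonymous` — counts substitutions classified synonymous;
  1 change = 6,760 years. RNA-gene and control-region changes never count.
* `soares_complete` — counts all substitutions except positions 16182,
  16183, 16194, 16519; the years-per-change rate is user-supplied (the
  published rate curve is external to this package; only the counting and
  calibration contract is implemented).

The standard error treats each branch count as Poisson:
se(ρ)² = n⁻² Σ_b n_b² ℓ_b over branches inside the clade (n_b = leaves
below branch b, ℓ_b = filtered changes on it), reducing to √(ρ/n) on a
star. Published ± values for this class of analysis do not come with a
stated formula, so this estimator is isolated in one place for
substitution, and age uncertainties should be read as indicative. A
single-leaf "clade" is dated by its pendant-branch count. Recurrent-site
changes count once per occurrence (mutations, not states).

## Synthetic data

The generator drops Poisson mutation events onto a genealogy with branch
durations in years. Genome-wide per-class rates (events per lineage-year):

| class | default | rationale |
| --- | --- | --- |
| synonymous | 1/6760 | matches the synonymous-clock calibration, making parameter-recovery experiments self-consistent |
| non-synonymous | 1/20000 | slower than synonymous, as purifying selection leaves it in real mtDNA |
| RNA genes | 1/40000 | conservative rRNA/tRNA rate |
| control region | 1/8000 | faster, hypervariable region |

Transition:transversion ratio 20:1 (typical human mtDNA), configurable.
Synonymous/non-synonymous events are placed by rejection sampling in the
*current* genomic background, so classifications remain correct under
multiple hits; `recurrent_prob` optionally redirects events to
already-mutated sites to create parallel changes and reversions. Every
event is recorded (branch, time, site, bases, class) and replaying the
record reproduces the leaf sequences exactly — this invariant is tested.
Genealogies: star (all branches = TMRCA), Yule (ultrametric, scaled to the
requested depth), and a Kingman coalescent in coalescent units times a
direct year scale (deliberately no effective-population-size parameter).
The `q2a_preset` builds an 11-genome clade — a 7-way star at 22,430 years
with a 3-leaf subgroup (TMRCA 6,760 y) and two 2-leaf subgroups (9,000 and
12,000 y) — whose root carries the M-vertex haplotype (22 changes from the
rCRS), emulating the shape of a rapidly expanding island haplogroup.

What the generator does **not** emulate: selection, site-to-site rate
heterogeneity within a class, insertions, heteroplasmy, sequencing error,
and alignment uncertainty. Passing tests therefore demonstrate algorithmic
correctness under the stated stochastic model, not robustness to every
artefact of real data.

The packaged reference sequence is a synthetic stand-in for the rCRS: the
real 16,569-bp coordinate frame and gene annotation, the true rCRS base at
every site the documentation cites, and deterministic seeded filler
elsewhere (`scripts/build_reference_fixture.py` regenerates it). All
algorithms depend only on the coordinate frame, and real-data runs should
supply the genuine rCRS FASTA.

## Pipeline contract

The search operates on the masked, gap-free alignment (default 550–16050:
the control region is excluded because of its hypervariable sites); the
certificate refers to exactly that alignment. Annotation and dating run on
the full gap-free alignment, and every reported branch mutation carries an
`in_search` flag so display-only (control-region) changes are never
confused with characters that determined the score. Reports contain no
timestamps and are byte-identical for a fixed config and seed.

## Problem sizes and numerical choices

Exhaustive enumeration is capped at 9 taxa / 9 block patterns ((2n−5)!!
growth). The validation suite runs the search against the exhaustive oracle
on 200 random instances of 5–8 taxa, checks squeeze soundness against
exhaustive minima on 40 instances, and checks dating coverage and bias on
500 simulated star clades (n = 7, synonymous clock rate, TMRCA 22,430 y);
the full-pipeline checks use the 11-genome preset. These sizes keep the
whole suite in the minutes range while still exercising every code path at
the scale the method is designed for (the real analyses this serves are
~36 genomes, which the search handles; only the *oracle* needs small n).
Tie-breaks everywhere are deterministic (canonical orderings, lexicographic
state preference) so that identical inputs yield identical outputs.

## Known limitations

* The TBR pool cap can truncate very large plateaus of equal-best trees;
  the score and certificate are unaffected, and the strict consensus is
  computed from the retained pool.
* The set of incompatible splits is reported as a list rather than drawn as
  a consensus network.
* Branch mapping covers substitutions only (gapped columns are excluded
  alignment-wide).
* `unproven` certificates are inconclusive: the partition search is
  budgeted and greedy, so failing to prove minimality does not mean a
  shorter tree exists.
* Reference rooting assumes the reference haplotype is outgroup-like for
  the clade under study; for other data choose an explicit outgroup taxon.
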