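# Methods

## Problem setting

Ab initio protein structure prediction produces a *decoy set*: N candidate
3D structures for one target sequence, typically with a scoring-function
value ("energy", lower = better) per decoy. Under the standard funnel
hypothesis, a reasonably good sampler places many decoys near the correct
fold, so structurally dense regions mark candidate folds, and the practical
task is to return one decoy, not a full clustering. All structure
comparisons here use only the Cα trace; the distance is either the Cα RMSD
after optimal rigid superposition or a GDT-TS-derived distance
(1 − GDT-TS).

## Distances

**Kabsch superposition.** RMSD is minimised over rigid motions with the
SVD form of the Kabsch algorithm, including the determinant-sign
correction so reflections are excluded. The bulk path (pivot rows) uses
the singular-value identity `rmsd² = (‖A₀‖² + ‖B₀‖² − 2(σ₁+σ₂±σ₃))/N`
over batched 3×3 SVDs, which avoids forming rotation matrices and makes a
40×20,000 pivot matrix a few seconds' work. Degenerate (e.g. collinear)
point sets still return a minimising proper rotation. The test suite
checks the minimum against a brute-force rotation-grid oracle (Euler grid
+ step-halving refinement, exact centroid translation) to 1e-3 Å, and
against `scipy`'s `Rotation.align_vectors` as an independent library
cross-check.

**GDT-TS.** The score is the mean over cutoffs 1/2/4/8 Å of the maximal
fraction of residues placeable within the cutoff under some rigid
superposition. The exact maximisation is combinatorial; we use the
standard seed-and-refine heuristic: superposition seeds are the global
Kabsch fit plus sliding windows of lengths 3, 5 and N/2 at every offset,
each refined by re-fitting on the residues currently within the cutoff
(≤ 10 iterations). This is an approximation — on chains short enough for
exhaustive subset enumeration it is exact in our tests, but on long chains
a third-decimal difference from other GDT implementations is possible.

**Evaluation counting.** A `DistanceCache` memoises unordered pairs and
counts *unique* pair evaluations; self-distances, memo hits and pivot-row
lookups are free. Every selection run asserts the budget
`eval_count ≤ P·N + T·S·E + C(T,2)`. The pivot matrix itself charges
`P·(N−1) − C(P,2)` (self free, pivot–pivot pairs once).

## Hashing and trees

Each pivot's hash threshold is the **lower-upper median**: the sorted
distance at 0-based index ⌊N/2⌋ of its full distance row. The split is
strict (`d < threshold` → bin0), ties go to bin1. For distinct distances
this yields ⌊N/2⌋ | ⌈N/2⌉ bins, so the larger bin is ≤ 2N/3 with equality
only at N = 3; a constant row leaves the node unsplittable. Pivots (and
their hash functions) are drawn once per forest and shared by all trees;
each tree samples H_max functions without replacement and uses one
function per level.

**Height convention.** The root has h = 0; each split increments h. The
cluster-node rule `h/H_max ≥ log z / log N` (any log base; natural log
used) is checked top-down and descent stops at the first satisfying node,
which realises the "shallowest satisfying node per path" semantics
directly — the root never qualifies, a singleton at h ≥ 1 always does.
A node whose split is degenerate (one empty bin) becomes a non-cluster
leaf; this prevents infinite descent on duplicated structures.

**H_max approximation and empty results.** Production trees stop at
H_max = P/2 without knowing the realised height, so only a sliver of the
tree is built; the price is that a tree whose every path dies in a
degenerate split before satisfying the rule has no cluster node and
raises `EmptyResultError` (remedy: lower H_max). This is rare in the
diffuse sets the method targets but becomes common on small sets of very
tight, very well-separated clusters, where whole nodes sit on one side of
every threshold. In *exact-height* mode (`build_tree(exact_height=True)`,
used for validation) the tree is grown fully and the realised height H
replaces H_max; the deepest leaf then always satisfies h/H = 1 ≥
log z / log N, so at least one cluster node is guaranteed — the property
the acceptance script measures over 200 randomized trees.

**Representatives and candidates.** A cluster's representative minimises
the precomputed total distance to the pivots (no new evaluations; ties to
the lowest index). Per tree, the S largest clusters (size ties by
discovery order) have their representatives ranked by total distance to
the E lowest-energy decoys; the E-list is global, computed once per
forest, with energy ties broken toward lower index. Without an energy
table the consensus pseudo-energy — each decoy's total distance to the P
pivot reference structures — takes its place.

**Consensus.** Candidates keep multiplicity: the winner minimises the
total distance to all T candidates, so repeated candidates act as votes
and contribute zero to themselves; ties break to the lowest decoy index.
Adding another vote for the current winner can never change the outcome.

## Parameters

| name | default | meaning |
|------|---------|---------|
| P | 40 | pivots = hash pool size; also the pseudo-energy reference count |
| T | 30 | trees; more trees stabilise the consensus |
| S | 30 | largest clusters ranked per tree |
| E | 10 | lowest-energy decoys used for ranking |
| H_max | P/2 | per-tree height bound; P/2 keeps tree function sets partially disjoint |
| seed | 0 | drives pivot draw and per-tree function sampling; fixes the whole run |

Distances are in Å (RMSD) or in [0,1] (GDT distance). Performance is flat
over a broad parameter range; P between 20 and 60 is sensible, and very
large P (hence H_max) weakens the cluster rule.

## Synthetic decoy sets

The generator emulates the statistical shape of predictor output, not its
physics: a native Cα chain is a self-avoiding random walk with exact
3.8 Å virtual bonds, pseudo-bond angles in 85–145° and a 3.0 Å
non-adjacent clash floor; each cluster centre is the native plus Gaussian
coordinate noise rescaled by bisection until its superposed RMSD hits the
requested offset (±0.05 Å; bisection because superposition makes the
scale→RMSD map closed-form-free but monotone); members add isotropic
Gaussian spread; outliers are calibrated to 8–16 Å. Pseudo-energies are
`slope · RMSD-to-native + N(0, σ_E)` with σ_E = 2.0 by default, giving an
energy–RMSD correlation around 0.6–0.8 on the default layout — a
"reasonably good but imperfect" scoring function; `invert_energy` flips
the sign to model an adversarially wrong one. The default recipe
(308 decoys of 40 residues: clusters of 150/80/50 at 2/5/8 Å, σ = 0.8 Å
within clusters, 10% outliers) keeps at least one decoy under 4 Å of the
native, matching the usual decoy-set inclusion rule.

What passing tests on these sets shows: the hashing/tree machinery finds
coordinate-space density and the consensus prefers the dominant basin
even under corrupted energies. What it does not show: behaviour on real
energy landscapes, non-Gaussian cluster shapes, or sequence-dependent
pathologies — synthetic clusters are isotropic and unimodal by
construction.

## Validation experiment sizes

The exact-height guarantee is measured over 200 trees on sets of sizes
{2, 3, 5, 10, 100, 1000} (fresh pivots per tree, P = min(N, 16)); the
distance-budget check runs one full selection at N = 20,000 (P=40, T=30);
the fold-detection comparison uses 20 seeded sets of 207 decoys with 2
adversarially inverted energy tables, scaled-down forests (P=10, T=5,
S=5, E=3). These sizes keep the whole suite under a minute of compute
while exercising every code path at realistic multimodality.

## Design choices and limitations

- Exclude-and-warn (not error) for decoys of deviant chain length;
  the modal length defines the set.
- Energies join decoys by filename stem; first PDB model and first
  alternate location only; mmCIF and full-atom parsing are out of scope.
- The purity of cluster nodes on well-separated synthetic clusters
  depends on trees drawing at least one hash function whose median falls
  on the cluster boundary; deep trees (H_max near P) make this almost
  sure, shallow trees can stop on a mixed node.
- Tree construction is serial by contract: the result is a deterministic
  function of (inputs, seed). Parallelism would have to preserve that.
- `EmptyResultError` propagates to the caller rather than being retried
  internally, keeping the evaluation-count contract exact.
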