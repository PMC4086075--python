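# Methods

## Problem and scope

The package predicts a single sub-cellular localization class per protein:
18 classes for eukaryota (10 non-membrane, 8 membrane), 6 for bacteria
(cytosol, plasma membrane, periplasmic space, outer membrane, fimbrium,
extra-cellular) and 3 for archaea (cytosol, plasma membrane,
extra-cellular). Proteins with multiple compartments are out of scope: the
annotation reader rejects conflicting labels for one identifier. Running
alignment searches is also out of scope — the package consumes hit lists
and profiles, it does not produce them.

## Profile representation

All scoring is done on per-position residue profiles. An NCBI ASCII PSSM's
20 percentage columns are read as the per-position residue probabilities
p, clamped to [0.001, 1], and stored as costs −ln p; the clamp makes the
largest cost −ln 0.001 ≈ 6.908, so k-mer window scores are bounded and the
trie traversal below can prune. The log-odds columns are ignored: the
kernel needs probabilities, and the percentages are the estimated profile
distribution. When no PSSM is supplied, a deterministic surrogate profile
is fabricated from the sequence: the observed residue gets p_self = 0.9,
the remaining 0.1 is spread over the other 19 letters, and X positions get
a uniform column. This is a soft one-hot encoding — it keeps the de novo
route usable from sequence alone and is the scale on which the default
threshold θ is calibrated.

## Profile k-mer kernel

A k-mer hits a window position when its summed cost is **strictly below**
θ (strict, so θ → 0 yields an empty feature vector rather than an
alphabet-complete one). The feature map counts hits over all positions;
the kernel is the cosine of two count vectors, hence symmetric, in [0, 1],
and exactly 1 on the diagonal.

* **k** defaults to 6 (eukaryota), 5 (bacteria), 3 (archaea); k > 6 is
  rejected unless explicitly overridden, because the enumeration oracle
  becomes infeasible there.
* **θ** defaults to (k−1)·(−ln 0.9) + (−ln(0.1/19)) + 0.05. On the
  fabricated-profile scale this admits the exact-match k-mer plus every
  single-substitution neighbour — 1 + 19k hits per position, sparse
  relative to 20^k yet never empty, and tolerant of point substitutions in
  homologs. A calibration aiming at a specific expected hit count per
  position is not attainable on this scale: fabricated columns take only
  two values, so per-position hit counts jump discretely (1, then 1+19k,
  then the two-substitution shell). The one-substitution shell is the
  chosen operating point; real PSSMs have continuous columns and simply
  see θ as a bounded cost budget.
* **Implementation.** The production feature map is a pruned traversal of
  the k-mer trie, processed one level at a time with the surviving
  (position, prefix) states held in flat numpy arrays — the pruning rule
  (drop a prefix once its partial cost reaches θ; costs are non-negative,
  so no descendant can recover) is identical to a depth-first traversal,
  and the output is order-independent; the level-synchronous form is
  simply vastly faster in Python. A brute-force enumerator over all 20^k
  k-mers (guarded at 10^6) is kept as an independent oracle and checked
  exhaustively in the tests for k ≤ 3.
* Gram matrices are assembled sparsely (CSR over the union vocabulary of
  k-mer codes), symmetrized, and given an exact unit diagonal.

## Hierarchical SVM tree

Tree topologies are config data, not code: JSON files list internal nodes
and their two children (child = node id or leaf class). The shipped
defaults follow the cell's sorting logic — secretory pathway first, then
membrane/soluble splits — and carry the correct leaf sets per domain; they
are this package's design choice, not recovered topologies from any
deployed predictor. Validation enforces a proper binary tree whose leaf
set equals the domain's class set exactly.

Each internal node is an independent soft-margin SVM (scikit-learn SVC on
the precomputed kernel, C = 1 by default) trained on the examples whose
class lies under the node, labelled by which child subtree holds their
class (+1 = left). Decision values are calibrated with a Platt sigmoid
p(+|f) = 1/(1+exp(a·f+b)) fitted by Newton's method with backtracking on
the training decision values (no inner cross-validation) using
Laplace-smoothed targets — robust for the small per-node sample sizes this
package targets. Degenerate flat fits are clamped to a barely negative
slope so that the stored model always satisfies a < 0.

Prediction descends from the root taking at each node the side whose Platt
probability is ≥ 0.5 (ties, including a decision value of exactly 0 with
b = 0, go to the positive child), recording max(p, 1−p) as the step
confidence — by construction ≥ 0.5 per step. This probability-based
descent coincides with sign-of-decision-value descent whenever |b| is
small, which holds for calibrations fitted on their own training values,
and it is what makes the reliability index interpretable. The RI is
round(100 · Π confidences), so a depth-d path is floored at 100·0.5^d.

Training is deterministic: fixed data, topology, kernel parameters and C
reproduce a byte-identical serialized model (JSON holding the topology,
kernel parameters, per-node support coefficients and calibrations, and the
training feature vectors as integer code/count arrays).

## Homology transfer

Hits (12-column tabular) are filtered to E-value ≤ 10⁻³, non-self, with
annotated subjects; the transfer takes the single best surviving hit by
highest PIDE, ties broken by lower E-value, then input order — one hit, no
voting. Its RI is round(100·(clamp(PIDE, 20, 100) − 20)/80): 0 at or below
the PIDE ≤ 20 saturation floor, 100 at identity. Only the floor and range
of this curve are externally constrained; the linear interpolation between
them is this package's choice and trivially replaceable. PIDE is taken
from the hit record as given; no re-alignment is performed.

## Combiner and outputs

One parameter chooses the route: homology transfer if any hit survives,
otherwise the SVM tree (fabricating a profile if none was supplied). Each
prediction carries the six output fields: identifier, RI, expected
accuracy, class, GO term(s), source. GO terms come from an editable
per-class config (one standard cellular-component term per class by
default). Expected accuracy is a step-function lookup in an RI
calibration — (threshold, observed accuracy) bins produced by evaluating
labeled data — and stays "n/a" until such a calibration has been computed,
since a fresh install has no benchmark of its own. Batch prediction
streams record by record; per-query failures are logged and reported, not
fatal.

## Evaluation

Acc(L) = 100·TP/(TP+FP), Cov(L) = 100·TP/(TP+FN), Qn = percentage of
proteins whose predicted class equals the observed one; class merging (for
comparisons against coarser methods: nuclear membrane→nucleus,
plastid→chloroplast, fimbrium→extra-cellular) is applied to both labels
before counting. Undefined ratios (zero denominators) are reported as
"n/a", never as 0 or 100.

Standard errors use a subsampling bootstrap: n_sets = 1000 draws of
⌈15%·N⌉ proteins **without replacement**; each draw's metric is compared
against the full-set value ⟨x⟩ (not the bootstrap mean), σ =
√(Σ(xᵢ−⟨x⟩)²/n), SE = σ/√(n−1). The draw contract is documented (one
`numpy.random.default_rng(seed)`, one `choice(N, size=m, replace=False)`
call per set, predictions indexed in list order) so an independent
re-implementation reproduces the draws bit-for-bit; the tests contain such
a re-implementation and require agreement to 10⁻¹². Draws on which a
metric is undefined are skipped and counted, and n is the number of used
draws.

## Synthetic data: what it emulates and what it does not

The generator's defaults are the package's study conditions: 6 bacterial
classes, 50 reference + 20 query proteins per class, sequence lengths
150–250, 2 motifs of length 8 per class planted 3 times per sequence
(non-overlapping, placement uniform over all valid configurations via the
standard gap bijection), uniform background residue frequencies, half the
queries being homologs at a target 60% identity. Motifs are mutually
distinct at Hamming distance ≥ 2 so classes are separable by k-mer
content. Homologs substitute exactly round((1−PIDE/100)·L) positions drawn
without replacement, always to a different letter; planted motifs get no
protection, so diverged homologs genuinely degrade the de novo signal.
Fabricated hits carry the documented E-value proxy 10^(−0.2·PIDE) — a
monotone, filterable surrogate, not an alignment statistic: a 60%-identity
homolog passes the 10⁻³ gate comfortably, and optional decoy hits at
PIDE 2–12 (off by default) fail it, which is what the filters-disabled
("forced transfer") comparison arm consumes.

What passing tests on this generator show: the kernel, tree, transfer
rule, combiner and evaluation machinery are internally correct and behave
as designed under the assumed signal structure. What they do not show:
performance on real proteins. Real localization signals are not clean
planted motifs, real profiles are not two-valued, real identity
distributions are not a point mass, and real class frequencies are heavily
skewed; the benchmark numbers produced here characterize the machinery,
not biological accuracy.

## Numerical choices and edge cases

* Profile probabilities clamped to [0.001, 1]; a profile row entirely at
  the clamp ceiling is rejected as invalid.
* Hit rule strict (< θ); trie pruning at partial ≥ θ.
* kernel(u, u) returns exactly 1.0 (identity short-circuit); Gram
  diagonals are set to 1.0 exactly and matrices symmetrized by averaging.
* Empty feature vectors make the kernel undefined and are signalled, never
  silently zero; profiles shorter than k are likewise signalled.
* Decision-value tie at a node goes to the positive-side child.
* Resample sizes round up (ceil); bootstrap with a single usable draw
  degrades to SE = σ.
* Alignment coordinates are 1-based inclusive at the format boundary,
  0-based half-open internally.
* Problem sizes in the shipped tests and the acceptance script (hundreds
  of training proteins, thousand-draw bootstraps, exhaustive kernel
  oracles at k ≤ 3) were chosen so a full run finishes in a few minutes on
  one CPU while still exercising every code path at non-trivial scale.

## Known limitations

* The de novo route's accuracy on real data depends entirely on profile
  quality and on tree topology/hyperparameters that would need tuning on a
  curated corpus; the shipped topologies are structural defaults.
* The transfer RI's linear PIDE map is a stand-in for a curve that should
  be re-estimated from data via `calibrate` when labeled data exist.
* Single-localization assumption throughout; no multi-compartment output.
* The profile kernel is exact, not approximate, and therefore scales as
  the number of surviving trie states; extremely permissive θ on long
  eukaryotic proteins is the worst case.
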