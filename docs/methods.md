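# Methods

`chemodti` treats drug–target interaction (DTI) prediction as binary
classification of (molecule, protein) pairs, the chemogenomics /
proteochemometrics formulation: one model is trained jointly over
chemical and protein space, so it can score pairs involving entities
with no known interactions (the orphan regimes that matter for
off-target prediction).

## The chemogenomic network (CN)

The CN composes four blocks.

**Molecule encoder — minimal graph neural network.** A molecule is an
undirected attributed graph G = (V, E) with per-atom input vectors x_i
(element one-hot over {C,N,O,S,F,P,Cl,Br,I,other}, hydrogen count,
heavy-neighbour count, formal charge, ring/aromatic flags, atomic polar
surface contribution, Gasteiger partial charge, chirality one-hot; 21
dimensions).  Node states start at h_i^(0) = x_i and are updated for
L layers by

    h_i^(l+1) = σ( W0^(l) h_i^(l) + Σ_{j∈N(i)} α_ij W1^(l) h_j^(l) )

with N(i) the one-hop neighbourhood.  The readout at each layer is the
node sum m^(l) = Σ_i h_i^(l), and the molecule embedding is the
last-layer readout m = m^(L).  The sum readout makes the embedding
invariant under node relabelling exactly in exact arithmetic; in
float64 the summation order changes, so tests assert equality at
1e-12.  Bond attribute vectors are computed (bond-type one-hot, ring,
aromatic, conjugated) and accepted by the interface, but the minimal
encoder does not consume them.

*The α_ij coefficients.* Free per-edge coefficients cannot transfer
across molecules (edges have no identity between graphs), so three
parameterisations are offered: `constant_one` (default; plain neighbour
sum), `degree_normalized` (α_ij = 1/deg(i)), and
`learned_scalar_per_layer` (a single trainable scalar shared by all
edges of a layer).

*Activation.* σ defaults to the sigmoid; a ReLU switch exists.  On the
synthetic planted-motif task both learn the rule; ReLU converges in
roughly a tenth of the epochs, which is why the down-scaled smoke model
uses it.

**Protein encoder — strided 1D CNN.** The input is the one-hot residue
matrix (L × 20; an optional 21st channel represents nonstandard
residues mapped to 'X').  Three stacked strided convolutions (100
filters, filter size 8, stride 3, ReLU, per-filter bias) produce
per-position states; the protein embedding h_prot is their sum, so its
dimension equals the last layer's filter count.  Padding defaults to
`same_zero` (output length ceil(L/stride)): with `valid` padding, three
layers of filter 8 / stride 3 reject any protein shorter than about 80
residues.  `valid` is available and errors below the minimum receptive
length, naming it.

**Comb block.** Concatenation [m ; h_prot], molecule first.

**Pair MLP.** One hidden layer of 100 ReLU units and a single sigmoid
output unit scoring the pair.  (Only the last prediction layer's width
is a tuned constant; depth is a configuration choice.)

### Training

Binary cross-entropy on logits (numerically stable form), Adam (SGD
available), initial learning rate 1e-3 multiplied by 0.9 after every
epoch, batch size 20 (100 for the descriptor FNN), at most 100 epochs,
early stopping when the validation AUPR has not increased for 10
successive epochs; the returned parameters are those of the best
validation epoch.  Loss and optimizer are this package's choices —
only the rates, batch sizes and the early-stopping rule above are
inherited tuned values.  Training negatives are drawn uniformly from
unlabelled pairs at a 1:5 positive:negative ratio, once per run (a
flag redraws them each epoch).  No class-imbalance correction is
applied by default.  Everything is float64, single-threaded and keyed
to one seed, so a fixed seed reproduces histories and parameters
bit-for-bit.

The networks run on a small in-package reverse-mode autodiff core
(`chemodti._autodiff`): dense affine maps, adjacency matmuls, strided
1D convolution, ReLU/sigmoid, sum reductions, concatenation and masked
BCE, each with a hand-written adjoint.  Gradients are verified against
central finite differences in the test suite.

## Baselines and multi-view variants

**FNN.** An MLP (hidden widths 2000/1000/100) on concatenated expert
descriptors: a 1021-bit folded circular substructure fingerprint for
the molecule and composition blocks for the protein (AAC 20, dipeptide
400, CTD 147 — the standard 7-property, 3-class
composition/transition/distribution scheme).  The fingerprint uses the
package's own deterministic FNV-based neighbourhood hashing over the
graph annotations, so parsed and synthetic molecules share one code
path; bit positions are implementation-defined but stable.  Full
externally computed descriptor tables (e.g. 1920-dimensional protein
vectors) can be loaded from CSV and used instead.

**Multi-view fusions.** The one-step model concatenates GNN embedding,
CNN embedding and two descriptor-MLP outputs into a single pair MLP.
The two-branch model (CN-feaMLP) sends the learnt pair representation
through MLP_raw-pair and the expert pair representation through
MLP_fea-pair, fusing the two outputs in a small joint MLP (one hidden
layer of 50 units).  `silence_branch` zeroes the joint layer's input
weights from one branch; the forward pass then provably reduces to the
composition of the remaining branch's modules, which the tests assert
exactly (the standard implementation sanity check for such fusions).

**Curriculum / transfer learning.** Checkpoints store each named block
(molecule_encoder, protein_encoder, pair_mlp, …) separately in a
versioned NumPy archive.  `transfer_load` initialises any subset of
blocks from a checkpoint and can freeze them (frozen blocks are
excluded from the optimizer, hence bit-identical after training).
Loading all blocks and training zero epochs reproduces the source
model's predictions exactly.  Multi-task pre-training fits a sigmoid
head over molecule embeddings on bioassay-style labels; entries
labelled unknown contribute zero loss and zero gradient (masked BCE),
so the gradient equals the one computed from the observed entries
alone — asserted against a finite-difference oracle.

**kronSVM.** The pair kernel is K((m,p),(m′,p′)) = Km(m,m′)·Kp(p,p′).
Only the requested pair-block is ever formed (lazy indexing into the
factor kernels); the full Kronecker matrix is never materialised.
Molecules use the Tanimoto kernel on binary fingerprints (|a∧b|/|a∨b|;
all-zero vectors are similar only to themselves).  Proteins use a
normalised Smith–Waterman local-alignment score kernel: affine gaps
(BLOSUM62, open 11, extend 1; a gap of length L costs open +
(L−1)·extend), normalisation K(x,y)/√(K(x,x)K(y,y)), then projection
onto the PSD cone by clipping negative eigenvalues and re-normalising
the diagonal — alignment scores are not positive semidefinite in
general.  A precomputed protein kernel (e.g. from local-alignment
kernel software) can be loaded from CSV instead.  The SVM itself is a
standard precomputed-kernel solver; the regularisation constant C is
selected by inner 5-fold cross-validation on AUPR over a user grid,
and the per-C table is retained on the fitted model for inspection.

## Evaluation protocol

Four split settings: S1 random pairs; S2 orphan proteins (a fold's
test proteins appear in no training pair of that fold); S3 orphan
molecules; S4 double orphan, built by intersecting an S2 and an S3
partition, giving k² folds for k groups (25 for k = 5).  Entity groups
are uniform random partitions (no degree stratification).  Negatives
are sampled uniformly without replacement from the unlabelled pairs
admissible for each fold — test negatives obey the fold's orphan
constraints too, a choice this package makes explicit.  On sparse data
some S4 folds can have empty test sets; they are reported but skipped
by the harness.

ROCAUC uses midranks for ties.  AUPR is the average-precision form
(step-wise integral of precision over recall, ties entering together);
no trapezoidal PR interpolation.  AUPR is the primary metric: with
unlabelled pairs treated as negatives and strong imbalance it is the
more informative score.  Both agree with brute-force
pairwise-comparison / curve-walk oracles to 1e-12 in the tests.
`nested_cv` runs outer folds per the splits above with optional inner
k-fold grid selection on AUPR, reporting per-fold scores and
mean ± standard deviation.

## Synthetic data

The generators emulate the statistical shape of curated DTI data, not
its chemistry: connected random graphs (random recursive tree plus
~0.3·n extra edges) of 8–18 heavy atoms with schema-valid annotations
(actual degrees, ring membership from the cycle basis, drug-like
element frequencies), i.i.d. 20-letter sequences of 40–80 residues,
and two interaction rules.  `motif_match` plants (sequence motif,
marker element) pairs — e.g. ("WHWKW", iodine) — in a
`carrier_fraction` of each entity set; a pair interacts iff protein
and molecule carry the same pair index.  `latent_factor` draws
logistic probabilities from low-rank latent vectors with the intercept
bisected so the mean probability matches a target rate (empirically
within ±20% relative).  RNG streams are split per entity type, so
enlarging one set does not perturb the other's draws.

Defaults are the package's study conditions: 200 molecules,
100 proteins, two motif pairs, carrier fraction 0.15.  With these
values ~85% of entities have no positive at all and the positive rate
is ~1–2%, mirroring the long-tailed sparsity of curated interaction
sets, while every planted match is labelled positive.  An optional
`max_positives_per_entity` cap truncates per-entity positive lists; it
is off by default for the motif rule because matches form bipartite
carrier blocks, so a cap silently relabels most true matches as
unlabelled — the resulting false negatives contaminate sampled
negatives and put a low ceiling on every ranking metric (even a
ground-truth oracle scorer drops to ~0.6 validation AUPR under a cap
of 3 with carrier fraction 0.5).  Enable the cap only to study that
censoring regime.

What passing the synthetic checks does and does not show: the planted
rule is far easier than real chemistry (a single atom type and a
5-residue motif carry all the signal), molecules are not chemically
realistic, and sequence composition is uniform.  Success demonstrates
that the encoders, combination, training loop, splits and metrics are
implemented correctly and can recover a recoverable signal — not that
the architecture reaches any particular performance on real interaction
data.

## Numerical and design choices

- Multi-fragment SMILES keep the largest fragment (logged); duplicate
  IDs are errors; nonstandard residues are rejected by default or
  mapped to an 'X' channel on request.
- `same_zero` padding splits the total pad with the smaller half on
  the left.  Early stopping counts *successive* non-improving epochs;
  with a constant validation score training stops at epoch 11 (best
  epoch 1 + patience 10).
- Glorot-uniform initialisation throughout, biases at zero, all blocks
  seeded from one integer via named sub-streams.
- Tanimoto on two all-zero fingerprints is 0 off-diagonal, 1 on the
  diagonal.
- The learnability smoke model shrinks widths (32-dim embeddings, 2
  layers per encoder) and uses the ReLU node update; problem sizes in
  the tests and the acceptance script (200×100 entities, ≤40 epochs)
  were chosen so the full suite re-runs in about two minutes.

## Known limitations

- No attention/gated aggregation or recurrent protein encoders; no
  co-training; no matrix-factorisation baseline (a pluggable scorer
  adapter accepts any external model).
- The Smith–Waterman kernel approximates, but is not, a local-alignment
  kernel that sums over all alignments; comparisons against results
  produced with such kernels are approximate by construction.
- Only AAC/DC/CTD protein descriptor groups are computed natively;
  richer descriptor sets must be supplied as external tables.
- Per-sample training (no cross-molecule batching of the graph math)
  keeps the implementation transparent but limits throughput to
  datasets in the tens of thousands of pairs.
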