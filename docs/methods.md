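# Methods

## Contact graphs

A protein chain is reduced to one representative atom per residue — Cα by
default, configurable to Cβ — and the contact graph connects residue
pairs whose Euclidean distance is strictly below a threshold (default
10.0 Å). Residues lacking the representative atom are dropped with a
warning and the sequence shortened consistently; common nonstandard
residues (selenomethionine, phosphoserine, …) are mapped to their
standard parent, anything else becomes the unknown marker `X`. Residues
are indexed 1..n in file order in all written output; internal arrays are
0-based. Multi-chain files require an explicit chain argument: one
protein is one graph.

## Laplacians and the band decomposition

Both the combinatorial Laplacian L = D − A and the normalized form
D^(−1/2) L D^(−1/2) are provided; the normalized kind is the default
because contact-graph degrees vary systematically with burial depth, and
degree normalization keeps the spectrum in [0, 2] regardless of protein
packing. Isolated vertices contribute zero rows to the normalized form.
One point deserves care: the zero-eigenvalue eigenvector is exactly
constant only for the *combinatorial* Laplacian (for the normalized kind
it is D^(1/2)·1, constant only on regular graphs). Tests of the
constant-null-vector property therefore run on the combinatorial kind;
everything else defaults to normalized.

Eigendecomposition is dense (`scipy.linalg.eigh`), capped at n = 3000
vertices with an explicit error — real protein chains sit far below the
cap and O(n³) is unproblematic there. Determinism across runs and
platforms is enforced by a sign convention (first eigenvector component
with magnitude > 1e−8 made positive) and a stable sort of eigenvalues.
Disconnected graphs are allowed with a logged warning; all
zero-eigenvalue vectors then land in the global band by the ascending
order.

Band cut points are k_G = max(1, ⌊np⌋) and k_D = min(n, max(k_G+1, ⌊nq⌋))
with defaults (p, q) = (0.01, 0.03). The clamping matters for short
proteins: at n = 50, ⌊np⌋ = 0, and without the clamp the global band
would be empty; with it, the zero-frequency mode always defines the
global band and the domain band is never empty. The decomposition is a
partition of an orthonormal basis, so F_G + F_D + F_L = F holds to
machine precision by construction, and the band projectors are idempotent
and mutually annihilating. Degenerate eigenvalues make individual
eigenvectors basis-dependent, but band *subspaces* are well-defined as
long as no degeneracy straddles a cut point; tests on graphs with known
degeneracies therefore assert projector-level quantities only.

## Features

Node features fuse a 20-column one-hot residue identity with a
per-residue contextual embedding, each linearly projected to a common
width d (default 128) and summed. Unknown residues get an all-zero
one-hot row rather than a 21st class; the contextual channel still
supplies a vector there. The fusion is strictly per-residue (no
cross-residue mixing), which the tests pin down via permutation
equivariance. A config flag disables the one-hot channel — the ablation
axis.

Contextual embeddings go through a provider contract (deterministic, one
row per residue) with a file-based cache, so heavy language models are
optional. The test harness uses a mock provider: each residue's embedding
is a seed-determined sum of lookup tables over a ±2 sequence window.
This preserves the two properties the pipeline actually relies on —
determinism and locality (a substitution perturbs only the five rows
whose window covers it) — while having none of a real model's semantics.
Passing tests therefore demonstrate the machinery, not that mock
embeddings carry evolutionary information.

## Attention pooling

Per scale, s super-nodes (default 8; the synthetic experiments use 4)
attend over residues with scaled dot-product attention,
softmax(QKᵀ/√c). Queries encode the protein's own spectral descriptor:
the s eigenvectors with the *smallest* eigenvalues (a config switch
selects the largest instead), stacked as rows and zero-padded to a fixed
`max_len` (default 1024) so one weight matrix serves proteins of any
length. A learned per-task embedding is added to every query row — the
only task-specific conditioning in the representation. Keys come from
the matching band (K_X = FC(F_X)), values from the full signal. The
protein-level vector is the mean over super-nodes within each scale,
concatenated across scales (3c total).

Two consequences are worth stating. First, the mechanism: because
low-band keys are nearly parallel across residues, global attention
rows are near-uniform (high entropy) while local rows are peaky — this
ordering is a statistical property over random encoder weights and is
tested as such (20 seeded trials on 4-cluster modular graphs). Second, a
limitation: the query encoder reads eigenvector *positions* through the
padded descriptor, so it is not permutation-equivariant as a whole —
only the key/value path is. The permutation test accordingly holds the
protein-level queries fixed and checks that permuting residues permutes
attention columns and leaves aggregates unchanged. Residue order in a
chain is meaningful, so position sensitivity in the descriptor is
acceptable; it is still a real asymmetry of the fixed-weight encoding of
variable-size eigenvectors.

## Classifier and training

The three scale summaries feed a shared one-hidden-layer ReLU trunk
(width 2c) and per-task affine heads with sigmoid outputs. The loss is
the summed multi-label cross-entropy per protein with probabilities
clamped to [1e−7, 1 − 1e−7], averaged over the minibatch. Tasks are
drawn round-robin, one minibatch per draw, with per-epoch reshuffling;
the optimizer is Adam (lr 1e−3, β = 0.9/0.999). Everything is seeded and
bit-reproducible: NumPy arithmetic has no nondeterministic reductions at
these sizes, so identical config + seed reproduces the loss trace
exactly.

The network is implemented directly in NumPy with hand-derived
gradients. This is a deliberate choice, not a compromise: the model has
tens of thousands of parameters, a CPU minibatch step costs
milliseconds, and writing the backward pass explicitly makes the
band-projector gradient (dF += U_X U_Xᵀ dF_X) and the attention softmax
Jacobian visible and testable. The analytic gradients are verified
against central finite differences (rel. tol. 1e−4 at ε = 1e−5) for
every parameter group, and a gradient-flow test asserts that a training
step touches all of them.

## Synthetic data

The generator emulates the geometry that matters to the method and
nothing more. Backbones are 3D self-avoiding random walks with exactly
3.8 Å consecutive-Cα spacing (the real Cα–Cα distance) and a 2.0 Å clash
limit; the two fold classes differ only in turning-angle distribution
(compact: 75° ± 15°; extended: 20° ± 10°), which at a 10 Å contact
threshold yields mean degrees of roughly 15 versus 4 — a whole-graph,
spectrum-visible difference, separable by nearest-centroid on mean
degree with ≥90% accuracy. The local task plants a three-residue
sequence motif (default `CHW`, rare enough that accidental occurrences
are negligible and resampled away) whose label requires all three Cα
atoms mutually within 7.0 Å. Positives get a forced ~90° turn at the
motif center so the geometric condition holds in both fold classes;
negatives carry no occurrence of the triplet. This keeps the motif label
independent of the fold label while remaining detectable only through
sequence *and* structure together. The motif label is assigned by
running the detector on the generated protein, not from generation
metadata.

Labels are wrapped in a 6-term toy ontology (two roots, four leaves) so
annotation propagation, IC estimation and all three metrics are
exercised end to end. Datasets are stratified over the four
(fold × motif) cells and split 60/20/20 per cell, with every split
guaranteed at least one protein per cell; generation is a pure function
of the spec's seed and regeneration is byte-identical.

What passing the end-to-end test shows — and does not. The planted tasks
are learnable from structure + sequence by construction, and the trained
model beating a composition-only logistic baseline on both tasks
demonstrates that the spectral bands and the scale-specific attention
transport usable multiscale signal. It does not demonstrate performance
on real GO annotation, which needs real structures, a real protein
language model and far larger label spaces.

## Evaluation

CAFA conventions throughout: truth and predictions are propagated over
is_a edges before scoring (prediction scores propagate by max over
descendants); Fmax uses a 0.01-step threshold grid, averaging precision
over proteins with ≥1 prediction at the threshold and recall over all
proteins with ≥1 true term; Smin uses IC estimated from propagated
training-set frequencies, with terms absent from the reference capped at
−log₂(1/(N+1)); AUPR is micro-averaged with step-wise interpolation
(`sklearn.average_precision_score`). Fmax and Smin are hand-implemented
(no installed package provides the protein-centric forms) and, together
with AUPR, are cross-checked against independent brute-force oracles to
1e−10 on random prediction sets.

## Problem sizes

The shipped experiments are desk-scale by design: 300 synthetic proteins
of 40–120 residues (180 train / 60 validation / 60 test), model widths
d = 64, c = 32, s = 4, 30 epochs — about ten seconds of training per
seed on one CPU core. The architecture and all sizes are config-exposed;
nothing in the implementation assumes these values.

## Known limitations

- The query encoder's padded-descriptor input makes protein
  representations depend on residue numbering (see above).
- Eigenvector sign and degeneracy handling make *individual* band
  boundaries reproducible but still basis-sensitive under exact
  eigenvalue ties at a cut point.
- Dense eigendecomposition caps chains at 3000 residues.
- The mock embedding provider carries no evolutionary signal; real
  contextual embedders plug in through the provider contract and cache.
- Single attention layer and a single head per scale; no hierarchical
  pooling stacks.
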