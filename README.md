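# bandfold

Multiscale spectral decomposition of protein contact graphs with
structure-aware attention pooling, for multitask protein function
prediction — plus the CAFA-style evaluation stack (Fmax, Smin, micro-AUPR)
and a synthetic-protein harness so the whole pipeline runs end to end with
no downloads.

## The problem

Protein function is determined jointly by sequence and 3D structure, at
several spatial scales at once: the overall fold, domain-level
organisation, and residue-level chemistry such as binding sites. Graph
neural networks over residue contact graphs capture structure but blur
residue-level signal through repeated neighborhood averaging
(over-smoothing), and proteins of very different lengths make pooled
graph representations hard to compare.

`bandfold` takes a spectral route instead of message passing. A protein
chain becomes a **contact graph** G = (V, E): one vertex per residue (Cα
position), an edge wherever two residues are closer than a distance
threshold (10 Å by default). Each residue carries a feature vector fusing
its one-hot identity with a contextual embedding, giving a graph signal
F ∈ ℝ^(n×d).

## The model

Let L be the graph Laplacian of G (normalized by default) with
eigenvalues 0 = λ₁ ≤ λ₂ ≤ … ≤ λₙ and orthonormal eigenvectors
U = [u₁ … uₙ]. The **Graph Fourier Transform** F̂ = Uᵀ F expresses the
signal in structural frequency modes: low-λ modes vary smoothly over the
graph (global structure), high-λ modes are localized (residue-level
detail). Splitting the eigen-index range at fractions p < q of n gives
the exact three-band decomposition

    F = F_G + F_D + F_L

with F_G built from eigenvectors 1..⌊np⌋ (global), F_D from the next
block up to ⌊nq⌋ (domain), and F_L from the rest (local). The defaults
are (p, q) = (0.01, 0.03).

Each scale X ∈ {G, D, L} is pooled by cross-attention onto s super-nodes:

    Q_X = FC_X(S) + task embedding      (S: the s lowest eigenvectors,
                                         zero-padded to a fixed length)
    K_X = FC_X^K(F_X),  V_X = FC_X^V(F)
    Attn_X = softmax(Q_X K_Xᵀ / √c),  Aggr_X = Attn_X V_X

Because F_G rows are nearly parallel across residues, global attention
spreads almost uniformly over the protein; F_L rows vary sharply, so
local attention is peaky — one mechanism, three scales. The three scale
summaries feed a shared ReLU trunk with per-task sigmoid heads, trained
with multi-label cross-entropy, tasks drawn round-robin. One model serves
all tasks; only task embeddings and heads are task-specific, which is why
the multitask model is strictly smaller than per-task clones.

Evaluation follows the CAFA conventions: annotations are propagated over
the ontology DAG (true-path rule), Fmax is the best protein-centric
F-score over a 0.01-step threshold grid, Smin the minimal
information-content-weighted semantic distance √(ru² + mi²), and AUPR the
micro-averaged area under the precision-recall curve.

## Worked example

Generate a 60-protein synthetic dataset (two planted tasks: a global
fold-class label and a local spatial-motif label, wrapped in a 6-term toy
ontology), train, predict, and evaluate:

```bash
bandfold synth data --n-proteins 60 --seed 0 --min-length 40 --max-length 80
# wrote 60 proteins to data (splits {'train': 36, 'val': 12, 'test': 12})

bandfold decompose data/structures/syn0000.pdb out-decompose
# syn0000: n=74, band sizes (1, 1, 72), reconstruction error 2.33e-14

cat > config.yaml <<EOF
d: 64
c: 32
s: 4
max_len: 128
context_width: 32
epochs: 30
batch_size: 16
seed: 0
EOF

bandfold train data runs/demo --config config.yaml
# trained 34918 parameters; loss 2.3294 -> 0.8364

bandfold predict data runs/demo/checkpoint.npz preds.tsv --split test --config config.yaml
bandfold evaluate preds.tsv data/annotations_test.tsv data/ontology_edges.tsv
# global-fold   Fmax=0.8327 (tau=0.28)  Smin=0.6509  AUPR=0.8943
# local-motif   Fmax=0.8575 (tau=0.30)  Smin=0.5270  AUPR=0.9268
```

The `decompose` line shows the exact band split: a 74-residue protein at
(p, q) = (0.01, 0.03) puts one eigenvector in the global band, one in the
domain band and 72 in the local band, and the three bands sum back to F
to machine precision. The evaluation lines are protein-centric Fmax with
its best threshold, semantic distance Smin (lower is better) and
micro-AUPR on the held-out test split; with more training data (the test
suite uses 300 proteins) both tasks reach Fmax ≈ 0.9, clearly above a
composition-only logistic baseline. `bandfold attention-dump` writes the
per-residue attention weights of a trained model as TSV for inspection.

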