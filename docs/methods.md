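# Methods

## Problem and model

Given a drug pair and a cancer cell line, the package predicts whether the
combination is synergistic (combined effect above the Loewe-additivity
expectation) or antagonistic.  Training data are triplets
(drug A, drug B, cell line) with binary labels derived from Loewe synergy
scores; inputs are each drug's SMILES, a cell-line × landmark-gene
expression matrix, and a protein–protein interaction (PPI) network over
those genes.

Two feature views are fused:

**1D view (1,792-d).**  Each drug maps to a 768-d chemical-language
vector.  The bundled backend hashes the molecule's Morgan (radius-2)
circular substructure identifiers into 768 buckets by identifier modulus,
accumulates counts, and L2-normalizes; a `pretrained` backend slot exists
for transformer-based chemical language models but no weights ship with
the package.  The cell line's expression profile (978 genes at full
scale), z-scored per gene over the training cell lines, is compressed by a
three-layer MLP (genes → 768 → 512 → 256, ReLU after the two hidden
layers, dropout in training).  The 1D feature is the concatenation
(drug A, drug B, cell line).

**2D view (256-d).**  Each drug becomes a heavy-atom molecular graph with
78-d binary atom features (element one-hot over 44 symbols with an
"other" bucket / degree 0–10 / attached H 0–10 / implicit valence 0–10 /
aromatic flag) and is encoded by a two-layer graph convolution

    h^(l+1) = ReLU( D̃^{-1/2} (A + I) D̃^{-1/2} h^(l) W^(l) ),   78 → 512 → 128.

Self-loops are added before degree normalization so an atom keeps its own
features; a flag reproduces the bare-adjacency form.  Every PPI protein
carries a frozen 128-d node2vec embedding (below).  The atom embeddings of
both drugs and all gene embeddings stack into one token set (no positional
encoding — the input is a set), pass through two post-norm transformer
encoder layers with 2-head scaled dot-product attention (d_k = 32, total
projection width 64, FFN 128 → 64 → 128 with ReLU, dropout 0.3 after each
sublayer, residual + LayerNorm), are mean-pooled over tokens, and
projected with ReLU to 256-d.  Because the token set is order-free, the
pooled feature is invariant under token permutation — including swapping
the two drugs.

**Classifier.**  The concatenated 2,048-d feature passes through ReLU
hidden layers 2048 → 512 → 128 → 32 → 2 with dropout, a softmax, and
cross-entropy loss (mean-reduced per batch; a sum reduction would couple
the effective learning rate to batch size).  Everything trains jointly by
Adam except the chemical-language drug vectors and the PPI embeddings,
which are precomputed and frozen.  Ablation variants: `1d_only` (1,792-d
input), `2d_only` (256-d), and `2d_no_graphtrans` (encoder stack replaced
by direct mean pooling of the raw tokens).

**Drug-pair symmetry.**  Pairs are unordered.  The 2D branch is symmetric
by construction; during training each example's 1D drug order is randomly
swapped per batch, and at prediction time the forward pass runs in both
orders and the class probabilities are averaged, so
predict(A, B, c) = predict(B, A, c) exactly.

## PPI embedding

Second-order biased random walks (return parameter p, in–out parameter q;
weight 1/p to return, 1 for a triangle step, 1/q otherwise) generate node
sentences; defaults p = q = 1, 10 walks per node of length 80, window 10,
128 dimensions.  The skip-gram-with-negative-sampling objective is
optimized in expectation form: window co-occurrence counts C are
accumulated from the walks and

    −Σ_ij C_ij log σ(v_i·u_j) − k Σ_i (Σ_j C_ij) Σ_j P_j log σ(−v_i·u_j)

(P ∝ unigram^0.75, k = 5 negatives) is minimized by full-batch Adam
(150 iterations, lr 0.05).  At the ~10³-node scale of a landmark-gene
network the problem is dense, and the full-batch form makes the table
bit-reproducible for a fixed seed where per-pair stochastic updates would
be orders of magnitude slower in pure NumPy.  Genes present in the
expression matrix but absent from the PPI edge list receive zero vectors
with a logged warning.  Embeddings are cached on disk keyed by a hash of
the edge set, node set, and configuration.

## Preprocessing

Replicated (unordered pair, cell line) measurements are averaged first;
then scores are binarized with strict inequalities — score > 10 is
synergistic, score < 0 antagonistic, and the ambiguous band [0, 10]
(including both boundaries) is dropped with a logged count.  Split plans:
shuffled k-fold, and four leave-group-out schemes (drug combination,
drug, cell line, tissue) in which every triplet matching a held-out group
is excluded from training; group frequency ranking breaks ties
lexicographically, and the tissue map is supplied as an explicit
two-column file.

## Training protocol

Adam, learning rate 5e-4, dropout 0.3, batch size 128 by default; a
seeded 10 % validation split drives early stopping (patience 10 epochs,
cap 100) with best-validation weights restored.  All randomness —
initialization, shuffling, dropout, order augmentation — derives from one
seed; training is single-threaded deterministic up to BLAS reduction
order.  Network parameters train in float32; gradient-check and
single-example evaluation paths use float64.  The gradient engine is a
small reverse-mode tape over NumPy arrays written for this package and
verified against central differences (relative agreement ≤ 1e-4 on
end-to-end losses; ~1e-9 typical).

For the desk-scale cross-validation experiments (n = 2,000 triplets, 60
genes, ≈ 100 tokens per pair) the package uses batch size 512 with at most
40 epochs and patience 8: at that scale an epoch is three parameter
updates, so the larger batch amortizes the shared drug-pair encoder work
across triplets and the run converges (early stopping typically triggers
near epoch 20–30) in about a minute per fold on one CPU core.

## Synthetic study conditions

The generator emulates the statistical structure the model assumes, with
no downloads: a curated library of 61 valid drug-like SMILES (38 aromatic,
23 aliphatic, ≤ 17 heavy atoms); a connected preferential-attachment PPI
graph (m = 2); standard-normal expression where exactly half the cell
lines carry a +2 shift on a 10-gene signature; and labels planted by the
rule *synergistic iff [both drugs contain an aromatic ring] XOR [the cell
line carries the signature]*, flipped independently with probability
ε (default 0.1).  Defaults: 20 drugs, 12 cell lines, 60 genes, 2,000
triplets sampled without replacement over (pair, cell line) keys — so
duplicate averaging never mixes labels and the noiseless classes are
balanced by construction.  Under symmetric flips the ranking ceiling of
any predictor is AUROC = 1 − ε.

What the fixture does *not* emulate: dose–response surfaces and the
Loewe-score computation, correlated gene–gene expression structure,
assay noise heteroscedasticity, and realistic PPI degree assortativity.
Passing the planted-rule tests therefore demonstrates that the
architecture can discover a cross-modal interaction from these input
formats — not that it attains any particular accuracy on real screens.

A known property of this design: the planted "structural" signal
(aromaticity) is recoverable from *both* drug representations — the
molecular graph's aromatic flags and the hashed circular-substructure
vectors — so the 1D-only ablation, which also sees the expression
signature, is not information-limited and performs at the same Bayes
ceiling as the fused model (the 2D-only ablations, which carry no
cell-line information, drop to chance).  The fused model's advantage over
1D-only on real screens rests on signals with no 1D counterpart, which
this rule does not create.

## Numerical choices and edge cases

- Degree normalization leaves zero-degree rows zero rather than dividing
  by zero; isolated atoms and edgeless fixture networks are handled, the
  latter with a degenerate-corpus warning.
- Softmax and log-softmax are max-shifted; cross-entropy floors
  probabilities at 1e-12; attention raises on non-finite inputs.
- Min–max column normalization of attention maps sends constant columns
  to zero with a logged note and is applied after slicing, so the scale is
  relative to the displayed sub-matrix.
- Gene ranking (`top_attended_genes`) aggregates max-over-atoms on the
  unnormalized attention slice and then min–max normalizes the per-gene
  scores: per-column normalization first would pin every non-constant
  column's maximum at 1 and erase between-gene differences.  Ties break
  lexicographically.
- The interpretability default reads the final encoder layer averaged
  over heads; per-head and per-layer views are available.
- UMAP projections require ≥ 10 rows and are seeded; classifier hidden
  activations are exported at widths 512 and 32.
- Frequency ties in group ranking break lexicographically for
  reproducibility.

## Limitations

- No pretrained chemical-language weights are bundled; the hashed
  fallback is deterministic and structure-sensitive but not a learned
  representation.
- Bond types, chirality, and 3D geometry are not used (binary adjacency
  only); salts/multi-fragment SMILES are kept whole.
- The attention block is dense; at the full 978-gene scale each drug-pair
  token set is ≈ 1,040 tokens, which is fine on a desktop but the
  implementation makes no sparsity attempt.
- Exact bit-level reproducibility across BLAS builds is best-effort;
  within one environment runs are deterministic per seed.
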