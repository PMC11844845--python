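# Methods

## Model

The package implements a two-tower regression model for drug–target
affinity. The drug tower operates on the heavy-atom molecular graph; the
protein tower on the integer-coded residue sequence; a fully connected
head fuses the two fixed-length embeddings into a scalar affinity.

### Molecular graphs and atom features

SMILES are parsed with RDKit; hydrogens stay implicit, and disconnected
SMILES (salts written with `.`) keep all components rather than silently
dropping fragments — matrix powers treat components independently. Each
atom carries a 78-dimensional feature row: a one-hot over a fixed
44-symbol table (last slot a wildcard), one-hot degree 0–10, one-hot
total hydrogens 0–10, one-hot implicit valence 0–10, and an aromaticity
flag. This layout is the de-facto convention of the GCN-based DTA model
family and keeps the feature width at exactly 78.

### Power graphs

For adjacency M, the k-hop support S_k (k = 1, 2, 3) is either the
indicator of "a walk of length exactly k exists between distinct atoms"
(`binary`, the default, with the diagonal zeroed) or the literal matrix
power M^k (`walkcount`, in which entries count walks and the k=2 diagonal
holds atom degrees). Both semantics are exposed because the connectivity
reading matches the power-graph idea while the literal power matches the
algebra; the choice is a run-time switch and both are tested. Powers
beyond 3 are excluded: on small-molecule graphs, longer hops add little
reachability. Self-loops are added uniformly (S + I) before symmetric
degree normalization D̃^(−1/2)(S + I)D̃^(−1/2) for all powers; the
normalized operator is symmetric with spectral radius ≤ 1 (verified
against dense eigendecomposition in the tests), which keeps stacked
message passing numerically stable.

### Drug encoder

Blocks of 3, 2 and 1 GCN layers consume the power-1, power-2 and power-3
operators respectively. Within a block the width is constant: atom
features are projected once from 78 to `hidden_dim`, then every layer
computes ReLU(Mₙ H W + b) followed by the gated skip connection. Keeping
the width constant is what makes the elementwise gate well-defined across
a layer; the gate is applied after every layer, matching the
architecture's per-layer skip-connection description. Per-node block
outputs are concatenated, max-pooled over atoms (making the encoder
invariant to atom relabeling), and mapped by two FC layers
(→ 2·embed_dim → embed_dim) to the drug vector.

### Protein encoder

Sequences are coded by alphabetical rank of the 20 canonical amino acids
(A=1 … Y=20), chosen because it is consistent with both anchor pairs of
the coding scheme (A→1, E→4); the six non-canonical letters collapse to a
single unknown index 21, and 0 is reserved for padding. Truncation keeps
the N-terminal prefix; the pad mask is carried everywhere so pooling and
attention see only real residues. Convolutions are 1-D, kernel 3, "same"
padding, constant channel width; stacks of depth 1/2/3 give receptive
fields 3/5/7. Outputs at padded positions are zeroed after every
convolution so the mask stays meaningful; as a consequence, padding a
sequence further never changes its encoding (asserted to 1e-6).

Multi-head linear attention pools each stack: head j assigns position i
the score (W_j·hᵢ)/d_k with d_k = √(channel width); scores are
softmax-normalized over unmasked positions with max-subtraction
stabilization, masked positions get exactly zero weight, per-position
weights are summed across heads, and the pooled vector is Σᵢ aᵢhᵢ. Note
the head weights each sum to 1, so with n heads the weight field aᵢ sums
to n — with all-zero score maps the pool degenerates to n × mean, which
the tests pin down. W_j is a single row map (one scalar score per
position per head), the only shape under which the positional softmax is
well-formed. Max and mean pooling are available as ablation switches.

### Fusion head and training

concat(drug, protein) → 1024 → 512 → 1 with ReLU and dropout after each
hidden layer. Dropout (rate 0.2) is applied in the FC stacks only, in
train mode only; the convolutional and graph layers stay deterministic,
which keeps the eval-mode forward pass bitwise reproducible. Training
minimizes MSE with Adam. Labels are standardized internally to zero mean
and unit variance of the training labels and predictions are mapped back,
so optimization is well-scaled regardless of the label range while all
logged losses are in label units. The epoch-0 log entry is the untrained
model evaluated on the training set; later entries are running means over
minibatch losses. With a validation split, the returned parameters are
the epoch checkpoint with lowest validation MSE; otherwise the final
epoch. All randomness (initialization, shuffling, dropout) flows from one
seeded generator: a fixed seed reproduces the training trajectory exactly
on the same platform.

The numerical core is a small reverse-mode autodiff engine over NumPy
float64 arrays (`powerdta._autograd`) providing exactly the primitives the
architecture needs, each verified against central finite differences in
the test suite.

## Metrics

- **MSE** — mean squared error.
- **CI** — over ordered pairs with yᵢ > yⱼ, score 1 if pᵢ > pⱼ, 0.5 on a
  prediction tie, 0 otherwise, divided by the number of such pairs.
  Pairs with tied labels are excluded, following the summation bound of
  the definition; implementations in the wild differ on this point, so
  the policy is stated here and pinned by tests against an O(n²)
  enumerator.
- **rm²** — r²·(1 − (r² − r₀²)) by default, where r² is the squared
  Pearson correlation and r₀² the squared correlation through the origin
  in Roy's external-validation form (observed-vs-predicted orientation:
  k = Σyp/Σp², r₀² = 1 − Σ(y − kp)²/Σ(y − ȳ)²). The classical variant
  with a square root on the difference is available via
  `sqrt_variant=True`; both are tested against explicit least-squares
  oracles. A negative difference r² − r₀² is clamped at zero and flagged
  in the report.
- **Pearson** — cov(p, y)/(σ(p)σ(y)) with population conventions (the
  ratio is convention-independent).

## Split protocols

Random: a seeded shuffle into six near-equal folds, fold 0 (⌊N/6⌋ or
⌈N/6⌉ records) as test, the rest as training. Cold-start: hold out a
fraction (default 1/6, mirroring the random protocol) of distinct drugs,
proteins, or both; in the pair-cold protocol records with exactly one
held-out entity are dropped, because any assignment of such a record
would leak an entity into one side or the other. Entity identity is the
exact string with SMILES canonicalized first, so alternative spellings of
one molecule cannot straddle a split. Splits are computed on a canonical
content ordering of the records, making them independent of input row
order, and every plan is checkable by a separate audit routine that tests
run against 50 random datasets per protocol.

## Synthetic data

The generator emulates benchmark-style affinity tables. Drugs come from a
packaged, curated list of 384 valid drug-like SMILES (common drugs plus
scaffold–substituent combinations), extendable by counterion decoration;
proteins are i.i.d. uniform sequences over the canonical alphabet with a
5-residue motif spliced into a configurable fraction (default 0.5) of
them. Default conditions: 60 drugs × 80 proteins, 2000 sampled pairs,
noise sd 0.3. The label is an affine rescaling of

bias + w_arom·(aromatic atoms) + w_hetero·(heteroatoms) + w_motif·(motif present)

into a pKd-like 5–11 range, plus Gaussian noise added after rescaling, so
the planted deterministic part is exactly recomputable from the emitted
records (`deterministic_labels`). Default weights (0.1, 0.1, 1.5) make
both towers matter: the motif contributes roughly half the signal
variance and is detectable by a receptive-field-7 convolution stack,
while the molecular counts are linear functionals of the atom features.
Default protein lengths are 50–120 residues with the scaled-down
encoder's window at 128 — long enough for realistic convolution and
masking behavior, short enough for minutes-scale CPU training.

What the generator does **not** emulate: the skewed label distributions,
assay noise structure, and entity imbalance of real benchmarks
(Davis/Kiba-style), structural correlation between similar drugs, or
evolutionary structure in protein families. Passing tests therefore
demonstrate that the architecture, optimization and evaluation machinery
work and can recover a realistic-magnitude signal from data of this
shape — not that the model attains any particular accuracy on real
benchmark corpora.

## Configurations and problem sizes

Two base configurations ship: the reference configuration (embed 128,
conv channels 128, 8 heads, batch 512, lr 5e-4, dropout 0.2, max protein
length 1000) and `ModelConfig.desk()` (embed 64, hidden 64, protein
embedding 32, conv channels 24, 4 heads, max length 128, batch 32,
head 128→64), the package's own choice of a configuration that trains in
minutes on one CPU while preserving every architectural element. The
acceptance pipeline trains the desk configuration for 15 epochs on 1666
training pairs, which is past the point where held-out CI and Pearson
plateau on the default synthetic conditions.

## Known limitations

- No GPU path and no minibatch parallelism; the NumPy engine is intended
  for correctness and desk-scale experiments, not benchmark-scale runs
  (2000 epochs at batch 512 on the full Table-style configuration is out
  of its intended envelope).
- Bond features, 3D conformers and protein contact-map graphs are out of
  scope by design.
- Checkpoints embed the configuration but not the training data; split
  plans are serialized separately to keep experiments replayable.
- `rm2` requires ≥ 3 points and non-constant vectors; CI requires at
  least one strictly ordered label pair. Both raise informative errors
  otherwise rather than returning NaN.
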