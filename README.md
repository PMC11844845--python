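# powerdta

Drug–target affinity (DTA) regression from SMILES strings and amino-acid
sequences, for computational chemists and ML practitioners who want a
fully tested, CPU-friendly reference implementation of a power-graph /
attention DTA architecture — including its ablation switches, evaluation
metrics, cold-start split protocols, and a synthetic-data generator that
makes the whole pipeline exercisable without downloading any benchmark.

## The model

Given a drug *D* (a SMILES string) and a protein *T* (a sequence), the
model regresses a real-valued affinity (e.g. pKd = −log₁₀(Kd/10⁹) for Kd
in nM).

**Drug encoder (power-graph GCN).** RDKit converts the SMILES into a
heavy-atom graph with adjacency *M* and a 78-dimensional atom-feature
matrix *X* (atom symbol, degree, hydrogen count, implicit valence,
aromaticity). Three GCN blocks consume the 1-, 2- and 3-hop power graphs
of *M*: block *k* uses the normalized operator

&nbsp;&nbsp;&nbsp;&nbsp;Mₙ⁽ᵏ⁾ = D̃^(−1/2) (S_k + I) D̃^(−1/2),

where S_k is the k-hop support (indicator of "a walk of length k exists",
or the literal matrix power M^k in `walkcount` mode). Block 1 stacks 3
GCN layers Hᵢ = σ(Mₙ H_{i−1} W), block 2 stacks 2 layers on Mₙ⁽²⁾, block 3
uses 1 layer on Mₙ⁽³⁾; every layer is followed by a gated skip connection

&nbsp;&nbsp;&nbsp;&nbsp;Z = sigmoid(H_new U₁ᵀ + H_old U₂ᵀ + b),  H ← Z⊙H_new + (1−Z)⊙H_old.

Block outputs are concatenated per node, globally max-pooled over atoms,
and mapped by FC layers to a 128-d drug vector.

**Protein encoder (attention-pooled multi-scale CNN).** Residues are
integer-coded (A=1, C=2, D=3, E=4, …, Y=20, unknown=21, pad=0; max length
1000), embedded into 128-d vectors, and fed to three parallel stacks of
1, 2 and 3 kernel-3 convolutions (receptive fields 3, 5 and 7). Each
stack is pooled by **multi-head linear attention**: head *j* scores
position *i* as (W_j·hᵢ)/d_k, softmax-normalizes the scores over (unmasked)
positions, the per-position weights are summed over the heads, and the
output is the weighted sum o = Σᵢ aᵢ hᵢ. The three pooled vectors are
concatenated and linearly mapped to a 128-d protein vector.

**Head and training.** The two vectors are concatenated and passed through
FC layers (1024 → 512 → 1, ReLU, dropout 0.2) to the affinity. Training
minimizes MSE with Adam (learning rate 5 × 10⁻⁴).

**Metrics.** MSE, concordance index (CI; ordered label pairs scored 1/0.5/0,
label ties excluded), rm² = r²·(1 − (r² − r₀²)) with r₀² the squared
correlation through the origin (a √ variant is available), and Pearson r.

All ablation switches are first-class configuration: `pool ∈ {mhla, max,
mean}`, `use_gate`, `powers ⊆ {1,2,3}`, `power_mode ∈ {binary, walkcount}`.

## Worked example

Generate a synthetic affinity table (600 drug–protein pairs with a planted
signal: aromatic-atom and heteroatom counts on the drug side, a 5-residue
sequence motif on the protein side, plus Gaussian noise), split it
5/6–1/6, train the scaled-down configuration for 10 epochs, and evaluate:

```bash
powerdta synth --out table.csv --n-drugs 30 --n-proteins 40 --n-pairs 600 --seed 42
powerdta split --table table.csv --out plan.json --mode random --seed 42
powerdta train --table table.csv --split plan.json --out model.npz --log log.csv \
               --epochs 10 --seed 42
powerdta eval  --table table.csv --split plan.json --checkpoint model.npz \
               --out metrics.json
```

This takes about half a minute and prints (in `metrics.json`):

```json
{
  "mse": 0.42169457745240524,
  "ci": 0.8925252525252525,
  "rm2": 0.8747791554063005,
  "pearson": 0.9406576844799852,
  "n": 100,
  "rm2_clamped": false
}
```

The 100 held-out pairs are predicted with CI ≈ 0.89 and Pearson ≈ 0.94:
the model has recovered most of the planted signal after 10 epochs, while
the residual MSE ≈ 0.42 reflects the injected noise plus what 10 epochs
leave unlearned. The training log (`log.csv`) starts at the untrained
model's MSE (≈ 3.34 here, the label variance) and decreases from there.
Cold-start splits (`--mode drug_cold | target_cold | pair_cold`) and the
ablation flags (`--pool max`, `--no-gate`, `--powers 1`) work the same way.

The same pipeline is available as a library:

```python
import powerdta as pk

records = pk.gen_affinity_table(pk.SyntheticSpec(seed=42))
plan = pk.random_split(records, seed=42)
model, log = pk.train_model(records, plan, pk.ModelConfig.desk(seed=42))
```

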