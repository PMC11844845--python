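"""The affinity model: gated power-graph drug encoder, multi-scale CNN +
multi-head linear attention protein encoder, and a fused FC regression head.

Architecture
------------
Drug side (power-graph GCN): the molecular graph is encoded by three GCN
blocks, one per normalized power operator.  Block 1 stacks 3 GCN layers on
the 1-hop operator, block 2 stacks 2 layers on the 2-hop operator, block 3
uses a single layer on the 3-hop operator.  Each layer computes
sigma(M_n H W) with sigma = ReLU, followed (when enabled) by a gated skip
connection Z = sigmoid(H_new U1^T + H_old U2^T + b),
H <- Z*H_new + (1-Z)*H_old.  Within a block the width is constant: atom
features are projected once to ``hidden_dim`` so the elementwise gate is
well-defined.  Per-node block outputs are concatenated, globally
max-pooled over atoms, and passed through FC layers to an
``embed_dim``-vector.

Protein side (attention-pooled multi-scale CNN): residue tokens are
embedded (128-d by default) and fed to three parallel stacks of 1, 2 and 3
kernel-3 "same" convolutions, giving receptive fields 3, 5 and 7.  Each
stack's output is pooled by multi-head linear attention — per head j a
scalar score (W_j h_i)/d_k per position, softmax-normalized over unmasked
positions; the per-position head weights are summed across heads and used
to weight a global sum of position states — then the three pooled vectors
are concatenated and mapped by a linear layer to ``embed_dim``.
Convolution outputs at padded positions are zeroed after every layer so
the pad mask stays meaningful.  Max- or mean-pooling can replace the
attention as an ablation, as can disabling the gate or dropping powers.

Training minimizes MSE with Adam; labels are standardized internally
(mean/sd of the training labels) and predictions are mapped back, so all
logged losses are in label units.  Dropout is applied in the fully
connected stacks only, in train mode only.  Everything is seeded: the same
seed reproduces the same trajectory on the same platform.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import _autograd as ag
from ._autograd import Tensor
from .chemgraph import MolecularGraph, PowerGraphSet, build_power_set, smiles_to_graph
from .metrics import concordance_index, mse as mse_metric
from .seqencode import EncodedProtein, encode_protein
from .splits import AffinityRecord, SplitPlan

N_TOKENS = 22  # pad + 20 canonical + unknown


class TrainingDivergedError(RuntimeError):
    def __init__(self, epoch: int):
        self.epoch = epoch
        super().__init__(f"training diverged (non-finite loss) at epoch {epoch}")


@dataclass
class ModelConfig:
    """Hyperparameters.  Defaults follow the reference configuration
    (lr 5e-4, batch 512, dropout 0.2, 8 heads, 128-d embeddings, GCN blocks
    of 3/2/1 layers, CNN stacks of 1/2/3 kernel-3 layers); ``desk()`` gives
    a scaled-down configuration that trains in minutes on one CPU."""

    embed_dim: int = 128
    hidden_dim: int = 64
    protein_embed_dim: int = 128
    conv_channels: int = 128
    n_heads: int = 8
    gcn_layers_per_block: tuple = (3, 2, 1)
    cnn_stacks_per_block: tuple = (1, 2, 3)
    kernel_size: int = 3
    max_len: int = 1000
    dropout: float = 0.2
    learning_rate: float = 5e-4
    batch_size: int = 512
    epochs: int = 2000
    seed: int = 0
    power_mode: str = "binary"
    pool: str = "mhla"  # mhla | max | mean
    use_gate: bool = True
    powers: tuple = (1, 2, 3)
    head_dims: tuple = (1024, 512)

    def __post_init__(self):
        self.powers = tuple(sorted(self.powers))
        if not self.powers or any(k not in (1, 2, 3) for k in self.powers):
            raise ValueError("powers must be a non-empty subset of {1, 2, 3}")
        if self.pool not in ("mhla", "max", "mean"):
            raise ValueError(f"unknown pool {self.pool!r}")
        if self.power_mode not in ("binary", "walkcount"):
            raise ValueError(f"unknown power_mode {self.power_mode!r}")
        for name in ("embed_dim", "hidden_dim", "protein_embed_dim", "conv_channels",
                     "n_heads", "max_len", "batch_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")

    @property
    def use_mhla(self) -> bool:
        return self.pool == "mhla"

    @classmethod
    def desk(cls, **overrides) -> "ModelConfig":
        """Scaled-down configuration for CPU-scale experiments."""
        base = dict(
            embed_dim=64, hidden_dim=64, protein_embed_dim=32, conv_channels=24,
            n_heads=4, max_len=128, batch_size=32, epochs=150, head_dims=(128, 64),
        )
        base.update(overrides)
        return cls(**base)


@dataclass
class GateParams:
    """Gated skip-connection parameters: Z = sigmoid(h_new U1^T + h_old U2^T + b)."""

    U1: np.ndarray
    U2: np.ndarray
    b: np.ndarray


@dataclass
class MhlaParams:
    """Multi-head linear attention parameters: one 1xd score map per head."""

    head_weights: list
    n_heads: int
    d_k: float


# ---------------------------------------------------------------------------
# Functional forms (forward-only, NumPy) of the core operations.
# ---------------------------------------------------------------------------

def gcn_layer(node_states: np.ndarray, normalized_op: np.ndarray,
              weights: np.ndarray) -> np.ndarray:
    """One graph convolution: ReLU(M_n H W)."""
    H = np.asarray(node_states, dtype=np.float64)
    M = np.asarray(normalized_op, dtype=np.float64)
    W = np.asarray(weights, dtype=np.float64)
    if M.shape[-1] != H.shape[-2] or H.shape[-1] != W.shape[0]:
        raise ValueError(
            f"shape mismatch: op {M.shape}, states {H.shape}, weights {W.shape}")
    if not np.allclose(M, np.swapaxes(M, -1, -2), atol=1e-9):
        raise ValueError("normalized_op must be symmetric")
    return np.maximum(M @ H @ W, 0.0)


def gated_skip(h_new: np.ndarray, h_old: np.ndarray, gate: GateParams) -> np.ndarray:
    """Elementwise sigmoid-gated convex combination of new and old states."""
    h_new = np.asarray(h_new, dtype=np.float64)
    h_old = np.asarray(h_old, dtype=np.float64)
    if h_new.shape != h_old.shape:
        raise ValueError(f"shape mismatch: {h_new.shape} vs {h_old.shape}")
    z = 1.0 / (1.0 + np.exp(-(h_new @ gate.U1.T + h_old @ gate.U2.T + gate.b)))
    return z * h_new + (1.0 - z) * h_old


def linear_attention_weights(head_weight: np.ndarray, states: np.ndarray,
                             mask: np.ndarray, d_k: float | None = None) -> np.ndarray:
    """Softmax-normalized per-position scores for one attention head.

    Scores are (head_weight . h_i)/d_k over unmasked positions, normalized
    with the max-subtraction stabilization; masked positions get exactly
    zero weight.
    """
    w = np.asarray(head_weight, dtype=np.float64).ravel()
    H = np.asarray(states, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("attention over an all-masked input")
    if d_k is None:
        d_k = float(np.sqrt(H.shape[-1]))
    s = (H @ w) / d_k
    s = np.where(mask, s, -np.inf)
    e = np.where(mask, np.exp(s - s.max()), 0.0)
    return e / e.sum()


def mhla_pool(states: np.ndarray, mask: np.ndarray, params: MhlaParams) -> np.ndarray:
    """Multi-head linear attention pooling: o = sum_i (sum_j w_ij) h_i."""
    H = np.asarray(states, dtype=np.float64)
    a = np.zeros(H.shape[0])
    for w in params.head_weights:
        a += linear_attention_weights(w, H, mask, d_k=params.d_k)
    return a @ H


# ---------------------------------------------------------------------------
# The trainable model.
# ---------------------------------------------------------------------------

class AffinityModel:
    """Trainable drug-target affinity regressor (see module docstring)."""

    def __init__(self, config: ModelConfig):
        self.config = config
        self.label_mean = 0.0
        self.label_std = 1.0
        self.params: dict[str, Tensor] = {}
        self._init_params(np.random.default_rng(config.seed))
        self._graph_cache: dict[str, tuple[MolecularGraph, PowerGraphSet]] = {}
        self._protein_cache: dict[str, EncodedProtein] = {}

    # -- parameters --

    def _add(self, name: str, array: np.ndarray) -> None:
        self.params[name] = Tensor(array)

    def _init_params(self, rng: np.random.Generator) -> None:
        c = self.config

        def he(fan_in, shape):
            return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)

        # drug encoder
        h = c.hidden_dim
        for k in c.powers:
            self._add(f"drug.p{k}.proj.W", he(78, (78, h)))
            self._add(f"drug.p{k}.proj.b", np.zeros(h))
            n_layers = c.gcn_layers_per_block[k - 1]
            for l in range(n_layers):
                self._add(f"drug.p{k}.layer{l}.W", he(h, (h, h)))
                self._add(f"drug.p{k}.layer{l}.b", np.zeros(h))
                if c.use_gate:
                    self._add(f"drug.p{k}.layer{l}.U1T", he(h, (h, h)))
                    self._add(f"drug.p{k}.layer{l}.U2T", he(h, (h, h)))
                    self._add(f"drug.p{k}.layer{l}.gb", np.zeros(h))
        cat = len(c.powers) * h
        self._add("drug.fc1.W", he(cat, (cat, 2 * c.embed_dim)))
        self._add("drug.fc1.b", np.zeros(2 * c.embed_dim))
        self._add("drug.fc2.W", he(2 * c.embed_dim, (2 * c.embed_dim, c.embed_dim)))
        self._add("drug.fc2.b", np.zeros(c.embed_dim))

        # protein encoder
        pe, cc, K = c.protein_embed_dim, c.conv_channels, c.kernel_size
        self._add("prot.embed", rng.normal(0.0, 0.1, size=(N_TOKENS, pe)))
        for bi, depth in enumerate(c.cnn_stacks_per_block, start=1):
            cin = pe
            for j in range(depth):
                self._add(f"prot.b{bi}.conv{j}.W", he(K * cin, (K * cin, cc)))
                self._add(f"prot.b{bi}.conv{j}.b", np.zeros(cc))
                cin = cc
            if c.pool == "mhla":
                self._add(f"prot.b{bi}.attn.W", rng.normal(0.0, 1.0 / np.sqrt(cc),
                                                           size=(cc, c.n_heads)))
        self._add("prot.out.W", he(3 * cc, (3 * cc, c.embed_dim)))
        self._add("prot.out.b", np.zeros(c.embed_dim))

        # fusion head
        dims = (2 * c.embed_dim, *c.head_dims, 1)
        for i in range(len(dims) - 1):
            self._add(f"head.fc{i + 1}.W", he(dims[i], (dims[i], dims[i + 1])))
            self._add(f"head.fc{i + 1}.b", np.zeros(dims[i + 1]))

    # -- caches --

    def _graph(self, smiles: str) -> tuple[MolecularGraph, PowerGraphSet]:
        if smiles not in self._graph_cache:
            g = smiles_to_graph(smiles)
            self._graph_cache[smiles] = (g, build_power_set(g, self.config.power_mode))
        return self._graph_cache[smiles]

    def _protein(self, seq: str) -> EncodedProtein:
        if seq not in self._protein_cache:
            self._protein_cache[seq] = encode_protein(seq, max_len=self.config.max_len)
        return self._protein_cache[seq]

    # -- forward pieces --

    def _dropout(self, x: Tensor, train: bool, rng) -> Tensor:
        p = self.config.dropout
        if not train or p == 0.0:
            return x
        keep = (rng.random(x.shape) >= p) / (1.0 - p)
        return x * keep

    def _drug_forward(self, X: Tensor, ops: dict[int, Tensor],
                      node_mask: np.ndarray, train: bool, rng) -> Tensor:
        c = self.config
        p = self.params
        blocks = []
        for k in c.powers:
            M = ops[k]
            H = X @ p[f"drug.p{k}.proj.W"] + p[f"drug.p{k}.proj.b"]
            for l in range(c.gcn_layers_per_block[k - 1]):
                Hn = ag.relu(M @ (H @ p[f"drug.p{k}.layer{l}.W"]) + p[f"drug.p{k}.layer{l}.b"])
                if c.use_gate:
                    Z = ag.sigmoid(Hn @ p[f"drug.p{k}.layer{l}.U1T"]
                                   + H @ p[f"drug.p{k}.layer{l}.U2T"]
                                   + p[f"drug.p{k}.layer{l}.gb"])
                    H = Z * Hn + (1.0 - Z) * H
                else:
                    H = Hn
            blocks.append(H)
        He = blocks[0] if len(blocks) == 1 else ag.concat(blocks, axis=-1)
        pooled = ag.masked_max(He, node_mask[:, :, None], axis=1)
        hid = self._dropout(ag.relu(pooled @ p["drug.fc1.W"] + p["drug.fc1.b"]), train, rng)
        return hid @ p["drug.fc2.W"] + p["drug.fc2.b"]

    def _protein_forward(self, tokens: np.ndarray, mask: np.ndarray,
                         train: bool, rng) -> Tensor:
        c = self.config
        p = self.params
        maskf = mask.astype(np.float64)[:, :, None]
        E = ag.embedding(p["prot.embed"], tokens) * maskf
        pooled = []
        for bi, depth in enumerate(c.cnn_stacks_per_block, start=1):
            h = E
            for j in range(depth):
                h = ag.relu(ag.conv1d_same(h, p[f"prot.b{bi}.conv{j}.W"],
                                           p[f"prot.b{bi}.conv{j}.b"], c.kernel_size))
                h = h * maskf  # keep padded positions at exactly zero
            if c.pool == "mhla":
                d_k = np.sqrt(c.conv_channels)
                scores = (h @ p[f"prot.b{bi}.attn.W"]) / d_k
                w = ag.masked_softmax(scores, mask[:, :, None], axis=1)
                a = w.sum(axis=2)  # (B, L): summed head weights per position
                pooled.append((a.reshape(*a.shape, 1) * h).sum(axis=1))
            elif c.pool == "max":
                pooled.append(ag.masked_max(h, mask[:, :, None], axis=1))
            else:
                pooled.append(ag.masked_mean(h, mask[:, :, None], axis=1))
        cat = ag.concat(pooled, axis=-1)
        return cat @ p["prot.out.W"] + p["prot.out.b"]

    def _head_forward(self, drug_vec: Tensor, prot_vec: Tensor,
                      train: bool, rng) -> Tensor:
        p = self.params
        z = ag.concat([drug_vec, prot_vec], axis=-1)
        n_hidden = len(self.config.head_dims)
        for i in range(1, n_hidden + 1):
            z = self._dropout(ag.relu(z @ p[f"head.fc{i}.W"] + p[f"head.fc{i}.b"]),
                              train, rng)
        z = z @ p[f"head.fc{n_hidden + 1}.W"] + p[f"head.fc{n_hidden + 1}.b"]
        return z.reshape(z.shape[0])

    # -- batching --

    def _make_batch(self, records: list[AffinityRecord]):
        c = self.config
        graphs = [self._graph(r.drug_smiles) for r in records]
        prots = [self._protein(r.protein_seq) for r in records]
        B = len(records)
        n_max = max(g.n_atoms for g, _ in graphs)
        X = np.zeros((B, n_max, 78))
        node_mask = np.zeros((B, n_max), dtype=bool)
        ops = {k: np.zeros((B, n_max, n_max)) for k in c.powers}
        for b, (g, ps) in enumerate(graphs):
            n = g.n_atoms
            X[b, :n] = g.atom_features
            node_mask[b, :n] = True
            for k in c.powers:
                ops[k][b, :n, :n] = ps.normalized_ops[k - 1]
        L = max(min(p.original_length, c.max_len) for p in prots)
        tokens = np.stack([p.tokens[:L] for p in prots])
        pmask = np.stack([p.mask[:L] for p in prots])
        return (Tensor(X), {k: Tensor(v) for k, v in ops.items()}, node_mask,
                tokens, pmask)

    def _forward_batch(self, records, train=False, rng=None) -> Tensor:
        X, ops, node_mask, tokens, pmask = self._make_batch(records)
        dvec = self._drug_forward(X, ops, node_mask, train, rng)
        pvec = self._protein_forward(tokens, pmask, train, rng)
        return self._head_forward(dvec, pvec, train, rng)

    # -- public inference --

    def predict(self, records: list[AffinityRecord],
                batch_size: int | None = None) -> np.ndarray:
        """Predictions in label units (eval mode, deterministic)."""
        bs = batch_size or self.config.batch_size
        out = []
        for i in range(0, len(records), bs):
            pred = self._forward_batch(records[i : i + bs], train=False)
            out.append(pred.data * self.label_std + self.label_mean)
        return np.concatenate(out)

    # -- persistence --

    def save(self, path: str | Path) -> None:
        arrays = {k.replace(".", "__"): t.data for k, t in self.params.items()}
        meta = json.dumps({
            "config": asdict(self.config),
            "label_mean": self.label_mean,
            "label_std": self.label_std,
        })
        np.savez(path, __meta__=np.array(meta), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "AffinityModel":
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["__meta__"]))
            cfg = meta["config"]
            for key in ("gcn_layers_per_block", "cnn_stacks_per_block", "powers", "head_dims"):
                cfg[key] = tuple(cfg[key])
            model = cls(ModelConfig(**cfg))
            model.label_mean = meta["label_mean"]
            model.label_std = meta["label_std"]
            for k in model.params:
                model.params[k] = Tensor(z[k.replace(".", "__")])
        return model

    def state_copy(self) -> dict[str, np.ndarray]:
        return {k: t.data.copy() for k, t in self.params.items()}

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k] = Tensor(state[k].copy())


# ---------------------------------------------------------------------------
# Spec-surface encoders over a model instance.
# ---------------------------------------------------------------------------

def pmgcn_encode(graph: MolecularGraph, powers: PowerGraphSet,
                 model: AffinityModel) -> np.ndarray:
    """Fixed-length drug vector (length embed_dim) for one molecule."""
    c = model.config
    n = graph.n_atoms
    X = Tensor(graph.atom_features[None])
    ops = {k: Tensor(powers.normalized_ops[k - 1][None]) for k in c.powers}
    mask = np.ones((1, n), dtype=bool)
    return model._drug_forward(X, ops, mask, train=False, rng=None).data[0]


def amcnn_encode(protein: EncodedProtein, model: AffinityModel) -> np.ndarray:
    """Fixed-length protein vector (length embed_dim) for one sequence."""
    tokens = protein.tokens[None]
    mask = protein.mask[None]
    return model._protein_forward(tokens, mask, train=False, rng=None).data[0]


def predict_affinity(drug_vec: np.ndarray, protein_vec: np.ndarray,
                     model: AffinityModel) -> float:
    """Scalar affinity (label units) from a drug and a protein vector."""
    e = model.config.embed_dim
    if drug_vec.shape[-1] != e or protein_vec.shape[-1] != e:
        raise ValueError(f"expected vectors of length {e}")
    d = Tensor(np.atleast_2d(drug_vec))
    p = Tensor(np.atleast_2d(protein_vec))
    out = model._head_forward(d, p, train=False, rng=None).data
    return float(out[0] * model.label_std + model.label_mean)


# ---------------------------------------------------------------------------
# Training.
# ---------------------------------------------------------------------------

def train_model(
    table: list[AffinityRecord],
    split: SplitPlan | None = None,
    config: ModelConfig | None = None,
    log_path: str | Path | None = None,
) -> tuple[AffinityModel, list[dict]]:
    """Train by Adam on MSE; returns the model and a per-epoch log.

    With a split, `train_indices` are fitted and `test_indices` serve as a
    validation set; the returned parameters are the checkpoint with the
    lowest validation MSE.  Without a split the whole table is fitted and
    the final epoch is returned.  The log's epoch-0 entry is the untrained
    model evaluated on the training set.
    """
    config = config or ModelConfig()
    if split is not None:
        train_recs = [table[i] for i in split.train_indices]
        val_recs = [table[i] for i in split.test_indices]
    else:
        train_recs, val_recs = list(table), []
    if not train_recs:
        raise ValueError("empty training split")

    model = AffinityModel(config)
    labels = np.array([r.label for r in train_recs])
    model.label_mean = float(labels.mean())
    model.label_std = float(labels.std()) or 1.0
    y_norm = (labels - model.label_mean) / model.label_std

    opt = ag.Adam(model.params, lr=config.learning_rate)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))

    def eval_mse(recs, ys) -> float:
        return mse_metric(ys, model.predict(recs))

    def val_entry() -> dict:
        if not val_recs:
            return {}
        yv = np.array([r.label for r in val_recs])
        pv = model.predict(val_recs)
        entry = {"val_mse": mse_metric(yv, pv)}
        try:
            entry["val_ci"] = concordance_index(yv, pv)
        except ValueError:
            entry["val_ci"] = float("nan")
        return entry

    log: list[dict] = []
    log.append({"epoch": 0, "train_mse": eval_mse(train_recs, labels), **val_entry()})
    best_state = model.state_copy()
    best_val = log[0].get("val_mse", np.inf)

    n = len(train_recs)
    var_scale = model.label_std**2
    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(n)
        batch_losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            recs = [train_recs[i] for i in idx]
            pred = model._forward_batch(recs, train=True, rng=rng)
            err = pred - y_norm[idx]
            loss = (err * err).mean()
            if not np.isfinite(loss.data):
                raise TrainingDivergedError(epoch)
            opt.zero_grad()
            loss.backward()
            opt.step()
            batch_losses.append(float(loss.data) * var_scale)
        entry = {"epoch": epoch, "train_mse": float(np.mean(batch_losses)), **val_entry()}
        log.append(entry)
        if val_recs and entry["val_mse"] < best_val:
            best_val = entry["val_mse"]
            best_state = model.state_copy()

    if val_recs:
        model.load_state(best_state)
    if log_path is not None:
        import pandas as pd

        pd.DataFrame(log).to_csv(log_path, index=False)
    return model, log
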