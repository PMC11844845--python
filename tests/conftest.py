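"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

import powerdta as pk


# ---------------------------------------------------------------------------
# Independent oracles (brute force / loop implementations).
# ---------------------------------------------------------------------------

def count_walks(adj: np.ndarray, start: int, end: int, length: int) -> int:
    """Count walks of exactly `length` edges from start to end by recursion."""
    if length == 0:
        return 1 if start == end else 0
    total = 0
    for nxt in range(adj.shape[0]):
        if adj[start, nxt] > 0:
            total += count_walks(adj, nxt, end, length - 1)
    return total


def ci_loop(y, p) -> float:
    """O(n^2) loop concordance index; label ties excluded, prediction ties 0.5."""
    num = 0.0
    z = 0
    n = len(y)
    for i in range(n):
        for j in range(n):
            if y[i] > y[j]:
                z += 1
                if p[i] > p[j]:
                    num += 1.0
                elif p[i] == p[j]:
                    num += 0.5
    return num / z


def pearson_loop(y, p) -> float:
    n = len(y)
    my = sum(y) / n
    mp = sum(p) / n
    cov = sum((yi - my) * (pi - mp) for yi, pi in zip(y, p)) / n
    sy = (sum((yi - my) ** 2 for yi in y) / n) ** 0.5
    sp = (sum((pi - mp) ** 2 for pi in p) / n) ** 0.5
    return cov / (sy * sp)


def rm2_loop(y, p, sqrt_variant=False) -> float:
    """rm2 via explicit least squares with and without intercept."""
    y = np.asarray(y, float)
    p = np.asarray(p, float)
    r2 = pearson_loop(list(y), list(p)) ** 2
    k = float(np.linalg.lstsq(p[:, None], y, rcond=None)[0][0])  # through origin
    r02 = 1.0 - np.sum((y - k * p) ** 2) / np.sum((y - y.mean()) ** 2)
    diff = max(r2 - r02, 0.0)
    return r2 * (1.0 - np.sqrt(diff)) if sqrt_variant else r2 * (1.0 - diff)


def mhla_loop(states, mask, head_weights, d_k) -> np.ndarray:
    """Literal loop implementation of multi-head linear attention pooling."""
    m, d = states.shape
    a = np.zeros(m)
    for w in head_weights:
        scores = [float(np.dot(w, states[i])) / d_k for i in range(m)]
        exps = [np.exp(s) if mask[i] else 0.0 for i, s in enumerate(scores)]
        tot = sum(exps)
        for i in range(m):
            a[i] += exps[i] / tot
    out = np.zeros(d)
    for i in range(m):
        out += a[i] * states[i]
    return out


def random_simple_graph(rng: np.random.Generator, n_max: int = 6) -> np.ndarray:
    """Random symmetric zero-diagonal binary adjacency on 1..n_max nodes."""
    n = int(rng.integers(1, n_max + 1))
    a = (rng.random((n, n)) < rng.uniform(0.2, 0.8)).astype(float)
    a = np.triu(a, 1)
    return a + a.T


def _np_relu(x):
    return np.maximum(x, 0.0)


def reference_drug_encoder(graph, powerset, model) -> np.ndarray:
    """Plain NumPy re-implementation of the drug encoder (no autodiff path).

    Handles any powers subset and the gate switch, so it doubles as the
    simpler reference for the ablation configurations (single power, no
    gate reduces to a plain stacked GCN encoder).
    """
    c = model.config
    p = {k: t.data for k, t in model.params.items()}
    blocks = []
    for k in c.powers:
        M = powerset.normalized_ops[k - 1]
        H = graph.atom_features @ p[f"drug.p{k}.proj.W"] + p[f"drug.p{k}.proj.b"]
        for l in range(c.gcn_layers_per_block[k - 1]):
            Hn = _np_relu(M @ H @ p[f"drug.p{k}.layer{l}.W"] + p[f"drug.p{k}.layer{l}.b"])
            if c.use_gate:
                z = 1.0 / (1.0 + np.exp(-(Hn @ p[f"drug.p{k}.layer{l}.U1T"]
                                          + H @ p[f"drug.p{k}.layer{l}.U2T"]
                                          + p[f"drug.p{k}.layer{l}.gb"])))
                H = z * Hn + (1.0 - z) * H
            else:
                H = Hn
        blocks.append(H)
    He = np.concatenate(blocks, axis=-1)
    pooled = He.max(axis=0)
    hid = _np_relu(pooled @ p["drug.fc1.W"] + p["drug.fc1.b"])
    return hid @ p["drug.fc2.W"] + p["drug.fc2.b"]


def reference_protein_encoder(protein, model, pool: str) -> np.ndarray:
    """Loop-style NumPy protein encoder with max/mean/mhla pooling."""
    c = model.config
    p = {k: t.data for k, t in model.params.items()}
    mask = protein.mask
    L = len(mask)
    E = p["prot.embed"][protein.tokens] * mask[:, None]
    pooled = []
    for bi, depth in enumerate(c.cnn_stacks_per_block, start=1):
        h = E
        for j in range(depth):
            W = p[f"prot.b{bi}.conv{j}.W"]
            b = p[f"prot.b{bi}.conv{j}.b"]
            cin = h.shape[1]
            hp = np.vstack([np.zeros((1, cin)), h, np.zeros((1, cin))])
            out = np.empty((L, W.shape[1]))
            for t in range(L):
                window = np.concatenate([hp[t], hp[t + 1], hp[t + 2]])
                out[t] = window @ W + b
            h = _np_relu(out) * mask[:, None]
        valid = h[mask]
        if pool == "max":
            pooled.append(valid.max(axis=0))
        elif pool == "mean":
            pooled.append(valid.mean(axis=0))
        else:
            d_k = np.sqrt(c.conv_channels)
            heads = [p[f"prot.b{bi}.attn.W"][:, j] for j in range(c.n_heads)]
            pooled.append(mhla_loop(h, mask, heads, d_k))
    cat = np.concatenate(pooled)
    return cat @ p["prot.out.W"] + p["prot.out.b"]


def permute_graph(graph, perm: np.ndarray):
    """Relabel atoms by `perm` (features rows and adjacency consistently)."""
    P = np.eye(len(perm))[perm]
    return pk.MolecularGraph(
        smiles=graph.smiles,
        atom_features=graph.atom_features[perm],
        adjacency=P @ graph.adjacency @ P.T,
    )


# ---------------------------------------------------------------------------
# Fixtures.
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def tiny_config() -> pk.ModelConfig:
    """A very small but structurally complete configuration."""
    return pk.ModelConfig.desk(
        embed_dim=16, hidden_dim=12, protein_embed_dim=8, conv_channels=10,
        n_heads=3, max_len=64, head_dims=(24, 12), seed=11,
    )


@pytest.fixture(scope="session")
def tiny_model(tiny_config) -> pk.AffinityModel:
    return pk.AffinityModel(tiny_config)


@pytest.fixture(scope="session")
def sample_smiles() -> list[str]:
    from powerdta.synth import fixture_smiles

    return fixture_smiles()


@pytest.fixture(scope="session")
def small_table() -> list[pk.AffinityRecord]:
    spec = pk.SyntheticSpec(n_drugs=10, n_proteins=12, n_pairs=48,
                            length_range=(30, 60), seed=5)
    return pk.gen_affinity_table(spec)
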