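"""Drug molecular graphs and normalized power-graph operators.

A drug SMILES is converted (via RDKit) into a heavy-atom molecular graph:
a 78-dimensional per-atom feature matrix and a binary symmetric adjacency
matrix.  The drug encoder consumes the graph through three "power graph"
operators — the 1-, 2- and 3-hop connectivity structures, each
degree-normalized as D̃^(−1/2) (S + I) D̃^(−1/2) — so message passing can
mix information from progressively wider neighborhoods.  Walks longer than
3 hops add little reachability on small molecules and are excluded.

Power semantics: ``mode="binary"`` (default) builds the indicator of
k-walk reachability with a zeroed diagonal, reading "power graph" as a
connectivity structure; ``mode="walkcount"`` keeps the literal k-th matrix
power, whose entries count walks (and whose diagonal is nonzero for k=2).
Both are supported throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

POWERS = (1, 2, 3)
N_ATOM_FEATURES = 78

# 44-symbol table (last entry is the wildcard bucket), then one-hot degree
# 0-10, one-hot total hydrogens 0-10, one-hot implicit valence 0-10, and a
# single aromaticity flag: 44 + 11 + 11 + 11 + 1 = 78.
ATOM_SYMBOLS = [
    "C", "N", "O", "S", "F", "Si", "P", "Cl", "Br", "Mg", "Na", "Ca", "Fe",
    "As", "Al", "I", "B", "V", "K", "Tl", "Yb", "Sb", "Sn", "Ag", "Pd", "Co",
    "Se", "Ti", "Zn", "H", "Li", "Ge", "Cu", "Au", "Ni", "Cd", "In", "Mn",
    "Zr", "Cr", "Pt", "Hg", "Pb", "*",
]


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed into a molecule."""

    def __init__(self, smiles: str, reason: str = "not parsable"):
        self.smiles = smiles
        super().__init__(f"invalid SMILES {smiles!r}: {reason}")


@dataclass
class MolecularGraph:
    """Heavy-atom graph of one drug molecule."""

    smiles: str
    atom_features: np.ndarray  # (n_atoms, 78)
    adjacency: np.ndarray  # (n_atoms, n_atoms), binary, zero diagonal

    @property
    def n_atoms(self) -> int:
        return self.adjacency.shape[0]


@dataclass
class PowerGraphSet:
    """The three normalized k-hop operators (k = 1, 2, 3) for one molecule."""

    normalized_ops: list = field(default_factory=list)
    power_mode: str = "binary"


def _one_hot(value, choices, clamp: bool = False) -> list[float]:
    if clamp:
        value = min(value, choices[-1])
    if value not in choices:
        value = choices[-1]
    return [1.0 if value == c else 0.0 for c in choices]


def atom_features(atom: Chem.Atom) -> np.ndarray:
    """78-dim feature row: symbol, degree, total Hs, implicit valence, aromatic."""
    feats = (
        _one_hot(atom.GetSymbol(), ATOM_SYMBOLS)
        + _one_hot(atom.GetDegree(), list(range(11)), clamp=True)
        + _one_hot(atom.GetTotalNumHs(), list(range(11)), clamp=True)
        + _one_hot(atom.GetImplicitValence(), list(range(11)), clamp=True)
        + [1.0 if atom.GetIsAromatic() else 0.0]
    )
    return np.asarray(feats, dtype=np.float64)


def smiles_to_graph(smiles: str) -> MolecularGraph:
    """Parse a SMILES string into a :class:`MolecularGraph`.

    Hydrogens stay implicit; disconnected SMILES (e.g. salts written with
    '.') keep all components.  Raises :class:`SmilesParseError` on
    unparsable input or a molecule with no heavy atoms.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(smiles)
    n = mol.GetNumAtoms()
    if n < 1:
        raise SmilesParseError(smiles, "molecule has zero atoms")
    x = np.stack([atom_features(a) for a in mol.GetAtoms()])
    adj = np.zeros((n, n), dtype=np.float64)
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        adj[i, j] = 1.0
        adj[j, i] = 1.0
    return MolecularGraph(smiles=smiles, atom_features=x, adjacency=adj)


def _check_adjacency(adj: np.ndarray) -> np.ndarray:
    adj = np.asarray(adj, dtype=np.float64)
    if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(adj, adj.T, atol=1e-12):
        raise ValueError("adjacency must be symmetric")
    return adj


def matrix_power_support(adjacency: np.ndarray, k: int, mode: str = "binary") -> np.ndarray:
    """k-hop support of a simple adjacency matrix, k in {1, 2, 3}.

    ``walkcount`` returns the literal k-th matrix power (entry (i, j) counts
    walks of length k).  ``binary`` returns the indicator of "a walk of
    length exactly k exists", with the diagonal forced to zero; self-loops
    are added later, uniformly, by :func:`normalize_adjacency`.
    """
    if k not in POWERS:
        raise ValueError(f"power k must be one of {POWERS}, got {k}")
    if mode not in ("binary", "walkcount"):
        raise ValueError(f"unknown power mode {mode!r}")
    adj = _check_adjacency(adjacency)
    if np.any(np.diag(adj) != 0):
        raise ValueError("adjacency diagonal must be zero")
    power = np.linalg.matrix_power(adj, k)
    if mode == "walkcount":
        return power
    support = (power > 0).astype(np.float64)
    np.fill_diagonal(support, 0.0)
    return support


def normalize_adjacency(support: np.ndarray) -> np.ndarray:
    """Symmetric degree normalization with self-loops.

    Computes D̃^(−1/2) (S + I) D̃^(−1/2) where D̃ is the degree matrix of
    the self-looped support; the result is symmetric with spectral radius
    at most 1.
    """
    support = np.asarray(support, dtype=np.float64)
    if support.ndim != 2 or support.shape[0] != support.shape[1]:
        raise ValueError("support must be square")
    if not np.allclose(support, support.T, atol=1e-9):
        raise ValueError("support must be symmetric")
    if np.any(support < 0):
        raise ValueError("support must be non-negative")
    a_tilde = support + np.eye(support.shape[0])
    d_inv_sqrt = 1.0 / np.sqrt(a_tilde.sum(axis=1))
    out = a_tilde * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]
    return 0.5 * (out + out.T)  # exact symmetry despite rounding


def build_power_set(graph: MolecularGraph, mode: str = "binary") -> PowerGraphSet:
    """Normalized operators for powers 1, 2, 3 of a molecule's adjacency."""
    ops = [
        normalize_adjacency(matrix_power_support(graph.adjacency, k, mode))
        for k in POWERS
    ]
    return PowerGraphSet(normalized_ops=ops, power_mode=mode)
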