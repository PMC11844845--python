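"""Synthetic drug-target affinity tables with a planted, auditable signal.

The generator emulates the three-column (SMILES, sequence, label) tables
used by affinity benchmarks, without any download: drugs are drawn from a
packaged list of curated valid drug-like SMILES, proteins are uniform
random sequences over the 20 canonical amino acids, and the label of a
pair is a deterministic signal plus Gaussian noise,

    raw = bias + w_arom * (aromatic atoms) + w_hetero * (heteroatoms)
               + w_motif * [motif in sequence],

with the deterministic part affinely rescaled into a pKd-like 5-11 range
before the noise is added.  The signal only uses features the two encoders
can plausibly extract — aromaticity and heteroatoms are visible in the
atom features, and a short motif is detectable by stacked kernel-3
convolutions — and it is exactly recomputable from the emitted records,
so tests can audit what was planted.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
from rdkit import Chem

from .chemgraph import smiles_to_graph
from .seqencode import CANONICAL
from .splits import AffinityRecord

LABEL_RANGE = (5.0, 11.0)
_COUNTERIONS = ("Cl", "Br", "O=C(O)C", "OS(=O)(=O)O")


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic table."""

    n_drugs: int = 60
    n_proteins: int = 80
    n_pairs: int = 2000
    noise_sd: float = 0.3
    w_arom: float = 0.1
    w_hetero: float = 0.1
    w_motif: float = 1.5
    bias: float = 0.0
    motif: str = "WHKWH"
    motif_fraction: float = 0.5
    length_range: tuple = (50, 120)
    seed: int = 0

    def __post_init__(self):
        if self.n_pairs > self.n_drugs * self.n_proteins:
            raise ValueError("n_pairs exceeds the drug x protein grid")
        if len(self.motif) > 10:
            raise ValueError("motif longer than 10 residues")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def fixture_smiles() -> list[str]:
    """The packaged list of curated valid drug-like SMILES."""
    text = resources.files("powerdta.data").joinpath("drug_smiles.txt").read_text()
    return [line for line in text.splitlines() if line.strip()]


def gen_drugs(n: int, seed: int = 0) -> list[str]:
    """Draw `n` distinct valid SMILES, decorating with counterion salts
    once the packaged fixture list is exhausted."""
    if n < 1:
        raise ValueError("n must be >= 1")
    base = fixture_smiles()
    pool = list(base)
    for ion in _COUNTERIONS:
        pool.extend(f"{s}.{ion}" for s in base)
    if n > len(pool):
        raise ValueError(f"cannot generate {n} distinct drugs (max {len(pool)})")
    rng = np.random.default_rng(seed)
    chosen = [pool[i] for i in rng.choice(len(pool), size=n, replace=False)]
    for s in chosen:
        smiles_to_graph(s)  # every emitted drug must parse
    return chosen


def gen_proteins(
    n: int,
    length_range: tuple = (50, 120),
    seed: int = 0,
    motif: str = "WHKWH",
    motif_fraction: float = 0.5,
) -> list[str]:
    """Uniform random sequences; a fraction carries the planted motif.

    The motif is spliced over a window at a random position, so lengths
    stay inside `length_range`.
    """
    lo, hi = length_range
    if not (20 <= lo <= hi <= 1500):
        raise ValueError(f"length_range must lie within [20, 1500], got {length_range}")
    if len(motif) > lo:
        raise ValueError("motif longer than the shortest sequence")
    rng = np.random.default_rng(seed)
    letters = np.array(list(CANONICAL))
    seqs = []
    n_motif = int(round(motif_fraction * n))
    with_motif = set(rng.choice(n, size=n_motif, replace=False).tolist()) if n_motif else set()
    for i in range(n):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(letters[rng.integers(0, 20, size=length)])
        if i in with_motif:
            pos = int(rng.integers(0, length - len(motif) + 1))
            seq = seq[:pos] + motif + seq[pos + len(motif):]
        seqs.append(seq)
    return seqs


def _mol_counts(smiles: str) -> tuple[int, int]:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES {smiles!r}")
    arom = sum(1 for a in mol.GetAtoms() if a.GetIsAromatic())
    hetero = sum(1 for a in mol.GetAtoms() if a.GetSymbol() not in ("C", "H"))
    return arom, hetero


def raw_signal(smiles: str, sequence: str, spec: SyntheticSpec) -> float:
    """The un-rescaled deterministic part of one pair's label."""
    arom, hetero = _mol_counts(smiles)
    return (
        spec.bias
        + spec.w_arom * arom
        + spec.w_hetero * hetero
        + spec.w_motif * (1.0 if spec.motif in sequence else 0.0)
    )


def _rescale(raws: np.ndarray) -> np.ndarray:
    lo, hi = LABEL_RANGE
    span = raws.max() - raws.min()
    if span == 0:
        return np.full_like(raws, 0.5 * (lo + hi))
    return lo + (hi - lo) * (raws - raws.min()) / span


def deterministic_labels(records: list[AffinityRecord], spec: SyntheticSpec) -> np.ndarray:
    """Recompute each record's noise-free label (the planted signal)."""
    raws = np.array([raw_signal(r.drug_smiles, r.protein_seq, spec) for r in records])
    return _rescale(raws)


def gen_affinity_table(spec: SyntheticSpec) -> list[AffinityRecord]:
    """Sample a synthetic affinity table under `spec`'s conditions."""
    rng = np.random.default_rng(spec.seed)
    drug_seed, prot_seed, pair_seed = (int(s) for s in rng.integers(2**31, size=3))
    drugs = gen_drugs(spec.n_drugs, seed=drug_seed)
    prots = gen_proteins(
        spec.n_proteins,
        length_range=spec.length_range,
        seed=prot_seed,
        motif=spec.motif,
        motif_fraction=spec.motif_fraction,
    )
    pair_rng = np.random.default_rng(pair_seed)
    cells = pair_rng.choice(spec.n_drugs * spec.n_proteins, size=spec.n_pairs, replace=False)
    pairs = [(int(c) // spec.n_proteins, int(c) % spec.n_proteins) for c in cells]
    raws = np.array([raw_signal(drugs[i], prots[j], spec) for i, j in pairs])
    det = _rescale(raws)
    noise = pair_rng.normal(0.0, spec.noise_sd, size=spec.n_pairs) if spec.noise_sd > 0 else 0.0
    labels = det + noise
    return [
        AffinityRecord(drugs[i], prots[j], float(lbl), "synthetic")
        for (i, j), lbl in zip(pairs, labels)
    ]
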